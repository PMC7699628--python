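"""Scaffold assembly, tailoring reactions and plan-space enumeration."""

import pytest

from bgcforge.chem import canonical_smiles, molecular_weight, parse_smiles
from bgcforge.predict import (AssemblyLine, Module, PathwayError,
                              ReactionApplicationError, apply_reaction,
                              assemble_scaffold, build_peptide,
                              derive_pathway, enumerate_products,
                              enumerate_sites, ripp_products)
from bgcforge.simulate import (FixtureConfig, sample_cluster_spec,
                               synthetic_bgc)
import numpy as np


from oracles import oracle_enumerate          # noqa: E402


def line(kb, monomer_ids, flags=None, release="linear"):
    flags = flags or [[] for _ in monomer_ids]
    return AssemblyLine(
        modules=[Module(monomer_choices=[m] if isinstance(m, str) else m,
                        flags=f)
                 for m, f in zip(monomer_ids, flags)],
        release=release)


class TestAssembly:
    def test_dipeptide_mass_balance(self, kb):
        (_, g), = assemble_scaffold(line(kb, ["Gly", "Ala"]), kb)
        # condensation loses one water: 75.07 + 89.09 - 18.02
        assert molecular_weight(g) == pytest.approx(146.14, abs=0.02)
        assert canonical_smiles(g) \
            == canonical_smiles("NCC(=O)NC(C)C(=O)O")

    def test_single_module_is_the_monomer(self, kb):
        (_, g), = assemble_scaffold(line(kb, ["Ser"]), kb)
        assert canonical_smiles(g) == canonical_smiles("NC(CO)C(=O)O")

    def test_choice_combinations_multiply(self, kb):
        al = line(kb, [["Gly", "Ala"], ["Ser", "Cys"], ["Val", "Leu"]])
        scaffolds = assemble_scaffold(al, kb)
        assert len(scaffolds) == 8
        assert len({canonical_smiles(g) for _, g in scaffolds}) == 8

    def test_polyketide_chain_and_reduction_states(self, kb):
        (_, g), = assemble_scaffold(line(kb, ["Mal", "Mal"]), kb)
        assert canonical_smiles(g) == canonical_smiles("CC(=O)CC(=O)O")
        (_, g), = assemble_scaffold(
            line(kb, ["Mal", "Mal"], flags=[[], ["ketoreduce"]]), kb)
        assert canonical_smiles(g) == canonical_smiles("CC(O)CC(=O)O")
        (_, g), = assemble_scaffold(
            line(kb, ["Mal", "Mal"], flags=[[], ["dehydrate"]]), kb)
        assert canonical_smiles(g) == canonical_smiles("CC=CC(=O)O")
        (_, g), = assemble_scaffold(
            line(kb, ["Mal", "Mal"], flags=[[], ["enoylreduce"]]), kb)
        assert canonical_smiles(g) == canonical_smiles("CCCC(=O)O")

    def test_n_methylation_flag(self, kb):
        (_, g), = assemble_scaffold(
            line(kb, ["Gly", "Ala"], flags=[[], ["n_methylate"]]), kb)
        assert canonical_smiles(g) \
            == canonical_smiles("NCC(=O)N(C)C(C)C(=O)O")

    def test_macrolactam_release(self, kb):
        (_, g), = assemble_scaffold(
            line(kb, ["Gly", "Ala", "Ser"], release="macrolactam"), kb)
        # cyclization loses a second water relative to the linear acid
        assert molecular_weight(g) == pytest.approx(
            75.07 + 89.09 + 105.09 - 3 * 18.02, abs=0.03)

    def test_wildcard_monomer_assembles(self, kb):
        (_, g), = assemble_scaffold(line(kb, ["Gly", "Xaa"]), kb)
        assert any(a.wildcard for a in g.atoms.values())


class TestSites:
    def test_chlorination_sites_on_phenol(self, kb):
        rxn = kb.reactions["chlorination_aromatic"]
        assert len(enumerate_sites(rxn, parse_smiles("Oc1ccccc1"))) == 5

    def test_free_hydroxyl_sites_on_glycerol(self, kb):
        rxn = kb.reactions["o_phosphorylation"]
        assert len(enumerate_sites(rxn, parse_smiles("OCC(O)CO"))) == 3

    def test_no_match_is_empty(self, kb):
        rxn = kb.reactions["chlorination_aromatic"]
        assert enumerate_sites(rxn, parse_smiles("CCCC")) == []

    def test_partner_binding_selects_alpha_carbon(self, kb):
        rxn = kb.reactions["ser_dehydration"]
        g = parse_smiles("NC(CO)C(=O)O")
        sites = enumerate_sites(rxn, g)
        assert len(sites) == 1
        beta, alpha = sites[0]
        assert g.atoms[beta].h_count == 2
        assert any(g.atoms[n].element == "N" for n in g.neighbors(alpha))


class TestApplyReaction:
    def test_chlorination_conserves_heavy_atoms(self, kb):
        rxn = kb.reactions["chlorination_aromatic"]
        g = parse_smiles("c1ccccc1")
        pool = {"Chloro": 1}
        out = apply_reaction(rxn, g, enumerate_sites(rxn, g)[0], pool, kb)
        assert out.heavy_atom_count() == 7          # 6 C + 1 Cl
        assert pool["Chloro"] == 0
        assert canonical_smiles(out) == canonical_smiles("Clc1ccccc1")

    def test_glycosylation_loses_water(self, kb):
        rxn = kb.reactions["glycosylation_glucose"]
        g = parse_smiles("NC(CO)C(=O)O")
        sites = enumerate_sites(rxn, g)
        before = molecular_weight(g)
        sugar = molecular_weight(kb.monomers["Glc"].graph())
        out = apply_reaction(rxn, g, sites[0], {"Glc": 1}, kb)
        assert molecular_weight(out) == pytest.approx(
            before + sugar - 18.02, abs=0.02)

    def test_empty_pool_is_precondition_error(self, kb):
        rxn = kb.reactions["chlorination_aromatic"]
        g = parse_smiles("c1ccccc1")
        with pytest.raises(ReactionApplicationError, match="pool"):
            apply_reaction(rxn, g, enumerate_sites(rxn, g)[0], {}, kb)

    def test_invalid_site_rejected(self, kb):
        rxn = kb.reactions["chlorination_aromatic"]
        g = parse_smiles("Cc1ccccc1")
        methyl = next(a for a in g.atom_ids()
                      if not g.atoms[a].aromatic)
        with pytest.raises(ReactionApplicationError):
            apply_reaction(rxn, g, (methyl,), {"Chloro": 1}, kb)

    def test_dehydration_yields_dehydroalanine(self, kb):
        rxn = kb.reactions["ser_dehydration"]
        g = build_peptide("AS", kb)
        site = enumerate_sites(rxn, g)[0]
        out = apply_reaction(rxn, g, site, {}, kb)
        assert canonical_smiles(out) \
            == canonical_smiles("NC(C)C(=O)NC(=C)C(=O)O")

    def test_atom_conservation_across_registry(self, kb,
                                               fixture_molecules):
        """No bundled reaction ever increases heavy atoms beyond the
        consumed fragment, on any applicable fixture substrate."""
        for smiles in fixture_molecules[:15]:
            g = parse_smiles(smiles)
            for rxn in kb.reactions.values():
                frag = 0
                if rxn.consumes_fragment:
                    frag = kb.monomers[
                        rxn.consumes_fragment].graph().heavy_atom_count()
                for site in enumerate_sites(rxn, g)[:3]:
                    pool = ({rxn.consumes_fragment: 1}
                            if rxn.consumes_fragment else {})
                    try:
                        out = apply_reaction(rxn, g, site, pool, kb)
                    except ReactionApplicationError:
                        continue
                    assert out.heavy_atom_count() \
                        <= g.heavy_atom_count() + frag


def spec_bgc(kb, rng_seed, family, cfg=None):
    cfg = cfg or FixtureConfig(seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    spec = sample_cluster_spec(rng, family, "t", cfg)
    return spec, synthetic_bgc(spec, kb)


class TestDerivePathway:
    def test_nrps_with_halogenase(self, kb):
        cfg = FixtureConfig(seed=0)
        for seed in range(30):
            spec, bgc = spec_bgc(kb, seed, "nrps", cfg)
            if "halogenase" in spec.tailoring_models:
                break
        else:
            pytest.fail("no halogenase cluster drawn")
        pathway = derive_pathway(bgc, kb)
        assert pathway.kind == "assembly_line"
        assert [m.monomer_choices[0] for m in pathway.line.modules] \
            == spec.residues
        assert "Chloro" in pathway.pool
        assert [r.id for r in pathway.reactions] \
            == ["chlorination_aromatic"]

    def test_glycosyltransferase_contributes_sugar(self, kb):
        spec, bgc = spec_bgc(kb, 2, "glycosylated")
        pathway = derive_pathway(bgc, kb)
        assert "Glc" in pathway.pool
        assert any(r.id == "glycosylation_glucose"
                   for r in pathway.reactions)

    def test_bacteriocin_cluster_unpredictable(self, kb):
        _, bgc = spec_bgc(kb, 3, "other")
        with pytest.raises(PathwayError):
            derive_pathway(bgc, kb)


class TestEnumerateProducts:
    def test_three_sites_one_application_gives_four_products(self, kb):
        from bgcforge.predict import _predict_from_scaffolds
        g = parse_smiles("Oc1ccc(C)c(C)c1")  # three inequivalent ring CH
        rxn = kb.reactions["chlorination_aromatic"]
        assert len(enumerate_sites(rxn, g)) == 3
        ps = _predict_from_scaffolds("x", [g], [rxn], {"Chloro": 1}, kb,
                                     cap=100, seed=0, kind="assembly_line")
        assert ps.plan_space_size == 4
        assert len(ps.structures) == 4

    def test_two_independent_reactions_multiply(self, kb):
        from bgcforge.predict import _predict_from_scaffolds
        g = parse_smiles("OCC(N)c1ccc(C)cc1")
        chlor = kb.reactions["chlorination_aromatic"]
        phos = kb.reactions["o_phosphorylation"]
        n_c = len(enumerate_sites(chlor, g))
        n_p = len(enumerate_sites(phos, g))
        ps = _predict_from_scaffolds(
            "x", [g], [chlor, phos], {"Chloro": 1, "Phospho": 1}, kb,
            cap=1000, seed=0, kind="assembly_line")
        assert ps.plan_space_size == (n_c + 1) * (n_p + 1)

    def test_sampling_caps_and_is_reproducible(self, kb):
        from bgcforge.predict import _predict_from_scaffolds
        g = build_peptide("WYFWY", kb)     # many aromatic sites
        rxn = kb.reactions["chlorination_aromatic"]
        rxn3 = kb.reactions["c_methylation_aromatic"]
        n1 = len(enumerate_sites(rxn, g))
        ps = _predict_from_scaffolds(
            "x", [g], [rxn, rxn3], {"Chloro": 5, "Me": 5}, kb,
            cap=50, seed=9, kind="assembly_line")
        assert ps.plan_space_size == (n1 + 1) ** 2
        assert ps.plan_space_size > 50
        assert ps.sampled
        assert len(ps.structures) <= 50
        ps2 = _predict_from_scaffolds(
            "x", [g], [rxn, rxn3], {"Chloro": 5, "Me": 5}, kb,
            cap=50, seed=9, kind="assembly_line")
        assert ps.structures == ps2.structures
        # sampled structures are a subset of the full enumeration
        full = _predict_from_scaffolds(
            "x", [g], [rxn, rxn3], {"Chloro": 5, "Me": 5}, kb,
            cap=10**6, seed=9, kind="assembly_line")
        assert not full.sampled
        assert set(ps.structures) <= set(full.structures)

    @pytest.mark.parametrize("family", ["nrps", "pks", "hybrid",
                                        "glycosylated"])
    def test_oracle_equivalence(self, kb, family):
        for seed in range(4):
            spec, bgc = spec_bgc(kb, 50 + seed, family)
            pathway = derive_pathway(bgc, kb)
            scaffolds = [g for _, g in
                         assemble_scaffold(pathway.line, kb)]
            expected, n_plans = oracle_enumerate(
                scaffolds, pathway.reactions, pathway.pool, kb)
            if n_plans > 500:
                continue
            ps = enumerate_products(bgc, kb, cap=1000, seed=1)
            assert ps.plan_space_size == n_plans
            assert set(ps.structures) == expected

    def test_truth_recovered_and_median_below_max(self, kb):
        spec, bgc = spec_bgc(kb, 6, "glycosylated")
        ps = enumerate_products(bgc, kb, cap=100, seed=2)
        assert spec.product_smiles in ps.structures
        assert len(ps.structures) > 1


class TestRipp:
    def test_core_cleaved_and_modified(self, kb):
        spec, bgc = spec_bgc(kb, 8, "ripp")
        pathway = derive_pathway(bgc, kb)
        assert pathway.kind == "ripp"
        assert spec.ripp_core in pathway.ripp.cores
        ps = enumerate_products(bgc, kb, cap=100, seed=3)
        assert spec.product_smiles in ps.structures
        # unmodified core peptide is the zero-application plan
        core_plain = canonical_smiles(build_peptide(spec.ripp_core, kb))
        assert core_plain in ps.structures

    def test_two_motif_matches_give_two_cores(self, kb):
        from bgcforge.clusters import Bgc
        from bgcforge.domains import DomainHit
        from bgcforge.seqio import Orf

        model = kb.models["ripp_precursor"]
        aa = model.consensus + "GG" + "ATS" + "GG" + "VC"
        orf = Orf(contig_id="c", start=0, end=3 * (len(aa) + 1),
                  strand="+", aa_sequence=aa)
        hits = [DomainHit(orf=orf, model_id=model.id, score=99,
                          env_start=0, env_end=model.length)]
        bgc = Bgc(contig_id="c", start=0, end=orf.end, orfs=[orf],
                  hits=hits, families={"ripp"}, category="ripp")
        pathway = derive_pathway(bgc, kb)
        assert "ATSGGVC" in pathway.ripp.cores
        assert "VC" in pathway.ripp.cores

    def test_no_motif_falls_back_to_window(self, kb):
        from bgcforge.predict import _candidate_cores
        cores = _candidate_cores("M" + "A" * 40, kb)
        assert cores == ["A" * kb.ripp.fallback_window]
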