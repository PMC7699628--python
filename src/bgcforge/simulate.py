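"""Seeded synthetic-data generation: knowledgebases, genomes with
planted BGCs, matched true product structures, decoys and activity
labels.  Everything downstream is testable from these fixtures without
any download.

The knowledgebase builder attaches seeded consensus sequences to a
static, curated chemistry (monomer library, tailoring-reaction registry,
cluster rules).  Genomes are i.i.d.-uniform background DNA carrying
back-translated domain genes with a low substitution rate; decoys are
isolated single-domain genes and shuffled pseudo-genes.

True products are composed by *string templates* in this module — a
code path deliberately independent of the prediction engine
(:mod:`bgcforge.predict` is never imported here), so that recovering the
truth SMILES from detect->predict is a genuine end-to-end test.  The
shared molgraph canonicalizer is used only to normalize the SMILES text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .chem import canonical_smiles, parse_smiles, MolecularGraph
from .seqio import reverse_complement
from .knowledgebase import (AA_ALPHABET, ClusterRule, DomainModel,
                            Knowledgebase, Monomer, ReactionStep, RippConfig,
                            TailoringReaction, save_knowledgebase)

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
STOP_CODONS = ["TAA", "TAG", "TGA"]

AMINO_ACIDS = {
    # id: (letter, SMILES, truth fragment)
    "Gly": ("G", "NCC(=O)O", "NCC(=O)"),
    "Ala": ("A", "NC(C)C(=O)O", "NC(C)C(=O)"),
    "Ser": ("S", "NC(CO)C(=O)O", "NC(CO)C(=O)"),
    "Thr": ("T", "NC(C(C)O)C(=O)O", "NC(C(C)O)C(=O)"),
    "Cys": ("C", "NC(CS)C(=O)O", "NC(CS)C(=O)"),
    "Val": ("V", "NC(C(C)C)C(=O)O", "NC(C(C)C)C(=O)"),
    "Leu": ("L", "NC(CC(C)C)C(=O)O", "NC(CC(C)C)C(=O)"),
    "Phe": ("F", "NC(Cc1ccccc1)C(=O)O", "NC(Cc1ccccc1)C(=O)"),
    "Tyr": ("Y", "NC(Cc1ccc(O)cc1)C(=O)O", "NC(Cc1ccc(O)cc1)C(=O)"),
    "Trp": ("W", "NC(Cc1c[nH]c2ccccc12)C(=O)O",
            "NC(Cc1c[nH]c2ccccc12)C(=O)"),
}

#: tailored truth fragments: reaction -> residue -> replacement fragment
TAILORED_FRAGMENTS = {
    "chlorination_aromatic": {
        "Phe": "NC(Cc1ccc(Cl)cc1)C(=O)",
        "Tyr": "NC(Cc1ccc(O)c(Cl)c1)C(=O)",
    },
    "hydroxylation_aromatic": {
        "Phe": "NC(Cc1ccc(O)cc1)C(=O)",
    },
    "glycosylation_glucose": {
        "Ser": "NC(COC1OC(CO)C(O)C(O)C1O)C(=O)",
    },
    "o_phosphorylation": {
        "Ser": "NC(COP(=O)(O)O)C(=O)",
    },
    "o_methylation": {
        "Ser": "NC(COC)C(=O)",
    },
    "o_acetylation": {
        "Ser": "NC(COC(C)=O)C(=O)",
    },
    "ser_dehydration": {
        "Ser": "NC(=C)C(=O)",
    },
}

PHARMACOPHORES = {
    "antibacterial": "Oc1ccccc1",          # phenol
    "antifungal": "c1c[nH]c2ccccc12",      # indole
    "antiviral": "CS",                     # thiol / thioether carbon
    "antitumor": "CC(C)C",                 # isopropyl branch
    "immunomodulatory": "C1CCCCO1",        # pyranose ring
}
ACTIVITIES = list(PHARMACOPHORES)

#: residue draw weights chosen so each pharmacophore lands in roughly
#: half of the generated clusters (2-4 residues per cluster)
RESIDUE_WEIGHTS = {
    "Tyr": 0.20, "Trp": 0.20, "Cys": 0.20, "Val": 0.10, "Leu": 0.10,
    "Ser": 0.08, "Gly": 0.03, "Ala": 0.03, "Thr": 0.03, "Phe": 0.03,
}

FAMILIES = ("nrps", "pks", "hybrid", "ripp", "glycosylated", "other")


@dataclass
class FixtureConfig:
    seed: int = 0
    n_genomes: int = 20
    clusters_per_genome: int = 3
    family_mix: dict[str, float] = field(default_factory=lambda: {
        "nrps": 0.30, "pks": 0.20, "hybrid": 0.10, "ripp": 0.20,
        "glycosylated": 0.10, "other": 0.10})
    decoy_rate: float = 0.5
    pharmacophores: dict[str, str] = field(
        default_factory=lambda: dict(PHARMACOPHORES))
    label_noise: float = 0.1
    mutation_rate: float = 0.03
    consensus_length: int = 30

    def __post_init__(self) -> None:
        total = sum(self.family_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("family_mix weights must sum to 1")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")


# ---------------------------------------------------------------------
# knowledgebase construction
# ---------------------------------------------------------------------

def _random_consensus(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _curated_monomers() -> dict[str, Monomer]:
    monomers: dict[str, Monomer] = {}
    for mid, (letter, smiles, _) in AMINO_ACIDS.items():
        monomers[mid] = Monomer(id=mid, smiles=smiles, mclass="amino_acid",
                                aa_letter=letter)
    monomers["Xaa"] = Monomer(id="Xaa", smiles="NC([*])C(=O)O",
                              mclass="amino_acid")
    monomers["Mal"] = Monomer(id="Mal", smiles="CC(=O)O",
                              mclass="ketide_unit")
    monomers["Glc"] = Monomer(id="Glc", smiles="OC1OC(CO)C(O)C(O)C1O",
                              mclass="sugar")
    monomers["Ara"] = Monomer(id="Ara", smiles="OC1OCC(O)C(O)C1O",
                              mclass="sugar")
    for fid, smiles in [("Chloro", "Cl"), ("Bromo", "Br"),
                        ("Hydroxy", "O"), ("Amino", "N"), ("Me", "C"),
                        ("Phospho", "P(=O)(O)O"), ("Sulfo", "S(=O)(=O)O")]:
        monomers[fid] = Monomer(id=fid, smiles=smiles, mclass="fragment",
                                attachments={"head": 0})
    monomers["Acetyl"] = Monomer(id="Acetyl", smiles="CC(O)=O",
                                 mclass="fragment",
                                 attachments={"carbonyl": 1,
                                              "leaving_oh": 2})
    return monomers


def _s(op, a, b=None, order=None) -> ReactionStep:
    return ReactionStep(op=op, a=a, b=b, order=order)


def _curated_reactions() -> dict[str, TailoringReaction]:
    aromatic_ch = {"element": "C", "aromatic": True, "min_h": 1}
    free_oh = {"element": "O", "min_h": 1,
               "neighbors": [{"element": "C"}]}
    add_head = [_s("add_bond", "site", "frag.head", order=1)]
    rxns = [
        TailoringReaction("chlorination_aromatic", aromatic_ch,
                          add_head, consumes_fragment="Chloro"),
        TailoringReaction("bromination_aromatic", aromatic_ch,
                          add_head, consumes_fragment="Bromo"),
        TailoringReaction(
            "chlorination_aliphatic",
            {"element": "C", "aromatic": False, "min_h": 3},
            add_head, consumes_fragment="Chloro"),
        TailoringReaction("hydroxylation_aromatic", aromatic_ch,
                          add_head, consumes_fragment="Hydroxy"),
        TailoringReaction(
            "hydroxylation_aliphatic",
            {"element": "C", "aromatic": False, "min_h": 3},
            add_head, consumes_fragment="Hydroxy"),
        TailoringReaction("o_methylation", free_oh, add_head,
                          consumes_fragment="Me"),
        TailoringReaction(
            "n_methylation",
            {"element": "N", "aromatic": False, "min_h": 1},
            add_head, consumes_fragment="Me"),
        TailoringReaction("c_methylation_aromatic", aromatic_ch, add_head,
                          consumes_fragment="Me"),
        TailoringReaction("o_phosphorylation", free_oh, add_head,
                          consumes_fragment="Phospho"),
        TailoringReaction("o_sulfonation", free_oh, add_head,
                          consumes_fragment="Sulfo"),
        TailoringReaction(
            "glycosylation_glucose", free_oh,
            [_s("remove_atom", "frag.donor_oh"),
             _s("add_bond", "site", "frag.donor", order=1)],
            consumes_fragment="Glc"),
        TailoringReaction(
            "glycosylation_arabinose", free_oh,
            [_s("remove_atom", "frag.donor_oh"),
             _s("add_bond", "site", "frag.donor", order=1)],
            consumes_fragment="Ara"),
        TailoringReaction(
            "ser_dehydration",
            {"element": "C", "aromatic": False, "min_h": 2,
             "neighbors": [{"element": "O", "min_h": 1, "order": 1}],
             "partner": {"element": "C",
                         "neighbors": [{"element": "N"}]}},
            [_s("remove_atom", "site.O"),
             _s("set_bond_order", "site", "site.partner", order=2)]),
        TailoringReaction(
            "thr_dehydration",
            {"element": "C", "aromatic": False, "min_h": 1,
             "neighbors": [{"element": "O", "min_h": 1, "order": 1},
                           {"element": "C", "min_h": 3}],
             "partner": {"element": "C",
                         "neighbors": [{"element": "N"}]}},
            [_s("remove_atom", "site.O"),
             _s("set_bond_order", "site", "site.partner", order=2)]),
        TailoringReaction(
            "decarboxylation",
            {"element": "C",
             "neighbors": [{"element": "O", "order": 2},
                           {"element": "O", "min_h": 1, "order": 1}]},
            [_s("remove_atom", "site.O"), _s("remove_atom", "site.O"),
             _s("remove_atom", "site")]),
        TailoringReaction(
            "ketoreduction",
            {"element": "C",
             "neighbors": [{"element": "O", "order": 2}],
             "not_neighbors": [{"element": "O", "order": 1},
                               {"element": "N"}, {"element": "S"}]},
            [_s("set_bond_order", "site", "site.O", order=1)]),
        TailoringReaction(
            "alcohol_oxidation",
            {"element": "C", "min_h": 1,
             "neighbors": [{"element": "O", "min_h": 1, "order": 1}],
             "not_neighbors": [{"element": "O", "order": 2}]},
            [_s("set_bond_order", "site", "site.O", order=2)]),
        TailoringReaction(
            "desaturation",
            {"element": "C", "aromatic": False, "min_h": 2,
             "partner": {"element": "C", "aromatic": False, "min_h": 2}},
            [_s("set_bond_order", "site", "site.partner", order=2)]),
        TailoringReaction("amination_aromatic", aromatic_ch, add_head,
                          consumes_fragment="Amino"),
        TailoringReaction(
            "o_acetylation", free_oh,
            [_s("remove_atom", "frag.leaving_oh"),
             _s("add_bond", "site", "frag.carbonyl", order=1)],
            consumes_fragment="Acetyl"),
    ]
    return {r.id: r for r in rxns}


#: tailoring enzymes: model id -> (fragment, reactions)
TAILORING_ENZYMES = {
    "halogenase": ("Chloro", ["chlorination_aromatic"]),
    "p450_hydroxylase": ("Hydroxy", ["hydroxylation_aromatic"]),
    "glycosyltransferase": ("Glc", ["glycosylation_glucose"]),
    "o_mtase": ("Me", ["o_methylation"]),
    "n_mtase": ("Me", ["n_methylation"]),
    "phosphotransferase": ("Phospho", ["o_phosphorylation"]),
    "acetyltransferase": ("Acetyl", ["o_acetylation"]),
    "ripp_dehydratase": (None, ["ser_dehydration"]),
    "pks_ketoreductase": (None, ["ketoreduction"]),
    "aliphatic_halogenase": ("Chloro", ["chlorination_aliphatic"]),
}

#: which residue classes a tailoring reaction needs / targets in truth
_TAILORING_REQUIRES = {
    "halogenase": ("chlorination_aromatic", ["Phe", "Tyr"]),
    "p450_hydroxylase": ("hydroxylation_aromatic", ["Phe"]),
    "glycosyltransferase": ("glycosylation_glucose", ["Ser"]),
    "o_mtase": ("o_methylation", ["Ser"]),
    "phosphotransferase": ("o_phosphorylation", ["Ser"]),
    "acetyltransferase": ("o_acetylation", ["Ser"]),
    "ripp_dehydratase": ("ser_dehydration", ["Ser"]),
}


def build_knowledgebase(config: FixtureConfig) -> Knowledgebase:
    """Curated chemistry + seeded consensus sequences for every model."""
    rng = np.random.default_rng(config.seed)
    L = config.consensus_length
    monomers = _curated_monomers()
    reactions = _curated_reactions()
    models: dict[str, DomainModel] = {}

    def add_model(mid: str, family: str, role: str, **kw) -> DomainModel:
        model = DomainModel(
            id=mid, family=family, role=role,
            consensus=_random_consensus(rng, L),
            bit_threshold=L, **kw)   # threshold = half the perfect score
        models[mid] = model
        return model

    sig_pos = [6, 11, 17, 23]
    for aa_id in AMINO_ACIDS:
        model = add_model(f"A_{aa_id.lower()}", "adenylation", "scaffold",
                          signature_positions=sig_pos,
                          contributes_subgraph="Xaa")
        signature = "".join(model.consensus[p] for p in sig_pos)
        model.substrate_map = {signature: aa_id}
    for ks_id, flags in [("ks_keto", []), ("ks_kr", ["ketoreduce"]),
                         ("ks_dh", ["dehydrate"]),
                         ("ks_er", ["enoylreduce"])]:
        add_model(ks_id, "ketosynthase", "scaffold",
                  contributes_subgraph="Mal", module_flags=flags)
    add_model("ripp_precursor", "precursor-peptide", "precursor")
    for tid, (fragment, rids) in TAILORING_ENZYMES.items():
        add_model(tid, tid, "tailoring", contributes_subgraph=fragment,
                  contributes_reactions=rids)
    add_model("bact_a", "bacteriocin", "resistance-other")
    add_model("bact_b", "bacteriocin", "resistance-other")

    rules = [
        ClusterRule(family="nrps", required=[["adenylation"]]),
        ClusterRule(family="pks", required=[["ketosynthase"]]),
        ClusterRule(family="ripp", required=[["precursor-peptide"]]),
        ClusterRule(family="bacteriocin", required=[["bacteriocin"]],
                    predictable=False),
    ]
    kb = Knowledgebase(models=models, monomers=monomers,
                       reactions=reactions, rules=rules,
                       ripp=RippConfig())
    kb.validate()
    return kb


def generate_knowledgebase(config: FixtureConfig, path) -> Knowledgebase:
    """Build and write the knowledgebase; same seed, same bytes."""
    kb = build_knowledgebase(config)
    save_knowledgebase(kb, path)
    return kb


# ---------------------------------------------------------------------
# cluster specifications and independent truth composition
# ---------------------------------------------------------------------

@dataclass
class ClusterSpec:
    cluster_id: str
    family: str
    scaffold_models: list[str]        # ordered gene content
    tailoring_models: list[str]
    residues: list[str]               # monomer ids in biosynthetic order
    ripp_core: str | None = None
    product_smiles: str = ""          # canonical truth SMILES


def _draw_residues(rng: np.random.Generator, k: int,
                   require: list[str] | None = None) -> list[str]:
    ids = list(RESIDUE_WEIGHTS)
    w = np.array([RESIDUE_WEIGHTS[i] for i in ids])
    residues = [str(r) for r in rng.choice(ids, size=k, p=w / w.sum())]
    if require and not any(r in require for r in residues):
        residues[int(rng.integers(k))] = require[int(rng.integers(
            len(require)))]
    return residues


def compose_peptide_truth(residues: list[str],
                          tailored: dict[int, str] | None = None) -> str:
    """Canonical truth SMILES of a linear peptide by string templates.

    ``tailored`` maps residue index -> replacement fragment (a tailored
    variant from :data:`TAILORED_FRAGMENTS`).
    """
    frags = []
    for i, rid in enumerate(residues):
        if tailored and i in tailored:
            frags.append(tailored[i])
        else:
            frags.append(AMINO_ACIDS[rid][2])
    return canonical_smiles("".join(frags) + "O")


def compose_polyketide_truth(states: list[str],
                             chlorinated: bool = False) -> str:
    """Truth SMILES of a linear polyketide chain.

    ``states`` gives the reduction state written into the chain at each
    extension (state of module i+1 acting on unit i's carbonyl).
    """
    link = {"keto": "C(=O)C", "kr": "C(O)C", "dh": "C=C", "er": "CC"}
    body = "".join(link[s] for s in states)
    # first unit contributes the terminal methyl; the last the free acid
    prefix = "ClC" if chlorinated else "C"
    return canonical_smiles(prefix + body + "C(=O)O")


_KS_STATE = {"ks_keto": "keto", "ks_kr": "kr", "ks_dh": "dh",
             "ks_er": "er"}


def sample_cluster_spec(rng: np.random.Generator, family: str,
                        cluster_id: str,
                        config: FixtureConfig) -> ClusterSpec:
    """Draw one planted-cluster specification with a composable truth."""
    tailorings: list[str] = []
    if family in ("nrps", "hybrid", "glycosylated"):
        k = int(rng.integers(2, 5))
        if family == "glycosylated":
            tailoring_pool = ["glycosyltransferase"]
        else:
            tailoring_pool = ["halogenase", "p450_hydroxylase", "o_mtase",
                              "phosphotransferase", "acetyltransferase",
                              "glycosyltransferase"]
        n_tail = (1 if family == "glycosylated"
                  else int(rng.integers(0, 2)))
        tailorings = ([str(t) for t in rng.choice(
            tailoring_pool, size=n_tail, replace=False)]
            if n_tail else [])
        require: list[str] = []
        for t in tailorings:
            require += _TAILORING_REQUIRES[t][1]
        residues = _draw_residues(rng, k, require or None)
        # make sure each required residue class is actually present
        for t in tailorings:
            need = _TAILORING_REQUIRES[t][1]
            if not any(r in need for r in residues):
                residues[0] = need[0]
        if family == "hybrid":
            # replace the last module with a ketide extension
            residues = residues[:-1]
            ks = str(rng.choice(["ks_keto", "ks_kr", "ks_er"]))
            scaffold = [f"A_{r.lower()}" for r in residues] + [ks]
        else:
            scaffold = [f"A_{r.lower()}" for r in residues]
        tailored: dict[int, str] = {}
        for t in tailorings:
            rid, targets = _TAILORING_REQUIRES[t]
            for i, r in enumerate(residues):
                if r in targets and i not in tailored:
                    tailored[i] = TAILORED_FRAGMENTS[rid][r]
                    break
        if family == "hybrid":
            state = _KS_STATE[ks]
            frags = []
            for i, r in enumerate(residues):
                frags.append(tailored.get(i, AMINO_ACIDS[r][2]))
            link = {"keto": "C(=O)", "kr": "C(O)", "er": "C"}[state]
            # amide C of the last residue becomes the beta position; the
            # ketide unit extends it and leaves the free acid
            body = "".join(frags)
            body = body[:-len("C(=O)")] + (
                "C(=O)" if state == "keto" else
                "C(O)" if state == "kr" else "C")
            truth = canonical_smiles(body + "CC(=O)O")
        else:
            truth = compose_peptide_truth(residues, tailored)
        return ClusterSpec(cluster_id=cluster_id, family=family,
                           scaffold_models=scaffold,
                           tailoring_models=tailorings,
                           residues=residues, product_smiles=truth)

    if family == "pks":
        n_ext = int(rng.integers(1, 4))
        ks_choices = ["ks_keto", "ks_kr", "ks_dh", "ks_er"]
        exts = [str(rng.choice(ks_choices)) for _ in range(n_ext)]
        scaffold = ["ks_keto"] + exts          # loading + extensions
        chlorinate = bool(rng.random() < 0.3)
        tailorings = ["aliphatic_halogenase"] if chlorinate else []
        truth = compose_polyketide_truth([_KS_STATE[e] for e in exts],
                                         chlorinated=chlorinate)
        return ClusterSpec(cluster_id=cluster_id, family="pks",
                           scaffold_models=scaffold,
                           tailoring_models=tailorings,
                           residues=["Mal"] * (n_ext + 1),
                           product_smiles=truth)

    if family == "ripp":
        core_len = int(rng.integers(4, 7))
        residues = _draw_residues(rng, core_len, require=["Ser"])
        if "Ser" not in residues:
            residues[0] = "Ser"
        core = "".join(AMINO_ACIDS[r][0] for r in residues)
        tailored = {}
        for i, r in enumerate(residues):
            if r == "Ser":
                tailored[i] = TAILORED_FRAGMENTS["ser_dehydration"]["Ser"]
                break
        truth = compose_peptide_truth(residues, tailored)
        return ClusterSpec(cluster_id=cluster_id, family="ripp",
                           scaffold_models=["ripp_precursor"],
                           tailoring_models=["ripp_dehydratase"],
                           residues=residues, ripp_core=core,
                           product_smiles=truth)

    if family == "other":
        return ClusterSpec(cluster_id=cluster_id, family="other",
                           scaffold_models=["bact_a", "bact_b"],
                           tailoring_models=[], residues=[],
                           product_smiles="")
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------

def _back_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(CODONS[c][int(rng.integers(len(CODONS[c])))]
                   for c in aa)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(aa: str, rng: np.random.Generator, rate: float,
            protected: set[int]) -> str:
    out = list(aa)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
    return "".join(out)


def _gene_for_model(model: DomainModel, rng: np.random.Generator,
                    config: FixtureConfig,
                    core: str | None = None) -> str:
    """Nucleotide gene embedding the (mutated) model consensus."""
    protected = set(model.signature_positions)
    body = _mutate(model.consensus, rng, config.mutation_rate, protected)
    if core is not None:     # RiPP precursor: leader + cleavage + core
        aa = _random_flank(rng, 30) + body + "GG" + core
    else:
        aa = _random_flank(rng, 22) + body + _random_flank(rng, 22)
    return "ATG" + _back_translate(aa, rng) + STOP_CODONS[
        int(rng.integers(3))]


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
                   for _ in range(n))


@dataclass
class PlantedCluster:
    spec: ClusterSpec
    contig_id: str
    start: int
    end: int


def build_genome(specs: list[ClusterSpec], kb: Knowledgebase,
                 rng: np.random.Generator, config: FixtureConfig,
                 contig_id: str,
                 n_decoys: int = 2) -> tuple[str, list[PlantedCluster]]:
    """One contig: planted clusters separated by >max_gap spacers, plus
    decoy loci (isolated single domains, shuffled pseudo-genes)."""
    parts: list[str] = [_random_dna(rng, int(rng.integers(300, 600)))]
    planted: list[PlantedCluster] = []
    gap = kb.max_gap() + 5000
    pos = len(parts[0])
    for spec in specs:
        genes = []
        model_ids = list(spec.scaffold_models) + list(spec.tailoring_models)
        for mid in model_ids:
            core = spec.ripp_core if mid == "ripp_precursor" else None
            genes.append(_gene_for_model(kb.models[mid], rng, config, core))
        cluster_start = pos
        n_scaffold = len(spec.scaffold_models)
        block: list[str] = []
        for i, gene in enumerate(genes):
            if i:
                spacer = _random_dna(rng, int(rng.integers(100, 400)))
                block.append(spacer)
            # tailoring genes may sit on the minus strand; scaffold genes
            # stay colinear so genomic order is biosynthetic order
            if i >= n_scaffold and rng.random() < 0.5:
                gene = reverse_complement(gene)
            block.append(gene)
        block_seq = "".join(block)
        parts.append(block_seq)
        pos += len(block_seq)
        planted.append(PlantedCluster(spec=spec, contig_id=contig_id,
                                      start=cluster_start, end=pos))
        spacer = _random_dna(rng, gap)
        parts.append(spacer)
        pos += len(spacer)
    tailoring_ids = list(TAILORING_ENZYMES)
    for _ in range(n_decoys):
        if rng.random() < 0.5:
            mid = tailoring_ids[int(rng.integers(len(tailoring_ids)))]
            gene = _gene_for_model(kb.models[mid], rng, config)
        else:
            mid = tailoring_ids[int(rng.integers(len(tailoring_ids)))]
            shuffled = "".join(rng.permutation(
                list(kb.models[mid].consensus)))
            aa = _random_flank(rng, 22) + shuffled + _random_flank(rng, 22)
            gene = "ATG" + _back_translate(aa, rng) + STOP_CODONS[
                int(rng.integers(3))]
        parts.append(gene)
        spacer = _random_dna(rng, gap)
        parts.append(spacer)
        pos += len(gene) + len(spacer)
    return "".join(parts), planted


def generate_genomes(config: FixtureConfig, kb: Knowledgebase,
                     outdir=None) -> tuple[dict[str, str], dict]:
    """Genomes with planted BGCs and the matching truth record.

    Returns ``(contigs, truth)`` where ``contigs`` maps contig id to DNA
    and ``truth`` is the JSON-serializable truth record.  With
    ``outdir`` set, writes one FASTA per genome plus ``truth.json``.
    """
    rng = np.random.default_rng(config.seed + 1)
    families = list(config.family_mix)
    weights = np.array([config.family_mix[f] for f in families])
    contigs: dict[str, str] = {}
    clusters = []
    counter = 0
    for g in range(config.n_genomes):
        contig_id = f"genome{g:03d}"
        specs = []
        for _ in range(config.clusters_per_genome):
            family = str(rng.choice(families, p=weights / weights.sum()))
            specs.append(sample_cluster_spec(
                rng, family, f"bgc{counter:04d}", config))
            counter += 1
        n_decoys = int(round(config.decoy_rate
                             * config.clusters_per_genome))
        dna, planted = build_genome(specs, kb, rng, config, contig_id,
                                    n_decoys=n_decoys)
        contigs[contig_id] = dna
        for p in planted:
            clusters.append({
                "cluster_id": p.spec.cluster_id,
                "contig_id": p.contig_id,
                "start": p.start, "end": p.end,
                "family": p.spec.family,
                "models": (p.spec.scaffold_models
                           + p.spec.tailoring_models),
                "residues": p.spec.residues,
                "ripp_core": p.spec.ripp_core,
                "product_smiles": p.spec.product_smiles,
            })
    truth = {"seed": config.seed, "clusters": clusters}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for contig_id, dna in contigs.items():
            lines = [f">{contig_id}"]
            lines += [dna[i:i + 70] for i in range(0, len(dna), 70)]
            (outdir / f"{contig_id}.fasta").write_text(
                "\n".join(lines) + "\n")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return contigs, truth


# ---------------------------------------------------------------------
# activity labels
# ---------------------------------------------------------------------

def _to_nx(g: MolecularGraph) -> nx.Graph:
    gx = nx.Graph()
    for a in g.atom_ids():
        at = g.atoms[a]
        gx.add_node(a, element=at.element, aromatic=at.aromatic)
    for a, b, _ in g.bonds():
        gx.add_edge(a, b)
    return gx


def contains_substructure(molecule_smiles: str,
                          pattern_smiles: str) -> bool:
    """Subgraph-monomorphism test on element + aromatic flags."""
    host = _to_nx(parse_smiles(molecule_smiles))
    patt = _to_nx(parse_smiles(pattern_smiles))
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        host, patt,
        node_match=lambda a, b: (a["element"] == b["element"]
                                 and a["aromatic"] == b["aromatic"]))
    return any(True for _ in matcher.subgraph_monomorphisms_iter())


def generate_activity_labels(truth: dict, config: FixtureConfig,
                             noiseless: bool = False) -> pd.DataFrame:
    """Binary labels per activity: positive iff the true product contains
    the activity's pharmacophore, then flipped independently with
    probability ``label_noise`` (seeded).

    With ``noiseless=True`` the flip step is skipped, yielding the clean
    ground-truth labels (useful to measure how much pharmacophore signal
    a model recovers despite training on noisy labels)."""
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for cluster in truth["clusters"]:
        smiles = cluster["product_smiles"]
        if not smiles:
            continue
        row = {"bgc_id": cluster["cluster_id"]}
        for activity, pattern in config.pharmacophores.items():
            label = int(contains_substructure(smiles, pattern))
            if not noiseless and rng.random() < config.label_noise:
                label = 1 - label
            row[activity] = label
        rows.append(row)
    return pd.DataFrame(rows).set_index("bgc_id")


# ---------------------------------------------------------------------
# in-memory BGC panel (fast path for model training experiments)
# ---------------------------------------------------------------------

def synthetic_bgc(spec: ClusterSpec, kb: Knowledgebase):
    """A synthetic annotated cluster built directly from a spec.

    Skips DNA synthesis/detection: domain hits are materialized with
    their known substrates, which is exactly what detection recovers on
    clean fixtures.  Used for model-training experiments at scale.
    """
    from .clusters import Bgc
    from .domains import DomainHit
    from .seqio import Orf

    orf_pos = 0
    hits = []
    orfs = []
    residue_iter = iter(spec.residues)
    for mid in list(spec.scaffold_models) + list(spec.tailoring_models):
        model = kb.models[mid]
        aa = model.consensus
        if mid == "ripp_precursor":
            aa = model.consensus + "GG" + (spec.ripp_core or "")
        orf = Orf(contig_id=spec.cluster_id, start=orf_pos,
                  end=orf_pos + 3 * (len(aa) + 1), strand="+",
                  aa_sequence=aa)
        orf_pos = orf.end + 200
        orfs.append(orf)
        substrate = None
        if model.family == "adenylation":
            substrate = next(residue_iter, None)
        hits.append(DomainHit(orf=orf, model_id=mid,
                              score=model.bit_threshold * 2,
                              env_start=0, env_end=model.length,
                              substrate=substrate))
    bgc = Bgc(contig_id=spec.cluster_id, start=0, end=orf_pos,
              orfs=orfs, hits=hits, families={spec.family},
              category=spec.family, label=spec.cluster_id)
    return bgc


def sample_bgc_panel(n: int, config: FixtureConfig,
                     kb: Knowledgebase) -> tuple[list, dict, pd.DataFrame]:
    """``n`` synthetic structure-bearing clusters + truth + labels."""
    rng = np.random.default_rng(config.seed + 3)
    families = [f for f in config.family_mix if f != "other"]
    weights = np.array([config.family_mix[f] for f in families])
    bgcs = []
    clusters = []
    for i in range(n):
        family = str(rng.choice(families, p=weights / weights.sum()))
        spec = sample_cluster_spec(rng, family, f"panel{i:04d}", config)
        bgcs.append(synthetic_bgc(spec, kb))
        clusters.append({"cluster_id": spec.cluster_id,
                         "product_smiles": spec.product_smiles})
    truth = {"seed": config.seed, "clusters": clusters}
    labels = generate_activity_labels(truth, config)
    return bgcs, truth, labels
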