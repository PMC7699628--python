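"""Combinatorial, graph-based structure prediction.

A detected cluster is turned into (i) a scaffold — an assembly line of
monomer subgraphs for thiotemplated clusters, or a cleaved core peptide
for RiPPs — and (ii) a pool of reagent fragments plus a list of virtual
tailoring reactions contributed by the tailoring enzymes.  Because the
exact site of many tailoring reactions cannot be inferred from sequence,
the engine enumerates the whole plan space: every monomer-choice
combination crossed with, for every reaction, every subset of its
candidate sites of size 0..max_applications.  Candidate sites are
enumerated against the assembled scaffold; during realization reactions
run in fixed knowledgebase order and every chosen site is re-validated
against the working graph (a consumed site is skipped with a warning).
This makes the plan count closed-form, so plan spaces larger than the
structure cap can be sampled uniformly, without replacement and
reproducibly, by unranking seeded plan indices.

Tailoring transformations change bond orders, add or remove bonds and
remove atoms, but never create atoms; heavy atoms only enter via pooled
reagent subgraphs, so the heavy-atom count of (working graph + consumed
fragment) never increases through an application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb

import numpy as np

from .chem import MolecularGraph, ValenceError, write_smiles
from .clusters import Bgc
from .knowledgebase import (Knowledgebase, Monomer, TailoringReaction,
                            PRECURSOR, SCAFFOLD, TAILORING)

logger = logging.getLogger(__name__)

WILDCARD_AA = "Xaa"
KETIDE_FLAGS = ("ketoreduce", "dehydrate", "enoylreduce")


class PathwayError(ValueError):
    """No structure can be predicted for this cluster."""


class ReactionApplicationError(ValueError):
    """A transformation step failed (e.g. valence violation) at a site."""


@dataclass
class Module:
    monomer_choices: list[str]
    flags: list[str] = field(default_factory=list)


@dataclass
class AssemblyLine:
    modules: list[Module]
    release: str = "linear"      # linear | macrolactam | macrolactone | none


@dataclass
class RippSpec:
    precursor_aa: str
    cores: list[str]


@dataclass
class Pathway:
    kind: str                    # assembly_line | ripp | unpredictable
    line: AssemblyLine | None
    ripp: RippSpec | None
    pool: dict[str, int]
    reactions: list[TailoringReaction]


@dataclass
class PredictionSet:
    bgc_id: str
    structures: list[str]        # deduplicated canonical SMILES
    plan_space_size: int
    sampled: bool
    seed: int
    cap: int = 100
    kind: str = "assembly_line"


# ---------------------------------------------------------------------
# pathway derivation
# ---------------------------------------------------------------------

def derive_pathway(bgc: Bgc, kb: Knowledgebase) -> Pathway:
    """Map a cluster's enzymatic content to scaffold + pool + reactions."""
    scaffold_hits = []
    precursor_hits = []
    tailoring_hits = []
    for hit in bgc.hits:
        role = kb.models[hit.model_id].role
        if role == SCAFFOLD:
            scaffold_hits.append(hit)
        elif role == PRECURSOR:
            precursor_hits.append(hit)
        elif role == TAILORING:
            tailoring_hits.append(hit)
    pool: dict[str, int] = {}
    reactions: dict[str, TailoringReaction] = {}
    for hit in tailoring_hits:
        model = kb.models[hit.model_id]
        for rid in model.contributes_reactions:
            reactions[rid] = kb.reactions[rid]
        if model.contributes_subgraph:
            n = sum(kb.reactions[r].max_applications
                    for r in model.contributes_reactions) or 1
            pool[model.contributes_subgraph] = (
                pool.get(model.contributes_subgraph, 0) + n)
    ordered = [reactions[rid] for rid in kb.reaction_order
               if rid in reactions]

    if scaffold_hits:
        scaffold_hits.sort(key=lambda h: (h.orf.start, h.env_start))
        minus = sum(1 for h in scaffold_hits if h.orf.strand == "-")
        if minus > len(scaffold_hits) / 2:
            scaffold_hits.reverse()   # biosynthetic order follows the genes
        modules = []
        release = "linear"
        for hit in scaffold_hits:
            model = kb.models[hit.model_id]
            monomer = hit.substrate or model.contributes_subgraph \
                or WILDCARD_AA
            modules.append(Module(monomer_choices=[monomer],
                                  flags=list(model.module_flags)))
            if model.release:
                release = model.release
        return Pathway(kind="assembly_line",
                       line=AssemblyLine(modules=modules, release=release),
                       ripp=None, pool=pool, reactions=ordered)

    if precursor_hits:
        precursor = precursor_hits[0].orf.aa_sequence
        cores = _candidate_cores(precursor, kb)
        return Pathway(kind="ripp", line=None,
                       ripp=RippSpec(precursor_aa=precursor, cores=cores),
                       pool=pool, reactions=ordered)

    raise PathwayError(
        f"cluster {bgc.bgc_id}: no scaffold or precursor domain — "
        "detected but unpredictable")


def _candidate_cores(precursor: str, kb: Knowledgebase) -> list[str]:
    cores: list[str] = []
    for motif in kb.ripp.cleavage_motifs:
        start = 0
        while True:
            pos = precursor.find(motif, start)
            if pos < 0:
                break
            core = precursor[pos + len(motif):]
            if core and core not in cores:
                cores.append(core)
            start = pos + 1
    if not cores:
        cores.append(precursor[-kb.ripp.fallback_window:])
    return cores


# ---------------------------------------------------------------------
# scaffold assembly
# ---------------------------------------------------------------------

def _attach(g: MolecularGraph, mapping: dict[int, int],
            monomer: Monomer, name: str) -> int:
    return mapping[monomer.attachments[name]]


def _head_name(monomer: Monomer) -> str:
    return "alpha" if monomer.mclass == "ketide_unit" else "n_terminus"


def _hydroxyl_on(g: MolecularGraph, c: int) -> int:
    for b in g.neighbors(c):
        nb = g.atoms[b]
        if nb.element == "O" and g.bond_order(c, b) == 1 and nb.h_count >= 1:
            return b
    raise ReactionApplicationError(f"no hydroxyl on atom {c}")


def _condense(g: MolecularGraph, tail: int, head: int) -> None:
    """Join tail carboxyl to head amine/alpha with loss of water."""
    g.excise_atom(_hydroxyl_on(g, tail))
    g.form_bond(tail, head, 1)


def _apply_ketide_flags(g: MolecularGraph, beta: int, alpha: int,
                        flags: list[str]) -> None:
    """Reduction state of the freshly formed beta-keto group."""
    if not any(f in flags for f in KETIDE_FLAGS):
        return
    o = next(b for b in g.neighbors(beta)
             if g.atoms[b].element == "O" and g.bond_order(beta, b) == 2)
    g.change_bond_order(beta, o, 1)                  # ketoreduction
    if "dehydrate" in flags or "enoylreduce" in flags:
        g.excise_atom(o)
        g.change_bond_order(beta, alpha, 2)          # dehydration
        if "enoylreduce" in flags:
            g.change_bond_order(beta, alpha, 1)      # enoyl reduction


def assemble_scaffold(line: AssemblyLine, kb: Knowledgebase
                      ) -> list[tuple[tuple[str, ...], MolecularGraph]]:
    """One scaffold graph per monomer-choice combination.

    Amino-acid condensation forms an amide with loss of water; ketide
    extension is a Claisen-type C-C join whose beta-keto state follows
    the extending module's reduction flags; release closes a macrocycle
    or leaves the linear acid.
    """
    out = []
    choice_sets = [m.monomer_choices for m in line.modules]
    for combo in product(*choice_sets):
        g = MolecularGraph()
        first = kb.monomers[combo[0]]
        mapping = g.union(first.graph())
        first_head = _attach(g, mapping, first, _head_name(first))
        prev_tail = _attach(g, mapping, first, "c_terminus")
        _apply_module_decorations(g, mapping, first, line.modules[0], kb)
        for idx in range(1, len(combo)):
            monomer = kb.monomers[combo[idx]]
            mod = line.modules[idx]
            mapping = g.union(monomer.graph())
            head = _attach(g, mapping, monomer, _head_name(monomer))
            beta = prev_tail
            _condense(g, prev_tail, head)
            if monomer.mclass == "ketide_unit":
                _apply_ketide_flags(g, beta, head, mod.flags)
            _apply_module_decorations(g, mapping, monomer, mod, kb)
            prev_tail = _attach(g, mapping, monomer, "c_terminus")
        if line.release == "macrolactam" and len(combo) > 1:
            try:
                g.excise_atom(_hydroxyl_on(g, prev_tail))
                g.form_bond(prev_tail, first_head, 1)
            except (ReactionApplicationError, ValenceError):
                pass     # fall back to the linear acid
        out.append((combo, g))
    return out


def _apply_module_decorations(g: MolecularGraph, mapping: dict[int, int],
                              monomer: Monomer, module: Module,
                              kb: Knowledgebase) -> None:
    if "n_methylate" in module.flags and monomer.mclass == "amino_acid":
        n = _attach(g, mapping, monomer, "n_terminus")
        me = g.union(kb.monomers["Me"].graph())
        g.form_bond(n, next(iter(me.values())), 1)
    # epimerize is a no-op: stereochemistry is outside the model


def build_peptide(core: str, kb: Knowledgebase) -> MolecularGraph:
    """Linear peptide graph from amino-acid letters (RiPP core)."""
    modules = [Module(monomer_choices=[kb.aa_monomer(c).id]) for c in core]
    (_, g), = assemble_scaffold(AssemblyLine(modules=modules), kb)
    return g


# ---------------------------------------------------------------------
# site predicates and reaction application
# ---------------------------------------------------------------------

def _order_matches(order, want) -> bool:
    if want is None:
        return True
    return float(order if order != 1.5 else 1.5) == float(want)


def _atom_matches(g: MolecularGraph, a: int, pred: dict,
                  exclude: int | None = None) -> bool:
    at = g.atoms[a]
    if at.wildcard:
        return False
    el = pred.get("element")
    if el is not None:
        allowed = el if isinstance(el, list) else [el]
        if at.element not in allowed:
            return False
    if "aromatic" in pred and at.aromatic != pred["aromatic"]:
        return False
    if at.h_count < pred.get("min_h", 0):
        return False
    if "charge" in pred and at.charge != pred["charge"]:
        return False
    nbrs = [b for b in g.neighbors(a) if b != exclude]
    for sub in pred.get("neighbors", []):
        pool = [b for b in nbrs
                if _atom_matches(g, b, sub)
                and _order_matches(g.bond_order(a, b), sub.get("order"))]
        if not pool:
            return False
        nbrs.remove(pool[0])     # each sub-predicate binds a distinct atom
    for sub in pred.get("not_neighbors", []):
        for b in g.neighbors(a):
            if (_atom_matches(g, b, sub)
                    and _order_matches(g.bond_order(a, b),
                                       sub.get("order"))):
                return False
    return True


def enumerate_sites(reaction: TailoringReaction,
                    g: MolecularGraph) -> list[tuple]:
    """All (atom,) or (atom, partner) sites matching the predicate,
    in canonical (ascending atom-id) order."""
    pred = reaction.site
    partner_pred = pred.get("partner")
    sites: list[tuple] = []
    for a in g.atom_ids():
        if not _atom_matches(g, a, pred):
            continue
        if partner_pred is None:
            sites.append((a,))
        else:
            for b in g.neighbors(a):
                if (_atom_matches(g, b, partner_pred)
                        and _order_matches(g.bond_order(a, b),
                                           partner_pred.get("order"))):
                    sites.append((a, b))
                    break            # one canonical partner per site atom
    return sites


def _site_valid(reaction: TailoringReaction, g: MolecularGraph,
                site: tuple) -> bool:
    if any(a not in g.atoms for a in site):
        return False
    a = site[0]
    if not _atom_matches(g, a, reaction.site):
        return False
    partner_pred = reaction.site.get("partner")
    if partner_pred is not None:
        b = site[1]
        if b not in g.neighbors(a):
            return False
        if not _atom_matches(g, b, partner_pred):
            return False
        if not _order_matches(g.bond_order(a, b), partner_pred.get("order")):
            return False
    return True


def _resolve(ref: str, g: MolecularGraph, site: tuple,
             frag_map: dict[str, int] | None) -> int:
    if ref == "site":
        return site[0]
    if ref == "site.partner":
        if len(site) < 2:
            raise ReactionApplicationError("site has no partner")
        return site[1]
    if ref.startswith("site."):
        element = ref.split(".", 1)[1]
        exclude = site[1] if len(site) > 1 else None
        for b in g.neighbors(site[0]):
            if b != exclude and g.atoms[b].element == element:
                return b
        raise ReactionApplicationError(f"no {element} neighbour of site")
    if ref.startswith("frag."):
        if frag_map is None:
            raise ReactionApplicationError("step references a fragment "
                                           "but none was consumed")
        name = ref.split(".", 1)[1]
        if name not in frag_map:
            raise ReactionApplicationError(f"unknown fragment atom {name!r}")
        return frag_map[name]
    raise ReactionApplicationError(f"unresolvable operand {ref!r}")


def apply_reaction(reaction: TailoringReaction, g: MolecularGraph,
                   site: tuple, pool: dict[str, int],
                   kb: Knowledgebase) -> MolecularGraph:
    """Apply one tailoring reaction at one site, returning a new graph.

    The consumed fragment (if any) is unioned in first and removed from
    the pool; transformation steps then run in order with full hydrogen
    bookkeeping.  Raises :class:`ReactionApplicationError` on a valence
    violation (callers skip the site with a warning).
    """
    if not _site_valid(reaction, g, site):
        raise ReactionApplicationError(
            f"site {site} does not satisfy {reaction.id}")
    work = g.copy()
    frag_map: dict[str, int] | None = None
    before = work.heavy_atom_count()
    frag_atoms = 0
    if reaction.consumes_fragment:
        if pool.get(reaction.consumes_fragment, 0) < 1:
            raise ReactionApplicationError(
                f"fragment {reaction.consumes_fragment!r} not in pool")
        fragment = kb.monomers[reaction.consumes_fragment]
        fgraph = fragment.graph()
        frag_atoms = fgraph.heavy_atom_count()
        mapping = work.union(fgraph)
        frag_map = {name: mapping[idx]
                    for name, idx in fragment.attachments.items()}
        if not frag_map:
            frag_map = {"head": mapping[min(mapping)]}
    try:
        for step in reaction.steps:
            a = _resolve(step.a, work, site, frag_map)
            if step.op == "remove_atom":
                work.excise_atom(a)
                continue
            b = _resolve(step.b, work, site, frag_map)
            if step.op == "add_bond":
                work.form_bond(a, b, step.order or 1)
            elif step.op == "remove_bond":
                work.cleave_bond(a, b)
            elif step.op == "set_bond_order":
                work.change_bond_order(a, b, step.order)
    except ValenceError as exc:
        raise ReactionApplicationError(
            f"{reaction.id} at {site}: {exc}") from exc
    if work.heavy_atom_count() > before + frag_atoms:
        raise ReactionApplicationError(
            f"{reaction.id} increased heavy-atom count")
    if reaction.consumes_fragment:
        pool[reaction.consumes_fragment] -= 1
    return work


# ---------------------------------------------------------------------
# plan-space enumeration and sampling
# ---------------------------------------------------------------------

def _subset_count(n: int, kmax: int) -> int:
    return sum(comb(n, k) for k in range(min(n, kmax) + 1))


def _unrank_subset(n: int, kmax: int, index: int) -> tuple[int, ...]:
    """The ``index``-th subset of range(n) with size 0..kmax, ordered by
    size then lexicographically."""
    for k in range(min(n, kmax) + 1):
        block = comb(n, k)
        if index < block:
            return _unrank_combination(n, k, index)
        index -= block
    raise IndexError("subset index out of range")


def _unrank_combination(n: int, k: int, index: int) -> tuple[int, ...]:
    out: list[int] = []
    x = 0
    while k > 0:
        rest = comb(n - x - 1, k - 1)
        if index < rest:
            out.append(x)
            k -= 1
        else:
            index -= rest
        x += 1
    return tuple(out)


def _scaffold_component(g: MolecularGraph,
                        scaffold_ids: set[int]) -> MolecularGraph:
    comps = g.connected_components()
    if len(comps) == 1:
        return g
    best = max(comps, key=lambda c: (len(c & scaffold_ids), len(c)))
    return g.subgraph(best)


def _realize(scaffold: MolecularGraph, reactions: list[TailoringReaction],
             site_sets: list[list[tuple]], subset_ids: list[tuple[int, ...]],
             pool: dict[str, int], kb: Knowledgebase) -> MolecularGraph:
    work = scaffold
    local_pool = dict(pool)
    for rxn, sites, chosen in zip(reactions, site_sets, subset_ids):
        for s in chosen:
            site = sites[s]
            try:
                work = apply_reaction(rxn, work, site, local_pool, kb)
            except ReactionApplicationError as exc:
                logger.warning("skipping %s: %s", rxn.id, exc)
    return work


def _predict_from_scaffolds(
        bgc_id: str, scaffolds: list[MolecularGraph],
        reactions: list[TailoringReaction], pool: dict[str, int],
        kb: Knowledgebase, cap: int, seed: int,
        kind: str) -> PredictionSet:
    per_scaffold = []
    total = 0
    for g in scaffolds:
        site_sets = [enumerate_sites(r, g) for r in reactions]
        sizes = [_subset_count(len(s), r.max_applications)
                 for s, r in zip(site_sets, reactions)]
        space = 1
        for s in sizes:
            space *= s
        per_scaffold.append((g, site_sets, sizes, space))
        total += space

    sampled = total > cap
    if sampled:
        rng = np.random.default_rng(seed)
        picks = sorted(int(i) for i in
                       rng.choice(total, size=cap, replace=False))
    else:
        picks = list(range(total))

    smiles: list[str] = []
    seen: set[str] = set()
    offset = 0
    per_iter = iter(per_scaffold)
    g, site_sets, sizes, space = next(per_iter)
    for index in picks:
        while index >= offset + space:
            offset += space
            g, site_sets, sizes, space = next(per_iter)
        rem = index - offset
        subset_ids = []
        for s_len, rxn, size in zip(site_sets, reactions, sizes):
            rem, sub_index = divmod(rem, size)
            subset_ids.append(_unrank_subset(
                len(s_len), rxn.max_applications, sub_index))
        scaffold_ids = set(g.atoms)
        result = _realize(g, reactions, site_sets, subset_ids, pool, kb)
        result = _scaffold_component(result, scaffold_ids)
        cs = write_smiles(result)
        if cs not in seen:
            seen.add(cs)
            smiles.append(cs)
    return PredictionSet(bgc_id=bgc_id, structures=smiles,
                         plan_space_size=total, sampled=sampled,
                         seed=seed, cap=cap, kind=kind)


def enumerate_products(bgc: Bgc, kb: Knowledgebase, cap: int = 100,
                       seed: int = 0) -> PredictionSet:
    """Enumerate (or uniformly sample) the products of a cluster's plan
    space, deduplicated by canonical SMILES.  At most ``cap`` structures
    are returned, matching the evaluation protocol."""
    pathway = derive_pathway(bgc, kb)
    if pathway.kind == "ripp":
        return ripp_products(pathway, kb, bgc.bgc_id, cap=cap, seed=seed)
    scaffolds = [g for _, g in assemble_scaffold(pathway.line, kb)]
    return _predict_from_scaffolds(
        bgc.bgc_id, scaffolds, pathway.reactions, pathway.pool, kb,
        cap, seed, kind="assembly_line")


def ripp_products(pathway: Pathway, kb: Knowledgebase, bgc_id: str,
                  cap: int = 100, seed: int = 0) -> PredictionSet:
    """Products for a RiPP cluster: every candidate core peptide enters
    the plan space, crossed with the modification reactions."""
    scaffolds = [build_peptide(core, kb) for core in pathway.ripp.cores]
    return _predict_from_scaffolds(
        bgc_id, scaffolds, pathway.reactions, pathway.pool, kb,
        cap, seed, kind="ripp")
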