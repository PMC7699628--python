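"""The bundled knowledgebase: domain models, monomer library, tailoring
reactions and cluster rules.

This is a deliberately small, representative stand-in for a production
library of profile HMMs and reaction classes: enough domain models and
reactions to exercise every code path (thiotemplated assembly lines,
RiPPs, glycosylation, a spread of tailoring chemistries) at desk scale.

Site predicates are a small declarative pattern grammar (dicts):

``element``      atom element symbol (or list of symbols)
``aromatic``     required aromatic flag
``min_h``        minimum implicit hydrogen count
``charge``       required formal charge
``neighbors``    list of sub-predicates, each of which must match a
                 distinct neighbour; a sub-predicate may carry ``order``
                 (required bond order; 1.5 denotes aromatic)
``not_neighbors``
                 list of sub-predicates no neighbour may match
``partner``      sub-predicate selecting a distinguished neighbour; when
                 present, a site is the (atom, partner) pair

Transformation step operands: ``site``, ``site.partner``,
``site.<Element>`` (lowest-id neighbour of the site with that element,
excluding the partner) and ``frag.<name>`` (named attachment point of
the consumed fragment).  Steps may change bond orders, add or remove
bonds, and remove atoms — never create atoms; new heavy atoms only ever
enter a structure by consuming a pooled reagent fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chem import MolecularGraph, parse_smiles

SCAFFOLD, TAILORING, PRECURSOR, OTHER_ROLE = (
    "scaffold", "tailoring", "precursor", "resistance-other")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Monomer:
    id: str
    smiles: str
    mclass: str                      # amino_acid | ketide_unit | sugar | fragment
    aa_letter: str | None = None
    attachments: dict[str, int] = field(default_factory=dict)
    _graph: MolecularGraph | None = None

    def graph(self) -> MolecularGraph:
        if self._graph is None:
            self._graph = parse_smiles(self.smiles)
            self._derive_attachments()
        return self._graph

    def _derive_attachments(self) -> None:
        g = self._graph
        assert g is not None
        att = dict(self.attachments)
        if self.mclass == "amino_acid":
            att.setdefault("n_terminus", _find_amine_n(g))
            att.setdefault("c_terminus", _find_carboxyl_c(g))
        elif self.mclass == "ketide_unit":
            att.setdefault("alpha", _find_alpha_c(g))
            att.setdefault("c_terminus", _find_carboxyl_c(g))
        elif self.mclass == "sugar":
            donor, donor_oh = _find_anomeric(g)
            att.setdefault("donor", donor)
            att.setdefault("donor_oh", donor_oh)
        self.attachments = att


def _find_amine_n(g: MolecularGraph) -> int:
    for a in g.atom_ids():
        at = g.atoms[a]
        if at.element == "N" and not at.aromatic and at.h_count >= 1:
            return a
    raise ValueError("no amine nitrogen found")


def _find_carboxyl_c(g: MolecularGraph) -> int:
    for a in g.atom_ids():
        if g.atoms[a].element != "C":
            continue
        has_dbl_o = any(g.atoms[b].element == "O" and g.bond_order(a, b) == 2
                        for b in g.neighbors(a))
        has_oh = any(g.atoms[b].element == "O" and g.bond_order(a, b) == 1
                     and g.atoms[b].h_count >= 1 for b in g.neighbors(a))
        if has_dbl_o and has_oh:
            return a
    raise ValueError("no carboxyl carbon found")


def _find_alpha_c(g: MolecularGraph) -> int:
    best, best_h = None, -1
    for a in g.atom_ids():
        at = g.atoms[a]
        if at.element == "C" and at.h_count > best_h:
            best, best_h = a, at.h_count
    if best is None:
        raise ValueError("no alpha carbon found")
    return best


def _find_anomeric(g: MolecularGraph) -> tuple[int, int]:
    for a in g.atom_ids():
        if g.atoms[a].element != "C":
            continue
        ring_o = hydroxyl_o = None
        for b in g.neighbors(a):
            nb = g.atoms[b]
            if nb.element != "O" or g.bond_order(a, b) != 1:
                continue
            if nb.h_count >= 1:
                hydroxyl_o = b
            elif g.degree(b) == 2:
                ring_o = b
        if ring_o is not None and hydroxyl_o is not None:
            return a, hydroxyl_o
    raise ValueError("no anomeric carbon found")


@dataclass
class ReactionStep:
    op: str                         # set_bond_order | add_bond | remove_bond | remove_atom
    a: str
    b: str | None = None
    order: int | None = None


@dataclass
class TailoringReaction:
    id: str
    site: dict
    steps: list[ReactionStep]
    max_applications: int = 1
    consumes_fragment: str | None = None

    def validate(self) -> None:
        allowed = {"set_bond_order", "add_bond", "remove_bond",
                   "remove_atom"}
        for step in self.steps:
            if step.op not in allowed:
                raise ValueError(
                    f"reaction {self.id}: illegal step {step.op!r} "
                    "(atom creation is never allowed)")
        if self.max_applications < 1:
            raise ValueError(f"reaction {self.id}: max_applications < 1")


@dataclass
class DomainModel:
    id: str
    family: str
    role: str
    consensus: str
    bit_threshold: float
    match_score: float = 2.0
    mismatch_score: float = -1.0
    signature_positions: list[int] = field(default_factory=list)
    substrate_map: dict[str, str] = field(default_factory=dict)
    module_flags: list[str] = field(default_factory=list)
    contributes_subgraph: str | None = None
    contributes_reactions: list[str] = field(default_factory=list)
    release: str | None = None      # scaffold models may set the release mode

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class ClusterRule:
    family: str
    required: list[list[str]]       # all-of over any-of domain families
    min_domains: int = 2
    max_gap_nt: int = 10000
    predictable: bool = True


@dataclass
class RippConfig:
    cleavage_motifs: list[str] = field(default_factory=lambda: ["GG"])
    fallback_window: int = 12


@dataclass
class Knowledgebase:
    models: dict[str, DomainModel]
    monomers: dict[str, Monomer]
    reactions: dict[str, TailoringReaction]
    rules: list[ClusterRule]
    ripp: RippConfig = field(default_factory=RippConfig)
    reaction_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reaction_order:
            self.reaction_order = list(self.reactions)

    def validate(self) -> None:
        for model in self.models.values():
            if not all(0 <= p < model.length
                       for p in model.signature_positions):
                raise ValueError(f"model {model.id}: bad signature position")
            for rid in model.contributes_reactions:
                if rid not in self.reactions:
                    raise ValueError(
                        f"model {model.id}: unknown reaction {rid!r}")
            if (model.contributes_subgraph is not None
                    and model.contributes_subgraph not in self.monomers):
                raise ValueError(
                    f"model {model.id}: unknown monomer "
                    f"{model.contributes_subgraph!r}")
            for sub in model.substrate_map.values():
                if sub not in self.monomers:
                    raise ValueError(
                        f"model {model.id}: unknown substrate {sub!r}")
        for rxn in self.reactions.values():
            rxn.validate()
            if (rxn.consumes_fragment is not None
                    and rxn.consumes_fragment not in self.monomers):
                raise ValueError(
                    f"reaction {rxn.id}: unknown fragment "
                    f"{rxn.consumes_fragment!r}")
        for rule in self.rules:
            if rule.min_domains < 1 or rule.max_gap_nt <= 0:
                raise ValueError(f"rule {rule.family}: bad thresholds")
        for mono in self.monomers.values():
            mono.graph()     # raises on unparseable SMILES

    def aa_monomer(self, letter: str) -> Monomer:
        """Monomer for an amino-acid letter; glycine for unknown letters."""
        for mono in self.monomers.values():
            if mono.aa_letter == letter:
                return mono
        return self.monomers["Gly"]

    def max_gap(self) -> int:
        return max((r.max_gap_nt for r in self.rules), default=10000)


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def _model_to_dict(m: DomainModel) -> dict:
    return {
        "id": m.id, "family": m.family, "role": m.role,
        "consensus": m.consensus, "bit_threshold": m.bit_threshold,
        "match_score": m.match_score, "mismatch_score": m.mismatch_score,
        "signature_positions": list(m.signature_positions),
        "substrate_map": dict(m.substrate_map),
        "module_flags": list(m.module_flags),
        "contributes_subgraph": m.contributes_subgraph,
        "contributes_reactions": list(m.contributes_reactions),
        "release": m.release,
    }


def save_knowledgebase(kb: Knowledgebase, path) -> None:
    doc = {
        "models": [_model_to_dict(m) for m in kb.models.values()],
        "monomers": [
            {"id": m.id, "smiles": m.smiles, "class": m.mclass,
             "aa_letter": m.aa_letter,
             "attachments": dict(m.attachments) if m.attachments else {}}
            for m in kb.monomers.values()],
        "reactions": [
            {"id": r.id, "site": r.site,
             "steps": [{k: v for k, v in
                        {"op": s.op, "a": s.a, "b": s.b,
                         "order": s.order}.items() if v is not None}
                       for s in r.steps],
             "max_applications": r.max_applications,
             "consumes_fragment": r.consumes_fragment}
            for r in kb.reactions.values()],
        "rules": [
            {"family": r.family, "required": r.required,
             "min_domains": r.min_domains, "max_gap_nt": r.max_gap_nt,
             "predictable": r.predictable}
            for r in kb.rules],
        "ripp": {"cleavage_motifs": kb.ripp.cleavage_motifs,
                 "fallback_window": kb.ripp.fallback_window},
        "reaction_order": kb.reaction_order,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_knowledgebase(path) -> Knowledgebase:
    doc = yaml.safe_load(Path(path).read_text())
    models = {}
    for d in doc.get("models", []):
        models[d["id"]] = DomainModel(
            id=d["id"], family=d["family"], role=d["role"],
            consensus=d["consensus"], bit_threshold=d["bit_threshold"],
            match_score=d.get("match_score", 2.0),
            mismatch_score=d.get("mismatch_score", -1.0),
            signature_positions=d.get("signature_positions", []),
            substrate_map=d.get("substrate_map", {}) or {},
            module_flags=d.get("module_flags", []) or [],
            contributes_subgraph=d.get("contributes_subgraph"),
            contributes_reactions=d.get("contributes_reactions", []) or [],
            release=d.get("release"))
    monomers = {}
    for d in doc.get("monomers", []):
        monomers[d["id"]] = Monomer(
            id=d["id"], smiles=d["smiles"], mclass=d["class"],
            aa_letter=d.get("aa_letter"),
            attachments=d.get("attachments", {}) or {})
    reactions = {}
    for d in doc.get("reactions", []):
        reactions[d["id"]] = TailoringReaction(
            id=d["id"], site=d["site"],
            steps=[ReactionStep(op=s["op"], a=s["a"], b=s.get("b"),
                                order=s.get("order"))
                   for s in d["steps"]],
            max_applications=d.get("max_applications", 1),
            consumes_fragment=d.get("consumes_fragment"))
    rules = [ClusterRule(family=d["family"], required=d["required"],
                         min_domains=d.get("min_domains", 2),
                         max_gap_nt=d.get("max_gap_nt", 10000),
                         predictable=d.get("predictable", True))
             for d in doc.get("rules", [])]
    ripp_doc = doc.get("ripp", {}) or {}
    kb = Knowledgebase(
        models=models, monomers=monomers, reactions=reactions, rules=rules,
        ripp=RippConfig(
            cleavage_motifs=ripp_doc.get("cleavage_motifs", ["GG"]),
            fallback_window=ripp_doc.get("fallback_window", 12)),
        reaction_order=doc.get("reaction_order", []))
    kb.validate()
    return kb


def default_knowledgebase_path() -> Path:
    return Path(__file__).parent / "data" / "knowledgebase.yaml"


def default_knowledgebase() -> Knowledgebase:
    return load_knowledgebase(default_knowledgebase_path())
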