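"""Physicochemical descriptors: MW, H-bond donors/acceptors, logP,
Bertz-style topological complexity, and the rule-of-five flag.

Conventions:

* ``hbd`` counts hydrogens attached to N or O (the original rule-of-five
  OH+NH count); ``hba`` counts N and O atoms.
* ``logp`` is a bundled atom-contribution sum over coarse Crippen-style
  classes.  It is approximate by design: only distribution and rank-order
  comparisons use it.
* ``bertz`` combines a bonding-information term over "connections" (pairs
  of bonds sharing an atom, counted with bond-order multiplicity and
  classified by the elements involved) with a heteroatom-distribution
  information term.  Several variants of the index exist in the
  literature; this one is validated for rank order against an external
  toolkit, not for absolute values.

Wildcard atoms have no defined mass or contributions, so descriptor
computation on a graph containing ``[*]`` is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .graph import AROMATIC, MolecularGraph

ATOMIC_WEIGHTS = {
    "H": 1.008, "B": 10.812, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.067, "Cl": 35.453, "Br": 79.904,
    "I": 126.904, "Se": 78.96,
}

# coarse per-atom logP contributions (hydrophobic positive)
_LOGP_ATOM = {
    "C": 0.14, "B": 0.0, "N": -0.60, "O": -0.55, "P": -0.50, "S": 0.25,
    "F": 0.20, "Cl": 0.60, "Br": 0.85, "I": 1.10, "Se": 0.25,
}
_LOGP_AROMATIC_C = 0.29
_LOGP_H = 0.11


class WildcardError(ValueError):
    """Descriptors are undefined for structures containing wildcards."""


@dataclass(frozen=True)
class DescriptorRecord:
    mw: float
    hbd: int
    hba: int
    logp: float
    bertz: float
    lipinski_pass: bool


def _require_no_wildcards(g: MolecularGraph) -> None:
    if any(at.wildcard for at in g.atoms.values()):
        raise WildcardError("graph contains wildcard atoms")


def molecular_weight(g: MolecularGraph) -> float:
    _require_no_wildcards(g)
    mw = 0.0
    for at in g.atoms.values():
        mw += ATOMIC_WEIGHTS[at.element] + at.h_count * ATOMIC_WEIGHTS["H"]
    return mw


def h_bond_donors(g: MolecularGraph) -> int:
    return sum(at.h_count for at in g.atoms.values()
               if at.element in ("N", "O"))


def h_bond_acceptors(g: MolecularGraph) -> int:
    return sum(1 for at in g.atoms.values() if at.element in ("N", "O"))


def logp(g: MolecularGraph) -> float:
    _require_no_wildcards(g)
    total = 0.0
    for at in g.atoms.values():
        if at.element == "C" and at.aromatic:
            total += _LOGP_AROMATIC_C
        else:
            total += _LOGP_ATOM.get(at.element, 0.0)
        total += at.h_count * _LOGP_H
    return total


def _plogp_sum(counts: list[int]) -> float:
    return sum(n * math.log2(n) for n in counts if n > 0)


def bertz(g: MolecularGraph) -> float:
    _require_no_wildcards(g)
    # bonding term: connections = pairs of bond "slots" sharing an atom,
    # where a bond of order m occupies m slots (aromatic counts as 2)
    mult = {1: 1, 2: 2, 3: 3}
    classes: dict[tuple, int] = {}
    total = 0
    for a in g.atom_ids():
        slots: list[tuple[int, str]] = []
        for b in g.neighbors(a):
            order = g.bond_order(a, b)
            m = 2 if order == AROMATIC else mult[int(order)]
            slots.append((m, g.atoms[b].element))
        for (m1, e1), (m2, e2) in combinations(slots, 2):
            weight = m1 * m2
            key = (g.atoms[a].element, tuple(sorted([(m1, e1), (m2, e2)])))
            classes[key] = classes.get(key, 0) + weight
            total += weight
    if total > 0:
        c_bond = 2 * total * math.log2(total) - _plogp_sum(
            list(classes.values()))
    else:
        c_bond = 0.0
    # heteroatom-distribution term over heavy-atom element counts
    elem_counts: dict[str, int] = {}
    for at in g.atoms.values():
        elem_counts[at.element] = elem_counts.get(at.element, 0) + 1
    n_heavy = len(g)
    if n_heavy > 1 and len(elem_counts) > 1:
        c_het = n_heavy * math.log2(n_heavy) - _plogp_sum(
            list(elem_counts.values()))
    else:
        c_het = 0.0
    return c_bond + c_het


def descriptors(g: MolecularGraph) -> DescriptorRecord:
    _require_no_wildcards(g)
    mw = molecular_weight(g)
    hbd = h_bond_donors(g)
    hba = h_bond_acceptors(g)
    lp = logp(g)
    bz = bertz(g)
    ok = mw <= 500 and hbd <= 5 and hba <= 10 and lp <= 5
    return DescriptorRecord(mw=mw, hbd=hbd, hba=hba, logp=lp, bertz=bz,
                            lipinski_pass=ok)
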