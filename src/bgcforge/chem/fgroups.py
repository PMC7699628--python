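"""Unbiased functional-group extraction.

Implements the marking-and-merging procedure of Ertl-style functional
group perception, without any prespecified group list:

1. mark every heteroatom (anything other than carbon);
2. mark carbons doubly or triply bonded to a heteroatom (carbonyl,
   imine, nitrile, thiocarbonyl, ...);
3. mark acetal-like carbons: non-aromatic carbons with two or more
   single bonds to O, N or S;
4. mark carbons in non-aromatic carbon-carbon double or triple bonds;
5. mark all atoms of three-membered rings that contain a heteroatom
   (oxirane, aziridine, thiirane).

Connected marked atoms are merged into one group; each group is keyed by
the canonical SMILES of its induced subgraph (with hydrogen counts
cleared, so e.g. primary and secondary amines collapse to one amine key).
Aromatic ring heteroatoms are reported as single-atom groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .graph import AROMATIC, MolecularGraph
from .smiles import write_smiles

_HET = ("N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Se")


@dataclass(frozen=True)
class FunctionalGroupProfile:
    groups: tuple[tuple[str, int], ...]

    def counts(self) -> dict[str, int]:
        return dict(self.groups)

    def normalized(self) -> dict[str, float]:
        total = sum(n for _, n in self.groups)
        if total == 0:
            return {}
        return {k: n / total for k, n in self.groups}


def _marked_atoms(g: MolecularGraph) -> set[int]:
    marked: set[int] = set()
    for a in g.atom_ids():
        at = g.atoms[a]
        if at.wildcard:
            continue
        if at.element != "C":
            marked.add(a)
            continue
        for b in g.neighbors(a):
            nb = g.atoms[b]
            order = g.bond_order(a, b)
            if nb.element in _HET and order in (2, 3):
                marked.add(a)
            if (nb.element == "C" and order in (2, 3)
                    and not (at.aromatic and nb.aromatic)):
                marked.add(a)
        if not at.aromatic:
            single_het = sum(
                1 for b in g.neighbors(a)
                if g.bond_order(a, b) == 1
                and g.atoms[b].element in ("N", "O", "S"))
            if single_het >= 2:
                marked.add(a)
    # three-membered rings with a heteroatom
    for ring in g.rings():
        if len(ring) == 3 and any(g.atoms[a].element in _HET for a in ring):
            marked.update(ring)
    return marked


def functional_groups(g: MolecularGraph) -> FunctionalGroupProfile:
    marked = _marked_atoms(g)
    if not marked:
        return FunctionalGroupProfile(groups=())
    # connected components over marked atoms
    comps: list[set[int]] = []
    seen: set[int] = set()
    for start in sorted(marked):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in g.neighbors(cur):
                if nb in marked and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        comps.append(comp)
    keys = Counter()
    for comp in comps:
        sub = g.subgraph(comp)
        for a in sub.atom_ids():
            sub.atoms[a].h_count = 0
        keys[write_smiles(sub)] += 1
    return FunctionalGroupProfile(groups=tuple(sorted(keys.items())))
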