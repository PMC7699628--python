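"""Molecular graphs with an implicit-hydrogen model.

Atoms live in a dict keyed by persistent integer ids (never reused), so a
site reference survives deletion of unrelated atoms.  Bond orders are 1, 2,
3 or :data:`AROMATIC` (valence contribution 1.5).  All mutating operations
keep the hydrogen ledger consistent: forming a bond consumes implicit
hydrogens from both endpoints, breaking one restores them, and removing an
atom restores hydrogens to its neighbours.  Atom *creation* only happens at
parse time or by unioning in a pooled fragment graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

AROMATIC = 1.5

#: default valences used to fill implicit hydrogens (smallest value that
#: accommodates the bond-order sum is chosen)
DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

#: permissive per-element maximum valence for the consistency check
MAX_VALENCE: dict[str, int] = {
    "B": 3, "C": 4, "N": 5, "O": 3, "P": 5, "S": 6,
    "F": 1, "Cl": 3, "Br": 3, "I": 3, "Se": 6, "H": 1,
}


class MoleculeError(ValueError):
    """Raised for structurally invalid molecular graphs."""


class ValenceError(MoleculeError):
    """Raised when an operation would violate an atom's valence."""


@dataclass
class Atom:
    element: str
    charge: int = 0
    aromatic: bool = False
    h_count: int = 0
    wildcard: bool = False

    def copy(self) -> "Atom":
        return replace(self)


def _order_value(order) -> float:
    return 1.5 if order == AROMATIC else float(order)


class MolecularGraph:
    """Undirected chemical graph over :class:`Atom` nodes."""

    def __init__(self) -> None:
        self.atoms: dict[int, Atom] = {}
        self._adj: dict[int, dict[int, float]] = {}
        self._next_id = 0
        self.provenance: str | None = None

    # -- construction -------------------------------------------------

    def add_atom(self, atom: Atom) -> int:
        idx = self._next_id
        self._next_id += 1
        self.atoms[idx] = atom
        self._adj[idx] = {}
        return idx

    def add_bond(self, a: int, b: int, order) -> None:
        if a == b:
            raise MoleculeError("bond endpoints must be distinct")
        if a not in self.atoms or b not in self.atoms:
            raise MoleculeError("bond endpoint not in graph")
        if b in self._adj[a]:
            raise MoleculeError(f"duplicate bond {a}-{b}")
        self._adj[a][b] = order
        self._adj[b][a] = order

    # -- queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_ids(self) -> list[int]:
        return sorted(self.atoms)

    def neighbors(self, a: int) -> list[int]:
        return sorted(self._adj[a])

    def bond_order(self, a: int, b: int):
        return self._adj[a][b]

    def has_bond(self, a: int, b: int) -> bool:
        return b in self._adj.get(a, {})

    def bonds(self) -> Iterator[tuple[int, int, float]]:
        for a in sorted(self._adj):
            for b, order in sorted(self._adj[a].items()):
                if a < b:
                    yield a, b, order

    def degree(self, a: int) -> int:
        return len(self._adj[a])

    def order_sum(self, a: int) -> float:
        return sum(_order_value(o) for o in self._adj[a].values())

    def heavy_atom_count(self) -> int:
        return sum(1 for at in self.atoms.values() if not at.wildcard)

    def total_h(self) -> int:
        return sum(at.h_count for at in self.atoms.values())

    def connected_components(self) -> list[set[int]]:
        seen: set[int] = set()
        comps: list[set[int]] = []
        for start in sorted(self.atoms):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                cur = stack.pop()
                for nb in self._adj[cur]:
                    if nb not in comp:
                        comp.add(nb)
                        stack.append(nb)
            seen |= comp
            comps.append(comp)
        return comps

    # -- implicit-hydrogen bookkeeping ---------------------------------

    def default_h(self, a: int) -> int:
        """Implicit H a SMILES reader would assign from bonds alone."""
        atom = self.atoms[a]
        if atom.wildcard:
            return 0
        used = int(math.ceil(self.order_sum(a) - 1e-9))
        for v in DEFAULT_VALENCES.get(atom.element, (0,)):
            if used <= v:
                return v - used
        return 0

    def fill_implicit_h(self, a: int) -> None:
        self.atoms[a].h_count = self.default_h(a)

    def check_valence(self, a: int) -> None:
        atom = self.atoms[a]
        if atom.wildcard:
            return
        limit = MAX_VALENCE.get(atom.element)
        if limit is None:
            return
        # a ring-fusion aromatic atom has bond orders summing to
        # floor(1.5 * n_aromatic) in any Kekule assignment
        ar = sum(1 for o in self._adj[a].values() if o == AROMATIC)
        other = sum(_order_value(o) for o in self._adj[a].values()
                    if o != AROMATIC)
        total = math.floor(1.5 * ar) + other + atom.h_count
        if total > limit + 1e-9:
            raise ValenceError(
                f"valence {total} exceeds {limit} for {atom.element}")

    def validate(self) -> None:
        for a in self.atoms:
            if self.atoms[a].h_count < 0:
                raise MoleculeError(f"negative H count on atom {a}")
            self.check_valence(a)
        for a, b, _ in self.bonds():
            if a not in self.atoms or b not in self.atoms:
                raise MoleculeError("dangling bond")

    # -- chemistry-aware mutation --------------------------------------

    def _take_h(self, a: int, n: int) -> None:
        atom = self.atoms[a]
        if atom.wildcard:
            return
        if atom.h_count < n:
            raise ValenceError(
                f"atom {a} ({atom.element}) lacks {n} hydrogens")
        atom.h_count -= n

    def _give_h(self, a: int, n: int) -> None:
        if not self.atoms[a].wildcard:
            self.atoms[a].h_count += n

    def form_bond(self, a: int, b: int, order: int = 1) -> None:
        """Create a bond, consuming ``order`` implicit H on each endpoint."""
        if self.has_bond(a, b):
            raise MoleculeError(f"bond {a}-{b} already exists")
        n = int(_order_value(order)) if order != AROMATIC else 1
        self._take_h(a, n)
        try:
            self._take_h(b, n)
        except ValenceError:
            self._give_h(a, n)
            raise
        self.add_bond(a, b, order)

    def cleave_bond(self, a: int, b: int) -> None:
        """Delete a bond, restoring implicit hydrogens to both endpoints."""
        order = self._adj[a].pop(b)
        self._adj[b].pop(a)
        n = int(round(_order_value(order)))
        self._give_h(a, n)
        self._give_h(b, n)

    def change_bond_order(self, a: int, b: int, order: int) -> None:
        old = int(round(_order_value(self._adj[a][b])))
        new = int(round(_order_value(order)))
        delta = new - old
        if delta > 0:
            self._take_h(a, delta)
            try:
                self._take_h(b, delta)
            except ValenceError:
                self._give_h(a, delta)
                raise
        elif delta < 0:
            self._give_h(a, -delta)
            self._give_h(b, -delta)
        self._adj[a][b] = order
        self._adj[b][a] = order

    def excise_atom(self, a: int) -> None:
        """Remove an atom (and its implicit H), restoring H to neighbours."""
        for nb, order in list(self._adj[a].items()):
            self._adj[nb].pop(a)
            self._give_h(nb, int(round(_order_value(order))))
        del self._adj[a]
        del self.atoms[a]

    # -- structural helpers --------------------------------------------

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph()
        g._next_id = self._next_id
        g.provenance = self.provenance
        g.atoms = {i: at.copy() for i, at in self.atoms.items()}
        g._adj = {i: dict(nbrs) for i, nbrs in self._adj.items()}
        return g

    def union(self, other: "MolecularGraph") -> dict[int, int]:
        """Union a copy of ``other`` into this graph.

        Returns the mapping from ``other`` atom ids to new ids here.
        """
        mapping: dict[int, int] = {}
        for i in sorted(other.atoms):
            mapping[i] = self.add_atom(other.atoms[i].copy())
        for a, b, order in other.bonds():
            self.add_bond(mapping[a], mapping[b], order)
        return mapping

    def subgraph(self, keep: Iterable[int]) -> "MolecularGraph":
        keep = set(keep)
        g = MolecularGraph()
        mapping = {}
        for i in sorted(keep):
            mapping[i] = g.add_atom(self.atoms[i].copy())
        for a, b, order in self.bonds():
            if a in keep and b in keep:
                g.add_bond(mapping[a], mapping[b], order)
        return g

    def relabeled(self, perm: dict[int, int]) -> "MolecularGraph":
        """Return a copy with atom ids permuted (testing aid)."""
        g = MolecularGraph()
        g._next_id = max(perm.values()) + 1 if perm else 0
        g.atoms = {perm[i]: at.copy() for i, at in self.atoms.items()}
        g._adj = {perm[i]: {perm[j]: o for j, o in nbrs.items()}
                  for i, nbrs in self._adj.items()}
        return g

    def rings(self) -> list[list[int]]:
        """Smallest-set-of-smallest-rings approximation: cycle basis."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.atoms)
        g.add_edges_from((a, b) for a, b, _ in self.bonds())
        return [list(c) for c in nx.cycle_basis(g)]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<MolecularGraph atoms={len(self.atoms)} "
                f"bonds={sum(1 for _ in self.bonds())}>")
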