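"""SMILES reading and deterministic (canonical) writing.

Supported dialect: the organic subset (B C N O P S F Cl Br I), bracket
atoms with charge and explicit hydrogen counts, branches, ring closures
(including ``%nn``), aromatic lowercase atoms, the wildcard ``[*]`` / ``*``,
dot-separated components, and explicit bond symbols ``- = # :``.  Stereo
markers (``/ \\ @``) are accepted and discarded: configurations such as
glycosidic-bond stereochemistry cannot be inferred from primary sequence,
so the whole package works on constitution only.

The writer produces a canonical string via invariant-based refinement of
atom ranks, so two graphs that are isomorphic (including hydrogen counts,
charges and aromatic flags) serialize identically.
"""

from __future__ import annotations

import re

from .graph import AROMATIC, Atom, MoleculeError, MolecularGraph

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
AROMATIC_SYMBOLS = {"b", "c", "n", "o", "p", "s"}
#: explicit hydrogen atoms are not representable: H lives in counts only
KNOWN_ELEMENTS = ORGANIC_SUBSET | {"Se"}

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<symbol>\*|[A-Z][a-z]?|[a-z]{1,2})"
    r"(?P<chiral>@{1,2}(?:TH\d|AL\d|SP\d|TB\d+|OH\d+)?)?"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+{1,3}|-{1,3}|\+\d+|-\d+)?"
    r"(?::(?P<map>\d+))?\]"
)

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": AROMATIC, "/": 1, "\\": 1}


class SmilesError(MoleculeError):
    """Raised for malformed SMILES input."""


def _parse_bracket(token: str) -> Atom:
    m = _BRACKET_RE.fullmatch(token)
    if m is None:
        raise SmilesError(f"malformed bracket atom {token!r}")
    symbol = m.group("symbol")
    if symbol == "*":
        atom = Atom(element="*", wildcard=True)
    elif symbol in AROMATIC_SYMBOLS:
        atom = Atom(element=symbol.upper(), aromatic=True)
    elif symbol in KNOWN_ELEMENTS:
        atom = Atom(element=symbol)
    else:
        raise SmilesError(f"unknown element {symbol!r}")
    h = m.group("hcount")
    if h is not None:
        atom.h_count = 1 if h == "H" else int(h[1:])
    c = m.group("charge")
    if c:
        if c in {"+", "++", "+++"}:
            atom.charge = len(c)
        elif c in {"-", "--", "---"}:
            atom.charge = -len(c)
        else:
            atom.charge = int(c)
    return atom


def parse_smiles(s: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Implicit hydrogens are filled from default valences for non-bracket
    atoms; bracket atoms keep their explicit H count (default 0).
    """
    if not s:
        raise SmilesError("empty SMILES")
    g = MolecularGraph()
    g.provenance = s
    prev: int | None = None
    pending_order = None  # explicit bond symbol awaiting next atom
    stack: list[int | None] = []
    ring_open: dict[int, tuple[int, object]] = {}
    bracket_atoms: set[int] = set()
    i = 0
    n = len(s)

    def attach(idx: int) -> None:
        nonlocal prev, pending_order
        if prev is not None:
            order = pending_order
            if order is None:
                order = (AROMATIC if g.atoms[prev].aromatic
                         and g.atoms[idx].aromatic else 1)
            g.add_bond(prev, idx, order)
        pending_order = None
        prev = idx

    def close_ring(num: int) -> None:
        nonlocal pending_order
        if prev is None:
            raise SmilesError("ring bond before any atom")
        if num in ring_open:
            other, order0 = ring_open.pop(num)
            order = pending_order if pending_order is not None else order0
            if order is None:
                order = (AROMATIC if g.atoms[prev].aromatic
                         and g.atoms[other].aromatic else 1)
            if other == prev:
                raise SmilesError(f"ring bond {num} closes on itself")
            g.add_bond(prev, other, order)
        else:
            ring_open[num] = (prev, pending_order)
        pending_order = None

    while i < n:
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise SmilesError("unclosed bracket atom")
            atom = _parse_bracket(s[i:j + 1])
            idx = g.add_atom(atom)
            bracket_atoms.add(idx)
            attach(idx)
            i = j + 1
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced parentheses")
            prev = stack.pop()
            i += 1
        elif ch in _BOND_ORDERS:
            pending_order = _BOND_ORDERS[ch]
            i += 1
        elif ch == ".":
            prev = None
            pending_order = None
            i += 1
        elif ch == "%":
            if i + 2 >= n or not s[i + 1:i + 3].isdigit():
                raise SmilesError("malformed %nn ring closure")
            close_ring(int(s[i + 1:i + 3]))
            i += 3
        elif ch.isdigit():
            close_ring(int(ch))
            i += 1
        elif ch == "*":
            idx = g.add_atom(Atom(element="*", wildcard=True))
            bracket_atoms.add(idx)
            attach(idx)
            i += 1
        else:
            # organic-subset atom, possibly two letters (Cl, Br)
            two = s[i:i + 2]
            if two in {"Cl", "Br"}:
                idx = g.add_atom(Atom(element=two))
                attach(idx)
                i += 2
            elif ch in ORGANIC_SUBSET and len(ch) == 1:
                idx = g.add_atom(Atom(element=ch))
                attach(idx)
                i += 1
            elif ch in AROMATIC_SYMBOLS:
                idx = g.add_atom(Atom(element=ch.upper(), aromatic=True))
                attach(idx)
                i += 1
            else:
                raise SmilesError(f"unexpected character {ch!r} at {i}")
    if stack:
        raise SmilesError("unbalanced parentheses")
    if ring_open:
        raise SmilesError(f"unclosed ring bonds: {sorted(ring_open)}")
    for idx in g.atom_ids():
        if idx not in bracket_atoms:
            g.fill_implicit_h(idx)
        g.check_valence(idx)
    return g


# ---------------------------------------------------------------------
# canonical writing
# ---------------------------------------------------------------------

def _initial_invariant(g: MolecularGraph, a: int) -> tuple:
    at = g.atoms[a]
    return (at.wildcard, at.element, at.aromatic, at.charge, at.h_count,
            g.degree(a), round(g.order_sum(a) * 2))


def _refine(g: MolecularGraph, ranks: dict[int, int]) -> dict[int, int]:
    ids = g.atom_ids()
    while True:
        keys = {}
        for a in ids:
            nbr = sorted((round(2 * (1.5 if g.bond_order(a, b) == AROMATIC
                                     else g.bond_order(a, b))), ranks[b])
                         for b in g.neighbors(a))
            keys[a] = (ranks[a], tuple(nbr))
        uniq = sorted(set(keys.values()))
        new = {a: uniq.index(keys[a]) for a in ids}
        if new == ranks:
            return ranks
        ranks = new


def _signature(g: MolecularGraph, a: int, ranks: dict[int, int]) -> tuple:
    """BFS-layer signature used to break residual rank ties."""
    seen = {a}
    layer = [a]
    sig = [ranks[a]]
    while layer:
        nxt: list[int] = []
        layer_sig = []
        for x in layer:
            for b in g.neighbors(x):
                if b not in seen:
                    seen.add(b)
                    nxt.append(b)
                layer_sig.append((ranks[x], ranks[b]))
        sig.append(tuple(sorted(layer_sig)))
        layer = nxt
    return tuple(sig)


def canonical_ranks(g: MolecularGraph) -> dict[int, int]:
    ids = g.atom_ids()
    inv = sorted({_initial_invariant(g, a) for a in ids})
    ranks = {a: inv.index(_initial_invariant(g, a)) for a in ids}
    ranks = _refine(g, ranks)
    while True:
        by_rank: dict[int, list[int]] = {}
        for a in ids:
            by_rank.setdefault(ranks[a], []).append(a)
        tied = sorted(r for r, members in by_rank.items() if len(members) > 1)
        if not tied:
            return ranks
        members = by_rank[tied[0]]
        # choose canonically among tied atoms; remaining ties are
        # automorphic, so the resulting string does not depend on the pick
        chosen = min(members, key=lambda a: _signature(g, a, ranks))
        ranks = {a: r * 2 for a, r in ranks.items()}
        ranks[chosen] -= 1
        ranks = _refine(g, ranks)


def _atom_token(g: MolecularGraph, a: int) -> str:
    at = g.atoms[a]
    if at.wildcard:
        return "[*]"
    symbol = at.element.lower() if at.aromatic else at.element
    needs_bracket = (
        at.element not in ORGANIC_SUBSET
        or at.charge != 0
        or g.default_h(a) != at.h_count
    )
    if not needs_bracket:
        return symbol
    h = ""
    if at.h_count == 1:
        h = "H"
    elif at.h_count > 1:
        h = f"H{at.h_count}"
    if at.charge == 0:
        c = ""
    elif at.charge == 1:
        c = "+"
    elif at.charge == -1:
        c = "-"
    else:
        c = f"{at.charge:+d}"
    return f"[{symbol}{h}{c}]"


def _bond_token(g: MolecularGraph, a: int, b: int) -> str:
    order = g.bond_order(a, b)
    if order == AROMATIC:
        return ""
    if order == 1:
        # explicit single bond between two aromatic atoms (e.g. biphenyl)
        if g.atoms[a].aromatic and g.atoms[b].aromatic:
            return "-"
        return ""
    return {2: "=", 3: "#"}[int(order)]


def _write_component(g: MolecularGraph, comp: set[int],
                     ranks: dict[int, int]) -> str:
    start = min(comp, key=lambda a: ranks[a])
    visited: set[int] = set()
    ring_bonds: dict[tuple[int, int], int] = {}
    counter = [0]

    # first pass: find ring-closure bonds via DFS tree
    tree: dict[int, list[int]] = {a: [] for a in comp}
    parent: dict[int, int | None] = {start: None}
    stack = [start]
    visited.add(start)
    while stack:
        cur = stack.pop()
        for nb in sorted(g.neighbors(cur), key=lambda x: ranks[x],
                         reverse=True):
            if nb in visited:
                if parent[cur] != nb:
                    key = (min(cur, nb), max(cur, nb))
                    if key not in ring_bonds:
                        counter[0] += 1
                        ring_bonds[key] = counter[0]
            else:
                visited.add(nb)
                parent[nb] = cur
                tree[cur].append(nb)
                stack.append(nb)

    for node in tree:
        tree[node].sort(key=lambda x: ranks[x])

    def ring_digit(num: int) -> str:
        return str(num) if num < 10 else f"%{num:02d}"

    out: list[str] = []

    def emit(cur: int) -> None:
        out.append(_atom_token(g, cur))
        closures = []
        for nb in g.neighbors(cur):
            key = (min(cur, nb), max(cur, nb))
            if key in ring_bonds:
                closures.append((ring_bonds[key], nb))
        for num, nb in sorted(closures):
            out.append(_bond_token(g, cur, nb) + ring_digit(num))
        children = tree[cur]
        for k, child in enumerate(children):
            last = k == len(children) - 1
            if not last:
                out.append("(")
            out.append(_bond_token(g, cur, child))
            emit(child)
            if not last:
                out.append(")")

    emit(start)
    return "".join(out)


def write_smiles(g: MolecularGraph) -> str:
    """Serialize a graph to a canonical SMILES string."""
    if len(g) == 0:
        raise MoleculeError("cannot write empty graph")
    ranks = canonical_ranks(g)
    parts = [_write_component(g, comp, ranks)
             for comp in g.connected_components()]
    return ".".join(sorted(parts))


def canonical_smiles(s_or_graph) -> str:
    """Canonical form of a SMILES string or graph."""
    g = (s_or_graph if isinstance(s_or_graph, MolecularGraph)
         else parse_smiles(s_or_graph))
    return write_smiles(g)
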