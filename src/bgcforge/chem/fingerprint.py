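"""Circular (ECFP-style) fingerprints and Tanimoto similarity.

The construction follows the extended-connectivity scheme: per-atom
invariants (element, charge, degree, hydrogen count, aromaticity) are
iteratively refined over neighbourhoods of radius 0..3 (diameter 6) and
every intermediate identifier is hashed into a fixed-length bit vector
(1024 bits by default).  The hash is BLAKE2b-based and therefore stable
across processes and platforms; it is not intended to reproduce the bit
assignments of any other toolkit — all similarity analyses in this package
are relative, so internal consistency is what matters.

Wildcard atoms contribute only their radius-0 identifier: a ``[*]`` marks a
site of uncertainty, and growing environments around it would hash
unknown context into the fingerprint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .graph import AROMATIC, MolecularGraph


def _stable_hash(parts: tuple) -> int:
    data = repr(parts).encode()
    return int.from_bytes(
        hashlib.blake2b(data, digest_size=8).digest(), "big")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint stored as the set of on-bit indices."""

    on_bits: frozenset[int]
    nbits: int = 1024
    radius: int = 3

    def to_array(self):
        import numpy as np

        arr = np.zeros(self.nbits, dtype=np.uint8)
        arr[list(self.on_bits)] = 1
        return arr

    def __len__(self) -> int:
        return self.nbits


def circular_fingerprint(g: MolecularGraph, radius: int = 3,
                         nbits: int = 1024) -> Fingerprint:
    if len(g) == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    ids = g.atom_ids()
    current: dict[int, int] = {}
    for a in ids:
        at = g.atoms[a]
        if at.wildcard:
            current[a] = _stable_hash(("*",))
        else:
            current[a] = _stable_hash(
                ("atom", at.element, at.charge, at.aromatic, at.h_count,
                 g.degree(a)))
    features: set[int] = set(current.values())
    for r in range(1, radius + 1):
        nxt: dict[int, int] = {}
        for a in ids:
            if g.atoms[a].wildcard:
                nxt[a] = current[a]
                continue
            env = sorted(
                (round(2 * (1.5 if g.bond_order(a, b) == AROMATIC
                            else g.bond_order(a, b))), current[b])
                for b in g.neighbors(a))
            nxt[a] = _stable_hash((r, current[a], tuple(env)))
            features.add(nxt[a])
        current = nxt
    return Fingerprint(frozenset(f % nbits for f in features),
                       nbits=nbits, radius=radius)


def tanimoto(fp1: Fingerprint, fp2: Fingerprint) -> float:
    """|intersection| / |union| over on bits; 0/0 is defined as 0."""
    if fp1.nbits != fp2.nbits:
        raise ValueError(
            f"fingerprint length mismatch: {fp1.nbits} vs {fp2.nbits}")
    union = len(fp1.on_bits | fp2.on_bits)
    if union == 0:
        return 0.0
    return len(fp1.on_bits & fp2.on_bits) / union
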