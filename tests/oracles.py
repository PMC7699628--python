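"""Independent oracles shared by the unit and acceptance suites.

These re-derive expected results by brute force (itertools enumeration,
permutation resampling) so the code paths under test are checked against
logic that does not share their enumeration/sampling machinery.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from bgcforge.chem import canonical_smiles
from bgcforge.predict import (ReactionApplicationError, apply_reaction,
                              enumerate_sites)


def oracle_enumerate(scaffolds, reactions, pool, kb):
    """Brute-force recursive enumeration of the whole plan space.

    Returns (set of canonical SMILES, exact plan count).
    """
    out = set()
    n_plans = 0
    for scaffold in scaffolds:
        site_sets = [enumerate_sites(r, scaffold) for r in reactions]
        subset_choices = []
        for r, sites in zip(reactions, site_sets):
            choices = []
            for k in range(min(len(sites), r.max_applications) + 1):
                choices.extend(combinations(range(len(sites)), k))
            subset_choices.append(choices)
        for plan in product(*subset_choices):
            n_plans += 1
            work = scaffold
            local_pool = dict(pool)
            for r, sites, chosen in zip(reactions, site_sets, plan):
                for idx in chosen:
                    try:
                        work = apply_reaction(r, work, sites[idx],
                                              local_pool, kb)
                    except ReactionApplicationError:
                        pass
            keep = max(work.connected_components(),
                       key=lambda c: (len(c & set(scaffold.atoms)),
                                      len(c)))
            out.add(canonical_smiles(work.subgraph(keep)))
    return out, n_plans


def paired_sign_flip_p(x, y, n_perm=10000, seed=0):
    """Permutation oracle for a paired location difference."""
    rng = np.random.default_rng(seed)
    d = np.asarray(x) - np.asarray(y)
    obs = abs(d.mean())
    flips = rng.choice([-1, 1], size=(n_perm, len(d)))
    null = np.abs((flips * d).mean(axis=1))
    return (1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1)


def studentized_permutation_p(x, y, statistic, n_perm=10000, seed=0):
    """Two-sample permutation oracle using ``statistic(x, y)``."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    obs = abs(statistic(x, y))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:len(x)], perm[len(x):])) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
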