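"""Evaluation machinery: Tanimoto accuracy against gold standards with a
random-pair null, functional-group divergence with bootstrap errors,
descriptor/diversity summaries, and the statistical tests used across
the pipeline.

Circular fingerprints tend to be sparse, so absolute Tc values are low
for any two non-identical molecules; significance is therefore always
judged against the distribution of Tc between predictions and the true
products of *non-matching* clusters ("random pairs").
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (circular_fingerprint, descriptors, functional_groups,
                   parse_smiles, tanimoto)

MW_FLOOR = 100.0


@dataclass
class GoldStandardEntry:
    bgc_id: str
    true_structures: list[str]
    family: str = ""
    activities: set[str] = field(default_factory=set)


def load_gold_standard(path) -> list[GoldStandardEntry]:
    """TSV with columns bgc_id, smiles (';'-separated), family,
    activities (';'-separated, may be empty)."""
    table = pd.read_csv(Path(path), sep="\t", dtype=str,
                        keep_default_na=False)
    entries = []
    seen = set()
    for row in table.itertuples(index=False):
        if row.bgc_id in seen:
            raise ValueError(f"duplicate bgc_id {row.bgc_id!r}")
        seen.add(row.bgc_id)
        smiles = [s for s in row.smiles.split(";") if s]
        for s in smiles:
            parse_smiles(s)
        entries.append(GoldStandardEntry(
            bgc_id=row.bgc_id, true_structures=smiles,
            family=getattr(row, "family", ""),
            activities={a for a in getattr(row, "activities", "").split(";")
                        if a}))
    return entries


# ---------------------------------------------------------------------
# Tc accuracy
# ---------------------------------------------------------------------

@dataclass
class TcSummary:
    bgc_id: str
    median_tc: float
    max_tc: float
    n_pred: int
    n_true: int


def _fingerprints(smiles_list, cache: dict | None = None):
    out = []
    for s in smiles_list:
        if cache is not None and s in cache:
            out.append(cache[s])
            continue
        fp = circular_fingerprint(parse_smiles(s))
        if cache is not None:
            cache[s] = fp
        out.append(fp)
    return out


def tc_summary(prediction_smiles: list[str], entry: GoldStandardEntry,
               cap: int = 100,
               _cache: dict | None = None) -> TcSummary | None:
    """Median and maximum Tc over all (prediction x true) pairs.

    Returns None for an empty prediction set (the cluster is counted as
    detected without a structure).
    """
    preds = prediction_smiles[:cap]
    if not preds or not entry.true_structures:
        return None
    pfps = _fingerprints(preds, _cache)
    tfps = _fingerprints(entry.true_structures, _cache)
    tcs = [tanimoto(p, t) for p in pfps for t in tfps]
    return TcSummary(bgc_id=entry.bgc_id,
                     median_tc=float(np.median(tcs)),
                     max_tc=float(max(tcs)),
                     n_pred=len(preds), n_true=len(entry.true_structures))


def random_pair_null(predictions: dict[str, list[str]],
                     gold: list[GoldStandardEntry],
                     cap: int = 100) -> list[float]:
    """Null Tc distribution: for each cluster, the median Tc between its
    predictions and the true structures of all non-matching clusters."""
    if len(gold) < 2:
        raise ValueError("need >= 2 gold entries for a random-pair null")
    cache: dict = {}
    null = []
    for entry in gold:
        preds = predictions.get(entry.bgc_id, [])[:cap]
        if not preds:
            continue
        pfps = _fingerprints(preds, cache)
        tcs = []
        for other in gold:
            if other.bgc_id == entry.bgc_id:
                continue
            tfps = _fingerprints(other.true_structures, cache)
            tcs.extend(tanimoto(p, t) for p in pfps for t in tfps)
        if tcs:
            null.append(float(np.median(tcs)))
    return null


def matched_vs_null(predictions: dict[str, list[str]],
                    gold: list[GoldStandardEntry], cap: int = 100):
    """Paired matched-median vs random-pair-median comparison."""
    cache: dict = {}
    matched, null = [], []
    for entry in gold:
        summ = tc_summary(predictions.get(entry.bgc_id, []), entry,
                          cap=cap, _cache=cache)
        if summ is None:
            continue
        matched.append(summ.median_tc)
    null = random_pair_null(predictions, gold, cap=cap)
    n = min(len(matched), len(null))
    return matched[:n], null[:n]


# ---------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    relative_effect: float | None = None
    small_sample_fallback: bool = False


def _mid_cdf(sample: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Normalized empirical mid-distribution of ``sample`` at ``points``."""
    less = np.searchsorted(np.sort(sample), points, side="left")
    leq = np.searchsorted(np.sort(sample), points, side="right")
    return (less + leq) / (2 * len(sample))


def brunner_munzel(x, y, paired: bool = False) -> TestResult:
    """Brunner-Munzel rank test of P(X < Y) + 0.5 P(X = Y) = 1/2.

    The paired variant uses the rank-based difference of placements with
    a t(n-1) reference.  With fewer than 10 observations per group the
    test's p-values are inflated, so a t-test (paired, or Welch for
    independent samples) is used instead and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if min(len(x), len(y)) < 2:
        raise ValueError("need >= 2 observations per group")

    if min(len(x), len(y)) < 10:
        if np.allclose(x, x[0]) and np.allclose(y, y[0]) and x[0] == y[0]:
            return TestResult(0.0, 1.0, "degenerate", 0.5, True)
        if paired:
            stat, p = stats.ttest_rel(x, y)
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=False)
        if math.isnan(p):
            stat, p = 0.0, 1.0
        return TestResult(float(stat), float(p),
                          "t-test", None, small_sample_fallback=True)

    if paired:
        n = len(x)
        fx_at_y = _mid_cdf(x, y)      # F_x evaluated at the y's
        gy_at_x = _mid_cdf(y, x)
        d = fx_at_y - gy_at_x
        p_hat = float(np.mean(fx_at_y))
        sd = float(np.std(d, ddof=1))
        if sd == 0:
            # degenerate placement variance: no effect at all, or
            # complete separation (every pair agrees in direction)
            if abs(p_hat - 0.5) < 1e-12:
                warnings.warn("zero variance in paired Brunner-Munzel")
                return TestResult(0.0, 1.0, "brunner-munzel-paired",
                                  p_hat)
            p = min(1.0, 2.0 * 0.5 ** n)     # exact sign-test bound
            return TestResult(math.copysign(math.inf, p_hat - 0.5),
                              p, "brunner-munzel-paired", p_hat)
        # mean(d) = 2(p_hat - 1/2); sd(d) estimates the sd of the
        # per-pair influence of (p_hat - 1/2) itself
        t = math.sqrt(n) * (p_hat - 0.5) / sd
        p = 2 * stats.t.sf(abs(t), df=n - 1)
        return TestResult(float(t), float(p), "brunner-munzel-paired",
                          p_hat)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.brunnermunzel(x, y)
    p_hat = float(np.mean(_mid_cdf(x, y)))
    if math.isnan(p):
        if abs(p_hat - 0.5) < 1e-12:
            warnings.warn("zero variance in Brunner-Munzel; p set to 1")
            return TestResult(0.0, 1.0, "brunner-munzel", 0.5)
        # complete separation: exact two-sided rank-permutation bound
        p = min(1.0, 2.0 / math.comb(len(x) + len(y), len(x)))
        return TestResult(math.copysign(math.inf, p_hat - 0.5), p,
                          "brunner-munzel", p_hat)
    return TestResult(float(stat), float(p), "brunner-munzel", p_hat)


def proportion_test(k1: int, n1: int, k2: int, n2: int):
    """2x2 chi-squared test of equal proportions, no continuity
    correction."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= k <= n:
            raise ValueError("k must lie in [0, n]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------
# functional-group divergence
# ---------------------------------------------------------------------

def _group_distribution(structures: list[str]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for s in structures:
        for key, n in functional_groups(parse_smiles(s)).groups:
            counts[key] = counts.get(key, 0) + n
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def _jsd(p: dict[str, float], q: dict[str, float]) -> float:
    """Jensen-Shannon divergence, base 2 (so bounded by [0, 1])."""
    keys = sorted(set(p) | set(q))
    if not keys:
        return 0.0
    pv = np.array([p.get(k, 0.0) for k in keys])
    qv = np.array([q.get(k, 0.0) for k in keys])
    return float(stats.entropy((pv + qv) / 2, base=2)
                 - (stats.entropy(pv, base=2)
                    + stats.entropy(qv, base=2)) / 2)


def functional_group_jsd(per_bgc_a: list[list[str]],
                         per_bgc_b: list[list[str]],
                         n_boot: int = 100,
                         seed: int = 0) -> tuple[float, float]:
    """JSD between the pooled functional-group distributions of two sets.

    One structure is sampled per cluster (seeded); the bootstrap
    resamples clusters to give the standard deviation of the estimate.
    """
    if not per_bgc_a or not per_bgc_b:
        raise ValueError("both structure sets must be non-empty")
    rng = np.random.default_rng(seed)
    pick_a = [lst[int(rng.integers(len(lst)))] for lst in per_bgc_a]
    pick_b = [lst[int(rng.integers(len(lst)))] for lst in per_bgc_b]
    point = _jsd(_group_distribution(pick_a), _group_distribution(pick_b))
    paired = len(pick_a) == len(pick_b)
    boots = []
    for _ in range(n_boot):
        ia = rng.integers(len(pick_a), size=len(pick_a))
        # when both sets cover the same clusters, resample them jointly,
        # so the bootstrap sd vanishes as the sets converge
        ib = ia if paired else rng.integers(len(pick_b),
                                            size=len(pick_b))
        boots.append(_jsd(
            _group_distribution([pick_a[i] for i in ia]),
            _group_distribution([pick_b[i] for i in ib])))
    return point, float(np.std(boots))


# ---------------------------------------------------------------------
# structure-set summaries
# ---------------------------------------------------------------------

def structure_set_metrics(structures: list[str],
                          reference_set: list[str] | None = None,
                          mw_floor: float = MW_FLOOR) -> dict:
    """Descriptor and diversity report for a set of predicted structures.

    Structures under ``mw_floor`` Da are removed first (tiny non-specific
    fragments carry no actionable information).  Internal diversity is
    each structure's median Tc to all others; similarity to a reference
    compound set is each structure's median Tc to that set.
    """
    graphs, kept = [], []
    for s in structures:
        g = parse_smiles(s)
        if any(a.wildcard for a in g.atoms.values()):
            continue
        if descriptors(g).mw >= mw_floor:
            graphs.append(g)
            kept.append(s)
    if not graphs:
        return {"n": 0, "empty": True}
    recs = [descriptors(g) for g in graphs]
    n = len(recs)
    p = sum(r.lipinski_pass for r in recs) / n
    fps = [circular_fingerprint(g) for g in graphs]
    diversity = []
    if n > 1:
        for i in range(n):
            others = [tanimoto(fps[i], fps[j]) for j in range(n) if j != i]
            diversity.append(float(np.median(others)))
    report = {
        "n": n,
        "empty": False,
        "structures": kept,
        "pct_lipinski": 100 * p,
        "pct_lipinski_se": 100 * math.sqrt(p * (1 - p) / n),
        "mw": [r.mw for r in recs],
        "hbd": [r.hbd for r in recs],
        "hba": [r.hba for r in recs],
        "logp": [r.logp for r in recs],
        "bertz": [r.bertz for r in recs],
        "internal_diversity": diversity,
    }
    if reference_set:
        rfps = [circular_fingerprint(parse_smiles(s))
                for s in reference_set]
        report["median_tc_to_reference"] = [
            float(np.median([tanimoto(f, r) for r in rfps])) for f in fps]
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float))
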