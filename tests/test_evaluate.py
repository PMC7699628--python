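"""Tc summaries, the random-pair null, rank tests, JSD, set metrics."""

import math

import numpy as np
import pytest
from scipy import stats

from bgcforge.chem import circular_fingerprint, parse_smiles, tanimoto
from bgcforge.evaluate import (GoldStandardEntry, brunner_munzel,
                               functional_group_jsd, matched_vs_null,
                               proportion_test, random_pair_null,
                               structure_set_metrics, tc_summary)
from bgcforge.evaluate import _jsd


MOLS = ["NCC(=O)O", "NC(C)C(=O)O", "NC(CO)C(=O)O", "c1ccccc1",
        "OC1OC(CO)C(O)C(O)C1O", "NC(CS)C(=O)O"]


class TestTcSummary:
    def test_identical_singletons(self):
        entry = GoldStandardEntry(bgc_id="a", true_structures=[MOLS[0]])
        s = tc_summary([MOLS[0]], entry)
        assert s.median_tc == s.max_tc == 1.0
        assert (s.n_pred, s.n_true) == (1, 1)

    def test_median_over_all_pairs(self):
        entry = GoldStandardEntry(bgc_id="a",
                                  true_structures=MOLS[3:5])
        preds = MOLS[:3]
        s = tc_summary(preds, entry)
        fps = {m: circular_fingerprint(parse_smiles(m)) for m in MOLS}
        pairs = sorted(tanimoto(fps[p], fps[t])
                       for p in preds for t in MOLS[3:5])
        assert len(pairs) == 6
        assert s.median_tc == pytest.approx(np.median(pairs))
        assert s.max_tc == max(pairs)
        assert s.median_tc <= s.max_tc

    def test_empty_predictions_give_none(self):
        entry = GoldStandardEntry(bgc_id="a", true_structures=[MOLS[0]])
        assert tc_summary([], entry) is None

    def test_cap_limits_predictions(self):
        entry = GoldStandardEntry(bgc_id="a", true_structures=[MOLS[0]])
        s = tc_summary([MOLS[1]] * 300, entry, cap=100)
        assert s.n_pred == 100


class TestRandomPairNull:
    def _gold(self, n=4):
        return [GoldStandardEntry(bgc_id=f"b{i}",
                                  true_structures=[MOLS[i]])
                for i in range(n)]

    def test_self_predictions_beat_null(self):
        gold = self._gold(5)
        preds = {e.bgc_id: list(e.true_structures) for e in gold}
        matched, null = matched_vs_null(preds, gold)
        assert all(m == 1.0 for m in matched)
        assert all(m > n for m, n in zip(matched, null))

    def test_two_entry_gold_counts(self):
        gold = self._gold(2)
        preds = {e.bgc_id: list(e.true_structures) for e in gold}
        null = random_pair_null(preds, gold)
        assert len(null) == 2

    def test_degenerate_identical_molecules(self):
        gold = [GoldStandardEntry(bgc_id=f"b{i}",
                                  true_structures=[MOLS[0]])
                for i in range(3)]
        preds = {e.bgc_id: [MOLS[0]] for e in gold}
        null = random_pair_null(preds, gold)
        assert null == [1.0, 1.0, 1.0]

    def test_single_entry_rejected(self):
        gold = self._gold(1)
        with pytest.raises(ValueError):
            random_pair_null({}, gold)


def paired_permutation_p(x, y, n_perm=10000, seed=0):
    """Sign-flip permutation oracle for a paired location difference."""
    rng = np.random.default_rng(seed)
    d = np.asarray(x) - np.asarray(y)
    obs = abs(d.mean())
    flips = rng.choice([-1, 1], size=(n_perm, len(d)))
    null = np.abs((flips * d).mean(axis=1))
    return (1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1)


def unpaired_permutation_p(x, y, n_perm=10000, seed=0):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    obs = abs(np.mean(x) - np.mean(y))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:len(x)].mean() - perm[len(x):].mean()) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


class TestBrunnerMunzel:
    def test_identical_paired_samples(self):
        x = np.arange(12, dtype=float)
        res = brunner_munzel(x, x, paired=True)
        assert res.relative_effect == pytest.approx(0.5)
        assert res.p_value == pytest.approx(1.0)

    def test_small_samples_take_t_branch(self):
        res = brunner_munzel([1, 2, 3, 4, 5], [2, 3, 4, 5, 6],
                             paired=True)
        assert res.small_sample_fallback
        assert res.method == "t-test"

    def test_unpaired_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1.5, 30)
        res = brunner_munzel(x, y)
        ref_stat, ref_p = stats.brunnermunzel(x, y)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_paired_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0.45, 0.6, 30)
        res = brunner_munzel(x, y, paired=True)
        p_perm = paired_permutation_p(x, y, seed=3)
        assert res.p_value == pytest.approx(p_perm, rel=0.35, abs=0.005)
        assert res.p_value < 0.05 and p_perm < 0.05

    def test_unpaired_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.7, 1, 30)
        res = brunner_munzel(x, y)
        p_perm = unpaired_permutation_p(x, y, n_perm=4000, seed=5)
        assert res.p_value == pytest.approx(p_perm, rel=0.5, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            brunner_munzel([1.0] * 12, [1.0] * 11, paired=True)


class TestProportionTest:
    def test_equal_proportions(self):
        chi2, p = proportion_test(50, 100, 50, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_value(self):
        # [[90,10],[10,90]]: chi2 = N(ad-bc)^2 / (r1 r2 c1 c2) = 128
        chi2, p = proportion_test(90, 100, 10, 100)
        assert chi2 == pytest.approx(128.0)
        assert p < 1e-20

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            proportion_test(5, 4, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(0, 0, 1, 10)


class TestJsd:
    def test_identical_sets_zero(self):
        per_bgc = [[m] for m in MOLS]
        jsd, sd = functional_group_jsd(per_bgc, per_bgc, n_boot=30,
                                       seed=1)
        assert jsd == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_one(self):
        a = [["CCO"]]          # hydroxyl only
        b = [["CCN"]]          # amine only
        jsd, _ = functional_group_jsd(a, b, n_boot=10, seed=1)
        assert jsd == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_two_category_case(self):
        p = {"x": 0.5, "y": 0.5}
        q = {"x": 0.9, "y": 0.1}

        def h(*vals):
            return -sum(v * math.log2(v) for v in vals if v)

        expected = h(0.7, 0.3) - (h(0.5, 0.5) + h(0.9, 0.1)) / 2
        assert _jsd(p, q) == pytest.approx(expected)

    def test_symmetry(self):
        p = {"x": 0.2, "y": 0.8}
        q = {"y": 0.5, "z": 0.5}
        assert _jsd(p, q) == pytest.approx(_jsd(q, p))
        assert 0 <= _jsd(p, q) <= 1


class TestStructureSetMetrics:
    def test_mw_floor_removes_small_fragments(self):
        report = structure_set_metrics(["NC(C)C(=O)O",      # 89 Da
                                        "NC(Cc1ccccc1)C(=O)O"])
        assert report["n"] == 1

    def test_identical_molecules_have_unit_diversity(self):
        report = structure_set_metrics(["NC(Cc1ccccc1)C(=O)O"] * 4)
        assert report["internal_diversity"] == [1.0] * 4

    def test_all_filtered_flags_empty(self):
        report = structure_set_metrics(["C", "CC"])
        assert report["empty"]

    def test_reference_similarity_column(self):
        report = structure_set_metrics(
            ["NC(Cc1ccccc1)C(=O)O"],
            reference_set=["NC(Cc1ccccc1)C(=O)O", "C1CCCCC1"])
        assert len(report["median_tc_to_reference"]) == 1
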