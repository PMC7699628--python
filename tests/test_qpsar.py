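"""QPSAR features, cross-validated training, DeLong/Fisher, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from bgcforge.chem import circular_fingerprint, parse_smiles
from bgcforge.qpsar import (FeatureMatrix, auc_vs_random,
                            build_domain_features,
                            build_fingerprint_features, calibrate_fdr,
                            compare_models, delong_one_sided,
                            fisher_combine, predict_activities, train_cv)


class TestFingerprintFeatures:
    def test_bit_set_in_two_of_ten_averages_to_point_two(self):
        sets = {"bgc1": ["CCl"] * 2 + ["C"] * 8}
        fm = build_fingerprint_features(sets)
        chloro_only = (circular_fingerprint(parse_smiles("CCl")).on_bits
                       - circular_fingerprint(parse_smiles("C")).on_bits)
        row = fm.values.loc["bgc1"]
        for bit in chloro_only:
            assert row[f"bit{bit}"] == pytest.approx(0.2)

    def test_single_structure_row_is_binary(self):
        fm = build_fingerprint_features({"b": ["CCO"]})
        vals = set(fm.values.loc["b"].unique())
        assert vals <= {0.0, 1.0}

    def test_shared_bits_average_to_one(self):
        fm = build_fingerprint_features({"b": ["CCO", "CCO", "CCO"]})
        on = circular_fingerprint(parse_smiles("CCO")).on_bits
        assert all(fm.values.loc["b", f"bit{i}"] == 1.0 for i in on)

    def test_empty_prediction_set_omitted(self):
        with pytest.warns(UserWarning, match="row omitted"):
            fm = build_fingerprint_features({"a": ["C"], "b": []})
        assert list(fm.values.index) == ["a"]

    def test_values_in_unit_interval(self):
        fm = build_fingerprint_features(
            {"b": ["CCO", "CCN", "CCS", "CC"]})
        assert ((fm.values.to_numpy() >= 0)
                & (fm.values.to_numpy() <= 1)).all()


class TestDomainFeatures:
    def test_counts_and_row_sums(self, kb):
        from bgcforge.simulate import (FixtureConfig, sample_cluster_spec,
                                       synthetic_bgc)
        rng = np.random.default_rng(0)
        cfg = FixtureConfig(seed=0)
        bgcs = [synthetic_bgc(sample_cluster_spec(
            rng, "nrps", f"b{i}", cfg), kb) for i in range(5)]
        fm = build_domain_features(bgcs, kb)
        assert fm.feature_mode == "domain_counts"
        for bgc in bgcs:
            assert fm.values.loc[bgc.bgc_id].sum() == len(bgc.hits)
            n_adenyl = sum(
                1 for h in bgc.hits
                if kb.models[h.model_id].family == "adenylation")
            assert fm.values.loc[bgc.bgc_id, "adenylation"] == n_adenyl


def separable_features(n=60, p=12, seed=0, flip=0.0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 0.2, size=(n, p))
    X[:, 0] += y * 3.0
    labels = y.copy()
    if flip:
        mask = rng.random(n) < flip
        labels[mask] = 1 - labels[mask]
    ids = [f"b{i}" for i in range(n)]
    fm = FeatureMatrix(values=pd.DataFrame(
        X, index=ids, columns=[f"f{j}" for j in range(p)]),
        feature_mode="fingerprint_avg")
    return fm, pd.Series(labels, index=ids)


class TestTrainCv:
    def test_separable_data_has_high_auc(self):
        fm, y = separable_features()
        model = train_cv(fm, y, "antibacterial", k=10, seed=1)
        assert model.cv_auc >= 0.99

    def test_permuted_labels_near_chance(self):
        fm, y = separable_features(n=80)
        rng = np.random.default_rng(6)
        aucs = []
        for _ in range(10):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            aucs.append(train_cv(fm, perm, "a", k=5, seed=2).cv_auc)
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_single_class_rejected(self):
        fm, y = separable_features()
        with pytest.raises(ValueError, match="single-class"):
            train_cv(fm, pd.Series(1, index=y.index), "a")

    def test_too_few_positives_rejected(self):
        fm, y = separable_features(n=60)
        y.iloc[:] = 0
        y.iloc[:5] = 1
        with pytest.raises(ValueError, match="per class"):
            train_cv(fm, y, "a", k=10)


class TestAucVsRandom:
    def test_same_distribution_not_significant(self):
        fm, y = separable_features(n=60)
        rng = np.random.default_rng(3)
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        model = train_cv(fm, perm, "a", k=5, seed=3)
        assert auc_vs_random(model) > 0.05

    def test_separated_scores_extreme_p(self):
        fm, y = separable_features(n=100)
        model = train_cv(fm, y, "a", k=10, seed=4)
        assert auc_vs_random(model) < 1e-10

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0.6, 0.15, 30),
                                 rng.normal(0.45, 0.15, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        p_exact = stats.mannwhitneyu(scores[:30], scores[30:],
                                     alternative="two-sided").pvalue
        n_perm, hits = 10000, 0
        obs = abs(roc_auc_score(labels, scores) - 0.5)
        for _ in range(n_perm):
            lp = rng.permutation(labels)
            if abs(roc_auc_score(lp, scores) - 0.5) >= obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert p_exact == pytest.approx(p_perm, rel=0.3, abs=0.005)


class TestDeLong:
    def test_identical_models_give_half(self):
        scores = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8])
        labels = np.array([0, 1, 0, 1, 0, 1])
        _, _, p = delong_one_sided(scores, scores, labels)
        assert p == 0.5

    def test_variance_matches_bruteforce_placements(self):
        scores_a = np.array([0.9, 0.8, 0.3, 0.1])
        scores_b = np.array([0.7, 0.2, 0.6, 0.4])
        labels = np.array([1, 1, 0, 0])

        def placements(s):
            x, y = s[labels == 1], s[labels == 0]
            v10 = [np.mean([(xi > yj) + 0.5 * (xi == yj) for yj in y])
                   for xi in x]
            v01 = [np.mean([(xi > yj) + 0.5 * (xi == yj) for xi in x])
                   for yj in y]
            return np.array(v10), np.array(v01)

        v10a, v01a = placements(scores_a)
        v10b, v01b = placements(scores_b)
        m = n = 2
        var = (np.cov(v10a, v10b)[0, 0] + np.cov(v10a, v10b)[1, 1]
               - 2 * np.cov(v10a, v10b)[0, 1]) / m \
            + (np.cov(v01a, v01b)[0, 0] + np.cov(v01a, v01b)[1, 1]
               - 2 * np.cov(v01a, v01b)[0, 1]) / n
        auc_a, auc_b, p = delong_one_sided(scores_a, scores_b, labels)
        assert auc_a == pytest.approx(
            float(np.mean(v10a)))
        z = (auc_a - auc_b) / math.sqrt(var)
        assert p == pytest.approx(float(stats.norm.sf(z)))

    def test_fisher_closed_form(self):
        chi2, p = fisher_combine([0.5] * 5)
        assert chi2 == pytest.approx(-2 * 5 * math.log(0.5))
        assert chi2 == pytest.approx(6.931, abs=0.001)
        assert p == pytest.approx(stats.chi2.sf(chi2, df=10))

    def test_compare_models_end_to_end(self):
        fm, y = separable_features(n=80)
        good = train_cv(fm, y, "a", k=5, seed=1)
        noise = FeatureMatrix(
            values=pd.DataFrame(
                np.random.default_rng(9).normal(size=(80, 12)),
                index=fm.values.index, columns=fm.values.columns),
            feature_mode="domain_counts")
        bad = train_cv(noise, y, "a", k=5, seed=1)
        res = compare_models({"a": good}, {"a": bad})
        assert res["per_activity"]["a"]["auc_a"] \
            > res["per_activity"]["a"]["auc_b"]
        assert res["combined_p"] < 0.05


class TestFdr:
    def _model_with_scores(self, scores, labels):
        from bgcforge.qpsar import TrainedActivityModel
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        return TrainedActivityModel(
            activity="a", classifier=None, feature_mode="fingerprint_avg",
            feature_columns=[], cv_scores=scores, cv_labels=labels,
            cv_auc=float(roc_auc_score(labels, scores)),
            cv_roc=(None, None, None))

    def test_separated_scores_choose_boundary(self):
        model = self._model_with_scores(
            [0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        t = calibrate_fdr(model, fdr=0.10)
        assert t == pytest.approx(0.7)   # smallest threshold with FDR 0
        assert not model.fdr_unachievable

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        scores = rng.random(10)
        labels = rng.integers(0, 2, 10)
        if labels.sum() in (0, 10):
            labels[0] = 1 - labels[0]
        model = self._model_with_scores(scores, labels)
        t = calibrate_fdr(model, fdr=0.25)
        feasible = []
        for cand in np.unique(scores):
            called = scores >= cand
            tp = int((called & (labels == 1)).sum())
            fp = int((called & (labels == 0)).sum())
            if tp + fp and fp / (tp + fp) <= 0.25:
                feasible.append(cand)
        if feasible:
            assert t == pytest.approx(min(feasible))
        else:
            assert model.fdr_unachievable

    def test_fdr_one_gives_minimum_score(self):
        model = self._model_with_scores(
            [0.9, 0.4, 0.3, 0.2], [1, 0, 1, 0])
        assert calibrate_fdr(model, fdr=1.0) \
            == pytest.approx(0.2)

    def test_unachievable_flagged(self):
        model = self._model_with_scores(
            [0.5, 0.6, 0.7, 0.8], [0, 0, 0, 1])
        calibrate_fdr(model, fdr=0.0)
        assert not model.fdr_unachievable   # top score calls 1 TP only
        model2 = self._model_with_scores(
            [0.8, 0.8, 0.8, 0.8], [1, 0, 1, 0])
        calibrate_fdr(model2, fdr=0.1)
        assert model2.fdr_unachievable


class TestPredictActivities:
    def test_multiple_and_empty_calls(self):
        fm, y = separable_features(n=60, seed=2)
        m1 = train_cv(fm, y, "a", k=5, seed=1)
        m2 = train_cv(fm, y, "b", k=5, seed=2)
        calibrate_fdr(m1)
        calibrate_fdr(m2)
        calls = predict_activities({"a": m1, "b": m2}, fm)
        both = calls[calls["a"] & calls["b"]]
        neither = calls[~calls["a"] & ~calls["b"]]
        assert len(both) > 0 and len(neither) > 0
        assert set(both["called"]) == {"a;b"}
        assert set(neither["called"]) == {""}

    def test_column_mismatch_rejected(self):
        fm, y = separable_features(n=60)
        model = train_cv(fm, y, "a", k=5, seed=1)
        other = FeatureMatrix(values=fm.values.rename(
            columns={"f0": "zzz"}), feature_mode="fingerprint_avg")
        with pytest.raises(ValueError, match="columns"):
            predict_activities({"a": model}, other)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(12)
    scores = rng.random(200)
    labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
    a1 = roc_auc_score(labels, scores)
    a2 = roc_auc_score(labels, np.exp(3 * scores))
    assert a1 == pytest.approx(a2)
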