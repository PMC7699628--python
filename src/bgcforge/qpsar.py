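"""Quantitative predicted structure-activity relationship (QPSAR)
modeling: predict the biological activity of a cluster's product from
the chemical fingerprints of its *predicted* structures.

Features per cluster are either (a) the per-bit mean of the 1024-bit
circular fingerprints over all predicted structures — a bit set in two
of ten structures contributes 0.2 — or (b) counts of biosynthetic
domain families, the genome-annotation baseline.  Each of the five
activities is an independent binary problem: a margin classifier with
probability outputs (default: RBF-kernel support vector classifier,
C=1, gamma='scale', Platt-calibrated probabilities) is evaluated by
stratified tenfold cross-validation, pooling out-of-fold scores into a
single ROC; the final model is refit on all data.  Decision thresholds
are calibrated to a 10% false-discovery rate on the pooled out-of-fold
scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .chem import circular_fingerprint, parse_smiles
from .knowledgebase import Knowledgebase

ACTIVITIES = ("antibacterial", "antifungal", "antiviral", "antitumor",
              "immunomodulatory")


@dataclass
class FeatureMatrix:
    values: pd.DataFrame          # rows: bgc ids; columns: feature ids
    feature_mode: str             # fingerprint_avg | domain_counts


def build_fingerprint_features(prediction_sets: dict[str, list[str]],
                               nbits: int = 1024) -> FeatureMatrix:
    """Per-cluster mean of each fingerprint bit over predicted structures.

    ``prediction_sets`` maps bgc id -> list of SMILES.  Clusters without
    structures are omitted with a warning.
    """
    rows = {}
    for bgc_id, smiles in prediction_sets.items():
        if not smiles:
            warnings.warn(f"{bgc_id}: no predicted structures; row omitted")
            continue
        acc = np.zeros(nbits)
        for s in smiles:
            fp = circular_fingerprint(parse_smiles(s), nbits=nbits)
            acc[list(fp.on_bits)] += 1
        rows[bgc_id] = acc / len(smiles)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"bit{i}" for i in range(nbits)])
    return FeatureMatrix(values=df, feature_mode="fingerprint_avg")


def build_domain_features(bgcs: list, kb: Knowledgebase) -> FeatureMatrix:
    """Counts of hits per domain family per cluster."""
    families = sorted({m.family for m in kb.models.values()})
    rows = {}
    for bgc in bgcs:
        counts = dict.fromkeys(families, 0)
        for hit in bgc.hits:
            counts[kb.models[hit.model_id].family] += 1
        rows[bgc.bgc_id] = [counts[f] for f in families]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=families)
    return FeatureMatrix(values=df, feature_mode="domain_counts")


@dataclass
class TrainedActivityModel:
    activity: str
    classifier: object
    feature_mode: str
    feature_columns: list[str]
    cv_scores: np.ndarray         # pooled out-of-fold probabilities
    cv_labels: np.ndarray
    cv_auc: float
    cv_roc: tuple                 # (fpr, tpr, thresholds)
    fdr_threshold: float = 1.0
    fdr_unachievable: bool = False
    train_seed: int = 0


def _default_backend(seed: int):
    svc = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    return CalibratedClassifierCV(svc, method="sigmoid", cv=5,
                                  ensemble=False)


def train_cv(features: FeatureMatrix, labels: pd.Series, activity: str,
             k: int = 10, seed: int = 0,
             backend_factory=None) -> TrainedActivityModel:
    """Stratified k-fold CV pooling out-of-fold probabilities, then a
    final refit on all data."""
    X = features.values.to_numpy(dtype=float)
    y = labels.reindex(features.values.index).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{activity}: labels are single-class")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"{activity}: need >= {k} examples per class for {k}-fold CV")
    factory = backend_factory or _default_backend
    oof = np.zeros(len(y))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in cv.split(X, y):
        clf = factory(seed)
        clf.fit(X[train_idx], y[train_idx])
        oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
    auc = float(roc_auc_score(y, oof))
    fpr, tpr, thresholds = roc_curve(y, oof)
    final = factory(seed)
    final.fit(X, y)
    return TrainedActivityModel(
        activity=activity, classifier=final,
        feature_mode=features.feature_mode,
        feature_columns=list(features.values.columns),
        cv_scores=oof, cv_labels=y, cv_auc=auc,
        cv_roc=(fpr, tpr, thresholds), train_seed=seed)


def auc_vs_random(model: TrainedActivityModel) -> float:
    """Wilcoxon rank-sum p-value for AUC = 0.5 (positives' scores vs
    negatives' scores)."""
    pos = model.cv_scores[model.cv_labels == 1]
    neg = model.cv_scores[model.cv_labels == 0]
    return float(stats.mannwhitneyu(pos, neg,
                                    alternative="two-sided").pvalue)


# ---------------------------------------------------------------------
# DeLong comparison of paired ROC curves, Fisher combination
# ---------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    x = scores[labels == 1]
    y = scores[labels == 0]
    # psi(X_i, Y_j) = 1 if X > Y, 0.5 if equal, 0 otherwise
    cmp = (x[:, None] > y[None, :]).astype(float)
    cmp += 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_one_sided(scores_a: np.ndarray, scores_b: np.ndarray,
                     labels: np.ndarray) -> tuple[float, float, float]:
    """One-sided DeLong test that AUC(A) > AUC(B) on paired scores.

    Returns (auc_a, auc_b, p).  Uses the placement-value covariance of
    the paired AUC estimates.
    """
    labels = np.asarray(labels, dtype=int)
    v10a, v01a, auc_a = _placements(np.asarray(scores_a, float), labels)
    v10b, v01b, auc_b = _placements(np.asarray(scores_b, float), labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    if var <= 0:
        p = 0.5 if auc_a == auc_b else (0.0 if auc_a > auc_b else 1.0)
        return auc_a, auc_b, p
    z = (auc_a - auc_b) / math.sqrt(var)
    return auc_a, auc_b, float(stats.norm.sf(z))


def fisher_combine(p_values: list[float]) -> tuple[float, float]:
    """Fisher's method: -2 sum(ln p) ~ chi-squared with 2m df."""
    ps = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    chi2 = float(-2 * np.log(ps).sum())
    return chi2, float(stats.chi2.sf(chi2, df=2 * len(ps)))


def compare_models(models_a: dict[str, TrainedActivityModel],
                   models_b: dict[str, TrainedActivityModel]) -> dict:
    """Per-activity one-sided DeLong tests (A more accurate than B),
    combined across activities by Fisher's method.

    Both model families must have been cross-validated on the same
    clusters with the same labels.
    """
    per_activity = {}
    ps = []
    for activity in models_a:
        a, b = models_a[activity], models_b[activity]
        if not np.array_equal(a.cv_labels, b.cv_labels):
            raise ValueError(f"{activity}: label vectors differ")
        auc_a, auc_b, p = delong_one_sided(a.cv_scores, b.cv_scores,
                                           a.cv_labels)
        per_activity[activity] = {"auc_a": auc_a, "auc_b": auc_b, "p": p}
        ps.append(p)
    chi2, p_comb = fisher_combine(ps)
    return {"per_activity": per_activity, "fisher_chi2": chi2,
            "combined_p": p_comb}


# ---------------------------------------------------------------------
# FDR calibration and prediction
# ---------------------------------------------------------------------

def calibrate_fdr(model: TrainedActivityModel,
                  fdr: float = 0.10) -> float:
    """Smallest probability threshold whose empirical out-of-fold FDR
    (FP / (FP + TP)) is <= ``fdr``.  If no threshold achieves it, the
    maximum observed score is stored and the model flagged."""
    scores, labels = model.cv_scores, model.cv_labels
    best = None
    for t in np.unique(scores):
        called = scores >= t
        tp = int((called & (labels == 1)).sum())
        fp = int((called & (labels == 0)).sum())
        if tp + fp == 0:
            continue
        if fp / (tp + fp) <= fdr:
            best = float(t)
            break        # unique scores ascending: first hit is smallest
    if best is None:
        model.fdr_threshold = float(scores.max())
        model.fdr_unachievable = True
    else:
        model.fdr_threshold = best
        model.fdr_unachievable = False
    return model.fdr_threshold


def predict_activities(models: dict[str, TrainedActivityModel],
                       features: FeatureMatrix) -> pd.DataFrame:
    """Per-cluster activity calls at each model's FDR threshold.

    Returns a frame with a probability and a boolean call per activity,
    plus a summary column: the set of called activities (possibly empty
    or multiple)."""
    out = pd.DataFrame(index=features.values.index)
    for activity, model in models.items():
        if list(features.values.columns) != model.feature_columns:
            raise ValueError(f"{activity}: feature columns do not match "
                             "the training matrix")
        proba = model.classifier.predict_proba(
            features.values.to_numpy(dtype=float))[:, 1]
        out[f"{activity}_p"] = proba
        out[activity] = proba >= model.fdr_threshold
    acts = [a for a in models]
    out["called"] = out[acts].apply(
        lambda row: ";".join(a for a in acts if row[a]), axis=1)
    return out


def train_all(features: FeatureMatrix, labels: pd.DataFrame, k: int = 10,
              seed: int = 0, fdr: float = 0.10,
              backend_factory=None) -> dict[str, TrainedActivityModel]:
    """One cross-validated, FDR-calibrated model per activity column."""
    models = {}
    for activity in labels.columns:
        model = train_cv(features, labels[activity], activity, k=k,
                         seed=seed, backend_factory=backend_factory)
        calibrate_fdr(model, fdr=fdr)
        models[activity] = model
    return models
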