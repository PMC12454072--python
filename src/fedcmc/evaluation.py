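"""Clinical-metrics and fairness evaluation suite.

ROC AUC (Mann-Whitney convention), DeLong confidence intervals and the
correlated-ROC DeLong test, Youden-index thresholding, confusion metrics,
PR-AUC, NRI/IDI reclassification statistics, decision-curve analysis, the
collaboration/model fairness summary, and a PCA projection helper for
inspecting core vs redundant samples.

Conventions used throughout: a prediction is positive when score >= the
threshold; AUC equals P(score+ > score-) + 0.5 * P(tie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvalReport",
    "FairnessReport",
    "roc_auc",
    "delong_ci",
    "delong_test",
    "youden_threshold",
    "confusion_metrics",
    "pr_auc",
    "nri_idi",
    "dca_curve",
    "fairness_report",
    "pca_projection",
    "make_report",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney U convention, ties count 1/2)."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


# ---------------------------------------------------------------------------
# DeLong machinery (structural components / midranks)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Per-sample structural components V10 (positives) and V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # P(neg < pos_i), ties half
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong normal-theory confidence interval, clipped to [0, 1].

    With zero estimated variance (e.g. perfect separation) the interval
    collapses to the point estimate and a warning is issued.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class for a DeLong CI")
    auc, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; CI collapses to the point", stacklevel=2)
        return float(auc), float(auc), float(auc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-tailed DeLong test for paired (correlated) ROC curves.

    Returns the p-value for AUC_a = AUC_b; identical score vectors give 1.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("paired scores must align with the labels")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# thresholding and confusion metrics
# ---------------------------------------------------------------------------

def youden_threshold(scores, labels) -> tuple[float, float]:
    """Cutpoint maximizing J = sensitivity + specificity - 1.

    Candidates are the observed score values (positive when score >= t);
    ties in J break toward the smallest such threshold.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    best_t, best_j = None, -np.inf
    for t in np.unique(s):  # ascending, so the smallest t wins ties
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return float(best_t), float(best_j)


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Counts and derived metrics at a threshold (positive iff score >= t)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "precision": precision,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, no interpolation)."""
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() == 0:
        raise ValueError("PR-AUC requires at least one positive sample")
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


# ---------------------------------------------------------------------------
# reclassification statistics
# ---------------------------------------------------------------------------

def nri_idi(scores_old, scores_new, labels, threshold: float) -> tuple[float, float]:
    """Categorical NRI at a threshold and the IDI, new model vs old.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    where up/down are threshold crossings from old to new; IDI is the gain
    in mean discrimination slope.
    """
    y = _check_binary(labels)
    old = np.asarray(scores_old, dtype=np.float64)
    new = np.asarray(scores_new, dtype=np.float64)
    if old.shape != new.shape or old.shape[0] != y.shape[0]:
        raise ValueError("paired scores must align with the labels")
    old_pos = old >= threshold
    new_pos = new >= threshold
    up = new_pos & ~old_pos
    down = ~new_pos & old_pos
    ev, nev = y == 1, y == 0
    nri = (up[ev].mean() - down[ev].mean()) + (down[nev].mean() - up[nev].mean())
    idi = (new[ev].mean() - new[nev].mean()) - (old[ev].mean() - old[nev].mean())
    return float(nri), float(idi)


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

def dca_curve(scores, labels, threshold_grid) -> dict[str, np.ndarray]:
    """Net benefit across threshold probabilities p_t.

    model: TP/n - (FP/n) * p_t / (1 - p_t) with positivity at score >= p_t;
    treat-all: prevalence - (1 - prevalence) * p_t / (1 - p_t); treat-none: 0.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    grid = np.asarray(threshold_grid, dtype=np.float64)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("threshold probabilities must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = grid / (1.0 - grid)
    nb, nb_all = [], []
    for pt, od in zip(grid, odds):
        pred = s >= pt
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb.append(tp - fp * od)
        nb_all.append(prev - (1.0 - prev) * od)
    return {
        "threshold": grid,
        "net_benefit": np.array(nb),
        "treat_all": np.array(nb_all),
        "treat_none": np.zeros_like(grid),
    }


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-center test metrics at the Youden-optimal threshold."""

    center_id: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    pr_auc: float
    f1: float
    counts: dict[str, int]
    dca: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "center_id": self.center_id,
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "threshold": self.threshold, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "pr_auc": self.pr_auc, "f1": self.f1,
        }
        d.update(self.counts)
        return d


def make_report(
    center_id: str,
    scores,
    labels,
    threshold: float | None = None,
    dca_grid=None,
) -> EvalReport:
    """Full per-center report; threshold defaults to the Youden optimum."""
    if threshold is None:
        threshold, _ = youden_threshold(scores, labels)
    auc, lo, hi = delong_ci(scores, labels)
    cm = confusion_metrics(scores, labels, threshold)
    if dca_grid is None:
        dca_grid = np.linspace(0.05, 0.95, 19)
    return EvalReport(
        center_id=center_id,
        auc=auc, ci_low=lo, ci_high=hi, threshold=float(threshold),
        accuracy=cm["accuracy"], sensitivity=cm["sensitivity"],
        specificity=cm["specificity"], pr_auc=pr_auc(scores, labels), f1=cm["f1"],
        counts={k: cm[k] for k in ("TP", "FP", "TN", "FN")},
        dca=dca_curve(scores, labels, dca_grid),
    )


@dataclass
class FairnessReport:
    """Collaboration-performance and model-fairness summary vs baselines."""

    auc_table: dict[str, dict[str, float]]  # algorithm -> center -> AUC
    performance_improvement_pct: float
    fairness_improvement_pct: float
    skipped_baselines: list[str] = field(default_factory=list)


def fairness_report(auc_table: Mapping[str, Mapping[str, float]]) -> FairnessReport:
    """Summarize fedcmc against baseline algorithms.

    performance improvement (%) = mean over baselines of the mean over
    centers of 100 * (AUC_fedcmc - AUC_baseline) / AUC_baseline;
    fairness improvement (%) = mean over baselines of
    100 * (sigma_baseline - sigma_fedcmc) / sigma_baseline, where sigma is
    the across-center AUC standard deviation (population sd). A baseline
    with sigma = 0 contributes no fairness term and is reported as skipped.
    """
    if "fedcmc" not in auc_table:
        raise ValueError("auc_table must contain a 'fedcmc' row")
    baselines = [a for a in auc_table if a != "fedcmc"]
    if not baselines:
        raise ValueError("auc_table must contain at least one baseline")
    centers = sorted(auc_table["fedcmc"])
    ours = np.array([auc_table["fedcmc"][c] for c in centers])
    perf_terms, fair_terms, skipped = [], [], []
    for b in baselines:
        if sorted(auc_table[b]) != centers:
            raise ValueError(f"baseline {b!r} does not cover the same centers")
        base = np.array([auc_table[b][c] for c in centers])
        perf_terms.append(np.mean(100.0 * (ours - base) / base))
        sigma_b = base.std()
        if sigma_b < 1e-12:  # all-equal baseline up to rounding
            warnings.warn(f"baseline {b!r} has zero AUC spread; fairness term skipped", stacklevel=2)
            skipped.append(b)
        else:
            fair_terms.append(100.0 * (sigma_b - ours.std()) / sigma_b)
    return FairnessReport(
        auc_table={a: dict(auc_table[a]) for a in auc_table},
        performance_improvement_pct=float(np.mean(perf_terms)),
        fairness_improvement_pct=float(np.mean(fair_terms)) if fair_terms else float("nan"),
        skipped_baselines=skipped,
    )


def pca_projection(feature_matrix: np.ndarray, out_dim: int = 2) -> np.ndarray:
    """Mean-centered projection onto the top principal axes.

    Constant feature columns are dropped (with a warning) before the
    decomposition; returns an (n, out_dim) coordinate array with component
    variances in non-increasing order.
    """
    X = np.asarray(feature_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] <= out_dim:
        raise ValueError("need n > out_dim samples in a 2-D feature matrix")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)", stacklevel=2)
        X = X[:, keep]
    return PCA(n_components=out_dim, svd_solver="full").fit_transform(X)
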