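"""Evaluation statistics: IoU, ROC/AUC, operating points, the DeLong paired
test and simple group comparisons.

The AUC is the Mann-Whitney statistic — the probability a random positive
case outscores a random negative one, ties counted one half.  Tie handling is
consequential here because pc-ASPECTS is integer valued.  The DeLong test
compares two correlated AUCs computed on the same cases using the
placement-value (structural component) covariance estimate and a two-sided
normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def iou(mask_a, mask_b) -> float:
    """Intersection over union |A∩B| / |A∪B| of two binary masks.

    Defined as 1.0 (with a warning) when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("both masks empty; IoU defined as 1.0")
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).ravel()
    if set(np.unique(y)) - {0, 1, False, True}:
        raise ValueError("labels must be binary 0/1 (1 = positive / poor prognosis)")
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one half.

    Equals the trapezoidal area under the ROC curve over all thresholds.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = sps.rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class ROCResult:
    """An ROC curve with its AUC and a chosen operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    positive_class: str = "poor"


def roc(scores, labels) -> ROCResult:
    """Full ROC point list (curve runs from (0,0) to (1,1)) plus the
    Mann-Whitney AUC and the Youden operating point."""
    from sklearn.metrics import roc_curve as _sk_roc

    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    fpr, tpr, thr = _sk_roc(y, s, drop_intermediate=False)
    res = ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc(s, y))
    res.threshold, res.sensitivity, res.specificity = operating_point(res)
    return res


def operating_point(roc_result: ROCResult, rule: str = "youden"):
    """Choose an ROC operating point.

    ``youden`` maximizes J = sensitivity + specificity - 1; ties are broken
    toward higher sensitivity, then toward the lower threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    if rule != "youden":
        raise ValueError(f"unknown operating-point rule {rule!r}")
    fpr, tpr, thr = roc_result.fpr, roc_result.tpr, roc_result.thresholds
    j = tpr - fpr
    best = 0
    for i in range(1, len(j)):
        if (
            j[i] > j[best] + 1e-12
            or (abs(j[i] - j[best]) <= 1e-12 and tpr[i] > tpr[best] + 1e-12)
            or (
                abs(j[i] - j[best]) <= 1e-12
                and abs(tpr[i] - tpr[best]) <= 1e-12
                and thr[i] < thr[best]
            )
        ):
            best = i
    return float(thr[best]), float(tpr[best]), float(1.0 - fpr[best])


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative):
    V10[i] = mean_j psi(pos_i, neg_j), psi = 1 if pos>neg, 0.5 if tie."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


@dataclass
class DeLongResult:
    """Paired comparison of two AUCs on the same cases."""

    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p_value: float

    def __str__(self):
        return (
            f"DeLong paired test: AUC_A={self.auc_a:.4f} AUC_B={self.auc_b:.4f} "
            f"dAUC={self.delta:+.4f} z={self.z:.3f} p={self.p_value:.4g}"
        )


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be evaluated on the same cases.  The variance of
    AUC_A - AUC_B is estimated from the empirical covariance of the placement
    values; the two-sided p comes from the normal reference z = dAUC/sqrt(var).
    A degenerate zero-variance comparison returns p = 1 when the AUCs are
    equal and raises otherwise.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != y.shape or b.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")

    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] - 2 * s10[0, 1] + s10[1, 1]) / m + (
        s01[0, 0] - 2 * s01[0, 1] + s01[1, 1]
    ) / n
    var = max(float(var), 0.0)
    delta = auc_a - auc_b
    if var == 0.0:
        if abs(delta) < 1e-12:
            return DeLongResult(auc_a, auc_b, delta, 0.0, 0.0, 1.0)
        raise ValueError("zero variance with unequal AUCs: degenerate comparison")
    z = delta / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, delta, var, float(z), min(p, 1.0))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, without continuity
    correction; returns (statistic, two-sided p)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


@dataclass
class TwoSampleSummary:
    """Mean ± SD per group with the Welch two-sample t test."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p_value: float

    def __str__(self):
        return (
            f"{self.mean_a:.2f} ± {self.sd_a:.2f} (n={self.n_a}) vs "
            f"{self.mean_b:.2f} ± {self.sd_b:.2f} (n={self.n_b}); "
            f"Welch t={self.t:.3f}, df={self.df:.1f}, p={self.p_value:.4g}"
        )


def two_sample_summary(values_a, values_b) -> TwoSampleSummary:
    """Group mean ± SD (ddof=1) and the Welch unequal-variance t test."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TwoSampleSummary(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=a.size,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=b.size,
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def plot_roc(results: dict[str, ROCResult], path=None):
    """Plot one or more ROC curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in results.items():
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC={r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
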