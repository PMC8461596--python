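"""Normality gating, ROC/AUC evaluation and detection-plane plots.

The Hotelling null assumes the (log mean, log variance) statistics of
normal images are bivariate Gaussian; a Shapiro-Wilk test on each
coordinate gates that parametric assumption.  Discrimination is measured
threshold-free by the area under the ROC curve of the Mahalanobis degree
of anomaly, computed with the Mann-Whitney rank formulation (ties counted
half) which equals the trapezoidal integral of the ROC curve.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .hotelling import HotellingModel, contour_levels
from .scoring import ScoreStat

__all__ = [
    "NormalityReport",
    "RocResult",
    "normality_gate",
    "roc_auc",
    "plot_detection_plane",
]

ANOMALY_LABEL = "Anomaly"


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk p-values for the two statistic coordinates."""

    p_log_mean: float
    p_log_var: float

    @property
    def passed(self) -> bool:
        return min(self.p_log_mean, self.p_log_var) > 0.05


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_normal: int
    n_anomaly: int


def normality_gate(stats: Sequence[ScoreStat]) -> NormalityReport:
    """Test Gaussianity of the log-mean and log-variance samples.

    A failed gate does not abort the pipeline -- the chi-square thresholds
    are then approximate -- but it is surfaced as a warning.
    """
    if len(stats) < 3:
        raise ValueError("invalid-input: Shapiro-Wilk needs at least 3 samples")
    lm = np.array([s.log_mean for s in stats])
    lv = np.array([s.log_var for s in stats])
    if np.ptp(lm) == 0 or np.ptp(lv) == 0:
        raise ValueError("invalid-input: constant sample, normality undefined")
    report = NormalityReport(
        p_log_mean=float(sps.shapiro(lm).pvalue),
        p_log_var=float(sps.shapiro(lv).pvalue),
    )
    if not report.passed:
        warnings.warn(
            "score statistics fail the Shapiro-Wilk gate (p <= 0.05); "
            "the Gaussian null of the Hotelling detector is suspect",
            stacklevel=2,
        )
    return report


def roc_auc(results: Sequence[tuple[float, str]]) -> RocResult:
    """ROC analysis of (a_value, label) pairs, anomalies as positives.

    AUC is computed by the Mann-Whitney rank formulation with half credit
    for ties; the swept curve itself comes from the standard cumulative
    construction and its trapezoidal integral equals the rank AUC.
    """
    scores = np.array([a for a, _ in results], dtype=float)
    labels = np.array([lab == ANOMALY_LABEL for _, lab in results])
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("invalid-input: ROC needs both classes present")
    ranks = sps.rankdata(scores)  # average ranks handle ties with half credit
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return RocResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc),
        n_normal=n_neg, n_anomaly=n_pos,
    )


def plot_detection_plane(
    stats: Sequence[ScoreStat],
    model: HotellingModel,
    probabilities: Sequence[float] = (0.30, 0.25, 0.20, 0.15, 0.10, 0.05),
    out_path: str | Path | None = None,
):
    """Scatter the statistic plane with nested detection-probability contours.

    Horizontal axis: log mean of the unregularized anomaly score; vertical
    axis: log variance.  Contours are the a(x') level sets back-calculated
    from each probability, nested with the smallest probability outermost.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.array([[s.log_mean, s.log_var] for s in stats])
    pad_x = 0.5 * max(np.ptp(X[:, 0]), 1.0)
    pad_y = 0.5 * max(np.ptp(X[:, 1]), 1.0)
    grid = (
        X[:, 0].min() - pad_x, X[:, 0].max() + pad_x,
        X[:, 1].min() - pad_y, X[:, 1].max() + pad_y,
    )
    cl = contour_levels(model, probabilities, grid)

    fig, ax = plt.subplots(figsize=(6, 5))
    levels = sorted(cl["levels"].values())
    cs = ax.contour(cl["x"], cl["y"], cl["a_surface"], levels=levels, colors="gray")
    ax.clabel(cs, fmt="%.2f", fontsize=7)
    is_anom = np.array([s.label == ANOMALY_LABEL for s in stats])
    ax.scatter(X[~is_anom, 0], X[~is_anom, 1], s=14, label="Normal", color="tab:blue")
    if is_anom.any():
        ax.scatter(X[is_anom, 0], X[is_anom, 1], s=14, label="Anomaly",
                   color="tab:red", marker="^")
    ax.set_xlabel("mean of unregularized anomaly score (log scale)")
    ax.set_ylabel("variance of unregularized anomaly score (log scale)")
    ax.legend(loc="best")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return Path(out_path)
    return fig
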