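"""Hotelling-theory anomaly detection on score-statistic vectors.

Normal-state statistic vectors x' = (log mean, log variance) are modeled
as a bivariate Gaussian with maximum-likelihood mean and covariance.  The
degree of anomaly of a test vector is the squared Mahalanobis distance

    a(x') = (x' - mu)^T Sigma^{-1} (x' - mu)

which under the fitted null is approximately chi-square distributed, so a
detection threshold can be back-calculated from a desired flagging
probability P as the (1 - P) chi-square quantile.  The default degrees of
freedom equal the dimension of x' (2); dof = 1 is available as an option.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import ScoreStat

__all__ = [
    "HotellingModel",
    "DetectionResult",
    "fit_hotelling",
    "mahalanobis_sq",
    "threshold_from_probability",
    "detect",
    "contour_levels",
    "save_hotelling",
    "load_hotelling",
    "write_detections",
]


@dataclass
class HotellingModel:
    """Fitted Gaussian null: ML mean/covariance plus chi-square dof."""

    mu_hat: np.ndarray
    sigma: np.ndarray
    dof: int
    n_fit: int

    def __post_init__(self) -> None:
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("covariance must be symmetric")
        # positive definiteness; also precompute the inverse
        try:
            self._sigma_inv = np.linalg.inv(self.sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate-covariance: singular Sigma") from exc
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("degenerate-covariance: Sigma not positive definite")


@dataclass(frozen=True)
class DetectionResult:
    frame_id: str
    label: str
    a_value: float
    threshold: float
    p_target: float
    decision: str


def _stat_matrix(stats: Sequence[ScoreStat]) -> np.ndarray:
    return np.array([[s.log_mean, s.log_var] for s in stats])


def fit_hotelling(stats: Sequence[ScoreStat], dof: int = 2) -> HotellingModel:
    """ML fit of the Gaussian null on (log mean, log variance) vectors.

    The covariance is the maximum-likelihood estimate (divide by n).  The
    fitting set should contain only Normal statistics: the method is
    normal-only learning, and the null calibrates the false-positive rate.
    """
    if len(stats) < 3:
        raise ValueError("invalid-input: need at least 3 statistics to fit")
    X = _stat_matrix(stats)
    mu = X.mean(axis=0)
    centered = X - mu
    sigma = centered.T @ centered / len(stats)
    if np.linalg.det(sigma) <= 0 or not np.isfinite(sigma).all():
        raise ValueError("degenerate-covariance: statistics have no 2-D spread")
    return HotellingModel(mu_hat=mu, sigma=sigma, dof=dof, n_fit=len(stats))


def mahalanobis_sq(x_prime: np.ndarray, model: HotellingModel) -> float:
    """Squared Mahalanobis distance a(x') of one statistic vector."""
    d = np.asarray(x_prime, dtype=float) - model.mu_hat
    return float(d @ model._sigma_inv @ d)


def threshold_from_probability(p_target: float, dof: int = 2) -> float:
    """Back-calculate the anomaly threshold from a flagging probability.

    Returns a_th with upper-tail mass P(chi2_dof > a_th) = p_target, i.e.
    the (1 - p_target) quantile; strictly decreasing in p_target.
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError("invalid-argument: p_target must lie in (0, 1)")
    return float(sps.chi2.ppf(1.0 - p_target, df=dof))


def detect(
    stats: Sequence[ScoreStat], model: HotellingModel, p_target: float
) -> list[DetectionResult]:
    """Classify each statistic vector against the back-calculated threshold.

    Decision is Anomaly iff a(x') strictly exceeds the threshold.
    """
    thr = threshold_from_probability(p_target, model.dof)
    out = []
    for s in stats:
        a = mahalanobis_sq(s.vector, model)
        out.append(
            DetectionResult(
                frame_id=s.frame_id,
                label=s.label,
                a_value=a,
                threshold=thr,
                p_target=p_target,
                decision="Anomaly" if a > thr else "Normal",
            )
        )
    return out


def contour_levels(
    model: HotellingModel,
    probabilities: Sequence[float],
    grid: tuple[float, float, float, float],
    n_grid: int = 200,
) -> dict:
    """Evaluate the nested detection-probability ellipses on a grid.

    ``grid = (x_min, x_max, y_min, y_max)`` spans the (log mean, log var)
    plane.  Returns the grid axes, the a(x') surface, and one threshold
    level per probability; smaller probabilities give larger ellipses.
    """
    x_min, x_max, y_min, y_max = grid
    xs = np.linspace(x_min, x_max, n_grid)
    ys = np.linspace(y_min, y_max, n_grid)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.stack([XX, YY], axis=-1) - model.mu_hat
    surface = np.einsum("...i,ij,...j->...", pts, model._sigma_inv, pts)
    levels = {
        float(p): threshold_from_probability(p, model.dof) for p in probabilities
    }
    return {"x": xs, "y": ys, "a_surface": surface, "levels": levels}


# ---------------------------------------------------------------------------
# persistence

def save_hotelling(model: HotellingModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mu_hat": model.mu_hat.tolist(),
                "sigma": model.sigma.tolist(),
                "dof": model.dof,
                "n_fit": model.n_fit,
            },
            indent=2,
        )
    )


def load_hotelling(path: str | Path) -> HotellingModel:
    d = json.loads(Path(path).read_text())
    return HotellingModel(
        mu_hat=np.array(d["mu_hat"]), sigma=np.array(d["sigma"]),
        dof=int(d["dof"]), n_fit=int(d["n_fit"]),
    )


def write_detections(results: Sequence[DetectionResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, index=False)
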