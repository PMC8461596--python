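"""Unregularized anomaly score of patches and per-image score statistics.

The score of a patch is the reconstruction half of the VAE objective,
evaluated deterministically at the posterior mode (z = mu_z, no sampling):

    L(x) = sum_i  (mu_xi - x_i)^2 / (2 sigma^2_xi)

i.e. an inverse-variance-weighted squared reconstruction error over the 64
pixels.  Each test FTI is reduced to a 2-vector x' = (log mean, log
variance) of the scores of random patches drawn from it; scores are
log-transformed because they span orders of magnitude (small decoder
variances make them diverge).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FTI, Patch, extract_patches
from .vae import TrainedVae

__all__ = [
    "PatchScore",
    "ScoreStat",
    "score_patch",
    "score_fti",
    "score_dataset",
    "write_score_stats",
    "read_score_stats",
]


@dataclass(frozen=True)
class PatchScore:
    """Unregularized anomaly score of one 8x8 patch (non-negative)."""

    value: float
    source_frame_id: str
    row0: int
    col0: int


@dataclass(frozen=True)
class ScoreStat:
    """Per-image log-scale statistics of patch anomaly scores (x')."""

    log_mean: float
    log_var: float
    n_patches: int
    frame_id: str
    label: str

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.log_mean, self.log_var])


def _score_batch(pixels: np.ndarray, model: TrainedVae) -> np.ndarray:
    """Vectorized Eq.-style scores for patches stacked as (n, 8, 8)."""
    x = pixels[:, None, :, :].astype(float)
    mu_z, _ = model.network.encode_batch(x, train=False)
    mu_x, logvar_x = model.network.decode_batch(mu_z, train=False)
    var_x = np.exp(logvar_x)
    scores = np.sum((mu_x - x) ** 2 / (2.0 * var_x), axis=(1, 2, 3))
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("numerical-failure: non-finite anomaly score")
    return scores


def score_patch(patch: Patch, model: TrainedVae) -> PatchScore:
    """Score one patch at the posterior mode z = mu_z (deterministic)."""
    value = float(_score_batch(patch.pixels[None], model)[0])
    return PatchScore(
        value=value,
        source_frame_id=patch.source_frame_id,
        row0=patch.row0,
        col0=patch.col0,
    )


def score_fti(fti: FTI, model: TrainedVae, n_patches: int = 100, seed: int = 0) -> ScoreStat:
    """Reduce one FTI to its log-scale score-statistic vector x'.

    Draws ``n_patches`` random patches, scores each, and returns
    (ln mean, ln unbiased variance) of the scores.  A zero-variance score
    sample has no defined log-variance and is rejected.
    """
    if n_patches < 2:
        raise ValueError("invalid-input: need n_patches >= 2 for a variance")
    ps = extract_patches(fti, n_patches, seed)
    scores = _score_batch(ps.as_array(), model)
    mean = float(scores.mean())
    var = float(scores.var(ddof=1))
    if mean <= 0.0 or var <= 0.0:
        raise ValueError(
            f"degenerate-statistics: patch scores of {fti.source_frame_id} "
            f"have mean {mean} and variance {var}"
        )
    return ScoreStat(
        log_mean=float(np.log(mean)),
        log_var=float(np.log(var)),
        n_patches=n_patches,
        frame_id=fti.source_frame_id,
        label=fti.label,
    )


def score_dataset(
    ftis: Sequence[FTI], model: TrainedVae, n_patches: int = 100, seed: int = 0
) -> list[ScoreStat]:
    """Score every FTI, deriving per-image seeds from the master seed."""
    if not ftis:
        raise ValueError("invalid-input: empty FTI list")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(ftis)) % (2**31)
    stats = []
    for fti, s in zip(ftis, child_seeds):
        try:
            stats.append(score_fti(fti, model, n_patches=n_patches, seed=int(s)))
        except Exception as exc:
            raise RuntimeError(f"scoring failed for frame {fti.source_frame_id}") from exc
    return stats


def write_score_stats(stats: Sequence[ScoreStat], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                frame_id=s.frame_id, label=s.label, n_patches=s.n_patches,
                log_mean=s.log_mean, log_var=s.log_var,
            )
            for s in stats
        ]
    ).to_csv(path, index=False)


def read_score_stats(path: str | Path) -> list[ScoreStat]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ScoreStat(
            log_mean=float(r.log_mean), log_var=float(r.log_var),
            n_patches=int(r.n_patches), frame_id=str(r.frame_id), label=str(r.label),
        )
        for r in df.itertuples(index=False)
    ]
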