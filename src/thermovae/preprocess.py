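"""Facial thermal image (FTI) preprocessing and 8x8 patch extraction.

Converts radiometric frames into per-image min-max normalized FTIs and
draws the random 8x8 patch sets used to train and score the patch VAE.
Normalizing each image independently to [0, 1] discards the absolute
temperature level (which drifts with room temperature and circadian
phase) and keeps the relative spatial pattern of skin temperature.

Coordinates are 0-based, row-major, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .synthetic import NORMAL, ThermalFrame

PATCH_SIZE = 8

__all__ = [
    "PATCH_SIZE",
    "FTI",
    "Patch",
    "PatchSet",
    "crop_fti",
    "normalize_fti",
    "frames_to_ftis",
    "extract_patches",
    "build_learning_set",
    "split_normal",
    "read_frames",
    "write_patchset",
    "read_patchset",
    "write_ftis",
    "read_ftis",
]


@dataclass
class FTI:
    """A cropped facial thermal image, min-max normalized to [0, 1]."""

    pixels: np.ndarray
    source_frame_id: str
    label: str = "Unlabeled"

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Patch:
    """An 8x8 sub-window of a normalized FTI (no resampling)."""

    pixels: np.ndarray
    source_frame_id: str
    row0: int
    col0: int


@dataclass
class PatchSet:
    """Ordered collection of patches for learning or scoring."""

    patches: list[Patch]
    role: str = "learning"
    seed: int = 0

    def __len__(self) -> int:
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        """Stack into shape (n, 8, 8) for vectorized model passes."""
        return np.stack([p.pixels for p in self.patches])


def crop_fti(frame: ThermalFrame, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Crop ``frame.pixels`` to ``roi = (row0, col0, height, width)``.

    The ROI must lie inside the frame and be at least one patch (8x8).
    """
    row0, col0, h, w = roi
    H, W = frame.pixels.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        raise ValueError(f"invalid-roi: ROI {h}x{w} smaller than one {PATCH_SIZE}x{PATCH_SIZE} patch")
    if row0 < 0 or col0 < 0 or row0 + h > H or col0 + w > W:
        raise ValueError(f"invalid-roi: ROI {roi} outside {H}x{W} frame")
    return frame.pixels[row0 : row0 + h, col0 : col0 + w]


def normalize_fti(
    cropped: np.ndarray, source_frame_id: str = "", label: str = "Unlabeled"
) -> FTI:
    """Min-max normalize a cropped temperature matrix to [0, 1].

    The map is affine and applied independently per image, so any affine
    transform of the input temperatures (unit change, offset drift)
    yields the identical FTI.  A constant image has no defined contrast
    and is rejected.
    """
    lo = float(cropped.min())
    hi = float(cropped.max())
    if not np.isfinite([lo, hi]).all():
        raise ValueError("degenerate-image: non-finite temperatures")
    if hi == lo:
        raise ValueError("degenerate-image: constant temperature, contrast undefined")
    return FTI(pixels=(cropped - lo) / (hi - lo), source_frame_id=source_frame_id, label=label)


def frames_to_ftis(
    frames: Sequence[ThermalFrame], roi: tuple[int, int, int, int] | None = None
) -> list[FTI]:
    """Crop (full image by default) and normalize a batch of frames."""
    out = []
    for fr in frames:
        if roi is None:
            full = (0, 0, fr.pixels.shape[0], fr.pixels.shape[1])
            cropped = crop_fti(fr, full)
        else:
            cropped = crop_fti(fr, roi)
        out.append(normalize_fti(cropped, source_frame_id=fr.frame_id, label=fr.label))
    return out


def _draw_patches(fti: FTI, count: int, rng: np.random.Generator) -> list[Patch]:
    h, w = fti.pixels.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        raise ValueError(f"invalid-input: FTI {h}x{w} smaller than a patch")
    rows = rng.integers(0, h - PATCH_SIZE + 1, size=count)
    cols = rng.integers(0, w - PATCH_SIZE + 1, size=count)
    return [
        Patch(
            pixels=fti.pixels[r : r + PATCH_SIZE, c : c + PATCH_SIZE],
            source_frame_id=fti.source_frame_id,
            row0=int(r),
            col0=int(c),
        )
        for r, c in zip(rows, cols)
    ]


def extract_patches(fti: FTI, count: int, seed: int) -> PatchSet:
    """Draw ``count`` 8x8 patches with corners uniform over valid positions.

    Sampling is with replacement over the (h-7) x (w-7) corner grid and
    reproducible under ``seed``.
    """
    if count < 1:
        raise ValueError("invalid-input: count must be >= 1")
    rng = np.random.default_rng(seed)
    return PatchSet(patches=_draw_patches(fti, count, rng), role="scoring", seed=seed)


def build_learning_set(ftis: Sequence[FTI], expansion_count: int, seed: int) -> PatchSet:
    """Expand normal FTIs into a learning patch set of exact size.

    Draws ``expansion_count`` patches total, cycling over the source
    images so every FTI contributes as evenly as possible, with uniformly
    random corner positions.
    """
    if not ftis:
        raise ValueError("invalid-input: no source FTIs")
    if expansion_count < 1:
        raise ValueError("invalid-input: expansion_count must be >= 1")
    rng = np.random.default_rng(seed)
    patches: list[Patch] = []
    n = len(ftis)
    # per-image quotas: cycle so counts differ by at most one
    base, extra = divmod(expansion_count, n)
    for i, fti in enumerate(ftis):
        quota = base + (1 if i < extra else 0)
        if quota:
            patches.extend(_draw_patches(fti, quota, rng))
    return PatchSet(patches=patches, role="learning", seed=seed)


def split_normal(
    ftis: Sequence[FTI],
    learning_fraction: float = 0.9,
    test_count: int = 60,
    seed: int = 0,
) -> tuple[list[FTI], list[FTI]]:
    """Split normal FTIs into a learning set and a held-out test subset.

    ``learning_fraction`` of the images (rounded down) are kept for
    learning; ``test_count`` images are subsampled uniformly from the
    remainder.  With the default 1920 inputs this yields 1728 learning
    and 60 test FTIs drawn from the 192 held out.
    """
    if not 0.0 < learning_fraction < 1.0:
        raise ValueError("invalid-split: learning_fraction must lie in (0, 1)")
    n = len(ftis)
    n_learn = int(np.floor(learning_fraction * n))
    n_holdout = n - n_learn
    if test_count > n_holdout:
        raise ValueError(
            f"invalid-split: test_count {test_count} exceeds holdout size {n_holdout}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    learn_idx = order[:n_learn]
    holdout_idx = order[n_learn:]
    test_idx = rng.choice(holdout_idx, size=test_count, replace=False)
    return [ftis[i] for i in learn_idx], [ftis[i] for i in sorted(test_idx)]


# ---------------------------------------------------------------------------
# file interfaces (TIFF stacks + CSV metadata; patch archives)

def read_frames(data_dir: str | Path) -> list[ThermalFrame]:
    """Load a frame stack written by :func:`thermovae.synthetic.write_frames`."""
    import tifffile

    data_dir = Path(data_dir)
    meta = pd.read_csv(data_dir / "metadata.csv")
    frames = []
    for row in meta.itertuples(index=False):
        pixels = tifffile.imread(data_dir / f"{row.frame_id}.tiff").astype(float)
        frames.append(
            ThermalFrame(
                pixels=pixels,
                subject_id=str(row.subject_id),
                session_hour=float(row.session_hour),
                segment=str(row.segment),
                t_offset_s=float(row.t_offset_s),
                label=str(row.label),
                frame_id=str(row.frame_id),
            )
        )
    return frames


def write_patchset(ps: PatchSet, path: str | Path) -> None:
    """Persist a patch set as an .npz archive with its manifest."""
    path = Path(path)
    np.savez_compressed(
        path,
        pixels=ps.as_array(),
        source_frame_id=np.array([p.source_frame_id for p in ps.patches]),
        row0=np.array([p.row0 for p in ps.patches]),
        col0=np.array([p.col0 for p in ps.patches]),
        role=np.array(ps.role),
        seed=np.array(ps.seed),
    )


def write_ftis(ftis: Sequence[FTI], path: str | Path) -> None:
    """Persist equally sized FTIs as an .npz stack with ids and labels."""
    np.savez_compressed(
        path,
        pixels=np.stack([f.pixels for f in ftis]),
        source_frame_id=np.array([f.source_frame_id for f in ftis]),
        label=np.array([f.label for f in ftis]),
    )


def read_ftis(path: str | Path) -> list[FTI]:
    with np.load(path, allow_pickle=False) as z:
        return [
            FTI(pixels=px, source_frame_id=str(sid), label=str(lab))
            for px, sid, lab in zip(z["pixels"], z["source_frame_id"], z["label"])
        ]


def read_patchset(path: str | Path) -> PatchSet:
    with np.load(path, allow_pickle=False) as z:
        patches = [
            Patch(pixels=px, source_frame_id=str(sid), row0=int(r), col0=int(c))
            for px, sid, r, c in zip(z["pixels"], z["source_frame_id"], z["row0"], z["col0"])
        ]
        return PatchSet(patches=patches, role=str(z["role"]), seed=int(z["seed"]))
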