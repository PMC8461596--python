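"""Seeded generator of facial thermal image time series.

Emulates an hourly rest/breath-hold measurement protocol on a synthetic
face so that every downstream stage (normalization, patch VAE, Hotelling
detector, ROC evaluation) is testable without subject data.

The simulated face is an elliptical warm region on a cooler room-temperature
background, carrying

* a diurnal sinusoid (circadian fluctuation of facial skin temperature),
* curvilinear warm "vessels" with Gaussian cross-sections -- the fine
  sub-patch-scale vascular texture the patch VAE is meant to learn,
* i.i.d. Gaussian sensor noise at the radiometric resolution bound, and
* during the task segment, a ramped temperature response that stands in
  for the forced skin-temperature change of a breath hold.

All randomness flows from explicit seeds; a frame sequence is a pure
function of (FaceModel, ProtocolConfig, AnomalyModel).
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolConfig",
    "FaceModel",
    "AnomalyModel",
    "ThermalFrame",
    "SUBJECT_PROFILES",
    "generate_face_model",
    "render_frame",
    "simulate_protocol",
    "write_frames",
]

REST = "Rest"
TASK = "Task"
NORMAL = "Normal"
ANOMALY = "Anomaly"
UNLABELED = "Unlabeled"

#: Subject profiles -> (height_px, width_px) of the cropped facial thermal
#: image, and an index used to decouple their random vessel layouts.
SUBJECT_PROFILES: dict[str, tuple[int, int, int]] = {
    "subA_like": (90, 83, 0),
    "subB_like": (73, 94, 1),
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Measurement protocol: hourly sessions of rest followed by a task.

    Defaults reproduce 16 hourly sessions (8:00-23:00) of 120 s rest at
    1 Hz plus a 60 s task whose last 20 s are the anomaly window, i.e.
    16 x 120 = 1920 normal frames and 20 anomaly frames per session.
    """

    hours: tuple[int, ...] = tuple(range(8, 24))
    rest_duration_s: int = 120
    task_duration_s: int = 60
    anomaly_window_s: int = 20
    sampling_hz: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hours:
            raise ValueError("protocol needs at least one session hour")
        if self.anomaly_window_s > self.task_duration_s:
            raise ValueError("anomaly_window_s cannot exceed task_duration_s")
        if min(self.rest_duration_s, self.task_duration_s, self.sampling_hz) <= 0:
            raise ValueError("durations and sampling rate must be positive")

    @property
    def n_normal_frames(self) -> int:
        return len(self.hours) * self.rest_duration_s * self.sampling_hz

    @property
    def n_task_frames_per_session(self) -> int:
        return self.task_duration_s * self.sampling_hz

    @property
    def n_anomaly_frames_per_session(self) -> int:
        return self.anomaly_window_s * self.sampling_hz


@dataclass
class FaceModel:
    """Geometry and thermal parameters of one synthetic face.

    ``vessel_field`` is the pre-rendered warm-vessel temperature offset in
    degC (non-negative, zero outside the face mask).  ``periorbital_weight``
    is a [0, 1] spatial profile peaking between the eyes, used by the
    periorbital anomaly mode.
    """

    height_px: int
    width_px: int
    face_mask: np.ndarray
    vessel_field: np.ndarray
    periorbital_weight: np.ndarray
    vessel_curves: list[dict] = field(default_factory=list)
    base_temp_c: float = 34.0
    background_temp_c: float = 22.1
    diurnal_amplitude_c: float = 0.3
    diurnal_phase_h: float = 10.0
    noise_sigma_c: float = 0.05

    def __post_init__(self) -> None:
        if self.face_mask.shape != (self.height_px, self.width_px):
            raise ValueError("face_mask shape does not match image dimensions")
        if self.noise_sigma_c <= 0:
            raise ValueError("noise_sigma_c must be positive")
        if self.diurnal_amplitude_c < 0:
            raise ValueError("diurnal_amplitude_c must be non-negative")
        # mask must not touch the image border (face strictly inside crop)
        border = np.concatenate(
            [self.face_mask[0], self.face_mask[-1], self.face_mask[:, 0], self.face_mask[:, -1]]
        )
        if border.any():
            raise ValueError("face_mask must lie strictly inside the image bounds")

    def diurnal_offset_c(self, hour: float) -> float:
        """Circadian temperature offset at clock time ``hour`` (degC)."""
        return self.diurnal_amplitude_c * np.sin(
            2.0 * np.pi * (hour - self.diurnal_phase_h) / 24.0
        )

    def anomaly_profile(self, spatial_profile: str) -> np.ndarray:
        if spatial_profile == "global_shift":
            return self.face_mask.astype(float)
        if spatial_profile == "periorbital_focus":
            return self.periorbital_weight
        raise ValueError(f"unknown spatial_profile: {spatial_profile!r}")


def _smoothstep(s: np.ndarray | float) -> np.ndarray | float:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


@dataclass(frozen=True)
class AnomalyModel:
    """Forced skin-temperature response during the task segment.

    The response is zero until ``onset_s`` seconds into the task, then
    rises smoothly (cubic smoothstep) to ``delta_temp_c`` degC at task end.
    ``spatial_profile`` selects where on the face the heat appears:
    ``periorbital_focus`` (default) concentrates it in the periorbital /
    forehead region, the classical site of acute autonomic thermal
    responses; ``global_shift`` warms the whole face uniformly (note a
    uniform shift is largely removed by per-image min-max normalization).
    A custom ramp can be supplied as ``ramp_fn(t, task_duration_s)`` and
    must satisfy ramp(0) = 0, ramp(T) = 1, non-decreasing.
    """

    onset_s: float = 10.0
    delta_temp_c: float = 0.8
    spatial_profile: str = "periorbital_focus"
    ramp_fn: Callable[[float, float], float] | None = None

    def ramp(self, t: float, task_duration_s: float) -> float:
        """Fraction of the full response developed ``t`` s into the task."""
        if self.ramp_fn is not None:
            return float(self.ramp_fn(t, task_duration_s))
        if task_duration_s <= self.onset_s:
            return float(_smoothstep(t / task_duration_s))
        s = (t - self.onset_s) / (task_duration_s - self.onset_s)
        return float(_smoothstep(s))


@dataclass
class ThermalFrame:
    """One radiometric image (degC per pixel) plus acquisition metadata."""

    pixels: np.ndarray
    subject_id: str
    session_hour: float
    segment: str
    t_offset_s: float
    label: str
    frame_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite temperatures")


def _quadratic_bezier(p0, p1, p2, n: int = 160) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_face_model(seed: int, subject_profile: str, **overrides) -> FaceModel:
    """Build a reproducible synthetic face for one subject profile.

    The same ``(seed, subject_profile)`` pair always yields a bitwise
    identical model; distinct profiles differ in crop size and vessel
    layout.  Keyword overrides are forwarded to :class:`FaceModel`
    (e.g. ``diurnal_amplitude_c=0.5``).
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if subject_profile not in SUBJECT_PROFILES:
        raise ValueError(
            f"unknown subject_profile {subject_profile!r}; "
            f"expected one of {sorted(SUBJECT_PROFILES)}"
        )
    h, w, profile_idx = SUBJECT_PROFILES[subject_profile]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), profile_idx]))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.44 * (h - 1), 0.42 * (w - 1)
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    # Warm vessels: smooth random quadratic curves with Gaussian cross
    # section; a ridge (max, not sum) so each vessel's crest equals its
    # amplitude.  Amplitudes 0.3-0.6 degC, widths 1-3 px.
    n_vessels = int(rng.integers(4, 8))
    field = np.zeros((h, w))
    curves: list[dict] = []
    for _ in range(n_vessels):
        ang = rng.uniform(0, 2 * np.pi, size=3)
        rad = rng.uniform(0.1, 0.85, size=3)
        pts = np.stack(
            [cy + rad * ry * np.sin(ang), cx + rad * rx * np.cos(ang)], axis=1
        )
        amp = float(rng.uniform(0.3, 0.6))
        width = float(rng.uniform(1.0, 3.0))
        curve = _quadratic_bezier(pts[0], pts[1], pts[2])
        d2 = (yy[:, :, None] - curve[:, 0]) ** 2 + (xx[:, :, None] - curve[:, 1]) ** 2
        ridge = amp * np.exp(-d2.min(axis=2) / (2.0 * width**2))
        field = np.maximum(field, ridge)
        curves.append({"points": pts, "amplitude_c": amp, "width_px": width})
    field *= mask

    peri = np.exp(
        -(((yy - 0.36 * h) / (0.13 * h)) ** 2 + ((xx - cx) / (0.24 * w)) ** 2) / 2.0
    )
    peri = np.where(mask, peri / peri.max(), 0.0)

    return FaceModel(
        height_px=h,
        width_px=w,
        face_mask=mask,
        vessel_field=field,
        periorbital_weight=peri,
        vessel_curves=curves,
        **overrides,
    )


def render_frame(
    face: FaceModel,
    hour: float,
    anomaly_strength: float,
    rng: np.random.Generator,
    anomaly: AnomalyModel | None = None,
    *,
    subject_id: str = "sim",
    segment: str = REST,
    t_offset_s: float = 0.0,
    label: str = UNLABELED,
) -> ThermalFrame:
    """Render one radiometric frame at clock time ``hour``.

    Inside the face mask the temperature is
    ``base + diurnal(hour) + vessels + strength * delta * profile``;
    outside it is the room background.  Gaussian sensor noise of std
    ``face.noise_sigma_c`` is added everywhere.
    """
    if not 0.0 <= anomaly_strength <= 1.0:
        raise ValueError("anomaly_strength must lie in [0, 1]")
    if anomaly is None:
        anomaly = AnomalyModel()

    pixels = np.full((face.height_px, face.width_px), face.background_temp_c)
    facial = face.base_temp_c + face.diurnal_offset_c(hour) + face.vessel_field
    pixels = np.where(face.face_mask, facial, pixels)
    if anomaly_strength > 0.0:
        pixels = pixels + (
            anomaly_strength * anomaly.delta_temp_c * face.anomaly_profile(anomaly.spatial_profile)
        )
    pixels = pixels + rng.normal(0.0, face.noise_sigma_c, size=pixels.shape)

    frame_id = f"{subject_id}_h{hour:05.1f}_{segment.lower()}_{t_offset_s:06.1f}"
    return ThermalFrame(
        pixels=pixels,
        subject_id=subject_id,
        session_hour=hour,
        segment=segment,
        t_offset_s=t_offset_s,
        label=label,
        frame_id=frame_id,
    )


def simulate_protocol(
    face: FaceModel,
    protocol: ProtocolConfig,
    anomaly: AnomalyModel | None = None,
    subject_id: str = "sim",
) -> list[ThermalFrame]:
    """Emit the full chronological frame sequence of the protocol.

    Per session hour: ``rest_duration_s * sampling_hz`` rest frames labeled
    Normal, then ``task_duration_s * sampling_hz`` task frames whose
    anomaly strength follows the ramp; frames in the final
    ``anomaly_window_s`` seconds are labeled Anomaly, earlier task frames
    Unlabeled (response still developing).
    """
    if anomaly is None:
        anomaly = AnomalyModel()
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 2]))
    dt = 1.0 / protocol.sampling_hz
    frames: list[ThermalFrame] = []
    anomaly_start = protocol.task_duration_s - protocol.anomaly_window_s
    for hour in protocol.hours:
        for i in range(protocol.rest_duration_s * protocol.sampling_hz):
            frames.append(
                render_frame(
                    face, hour, 0.0, rng, anomaly,
                    subject_id=subject_id, segment=REST,
                    t_offset_s=i * dt, label=NORMAL,
                )
            )
        for i in range(protocol.task_duration_s * protocol.sampling_hz):
            t = i * dt
            strength = anomaly.ramp(t + dt, protocol.task_duration_s)
            frames.append(
                render_frame(
                    face, hour, strength, rng, anomaly,
                    subject_id=subject_id, segment=TASK,
                    t_offset_s=t,
                    label=ANOMALY if t >= anomaly_start else UNLABELED,
                )
            )
    return frames


def write_frames(frames: Sequence[ThermalFrame], out_dir: str | Path) -> Path:
    """Write frames as per-frame 32-bit float TIFFs plus a metadata CSV.

    Returns the path of the metadata table.  The CSV schema
    (frame_id, subject_id, session_hour, segment, t_offset_s, label)
    is the interface consumed by the preprocessing stage.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fr in frames:
        tifffile.imwrite(out_dir / f"{fr.frame_id}.tiff", fr.pixels.astype(np.float32))
        rows.append(
            dict(
                frame_id=fr.frame_id,
                subject_id=fr.subject_id,
                session_hour=fr.session_hour,
                segment=fr.segment,
                t_offset_s=fr.t_offset_s,
                label=fr.label,
            )
        )
    meta_path = out_dir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path
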