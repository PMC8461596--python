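"""Shared fixtures: synthetic faces, small FTI sets, a small trained VAE.

Expensive fixtures are session-scoped so the suite trains a model once
and reuses it wherever only "a trained model" (not a specific training
condition) is needed.
"""

from __future__ import annotations

import numpy as np
import pytest

import thermovae as tv
from thermovae import preprocess as pp


@pytest.fixture(scope="session")
def face_a() -> tv.FaceModel:
    return tv.generate_face_model(0, "subA_like")


@pytest.fixture(scope="session")
def small_protocol() -> tv.ProtocolConfig:
    """Reduced protocol: 4 sessions of 30 s rest -> 120 normal frames."""
    return tv.ProtocolConfig(hours=(8, 12, 16, 20), rest_duration_s=30, seed=7)


@pytest.fixture(scope="session")
def small_frames(face_a, small_protocol) -> list[tv.ThermalFrame]:
    return tv.simulate_protocol(face_a, small_protocol)


@pytest.fixture(scope="session")
def small_ftis(small_frames) -> list[pp.FTI]:
    normal = [f for f in small_frames if f.label == "Normal"]
    return pp.frames_to_ftis(normal)


@pytest.fixture(scope="session")
def trained_model(small_ftis) -> tv.TrainedVae:
    """A VAE trained at reduced scale (1,280 patches, one candidate)."""
    patches = pp.build_learning_set(small_ftis[:100], 1280, seed=5)
    return tv.train_vae(patches, tv.VaeConfig(seed=5, n_candidates=1))


@pytest.fixture(scope="session")
def small_run_config() -> tv.RunConfig:
    """End-to-end pipeline config scaled down for per-test use."""
    return tv.RunConfig(
        protocol=tv.ProtocolConfig(hours=(8, 12, 16, 20), rest_duration_s=30),
        vae=tv.VaeConfig(n_candidates=1),
        expansion_count=1280,
        test_count=12,
        n_patches=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_summary(small_run_config) -> dict:
    return tv.run_pipeline(small_run_config)


@pytest.fixture(scope="session")
def gaussian_stats() -> list[tv.ScoreStat]:
    """Score statistics drawn exactly from a correlated 2-D Gaussian."""
    rng = np.random.default_rng(42)
    mean = np.array([2.0, -1.0])
    cov = np.array([[0.8, 0.3], [0.3, 0.5]])
    pts = rng.multivariate_normal(mean, cov, size=200)
    return [
        tv.ScoreStat(log_mean=float(x), log_var=float(y), n_patches=100,
                     frame_id=f"g{i}", label="Normal")
        for i, (x, y) in enumerate(pts)
    ]
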