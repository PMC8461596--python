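"""End-to-end pipeline: simulate -> preprocess -> train -> score -> detect -> evaluate.

Runs the whole normal-only anomaly-detection study on synthetic facial
thermal data and returns a summary of every stage.  Fully reproducible:
all stage seeds are derived from one master seed, and two runs with the
same resolved configuration produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import evaluation, hotelling, preprocess, scoring, synthetic, vae

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("thermovae")

DEFAULT_P_TARGETS = (0.30, 0.25, 0.20, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``seed`` is the master seed; every stage derives its own stream from
    it.  ``expansion_count`` is the learning-set size (10,000 for the
    smaller-face subject setting, 50,000 for the larger).
    """

    subject_profile: str = "subA_like"
    protocol: synthetic.ProtocolConfig = field(default_factory=synthetic.ProtocolConfig)
    anomaly: synthetic.AnomalyModel = field(default_factory=synthetic.AnomalyModel)
    vae: vae.VaeConfig = field(default_factory=vae.VaeConfig)
    expansion_count: int = 10_000
    learning_fraction: float = 0.9
    test_count: int = 60
    n_patches: int = 100
    p_targets: tuple[float, ...] = DEFAULT_P_TARGETS
    dof: int = 2
    seed: int = 0

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage integer seed below 2**31."""
        return int(np.random.SeedSequence([self.seed, 101 + stage]).generate_state(1)[0] % (2**31))

    def resolved_dict(self) -> dict:
        d = {
            "subject_profile": self.subject_profile,
            "protocol": asdict(self.protocol),
            "anomaly": {k: v for k, v in asdict(self.anomaly).items() if k != "ramp_fn"},
            "vae": asdict(self.vae),
            "expansion_count": self.expansion_count,
            "learning_fraction": self.learning_fraction,
            "test_count": self.test_count,
            "n_patches": self.n_patches,
            "p_targets": list(self.p_targets),
            "dof": self.dof,
            "seed": self.seed,
        }
        d["protocol"]["hours"] = list(d["protocol"]["hours"])
        return d


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage end-to-end; returns the summary dictionary.

    If ``out_dir`` is given, all intermediate artifacts (frame metadata,
    patch archive, model checkpoint, score statistics, detections, the
    detection-plane figure, the resolved config and the summary) are
    written there so any stage can be re-run from files.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(config.resolved_dict(), indent=2, sort_keys=True)
        )

    # -- simulate ----------------------------------------------------------
    logger.info("stage=simulate seed=%d subject=%s", config.seed, config.subject_profile)
    face = synthetic.generate_face_model(config.stage_seed(0), config.subject_profile)
    protocol = replace(config.protocol, seed=config.stage_seed(1))
    frames = synthetic.simulate_protocol(face, protocol, config.anomaly)
    normal_frames = [f for f in frames if f.label == synthetic.NORMAL]
    anomaly_frames = [f for f in frames if f.label == synthetic.ANOMALY]

    # -- preprocess --------------------------------------------------------
    normal_ftis = preprocess.frames_to_ftis(normal_frames)
    learn_ftis, test_normal = preprocess.split_normal(
        normal_ftis,
        learning_fraction=config.learning_fraction,
        test_count=config.test_count,
        seed=config.stage_seed(2),
    )
    # anomaly test samples: the last-20-s window of one session, chosen
    # at random among the session hours
    rng = np.random.default_rng(config.stage_seed(3))
    chosen_hour = float(rng.choice(sorted({f.session_hour for f in anomaly_frames})))
    test_anomaly = preprocess.frames_to_ftis(
        [f for f in anomaly_frames if f.session_hour == chosen_hour]
    )
    learning_set = preprocess.build_learning_set(
        learn_ftis, config.expansion_count, seed=config.stage_seed(4)
    )
    logger.info(
        "stage=preprocess n_learn=%d n_test_normal=%d n_test_anomaly=%d n_patches=%d",
        len(learn_ftis), len(test_normal), len(test_anomaly), len(learning_set),
    )

    # -- train -------------------------------------------------------------
    vae_config = replace(config.vae, seed=config.stage_seed(5))
    model = vae.train_vae(learning_set, vae_config)
    logger.info("stage=train final_loss=%.4f", model.training_loss_history[-1])

    # -- score -------------------------------------------------------------
    test_ftis = list(test_normal) + list(test_anomaly)
    stats = scoring.score_dataset(
        test_ftis, model, n_patches=config.n_patches, seed=config.stage_seed(6)
    )
    normal_stats = [s for s in stats if s.label == synthetic.NORMAL]
    anomaly_stats = [s for s in stats if s.label == synthetic.ANOMALY]

    # -- detect ------------------------------------------------------------
    gate = evaluation.normality_gate(normal_stats)
    hmodel = hotelling.fit_hotelling(normal_stats, dof=config.dof)
    confusion = {}
    detections_by_p = {}
    for p in config.p_targets:
        dets = hotelling.detect(stats, hmodel, p)
        detections_by_p[p] = dets
        tp = sum(1 for d in dets if d.label == synthetic.ANOMALY and d.decision == "Anomaly")
        fp = sum(1 for d in dets if d.label != synthetic.ANOMALY and d.decision == "Anomaly")
        fn = sum(1 for d in dets if d.label == synthetic.ANOMALY and d.decision == "Normal")
        tn = sum(1 for d in dets if d.label != synthetic.ANOMALY and d.decision == "Normal")
        confusion[f"{p:.2f}"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    # -- evaluate ----------------------------------------------------------
    roc = evaluation.roc_auc(
        [(hotelling.mahalanobis_sq(s.vector, hmodel), s.label) for s in stats]
    )
    summary = {
        "subject_profile": config.subject_profile,
        "n_frames_total": len(frames),
        "n_normal_frames": len(normal_frames),
        "n_learning_ftis": len(learn_ftis),
        "n_test_normal": len(test_normal),
        "n_test_anomaly": len(test_anomaly),
        "n_test_total": len(test_ftis),
        "n_learning_patches": len(learning_set),
        "anomaly_session_hour": chosen_hour,
        "final_training_loss": model.training_loss_history[-1],
        "training_loss_history": model.training_loss_history,
        "shapiro_p_log_mean": gate.p_log_mean,
        "shapiro_p_log_var": gate.p_log_var,
        "shapiro_passed": gate.passed,
        "auc": roc.auc,
        "confusion_by_p_target": confusion,
        "n_anomaly_stats": len(anomaly_stats),
        "seed": config.seed,
    }

    if out_dir is not None:
        synthetic.write_frames(frames, out_dir / "frames")
        preprocess.write_patchset(learning_set, out_dir / "learning_patches.npz")
        preprocess.write_ftis(test_ftis, out_dir / "test_ftis.npz")
        vae.save_model(model, out_dir / "model")
        scoring.write_score_stats(stats, out_dir / "score_stats.csv")
        hotelling.save_hotelling(hmodel, out_dir / "hotelling.json")
        hotelling.write_detections(
            [d for dets in detections_by_p.values() for d in dets],
            out_dir / "detections.csv",
        )
        evaluation.plot_detection_plane(
            stats, hmodel, config.p_targets, out_path=out_dir / "detection_plane.png"
        )
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
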