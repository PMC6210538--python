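"""Reference experiment protocols on the synthetic articulated figure.

These helpers pin down one reproducible set of study conditions — figure
geometry, training-set sizes, detector hyper-parameters — used by the
test suite, the acceptance script and the worked examples.  They exist so
that every entry point measures the same experiment instead of each
re-inventing slightly different settings.

The protocol trains on independently sampled poses of the default
120x160 px supine figure and evaluates joint localization (AJPE, WCA) on
held-out poses plus angle encoding (MAE) on a smooth motion sequence.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureConfig, pyramid_from_config
from .inference import infer_pose, track_frames
from .model import BodyModel
from .motion import JointTrajectory, ajpe, encode_motion, mae_angles, wca
from .synthetic import (
    FigureConfig,
    MotionConfig,
    generate_dataset,
    generate_sequence,
    render_negative,
)
from .training import AnnotatedFrame, TrainingConfig, train_model

__all__ = [
    "study_figure_config",
    "study_training_config",
    "study_negatives",
    "train_study_model",
    "evaluate_joint_recovery",
    "evaluate_angle_encoding",
    "margin_audit",
    "small_figure_config",
]

#: appearance states per part: distal parts articulate most (cf. the
#: larger cluster counts the source system used for elbows/knees)
STUDY_STATES = {
    "head": 2,
    "neck": 2,
    "left_shoulder": 2,
    "right_shoulder": 2,
    "left_hip": 2,
    "right_hip": 2,
    "left_elbow": 4,
    "right_elbow": 4,
    "left_hand": 4,
    "right_hand": 4,
    "left_knee": 4,
    "right_knee": 4,
    "left_foot": 4,
    "right_foot": 4,
}


def study_figure_config(**overrides) -> FigureConfig:
    """The default 120x160 px supine figure."""
    return FigureConfig(**overrides)


def study_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Detector settings for the synthetic study.

    4 px cells (20 px patches, twice the limb width); no rotation/flip
    augmentation — the generator samples dense pose variation directly and
    flipping would conflict with the figure's left/right texture cue.
    """
    defaults = dict(
        C=10.0,
        states_per_part=dict(STUDY_STATES),
        rotations=(),
        flip=False,
        mining_rounds=30,
        max_passes=200,
        patience=60,
        neg_top_k=15,
        seed=seed,
        feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=64),
    )
    defaults.update(overrides)
    return TrainingConfig(**defaults)


def study_negatives(
    config: FigureConfig, n: int = 20, seed: int = 99
) -> list[np.ndarray]:
    """Human-free frames: 1 in 4 plain noise, the rest with textured
    clutter (see :func:`infantpose.synthetic.render_negative`)."""
    rng = np.random.default_rng(seed)
    return [
        render_negative(config, rng, n_clutter=(0 if i % 4 == 0 else 12))
        for i in range(n)
    ]


def train_study_model(
    n_train: int = 200,
    seed: int = 1,
    figure: FigureConfig | None = None,
    config: TrainingConfig | None = None,
    n_negatives: int = 20,
):
    """Train the detector under the study conditions.

    Returns ``(model, training_log, positives)``.
    """
    fig = figure or study_figure_config()
    cfg = config or study_training_config(seed=seed)
    positives = generate_dataset(fig, n_train, seed=seed)
    negatives = study_negatives(fig, n_negatives, seed=seed + 98)
    model, log = train_model(positives, negatives, cfg)
    return model, log, positives


def detect_frames(model: BodyModel, frames) -> list:
    """Independent full-frame detection (no temporal restriction)."""
    out = []
    for f in frames:
        img = f.image if isinstance(f, AnnotatedFrame) else f
        pyr = pyramid_from_config(np.asarray(img, dtype=np.float64), model.feature_config)
        out.append(infer_pose(model, pyr, top_k=1)[0])
    return out


def evaluate_joint_recovery(
    model: BodyModel,
    figure: FigureConfig,
    n_test: int = 50,
    seed: int = 1001,
    omega_px: float | None = None,
):
    """AJPE (px) and WCA (%) of full-frame detection on held-out poses.

    ``omega_px`` defaults to the figure's limb width.  Returns a dict with
    the per-part table and the summary numbers.
    """
    omega = figure.limb_width if omega_px is None else omega_px
    test = generate_dataset(figure, n_test, seed=seed)
    poses = detect_frames(model, test)
    truth = JointTrajectory(
        frames=np.arange(n_test),
        joints={p: np.array([f.joints[p] for f in test]) for p in model.tree.parts},
    )
    pred = JointTrajectory.from_poses(poses)
    per_part, mean = ajpe(pred, truth)
    return {
        "ajpe_px": mean,
        "ajpe_per_part": per_part,
        "wca_pct": wca(pred, truth, omega_wca=omega, mm_per_px=1.0),
        "omega_px": omega,
        "n_test": n_test,
    }


def evaluate_angle_encoding(
    model: BodyModel,
    figure: FigureConfig,
    n_frames: int = 100,
    seed: int = 5,
    omega_dist: float = 30.0,
):
    """MAE (degrees) between detected and programmed joint angles on a
    smooth motion sequence, tracked with the temporal search restriction."""
    frames, truth_traj, truth_angles = generate_sequence(
        figure, MotionConfig(), n_frames=n_frames, seed=seed
    )
    poses = track_frames(model, [f.image for f in frames], omega_dist=omega_dist)
    pred_traj = JointTrajectory.from_poses(poses)
    pred_angles = encode_motion(pred_traj, model.tree)
    per_joint, avg = mae_angles(pred_angles, truth_angles)
    _, seq_ajpe = ajpe(pred_traj, truth_traj)
    return {
        "mae_deg": avg,
        "mae_per_joint": per_joint,
        "sequence_ajpe_px": seq_ajpe,
        "n_frames": n_frames,
    }


def margin_audit(n_pos: int = 50, n_neg: int = 20, seed: int = 7):
    """Train on a separable 80x80 set (plain-noise negatives) and return
    ``(model, log, positives)``; ``log.attrs['margins']`` holds the final
    margin audit over positives and the mined negative cache.

    One appearance state per part keeps the feasibility question (can the
    margin constraints be satisfied?) separate from mixture modelling and
    the optimization deep enough to converge tightly.
    """
    fig = small_figure_config()
    positives = generate_dataset(fig, n_pos, seed=seed)
    rng = np.random.default_rng(seed + 6)
    negatives = [render_negative(fig, rng, n_clutter=0) for _ in range(n_neg)]
    cfg = study_training_config(
        seed=seed,
        C=50.0,
        states_per_part=1,
        mining_rounds=24,
        max_passes=2000,
        tol=1e-10,
        patience=300,
        neg_top_k=10,
        feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=48),
    )
    model, log = train_model(positives, negatives, cfg)
    return model, log, positives


def small_figure_config(image_size=(80, 80)) -> FigureConfig:
    """A reduced figure for small-canvas experiments (margin audits)."""
    scale = 0.62
    from .synthetic import DEFAULT_LIMB_LENGTHS

    return FigureConfig(
        image_size=image_size,
        limb_lengths={k: v * scale for k, v in DEFAULT_LIMB_LENGTHS.items()},
        limb_width=7.0,
        head_radius=5.0,
    )
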