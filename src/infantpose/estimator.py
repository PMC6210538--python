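"""scikit-learn style front end for the part-based pose detector."""

from __future__ import annotations

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .features import FeatureConfig
from .inference import track_frames
from .model import PoseEstimate
from .motion import JointTrajectory, encode_motion, wca
from .training import AnnotatedFrame, TrainingConfig, train_model

__all__ = ["InfantPoseEstimator"]


class InfantPoseEstimator(BaseEstimator):
    """Detect 14 infant body joints in video frames.

    A tree-structured mixture-of-parts detector: per part a small set of
    HOG templates (one per appearance state), quadratic springs along the
    kinematic tree, co-occurrence scores over state assignments, trained
    as a structured SVM on annotated positives and human-free negatives.

    Parameters mirror :class:`~infantpose.training.TrainingConfig` plus
    the tracking thresholds; see there for details.

    Attributes
    ----------
    model_ : BodyModel
        The trained detector.
    training_log_ : pandas.DataFrame
        Objective per optimization pass.

    Examples
    --------
    >>> est = InfantPoseEstimator(states_per_part=2, rotations=(), flip=False)
    >>> est.fit(positive_frames, negatives=negative_images)  # doctest: +SKIP
    >>> poses = est.predict(test_frames)                     # doctest: +SKIP
    """

    def __init__(
        self,
        C: float = 0.1,
        states_per_part=2,
        rotations=(-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0),
        flip: bool = True,
        cell_size_px: int = 8,
        bins: int = 9,
        interval: int = 2,
        min_level_px: int = 40,
        mining_rounds: int = 4,
        max_passes: int = 20,
        neg_top_k: int = 10,
        omega_dist: float = 30.0,
        use_omega_score: bool = True,
        seed: int = 0,
    ):
        self.C = C
        self.states_per_part = states_per_part
        self.rotations = rotations
        self.flip = flip
        self.cell_size_px = cell_size_px
        self.bins = bins
        self.interval = interval
        self.min_level_px = min_level_px
        self.mining_rounds = mining_rounds
        self.max_passes = max_passes
        self.neg_top_k = neg_top_k
        self.omega_dist = omega_dist
        self.use_omega_score = use_omega_score
        self.seed = seed

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            C=self.C,
            states_per_part=self.states_per_part,
            rotations=tuple(self.rotations),
            flip=self.flip,
            mining_rounds=self.mining_rounds,
            max_passes=self.max_passes,
            neg_top_k=self.neg_top_k,
            seed=self.seed,
            feature_config=FeatureConfig(
                cell_size_px=self.cell_size_px,
                bins=self.bins,
                interval=self.interval,
                min_level_px=self.min_level_px,
            ),
        )

    def fit(self, X, y=None, *, negatives):
        """Train on annotated frames.

        Parameters
        ----------
        X : list of AnnotatedFrame
            Positive training frames with all 14 joints annotated.
        negatives : list of ndarray
            Human-free images for hard-negative mining.
        """
        if not X or not isinstance(X[0], AnnotatedFrame):
            raise ValueError("X must be a non-empty list of AnnotatedFrame")
        self.model_, self.training_log_ = train_model(
            list(X), list(negatives), self._training_config()
        )
        return self

    def predict(self, X) -> list[PoseEstimate | None]:
        """Detect the figure in a sequence of frames (temporal tracking:
        exhaustive search on the first frame, restricted afterwards)."""
        check_is_fitted(self, "model_")
        omega = self.model_.omega_score if self.use_omega_score else None
        return track_frames(
            self.model_, X, omega_dist=self.omega_dist, omega_score=omega
        )

    def predict_trajectory(self, X) -> JointTrajectory:
        return JointTrajectory.from_poses(self.predict(X))

    def predict_angles(self, X):
        """Joint-angle time series of the detected motion."""
        traj = self.predict_trajectory(X)
        return encode_motion(traj, self.model_.tree)

    def score(self, X, y) -> float:
        """Worst-case accuracy (fraction in [0, 1]) of detections on
        frames ``X`` against a ground-truth :class:`JointTrajectory`
        ``y``, at a threshold of half the part patch size."""
        check_is_fitted(self, "model_")
        pred = self.predict_trajectory(X)
        omega = self.model_.feature_config.patch_px / 2.0
        return wca(pred, y, omega_wca=omega, mm_per_px=1.0) / 100.0
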