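"""Learning a body model from annotated positives and human-free negatives.

Pipeline
--------
1. *Augmentation*: each positive is flipped and rotated (default -15..15
   degrees in 5-degree steps); joints follow the same affine map and
   left/right labels swap under the flip.
2. *Scale normalization*: a per-frame patch size is derived from limb
   lengths (75% quantile of per-limb length ratios against training-set
   medians) and each frame is resized so that its patch size equals the
   model's 5x5-cell template footprint.
3. *State assignment*: for every part, its displacement relative to its
   parent is clustered with k-means; each cluster is one appearance state
   and its centroid becomes the spring rest offset (anchor).  The cluster
   count is fixed per part or chosen by the Bayesian information
   criterion BIC = n ln(R/n) + k ln n with k = S (d + 1), d = 2.
4. *Margin training*: with states fixed, the score is linear in the
   parameter vector beta, and beta is learned by a structured SVM:
   minimize 0.5 ||beta||^2 + C (sum of slacks) subject to positives
   scoring >= +1 and mined negative configurations <= -1, where all
   negatives from one image share a single slack variable.  The dual is
   optimized by coordinate descent, one constraint at a time; hard
   negatives are re-mined (top root locations per negative image) before
   every optimization round.  Spring parameters start at [0, 0, 0.01,
   0.01] and their quadratic terms are clamped >= epsilon after every
   pass to keep the springs convex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, warp
from sklearn.cluster import KMeans

from .features import PATCH_CELLS, FeatureConfig, compute_hog, to_grayscale
from .model import (
    BodyModel,
    KinematicTree,
    FLIP_MAP,
    PartPlacement,
    deformation_feature,
    infant_tree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedFrame",
    "TrainingConfig",
    "augment",
    "bbox_size",
    "cluster_states",
    "bic_select",
    "build_feature_vector",
    "train_model",
    "cross_validate",
]


@dataclass
class AnnotatedFrame:
    """An image with all 14 ground-truth joint locations (pixels)."""

    image: np.ndarray
    joints: dict[str, tuple[float, float]]
    source_id: str = ""
    transform: np.ndarray | None = None  # 3x3 affine from the source frame

    def validate(self, parts) -> None:
        h, w = self.image.shape[:2]
        for p in parts:
            if p not in self.joints:
                raise ValueError(f"frame {self.source_id}: missing joint {p}")
            x, y = self.joints[p]
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"frame {self.source_id}: joint {p} outside image")


@dataclass
class TrainingConfig:
    """Hyper-parameters of the learning pipeline."""

    C: float = 0.1
    states_per_part: int | str | dict = 2  # int, per-part dict, or "bic"
    bic_range: tuple[int, int] = (1, 6)  # inclusive
    rotations: tuple[float, ...] = (-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0)
    flip: bool = True
    folds: int = 10
    seed: int = 0
    epsilon_def: float = 1e-4
    max_passes: int = 20
    mining_rounds: int = 4
    neg_top_k: int = 10
    tol: float = 1e-6
    patience: int = 25  # passes without significant primal improvement
    #: "proximal": each mining round re-centers the regularizer at the
    #: current weights and restarts the duals (proximal-point sequence,
    #: approaches the hard margin over rounds); "persistent": one global
    #: soft-margin SVM whose dual variables live across rounds
    round_mode: str = "proximal"
    omega_score_quantile: float = 0.10
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.states_per_part == "bic" and self.bic_range[1] < self.bic_range[0]:
            raise ValueError("bic_range must be non-empty")


# ---------------------------------------------------------------- augment


def _affine_joints(joints: dict, mat: np.ndarray) -> dict:
    out = {}
    for p, (x, y) in joints.items():
        v = mat @ np.array([x, y, 1.0])
        out[p] = (float(v[0]), float(v[1]))
    return out


def augment(
    frame: AnnotatedFrame,
    rotations=( -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0),
    flip: bool = True,
) -> list[AnnotatedFrame]:
    """Rotated (and flipped) copies of a frame with transformed joints.

    Output count is ``len(rotations) * (2 if flip else 1)``; with an empty
    rotation set and no flip the input is returned unchanged (identity
    transform).  If a rotation pushes a joint outside the canvas the
    variant is padded rather than dropped (logged).
    """
    img = np.asarray(frame.image, dtype=np.float64)
    h, w = img.shape[:2]
    base: list[tuple[np.ndarray, dict, str]] = []
    variants_in = list(rotations) if len(tuple(rotations)) else [0.0]

    for deg in variants_in:
        theta = np.deg2rad(deg)
        # rotate about the image center (counter-clockwise in x-right/y-down)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        T2 = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
        mat = T2 @ R @ T1
        joints = _affine_joints(frame.joints, mat)
        pad = 0
        for x, y in joints.values():
            pad = max(pad, int(np.ceil(max(-x, -y, x - (w - 1), y - (h - 1), 0))))
        if pad:
            logger.info(
                "augment: rotation %s deg pushes joints off canvas; padding by %d px",
                deg,
                pad,
            )
            T2p = np.array([[1, 0, cx + pad], [0, 1, cy + pad], [0, 0, 1.0]])
            mat = T2p @ R @ T1
            joints = _affine_joints(frame.joints, mat)
            shape = (h + 2 * pad, w + 2 * pad)
        else:
            shape = (h, w)
        bg = float(np.median(img))
        rot = warp(
            img,
            AffineTransform(matrix=np.linalg.inv(mat)),
            output_shape=shape,
            order=1,
            cval=bg,
            preserve_range=True,
        )
        base.append((rot, joints, mat, f"{frame.source_id}/rot{deg:+g}"))

    out: list[AnnotatedFrame] = []
    for rot, joints, mat, sid in base:
        out.append(AnnotatedFrame(image=rot, joints=joints, source_id=sid, transform=mat))
        if flip:
            hh, ww = rot.shape[:2]
            F = np.array([[-1, 0, ww - 1], [0, 1, 0], [0, 0, 1.0]])
            fj = _affine_joints(joints, F)
            fj = {FLIP_MAP[p]: xy for p, xy in fj.items()}
            out.append(
                AnnotatedFrame(
                    image=rot[:, ::-1].copy(),
                    joints=fj,
                    source_id=sid + "/flip",
                    transform=F @ mat,
                )
            )
    return out


# --------------------------------------------------------------- bbox size


def bbox_size(
    frames: list[AnnotatedFrame],
    tree: KinematicTree | None = None,
    base_patch_px: float = 40.0,
) -> np.ndarray:
    """Per-frame part-patch side in pixels.

    For every limb (tree edge) the ratio of its length in a frame to its
    median length over the training set is computed; a frame's patch side
    is the 75% quantile (linear interpolation between order statistics)
    of its ratios times the base patch size.  Zero-length limbs are
    excluded (logged).
    """
    if not frames:
        raise ValueError("need at least one frame")
    tree = tree or infant_tree()
    lengths = np.zeros((len(frames), len(tree.edges)))
    for i, f in enumerate(frames):
        for k, (p, c) in enumerate(tree.edges):
            lengths[i, k] = np.hypot(
                f.joints[c][0] - f.joints[p][0], f.joints[c][1] - f.joints[p][1]
            )
    med = np.median(np.where(lengths > 0, lengths, np.nan), axis=0)
    sides = np.empty(len(frames))
    for i in range(len(frames)):
        ratios = []
        for k in range(len(tree.edges)):
            if lengths[i, k] == 0:
                logger.info("bbox_size: zero-length limb %s in frame %d", tree.edges[k], i)
                continue
            if np.isnan(med[k]) or med[k] == 0:
                continue
            ratios.append(lengths[i, k] / med[k])
        if not ratios:
            raise ValueError(f"frame {i}: no measurable limbs")
        sides[i] = float(np.quantile(ratios, 0.75)) * base_patch_px
    return sides


# -------------------------------------------------------------- clustering


def cluster_states(displacements: np.ndarray, S: int, seed: int = 0):
    """k-means over a part's parent-relative displacements.

    Returns ``(labels, centroids)``; centroids later serve as the spring
    rest offsets.  Deterministic for a fixed seed (10 restarts, best
    inertia).
    """
    pts = np.asarray(displacements, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("displacements must be (n, 2)")
    if S < 1 or S > len(pts):
        raise ValueError(f"need 1 <= S <= n points, got S={S}, n={len(pts)}")
    km = KMeans(n_clusters=S, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    return labels, km.cluster_centers_


def bic_select(displacements: np.ndarray, S_range, seed: int = 0):
    """Pick the cluster count minimizing BIC = n ln(R/n) + k ln(n),
    k = S (d + 1) with d = 2.

    A perfect fit (R = 0) wins immediately (the log term is guarded).
    Returns ``(best_S, {S: BIC})``.
    """
    pts = np.asarray(displacements, dtype=np.float64)
    n = len(pts)
    d = 2
    values: dict[int, float] = {}
    best_S, best = None, np.inf
    for S in S_range:
        if S > n:
            raise ValueError(f"S={S} exceeds n={n}")
        labels, centroids = cluster_states(pts, S, seed)
        R = float(((pts - centroids[labels]) ** 2).sum())
        if R <= 0.0:
            values[S] = -np.inf
            return S, values
        bic = n * np.log(R / n) + S * (d + 1) * np.log(n)
        values[S] = bic
        if bic < best:
            best_S, best = S, bic
    return best_S, values


# ----------------------------------------------------- feature vector phi


def _joint_to_placement(joint_px, cell: int, grid_shape) -> tuple[int, int]:
    """Top-left cell of the 5x5 patch whose center pixel is closest to a
    joint, clipped into the grid."""
    H, W = grid_shape
    # patch center pixel = (x + 2.5) * cell - 0.5  =>  x = (j + 0.5)/cell - 2.5
    x = round((joint_px[0] + 0.5) / cell - PATCH_CELLS / 2.0)
    y = round((joint_px[1] + 0.5) / cell - PATCH_CELLS / 2.0)
    return (
        int(np.clip(x, 0, W - PATCH_CELLS)),
        int(np.clip(y, 0, H - PATCH_CELLS)),
    )


def placements_from_joints(
    joints: dict, states: dict[str, int], level, tree: KinematicTree
) -> dict[str, PartPlacement]:
    """Map annotated pixel joints to cell placements with given states."""
    c = level.cell_size_px
    out = {}
    for p in tree.parts:
        x, y = _joint_to_placement(joints[p], c, level.grid_shape)
        out[p] = PartPlacement(x=x, y=y, state=int(states[p]))
    return out


def build_feature_vector(
    level, placements: dict[str, PartPlacement], model: BodyModel
) -> np.ndarray:
    """Feature vector phi(I, z) such that <beta, phi> equals the
    configuration score: HOG patches in the active filter slots, negated
    displacement features in the spring slots, indicators in the
    co-occurrence slots and 1 in the bias slot."""
    lay = model.layout
    phi = np.zeros(lay.dim)
    for p, pl in placements.items():
        patch = level.cells[
            pl.y : pl.y + PATCH_CELLS, pl.x : pl.x + PATCH_CELLS, :
        ]
        phi[lay.filter_slice(p, pl.state)] = patch.ravel()
        phi[lay.unary_slice(p).start + pl.state] += 1.0
    for e in model.tree.edges:
        pp, pc = placements[e[0]], placements[e[1]]
        r = model.anchors[e][pp.state, pc.state]
        v = deformation_feature((pc.x - r[0], pc.y - r[1]), (pp.x, pp.y))
        phi[lay.deformation_entry(e, pp.state, pc.state)] = -v
        phi[lay.pair_entry(e, pp.state, pc.state)] += 1.0
    phi[lay.bias_index] = 1.0
    return phi


# ------------------------------------------------------------ optimization


def _primal_objective(beta, center, C, pos_phis, neg_groups):
    """Primal value of the margin problem regularized toward ``center``
    (the spring initialization plus accumulated floor projections)."""
    d = beta - center
    obj = 0.5 * float(d @ d)
    for phi in pos_phis:
        obj += C * max(0.0, 1.0 - float(beta @ phi))
    for phis in neg_groups:
        worst = max((max(0.0, 1.0 + float(beta @ phi)) for phi in phis), default=0.0)
        obj += C * worst
    return obj


class _WorkingSet:
    """Constraint cache with persistent dual variables.

    Every constraint is ``beta . phi_signed >= 1`` (negatives enter
    sign-folded).  Positives each own a slack (alpha in [0, C]); all
    negatives mined from one image share a slack, so their alphas jointly
    sum to at most C.  Alphas persist across mining rounds, keeping
    ``beta = beta_init + sum_i alpha_i phi_i`` consistent as the cache
    grows.
    """

    def __init__(self):
        self.phis: list[np.ndarray] = []
        self.q: list[float] = []
        self.group: list[int] = []  # -1 for positives, image id for negatives
        self.alpha: list[float] = []
        self.pos_phis: list[np.ndarray] = []  # unfolded, for the objective
        self.neg_phis: dict[int, list[np.ndarray]] = {}

    def add_positive(self, phi: np.ndarray) -> None:
        self.phis.append(phi)
        self.q.append(float(phi @ phi))
        self.group.append(-1)
        self.alpha.append(0.0)
        self.pos_phis.append(phi)

    def add_negative(self, phi: np.ndarray, image_id: int) -> None:
        self.phis.append(-phi)
        self.q.append(float(phi @ phi))
        self.group.append(image_id)
        self.alpha.append(0.0)
        self.neg_phis.setdefault(image_id, []).append(phi)

    def group_sums(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for a, g in zip(self.alpha, self.group):
            if g >= 0:
                out[g] = out.get(g, 0.0) + a
        return out


def _dcd_optimize(beta, center, ws: _WorkingSet, C, max_passes, tol, quad_idx, eps_def, patience=25):
    """One optimization round: dual coordinate descent over the working
    set, then a spring-floor projection folded into the proximal center.

    The invariant ``beta = center + sum_i alpha_i phi_i`` holds throughout,
    so every alpha update is an exact coordinate step on the dual of
    ``min 0.5 ||beta - center||^2 + C sum(slacks)``.  Dual ascent does not
    make the *primal* monotone pass by pass, so the round retains the
    best (lowest-primal) iterate seen: the logged trace and the returned
    state are those of the retained iterate, while exploration continues
    from the raw one.

    Projecting the quadratic spring weights onto their positivity floor
    happens once per round, *after* the passes (projecting inside the
    loop fights the positives' preference for soft springs and
    oscillates); the projection delta is absorbed into ``center`` so the
    invariant survives into the next round.  Inference tolerates
    transiently unclamped springs because the spring maximization is
    exact for any coefficient sign.

    Returns ``(beta, center, trace)``.
    """
    gsum = ws.group_sums()
    trace = []
    best_obj = np.inf
    best = None
    since_improved = 0
    for _ in range(max_passes):
        for i, phi in enumerate(ws.phis):
            q = ws.q[i]
            if q == 0.0:
                continue
            g = ws.group[i]
            grad = float(beta @ phi) - 1.0
            upper = C if g < 0 else C - (gsum[g] - ws.alpha[i])
            new = float(np.clip(ws.alpha[i] - grad / q, 0.0, max(upper, 0.0)))
            if new != ws.alpha[i]:
                beta += (new - ws.alpha[i]) * phi
                if g >= 0:
                    gsum[g] += new - ws.alpha[i]
                ws.alpha[i] = new
        obj = _primal_objective(beta, center, C, ws.pos_phis, list(ws.neg_phis.values()))
        if obj < best_obj:
            since_improved = 0 if obj < best_obj - tol * max(1.0, abs(obj)) else since_improved + 1
            best_obj = obj
            best = (beta.copy(), list(ws.alpha))
        else:
            since_improved += 1
        trace.append(best_obj)
        # improvements arrive through dual oscillation, so be patient
        if since_improved >= patience:
            break
    if best is not None:
        beta, ws.alpha = best[0], best[1]
    before = beta[quad_idx].copy()
    np.maximum(beta[quad_idx], eps_def, out=beta[quad_idx])
    center = center.copy()
    center[quad_idx] += beta[quad_idx] - before
    return beta, center, trace


def _cache_margins_ok(beta, ws: _WorkingSet, tol: float = 1e-3) -> bool:
    for phi in ws.pos_phis:
        if float(beta @ phi) < 1.0 - tol:
            return False
    for phis in ws.neg_phis.values():
        for phi in phis:
            if float(beta @ phi) > -1.0 + tol:
                return False
    return True


# ------------------------------------------------------------ train_model


def _resolve_states(cfg: TrainingConfig, tree: KinematicTree) -> dict | str:
    if cfg.states_per_part == "bic":
        return "bic"
    if isinstance(cfg.states_per_part, dict):
        return dict(cfg.states_per_part)
    return {p: int(cfg.states_per_part) for p in tree.parts}


def _prepare_positives(frames, tree, cfg):
    """Scale-normalize frames and compute HOG level-0 grids."""
    cell = cfg.feature_config.cell_size_px
    base = float(PATCH_CELLS * cell)
    # patch sizes are measured on the upsampled frames the model sees
    sides = bbox_size(frames, tree, base_patch_px=base) / cfg.feature_config.upsample
    prepared = []
    for f, side in zip(frames, sides):
        s = base / side
        img = np.asarray(to_grayscale(f.image), dtype=np.float64)
        if abs(s - 1.0) > 1e-3:
            shape = (max(int(round(img.shape[0] * s)), cell * PATCH_CELLS),
                     max(int(round(img.shape[1] * s)), cell * PATCH_CELLS))
            img = resize(img, shape, order=1, anti_aliasing=True, preserve_range=True)
        joints = {p: (x * s, y * s) for p, (x, y) in f.joints.items()}
        level = compute_hog(
            img, cell, cfg.feature_config.bins, cfg.feature_config.normalize
        )
        prepared.append((img, joints, level))
    return prepared


def _assign_states(prepared, tree, cfg):
    """Cluster per-part parent-relative displacements (cell units)."""
    cell = cfg.feature_config.cell_size_px
    want = _resolve_states(cfg, tree)
    states_per_part: dict[str, int] = {}
    labels: dict[str, np.ndarray] = {}
    centroids: dict[str, np.ndarray] = {}
    for p in tree.parts:
        parent = tree.parent_of(p)
        if parent is None:
            states_per_part[p] = 1
            labels[p] = np.zeros(len(prepared), dtype=int)
            centroids[p] = np.zeros((1, 2))
            continue
        disp = np.array(
            [
                [
                    (joints[p][0] - joints[parent][0]) / cell,
                    (joints[p][1] - joints[parent][1]) / cell,
                ]
                for _, joints, _ in prepared
            ]
        )
        if want == "bic":
            lo, hi = cfg.bic_range
            S, _ = bic_select(disp, range(lo, min(hi, len(disp)) + 1), cfg.seed)
        else:
            S = min(want[p], len(disp))
        lab, cen = cluster_states(disp, S, cfg.seed)
        states_per_part[p] = S
        labels[p] = lab
        centroids[p] = cen
    return states_per_part, labels, centroids


def train_model(
    positives: list[AnnotatedFrame],
    negatives: list[np.ndarray],
    config: TrainingConfig | None = None,
    tree: KinematicTree | None = None,
):
    """Learn a :class:`BodyModel`; returns ``(model, log)`` where ``log``
    is a DataFrame with one row per optimization pass (round, pass,
    objective, negative-cache size)."""
    from .features import HOGPyramid
    from .inference import infer_pose

    cfg = config or TrainingConfig()
    tree = tree or infant_tree()
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative image")
    for f in positives:
        f.validate(tree.parts)

    frames = []
    for f in positives:
        frames.extend(augment(f, cfg.rotations, cfg.flip))
    prepared = _prepare_positives(frames, tree, cfg)
    states_per_part, labels, centroids = _assign_states(prepared, tree, cfg)

    model = BodyModel.empty(tree, states_per_part, cfg.feature_config)
    for p, c in tree.edges:
        # anchors: child-state centroid, replicated over parent states
        model.anchors[(p, c)][:] = centroids[c][None, :, :]

    cell = cfg.feature_config.cell_size_px
    pos_phis, pos_levels, pos_placements = [], [], []
    for i, (_, joints, level) in enumerate(prepared):
        st = {p: labels[p][i] for p in tree.parts}
        pl = placements_from_joints(joints, st, level, tree)
        pos_placements.append(pl)
        pos_levels.append(level)
        pos_phis.append(build_feature_vector(level, pl, model))

    lay = model.layout
    quad_idx = lay.quadratic_indices()
    beta = model.flatten()
    center = beta.copy()  # proximal center: the spring initialization

    # hard negatives are mined at the single scale the model was built for
    from .features import upsample_image

    neg_images = [
        upsample_image(np.asarray(n, dtype=np.float64), cfg.feature_config.upsample)
        for n in negatives
    ]
    neg_levels = [
        compute_hog(n, cell, cfg.feature_config.bins, cfg.feature_config.normalize)
        for n in neg_images
    ]

    rows = []
    if cfg.round_mode not in ("proximal", "persistent"):
        raise ValueError(f"unknown round_mode {cfg.round_mode!r}")
    # growing hard-negative cache; dual variables persist across rounds in
    # "persistent" mode and restart from the re-centered weights in
    # "proximal" mode
    ws = _WorkingSet()
    for phi in pos_phis:
        ws.add_positive(phi)
    seen: list[set] = [set() for _ in neg_levels]
    for rnd in range(cfg.mining_rounds):
        model.unflatten(beta)
        new = 0
        for gi, lvl in enumerate(neg_levels):
            pyr = HOGPyramid(levels=[lvl], interval=cfg.feature_config.interval)
            cands = infer_pose(model, pyr, top_k=cfg.neg_top_k)
            for c in cands:
                if c.score <= -1.0 + 1e-3:
                    continue  # not a margin violator
                key = tuple(sorted((p, pl.x, pl.y, pl.state) for p, pl in c.placements.items()))
                if key in seen[gi]:
                    continue
                seen[gi].add(key)
                ws.add_negative(build_feature_vector(lvl, c.placements, model), gi)
                new += 1
        if rnd > 0 and new == 0 and _cache_margins_ok(beta, ws):
            break  # no unseen violator and the cached constraints hold
        if cfg.round_mode == "proximal":
            center = beta.copy()
            ws.alpha = [0.0] * len(ws.alpha)
        n_neg = sum(len(v) for v in ws.neg_phis.values())
        beta, center, trace = _dcd_optimize(
            beta, center, ws, cfg.C, cfg.max_passes, cfg.tol, quad_idx,
            cfg.epsilon_def, cfg.patience,
        )
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"non-finite parameters after round {rnd}")
        for k, obj in enumerate(trace):
            rows.append({"round": rnd, "pass": k, "objective": obj, "n_negatives": n_neg})

    model.unflatten(beta)

    # final margin audit over the working set
    pos_scores = np.array([float(beta @ phi) for phi in ws.pos_phis])
    neg_scores = np.array(
        [float(beta @ phi) for phis in ws.neg_phis.values() for phi in phis]
    )
    margins = {
        "positive_min": float(pos_scores.min()) if len(pos_scores) else np.nan,
        "negative_max": float(neg_scores.max()) if len(neg_scores) else np.nan,
        "n_negatives_mined": int(len(neg_scores)),
    }

    # occlusion threshold: low quantile of per-part appearance scores on positives
    part_scores = {p: [] for p in tree.parts}
    for level, pl in zip(pos_levels, pos_placements):
        for p, place in pl.items():
            patch = level.cells[
                place.y : place.y + PATCH_CELLS, place.x : place.x + PATCH_CELLS, :
            ]
            s = float(np.vdot(model.filters[(p, place.state)], patch))
            s += float(model.cooc_unary[p][place.state])
            part_scores[p].append(s)
    model.omega_score = {
        p: float(np.quantile(v, cfg.omega_score_quantile)) for p, v in part_scores.items()
    }
    log = pd.DataFrame(rows)
    log.attrs["margins"] = margins
    return model, log


# -------------------------------------------------------- cross-validation


def cross_validate(
    positives: list[AnnotatedFrame],
    negatives: list[np.ndarray],
    C_grid,
    folds: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
    refine_factor: float = 3.0,
    metric_fn=None,
):
    """Two-stage search for the regularization constant C.

    Stage 1 scores a coarse grid by k-fold CV; stage 2 refines a narrow
    geometric grid around the winner.  The selection metric is mean
    held-out WCA at a threshold of half the base patch size; ties break
    toward the smallest C.  Returns ``(best_C, table)``.
    """
    from .inference import track_frames
    from .motion import JointTrajectory, wca

    cfg = config or TrainingConfig()
    C_grid = sorted(set(float(c) for c in C_grid))
    if folds > len(positives):
        raise ValueError("more folds than positive frames")

    def default_metric(C: float) -> float:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(positives))
        splits = np.array_split(idx, folds)
        scores = []
        for k in range(folds):
            test_idx = splits[k]
            train_idx = np.concatenate([splits[j] for j in range(folds) if j != k])
            if len(train_idx) == 0 or len(test_idx) == 0:
                continue
            sub = replace(cfg, C=C)
            m, _ = train_model([positives[i] for i in train_idx], negatives, sub)
            held = [positives[i] for i in test_idx]
            poses = track_frames(m, [f.image for f in held])
            pred = JointTrajectory.from_poses(poses)
            truth = JointTrajectory(
                frames=np.arange(len(held)),
                joints={
                    p: np.array([f.joints[p] for f in held]) for p in m.tree.parts
                },
            )
            omega = cfg.feature_config.patch_px / (2.0 * cfg.feature_config.upsample)
            scores.append(wca(pred, truth, omega_wca=omega, mm_per_px=1.0))
        return float(np.mean(scores)) if scores else 0.0

    cv_metric = metric_fn or default_metric
    table = []
    best_C, best = C_grid[0], -np.inf
    for C in C_grid:
        m = cv_metric(C)
        table.append({"stage": "coarse", "C": C, "wca": m})
        if m > best:  # strict: earlier (smaller) C wins ties
            best_C, best = C, m
    if len(C_grid) > 1:
        for C in (best_C / refine_factor, best_C * refine_factor):
            m = cv_metric(C)
            table.append({"stage": "refine", "C": C, "wca": m})
            if m > best:
                best_C, best = C, m
    return best_C, pd.DataFrame(table)
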