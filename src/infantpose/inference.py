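"""Part detection: template responses, tree dynamic programming, NMS,
occlusion-aware thresholding and temporal search-space restriction.

The detection score of a full part placement is the sum of HOG template
responses, quadratic spring penalties along tree edges, co-occurrence
scores and a bias.  Because the graph is a tree, the global maximum over
all (location x state) assignments is found exactly with one leaf-to-root
message pass: each child sends its parent, for every parent state and
location, the best achievable child subtree score including the spring
between them.  Argmax backpointers are kept so the maximizing placement
of every part is recovered by backtracking from the best root location.

The inner "best child location per parent location" maximization is a
generalized distance transform; it separates per axis because the spring
cost is a sum of per-axis linear + quadratic terms.  It is computed here
as two vectorized per-axis max-reductions (exact for any sign of the
linear terms), with a brute-force non-separable version retained as the
test oracle.

All argmax operations break ties toward the smallest (level, y, x, state)
in lexicographic order, so detections are deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import PATCH_CELLS, HOGLevel, HOGPyramid
from .model import (
    BodyModel,
    PartPlacement,
    PoseEstimate,
    deformation_feature,
)

__all__ = [
    "filter_response",
    "response_map",
    "deformation_feature",
    "deformation_score",
    "infer_pose",
    "nms",
    "apply_occlusion_threshold",
    "restrict_search_space",
    "track_frames",
]

#: sentinel for disallowed placements (finite, so arithmetic stays NaN-free)
NEG_INF = -1e15


def filter_response(filt: np.ndarray, level: HOGLevel, l: tuple[int, int]) -> float:
    """Cross-correlation of one part template with the HOG grid at cell
    location ``l = (x, y)`` (top-left cell of the 5x5 footprint)."""
    x, y = l
    H, W = level.grid_shape
    if not (0 <= x <= W - PATCH_CELLS and 0 <= y <= H - PATCH_CELLS):
        raise ValueError(f"footprint at {l} outside {H}x{W} grid")
    patch = level.cells[y : y + PATCH_CELLS, x : x + PATCH_CELLS, :]
    return float(np.vdot(filt, patch))


def _level_windows(level: HOGLevel) -> np.ndarray:
    """All 5x5-cell patches of a level as a (rows', cols', 225) matrix.

    Cached on the level instance: the grid is immutable once computed, and
    hard-negative mining rescans the same levels every round.
    """
    cached = getattr(level, "_windows", None)
    if cached is not None:
        return cached
    H, W = level.grid_shape
    if H < PATCH_CELLS or W < PATCH_CELLS:
        raise ValueError("level grid smaller than the template footprint")
    win = sliding_window_view(level.cells, (PATCH_CELLS, PATCH_CELLS, level.bins))
    flat = np.ascontiguousarray(
        win.reshape(H - PATCH_CELLS + 1, W - PATCH_CELLS + 1, -1)
    )
    level._windows = flat
    return flat


def response_map(filt: np.ndarray, level: HOGLevel) -> np.ndarray:
    """Template response at every valid top-left cell; shape
    ``(rows - 4, cols - 4)`` indexed ``[y, x]``."""
    return _level_windows(level) @ filt.ravel()


def deformation_score(zeta: np.ndarray, la, lb, anchor=(0.0, 0.0)) -> float:
    """Spring contribution of edge (child a, parent b):
    ``-<zeta, psi(la - lb - anchor)>`` (zero at the rest offset)."""
    v = deformation_feature(
        (la[0] - anchor[0], la[1] - anchor[1]), (lb[0], lb[1])
    )
    return -float(np.asarray(zeta) @ v)


def _axis_max(values: np.ndarray, lin: float, quad: float, rest: float):
    """For each target index p, max over source index q of
    ``values[..., q] - lin*(q - p - rest) - quad*(q - p - rest)**2``
    along the last axis.  Returns (max, argmax-q)."""
    n = values.shape[-1]
    q = np.arange(n, dtype=np.float64)
    v = q[None, :] - q[:, None] - rest  # [p, q]
    cost = lin * v + quad * v * v
    a = values[..., None, :] - cost  # [..., p, q]
    arg = a.argmax(-1)
    best = np.take_along_axis(a, arg[..., None], -1)[..., 0]
    return best, arg


def spring_max(child_total: np.ndarray, zeta: np.ndarray, anchor: np.ndarray):
    """Best child subtree score per parent location, under the spring.

    ``child_total`` is the child's accumulated score map ``[yc, xc]``;
    returns ``(msg[yp, xp], argy[yp, xp], argx[yp, xp])`` where
    ``msg(lp) = max_lc child_total(lc) - <zeta, psi(lc - lp - anchor)>``.
    """
    zx_l, zy_l, zx_q, zy_q = (float(z) for z in np.asarray(zeta))
    rx, ry = float(anchor[0]), float(anchor[1])
    # x pass: for each row yc, best xc per xp
    mx, argx_row = _axis_max(child_total, zx_l, zx_q, rx)  # [yc, xp]
    # y pass: for each column xp, best yc per yp
    my, argy = _axis_max(mx.T, zy_l, zy_q, ry)  # [xp, yp]
    msg = my.T
    argy = argy.T  # [yp, xp] -> best yc
    argx = np.take_along_axis(argx_row.T, argy.T, -1).T  # argx_row[argy, xp]
    return msg, argy, argx


def spring_max_bruteforce(child_total: np.ndarray, zeta: np.ndarray, anchor: np.ndarray):
    """O(n^2) reference for :func:`spring_max` (test oracle)."""
    H, W = child_total.shape
    msg = np.full((H, W), -np.inf)
    argy = np.zeros((H, W), dtype=np.intp)
    argx = np.zeros((H, W), dtype=np.intp)
    for yp in range(H):
        for xp in range(W):
            for yc in range(H):
                for xc in range(W):
                    s = child_total[yc, xc] + deformation_score(
                        zeta, (xc, yc), (xp, yp), anchor
                    )
                    if s > msg[yp, xp]:
                        msg[yp, xp], argy[yp, xp], argx[yp, xp] = s, yc, xc
    return msg, argy, argx


def _level_region_mask(level: HOGLevel, region) -> np.ndarray | None:
    """Additive mask over valid placements: 0 inside the region (judged by
    patch center in original-image pixels), NEG_INF outside."""
    if region is None:
        return None
    x0, y0, x1, y1 = region
    H, W = level.grid_shape
    h, w = H - PATCH_CELLS + 1, W - PATCH_CELLS + 1
    if h <= 0 or w <= 0 or x1 <= x0 or y1 <= y0:
        return np.full((max(h, 0), max(w, 0)), NEG_INF)
    xs = np.arange(w)
    ys = np.arange(h)
    cx = np.array([level.patch_center_px(x, 0)[0] for x in xs])
    cy = np.array([level.patch_center_px(0, y)[1] for y in ys])
    ok = ((cy >= y0) & (cy <= y1))[:, None] & ((cx >= x0) & (cx <= x1))[None, :]
    return np.where(ok, 0.0, NEG_INF)


def _dp_level(model: BodyModel, level: HOGLevel, region=None):
    """One leaf-to-root pass; returns root score maps and backpointers."""
    tree = model.tree
    mask = _level_region_mask(level, region)
    if mask is not None and (mask.size == 0 or mask.max() < 0):
        return None  # empty search region at this level

    totals: dict[str, np.ndarray] = {}
    backptr: dict[tuple[str, str], tuple] = {}
    resp: dict[str, np.ndarray] = {}
    # one GEMM for all part filters against all patches of the level
    win = _level_windows(level)
    fkeys = [(p, s) for p in tree.parts for s in range(model.states_per_part[p])]
    fmat = np.stack([model.filters[k].ravel() for k in fkeys])
    all_resp = win @ fmat.T  # (rows', cols', n_filters)
    resp_by_key = {k: all_resp[..., i] for i, k in enumerate(fkeys)}
    for part in tree.leaves_to_root():
        S = model.states_per_part[part]
        maps = np.stack([resp_by_key[(part, s)] for s in range(S)])
        resp[part] = maps + model.cooc_unary[part][:, None, None]
        t = resp[part].copy()
        if mask is not None:
            t = t + mask[None, :, :]
        for child in tree.children_of(part):
            Sc = model.states_per_part[child]
            zeta = model.deformations[(part, child)]
            anch = model.anchors[(part, child)]
            pair = model.cooc_pair[(part, child)]
            msgs = np.empty_like(t)
            st = np.empty(t.shape, dtype=np.intp)
            ay = np.empty(t.shape, dtype=np.intp)
            ax = np.empty(t.shape, dtype=np.intp)
            for sp in range(S):
                best = None
                for sc in range(Sc):
                    m, ayc, axc = spring_max(totals[child][sc], zeta[sp, sc], anch[sp, sc])
                    m = m + pair[sp, sc]
                    if best is None:
                        best, bst, bay, bax = m, np.full(m.shape, sc, np.intp), ayc, axc
                    else:
                        upd = m > best  # strict: earliest state wins ties
                        best = np.where(upd, m, best)
                        bst = np.where(upd, sc, bst)
                        bay = np.where(upd, ayc, bay)
                        bax = np.where(upd, axc, bax)
                msgs[sp], st[sp], ay[sp], ax[sp] = best, bst, bay, bax
            backptr[(part, child)] = (st, ay, ax)
            t = t + msgs
        totals[part] = t
    root_map = totals[tree.root] + model.bias
    return root_map, backptr, resp


def _backtrack(model: BodyModel, backptr, resp, s_root: int, y: int, x: int):
    placements = {model.tree.root: PartPlacement(x=x, y=y, state=s_root)}
    part_scores = {model.tree.root: float(resp[model.tree.root][s_root, y, x])}
    stack = [model.tree.root]
    while stack:
        parent = stack.pop()
        pl = placements[parent]
        for child in model.tree.children_of(parent):
            st, ay, ax = backptr[(parent, child)]
            sc = int(st[pl.state, pl.y, pl.x])
            yc = int(ay[pl.state, pl.y, pl.x])
            xc = int(ax[pl.state, pl.y, pl.x])
            placements[child] = PartPlacement(x=xc, y=yc, state=sc)
            part_scores[child] = float(resp[child][sc, yc, xc])
            stack.append(child)
    return placements, part_scores


def infer_pose(
    model: BodyModel,
    pyramid: HOGPyramid,
    search_region=None,
    top_k: int = 5,
) -> list[PoseEstimate]:
    """Detect part configurations in a frame.

    Parameters
    ----------
    search_region : (x0, y0, x1, y1) pixel box or None
        If given, every part placement is restricted to patch centers
        inside the box (whole-body temporal restriction).
    top_k : int
        Root locations kept per pyramid level before NMS.

    Returns score-sorted :class:`PoseEstimate` candidates across levels.
    An empty list (with a warning logged by callers) results from an
    empty search region.
    """
    up = model.feature_config.upsample
    region = None
    if search_region is not None:
        region = tuple(v * up for v in search_region)
    candidates: list[PoseEstimate] = []
    for li, level in enumerate(pyramid):
        H, W = level.grid_shape
        if H < PATCH_CELLS or W < PATCH_CELLS:
            continue
        out = _dp_level(model, level, region)
        if out is None:
            continue
        root_map, backptr, resp = out
        flat = root_map.max(axis=0)  # best over root states, [y, x]
        order = np.argsort(-flat, axis=None, kind="stable")[:top_k]
        for idx in order:
            y, x = np.unravel_index(idx, flat.shape)
            s_root = int(root_map[:, y, x].argmax())
            score = float(root_map[s_root, y, x])
            if score < NEG_INF / 2:
                continue
            placements, part_scores = _backtrack(model, backptr, resp, s_root, int(y), int(x))
            joints = {}
            for p, pl in placements.items():
                cx, cy = level.patch_center_px(pl.x, pl.y)
                joints[p] = (cx / up, cy / up)  # back to native pixels
            candidates.append(
                PoseEstimate(
                    placements=placements,
                    part_scores=part_scores,
                    joints_px=joints,
                    score=score,
                    level=li,
                )
            )
    candidates.sort(
        key=lambda c: (
            -c.score,
            c.level,
            c.placements[model.tree.root].y,
            c.placements[model.tree.root].x,
            c.placements[model.tree.root].state,
        )
    )
    return candidates


def _root_box(model: BodyModel, pose: PoseEstimate, pyramid: HOGPyramid):
    level = pyramid.levels[pose.level]
    pl = pose.placements[model.tree.root]
    x0, y0 = level.cell_topleft_px(pl.x, pl.y)
    side = PATCH_CELLS * level.cell_size_px / level.scale
    return x0, y0, x0 + side, y0 + side


def _iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / area


def nms(
    candidates: list[PoseEstimate],
    overlap_threshold: float = 0.3,
    model: BodyModel | None = None,
    pyramid: HOGPyramid | None = None,
    boxes: list[tuple] | None = None,
    single_subject: bool = True,
) -> list[PoseEstimate]:
    """Greedy non-maximum suppression on root boxes (IoU).

    Root boxes are derived from ``model``/``pyramid`` or passed explicitly
    via ``boxes`` (same order as ``candidates``).  With ``single_subject``
    (the recording scenario: one infant per frame) only the top survivor
    is returned.
    """
    if boxes is None:
        if model is None or pyramid is None:
            raise ValueError("nms needs either boxes or (model, pyramid)")
        boxes = [_root_box(model, c, pyramid) for c in candidates]
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].score)
    keep: list[int] = []
    for i in order:
        if all(_iou(boxes[i], boxes[j]) <= overlap_threshold for j in keep):
            keep.append(i)
    survivors = [candidates[i] for i in keep]
    return survivors[:1] if single_subject else survivors


def apply_occlusion_threshold(pose: PoseEstimate, omega_score) -> PoseEstimate:
    """Flag parts whose appearance score falls below the occlusion
    threshold; locations are retained but marked invisible so they are
    excluded from angle computation and metrics.

    ``omega_score`` is a global float or a per-part mapping (missing parts
    fall back to ``-inf``, i.e. always visible).
    """
    vis = {}
    for p, s in pose.part_scores.items():
        thr = omega_score.get(p, -np.inf) if isinstance(omega_score, dict) else omega_score
        vis[p] = bool(s >= thr)
    return PoseEstimate(
        placements=pose.placements,
        part_scores=pose.part_scores,
        joints_px=pose.joints_px,
        score=pose.score,
        level=pose.level,
        visible=vis,
    )


def restrict_search_space(prev_pose: PoseEstimate, omega_dist: float, image_shape):
    """Whole-body search box for the next frame: the bounding box of the
    previous joint estimates dilated by ``omega_dist`` pixels on every
    side, clipped to the image."""
    xs = [xy[0] for xy in prev_pose.joints_px.values()]
    ys = [xy[1] for xy in prev_pose.joints_px.values()]
    h, w = image_shape[:2]
    x0 = max(0.0, min(xs) - omega_dist)
    y0 = max(0.0, min(ys) - omega_dist)
    x1 = min(float(w - 1), max(xs) + omega_dist)
    y1 = min(float(h - 1), max(ys) + omega_dist)
    return (x0, y0, x1, y1)


def track_frames(
    model: BodyModel,
    frames,
    omega_dist: float = 30.0,
    omega_score=None,
    overlap_threshold: float = 0.3,
    full_search_every: int = 0,
) -> list[PoseEstimate | None]:
    """Detect the figure in every frame of a sequence.

    The exhaustive search runs on the first frame only; later frames are
    restricted to the previous detection's neighbourhood (and every
    ``full_search_every``-th frame if that is positive).
    """
    from .features import pyramid_from_config

    poses: list[PoseEstimate | None] = []
    prev: PoseEstimate | None = None
    for t, frame in enumerate(frames):
        img = np.asarray(frame, dtype=np.float64)
        pyr = pyramid_from_config(img, model.feature_config)
        region = None
        if prev is not None and not (full_search_every and t % full_search_every == 0):
            region = restrict_search_space(prev, omega_dist, img.shape)
        cands = infer_pose(model, pyr, search_region=region)
        if not cands and region is not None:  # lost track: fall back to full search
            cands = infer_pose(model, pyr)
        if not cands:
            poses.append(None)
            continue
        best = nms(cands, overlap_threshold, model=model, pyramid=pyr)[0]
        thr = omega_score if omega_score is not None else model.omega_score
        if thr is not None:
            best = apply_occlusion_threshold(best, thr)
        poses.append(best)
        prev = best
    return poses
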