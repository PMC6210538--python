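"""Synthetic supine articulated-figure generator with exact ground truth.

Emulates the recording scenario the detector is meant for: a single
infant lying on its back on a plain surface, filmed by a fixed overhead
camera.  The figure is a 2-D stick-figure proxy, not a photorealistic
infant: the detector consumes HOG statistics, so textured limb strips on
a noisy background exercise every code path while keeping ground truth
exact.

Kinematics: a 14-joint tree (head-rooted).  Each bone's direction is the
parent bone's direction rotated by ``sigma * (180 - theta)`` degrees,
where ``theta`` is the interior angle at the connecting joint and
``sigma`` (+1 left side, -1 right side) mirrors the two body halves.
Setting every angle to 180 therefore lays all limbs out collinearly
along the body axis.  The generating angles are returned with each pose
and are recoverable exactly from the joint coordinates, so angle-encoding
code can be validated end to end.

Left and right limbs carry different texture stripe periods by default
so that mirrored appearance states remain separable under orientation
features (which are blind to texture phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import KinematicTree, infant_tree
from .motion import AngleSeries, JointTrajectory
from .training import AnnotatedFrame

__all__ = [
    "FigureConfig",
    "MotionConfig",
    "sample_pose",
    "render_frame",
    "render_negative",
    "generate_sequence",
    "PoseSampleError",
]


class PoseSampleError(RuntimeError):
    """Raised when no pose fitting the canvas is found."""


#: default interior-angle ranges (degrees); *_attach angles place the
#: shoulder/hip girdle relative to the body axis
DEFAULT_ANGLE_RANGES = {
    "left_shoulder_attach": (78.0, 102.0),
    "right_shoulder_attach": (78.0, 102.0),
    "left_hip_attach": (150.0, 170.0),
    "right_hip_attach": (150.0, 170.0),
    "left_shoulder": (55.0, 125.0),
    "right_shoulder": (55.0, 125.0),
    "left_elbow": (90.0, 170.0),
    "right_elbow": (90.0, 170.0),
    "left_hip": (115.0, 165.0),
    "right_hip": (115.0, 165.0),
    "left_knee": (100.0, 170.0),
    "right_knee": (100.0, 170.0),
}

DEFAULT_LIMB_LENGTHS = {
    ("head", "neck"): 14.0,
    ("neck", "left_shoulder"): 11.0,
    ("neck", "right_shoulder"): 11.0,
    ("left_shoulder", "left_elbow"): 15.0,
    ("right_shoulder", "right_elbow"): 15.0,
    ("left_elbow", "left_hand"): 14.0,
    ("right_elbow", "right_hand"): 14.0,
    ("neck", "left_hip"): 26.0,
    ("neck", "right_hip"): 26.0,
    ("left_hip", "left_knee"): 16.0,
    ("right_hip", "right_knee"): 16.0,
    ("left_knee", "left_foot"): 15.0,
    ("right_knee", "right_foot"): 15.0,
}

#: angle name that orients bone (parent, child), and its mirror sign
_BONE_ANGLE = {
    ("neck", "left_shoulder"): ("left_shoulder_attach", +1.0),
    ("neck", "right_shoulder"): ("right_shoulder_attach", -1.0),
    ("left_shoulder", "left_elbow"): ("left_shoulder", +1.0),
    ("right_shoulder", "right_elbow"): ("right_shoulder", -1.0),
    ("left_elbow", "left_hand"): ("left_elbow", -1.0),
    ("right_elbow", "right_hand"): ("right_elbow", +1.0),
    ("neck", "left_hip"): ("left_hip_attach", +1.0),
    ("neck", "right_hip"): ("right_hip_attach", -1.0),
    ("left_hip", "left_knee"): ("left_hip", +1.0),
    ("right_hip", "right_knee"): ("right_hip", -1.0),
    ("left_knee", "left_foot"): ("left_knee", -1.0),
    ("right_knee", "right_foot"): ("right_knee", +1.0),
}


@dataclass
class FigureConfig:
    """Geometry, appearance and sampling ranges of the rendered figure."""

    image_size: tuple[int, int] = (120, 160)  # (rows, cols)
    limb_lengths: dict = field(default_factory=lambda: dict(DEFAULT_LIMB_LENGTHS))
    limb_width: float = 10.0
    head_radius: float = 8.0
    torso_width_factor: float = 1.5  # neck-hip strips are this much wider
    background: float = 0.15
    foreground: float = 0.70
    texture_amplitude: float = 0.18
    texture_period: float = 7.0
    #: left/right asymmetry cue: stripe period multipliers per body side,
    #: so mirrored limbs stay separable under orientation features
    side_period_factor: tuple[float, float] = (1.0, 1.6)  # (left, right)
    noise_sigma: float = 0.02
    aa_px: float = 1.0  # soft-edge width; 0 renders hard edges
    angle_ranges: dict = field(default_factory=lambda: dict(DEFAULT_ANGLE_RANGES))
    body_angle_range: tuple[float, float] = (-8.0, 8.0)  # vs +x axis, degrees
    margin: float = 4.0
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in self.angle_ranges.items():
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValueError(f"angle range for {name} outside [0, 180]")
        if self.limb_width <= 0 or any(v <= 0 for v in self.limb_lengths.values()):
            raise ValueError("limb lengths and width must be positive")

    @property
    def tree(self) -> KinematicTree:
        return infant_tree()


def _rot(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def forward_kinematics(config: FigureConfig, head_xy, body_angle_deg: float, angles: dict):
    """Joint coordinates from the head position, body-axis angle and the
    interior angles; pure geometry, no randomness."""
    tree = config.tree
    joints = {"head": np.asarray(head_xy, dtype=np.float64)}
    bone_dir = {("head", "neck"): _rot(body_angle_deg) @ np.array([1.0, 0.0])}
    joints["neck"] = joints["head"] + config.limb_lengths[("head", "neck")] * bone_dir[
        ("head", "neck")
    ]
    order = [p for p in reversed(tree.leaves_to_root())]  # root first
    for parent in order:
        for child in tree.children_of(parent):
            e = (parent, child)
            if e == ("head", "neck"):
                continue
            pedge = (tree.parent_of(parent), parent)
            name, sigma = _BONE_ANGLE[e]
            theta = float(angles[name])
            d = _rot(sigma * (180.0 - theta)) @ bone_dir[pedge]
            bone_dir[e] = d
            joints[child] = joints[parent] + config.limb_lengths[e] * d
    return {p: (float(v[0]), float(v[1])) for p, v in joints.items()}


def sample_pose(config: FigureConfig, rng: np.random.Generator):
    """Sample one pose; returns ``(joints, angles)`` where recomputing
    each articulated angle from the joints reproduces ``angles``.

    Resamples (bounded retries) until the whole figure, inflated by limb
    width and margin, fits the canvas.
    """
    h, w = config.image_size
    pad = config.limb_width / 2.0 + config.margin
    for _ in range(config.max_retries):
        angles = {
            name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in config.angle_ranges.items()
        }
        body = float(rng.uniform(*config.body_angle_range))
        head = (
            float(rng.uniform(pad + config.head_radius, w * 0.35)),
            float(rng.uniform(h * 0.38, h * 0.62)),
        )
        joints = forward_kinematics(config, head, body, angles)
        xs = [xy[0] for xy in joints.values()]
        ys = [xy[1] for xy in joints.values()]
        r = config.head_radius
        if (
            min(xs) - pad - r >= 0
            and min(ys) - pad - r >= 0
            and max(xs) + pad + r < w
            and max(ys) + pad + r < h
        ):
            return joints, angles
    raise PoseSampleError(
        f"no pose fitting a {h}x{w} canvas in {config.max_retries} tries"
    )


def _paint_capsule(img, alpha, p0, p1, width, value_fn, aa):
    """Paint a textured strip (capsule) between two points; painter's
    order, strongest-coverage-wins compositing."""
    h, w = img.shape
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    half = width / 2.0
    x0 = int(max(0, np.floor(min(p0[0], p1[0]) - half - aa - 1)))
    x1 = int(min(w - 1, np.ceil(max(p0[0], p1[0]) + half + aa + 1)))
    y0 = int(max(0, np.floor(min(p0[1], p1[1]) - half - aa - 1)))
    y1 = int(min(h - 1, np.ceil(max(p0[1], p1[1]) + half + aa + 1)))
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    X, Y = np.meshgrid(xs, ys)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        t = np.zeros_like(X, dtype=np.float64)
    else:
        t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / L2
    tc = np.clip(t, 0.0, 1.0)
    px = p0[0] + tc * d[0]
    py = p0[1] + tc * d[1]
    dist = np.hypot(X - px, Y - py)
    if aa > 0:
        a = np.clip((half - dist) / aa + 0.5, 0.0, 1.0)
    else:
        a = (dist <= half).astype(np.float64)
    val = value_fn(t * np.sqrt(L2))
    sub = (slice(y0, y1 + 1), slice(x0, x1 + 1))
    upd = a > alpha[sub]
    img[sub][upd] = np.broadcast_to(val, a.shape)[upd]
    alpha[sub][upd] = a[upd]


def render_frame(
    pose: dict,
    config: FigureConfig,
    rng: np.random.Generator | None = None,
    occluded: frozenset | set = frozenset(),
) -> AnnotatedFrame:
    """Render one pose into a grayscale frame in [0, 1].

    Limbs are strips of the configured width with a sinusoidal texture
    along each bone (distinct phase per body side), the head is a disc,
    and additive Gaussian noise is applied last.  Bones whose child joint
    is in ``occluded`` are not drawn.
    """
    h, w = config.image_size
    fg = np.zeros((h, w))
    alpha = np.zeros((h, w))
    tree = config.tree
    for k, (parent, child) in enumerate(tree.edges):
        if child in occluded or parent in occluded:
            continue
        width = config.limb_width
        if (parent, child) in ((("neck", "left_hip")), ("neck", "right_hip")):
            width *= config.torso_width_factor
        phase = (np.pi / 2.0 if child.startswith("left") else 0.0) + 0.7 * k
        amp = config.texture_amplitude
        period = config.texture_period
        if child.startswith("left"):
            period *= config.side_period_factor[0]
        elif child.startswith("right"):
            period *= config.side_period_factor[1]

        def value_fn(s, phase=phase, amp=amp, period=period):
            return config.foreground + amp * np.sin(2.0 * np.pi * s / period + phase)

        _paint_capsule(
            fg, alpha, pose[parent], pose[child], width, value_fn, config.aa_px
        )
    if "head" not in occluded:
        hx, hy = pose["head"]
        _paint_capsule(
            fg,
            alpha,
            (hx, hy),
            (hx, hy),
            2.0 * config.head_radius,
            lambda s: config.foreground + config.texture_amplitude * 0.5,
            config.aa_px,
        )
    img = config.background * (1.0 - alpha) + fg * alpha
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return AnnotatedFrame(image=img, joints=dict(pose), source_id="synthetic")


def render_negative(
    config: FigureConfig, rng: np.random.Generator, n_clutter: int = 12
) -> np.ndarray:
    """A human-free frame: background, sensor noise and textured clutter.

    Clutter strips share the figure's width and texture statistics but are
    scattered with no body geometry (think blankets and equipment edges in
    a ward), so a detector cannot separate figures from negatives by mere
    texture presence -- it must learn part appearance and geometry.
    ``n_clutter = 0`` renders plain noise.
    """
    h, w = config.image_size
    fg = np.zeros((h, w))
    alpha = np.zeros((h, w))
    for _ in range(n_clutter):
        p0 = np.array([rng.uniform(0, w), rng.uniform(0, h)])
        ang = rng.uniform(0, 2 * np.pi)
        ln = rng.uniform(8.0, 30.0)
        p1 = p0 + ln * np.array([np.cos(ang), np.sin(ang)])
        period = config.texture_period * rng.uniform(0.6, 1.6)
        phase = rng.uniform(0, 2 * np.pi)
        width = config.limb_width * rng.uniform(0.7, 1.4)

        def value_fn(s, phase=phase, period=period):
            return config.foreground + config.texture_amplitude * np.sin(
                2.0 * np.pi * s / period + phase
            )

        _paint_capsule(fg, alpha, p0, p1, width, value_fn, config.aa_px)
    img = config.background * (1.0 - alpha) + fg * alpha
    img += rng.normal(0.0, max(config.noise_sigma, 1e-3), img.shape)
    return np.clip(img, 0.0, 1.0)


@dataclass
class MotionConfig:
    """Smooth per-angle sinusoidal motion around the range midpoints."""

    amplitude_frac: float = 0.6  # fraction of each angle's half-range
    period_frames: tuple[float, float] = (40.0, 90.0)
    moving_joints: tuple[str, ...] = (
        "left_shoulder",
        "right_shoulder",
        "left_elbow",
        "right_elbow",
        "left_hip",
        "right_hip",
        "left_knee",
        "right_knee",
    )
    max_step_px: float = 4.0  # cap on per-frame joint displacement
    programs: dict = field(default_factory=dict)  # name -> (center, amp, period, phase)


def generate_sequence(
    config: FigureConfig,
    motion: MotionConfig | None = None,
    n_frames: int = 100,
    seed: int = 0,
    occlusion_schedule: list | None = None,
):
    """Render a smooth motion sequence with exact ground truth.

    Returns ``(frames, trajectory, angle_series)``: the rendered
    :class:`AnnotatedFrame` list, the ground-truth joint trajectory and
    the programmed angle series.  ``occlusion_schedule`` is a list of
    ``(parts, t0, t1)`` entries masking the given parts (bones not drawn,
    visibility flags cleared) on frames ``t0 <= t < t1``.

    Sinusoid amplitudes are scaled down (deterministically) until the
    largest per-frame joint displacement respects ``motion.max_step_px``,
    which keeps temporal search-restriction experiments valid.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    motion = motion or MotionConfig()
    rng = np.random.default_rng(seed)

    traj = None
    for _ in range(config.max_retries):
        joints0, angles0 = sample_pose(config, rng)
        body_angle = float(rng.uniform(*config.body_angle_range))
        head = joints0["head"]

        programs = {}
        explicit = set(motion.programs)
        for name, (lo, hi) in config.angle_ranges.items():
            if name in motion.programs:
                programs[name] = motion.programs[name]
                continue
            if name not in motion.moving_joints:
                programs[name] = (angles0[name], 0.0, 1.0, 0.0)
                continue
            c = (lo + hi) / 2.0
            amp = motion.amplitude_frac * (hi - lo) / 2.0
            period = float(rng.uniform(*motion.period_frames))
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
            programs[name] = (c, amp, period, phase)

        def angles_at(t, scale=1.0):
            # explicit user programs are clamped only to the valid [0, 180]
            # interval; auto-generated ones also respect the config ranges
            out = {}
            for name, (c, a, T, ph) in programs.items():
                v = c + scale * a * np.sin(2.0 * np.pi * t / T + ph)
                lo, hi = (0.0, 180.0) if name in explicit else config.angle_ranges[name]
                out[name] = float(np.clip(v, lo, hi))
            return out

        scale = 1.0
        for _ in range(12):
            cand = [
                forward_kinematics(config, head, body_angle, angles_at(t, scale))
                for t in range(n_frames)
            ]
            steps = [
                max(
                    np.hypot(
                        cand[t][p][0] - cand[t - 1][p][0],
                        cand[t][p][1] - cand[t - 1][p][1],
                    )
                    for p in cand[0]
                )
                for t in range(1, n_frames)
            ]
            if steps and max(steps) > motion.max_step_px:
                scale *= 0.8
                continue
            if all(_fits_canvas(config, pose) for pose in cand):
                traj = cand
            break
        if traj is not None:
            break
    if traj is None:
        raise PoseSampleError("could not fit motion within step/canvas bounds")

    schedule = occlusion_schedule or []
    frames: list[AnnotatedFrame] = []
    parts = list(config.tree.parts)
    jt = {p: np.zeros((n_frames, 2)) for p in parts}
    vis = {p: np.ones(n_frames, dtype=bool) for p in parts}
    ang = {name: np.zeros(n_frames) for name in programs}
    for t in range(n_frames):
        occ = set()
        for entry in schedule:
            ps, t0, t1 = entry
            if t0 <= t < t1:
                occ.update(ps)
        frame = render_frame(traj[t], config, rng, occluded=frozenset(occ))
        frames.append(frame)
        th = angles_at(t, scale)
        for p in parts:
            jt[p][t] = traj[t][p]
            vis[p][t] = p not in occ
        for name in programs:
            ang[name][t] = th[name]
    trajectory = JointTrajectory(frames=np.arange(n_frames), joints=jt, visible=vis)
    # report only articulated joints present in the pose (drop attachments)
    angle_series = AngleSeries(
        frames=np.arange(n_frames),
        angles={k: v for k, v in ang.items() if not k.endswith("_attach")},
    )
    return frames, trajectory, angle_series


def _fits_canvas(config: FigureConfig, pose: dict) -> bool:
    h, w = config.image_size
    pad = config.limb_width / 2.0 + 1.0
    xs = [xy[0] for xy in pose.values()]
    ys = [xy[1] for xy in pose.values()]
    r = config.head_radius
    return (
        min(xs) - pad - r >= 0
        and min(ys) - pad - r >= 0
        and max(xs) + pad + r < w
        and max(ys) + pad + r < h
    )


def generate_dataset(config: FigureConfig, n_frames: int, seed: int = 0):
    """Independent random poses (no temporal coherence) for training."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_frames):
        joints, _ = sample_pose(config, rng)
        f = render_frame(joints, config, rng)
        f.source_id = f"synthetic/{i}"
        out.append(f)
    return out
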