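"""Domain types for the tree-structured mixture-of-parts body model.

A :class:`BodyModel` bundles everything the detector learns:

* a kinematic tree over 14 named joints (head is the root);
* per part, a small set of *states* (appearance modes obtained by
  clustering the part's displacement relative to its parent) and one
  5x5-cell HOG template ("part filter") per state;
* per edge and state pair, a quadratic spring penalty ``zeta`` on the
  child's displacement from its rest offset (anchor);
* co-occurrence scores for single states and parent-child state pairs;
* a global bias.

All learnable weights flatten into a single parameter vector ``beta``
(the structured-SVM parameter); :class:`ModelLayout` fixes the slot order
so that the detection score is the inner product of ``beta`` with a
feature vector built from an image and a full part placement.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np

from .features import PATCH_CELLS, FeatureConfig, HOGLevel

__all__ = [
    "PART_NAMES",
    "FLIP_MAP",
    "ANGLE_TRIPLES",
    "KinematicTree",
    "infant_tree",
    "PartPlacement",
    "PoseEstimate",
    "BodyModel",
    "ModelLayout",
    "score_configuration",
    "save_model",
    "load_model",
    "ModelFormatError",
]

MODEL_FORMAT = "infantpose-model"
MODEL_VERSION = "1"

#: the 14 annotated joints
PART_NAMES = (
    "head",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hand",
    "right_hand",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_foot",
    "right_foot",
)

#: left/right relabelling under a horizontal flip (head/neck map to themselves)
FLIP_MAP = {
    name: (
        name.replace("left_", "right_")
        if name.startswith("left_")
        else name.replace("right_", "left_")
        if name.startswith("right_")
        else name
    )
    for name in PART_NAMES
}

#: (endpoint child, angle joint, parent joint) triples used for motion encoding
ANGLE_TRIPLES = {
    "left_shoulder": ("left_elbow", "left_shoulder", "neck"),
    "right_shoulder": ("right_elbow", "right_shoulder", "neck"),
    "left_elbow": ("left_hand", "left_elbow", "left_shoulder"),
    "right_elbow": ("right_hand", "right_elbow", "right_shoulder"),
    "left_hip": ("left_knee", "left_hip", "neck"),
    "right_hip": ("right_knee", "right_hip", "neck"),
    "left_knee": ("left_foot", "left_knee", "left_hip"),
    "right_knee": ("right_foot", "right_knee", "right_hip"),
}


class ModelFormatError(ValueError):
    """Raised for corrupted or incompatible model files."""


@dataclass(frozen=True)
class KinematicTree:
    """Rooted tree over body parts; edges are (parent, child) pairs."""

    parts: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    root: str

    def __post_init__(self):
        parts = set(self.parts)
        if self.root not in parts:
            raise ValueError("root must be one of parts")
        parent = {}
        for p, c in self.edges:
            if p not in parts or c not in parts:
                raise ValueError(f"edge ({p}, {c}) references unknown part")
            if c in parent:
                raise ValueError(f"part {c} has two parents")
            parent[c] = p
        if self.root in parent:
            raise ValueError("root may not have a parent")
        if len(parent) != len(self.parts) - 1:
            raise ValueError("tree must be connected (every non-root has a parent)")
        # acyclicity: walking up from every part must reach the root
        for q in self.parts:
            seen = set()
            while q != self.root:
                if q in seen:
                    raise ValueError("edge set contains a cycle")
                seen.add(q)
                q = parent[q]

    def parent_of(self, part: str) -> str | None:
        for p, c in self.edges:
            if c == part:
                return p
        return None

    def children_of(self, part: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.edges if p == part)

    def leaves_to_root(self) -> tuple[str, ...]:
        """Parts ordered so every child precedes its parent."""
        order: list[str] = []

        def visit(p: str):
            for c in self.children_of(p):
                visit(c)
            order.append(p)

        visit(self.root)
        return tuple(order)


def infant_tree() -> KinematicTree:
    """The 14-joint supine-infant kinematic tree (head-rooted)."""
    edges = (
        ("head", "neck"),
        ("neck", "left_shoulder"),
        ("neck", "right_shoulder"),
        ("left_shoulder", "left_elbow"),
        ("right_shoulder", "right_elbow"),
        ("left_elbow", "left_hand"),
        ("right_elbow", "right_hand"),
        ("neck", "left_hip"),
        ("neck", "right_hip"),
        ("left_hip", "left_knee"),
        ("right_hip", "right_knee"),
        ("left_knee", "left_foot"),
        ("right_knee", "right_foot"),
    )
    return KinematicTree(parts=PART_NAMES, edges=edges, root="head")


@dataclass(frozen=True)
class PartPlacement:
    """Cell location (x = column, y = row, 0-based) of a template's
    top-left cell at some pyramid level, plus the active state."""

    x: int
    y: int
    state: int


@dataclass
class PoseEstimate:
    """One detected body configuration at a single pyramid level."""

    placements: dict[str, PartPlacement]
    part_scores: dict[str, float]
    joints_px: dict[str, tuple[float, float]]
    score: float
    level: int
    visible: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not self.visible:
            self.visible = {p: True for p in self.placements}


@dataclass
class BodyModel:
    """The full trained detector (see module docstring)."""

    tree: KinematicTree
    states_per_part: dict[str, int]
    filters: dict[tuple[str, int], np.ndarray]  # (part, state) -> (5, 5, d)
    deformations: dict[tuple[str, str], np.ndarray]  # edge -> (Sp, Sc, 4) zeta
    anchors: dict[tuple[str, str], np.ndarray]  # edge -> (Sp, Sc, 2) rest offsets
    cooc_unary: dict[str, np.ndarray]  # part -> (S,)
    cooc_pair: dict[tuple[str, str], np.ndarray]  # edge -> (Sp, Sc)
    bias: float
    feature_config: FeatureConfig
    omega_score: dict[str, float] | None = None
    version: str = MODEL_VERSION

    # -- construction -------------------------------------------------
    @classmethod
    def empty(
        cls,
        tree: KinematicTree,
        states_per_part: dict[str, int],
        feature_config: FeatureConfig,
        deformation_init=(0.0, 0.0, 0.01, 0.01),
    ) -> "BodyModel":
        """Zero-weight model with the standard spring initialization."""
        d = feature_config.bins
        filters = {
            (p, s): np.zeros((PATCH_CELLS, PATCH_CELLS, d))
            for p in tree.parts
            for s in range(states_per_part[p])
        }
        deformations, anchors, cooc_pair = {}, {}, {}
        init = np.asarray(deformation_init, dtype=np.float64)
        for p, c in tree.edges:
            sp, sc = states_per_part[p], states_per_part[c]
            deformations[(p, c)] = np.tile(init, (sp, sc, 1))
            anchors[(p, c)] = np.zeros((sp, sc, 2))
            cooc_pair[(p, c)] = np.zeros((sp, sc))
        cooc_unary = {p: np.zeros(states_per_part[p]) for p in tree.parts}
        return cls(
            tree=tree,
            states_per_part=dict(states_per_part),
            filters=filters,
            deformations=deformations,
            anchors=anchors,
            cooc_unary=cooc_unary,
            cooc_pair=cooc_pair,
            bias=0.0,
            feature_config=feature_config,
        )

    def validate(self) -> None:
        d = self.feature_config.bins
        for p in self.tree.parts:
            if p not in self.states_per_part or self.states_per_part[p] < 1:
                raise ValueError(f"missing state count for part {p}")
            for s in range(self.states_per_part[p]):
                f = self.filters.get((p, s))
                if f is None or f.shape != (PATCH_CELLS, PATCH_CELLS, d):
                    raise ValueError(f"bad filter for ({p}, {s})")
                if not np.all(np.isfinite(f)):
                    raise ValueError(f"non-finite filter weights for ({p}, {s})")
        for e in self.tree.edges:
            sp = self.states_per_part[e[0]]
            sc = self.states_per_part[e[1]]
            if self.deformations[e].shape != (sp, sc, 4):
                raise ValueError(f"bad deformation table for edge {e}")
            if self.anchors[e].shape != (sp, sc, 2):
                raise ValueError(f"bad anchor table for edge {e}")
            if self.cooc_pair[e].shape != (sp, sc):
                raise ValueError(f"bad pairwise co-occurrence table for edge {e}")

    # -- beta vector --------------------------------------------------
    @property
    def layout(self) -> "ModelLayout":
        return ModelLayout(self.tree, self.states_per_part, self.feature_config)

    def flatten(self) -> np.ndarray:
        """Concatenate all learnable weights into the beta vector."""
        lay = self.layout
        beta = np.zeros(lay.dim)
        for (p, s), f in self.filters.items():
            beta[lay.filter_slice(p, s)] = f.ravel()
        for e, z in self.deformations.items():
            beta[lay.deformation_slice(e)] = z.ravel()
        for p, u in self.cooc_unary.items():
            beta[lay.unary_slice(p)] = u
        for e, t in self.cooc_pair.items():
            beta[lay.pair_slice(e)] = t.ravel()
        beta[lay.bias_index] = self.bias
        return beta

    def unflatten(self, beta: np.ndarray) -> None:
        """Load weights from a beta vector (inverse of :meth:`flatten`)."""
        lay = self.layout
        if beta.shape != (lay.dim,):
            raise ValueError(f"expected beta of length {lay.dim}, got {beta.shape}")
        d = self.feature_config.bins
        for p in self.tree.parts:
            for s in range(self.states_per_part[p]):
                self.filters[(p, s)] = beta[lay.filter_slice(p, s)].reshape(
                    PATCH_CELLS, PATCH_CELLS, d
                )
            self.cooc_unary[p] = beta[lay.unary_slice(p)].copy()
        for e in self.tree.edges:
            sp, sc = self.states_per_part[e[0]], self.states_per_part[e[1]]
            self.deformations[e] = beta[lay.deformation_slice(e)].reshape(sp, sc, 4)
            self.cooc_pair[e] = beta[lay.pair_slice(e)].reshape(sp, sc)
        self.bias = float(beta[lay.bias_index])


class ModelLayout:
    """Slot bookkeeping for the flattened beta / feature vectors.

    Order: filters (part order, state order), spring parameters (edge
    order, parent-state-major), unary co-occurrence (part order), pairwise
    co-occurrence (edge order), bias.
    """

    def __init__(self, tree: KinematicTree, states_per_part: dict[str, int], cfg: FeatureConfig):
        self.tree = tree
        self.states = states_per_part
        fdim = PATCH_CELLS * PATCH_CELLS * cfg.bins
        self._filter_off: dict[tuple[str, int], int] = {}
        off = 0
        for p in tree.parts:
            for s in range(states_per_part[p]):
                self._filter_off[(p, s)] = off
                off += fdim
        self._fdim = fdim
        self._def_off: dict[tuple[str, str], int] = {}
        for e in tree.edges:
            self._def_off[e] = off
            off += states_per_part[e[0]] * states_per_part[e[1]] * 4
        self._unary_off: dict[str, int] = {}
        for p in tree.parts:
            self._unary_off[p] = off
            off += states_per_part[p]
        self._pair_off: dict[tuple[str, str], int] = {}
        for e in tree.edges:
            self._pair_off[e] = off
            off += states_per_part[e[0]] * states_per_part[e[1]]
        self.bias_index = off
        self.dim = off + 1

    def filter_slice(self, part: str, state: int) -> slice:
        o = self._filter_off[(part, state)]
        return slice(o, o + self._fdim)

    def deformation_slice(self, edge: tuple[str, str]) -> slice:
        o = self._def_off[edge]
        return slice(o, o + self.states[edge[0]] * self.states[edge[1]] * 4)

    def deformation_entry(self, edge: tuple[str, str], sp: int, sc: int) -> slice:
        o = self._def_off[edge] + (sp * self.states[edge[1]] + sc) * 4
        return slice(o, o + 4)

    def quadratic_indices(self) -> np.ndarray:
        """Indices of all dx^2/dy^2 spring weights (clamped positive)."""
        idx = []
        for e in self.tree.edges:
            o = self._def_off[e]
            n = self.states[e[0]] * self.states[e[1]]
            for k in range(n):
                idx.extend([o + 4 * k + 2, o + 4 * k + 3])
        return np.asarray(idx, dtype=np.intp)

    def unary_slice(self, part: str) -> slice:
        o = self._unary_off[part]
        return slice(o, o + self.states[part])

    def pair_slice(self, edge: tuple[str, str]) -> slice:
        o = self._pair_off[edge]
        return slice(o, o + self.states[edge[0]] * self.states[edge[1]])

    def pair_entry(self, edge: tuple[str, str], sp: int, sc: int) -> int:
        return self._pair_off[edge] + sp * self.states[edge[1]] + sc


def deformation_feature(la, lb) -> np.ndarray:
    """Displacement feature [dx, dy, dx^2, dy^2] of location a minus b."""
    dx = float(la[0]) - float(lb[0])
    dy = float(la[1]) - float(lb[1])
    return np.array([dx, dy, dx * dx, dy * dy])


def score_configuration(
    model: BodyModel, level: HOGLevel, placements: dict[str, PartPlacement]
) -> float:
    """Reference detection score of a full part placement (slow, explicit).

    Sum of template responses, spring penalties over edges, co-occurrence
    scores and the bias.  DP inference and the beta/feature inner product
    must both reproduce this total.
    """
    missing = set(model.tree.parts) - set(placements)
    if missing:
        raise ValueError(f"placements missing parts: {sorted(missing)}")
    H, W = level.grid_shape
    total = model.bias
    for p in model.tree.parts:
        pl = placements[p]
        if not (0 <= pl.x <= W - PATCH_CELLS and 0 <= pl.y <= H - PATCH_CELLS):
            raise ValueError(f"placement of {p} out of bounds")
        patch = level.cells[pl.y : pl.y + PATCH_CELLS, pl.x : pl.x + PATCH_CELLS, :]
        total += float(np.vdot(model.filters[(p, pl.state)], patch))
        total += float(model.cooc_unary[p][pl.state])
    for e in model.tree.edges:
        pp, pc = placements[e[0]], placements[e[1]]
        r = model.anchors[e][pp.state, pc.state]
        v = deformation_feature((pc.x - r[0], pc.y - r[1]), (pp.x, pp.y))
        total -= float(model.deformations[e][pp.state, pc.state] @ v)
        total += float(model.cooc_pair[e][pp.state, pc.state])
    return total


# -- serialization ----------------------------------------------------


def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype="<f8")
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d: dict) -> np.ndarray:
    try:
        raw = base64.b64decode(d["data"], validate=True)
        a = np.frombuffer(raw, dtype="<f8").reshape(d["shape"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupt weight block: {exc}") from exc
    return a.astype(np.float64)


def save_model(model: BodyModel, path) -> None:
    """Write a model as versioned JSON (weights as base64 little-endian f8)."""
    model.validate()
    doc = {
        "format": MODEL_FORMAT,
        "version": model.version,
        "tree": {
            "parts": list(model.tree.parts),
            "edges": [list(e) for e in model.tree.edges],
            "root": model.tree.root,
        },
        "states_per_part": model.states_per_part,
        "feature_config": model.feature_config.to_dict(),
        "bias": model.bias,
        "omega_score": model.omega_score,
        "filters": {f"{p}|{s}": _enc(f) for (p, s), f in model.filters.items()},
        "deformations": {f"{e[0]}|{e[1]}": _enc(z) for e, z in model.deformations.items()},
        "anchors": {f"{e[0]}|{e[1]}": _enc(r) for e, r in model.anchors.items()},
        "cooc_unary": {p: _enc(u) for p, u in model.cooc_unary.items()},
        "cooc_pair": {f"{e[0]}|{e[1]}": _enc(t) for e, t in model.cooc_pair.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> BodyModel:
    """Load a model saved by :func:`save_model`; rejects foreign files."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"not a model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError("not an infantpose model file")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unsupported model version {doc.get('version')!r}"
        )
    try:
        tree = KinematicTree(
            parts=tuple(doc["tree"]["parts"]),
            edges=tuple(tuple(e) for e in doc["tree"]["edges"]),
            root=doc["tree"]["root"],
        )
        model = BodyModel(
            tree=tree,
            states_per_part={p: int(s) for p, s in doc["states_per_part"].items()},
            filters={
                (k.split("|")[0], int(k.split("|")[1])): _dec(v)
                for k, v in doc["filters"].items()
            },
            deformations={tuple(k.split("|")): _dec(v) for k, v in doc["deformations"].items()},
            anchors={tuple(k.split("|")): _dec(v) for k, v in doc["anchors"].items()},
            cooc_unary={p: _dec(u) for p, u in doc["cooc_unary"].items()},
            cooc_pair={tuple(k.split("|")): _dec(v) for k, v in doc["cooc_pair"].items()},
            bias=float(doc["bias"]),
            feature_config=FeatureConfig.from_dict(doc["feature_config"]),
            omega_score=doc.get("omega_score"),
            version=doc["version"],
        )
        model.validate()
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"malformed model file: {exc}") from exc
    return model
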