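"""DP inference against exhaustive enumeration, spring transforms against
brute force, NMS against a quadratic reference, and the temporal helpers."""

import itertools

import numpy as np
import pytest

from infantpose.features import HOGPyramid
from infantpose.inference import (
    apply_occlusion_threshold,
    deformation_feature,
    deformation_score,
    filter_response,
    infer_pose,
    nms,
    response_map,
    restrict_search_space,
    spring_max,
    spring_max_bruteforce,
)
from infantpose.model import PartPlacement, score_configuration

from conftest import random_level, random_tiny_model


def enumerate_best(model, level):
    """Dense enumeration over every (location x state) assignment."""
    H, W = level.grid_shape
    locs = [(x, y) for y in range(H - 4) for x in range(W - 4)]
    options = {
        p: [(x, y, s) for (x, y) in locs for s in range(model.states_per_part[p])]
        for p in model.tree.parts
    }
    best, best_pl = -np.inf, None
    for combo in itertools.product(*(options[p] for p in model.tree.parts)):
        pls = {p: PartPlacement(*c) for p, c in zip(model.tree.parts, combo)}
        s = score_configuration(model, level, pls)
        if s > best:
            best, best_pl = s, pls
    return best, best_pl


class TestFilterResponse:
    def test_zero_filter_zero_everywhere(self, rng, tiny_level):
        f = np.zeros((5, 5, 2))
        assert np.all(response_map(f, tiny_level) == 0.0)

    def test_self_correlation_equals_squared_norm(self, rng, tiny_level):
        patch = tiny_level.cells[1:6, 2:7, :].copy()
        r = filter_response(patch, tiny_level, (2, 1))
        assert r == pytest.approx(float((patch ** 2).sum()), abs=1e-9)

    def test_full_map_matches_triple_loop_oracle(self, rng):
        lv = random_level(rng, 10, 10, 3)
        f = rng.normal(size=(5, 5, 3))
        rm = response_map(f, lv)
        for y in range(6):
            for x in range(6):
                expected = 0.0
                for m in range(5):
                    for n in range(5):
                        for c in range(3):
                            expected += f[m, n, c] * lv.cells[y + m, x + n, c]
                assert rm[y, x] == pytest.approx(expected, abs=1e-9)

    def test_out_of_bounds_rejected(self, rng, tiny_level):
        with pytest.raises(ValueError):
            filter_response(np.zeros((5, 5, 2)), tiny_level, (5, 0))


class TestDeformation:
    def test_coincident_zero(self):
        np.testing.assert_array_equal(deformation_feature((3, 4), (3, 4)), np.zeros(4))

    def test_direct_arithmetic(self):
        np.testing.assert_array_equal(
            deformation_feature((5, 7), (2, 3)), [3.0, 4.0, 9.0, 16.0]
        )

    def test_swap_parity(self, rng):
        a, b = rng.integers(0, 10, 2), rng.integers(0, 10, 2)
        f1, f2 = deformation_feature(a, b), deformation_feature(b, a)
        np.testing.assert_array_equal(f1[:2], -f2[:2])
        np.testing.assert_array_equal(f1[2:], f2[2:])

    def test_default_initialization_example(self):
        # init [0, 0, 0.01, 0.01], displacement (3, 4) off anchor -> -0.25
        z = np.array([0.0, 0.0, 0.01, 0.01])
        assert deformation_score(z, (3, 4), (0, 0)) == pytest.approx(-0.25)

    def test_pure_quadratic_is_nonpositive_and_decreasing(self):
        z = np.array([0.0, 0.0, 0.02, 0.03])
        prev = 0.0
        for d in range(0, 5):
            s = deformation_score(z, (d, d), (0, 0))
            assert s <= 0.0 and s <= prev
            prev = s

    def test_matches_dot_product_oracle(self, rng):
        for _ in range(100):
            z = rng.normal(size=4)
            la, lb, r = rng.normal(size=2), rng.normal(size=2), rng.normal(size=2)
            got = deformation_score(z, la, lb, r)
            v = la - lb - r
            expected = -(z[0] * v[0] + z[1] * v[1] + z[2] * v[0] ** 2 + z[3] * v[1] ** 2)
            assert got == pytest.approx(expected, abs=1e-9)


class TestSpringMax:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce(self, rng, trial):
        T = rng.normal(size=(int(rng.integers(5, 9)), int(rng.integers(5, 9))))
        z = np.array([*rng.normal(size=2) * 0.1, *np.abs(rng.normal(size=2)) * 0.3])
        r = rng.normal(size=2)
        m1, ay1, ax1 = spring_max(T, z, r)
        m2, ay2, ax2 = spring_max_bruteforce(T, z, r)
        np.testing.assert_allclose(m1, m2, atol=1e-9)
        # achieved values agree even if tie-broken argmaxes differ
        for yp in range(T.shape[0]):
            for xp in range(T.shape[1]):
                v1 = T[ay1[yp, xp], ax1[yp, xp]] + deformation_score(
                    z, (ax1[yp, xp], ay1[yp, xp]), (xp, yp), r
                )
                assert v1 == pytest.approx(m1[yp, xp], abs=1e-9)


class TestInferPose:
    @pytest.mark.parametrize("trial", range(8))
    def test_dp_equals_enumeration_random_tiny(self, rng, trial):
        n = int(rng.integers(2, 4))
        m = random_tiny_model(rng, n_parts=n, states=2)
        lv = random_level(rng, 6, 6, 2)
        pyr = HOGPyramid(levels=[lv], interval=2)
        best, _ = enumerate_best(m, lv)
        cands = infer_pose(m, pyr, top_k=1)
        assert cands[0].score == pytest.approx(best, abs=1e-9)
        # the backtracked placements achieve the reported score
        assert score_configuration(m, lv, cands[0].placements) == pytest.approx(
            cands[0].score, abs=1e-6
        )

    def test_five_part_star_equals_enumeration(self, rng):
        parts = tuple(f"p{i}" for i in range(5))
        from infantpose.model import BodyModel, KinematicTree
        from infantpose.features import FeatureConfig

        tree = KinematicTree(
            parts=parts, edges=tuple(("p0", p) for p in parts[1:]), root="p0"
        )
        m = BodyModel.empty(tree, {p: 1 for p in parts}, FeatureConfig(cell_size_px=1, bins=2))
        for k in m.filters:
            m.filters[k] = rng.normal(size=(5, 5, 2))
        for e in m.deformations:
            m.anchors[e] = rng.normal(size=(1, 1, 2))
        lv = random_level(rng, 6, 6, 2)
        best, _ = enumerate_best(m, lv)
        got = infer_pose(m, HOGPyramid(levels=[lv], interval=2), top_k=1)[0]
        assert got.score == pytest.approx(best, abs=1e-9)

    def test_flat_model_returns_bias_and_first_cell(self, rng, tiny_level):
        m = random_tiny_model(rng)
        for k in m.filters:
            m.filters[k] = np.zeros_like(m.filters[k])
        for e in m.deformations:
            m.deformations[e][:] = 0.0
            m.anchors[e][:] = 0.0
            m.cooc_pair[e][:] = 0.0
        for p in m.cooc_unary:
            m.cooc_unary[p][:] = 0.0
        m.bias = 1.25
        got = infer_pose(m, HOGPyramid(levels=[tiny_level], interval=2), top_k=1)[0]
        assert got.score == pytest.approx(1.25)
        root = got.placements[m.tree.root]
        assert (root.y, root.x, root.state) == (0, 0, 0)  # documented tie-break

    def test_empty_search_region_yields_no_detections(self, rng, tiny_model, tiny_level):
        pyr = HOGPyramid(levels=[tiny_level], interval=2)
        assert infer_pose(tiny_model, pyr, search_region=(5, 5, 4, 4)) == []

    def test_restriction_never_beats_full_search(self, rng):
        for _ in range(10):
            m = random_tiny_model(rng)
            lv = random_level(rng, 8, 8, 2)
            pyr = HOGPyramid(levels=[lv], interval=2)
            full = infer_pose(m, pyr, top_k=1)[0]
            sub = infer_pose(m, pyr, search_region=(0, 0, 4, 4), top_k=1)
            if sub:
                assert sub[0].score <= full.score + 1e-9
            # region covering everything reproduces the unrestricted result
            whole = infer_pose(m, pyr, search_region=(0, 0, 100, 100), top_k=1)[0]
            assert whole.score == pytest.approx(full.score, abs=1e-12)


def _pose(score, x, y, side=10.0, level=0):
    from infantpose.model import PoseEstimate

    return (
        PoseEstimate(
            placements={"root": PartPlacement(int(x), int(y), 0)},
            part_scores={"root": score},
            joints_px={"root": (x + side / 2, y + side / 2)},
            score=score,
            level=level,
        ),
        (x, y, x + side, y + side),
    )


def reference_nms(cands, boxes, thr):
    """O(n^2) reference: repeatedly take the global best, drop overlaps."""
    def iou(a, b):
        ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
        i = ix * iy
        if i == 0:
            return 0.0
        u = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - i
        return i / u

    rest = sorted(range(len(cands)), key=lambda i: -cands[i].score)
    keep = []
    while rest:
        i = rest.pop(0)
        keep.append(i)
        rest = [j for j in rest if iou(boxes[i], boxes[j]) <= thr]
    return [cands[i] for i in keep]


class TestNMS:
    def test_identical_candidates_collapse(self):
        a, ba = _pose(1.0, 0, 0)
        b, bb = _pose(0.9, 0, 0)
        out = nms([a, b], 0.3, boxes=[ba, bb], single_subject=False)
        assert out == [a]

    def test_disjoint_candidates_survive(self):
        a, ba = _pose(1.0, 0, 0)
        b, bb = _pose(0.9, 50, 50)
        out = nms([a, b], 0.3, boxes=[ba, bb], single_subject=False)
        assert out == [a, b]

    def test_matches_quadratic_reference(self, rng):
        for _ in range(20):
            cands, boxes = [], []
            for _ in range(int(rng.integers(2, 12))):
                c, b = _pose(float(rng.normal()), float(rng.uniform(0, 40)), float(rng.uniform(0, 40)))
                cands.append(c)
                boxes.append(b)
            got = nms(cands, 0.3, boxes=boxes, single_subject=False)
            ref = reference_nms(cands, boxes, 0.3)
            assert [id(c) for c in got] == [id(c) for c in ref]
            assert set(map(id, got)) <= set(map(id, cands))

    def test_single_subject_returns_top_survivor(self):
        a, ba = _pose(1.0, 0, 0)
        b, bb = _pose(2.0, 50, 50)
        out = nms([a, b], 0.3, boxes=[ba, bb], single_subject=True)
        assert out == [b]


class TestOcclusion:
    def test_vacuous_and_saturating_thresholds(self):
        p, _ = _pose(0.5, 0, 0)
        assert all(apply_occlusion_threshold(p, -np.inf).visible.values())
        assert not any(apply_occlusion_threshold(p, 1e9).visible.values())

    def test_locations_retained(self):
        p, _ = _pose(0.5, 3, 4)
        flagged = apply_occlusion_threshold(p, 1e9)
        assert flagged.joints_px == p.joints_px and flagged.placements == p.placements


class TestRestrictSearchSpace:
    def test_dilation_arithmetic(self):
        from infantpose.model import PoseEstimate

        pose = PoseEstimate(
            placements={"a": PartPlacement(0, 0, 0), "b": PartPlacement(0, 0, 0)},
            part_scores={"a": 0, "b": 0},
            joints_px={"a": (30, 40), "b": (70, 80)},
            score=0.0,
            level=0,
        )
        box = restrict_search_space(pose, 20.0, (200, 200))
        assert box == (10.0, 20.0, 90.0, 100.0)

    def test_saturates_to_full_frame(self):
        from infantpose.model import PoseEstimate

        pose = PoseEstimate(
            placements={"a": PartPlacement(0, 0, 0)},
            part_scores={"a": 0},
            joints_px={"a": (50, 50)},
            score=0.0,
            level=0,
        )
        box = restrict_search_space(pose, 1e6, (100, 120))
        assert box == (0.0, 0.0, 119.0, 99.0)
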