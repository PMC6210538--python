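"""Augmentation, bounding-box sizing, state clustering, feature vectors
and the learning loop contracts."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from infantpose.features import FeatureConfig, compute_hog
from infantpose.model import PartPlacement, infant_tree, score_configuration
from infantpose.synthetic import FigureConfig, render_frame, sample_pose
from infantpose.training import (
    AnnotatedFrame,
    TrainingConfig,
    augment,
    bbox_size,
    bic_select,
    build_feature_vector,
    cluster_states,
    cross_validate,
    train_model,
)

from conftest import random_level, random_tiny_model


@pytest.fixture(scope="module")
def synth_frame():
    fig = FigureConfig()
    rng = np.random.default_rng(31)
    joints, _ = sample_pose(fig, rng)
    return render_frame(joints, fig, rng)


class TestAugment:
    def test_standard_recipe_yields_14_variants(self, synth_frame):
        out = augment(synth_frame)
        assert len(out) == 14

    def test_empty_recipe_is_identity(self, synth_frame):
        out = augment(synth_frame, rotations=(), flip=False)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].image, synth_frame.image)
        assert out[0].joints == synth_frame.joints

    def test_transform_round_trip_below_half_pixel(self, synth_frame):
        for var in augment(synth_frame):
            src = synth_frame.joints
            for p, (x, y) in var.joints.items():
                # flipped variants carry swapped left/right labels
                q = p
                if var.source_id.endswith("/flip"):
                    from infantpose.model import FLIP_MAP

                    q = FLIP_MAP[p]
                v = var.transform @ np.array([*src[q], 1.0])
                assert np.hypot(v[0] - x, v[1] - y) < 0.5

    def test_flip_swaps_left_right_labels(self, synth_frame):
        flipped = augment(synth_frame, rotations=(), flip=True)[1]
        w = flipped.image.shape[1]
        lx = synth_frame.joints["left_hand"][0]
        assert flipped.joints["right_hand"][0] == pytest.approx(w - 1 - lx)

    def test_out_of_canvas_rotation_pads(self):
        img = np.zeros((40, 40))
        joints = {p: (38.0, 38.0) for p in infant_tree().parts}
        frame = AnnotatedFrame(image=img, joints=joints)
        out = augment(frame, rotations=(45.0,), flip=False)
        h, w = out[0].image.shape
        assert h > 40 and w > 40
        for x, y in out[0].joints.values():
            assert 0 <= x < w and 0 <= y < h


class TestBBoxSize:
    def _frames(self, scales):
        tree = infant_tree()
        fig = FigureConfig(image_size=(400, 400), max_retries=500)
        joints, _ = sample_pose(fig, np.random.default_rng(17))
        out = []
        for s in scales:
            j = {p: (x * s + 50, y * s + 50) for p, (x, y) in joints.items()}
            out.append(AnnotatedFrame(image=np.zeros((900, 900)), joints=j))
        return out

    def test_homogeneous_set_gives_base_patch(self):
        sides = bbox_size(self._frames([1.0] * 5), base_patch_px=40.0)
        np.testing.assert_allclose(sides, 40.0)

    def test_doubled_frame_gets_doubled_box(self):
        sides = bbox_size(self._frames([1.0, 1.0, 1.0, 2.0]), base_patch_px=40.0)
        np.testing.assert_allclose(sides[:3], 40.0)
        np.testing.assert_allclose(sides[3], 80.0)

    def test_quantile_matches_sort_oracle(self, rng):
        tree = infant_tree()
        frames = self._frames(rng.uniform(0.5, 2.0, size=6))
        sides = bbox_size(frames, base_patch_px=40.0)
        lengths = np.array(
            [
                [
                    np.hypot(
                        f.joints[c][0] - f.joints[p][0], f.joints[c][1] - f.joints[p][1]
                    )
                    for (p, c) in tree.edges
                ]
                for f in frames
            ]
        )
        med = np.median(lengths, axis=0)
        for i, f in enumerate(frames):
            ratios = sorted(lengths[i] / med)
            # linear-interpolation quantile of the sorted ratios
            pos = 0.75 * (len(ratios) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            q = ratios[lo] + (pos - lo) * (ratios[hi] - ratios[lo])
            assert sides[i] == pytest.approx(q * 40.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bbox_size([])


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        truth = np.repeat(np.arange(3), 50)
        pts = centers[truth] + rng.normal(0, 0.5, size=(150, 2))
        labels, cents = cluster_states(pts, 3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster_is_mean(self, rng):
        pts = rng.normal(size=(30, 2))
        _, cents = cluster_states(pts, 1, seed=0)
        np.testing.assert_allclose(cents[0], pts.mean(axis=0), atol=1e-9)

    def test_duplicated_data_same_centroids(self, rng):
        centers = np.array([[0, 0], [15, 0], [0, 15]])
        pts = centers[np.repeat(np.arange(3), 20)] + rng.normal(0, 0.8, (60, 2))
        _, c1 = cluster_states(pts, 3, seed=0)
        _, c2 = cluster_states(np.vstack([pts, pts]), 3, seed=0)
        order1 = np.lexsort(c1.T)
        order2 = np.lexsort(c2.T)
        np.testing.assert_allclose(c1[order1], c2[order2], atol=1e-7)

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_states(rng.normal(size=(3, 2)), 5, seed=0)

    def test_bic_selects_generating_component_count(self, rng):
        # small per-blob samples: the ln(n) penalty is only effective
        # against the (linear-in-n) split gain at modest sample sizes
        centers = np.array([[0, 0], [25, 0], [0, 25]])
        pts = centers[np.repeat(np.arange(3), 10)] + rng.normal(0, 1.0, (30, 2))
        S, values = bic_select(pts, range(1, 9), seed=0)
        assert S == 3
        assert values[3] == min(values.values())

    def test_bic_perfect_fit_guard(self):
        pts = np.zeros((10, 2))
        S, values = bic_select(pts, [1, 2], seed=0)
        assert S == 1 and values[1] == -np.inf


class TestFeatureVector:
    def test_dual_path_score_equality(self, rng):
        for _ in range(20):
            m = random_tiny_model(rng, n_parts=3, states=2)
            lv = random_level(rng, 9, 9, 2)
            pls = {
                p: PartPlacement(int(rng.integers(0, 5)), int(rng.integers(0, 5)),
                                 int(rng.integers(0, m.states_per_part[p])))
                for p in m.tree.parts
            }
            phi = build_feature_vector(lv, pls, m)
            assert m.flatten() @ phi == pytest.approx(
                score_configuration(m, lv, pls), abs=1e-6
            )

    def test_zero_image_zeroes_only_filter_slots(self, rng):
        m = random_tiny_model(rng, n_parts=2, states=2)
        lay = m.layout
        lv = random_level(rng, 8, 8, 2)
        lv.cells[:] = 0.0
        pls = {p: PartPlacement(1, 1, 0) for p in m.tree.parts}
        phi = build_feature_vector(lv, pls, m)
        for p in m.tree.parts:
            assert np.all(phi[lay.filter_slice(p, 0)] == 0.0)
        assert phi[lay.bias_index] == 1.0
        e = m.tree.edges[0]
        assert phi[lay.pair_entry(e, 0, 0)] == 1.0

    def test_state_change_is_local(self, rng):
        m = random_tiny_model(rng, n_parts=3, states=2, chain=True)
        lay = m.layout
        lv = random_level(rng, 9, 9, 2)
        base = {p: PartPlacement(1, 1, 0) for p in m.tree.parts}
        alt = dict(base)
        alt["p1"] = PartPlacement(1, 1, 1)  # same cell, different state
        d = build_feature_vector(lv, alt, m) - build_feature_vector(lv, base, m)
        changed = set(np.nonzero(d)[0])
        allowed = set()
        for s in range(2):
            allowed |= set(range(*lay.filter_slice("p1", s).indices(lay.dim)))
        allowed |= set(range(*lay.unary_slice("p1").indices(lay.dim)))
        for e in (("p0", "p1"), ("p1", "p2")):
            allowed |= set(range(*lay.deformation_slice(e).indices(lay.dim)))
            allowed |= set(range(*lay.pair_slice(e).indices(lay.dim)))
        assert changed <= allowed


class TestTrainModel:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(C=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(states_per_part="bic", bic_range=(5, 2))

    def test_requires_positives_and_negatives(self):
        with pytest.raises(ValueError):
            train_model([], [np.zeros((64, 64))], TrainingConfig())

    def test_seeded_training_is_reproducible(self):
        from infantpose.protocol import small_figure_config, study_training_config
        from infantpose.synthetic import generate_dataset, render_negative

        fig = small_figure_config()
        pos = generate_dataset(fig, 8, seed=3)
        rng = np.random.default_rng(4)
        neg = [render_negative(fig, rng, n_clutter=6) for _ in range(3)]
        cfg = study_training_config(
            seed=3, states_per_part=1, mining_rounds=2, max_passes=10,
            feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=48),
        )
        m1, _ = train_model(pos, neg, cfg)
        m2, _ = train_model(pos, neg, cfg)
        np.testing.assert_array_equal(m1.flatten(), m2.flatten())

    def test_beta_norm_shrinks_with_smaller_C(self):
        from infantpose.protocol import small_figure_config, study_training_config
        from infantpose.synthetic import generate_dataset, render_negative

        fig = small_figure_config()
        pos = generate_dataset(fig, 8, seed=3)
        rng = np.random.default_rng(4)
        neg = [render_negative(fig, rng, n_clutter=6) for _ in range(3)]
        norms = []
        for C in (1e-4, 1e-2, 1.0):
            cfg = study_training_config(
                seed=3, C=C, states_per_part=1, mining_rounds=2, max_passes=30,
                feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=48),
            )
            m, _ = train_model(pos, neg, cfg)
            beta = m.flatten()
            ref = m.layout
            norms.append(float(np.linalg.norm(beta)))
        assert norms[0] <= norms[1] <= norms[2] + 1e-9

    def test_omega_score_stored_per_part(self):
        from infantpose.protocol import small_figure_config, study_training_config
        from infantpose.synthetic import generate_dataset, render_negative

        fig = small_figure_config()
        pos = generate_dataset(fig, 6, seed=5)
        rng = np.random.default_rng(6)
        neg = [render_negative(fig, rng, n_clutter=4) for _ in range(2)]
        cfg = study_training_config(
            seed=5, states_per_part=1, mining_rounds=1, max_passes=5,
            feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=48),
        )
        m, _ = train_model(pos, neg, cfg)
        assert set(m.omega_score) == set(m.tree.parts)


class TestCrossValidate:
    def _data(self):
        from infantpose.protocol import small_figure_config
        from infantpose.synthetic import generate_dataset, render_negative

        fig = small_figure_config()
        pos = generate_dataset(fig, 6, seed=9)
        rng = np.random.default_rng(10)
        neg = [render_negative(fig, rng, n_clutter=4) for _ in range(2)]
        return pos, neg

    def test_singleton_grid_returns_it_without_refinement(self):
        pos, neg = self._data()
        best, table = cross_validate(
            pos, neg, [0.5], folds=2, metric_fn=lambda C: 50.0
        )
        assert best == 0.5
        assert set(table["stage"]) == {"coarse"}

    def test_tie_breaks_to_smallest_C(self):
        pos, neg = self._data()
        best, _ = cross_validate(pos, neg, [1.0, 0.01, 0.1], folds=2, metric_fn=lambda C: 42.0)
        assert best == 0.01

    def test_refinement_never_worse_than_coarse(self):
        pos, neg = self._data()
        metric = lambda C: -abs(np.log10(C) - 0.2)  # peak near C ~ 1.6
        best, table = cross_validate(pos, neg, [1e-2, 1.0, 1e2], folds=2, metric_fn=metric)
        coarse_best = table[table.stage == "coarse"]["wca"].max()
        assert metric(best) >= coarse_best

    def test_too_many_folds_rejected(self):
        pos, neg = self._data()
        with pytest.raises(ValueError):
            cross_validate(pos, neg, [1.0], folds=99)

    def test_real_tiny_cv_runs(self):
        pos, neg = self._data()
        from infantpose.protocol import study_training_config

        cfg = study_training_config(
            seed=9, states_per_part=1, mining_rounds=1, max_passes=5,
            feature_config=FeatureConfig(cell_size_px=4, bins=9, min_level_px=48),
        )
        best, table = cross_validate(pos, neg, [0.5], folds=2, config=cfg)
        assert best == 0.5 and len(table) == 1
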