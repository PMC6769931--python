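"""Generator contracts: determinism, exact ground truth, invariant checks."""

import numpy as np
import pytest

from spheromet import (
    SceneConfigError,
    SpheroidScene,
    generate_cytometry_events,
    generate_spheroid_image,
    generate_timelapse,
)
from spheromet.outgrowth import DEAD_MEAN_CUTOFF

from conftest import brute_force_min_dist


class TestSpheroidScene:
    def test_deterministic_for_fixed_seed(self):
        a_img, a_gt = generate_spheroid_image(SpheroidScene(seed=3, noise_sd=50.0))
        b_img, b_gt = generate_spheroid_image(SpheroidScene(seed=3, noise_sd=50.0))
        for ch in a_img.channels:
            np.testing.assert_array_equal(a_img[ch], b_img[ch])
        np.testing.assert_array_equal(a_gt.matrix_cell_positions,
                                      b_gt.matrix_cell_positions)
        assert a_gt.matrix_cell_labels == b_gt.matrix_cell_labels

    def test_label_counts_by_construction(self):
        _, gt = generate_spheroid_image(
            SpheroidScene(seed=1, n_matrix_cells=30, dead_fraction=1 / 3,
                          n_conglomerates=3))
        labels = gt.matrix_cell_labels
        assert labels.count("dead") == 10
        assert labels.count("live") == 20
        assert labels.count("conglomerate") == 3

    def test_requested_distances_realised(self):
        scene = SpheroidScene(seed=2, n_matrix_cells=2,
                              matrix_cell_distances=[50.0, 120.0],
                              n_conglomerates=0, spheroid_radius=100.0)
        _, gt = generate_spheroid_image(scene)
        # brute-force oracle over every border pixel, from the true centers
        pos_px = gt.matrix_cell_positions / scene.pixel_size
        d_px = brute_force_min_dist(pos_px, gt.spheroid_border)
        np.testing.assert_allclose(d_px * scene.pixel_size, [50.0, 120.0],
                                   atol=0.5 * scene.pixel_size)
        np.testing.assert_allclose(gt.true_distances, d_px * scene.pixel_size,
                                   atol=1e-9)

    def test_ground_truth_distances_match_brute_force(self, scenes20):
        for scene, _, gt, _ in scenes20[:5]:
            pos_px = gt.matrix_cell_positions / scene.pixel_size
            d = brute_force_min_dist(pos_px, gt.spheroid_border)
            np.testing.assert_allclose(gt.true_distances, d * scene.pixel_size,
                                       atol=1e-9)

    def test_sytox_separation_guarantees_recoverability(self, scenes20):
        """Dead objects carry sytox strictly above, live strictly below, the
        classification cut-off at zero noise."""
        scene, img, gt, _ = scenes20[0]
        sytox = img["sytox"]
        for (x, y), label in zip(gt.matrix_cell_positions / scene.pixel_size,
                                 gt.matrix_cell_labels):
            if label == "conglomerate":
                continue
            yy, xx = np.mgrid[int(y) - 2:int(y) + 3, int(x) - 2:int(x) + 3]
            mean = sytox[yy, xx].mean()
            if label == "dead":
                assert mean > DEAD_MEAN_CUTOFF
            else:
                assert mean < DEAD_MEAN_CUTOFF

    def test_symmetric_scene_is_rotation_invariant(self):
        scene = SpheroidScene(seed=4, n_matrix_cells=0, n_conglomerates=0)
        img, _ = generate_spheroid_image(scene)
        # image center falls on the rotation fixed point of the pixel grid
        np.testing.assert_array_equal(img["dil"], np.rot90(img["dil"]))

    def test_cells_do_not_overlap_spheroid_mask(self, scenes20):
        for scene, img, gt, _ in scenes20[:5]:
            assert img["sytox"][gt.spheroid_mask].max() == 0.0

    @pytest.mark.parametrize("kwargs, fragment", [
        (dict(spheroid_radius=400.0), "margin"),
        (dict(dead_fraction=1.5), "dead_fraction"),
        (dict(n_matrix_cells=2, matrix_cell_distances=[10.0]), "length"),
        (dict(n_matrix_cells=1, matrix_cell_distances=[-5.0]), "nonnegative"),
        (dict(lobe_amplitude=1.2), "lobe_amplitude"),
        (dict(core_fraction=1.5), "core_fraction"),
        (dict(intensity_profile="banana"), "intensity_profile"),
    ])
    def test_invariant_violations_name_the_constraint(self, kwargs, fragment):
        with pytest.raises(SceneConfigError, match=fragment):
            generate_spheroid_image(SpheroidScene(seed=0, **kwargs))


class TestTimelapse:
    def test_straight_paths_have_exact_accumulated_length(self):
        _, gt = generate_timelapse(10, 13, 5.0, "straight", seed=5)
        for path in gt.track_paths:
            steps = np.hypot(*np.diff(path, axis=0).T)
            assert np.isclose(steps.sum(), 60.0, atol=1e-9)

    def test_random_walk_mean_step_matches_rayleigh(self):
        """Step lengths are Rayleigh(scale=step_length): mean sqrt(pi/2)·scale."""
        _, gt = generate_timelapse(100, 13, 5.0, "random_walk", seed=5)
        steps = np.concatenate([np.hypot(*np.diff(p, axis=0).T)
                                for p in gt.track_paths])
        expect = 5.0 * np.sqrt(np.pi / 2)
        se = steps.std() / np.sqrt(len(steps))
        assert abs(steps.mean() - expect) < 3 * se

    def test_zero_cells_gives_empty_frames_and_paths(self):
        frames, gt = generate_timelapse(0, 3, 5.0, "straight", seed=0)
        assert frames.sum() == 0.0
        assert len(gt.track_paths) == 0

    def test_determinism(self):
        f1, g1 = generate_timelapse(20, 5, 5.0, "random_walk", seed=11)
        f2, g2 = generate_timelapse(20, 5, 5.0, "random_walk", seed=11)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(g1.track_paths, g2.track_paths)

    def test_cluster_mode_area_factor(self):
        _, gt = generate_timelapse(0, 5, 0.0, "clustered", seed=0,
                                   cluster_area_factor=0.9)
        ratios = gt.cluster_areas / gt.cluster_areas[0]
        np.testing.assert_allclose(ratios, 0.9 ** np.arange(5), rtol=1e-9)

    def test_spacing_precondition_enforced(self):
        with pytest.raises(SceneConfigError, match="min_spacing"):
            generate_timelapse(5, 5, 25.0, "straight", seed=0, min_spacing=40.0)

    def test_unsatisfiable_grid_raises(self):
        with pytest.raises(SceneConfigError, match="unsatisfiable"):
            generate_timelapse(5000, 5, 5.0, "straight", seed=0,
                               image_shape=(256, 256))

    def test_too_few_frames_raises(self):
        with pytest.raises(SceneConfigError, match="n_frames"):
            generate_timelapse(5, 1, 5.0, "straight", seed=0)


class TestCytometryEvents:
    def test_zero_stain_equalises_expected_mfis(self):
        _, gt = generate_cytometry_events(100, {"pecy7": 0.0}, 300.0, seed=0)
        for tr in ("untreated", "plasma"):
            assert (gt.expected_mfi[(True, tr)]["pecy7"]
                    == gt.expected_mfi[(False, tr)]["pecy7"])

    def test_stained_treated_mean_recovers_sum(self):
        table, _ = generate_cytometry_events(10_000, 500.0, 300.0, seed=1)
        sub = table[(table.stained) & (table.treatment == "plasma")]["pecy7"]
        se = sub.std() / np.sqrt(len(sub))
        assert abs(sub.mean() - 800.0) < 3 * se

    def test_doublet_count_exact(self):
        _, gt = generate_cytometry_events(1000, 500.0, 300.0,
                                          doublet_fraction=0.1, seed=2)
        per_cond = gt.event_flags.groupby(["stained", "treatment"])["doublet"].sum()
        assert (per_cond == 100).all()

    def test_determinism(self):
        t1, _ = generate_cytometry_events(500, 500.0, 300.0, seed=9)
        t2, _ = generate_cytometry_events(500, 500.0, 300.0, seed=9)
        assert t1.equals(t2)

    def test_bad_fraction_raises(self):
        with pytest.raises(SceneConfigError, match="doublet_fraction"):
            generate_cytometry_events(10, 500.0, 300.0, doublet_fraction=1.2)
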