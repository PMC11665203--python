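"""Phantom generator tests: determinism, ground-truth conservation, errors."""

import numpy as np
import pytest

import pamvasc as pv
from pamvasc.bins import DEFAULT_BINS_UM, assign_bin
from pamvasc.phantom import (
    Centerline,
    bin_lengths,
    phantom_from_centerlines,
    write_phantom,
)


class TestPhantomSpec:
    def test_anisotropic_pitch_rejected(self):
        with pytest.raises(ValueError, match="isotropic"):
            pv.PhantomSpec(field_size_um=(2000, 1000), grid_px=(512, 512))

    def test_unrenderable_diameter_rejected(self):
        with pytest.raises(ValueError, match="5"):
            pv.PhantomSpec(grid_px=(256, 256), min_diameter_um=5.0)  # pitch 7.8 um

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            pv.PhantomSpec(n_trees=-1)
        with pytest.raises(ValueError):
            pv.PhantomSpec(psf_fwhm_um=-1)

    def test_paper_geometry_pitch(self):
        assert pv.PhantomSpec().pixel_pitch_um == pytest.approx(3.90625)


class TestGenerateVesselPhantom:
    def test_empty_scene_constant_image(self):
        spec = pv.PhantomSpec(n_trees=0, noise_sigma=0.0, background_level=50.0, seed=0)
        image, truth = pv.generate_vessel_phantom(spec)
        assert np.all(image.pixels == 50.0)
        assert truth.centerlines == [] and truth.total_length_um == 0

    def test_single_straight_vessel_bin_lengths(self):
        spec = pv.PhantomSpec(n_trees=0, noise_sigma=0.0, background_level=20.0, seed=0)
        pts = np.stack([np.full(50, 1000.0), np.linspace(500.0, 1500.0, 50)], axis=1)
        _, truth = phantom_from_centerlines(spec, [Centerline(pts, np.full(50, 15.0))])
        assert truth.per_bin_length_um[(10.0, 20.0)] == pytest.approx(1000.0)
        for b, v in truth.per_bin_length_um.items():
            if b != (10.0, 20.0):
                assert v == 0.0

    def test_same_seed_identical_geometry_and_noise(self):
        spec = pv.PhantomSpec(n_trees=3, seed=42)
        img_a, truth_a = pv.generate_vessel_phantom(spec)
        img_b, truth_b = pv.generate_vessel_phantom(spec)
        assert np.array_equal(img_a.pixels, img_b.pixels)
        assert len(truth_a.centerlines) == len(truth_b.centerlines)
        for ca, cb in zip(truth_a.centerlines, truth_b.centerlines):
            assert np.array_equal(ca.points, cb.points)

    def test_different_seed_different_noise(self):
        a, _ = pv.generate_vessel_phantom(pv.PhantomSpec(n_trees=0, seed=1))
        b, _ = pv.generate_vessel_phantom(pv.PhantomSpec(n_trees=0, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_blur_does_not_move_centerlines(self):
        sharp = pv.PhantomSpec(n_trees=3, psf_fwhm_um=0.0, seed=9)
        blurred = pv.PhantomSpec(n_trees=3, psf_fwhm_um=8.0, seed=9)
        _, t_sharp = pv.generate_vessel_phantom(sharp)
        _, t_blur = pv.generate_vessel_phantom(blurred)
        for ca, cb in zip(t_sharp.centerlines, t_blur.centerlines):
            assert np.array_equal(ca.points, cb.points)

    def test_per_bin_conservation(self):
        spec = pv.PhantomSpec(n_trees=4, capillary_fraction=0.2, seed=5)
        _, truth = pv.generate_vessel_phantom(spec)
        assert sum(truth.per_bin_length_um.values()) == pytest.approx(
            truth.total_length_um, rel=1e-6
        )

    def test_noise_statistics(self):
        spec = pv.PhantomSpec(
            n_trees=0, noise_sigma=5.0, background_level=50.0, seed=11
        )
        image, _ = pv.generate_vessel_phantom(spec)
        n = image.pixels.size
        assert abs(image.pixels.mean() - 50.0) < 3 * 5.0 / np.sqrt(n)
        assert abs(image.pixels.std() - 5.0) < 3 * 5.0 / np.sqrt(n)

    def test_capillary_fraction_reached(self):
        spec = pv.PhantomSpec(n_trees=3, capillary_fraction=0.3, seed=2)
        _, truth = pv.generate_vessel_phantom(spec)
        cap = sum(c.length_um for c in truth.centerlines if c.mean_diameter_um < 10)
        assert cap / truth.total_length_um >= 0.28  # loop stops once target is hit

    def test_hemorrhage_mask_populated(self):
        spec = pv.PhantomSpec(n_trees=1, n_hemorrhages=2, hemorrhage_radius_um=150.0, seed=4)
        _, truth = pv.generate_vessel_phantom(spec)
        assert truth.hemorrhage_mask.sum() > 0

    def test_mask_covers_centerline_pixels(self):
        spec = pv.PhantomSpec(n_trees=2, seed=8)
        _, truth = pv.generate_vessel_phantom(spec)
        pitch = truth.pixel_pitch_um
        for c in truth.centerlines[:5]:
            for pt in c.points[1:-1:5]:
                r, col = int(round(pt[0] / pitch)), int(round(pt[1] / pitch))
                assert truth.mask[r, col]


class TestGeneratePlaquePhantom:
    def test_zero_plaques(self):
        image, truth = pv.generate_plaque_phantom(0, seed=1)
        assert truth.plaque_xy == []

    def test_pairwise_separation(self):
        _, truth = pv.generate_plaque_phantom(25, spot_fwhm_um=15.0, seed=1)
        xy = np.array(truth.plaque_xy)
        assert len(xy) == 25
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3 * 15.0

    def test_deterministic(self):
        _, a = pv.generate_plaque_phantom(10, seed=3)
        _, b = pv.generate_plaque_phantom(10, seed=3)
        assert a.plaque_xy == b.plaque_xy

    def test_infeasible_count_rejected(self):
        with pytest.raises(ValueError, match="separation|cannot place"):
            pv.generate_plaque_phantom(5000, spot_fwhm_um=50.0, seed=0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            pv.generate_plaque_phantom(-1)
        with pytest.raises(ValueError):
            pv.generate_plaque_phantom(1, spot_fwhm_um=0.0)


class TestSimulateCohort:
    def test_subject_counts(self):
        cohort = pv.CohortSpec(
            n_per_group=5, groups=[("WT", {}, 0.0), ("AD", {}, 0.0)], seed=1
        )
        base = pv.PhantomSpec(n_trees=2, seed=0)
        subjects = pv.simulate_cohort(cohort, base, render=False)
        labels = [s[0] for s in subjects]
        assert labels.count("WT") == 5 and labels.count("AD") == 5

    def test_null_design_equal_expected_vld(self):
        base = pv.PhantomSpec(n_trees=3, seed=0)
        means = {"A": [], "B": []}
        for rep in range(10):
            cohort = pv.CohortSpec(
                n_per_group=3, groups=[("A", {}, 0.0), ("B", {}, 0.0)], seed=rep
            )
            for label, _, truth in pv.simulate_cohort(cohort, base, render=False):
                means[label].append(truth.total_length_um)
        ma, mb = np.mean(means["A"]), np.mean(means["B"])
        assert abs(ma - mb) / ma < 0.15

    def test_multiplier_scales_bin_truth(self):
        base = pv.PhantomSpec(n_trees=4, root_diameter_um=45.0, branch_decay=0.56, seed=0)
        bin_ = (10.0, 20.0)
        ctrl, eff = [], []
        for rep in range(20):
            cohort = pv.CohortSpec(
                n_per_group=2,
                groups=[("C", {}, 0.0), ("E", {bin_: 0.8}, 0.0)],
                seed=1000 + rep,
            )
            for label, _, truth in pv.simulate_cohort(cohort, base, render=False):
                (ctrl if label == "C" else eff).append(truth.per_bin_length_um[bin_])
        ratio = np.mean(eff) / np.mean(ctrl)
        assert 0.7 < ratio < 0.9

    def test_render_false_gives_no_image(self):
        cohort = pv.CohortSpec(n_per_group=2, groups=[("A", {}, 0.0)], seed=1)
        subjects = pv.simulate_cohort(cohort, pv.PhantomSpec(n_trees=1, seed=0), render=False)
        assert all(s[1] is None for s in subjects)

    def test_invalid_cohort(self):
        with pytest.raises(ValueError):
            pv.CohortSpec(n_per_group=1, groups=[("A", {}, 0.0)])
        with pytest.raises(ValueError):
            pv.CohortSpec(n_per_group=2, groups=[("A", {(0.0, 10.0): -1.0}, 0.0)])


class TestTruthInvariants:
    def test_bin_assignment_edge_goes_up(self):
        assert assign_bin(10.0) == (10.0, 20.0)
        assert assign_bin(9.999) == (0.0, 10.0)
        assert assign_bin(200.0) == (50.0, float("inf"))

    def test_bin_lengths_sum(self):
        pts = np.stack([np.zeros(10), np.linspace(0, 90, 10)], axis=1)
        cls = [Centerline(pts, np.full(10, d)) for d in (5.0, 15.0, 55.0)]
        total = sum(c.length_um for c in cls)
        assert sum(bin_lengths(cls).values()) == pytest.approx(total)


def test_write_phantom_round_trip(tmp_path):
    import json

    import tifffile

    spec = pv.PhantomSpec(n_trees=1, seed=6)
    image, truth = pv.generate_vessel_phantom(spec)
    paths = write_phantom(tmp_path, "p", image, truth)
    assert tifffile.imread(paths["image"]).shape == image.pixels.shape
    payload = json.loads((tmp_path / "p_truth.json").read_text())
    assert payload["pixel_pitch_um"] == pytest.approx(truth.pixel_pitch_um)
    assert len(payload["centerlines"]) == len(truth.centerlines)
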