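"""Skeleton, segment-graph, VLD and ESF tests against constructed geometry."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import pamvasc as pv
from pamvasc.bins import DEFAULT_BINS_UM
from pamvasc.morphometry import (
    EdgeDescriptor,
    Segment,
    VesselGraph,
    build_graph,
    measure_esf,
    skeletonize_mask,
    vld_profile,
)
from pamvasc.phantom import Centerline, phantom_from_centerlines
from tests.conftest import straight_tube

PITCH = 2000.0 / 512.0


def tube_phantom(diameter_um, angle_deg=0.0, length_um=1000.0):
    spec = pv.PhantomSpec(n_trees=0, psf_fwhm_um=0.0, noise_sigma=0.0, seed=1)
    cl = straight_tube(diameter_um, length_um=length_um, angle_deg=angle_deg)
    return phantom_from_centerlines(spec, [cl])


class TestSkeletonize:
    def test_empty_mask(self):
        assert not skeletonize_mask(np.zeros((16, 16), bool)).any()

    def test_skeleton_subset_of_mask(self):
        _, truth = tube_phantom(20.0)
        skel = skeletonize_mask(truth.mask)
        assert np.all(truth.mask[skel])

    def test_straight_bar_midline(self):
        mask = np.zeros((40, 220), bool)
        mask[15:25, 10:210] = True  # 200 x 10 bar, midline at row 19.5
        skel = skeletonize_mask(mask)
        rows = np.where(skel.any(axis=1))[0]
        assert np.all(np.abs(rows - 19.5) <= 1.0)
        assert abs(skel.sum() - 200) < 15

    def test_solid_disk_degenerates(self):
        r, c = np.mgrid[0:64, 0:64]
        disk = (r - 32) ** 2 + (c - 32) ** 2 <= 20**2
        skel = skeletonize_mask(disk)
        assert skel.sum() < 40  # total skeleton length < disk diameter


class TestBuildGraph:
    def test_empty_skeleton(self):
        g = build_graph(np.zeros((8, 8), bool), np.zeros((8, 8), bool), PITCH)
        assert g.segments == []

    def test_single_tube_length_and_diameter(self):
        _, truth = tube_phantom(20.0)
        g = build_graph(skeletonize_mask(truth.mask), truth.mask, PITCH)
        assert len(g.segments) == 1
        assert abs(g.segments[0].length_um - 1000.0) <= 2 * PITCH
        assert abs(g.segments[0].mean_diameter_um - 20.0) <= PITCH

    @pytest.mark.parametrize("angle", [0, 17, 30, 45, 63, 90])
    def test_length_recovery_any_orientation(self, angle):
        _, truth = tube_phantom(20.0, angle_deg=angle)
        g = build_graph(skeletonize_mask(truth.mask), truth.mask, PITCH)
        assert abs(g.total_length_um - 1000.0) <= 2 * PITCH

    def test_y_junction_three_segments_one_branch(self):
        spec = pv.PhantomSpec(n_trees=0, psf_fwhm_um=0.0, noise_sigma=0.0, seed=1)
        trunk = np.stack([np.full(80, 1000.0), np.linspace(200, 1000, 80)], axis=1)
        up = np.stack([np.linspace(1000, 400, 80), np.linspace(1000, 1700, 80)], axis=1)
        dn = np.stack([np.linspace(1000, 1600, 80), np.linspace(1000, 1700, 80)], axis=1)
        _, truth = phantom_from_centerlines(
            spec, [Centerline(p, np.full(80, 20.0)) for p in (trunk, up, dn)]
        )
        g = build_graph(skeletonize_mask(truth.mask), truth.mask, PITCH)
        assert len(g.segments) == 3
        assert len(g.branch_points) == 1

    def test_spur_pruning(self):
        mask = np.zeros((60, 200), bool)
        mask[28:33, 10:190] = True
        mask[33:37, 100:103] = True  # 4-px nub -> spur after thinning
        g = build_graph(skeletonize_mask(mask), mask, 1.0, prune_len_px=10.0)
        assert len(g.segments) == 1

    def test_psf_broadening_biases_diameter_up(self):
        # sub-resolution tube imaged with an 8 um PSF; threshold the blurred
        # image and confirm the measured diameter is biased upward
        spec = pv.PhantomSpec(
            n_trees=0, psf_fwhm_um=8.0, noise_sigma=0.0, background_level=20.0, seed=1
        )
        img, truth = phantom_from_centerlines(spec, [straight_tube(6.0)])
        bg = pv.estimate_background(img)
        mask = pv.map1_global(img, bg).mask
        g = build_graph(skeletonize_mask(mask), mask, PITCH)
        assert len(g.segments) >= 1
        assert max(s.mean_diameter_um for s in g.segments) >= 6.0


class TestVldProfile:
    def _graph(self, segments, area_mm2=4.0):
        return VesselGraph([], segments, area_mm2, PITCH)

    def test_single_segment_arithmetic(self):
        seg = Segment(np.zeros((2, 2)), length_um=1000.0, mean_diameter_um=15.0)
        prof = vld_profile(self._graph([seg]))
        assert prof.vld_per_bin[(10.0, 20.0)] == pytest.approx(0.25)
        assert sum(v for b, v in prof.vld_per_bin.items() if b != (10.0, 20.0)) == 0

    def test_empty_graph_zero_profile(self):
        prof = vld_profile(self._graph([]))
        assert prof.total_vld == 0

    def test_edge_diameter_goes_to_upper_bin(self):
        seg = Segment(np.zeros((2, 2)), length_um=500.0, mean_diameter_um=20.0)
        prof = vld_profile(self._graph([seg]))
        assert prof.vld_per_bin[(20.0, 30.0)] > 0
        assert prof.vld_per_bin[(10.0, 20.0)] == 0

    def test_total_is_sum(self):
        segs = [
            Segment(np.zeros((2, 2)), length_um=l, mean_diameter_um=d)
            for l, d in [(100.0, 5.0), (300.0, 25.0), (50.0, 80.0)]
        ]
        prof = vld_profile(self._graph(segs))
        assert prof.total_vld == pytest.approx(sum(prof.vld_per_bin.values()))

    def test_additivity_of_disjoint_fields(self):
        segs_a = [Segment(np.zeros((2, 2)), 800.0, 15.0)]
        segs_b = [Segment(np.zeros((2, 2)), 400.0, 35.0)]
        pa = vld_profile(self._graph(segs_a, 4.0))
        pb = vld_profile(self._graph(segs_b, 4.0))
        pu = vld_profile(self._graph(segs_a + segs_b, 8.0))
        for b in pu.vld_per_bin:
            assert pu.vld_per_bin[b] == pytest.approx(
                (pa.vld_per_bin[b] + pb.vld_per_bin[b]) / 2.0, abs=1e-6
            )

    def test_adding_vessel_monotone(self):
        segs = [Segment(np.zeros((2, 2)), 800.0, 15.0)]
        before = vld_profile(self._graph(segs)).total_vld
        segs.append(Segment(np.zeros((2, 2)), 100.0, 45.0))
        after = vld_profile(self._graph(segs)).total_vld
        assert after > before

    def test_multi_tree_recovery_from_truth_mask(self):
        spec = pv.PhantomSpec(
            field_size_um=(2000.0, 2000.0),
            grid_px=(1024, 1024),
            n_trees=5,
            root_diameter_um=45.0,
            branch_decay=0.56,
            psf_fwhm_um=0.0,
            noise_sigma=0.0,
            seed=7,
        )
        _, truth = pv.generate_vessel_phantom(spec)
        g = build_graph(skeletonize_mask(truth.mask), truth.mask, spec.pixel_pitch_um)
        prof = vld_profile(g)
        for b, true_vld in truth.true_vld().items():
            if true_vld >= 0.5:
                assert abs(prof.vld_per_bin[b] - true_vld) <= 0.15 * true_vld


class TestMeasureEsf:
    @staticmethod
    def blurred_edge(sigma_um, pitch_um, height=100.0):
        img = np.zeros((60, 400))
        img[:, 200:] = height
        img = gaussian_filter(img, sigma_um / pitch_um, mode="nearest")
        return pv.IntensityImage(img, pitch_um)

    def test_closed_form_fwhm(self):
        img = self.blurred_edge(3.397, 0.5)
        f = measure_esf(img, EdgeDescriptor(rows=slice(5, 55), cols=slice(100, 300)))
        assert f == pytest.approx(8.0, rel=0.02)

    def test_linearity_in_sigma(self):
        d = EdgeDescriptor(rows=slice(5, 55), cols=slice(100, 300))
        f1 = measure_esf(self.blurred_edge(3.0, 0.5), d)
        f2 = measure_esf(self.blurred_edge(6.0, 0.5), d)
        assert f2 == pytest.approx(2 * f1, rel=0.02)

    def test_unblurred_discretization_floor(self):
        img = np.zeros((100, 200))
        img[:, 100:] = 100.0
        f = measure_esf(
            pv.IntensityImage(img, PITCH),
            EdgeDescriptor(rows=slice(10, 90), cols=slice(50, 150)),
        )
        assert f <= 1.5 * PITCH

    def test_horizontal_orientation(self):
        img = self.blurred_edge(3.397, 0.5)
        transposed = pv.IntensityImage(img.pixels.T, 0.5)
        f = measure_esf(
            transposed,
            EdgeDescriptor(rows=slice(100, 300), cols=slice(5, 55), orientation="horizontal"),
        )
        assert f == pytest.approx(8.0, rel=0.02)

    def test_no_edge_raises(self):
        img = pv.IntensityImage(np.random.default_rng(0).uniform(1, 2, (60, 200)), 1.0)
        with pytest.raises(ValueError, match="edge|monotone"):
            measure_esf(img, EdgeDescriptor(rows=slice(5, 55), cols=slice(50, 150)))
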