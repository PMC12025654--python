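"""Binarization, centerlines, network graphs and the four parameters."""
import warnings

import numpy as np
import pytest

import mnvquant as m
from mnvquant.errors import (
    ContractViolationError,
    DegenerateInputError,
    InsufficientScalesError,
)
from mnvquant.morphometry import fd_box_ladder

from conftest import make_line_skeleton


def brute_force_box_count(grid, s):
    """Exhaustive oracle: scan every box of size s over the bounding box."""
    rows, cols = np.where(grid)
    g = grid[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    count = 0
    for r0 in range(0, g.shape[0], s):
        for c0 in range(0, g.shape[1], s):
            if g[r0 : r0 + s, c0 : c0 + s].any():
                count += 1
    return count


class TestBoxCounting:
    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((12, 12)) < 0.3
        if not grid.any():
            grid[4, 7] = True
        sizes = [1, 2, 3, 4, 5, 6]
        counts = m.box_counts(grid, sizes)
        expected = [brute_force_box_count(grid, s) for s in sizes]
        assert counts == expected

    def test_straight_line_dimension_one(self):
        grid = np.zeros((512, 512), dtype=bool)
        grid[256, :] = True
        fd, table = m.compute_fd(grid)
        assert fd == pytest.approx(1.0, abs=0.05)
        assert len(table["sizes"]) >= 3

    def test_filled_square_dimension_two(self):
        fd, _ = m.compute_fd(np.ones((512, 512), dtype=bool))
        assert fd == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_carpet_dimension(self):
        grid = np.ones((1, 1), dtype=bool)
        for _ in range(5):
            grid = np.block([[grid, grid, grid],
                             [grid, np.zeros_like(grid), grid],
                             [grid, grid, grid]])
        assert grid.shape == (243, 243)
        fd, _ = m.compute_fd(grid)
        assert fd == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_insufficient_scales(self):
        tiny = np.ones((6, 6), dtype=bool)
        with pytest.raises(InsufficientScalesError):
            m.compute_fd(tiny)

    def test_empty_structure(self):
        with pytest.raises(DegenerateInputError):
            m.box_counts(np.zeros((8, 8), dtype=bool), [2])

    def test_ladder_quarters_the_long_side(self):
        grid = np.zeros((512, 512), dtype=bool)
        grid[256, :] = True  # bounding box 1 x 512
        assert fd_box_ladder(grid) == [2, 4, 8, 16, 32, 64, 128]


class TestCenterlines:
    def test_wide_bar_thins_to_straight_midline(self):
        bar = np.zeros((11, 120), dtype=bool)
        bar[3:8, 10:111] = True  # 5 px wide, 101 px long
        skel = m.extract_centerlines(bar)
        rows = np.unique(np.where(skel)[0])
        assert len(rows) == 1
        assert abs(int(skel.sum()) - 101) <= 2  # end effects only

    def test_idempotent_on_thin_input(self):
        thin = make_line_skeleton()
        np.testing.assert_array_equal(m.extract_centerlines(thin), thin)

    def test_topology_preserved(self, mask0):
        from scipy import ndimage

        skel = m.extract_centerlines(mask0)
        structure = np.ones((3, 3), dtype=int)
        n_mask = ndimage.label(mask0, structure=structure)[1]
        n_skel = ndimage.label(skel, structure=structure)[1]
        assert n_skel == n_mask

    def test_empty_mask(self):
        assert not m.extract_centerlines(np.zeros((10, 10), dtype=bool)).any()

    def test_plus_shape_topology(self):
        plus = np.zeros((61, 61), dtype=bool)
        plus[28:33, 5:56] = True
        plus[5:56, 28:33] = True
        skel = m.extract_centerlines(plus)
        net = m.build_network(skel, 0.012)
        assert net.n_junctions == 1
        assert net.n_endpoints == 4
        assert net.graph.number_of_edges() == 4


class TestNetwork:
    def test_straight_line_single_edge(self):
        net = m.build_network(make_line_skeleton(101), 0.012)
        assert net.n_endpoints == 2
        assert net.graph.number_of_edges() == 1
        assert m.compute_suml(net) == pytest.approx(100 * 0.012)

    def test_diagonal_line_sqrt2_steps(self):
        sk = np.zeros((120, 120), dtype=bool)
        for i in range(101):
            sk[5 + i, 5 + i] = True
        net = m.build_network(sk, 0.012)
        assert m.compute_suml(net) == pytest.approx(100 * np.sqrt(2) * 0.012)

    def test_plus_edge_lengths(self):
        # four 25-step arms meeting at one junction pixel
        sk = np.zeros((61, 61), dtype=bool)
        sk[30, 5:56] = True
        sk[5:56, 30] = True
        net = m.build_network(sk, 1.0)
        assert net.n_junctions == 1
        lengths = sorted(d["length_mm"] for _, _, d in net.graph.edges(data=True))
        assert lengths == pytest.approx([25.0] * 4)
        assert m.compute_suml(net) == pytest.approx(100.0)

    def test_empty_skeleton(self):
        net = m.build_network(np.zeros((5, 5), dtype=bool), 0.012)
        assert net.graph.number_of_nodes() == 0
        assert m.compute_suml(net) == 0.0

    def test_isolated_cycle_single_self_edge(self):
        # diamond ring: every pixel has exactly two 8-neighbors
        sk = np.zeros((15, 15), dtype=bool)
        for r in range(15):
            for c in range(15):
                if abs(r - 7) + abs(c - 7) == 5:
                    sk[r, c] = True
        net = m.build_network(sk, 1.0)
        assert net.graph.number_of_edges() == 1
        u, v, d = next(iter(net.graph.edges(data=True)))
        assert u == v
        assert d["length_mm"] == pytest.approx(20 * np.sqrt(2))

    def test_non_thin_input_rejected(self):
        blob = np.zeros((8, 8), dtype=bool)
        blob[2:5, 2:5] = True
        with pytest.raises(ContractViolationError):
            m.build_network(blob, 0.012)


class TestParameters:
    def test_area_values(self):
        assert m.compute_area(np.zeros((10, 10), dtype=bool), 0.012) == 0.0
        mask = np.zeros((500, 500), dtype=bool)
        mask.ravel()[:1000] = True
        assert m.compute_area(mask, 0.012) == pytest.approx(0.144)
        assert m.compute_area(np.ones((500, 500), dtype=bool), 0.012) == pytest.approx(36.0)

    def test_flow_density_values(self):
        roi = m.MnvRoi(np.ones((40, 25), dtype=bool))
        assert m.compute_flow_density(roi.mask, roi) == 100.0
        assert m.compute_flow_density(np.zeros((40, 25), dtype=bool), roi) == 0.0
        mask = np.zeros((40, 25), dtype=bool)
        mask.ravel()[:412] = True
        assert m.compute_flow_density(mask, roi) == pytest.approx(41.2)

    def test_flow_density_empty_roi(self):
        with pytest.raises(DegenerateInputError):
            m.compute_flow_density(np.zeros((4, 4), bool), m.MnvRoi(np.zeros((4, 4), bool)))


class TestBinarize:
    def test_noiseless_two_level_exact(self, mask0, roi0, noiseless_img):
        vm = m.binarize(noiseless_img, roi0, smooth_sigma=0.0)
        np.testing.assert_array_equal(vm.mask, mask0)

    def test_threshold_from_roi_only(self, noiseless_img, roi0):
        # corrupting intensities outside the ROI must not change the result
        img2 = m.EnFaceAngiogram(noiseless_img.data.copy(), noiseless_img.pixel_scale_mm)
        img2.data[~roi0.mask] = 1.0
        a = m.binarize(noiseless_img, roi0, smooth_sigma=0.0)
        b = m.binarize(img2, roi0, smooth_sigma=0.0)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.threshold == b.threshold

    def test_background_roi_gives_empty_mask(self, noiseless_img, mask0):
        # a delineation over pure background holds no flow signal
        background = np.zeros_like(mask0)
        background[:40, :40] = True
        assert not (background & mask0).any()
        with pytest.warns(UserWarning):
            vm = m.binarize(noiseless_img, m.MnvRoi(background), smooth_sigma=0.0)
        assert not vm.mask.any()

    def test_constant_bright_roi_degenerate(self):
        img = m.EnFaceAngiogram(np.full((20, 20), 0.8), 0.012)
        img.data[0, 0] = 0.1  # background reference elsewhere
        roi = m.MnvRoi(np.pad(np.ones((10, 10), bool), 5))
        with pytest.raises(DegenerateInputError):
            m.binarize(img, roi, smooth_sigma=0.0)

    def test_empty_roi_rejected(self, noiseless_img):
        with pytest.raises(DegenerateInputError):
            m.binarize(noiseless_img, m.MnvRoi(np.zeros(noiseless_img.shape, bool)))

    def test_default_noise_dice(self, mask0, roi0, noisy_img):
        vm = m.binarize(noisy_img, roi0)
        dice = 2 * (vm.mask & mask0).sum() / (vm.mask.sum() + mask0.sum())
        assert dice >= 0.8

    def test_fixed_threshold(self, noiseless_img, roi0, mask0):
        vm = m.binarize(noiseless_img, roi0, method="fixed:0.5", smooth_sigma=0.0)
        np.testing.assert_array_equal(vm.mask, mask0)
        assert vm.threshold == 0.5


class TestQuantify:
    def test_noiseless_matches_ground_truth(self, tree0, mask0, roi0, noiseless_img):
        cfg = m.QuantConfig(smooth_sigma=0.0, area_substrate="mask")
        metrics = m.quantify(noiseless_img, roi0, cfg)
        assert metrics.area_mm2 == pytest.approx(mask0.sum() * 0.012**2)
        assert metrics.suml_mm == pytest.approx(tree0.total_length_mm, rel=0.10)
        assert metrics.flow_density_pct == pytest.approx(100 * mask0.sum() / roi0.n_pixels)

    def test_deterministic(self, roi0, noisy_img):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = m.quantify(noisy_img, roi0)
            b = m.quantify(noisy_img, roi0)
        assert a.to_dict() == b.to_dict()

    def test_scale_equivariance(self, roi0, noiseless_img):
        cfg = m.QuantConfig(smooth_sigma=0.0)
        base = m.quantify(noiseless_img, roi0, cfg)
        doubled_img = m.EnFaceAngiogram(noiseless_img.data, pixel_scale_mm=0.024)
        doubled = m.quantify(doubled_img, roi0, cfg)
        assert doubled.suml_mm == pytest.approx(2 * base.suml_mm)
        assert doubled.area_mm2 == pytest.approx(4 * base.area_mm2)
        assert doubled.fd == pytest.approx(base.fd)
        assert doubled.flow_density_pct == pytest.approx(base.flow_density_pct)

    def test_rotation_robustness(self):
        """A 2 mm straight segment measured at 0, 45 and 90 degrees."""
        scale = 0.012
        results = []
        for angle in (0.0, 45.0, 90.0):
            theta = np.deg2rad(angle)
            seg = np.array([[1.5, 1.5],
                            [1.5 + 2.0 * np.cos(theta), 1.5 + 2.0 * np.sin(theta)]])
            net = m.GroundTruthNetwork(
                segments=[seg], lengths_mm=[2.0], roots_mm=[(1.5, 1.5)],
                params=m.GrowthParams(), total_length_mm=2.0,
            )
            mask = m.rasterize_network(net, scale, vessel_width_px=3)
            skel = m.extract_centerlines(mask)
            results.append(m.compute_suml(m.build_network(skel, scale)))
        assert max(results) / min(results) < 1.05

    def test_fd_substrate_switch(self, roi0, noiseless_img):
        cfg_skel = m.QuantConfig(smooth_sigma=0.0, fd_substrate="skeleton")
        cfg_mask = m.QuantConfig(smooth_sigma=0.0, fd_substrate="mask")
        fd_skel = m.quantify(noiseless_img, roi0, cfg_skel).fd
        fd_mask = m.quantify(noiseless_img, roi0, cfg_mask).fd
        assert fd_mask > fd_skel  # filled tubes are denser than centerlines
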