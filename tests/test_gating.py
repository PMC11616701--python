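"""Density estimation, half-max contours, gating, and rare-cell ratios."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vdcyto.gating import (
    GateRegion,
    apply_gate,
    density_map,
    derive_gate,
    half_max_contour,
    rare_cell_ratio,
)


def bivariate_gaussian(n, mean=(100.0, 0.1), sd=(10.0, 0.02), seed=0):
    rng = np.random.default_rng(seed)
    return np.column_stack([
        rng.normal(mean[0], sd[0], n),
        rng.normal(mean[1], sd[1], n),
    ])


class TestDensityMap:
    def test_argmax_near_true_mean(self):
        pts = bivariate_gaussian(100_000)
        grid = density_map(pts, "histogram", bins=64)
        i, j = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        dx = grid.x_edges[1] - grid.x_edges[0]
        dy = grid.y_edges[1] - grid.y_edges[0]
        assert abs(grid.x_centers[i] - 100.0) <= 2 * dx
        assert abs(grid.y_centers[j] - 0.1) <= 2 * dy

    def test_histogram_integral_is_one(self):
        pts = bivariate_gaussian(20_000, seed=1)
        grid = density_map(pts, "histogram")
        assert grid.integral() == pytest.approx(1.0, abs=1e-6)

    def test_kde_integral_is_one(self):
        pts = bivariate_gaussian(20_000, seed=2)
        grid = density_map(pts, "kde")
        assert grid.integral() == pytest.approx(1.0, abs=1e-3)

    def test_identical_points_single_bin(self):
        pts = np.tile([50.0, 0.05], (100, 1))
        grid = density_map(pts, "histogram")
        assert (grid.density > 0).sum() == 1

    def test_degenerate_axis_named_in_error(self):
        pts = np.column_stack([np.full(100, 50.0), np.linspace(0, 0.1, 100)])
        with pytest.raises(ValueError, match="area"):
            density_map(pts, "kde")

    def test_uniform_density_flattens(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 1, 1_000_000),
                               rng.uniform(0, 1, 1_000_000)])
        grid = density_map(pts, "histogram", bins=16,
                           ranges=((0.0, 1.0), (0.0, 1.0)))
        assert grid.density.max() / grid.density.min() < 1.2

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            density_map(np.zeros((5, 2)))


class TestHalfMaxContour:
    def test_gaussian_half_max_radius(self):
        # the 50%-of-max level set of an isotropic Gaussian KDE is a circle
        # of radius sqrt((sigma^2 + h^2) * 2 ln 2) around the mode
        sigma = 1.0
        pts = bivariate_gaussian(100_000, mean=(0.0, 0.0), sd=(sigma, sigma), seed=4)
        grid = density_map(pts, "kde", bins=128)
        h = grid.bandwidth[0]
        regions = half_max_contour(grid, 0.5)
        poly = regions[0].polygon
        r = np.hypot(poly[:, 0] - pts[:, 0].mean(), poly[:, 1] - pts[:, 1].mean())
        expected = np.sqrt((sigma**2 + h**2) * 2 * np.log(2))
        assert np.median(r) == pytest.approx(expected, rel=0.05)

    def test_hausdorff_distance_to_analytic_ellipse(self):
        sx, sy = 10.0, 0.02
        pts = bivariate_gaussian(100_000, mean=(100.0, 0.1), sd=(sx, sy), seed=5)
        grid = density_map(pts, "kde", bins=128)
        hx, hy = grid.bandwidth
        region = half_max_contour(grid, 0.5)[0]
        t = np.linspace(0, 2 * np.pi, 720)
        scale = np.sqrt(2 * np.log(2))
        ellipse = np.column_stack([
            100.0 + np.sqrt(sx**2 + hx**2) * scale * np.cos(t),
            0.1 + np.sqrt(sy**2 + hy**2) * scale * np.sin(t),
        ])
        # Hausdorff in grid-cell units (axes have very different scales)
        dx = grid.x_edges[1] - grid.x_edges[0]
        dy = grid.y_edges[1] - grid.y_edges[0]
        a = region.polygon / [dx, dy]
        b = ellipse / [dx, dy]
        d = cdist(a, b)
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert hausdorff <= 2.0

    def test_two_separated_modes_two_contours(self):
        pts = np.vstack([
            bivariate_gaussian(20_000, mean=(50.0, 0.05), sd=(3.0, 0.005), seed=6),
            bivariate_gaussian(20_000, mean=(150.0, 0.25), sd=(3.0, 0.005), seed=7),
        ])
        grid = density_map(pts, "kde", bins=128)
        regions = half_max_contour(grid, 0.5)
        assert len(regions) == 2

    def test_level_validation(self):
        grid = density_map(bivariate_gaussian(1000, seed=8))
        with pytest.raises(ValueError, match="level"):
            half_max_contour(grid, 0.0)
        with pytest.raises(ValueError, match="level"):
            half_max_contour(grid, 1.5)

    def test_level_one_degenerates_to_mode(self):
        pts = bivariate_gaussian(50_000, seed=9)
        grid = density_map(pts, "kde", bins=64)
        regions = half_max_contour(grid, 0.999)
        assert regions
        assert regions[0].area < half_max_contour(grid, 0.5)[0].area / 10


class TestDeriveApplyGate:
    def test_gate_encloses_about_half_the_reference(self):
        pts = bivariate_gaussian(50_000, mean=(150.0, 0.08), sd=(15.0, 0.015), seed=10)
        gate = derive_gate(pts)
        frac = apply_gate(pts, gate).mean()
        # the half-max region of a Gaussian holds 50% of its mass
        assert frac >= 0.40
        assert gate.provenance["reference_n"] == 50_000

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            derive_gate(bivariate_gaussian(10, seed=11))

    def test_derivation_deterministic(self):
        pts = bivariate_gaussian(5000, seed=12)
        g1 = derive_gate(pts)
        g2 = derive_gate(pts)
        assert np.array_equal(g1.polygon, g2.polygon)

    def test_unit_square_gate_membership(self):
        gate = GateRegion(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
                          level=0.5)
        pts = np.array([[0.5, 0.5], [0.5, 0.0], [1.5, 0.5], [0.0, 0.0]])
        inside = apply_gate(pts, gate)
        # boundary (including vertices) counts as inside
        assert inside.tolist() == [True, True, False, True]

    def test_gating_invariant_to_point_order_and_rescaling(self):
        pts = bivariate_gaussian(2000, seed=13)
        gate = derive_gate(pts, method="histogram")
        inside = apply_gate(pts, gate)
        perm = np.random.default_rng(14).permutation(len(pts))
        assert np.array_equal(apply_gate(pts[perm], gate), inside[perm])
        # consistent affine rescaling of both points and gate
        scale, shift = np.array([3.0, 100.0]), np.array([-5.0, 2.0])
        gate2 = GateRegion(gate.polygon * scale + shift, gate.level)
        assert np.array_equal(apply_gate(pts * scale + shift, gate2), inside)

    def test_mixture_count_within_binomial_noise(self):
        # well-separated (>= 4 SD in both axes) spike recovered by gating
        rng = np.random.default_rng(15)
        n_major, n_spike = 100_000, 300
        major = np.column_stack([rng.normal(35, 3, n_major), rng.normal(0.16, 0.02, n_major)])
        spike = np.column_stack([rng.normal(160, 15, n_spike), rng.normal(0.06, 0.012, n_spike)])
        ref = np.column_stack([rng.normal(160, 15, 30_000), rng.normal(0.06, 0.012, 30_000)])
        gate = derive_gate(ref)
        capture = apply_gate(ref, gate).mean()
        mix = np.vstack([major, spike])
        gated = int(apply_gate(mix, gate).sum())
        expected = capture * n_spike
        assert abs(gated - expected) <= 3 * np.sqrt(expected) + 1


class TestRareCellRatio:
    def test_clopper_pearson_reference_values(self):
        ratio, (lo, hi) = rare_cell_ratio(100, 1_000_000)
        assert ratio == pytest.approx(1e-4)
        # reference values quoted to three significant figures
        assert lo == pytest.approx(8.14e-5, abs=5e-8)
        assert hi == pytest.approx(1.22e-4, abs=5e-7)

    def test_zero_and_full_counts(self):
        r0, (lo0, hi0) = rare_cell_ratio(0, 1000)
        assert r0 == 0.0 and lo0 == 0.0 and hi0 > 0
        r1, (lo1, hi1) = rare_cell_ratio(1000, 1000)
        assert r1 == 1.0 and hi1 == 1.0 and lo1 < 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            rare_cell_ratio(5, 0)
        with pytest.raises(ValueError):
            rare_cell_ratio(11, 10)
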