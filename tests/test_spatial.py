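"""Moran's I, pattern labels, the deviational ellipse and its land mask."""

import numpy as np
import pytest

from habsuit.geodata import EnvRaster, InputError, ProjectedPoints
from habsuit.spatial import (
    DegeneracyError,
    MoranResult,
    build_weights,
    classify_pattern,
    directional_distribution,
    ellipse_mask,
    morans_i,
)
from habsuit.synthetic import gen_gaussian_points


def brute_force_moran(values, w):
    z = values - values.mean()
    n = len(z)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return (n / w.sum()) * num / np.sum(z**2)


class TestWeights:
    def test_unit_square_inverse_distance(self):
        pts = ProjectedPoints(
            x=np.array([0.0, 1, 0, 1]), y=np.array([0.0, 0, 1, 1])
        )
        W = build_weights(pts, row_standardize=False)
        assert W.w[0, 1] == pytest.approx(1.0)            # side
        assert W.w[0, 3] == pytest.approx(1 / np.sqrt(2))  # diagonal < side
        assert np.allclose(W.w, W.w.T)
        assert np.all(np.diag(W.w) == 0)

    def test_row_standardized_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        pts = ProjectedPoints(x=rng.uniform(0, 10, 15), y=rng.uniform(0, 10, 15))
        W = build_weights(pts)
        assert np.allclose(W.w.sum(axis=1), 1.0)

    def test_k_nearest_one_on_a_line(self):
        pts = ProjectedPoints(x=np.array([0.0, 1, 3, 6]), y=np.zeros(4))
        W = build_weights(pts, scheme="k_nearest", k=1, row_standardize=False)
        assert W.w[0].tolist() == [0, 1, 0, 0]
        assert W.w[2].tolist() == [0, 1, 0, 0]


class TestMoransI:
    @pytest.mark.parametrize(
        "n,expected",
        [(91, -0.011111), (49, -0.020833), (121, -0.008333), (27, -0.038462)],
    )
    def test_expected_index(self, n, expected):
        rng = np.random.default_rng(n)
        pts = ProjectedPoints(x=rng.uniform(0, 100, n), y=rng.uniform(0, 100, n))
        res = morans_i(rng.normal(size=n), build_weights(pts))
        assert round(res.expected, 6) == expected

    def test_matches_brute_force_double_loop(self):
        pts = ProjectedPoints(
            x=np.array([0.0, 1, 0, 1]), y=np.array([0.0, 0, 1, 1])
        )
        values = np.array([1.0, -1, 1, -1])
        W = build_weights(pts, row_standardize=False)
        res = morans_i(values, W)
        assert res.I == pytest.approx(brute_force_moran(values, W.w), abs=1e-12)

    def test_constant_values_degenerate(self):
        rng = np.random.default_rng(2)
        pts = ProjectedPoints(x=rng.uniform(0, 10, 8), y=rng.uniform(0, 10, 8))
        with pytest.raises(DegeneracyError):
            morans_i(np.ones(8), build_weights(pts))

    def test_permutation_p_agrees_with_analytic(self):
        rng = np.random.default_rng(3)
        n = 40
        pts = ProjectedPoints(x=rng.uniform(0, 100, n), y=rng.uniform(0, 100, n))
        vals = rng.normal(size=n)
        W = build_weights(pts)
        analytic = morans_i(vals, W)
        mc = morans_i(vals, W, permutations=999, rng=np.random.default_rng(0))
        assert mc.I == analytic.I
        assert abs(mc.p_value - analytic.p_value) < 0.15

    def test_type_one_error_calibration(self):
        # i.i.d. noise: Z should be centred and the 5% test should reject
        # at roughly its nominal rate
        rng = np.random.default_rng(4)
        n, sims = 30, 500
        pts = ProjectedPoints(x=rng.uniform(0, 100, n), y=rng.uniform(0, 100, n))
        W = build_weights(pts)
        zs, rejects = [], 0
        for _ in range(sims):
            res = morans_i(rng.normal(size=n), W)
            zs.append(res.z)
            rejects += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / sims)
        assert abs(np.mean(zs)) < 0.1
        assert abs(rejects / sims - 0.05) < 3 * se


class TestPatternLabels:
    @pytest.mark.parametrize(
        "I,z,p,label",
        [
            (0.061917, 0.544034, 0.586418, "random"),
            (-0.349273, -1.767073, 0.077216, "quasi-random"),
            (-0.260731, -3.091786, 0.001990, "quasi-dispersed"),
            (0.132592, 0.547811, 0.583822, "random"),
        ],
    )
    def test_reference_triples(self, I, z, p, label):
        res = MoranResult(I=I, expected=-1 / 90, variance=1.0, z=z, p_value=p, n=91)
        assert classify_pattern(res) == label

    def test_strongly_significant_labels(self):
        res = MoranResult(I=0.8, expected=-0.01, variance=0.01, z=8.0, p_value=1e-8, n=50)
        assert classify_pattern(res) == "clustered"
        res = MoranResult(I=-0.8, expected=-0.01, variance=0.01, z=-8.0, p_value=1e-8, n=50)
        assert classify_pattern(res) == "dispersed"


class TestDirectionalEllipse:
    def test_axis_aligned_symmetric_cloud(self):
        pts = ProjectedPoints(
            x=np.array([1.0, -1, 0, 0]), y=np.array([0.0, 0, 2, -2])
        )
        ell = directional_distribution(pts)
        assert ell.center_x == pytest.approx(0.0)
        assert ell.center_y == pytest.approx(0.0)
        assert ell.theta == pytest.approx(0.0)
        assert ell.semi_y > ell.semi_x  # north-south major axis

    def test_matches_eigen_decomposition_oracle(self):
        pts = gen_gaussian_points(5, 500, covariance=[[3.0, 1.2], [1.2, 1.0]])
        ell = directional_distribution(pts, n_sd=3)
        xy = pts.xy - pts.xy.mean(axis=0)
        cov = xy.T @ xy / len(xy)
        eigvals = np.sort(np.linalg.eigvalsh(cov))
        assert np.allclose(
            np.sort([ell.semi_x, ell.semi_y]), 3 * np.sqrt(eigvals), atol=1e-8
        )
        # the rotated frame really decorrelates the deviations
        ct, st = np.cos(ell.theta), np.sin(ell.theta)
        u = xy[:, 0] * ct - xy[:, 1] * st
        v = xy[:, 0] * st + xy[:, 1] * ct
        assert abs(np.mean(u * v)) < 1e-6 * np.std(u) * np.std(v) * len(xy)

    def test_rotation_equivariance(self):
        pts = gen_gaussian_points(6, 300, covariance=[[2.0, 0.5], [0.5, 1.0]])
        ell1 = directional_distribution(pts)
        phi = np.radians(25)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        xy = pts.xy @ R.T
        ell2 = directional_distribution(ProjectedPoints(x=xy[:, 0], y=xy[:, 1]))
        assert np.allclose(
            sorted([ell1.semi_x, ell1.semi_y]),
            sorted([ell2.semi_x, ell2.semi_y]),
            atol=1e-9,
        )
        # rotating the points counter-clockwise turns the clockwise-from-north
        # azimuth back by the same angle (modulo the ellipse's pi symmetry)
        dtheta = (ell1.theta - ell2.theta) % np.pi
        assert min(abs(dtheta - phi), abs(dtheta - phi + np.pi), abs(dtheta - phi - np.pi)) < 1e-6

    def test_three_sd_containment_fraction(self):
        pts = gen_gaussian_points(7, 100_000, covariance=[[2.0, 0.6], [0.6, 1.0]])
        ell = directional_distribution(pts, n_sd=3)
        frac = ell.contains(pts.x, pts.y).mean()
        assert frac == pytest.approx(1 - np.exp(-4.5), abs=0.003)

    def test_collinear_points_degenerate(self):
        pts = ProjectedPoints(x=np.arange(5.0), y=np.arange(5.0))
        with pytest.raises(DegeneracyError):
            directional_distribution(pts)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            directional_distribution(ProjectedPoints(x=np.array([0.0, 1]), y=np.array([0.0, 1])))

    def test_polygon_area_matches_pi_ab(self):
        pts = gen_gaussian_points(8, 200, covariance=[[4.0, 0.0], [0.0, 1.0]])
        ell = directional_distribution(pts)
        assert ell.polygon().area == pytest.approx(ell.area_m2, rel=1e-3)


class TestEllipseMask:
    def _circle_ellipse(self, r_m):
        from habsuit.spatial import DirectionalEllipse

        return DirectionalEllipse(
            center_x=0.0, center_y=0.0, theta=0.0, semi_x=r_m, semi_y=r_m, n_sd=3
        )

    def test_lattice_count_for_circle(self):
        # 7x7 one-degree grid centred on the origin; radius 2.5 cells
        grid = np.ones((7, 7))
        glc = EnvRaster("GLC", grid, west=-3.5, north=3.5, cell_size=1.0)
        from habsuit.projection import geographic_to_equal_area

        # radius 2.5 cells in projected metres (cells are ~111 km at the equator)
        x1, _ = geographic_to_equal_area(2.5, 0.0)
        mask = ellipse_mask(self._circle_ellipse(abs(x1) * 1.0001), glc)
        assert mask.sum() == 21  # lattice points with i^2+j^2 <= 6.25

    def test_all_water_empty_mask(self, caplog):
        glc = EnvRaster("GLC", np.full((7, 7), 20.0), west=-3.5, north=3.5, cell_size=1.0)
        mask = ellipse_mask(self._circle_ellipse(3e5), glc)
        assert mask.sum() == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_masked_area_approximates_ellipse_area(self):
        # fine grid, no water: cell-count area ~ pi a b
        n = 200
        cell = 0.02
        glc = EnvRaster("GLC", np.ones((n, n)), west=-2, north=2, cell_size=cell)
        from habsuit.projection import geographic_to_equal_area

        a, _ = geographic_to_equal_area(1.2, 0.0)
        b, _ = geographic_to_equal_area(0.7, 0.0)
        from habsuit.spatial import DirectionalEllipse

        ell = DirectionalEllipse(0.0, 0.0, 0.0, abs(a), abs(b), 3)
        mask = ellipse_mask(ell, glc)
        cell_m, _ = geographic_to_equal_area(cell, 0.0)
        got = mask.sum() * cell_m**2
        assert got == pytest.approx(ell.area_m2, rel=0.05)
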