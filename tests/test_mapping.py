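"""Rank reclassification, combination, focal smoothing and the final classes."""

import numpy as np
import pytest

from habsuit.geodata import ConfigurationError, EnvRaster
from habsuit.mapping import (
    NODATA_RANK,
    RankRaster,
    classify_suitability,
    combine_equal_weight,
    disk_offsets,
    focal_smooth,
    rank_raster,
    run_species_model,
)
from habsuit.sampling import FrequencyClassTable


def make_class_table(code="ALT"):
    return FrequencyClassTable(
        code=code,
        bins=[(0.0, 10.0), (10.0, 20.0), (20.0, 30.0)],
        counts=np.array([10, 5, 1]),
        classes=np.array([3, 2, 1]),
        categorical=False,
    )


def toy_raster(grid, code="ALT"):
    g = np.asarray(grid, dtype=float)
    return EnvRaster(code, g, west=0, north=g.shape[0], cell_size=1.0)


class TestRankRaster:
    def test_hand_enumerated_3x3(self):
        grid = [[5.0, 15.0, 25.0], [5.0, 99.0, 15.0], [25.0, 5.0, 15.0]]
        r = toy_raster(grid)
        mask = np.ones((3, 3), dtype=bool)
        rr = rank_raster(r, make_class_table(), mask)
        expected = np.array([[3, 2, 1], [3, 0, 2], [1, 3, 2]])
        assert np.array_equal(rr.grid, expected)

    def test_unmasked_and_outlier_cells_nodata(self):
        r = toy_raster([[5.0, 999.0], [5.0, 5.0]])
        mask = np.array([[True, True], [False, True]])
        rr = rank_raster(r, make_class_table(), mask)
        assert rr.grid[0, 1] == NODATA_RANK  # never-observed value
        assert rr.grid[1, 0] == NODATA_RANK  # outside mask

    def test_code_mismatch_is_configuration_error(self):
        r = toy_raster([[5.0]], code="TMA")
        with pytest.raises(ConfigurationError):
            rank_raster(r, make_class_table("ALT"), np.ones((1, 1), dtype=bool))

    def test_conservation_within_mask(self, raster_quartet):
        alt = raster_quartet["ALT"]
        mask = np.zeros(alt.shape, dtype=bool)
        mask[20:60, 20:60] = True
        classes = make_class_table()
        classes.bins = [(0.0, 1000.0), (1000.0, 2000.0), (2000.0, 3400.0)]
        rr = rank_raster(alt, classes, mask)
        ranked = np.isin(rr.grid, [1, 2, 3]) & mask
        nodata_in_mask = (rr.grid == NODATA_RANK) & mask
        assert ranked.sum() + nodata_in_mask.sum() == mask.sum()


class TestCombine:
    def test_mean_and_nodata_propagation(self):
        t = toy_raster([[5.0, 5.0, 5.0]])
        r1 = RankRaster("ALT", np.array([[3, 3, 0]]), t)
        r2 = RankRaster("TMA", np.array([[3, 1, 2]]), t)
        out = combine_equal_weight(r1, r2)
        assert out[0, 0] == 3.0
        assert out[0, 1] == 2.0
        assert np.isnan(out[0, 2])

    def test_geometry_mismatch_raises(self):
        r1 = RankRaster("ALT", np.array([[3]]), toy_raster([[5.0]]))
        r2 = RankRaster(
            "TMA",
            np.array([[3]]),
            EnvRaster("TMA", np.array([[5.0]]), west=10, north=1, cell_size=1.0),
        )
        with pytest.raises(ConfigurationError):
            combine_equal_weight(r1, r2)


class TestFocalSmooth:
    def test_disk_cell_counts(self):
        # lattice-point enumeration oracle
        assert disk_offsets(9).sum() == 253
        assert disk_offsets(2.5).sum() == 21
        assert disk_offsets(1).sum() == 5

    def test_constant_grid_unchanged(self):
        g = np.full((30, 30), 2.0)
        assert np.allclose(focal_smooth(g, 9), 2.0)

    def test_single_high_cell_radius_nine(self):
        g = np.ones((40, 40))
        g[20, 20] = 3.0
        out = focal_smooth(g, 9)
        assert out[20, 20] == pytest.approx((252 * 1 + 3) / 253)

    def test_corner_uses_clipped_neighbourhood(self):
        g = np.ones((30, 30))
        g[0, 0] = 3.0
        out = focal_smooth(g, 9)
        # oracle: enumerate in-bounds disk cells around the corner
        cnt = sum(
            1
            for di in range(-9, 10)
            for dj in range(-9, 10)
            if di * di + dj * dj <= 81 and 0 <= di < 30 and 0 <= dj < 30
        )
        assert out[0, 0] == pytest.approx((cnt - 1 + 3) / cnt)

    def test_nan_centre_stays_nan_and_is_ignored(self):
        g = np.ones((25, 25))
        g[12, 12] = np.nan
        out = focal_smooth(g, 3)
        assert np.isnan(out[12, 12])
        assert out[12, 11] == pytest.approx(1.0)

    def test_radius_below_one_is_identity(self):
        g = np.random.default_rng(0).uniform(1, 3, (10, 10))
        assert np.array_equal(focal_smooth(g, 0.5), g)

    def test_output_within_input_bounds(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(1, 3, (40, 40))
        out = focal_smooth(g, 9)
        assert out.min() >= g.min() - 1e-12 and out.max() <= g.max() + 1e-12

    def test_matches_exhaustive_oracle_on_20x20(self):
        rng = np.random.default_rng(2)
        g = rng.choice([1.0, 2.0, 3.0, np.nan], size=(20, 20), p=[0.3, 0.3, 0.3, 0.1])
        out = focal_smooth(g, 9)
        for i in range(20):
            for j in range(20):
                if np.isnan(g[i, j]):
                    assert np.isnan(out[i, j])
                    continue
                vals = [
                    g[i + di, j + dj]
                    for di in range(-9, 10)
                    for dj in range(-9, 10)
                    if di * di + dj * dj <= 81
                    and 0 <= i + di < 20
                    and 0 <= j + dj < 20
                    and not np.isnan(g[i + di, j + dj])
                ]
                assert out[i, j] == pytest.approx(np.mean(vals), abs=1e-9)


class TestClassifySuitability:
    @pytest.mark.parametrize(
        "value,expected",
        [(3.0, 3), (2.0, 2), (1.0, 1), (5 / 3, 2), (7 / 3, 3), (1.6, 1), (2.4, 3)],
    )
    def test_thirds_with_upward_boundaries(self, value, expected):
        out = classify_suitability(np.array([[value]]))
        assert out[0, 0] == expected

    def test_nan_maps_to_zero(self):
        assert classify_suitability(np.array([[np.nan]]))[0, 0] == 0

    def test_out_of_range_is_contract_violation(self):
        with pytest.raises(ValueError):
            classify_suitability(np.array([[4.0]]))

    def test_monotone_in_input_ranks(self):
        # raising both input ranks never lowers the final class
        t = toy_raster([[5.0] * 5] * 5)
        lo1 = RankRaster("ALT", np.full((5, 5), 1), t)
        lo2 = RankRaster("TMA", np.full((5, 5), 2), t)
        hi1 = RankRaster("ALT", np.full((5, 5), 2), t)
        hi2 = RankRaster("TMA", np.full((5, 5), 3), t)
        lo = classify_suitability(focal_smooth(combine_equal_weight(lo1, lo2), 2))
        hi = classify_suitability(focal_smooth(combine_equal_weight(hi1, hi2), 2))
        assert (hi >= lo).all()


class TestRunSpeciesModel:
    def test_deterministic_end_to_end(self, raster_quartet, niche_fixture):
        table, _ = niche_fixture
        rep1, suit1 = run_species_model(table, raster_quartet, "synthetic_sp")
        rep2, suit2 = run_species_model(table, raster_quartet, "synthetic_sp")
        assert np.array_equal(suit1.classified, suit2.classified)
        assert rep1.gwr.aicc == rep2.gwr.aicc
        assert rep1.moran.I == rep2.moran.I

    def test_high_suitability_concentrates_in_niche(self, raster_quartet, niche_fixture):
        table, truth = niche_fixture
        rep, suit = run_species_model(table, raster_quartet, "synthetic_sp")
        niche_cells = truth["niche_cell_mask"]
        inside = suit.classified[niche_cells]
        # most truth-niche cells inside the ellipse come out >= moderate
        judged = inside[inside > 0]
        assert len(judged) > 0
        assert (judged >= 2).mean() >= 0.7

    def test_sparse_species_skipped_with_reason(self, raster_quartet, niche_fixture):
        import pandas as pd

        from habsuit.geodata import LocalityTable

        table, _ = niche_fixture
        few = LocalityTable(table.frame.head(10).assign(species="rare_sp"))
        rep, suit = run_species_model(few, raster_quartet, "rare_sp", min_records=30)
        assert rep.skipped and suit is None
        assert "10" in rep.skip_reason

    def test_report_carries_all_reference_metrics(self, raster_quartet, niche_fixture):
        table, _ = niche_fixture
        rep, _ = run_species_model(table, raster_quartet, "synthetic_sp")
        d = rep.to_dict()
        assert {"AIC", "adj_R2", "R2", "VIF"} <= set(d["ols_selected_pair"])
        assert {"AICc", "R2", "adj_R2"} <= set(d["gwr"])
        assert {"morans_I", "expected_I", "variance", "z_score", "p_value", "pattern"} <= set(
            d["moran"]
        )
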