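import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, box

from lichenline import mapping as mp
from lichenline import synthetic as syn
from lichenline.rasters import Grid


class TestPlotFormulas:
    @pytest.mark.parametrize("cover3d, height, expected", [
        (100.0, 50.0, 50.0),   # full cover, 50 mm mat -> 50 dm^3 m^-2
        (0.0, 80.0, 0.0),
        (40.0, 25.0, 10.0),
    ])
    def test_volume_formula(self, cover3d, height, expected):
        assert mp.plot_volume(cover3d, height) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mp.plot_volume(-1.0, 10.0)

    @pytest.mark.parametrize("volume, expected", [
        (1.0, 22.0),
        (10_000.0, 220_000.0),   # 10 m^3 of lichen weighs 220 kg dry
        (0.0, 0.0),
    ])
    def test_biomass_formula(self, volume, expected):
        assert mp.plot_biomass(volume) == pytest.approx(expected)


class TestPointIntercept:
    def test_half_hits_give_half_cover(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:25, :] = True          # top half lichen
        assert mp.point_intercept_cover(mask, 100) == 50.0

    def test_full_mask_gives_full_cover(self):
        assert mp.point_intercept_cover(np.ones((30, 30)), 100) == 100.0

    def test_random_mask_within_binomial_bound(self):
        rng = np.random.default_rng(11)
        p = 0.3
        mask = rng.random((50, 50)) < p
        est = mp.point_intercept_cover(mask, 100)
        # 99 % binomial bound for 100 crosshairs
        assert abs(est - 100 * mask.mean()) <= 2.58 * 100 * np.sqrt(
            p * (1 - p) / 100)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            mp.point_intercept_cover(np.zeros((0, 0)))

    def test_non_square_grid_rejected(self):
        with pytest.raises(ValueError):
            mp.point_intercept_cover(np.ones((10, 10)), grid_n=99)


def linear_plots(slope_c=200.0, icpt_c=-24.0, slope_b=900.0, icpt_b=-110.0,
                 n=20):
    grey = np.linspace(0.13, 0.55, n)
    return pd.DataFrame({
        "grey_mean": grey,
        "cover2d_pct": slope_c * grey + icpt_c,
        "biomass_g_m2": slope_b * grey + icpt_b})


class TestFitPlotRegressions:
    def test_exact_line_recovered(self):
        reg = mp.fit_plot_regressions(linear_plots())
        assert reg.cover_slope == pytest.approx(200.0)
        assert reg.cover_intercept == pytest.approx(-24.0)
        assert reg.r2_cover == pytest.approx(1.0)
        assert reg.r2_biomass == pytest.approx(1.0)

    def test_zero_crossing_matches_root_finder(self):
        from scipy.optimize import brentq
        reg = mp.fit_plot_regressions(linear_plots())
        root = brentq(lambda g: reg.cover_slope * g + reg.cover_intercept,
                      -10, 10)
        assert reg.zero_cross_grey == pytest.approx(root, abs=1e-10)

    def test_cap_is_biomass_at_full_cover_grey(self):
        reg = mp.fit_plot_regressions(linear_plots())
        g100 = (100.0 - reg.cover_intercept) / reg.cover_slope
        assert reg.cap_biomass_g_m2 == pytest.approx(
            reg.biomass_slope * g100 + reg.biomass_intercept)

    def test_cover_fits_better_than_biomass_on_synthetic_plots(self,
                                                               train_site):
        """Mat-height variation degrades the biomass fit relative to the
        cover fit, the direction seen in real plot data."""
        reg = mp.fit_plot_regressions(train_site.plots)
        assert reg.r2_cover > reg.r2_biomass
        assert reg.p_cover < 0.001

    def test_degenerate_grey_rejected(self):
        df = linear_plots()
        df["grey_mean"] = 5.0
        with pytest.raises(ValueError, match="degenerate"):
            mp.fit_plot_regressions(df)


def reg_for_maps():
    return mp.fit_plot_regressions(linear_plots())


class TestPredictMaps:
    def grid_of(self, values):
        v = np.asarray(values, dtype=float)
        return Grid(v, 0, v.shape[0], 1.0, {"year": 1992})

    def test_grey_below_zero_cross_maps_to_zero(self):
        reg = reg_for_maps()
        grey = self.grid_of([[reg.zero_cross_grey - 0.05]])
        pair = mp.predict_maps(grey, reg, landcover=None,
                               exclude=frozenset())
        assert pair.cover.values[0, 0] == 0.0
        assert pair.biomass.values[0, 0] == 0.0

    def test_biomass_hits_cap_at_full_cover_grey(self):
        reg = reg_for_maps()
        grey = self.grid_of([[reg.grey_at_full_cover]])
        pair = mp.predict_maps(grey, reg, landcover=None,
                               exclude=frozenset())
        assert pair.biomass.values[0, 0] == pytest.approx(
            reg.cap_biomass_g_m2)

    def test_water_cells_become_nodata(self):
        reg = reg_for_maps()
        grey = self.grid_of([[0.3, 0.3]])
        lc = np.array([[syn.WATER, syn.HEATH]])
        pair = mp.predict_maps(grey, reg, landcover=lc)
        assert np.isnan(pair.cover.values[0, 0])
        assert np.isfinite(pair.cover.values[0, 1])
        assert pair.excluded_mask[0, 0]

    def test_clamp_conservation_everywhere(self):
        reg = reg_for_maps()
        rng = np.random.default_rng(2)
        grey = self.grid_of(rng.uniform(-1.0, 2.0, (40, 40)))
        pair = mp.predict_maps(grey, reg, landcover=None,
                               exclude=frozenset())
        assert np.nanmin(pair.cover.values) >= 0
        assert np.nanmax(pair.cover.values) <= 100
        assert np.nanmin(pair.biomass.values) >= 0
        assert np.nanmax(pair.biomass.values) <= reg.cap_biomass_g_m2

    def test_biomass_zero_wherever_cover_zero(self):
        reg = reg_for_maps()
        rng = np.random.default_rng(3)
        grey = self.grid_of(rng.uniform(-1.0, 1.0, (30, 30)))
        pair = mp.predict_maps(grey, reg, landcover=None,
                               exclude=frozenset())
        zero_cover = pair.cover.values == 0
        assert (pair.biomass.values[zero_cover] == 0).all()


def map_pair_from_cover(cover_values, pixel=100.0):
    v = np.asarray(cover_values, dtype=float)
    cover = Grid(v, 0.0, v.shape[0] * pixel, pixel, {"year": 1963})
    biomass = Grid(10.0 * v, 0.0, v.shape[0] * pixel, pixel)
    return mp.LichenMapPair(cover=cover, biomass=biomass, year=1963,
                            excluded_mask=np.zeros(v.shape, dtype=bool))


class TestZonalComparison:
    def borders(self, width_m, height_m):
        line = LineString([(width_m / 2, 0), (width_m / 2, height_m)])
        sides = {"sideA": box(0, 0, width_m / 2, height_m),
                 "sideB": box(width_m / 2, 0, width_m, height_m)}
        return line, sides

    def test_symmetric_map_gives_unit_ratio(self):
        v = np.tile([1.0, 2.0, 2.0, 1.0], (4, 1))
        pair = map_pair_from_cover(v)
        line, sides = self.borders(400.0, 400.0)
        for zc in mp.zonal_comparison(pair, line, sides,
                                      buffers=(100.0, 250.0)):
            assert zc.cover_ratio == pytest.approx(1.0)

    def test_constructed_42_28_comparison(self):
        # side B at 42 % cover, side A at 28 %: the zonal means recover the
        # construction and their ratio is 1.5
        v = np.tile([28.0] * 5 + [42.0] * 5, (6, 1))
        pair = map_pair_from_cover(v, pixel=1000.0)
        line, sides = self.borders(10_000.0, 6_000.0)
        zc = mp.zonal_comparison(pair, line, sides, buffers=(10_000.0,))[0]
        assert zc.mean_cover_sideA == pytest.approx(28.0)
        assert zc.mean_cover_sideB == pytest.approx(42.0)
        assert zc.cover_ratio == pytest.approx(1.5)

    def test_small_buffer_zone_is_subset_of_large(self):
        rng = np.random.default_rng(5)
        pair = map_pair_from_cover(rng.uniform(0, 50, (8, 8)))
        line, sides = self.borders(800.0, 800.0)
        from shapely import contains_xy
        X, Y = pair.cover.cell_centers()
        small = contains_xy(line.buffer(200.0), X.ravel(), Y.ravel())
        large = contains_xy(line.buffer(500.0), X.ravel(), Y.ravel())
        assert (small <= large).all()

    def test_empty_side_flagged_as_nan(self):
        pair = map_pair_from_cover(np.full((4, 4), np.nan))
        line, sides = self.borders(400.0, 400.0)
        zc = mp.zonal_comparison(pair, line, sides, buffers=(100.0,))[0]
        assert np.isnan(zc.mean_cover_sideA)


class TestDistrictMean:
    def test_constant_field_unit_identity(self):
        # 100 g m^-2 over any polygon is 100 t km^-2
        pair = map_pair_from_cover(np.full((5, 5), 10.0))
        assert mp.district_mean(pair, box(0, 0, 500, 500)) == pytest.approx(
            100.0)

    def test_single_cell_polygon(self):
        pair = map_pair_from_cover(np.arange(25.0).reshape(5, 5))
        val = mp.district_mean(pair, box(0, 400, 100, 500))
        assert val == pytest.approx(pair.biomass.values[0, 0])

    def test_including_zero_biomass_mires_lowers_mean(self):
        v = np.full((4, 4), 20.0)
        v[:, 0] = 0.0                      # a mire stripe with no lichen
        pair = map_pair_from_cover(v)
        lc = np.full((4, 4), syn.HEATH)
        lc[:, 0] = syn.MIRE
        poly = box(0, 0, 400, 400)
        with_mires = mp.district_mean(pair, poly, lc, include_mires=True)
        without = mp.district_mean(pair, poly, lc, include_mires=False)
        assert with_mires < without

    def test_empty_polygon_rejected(self):
        pair = map_pair_from_cover(np.ones((3, 3)))
        with pytest.raises(ValueError):
            mp.district_mean(pair, box(5000, 5000, 5100, 5100))


class TestRescaleCoefficients:
    def simple_reg(self):
        # cover = grey - 40, biomass = 10*grey - 400: zero-crossing at 40
        return mp.fit_plot_regressions(pd.DataFrame({
            "grey_mean": [40.0, 90.0, 140.0],
            "cover2d_pct": [0.0, 50.0, 100.0],
            "biomass_g_m2": [0.0, 500.0, 1000.0]}))

    def test_constant_scene_has_unit_coefficients(self):
        reg = self.simple_reg()
        grey = Grid(np.full((24, 24), 90.0), 0, 24, 1.0)
        table = mp.rescale_coefficients(grey, reg, target_pixels=(2.0, 4.0))
        np.testing.assert_allclose(table["coefficient"], 1.0)

    def test_isolated_bright_patches_fade_with_coarsening(self):
        """Patches brighter than the zero-crossing on a sub-threshold matrix
        lose biomass when averaged into coarse pixels."""
        grey = np.full((48, 48), 20.0)        # matrix below zero-crossing
        grey[10:12, 10:12] = 140.0            # isolated bright patches
        grey[30:32, 40:42] = 140.0
        g = Grid(grey, 0, 48, 1.0)
        reg = self.simple_reg()
        table = mp.rescale_coefficients(g, reg, target_pixels=(4.0, 8.0))
        coeffs = table["coefficient"].to_numpy()
        assert coeffs[0] == 1.0               # native, by definition
        assert (coeffs[1:] < 1.0).all()
        assert coeffs[2] <= coeffs[1] + 1e-12

    def test_brute_force_aggregation_oracle(self):
        """The coarse biomass equals predicting on explicit block means."""
        rng = np.random.default_rng(9)
        grey = rng.uniform(0.0, 160.0, (12, 12))
        g = Grid(grey, 0, 12, 1.0)
        reg = self.simple_reg()
        table = mp.rescale_coefficients(g, reg, target_pixels=(3.0,))
        manual = grey.reshape(4, 3, 4, 3).mean(axis=(1, 3))
        cap = reg.cap_biomass_g_m2
        pred = np.clip(reg.biomass_slope * manual + reg.biomass_intercept,
                       0, cap)
        pred[reg.cover_slope * manual + reg.cover_intercept <= 0] = 0.0
        assert table.loc[1, "mean_biomass_g_m2"] == pytest.approx(
            pred.mean())

    def test_incommensurate_factor_rejected(self):
        reg = self.simple_reg()
        g = Grid(np.ones((10, 10)), 0, 10, 1.0)
        with pytest.raises(ValueError):
            mp.rescale_coefficients(g, reg, target_pixels=(2.5,))


class TestWmape:
    def test_perfect_reconstruction_scores_zero(self):
        assert mp.wmape([100, 50], [100, 50]) == 0.0

    def test_worked_arithmetic(self):
        assert mp.wmape([100, 200], [150, 150]) == pytest.approx(1 / 3)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(1, 1e4), st.floats(0, 1e4)),
                    min_size=1, max_size=20))
    def test_equals_mae_over_mean_observed(self, pairs):
        o = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        assert mp.wmape(o, s) == pytest.approx(
            np.abs(o - s).mean() / np.abs(o).mean())

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            mp.wmape([0, 0], [1, 2])


class TestRoundTrip:
    def test_mapping_chain_self_consistent_on_noiseless_world(self):
        """Constant-height, noiseless world: the plot-trained chain
        reproduces the true district-mean biomass within 5 %."""
        from lichenline import calibration as cal
        spec = syn.LandscapeSpec(
            extent_m=(440.0, 400.0), base_pixel_m=0.5,
            lichen_patch_density=150.0, patch_biomass_range=(200.0, 800.0),
            matrix_biomass=40.0, matrix_height_mm=40.0,
            height_range_mm=(40.0, 40.0), patch_radius_m=(15.0, 50.0),
            n_lakes=0, n_fens=0, n_sandpits=0,
            landcover_fractions={"heath": 0.93, "forest": 0.02,
                                 "mire": 0.04, "water": 0.01},
            seed=17)
        land = syn.generate_landscape(spec)
        sensor = syn.SensorSpec("ideal", pixel_m=0.5, gain=1.0, offset=0.0,
                                noise_sd=0.0)
        grey = cal.to_greyscale(syn.render_scene(land, sensor))
        plots, _ = syn.generate_plots(land, 5, 40, cover3d_noise_sd=0.0)
        plots["grey_mean"] = [mp.extract_plot_grey(grey, x, y)
                              for x, y in zip(plots["x"], plots["y"])]
        reg = mp.fit_plot_regressions(plots)
        pair = mp.predict_maps(grey, reg, landcover=land.landcover)
        poly = box(0, 0, *spec.extent_m)
        predicted = mp.district_mean(pair, poly, land.landcover)
        excl = np.isin(land.landcover, [syn.FOREST, syn.WATER, syn.SAND])
        truth = float(land.biomass.values[~excl].mean())
        assert predicted == pytest.approx(truth, rel=0.05)
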