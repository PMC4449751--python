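import numpy as np
import pytest
from scipy import stats

from ibrkit import (
    Raster,
    build_variant_family,
    moving_window_mean,
    reverse_surface,
    road_decay,
    transform_high,
    transform_low,
)
from ibrkit.errors import ParameterError


class TestReversal:
    def test_constant_maps_to_floor(self):
        r = Raster(values=np.full((3, 3), 7.0), cell_size=300.0)
        assert np.allclose(reverse_surface(r).values, 0.1)

    def test_three_value_example(self, small_raster):
        out = reverse_surface(small_raster)
        np.testing.assert_allclose(out.values, [[3.1, 2.1, 0.1]], atol=1e-12)
        assert out.values.min() == pytest.approx(0.1, abs=1e-15)

    def test_double_reversal_restores_order(self, landscape):
        back = reverse_surface(reverse_surface(landscape))
        rho = stats.spearmanr(back.values.ravel(), landscape.values.ravel())[0]
        assert rho == pytest.approx(1.0)


class TestExponentialTransforms:
    def test_alpha_zero_homogenizes(self, small_raster):
        assert np.allclose(transform_high(small_raster, 0.0).values, 1.0)

    def test_maximum_maps_to_exp_alpha(self, small_raster):
        out = transform_high(small_raster, 10.0)
        assert out.values.max() == pytest.approx(np.exp(10.0), rel=1e-12)

    def test_high_three_value_vector(self, small_raster):
        out = transform_high(small_raster, 5.0)
        expected = np.exp([1.25, 2.5, 5.0])
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)

    def test_low_three_value_vector(self, small_raster):
        out = transform_low(small_raster, 5.0)
        f = np.exp([5.0, 10.0 / 3.0, 0.0])
        expected = f.max() - f + 0.1
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)
        assert out.values.min() == pytest.approx(0.1, abs=1e-12)

    def test_low_constant_input_degenerates_to_floor(self):
        r = Raster(values=np.full((2, 2), 5.0), cell_size=300.0)
        assert np.allclose(transform_low(r, 5.0).values, 0.1)

    def test_scale_invariance_of_high(self, small_raster):
        a = transform_high(small_raster, 5.0).values
        b = transform_high(small_raster.with_values(small_raster.values * 37.0), 5.0).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    @pytest.mark.parametrize("transform", [transform_high, transform_low])
    def test_rank_preserving(self, landscape, transform):
        out = transform(landscape, 10.0)
        rho = stats.spearmanr(out.values.ravel(), landscape.values.ravel())[0]
        assert rho == pytest.approx(1.0)

    def test_high_convex_low_concave(self):
        # evenly spaced inputs: second differences sign-check the curvature
        r = Raster(values=np.linspace(1, 10, 19)[None, :], cell_size=300.0)
        hi = transform_high(r, 5.0).values[0]
        lo = transform_low(r, 5.0).values[0]
        assert np.all(np.diff(hi, 2) > 0)
        assert np.all(np.diff(lo, 2) < 0)

    def test_overflow_guard(self, small_raster):
        with pytest.raises(ParameterError):
            transform_high(small_raster, 80.0)

    def test_high_requires_positive_input(self):
        r = Raster(values=np.array([[0.0, 1.0]]), cell_size=300.0)
        with pytest.raises(ParameterError):
            transform_high(r, 5.0)


class TestMovingWindow:
    def test_constant_unchanged(self):
        r = Raster(values=np.full((10, 10), 3.5), cell_size=300.0)
        assert np.allclose(moving_window_mean(r, 1500.0).values, 3.5)

    def test_spike_spreads_to_81_cells(self):
        vals = np.zeros((21, 21))
        vals[10, 10] = 81.0
        out = moving_window_mean(Raster(values=vals, cell_size=300.0), 1500.0)
        assert np.count_nonzero(out.values) == 81
        assert out.values[10, 10] == pytest.approx(1.0, abs=1e-12)

    def test_tiny_radius_is_identity_with_warning(self, landscape):
        with pytest.warns(UserWarning, match="identity"):
            out = moving_window_mean(landscape, 100.0)
        np.testing.assert_array_equal(out.values, landscape.values)

    def test_linearity_on_interior_cells(self, landscape):
        w = moving_window_mean(landscape, 3000.0).values
        scaled = landscape.with_values(2.5 * landscape.values + 7.0)
        w2 = moving_window_mean(scaled, 3000.0).values
        np.testing.assert_allclose(w2, 2.5 * w + 7.0, rtol=1e-10)

    def test_edge_cells_average_in_bounds_only(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        out = moving_window_mean(Raster(values=vals, cell_size=300.0), 310.0)
        # corner (0, 0): neighbors within one step are (0,1) and (1,0)
        assert out.values[0, 0] == pytest.approx((0 + 1 + 3) / 3)


class TestRoadDecay:
    def test_analytic_values(self):
        d = Raster(values=np.array([[0.0, 0.564, 5.64]]), cell_size=300.0)
        out = road_decay(d, alpha_km=0.564)
        np.testing.assert_allclose(
            out.values[0], [1.0, np.exp(-1.0), np.exp(-10.0)], rtol=1e-12
        )

    def test_negative_distance_rejected(self):
        d = Raster(values=np.array([[-1.0]]), cell_size=300.0)
        with pytest.raises(ParameterError):
            road_decay(d)


class TestVariantFamily:
    def test_windowed_family_has_15_members(self, landscape):
        family = build_variant_family("SAGE", landscape)
        assert len(family) == 15
        radii = {v.window_radius for v, _ in family}
        assert radii == {1500.0, 6440.0, 17330.0}

    def test_road_family_has_5_members(self, landscape):
        family = build_variant_family("ROAD", landscape, has_windows=False)
        assert len(family) == 5
        assert all(v.window_radius is None for v, _ in family)

    def test_transformation_labels(self, landscape):
        family = build_variant_family("RUGG", landscape, has_windows=False)
        labels = [(v.transformation, v.alpha) for v, _ in family]
        assert labels == [("untransformed", None), ("high", 5.0), ("high", 10.0),
                          ("low", 5.0), ("low", 10.0)]

    def test_all_variants_strictly_positive(self, landscape):
        for _, surf in build_variant_family("NEST", landscape):
            assert np.nanmin(surf.values) > 0

    def test_rejects_nonpositive_input(self):
        r = Raster(values=np.array([[0.0, 2.0]]), cell_size=300.0)
        with pytest.raises(ParameterError, match="positive"):
            build_variant_family("FOR", r)

    def test_family_manifest_round_trips(self, tmp_path, landscape):
        import pandas as pd

        from ibrkit import read_ascii_grid
        from ibrkit.surfaces import write_variant_family

        family = build_variant_family("ROAD", landscape, has_windows=False)
        manifest = write_variant_family(family, tmp_path / "fam")
        df = pd.read_csv(manifest)
        assert len(df) == 5
        back = read_ascii_grid(manifest.parent / df.iloc[1]["path"])
        np.testing.assert_allclose(back.values, family[1][1].values, rtol=1e-9)
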