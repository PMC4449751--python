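import numpy as np
import pytest

from ibrkit import (
    GeneticSimParams,
    LandscapeParams,
    PairwiseSimParams,
    place_groups,
    simulate_genotypes,
    simulate_landscape,
    simulate_pairwise_response,
)
from ibrkit.errors import ParameterError, PlacementError
from ibrkit.experiments import _reference_resistance


class TestLandscape:
    def test_same_seed_bitwise_identical(self):
        p = LandscapeParams(nrows=40, ncols=50, seed=1)
        np.testing.assert_array_equal(
            simulate_landscape(p).values, simulate_landscape(p).values
        )

    def test_values_respect_range(self):
        p = LandscapeParams(nrows=30, ncols=30, value_range=(2.0, 9.0), seed=3)
        vals = simulate_landscape(p).values
        assert vals.min() == pytest.approx(2.0) and vals.max() == pytest.approx(9.0)

    def test_degenerate_range_gives_constant(self):
        p = LandscapeParams(nrows=10, ncols=10, value_range=(1.0, 1.0), seed=4)
        assert np.all(simulate_landscape(p).values == 1.0)

    def test_tiny_correlation_range_decorrelates_neighbors(self):
        p = LandscapeParams(nrows=100, ncols=100, cell_size=300.0,
                            correlation_range=1.0, value_range=(0.0, 1.0), seed=5)
        vals = simulate_landscape(p).values
        r = np.corrcoef(vals[:, :-1].ravel(), vals[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_large_correlation_range_correlates_neighbors(self):
        p = LandscapeParams(nrows=100, ncols=100, cell_size=300.0,
                            correlation_range=6000.0, value_range=(0.0, 1.0),
                            seed=6)
        vals = simulate_landscape(p).values
        r = np.corrcoef(vals[:, :-1].ravel(), vals[:, 1:].ravel())[0, 1]
        assert r > 0.8

    def test_autocorrelation_decays_near_stated_scale(self):
        # correlation at the e-folding range should be near 1/e
        rng_m = 3000.0
        p = LandscapeParams(nrows=120, ncols=120, cell_size=300.0,
                            correlation_range=rng_m, value_range=(0.0, 1.0),
                            seed=7)
        vals = simulate_landscape(p).values
        lag = int(rng_m / 300.0)
        r = np.corrcoef(vals[:, :-lag].ravel(), vals[:, lag:].ravel())[0, 1]
        assert 0.15 < r < 0.6  # 1/e ~ 0.37, wide Monte-Carlo band

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            LandscapeParams(nrows=1, ncols=10)
        with pytest.raises(ParameterError):
            LandscapeParams(value_range=(5.0, 1.0))


class TestPlacement:
    def test_two_groups_on_large_extent(self):
        land = simulate_landscape(LandscapeParams(
            nrows=100, ncols=100, cell_size=1000.0, seed=1))
        g = place_groups(land, 2, min_separation=10_000.0, seed=2)
        assert len(g) == 2
        d = np.hypot(g[0].x - g[1].x, g[0].y - g[1].y)
        assert d >= 10_000.0

    def test_37_groups_pack_on_state_sized_extent(self):
        # 400 x 300 km extent comfortably admits 37 disks of 8 km radius
        land = simulate_landscape(LandscapeParams(
            nrows=30, ncols=40, cell_size=10_000.0, seed=3))
        g = place_groups(land, 37, min_separation=16_000.0, seed=4)
        assert len(g) == 37
        xy = np.array([(p.x, p.y) for p in g])
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
        assert d[~np.eye(37, dtype=bool)].min() >= 16_000.0

    def test_overpacking_raises(self):
        land = simulate_landscape(LandscapeParams(nrows=5, ncols=5,
                                                  cell_size=300.0, seed=5))
        with pytest.raises(PlacementError):
            place_groups(land, 50, min_separation=600.0, seed=6,
                         max_attempts_per_group=50)


class TestGenotypes:
    def test_no_missing_when_rate_zero(self):
        p = GeneticSimParams(n_groups=3, loci=5, individuals_per_group=10,
                             missing_rate=0.0, seed=1)
        t = simulate_genotypes(["a", "b", "c"], p)
        assert t.missing_fraction() == 0.0

    def test_missing_rate_respected(self):
        p = GeneticSimParams(n_groups=5, loci=14, individuals_per_group=30,
                             missing_rate=0.02, seed=2)
        t = simulate_genotypes([f"g{k}" for k in range(5)], p)
        assert t.missing_fraction() == pytest.approx(0.02, abs=0.01)

    def test_weak_drift_gives_negligible_differentiation(self):
        from ibrkit import pairwise_gst

        vals = []
        for rep in range(20):
            p = GeneticSimParams(n_groups=2, loci=50, alleles_per_locus=8,
                                 individuals_per_group=50,
                                 differentiation=0.001, missing_rate=0.0,
                                 seed=rep)
            t = simulate_genotypes(["a", "b"], p)
            vals.append(pairwise_gst(t).values[0, 1])
        assert np.mean(vals) < 0.01

    def test_moderate_drift_hits_expected_band(self):
        from ibrkit import pairwise_gst

        vals = []
        for rep in range(20):
            p = GeneticSimParams(n_groups=2, loci=50, alleles_per_locus=8,
                                 individuals_per_group=50, differentiation=0.2,
                                 missing_rate=0.0, seed=rep)
            t = simulate_genotypes(["a", "b"], p)
            vals.append(pairwise_gst(t).values[0, 1])
        assert 0.1 <= np.mean(vals) <= 0.3

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ParameterError):
            GeneticSimParams(alleles_per_locus=1)


@pytest.fixture(scope="module")
def resist():
    return _reference_resistance(12, seed=9)


class TestPairwiseResponse:
    def test_row_count_for_37_groups(self):
        resist = _reference_resistance(37, seed=1)
        y = simulate_pairwise_response(resist, PairwiseSimParams(seed=1))
        assert y.size == 666

    def test_deterministic_given_seed(self, resist):
        p = PairwiseSimParams(beta=(0.5,), seed=3)
        np.testing.assert_array_equal(
            simulate_pairwise_response(resist, p),
            simulate_pairwise_response(resist, p),
        )

    def test_noise_free_limit_is_collinear(self, resist):
        p = PairwiseSimParams(beta=(1.0,), sigma_u=0.0, sigma_e=1e-12, seed=4)
        y = simulate_pairwise_response(resist, p)
        z = (resist.condensed() - resist.condensed().mean())
        r2 = np.corrcoef(y, z)[0, 1] ** 2
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_mlpe_covariance_structure(self, resist):
        # beta = 0, sigma_u = 1, sigma_e ~ 0: Var(y) ~ 2, shared-group cov ~ 1
        members = resist.pair_members()
        share = (
            (members[:, None, 0] == members[None, :, 0])
            | (members[:, None, 0] == members[None, :, 1])
            | (members[:, None, 1] == members[None, :, 0])
            | (members[:, None, 1] == members[None, :, 1])
        )
        np.fill_diagonal(share, False)
        ys = np.array([
            simulate_pairwise_response(
                resist,
                PairwiseSimParams(beta=(0.0,), sigma_u=1.0, sigma_e=1e-6,
                                  seed=rep),
            )
            for rep in range(500)
        ])
        yc = ys - ys.mean(axis=0)
        cov = yc.T @ yc / (len(ys) - 1)
        var_mean = np.mean(np.diag(cov))
        cov_share = np.mean(cov[share])
        cov_noshare = np.mean(cov[(~share) & ~np.eye(cov.shape[0], dtype=bool)])
        assert var_mean == pytest.approx(2.0, rel=0.2)
        assert cov_share == pytest.approx(1.0, rel=0.25)
        assert abs(cov_noshare) < 0.15

    def test_dimension_mismatch_rejected(self, resist):
        with pytest.raises(ParameterError):
            simulate_pairwise_response(
                [resist, resist], PairwiseSimParams(beta=(0.5,), seed=1)
            )
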