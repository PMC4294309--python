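import numpy as np
import pytest

import paddygeo as pg
from paddygeo.exceptions import DomainError, InsufficientDataError, \
    ValidationError
from conftest import random_scatter
from _oracles import brute_force_variogram


class TestEmpiricalVariogram:
    def test_matches_brute_force_on_random_scatters(self):
        """Binned estimator equals explicit pair enumeration, 100 instances."""
        for seed in range(100):
            n = 10 + seed % 21  # 10..30 points
            s = random_scatter(seed, n)
            emp = pg.empirical_variogram(s, lag_width=17.0, max_lag=85.0,
                                         center="mean")
            oracle = brute_force_variogram(s.x, s.y, s.values, 17.0, 85.0)
            assert emp.n_bins == len(oracle)
            for c, g, np_ in zip(emp.lag_center, emp.gamma, emp.n_pairs):
                k = int((c + 1e-9) // 17.0)
                cnt, gam, dmean = oracle[k]
                assert np_ == cnt
                assert g == pytest.approx(gam, rel=1e-12)
                assert c == pytest.approx(dmean, rel=1e-12)

    def test_constant_field_has_zero_semivariance(self):
        coords = pg.generate_layout_coordinates(n_samples=12)
        s = pg.SampleSet("C", pg.Nutrient.NH4N, 0, 1, coords[:, 0],
                         coords[:, 1], np.full(12, 5.0))
        emp = pg.empirical_variogram(s, lag_width=12.0, max_lag=60.0)
        assert np.all(emp.gamma == 0.0)

    def test_translation_invariance(self, nh4_10_field):
        emp = pg.empirical_variogram(nh4_10_field)
        shifted = nh4_10_field.replace_values(nh4_10_field.values + 100.0)
        emp2 = pg.empirical_variogram(shifted)
        assert np.allclose(emp.gamma, emp2.gamma, rtol=1e-10)
        assert np.array_equal(emp.n_pairs, emp2.n_pairs)

    def test_pair_count_bound(self, nh4_10_field):
        emp = pg.empirical_variogram(nh4_10_field)
        n = nh4_10_field.n
        assert emp.n_pairs.sum() <= n * (n - 1) // 2
        assert np.all(np.diff(emp.lag_center) > 0)

    def test_requires_spatial_structure(self):
        s = random_scatter(0, 5)
        with pytest.raises(InsufficientDataError):
            pg.empirical_variogram(s)

    def test_no_pairs_within_max_lag(self):
        x = np.arange(10) * 500.0
        s = pg.SampleSet("FAR", pg.Nutrient.NH4N, 0, 1, x, np.zeros(10),
                         np.arange(1.0, 11.0))
        with pytest.raises(ValidationError, match="no point pairs"):
            pg.empirical_variogram(s, lag_width=20.0, max_lag=100.0)


class TestModelGamma:
    def test_zero_at_origin_all_families(self):
        for fam in pg.ModelFamily:
            m = pg.VariogramModel(fam, 1.0, 3.0, 50.0)
            assert pg.model_gamma(m, 0.0) == 0.0

    def test_spherical_reaches_printed_sill(self):
        m = pg.VariogramModel("spherical", 1.09, 14.20, 47.0)
        assert pg.model_gamma(m, 47.0) == pytest.approx(15.29)
        assert pg.model_gamma(m, 120.0) == pytest.approx(15.29)

    def test_spherical_half_range_closed_form(self):
        m = pg.VariogramModel("spherical", 1.09, 14.20, 47.0)
        assert pg.model_gamma(m, 23.5) == pytest.approx(
            1.09 + 0.6875 * 14.20)

    def test_exponential_practical_range_convention(self):
        m = pg.VariogramModel("exponential", 0.0, 12.25, 59.5)
        # at the practical range the model sits at 95% of its sill
        assert pg.model_gamma(m, 59.5) == pytest.approx(
            12.25 * (1 - np.exp(-3.0)))
        assert pg.model_cov(m, 59.5) == pytest.approx(12.25 * np.exp(-3.0))

    def test_monotone_nondecreasing_in_h(self):
        h = np.linspace(0, 300, 400)
        rng = np.random.default_rng(11)
        for fam in pg.ModelFamily:
            for _ in range(20):
                m = pg.VariogramModel(fam, rng.uniform(0, 5),
                                      rng.uniform(0.1, 20),
                                      rng.uniform(5, 150))
                g = pg.model_gamma(m, h)
                assert np.all(np.diff(g) >= -1e-12)

    def test_gamma_plus_cov_equals_sill(self):
        h = np.linspace(0.01, 200, 100)
        for fam in pg.ModelFamily:
            m = pg.VariogramModel(fam, 2.0, 7.0, 60.0)
            assert np.allclose(pg.model_gamma(m, h) + pg.model_cov(m, h),
                               m.sill, atol=1e-14)

    def test_negative_distance_rejected(self):
        m = pg.VariogramModel("spherical", 1.0, 1.0, 10.0)
        with pytest.raises(DomainError):
            pg.model_gamma(m, -1.0)


class TestNuggetRatioAndClassification:
    @pytest.mark.parametrize("c0,c1,expected", [
        (1.09, 14.20, 7.1),   # printed NH4-10 row
        (1.53, 1.97, 43.7),   # printed P-22 row
        (0.0, 12.25, 0.0),
    ])
    def test_printed_ratios(self, c0, c1, expected):
        m = pg.VariogramModel("spherical", c0, c1, 50.0)
        assert round(pg.nugget_sill_ratio(m), 1) == expected

    def test_all_27_printed_ratios_recompute(self, scenarios):
        ratios = [100.0 * r["c0"] / (r["c0"] + r["c1"])
                  for _, r in scenarios.iterrows()]
        assert np.abs(np.array(ratios) - scenarios["ratio"]).max() <= 0.1

    @pytest.mark.parametrize("ratio,expected", [
        (7.1, pg.SpatialDependence.STRONG),
        (24.999, pg.SpatialDependence.STRONG),
        (25.0, pg.SpatialDependence.MODERATE),
        (43.7, pg.SpatialDependence.MODERATE),
        (75.0, pg.SpatialDependence.MODERATE),
        (75.001, pg.SpatialDependence.WEAK),
        (100.0, pg.SpatialDependence.WEAK),
    ])
    def test_class_boundaries(self, ratio, expected):
        assert pg.classify_dependence(ratio) is expected

    def test_out_of_range_ratio(self):
        with pytest.raises(DomainError):
            pg.classify_dependence(101.0)

    def test_model_invariants(self):
        with pytest.raises(ValidationError):
            pg.VariogramModel("spherical", -0.1, 1.0, 10.0)
        with pytest.raises(ValidationError):
            pg.VariogramModel("spherical", 0.0, 0.0, 10.0)
        with pytest.raises(ValidationError):
            pg.VariogramModel("spherical", 1.0, 1.0, 0.0)
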