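import numpy as np
import pytest

import paddygeo as pg
from paddygeo.exceptions import DomainError, ValidationError
from conftest import random_scatter
from _oracles import variogram_form_ok_weights


def tiny_set(values, coords, code="T"):
    coords = np.asarray(coords, dtype=float)
    return pg.SampleSet(code, pg.Nutrient.NH4N, 0, 1, coords[:, 0],
                        coords[:, 1], np.asarray(values, dtype=float))


MODEL = pg.VariogramModel("spherical", 1.0, 8.0, 50.0)
NO_NUGGET = pg.VariogramModel("spherical", 0.0, 8.0, 50.0)


class TestOkPredict:
    def test_single_sample_returns_datum(self):
        s = tiny_set([7.3], [[10.0, 10.0]])
        value, variance, w = pg.ok_predict(s, MODEL, (99.0, -5.0))
        assert value == pytest.approx(7.3)
        assert w[0] == pytest.approx(1.0)
        assert variance >= 0

    def test_symmetric_pair_gets_equal_weights(self):
        s = tiny_set([4.0, 10.0], [[0.0, 0.0], [20.0, 0.0]])
        value, _, w = pg.ok_predict(s, MODEL, (10.0, 5.0))
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)
        assert value == pytest.approx(7.0)

    def test_zero_nugget_is_exact_interpolator(self):
        s = random_scatter(3, 8)
        for i in (0, 3, 7):
            value, variance, _ = pg.ok_predict(s, NO_NUGGET,
                                               (s.x[i], s.y[i]))
            assert value == pytest.approx(s.values[i], abs=1e-8)
            assert variance == pytest.approx(0.0, abs=1e-8)

    def test_weights_match_variogram_form_oracle(self):
        """Covariance-form solution equals an independently assembled
        variogram-form system, 5-point configurations."""
        for seed in range(20):
            s = random_scatter(seed, 5)
            target = np.random.default_rng(1000 + seed).uniform(0, 100, 2)
            _, _, w = pg.ok_predict(s, MODEL, target)
            w_oracle = variogram_form_ok_weights(
                s.coords, target, lambda h: pg.model_gamma(MODEL, h))
            assert np.allclose(w, w_oracle, atol=1e-10)

    def test_weights_sum_to_one(self):
        for seed in range(20):
            s = random_scatter(seed, 5 + seed % 10)
            target = np.random.default_rng(seed).uniform(-20, 120, 2)
            _, _, w = pg.ok_predict(s, MODEL, target)
            assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_linear_in_data(self):
        s = random_scatter(4, 10)
        target = (33.0, 41.0)
        v1, _, _ = pg.ok_predict(s, MODEL, target)
        s2 = s.replace_values(2.0 * s.values + 3.0)
        v2, _, _ = pg.ok_predict(s2, MODEL, target)
        assert v2 == pytest.approx(2.0 * v1 + 3.0, abs=1e-9)

    def test_variance_is_data_independent(self):
        s = random_scatter(6, 10)
        target = (15.0, 70.0)
        _, var1, _ = pg.ok_predict(s, MODEL, target)
        rng = np.random.default_rng(0)
        s2 = s.replace_values(rng.uniform(1, 50, s.n))
        _, var2, _ = pg.ok_predict(s2, MODEL, target)
        assert var1 == pytest.approx(var2, abs=1e-12)

    def test_nonfinite_target_rejected(self):
        s = random_scatter(2, 5)
        with pytest.raises(DomainError):
            pg.ok_predict(s, MODEL, (np.nan, 0.0))


class TestKrigeGrid:
    def test_matches_pointwise_prediction(self):
        s = random_scatter(8, 15)
        spec = pg.GridSpec(x0=0.0, y0=0.0, cell=20.0, nx=6, ny=6)
        grid = pg.krige_grid(s, MODEL, spec)
        centers = spec.cell_centers().reshape(6, 6, 2)
        rng = np.random.default_rng(1)
        for _ in range(20):
            i, j = rng.integers(0, 6, 2)
            value, variance, _ = pg.ok_predict(s, MODEL, centers[i, j])
            assert grid.values[i, j] == pytest.approx(value, abs=1e-9)
            assert grid.variances[i, j] == pytest.approx(variance, abs=1e-9)

    def test_constant_field_predicts_constant(self):
        coords = pg.generate_layout_coordinates(n_samples=20)
        s = tiny_set(np.full(20, 6.5), coords)
        grid = pg.krige_grid(s, MODEL, pg.grid_from_samples(s, cell=15.0))
        assert np.allclose(grid.values, 6.5, atol=1e-8)
        assert (grid.variances >= 0).all()

    def test_cell_containing_sample_is_exact_without_nugget(self):
        s = tiny_set([3.0, 9.0, 5.0, 7.0],
                     [[10.0, 10.0], [30.0, 10.0], [10.0, 30.0],
                      [30.0, 30.0]])
        spec = pg.GridSpec(x0=0.0, y0=0.0, cell=20.0, nx=2, ny=2)
        grid = pg.krige_grid(s, NO_NUGGET, spec)  # centers hit the samples
        assert np.allclose(grid.values, [[3.0, 9.0], [5.0, 7.0]], atol=1e-8)
        assert np.allclose(grid.variances, 0.0, atol=1e-8)


class TestAsciiGrid:
    def test_round_trip_is_bit_faithful(self, tmp_path):
        rng = np.random.default_rng(12)
        values = rng.normal(20, 4, (5, 7))
        values[2, 3] = np.nan
        grid = pg.KrigingGrid(x0=1.5, y0=-2.25, cell=5.0, nx=7, ny=5,
                              values=values, variances=np.zeros((5, 7)))
        p = tmp_path / "g.asc"
        pg.write_ascii_grid(grid, p)
        back = pg.read_ascii_grid(p)
        assert (back.x0, back.y0, back.cell) == (1.5, -2.25, 5.0)
        assert np.array_equal(back.values, grid.values, equal_nan=True)

    def test_single_cell_grid_layout(self, tmp_path):
        grid = pg.KrigingGrid(x0=0.0, y0=0.0, cell=1.0, nx=1, ny=1,
                              values=[[4.25]], variances=[[0.0]])
        p = tmp_path / "one.asc"
        pg.write_ascii_grid(grid, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 7  # 6 header lines + 1 data row
        assert lines[0].split() == ["ncols", "1"]
        assert float(lines[6]) == 4.25

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\nbogus\n1 2\n3 4\n5 6\n7 8\n")
        with pytest.raises(ValidationError):
            pg.read_ascii_grid(p)

    def test_grid_shape_validation(self):
        with pytest.raises(ValidationError):
            pg.KrigingGrid(x0=0, y0=0, cell=1.0, nx=3, ny=2,
                           values=np.zeros((3, 3)),
                           variances=np.zeros((2, 3)))
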