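"""Path-model estimation, Sobel test, and the factor x disease grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicage.mediation import (fit_paths, mediation_matrix, minmax_scale,
                               protein_mediator_variant, sobel_test)


class TestMinMax:
    def test_examples_and_idempotence(self):
        np.testing.assert_allclose(minmax_scale([0, 5, 10]), [0, 0.5, 1])
        v = np.array([0.0, 0.3, 1.0])
        np.testing.assert_allclose(minmax_scale(v), v)
        np.testing.assert_allclose(minmax_scale(minmax_scale(v)),
                                   minmax_scale(v))

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="bmi"):
            minmax_scale([2.0, 2.0, 2.0], name="bmi")


class TestFitPaths:
    def test_effect_decomposition_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=100)
            m = 0.4 * x + rng.normal(size=100)
            y = 0.3 * m - 0.2 * x + rng.normal(size=100)
            res = fit_paths(x, m, y)
            assert res.total == pytest.approx(res.c_prime + res.indirect,
                                              abs=1e-8)
            assert res.indirect == res.a * res.b

    def test_planted_full_mediation_recovered(self, rng):
        n = 5000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(scale=0.5, size=n)
        y = m.copy()     # Y depends on X only through M
        res = fit_paths(x, m, y)
        assert res.b == pytest.approx(1.0, abs=0.05)
        assert res.c_prime == pytest.approx(0.0, abs=0.05)
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.05)

    def test_coefficients_match_statsmodels_oracle(self, rng):
        # reference fit with an independent normal-equation solve
        x = rng.normal(size=200)
        m = 0.3 * x + rng.normal(size=200)
        y = 0.5 * m + 0.2 * x + rng.normal(size=200)
        res = fit_paths(x, m, y)
        X = np.column_stack([np.ones(200), x, m])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.c_prime == pytest.approx(beta[1], abs=1e-10)
        assert res.b == pytest.approx(beta[2], abs=1e-10)

    def test_a_path_p_uniform_under_null(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=80)
            m = rng.normal(size=80)
            z = None
            res = fit_paths(x, m, rng.normal(size=80))
            z_a = res.a / res.se_a
            pvals.append(2 * stats.norm.sf(abs(z_a)))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_mediator_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            fit_paths(x, x, rng.normal(size=50))

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_paths(rng.normal(size=10), rng.normal(size=10),
                      rng.normal(size=10))


class TestSobel:
    def test_arithmetic_example(self):
        # z = 0.2 / sqrt(0.16*0.01 + 0.25*0.01) = 3.1235...
        z, p = sobel_test(0.5, 0.1, 0.4, 0.1)
        assert z == pytest.approx(0.2 / np.sqrt(0.0041), abs=1e-6)
        assert p == pytest.approx(2 * stats.norm.sf(3.1235), abs=1e-4)

    def test_null_and_sign_symmetry(self):
        assert sobel_test(0.0, 0.1, 0.5, 0.1) == (0.0, 1.0)
        z1, p1 = sobel_test(0.5, 0.1, 0.4, 0.1)
        z2, p2 = sobel_test(-0.5, 0.1, 0.4, 0.1)
        assert z2 == pytest.approx(-z1) and p2 == pytest.approx(p1)

    def test_monotone_in_indirect_effect_magnitude(self):
        ps = [sobel_test(a, 0.1, 0.4, 0.1)[1] for a in (0.1, 0.3, 0.5)]
        assert ps[0] > ps[1] > ps[2]

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            sobel_test(0.5, 0.0, 0.4, 0.1)


class TestMatrix:
    def _data(self, rng, n=200):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        m = 0.5 * x1 + rng.normal(scale=0.5, size=n)
        d1 = (m + rng.normal(scale=0.5, size=n) > 0.5).astype(float)
        d2 = rng.integers(0, 2, n).astype(float)
        return pd.DataFrame({"f1": x1, "f2": x2, "med": m,
                             "d1": d1, "d2": d2})

    def test_grid_shape_and_flags(self, rng):
        data = self._data(rng)
        grid = mediation_matrix(data, ["f1", "f2"], "med", ["d1", "d2"])
        assert len(grid) == 4
        assert set(zip(grid["factor"], grid["disease"])) == {
            ("f1", "d1"), ("f1", "d2"), ("f2", "d1"), ("f2", "d2")}
        planted = grid[(grid["factor"] == "f1") & (grid["disease"] == "d1")]
        assert planted["sobel_p"].iloc[0] < 0.01

    def test_protein_variant_identical_for_same_mediator(self, rng):
        data = self._data(rng)
        g1 = mediation_matrix(data, ["f1"], "med", ["d1"])
        g2 = protein_mediator_variant(data, ["f1"], "med", ["d1"])
        pd.testing.assert_frame_equal(g1, g2)

    def test_inconsistent_mediation_flagged_not_clipped(self, rng):
        n = 500
        x = rng.normal(size=n)
        m = 0.8 * x + rng.normal(scale=0.3, size=n)
        y = 1.0 * m - 0.9 * x + rng.normal(scale=0.3, size=n)  # c near 0
        res = fit_paths(x, m, y)
        if res.proportion_mediated is not None:
            assert res.inconsistent == (
                not 0.0 <= res.proportion_mediated <= 1.0)
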