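"""Allometric power-law fitting: recovery, oracle equivalence, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatcc import AllometricModel, fit_allometric


def _normal_equations_loglog(x, y):
    """Independent oracle: closed-form OLS of ln y on ln x."""
    lx, ly = np.log(x), np.log(y)
    sxx = np.sum((lx - lx.mean()) ** 2)
    slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / sxx
    intercept = ly.mean() - slope * lx.mean()
    return np.exp(intercept), slope


class TestFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0.1, 0.9, 10)
        res = fit_allometric(x, 2.0 * x ** 1.5)
        assert res.a == pytest.approx(2.0, rel=1e-10)
        assert res.b == pytest.approx(1.5, rel=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.n == 10 and res.space == "log-linear"

    def test_identity_line(self):
        x = np.linspace(0.2, 2.0, 8)
        res = fit_allometric(x, x)
        assert res.a == pytest.approx(1.0, rel=1e-10)
        assert res.b == pytest.approx(1.0, rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0.1, 1.0, 60)
        y = 3.0 * x ** 1.2 * np.exp(rng.normal(0, 0.15, 60))
        res = fit_allometric(x, y)
        a_ref, b_ref = _normal_equations_loglog(x, y)
        assert res.a == pytest.approx(a_ref, rel=1e-12)
        assert res.b == pytest.approx(b_ref, rel=1e-12)

    def test_ci_brackets_estimate_and_is_asymmetric(self, rng):
        x = rng.uniform(0.1, 1.0, 40)
        y = 4.0 * x ** 1.8 * np.exp(rng.normal(0, 0.2, 40))
        res = fit_allometric(x, y)
        lo, hi = res.ci95_a
        assert lo < res.a < hi
        # back-transformed log CI: geometric, not arithmetic, symmetry
        assert hi - res.a != pytest.approx(res.a - lo, rel=1e-6)
        assert res.ci95_b[0] < res.b < res.ci95_b[1]

    def test_nonlinear_mode_converges_to_loglinear_as_noise_vanishes(self):
        x = np.linspace(0.1, 0.9, 30)
        y = 5.0 * x ** 1.6
        lin = fit_allometric(x, y, space="log-linear")
        nl = fit_allometric(x, y, space="nonlinear")
        assert nl.space == "nonlinear"
        assert nl.a == pytest.approx(lin.a, rel=1e-6)
        assert nl.b == pytest.approx(lin.b, rel=1e-6)

    def test_from_dataframe(self, noiseless_trial_config):
        import wheatcc

        df = wheatcc.generate_trial(noiseless_trial_config)
        sub = df[df["cultivar"] == "WM28"]
        res = AllometricModel.from_dataframe(sub, y="lai", x="cc").fit()
        assert res.a == pytest.approx(4.95, rel=1e-6)
        assert res.b == pytest.approx(1.36, rel=1e-6)


class TestValidation:
    def test_nonpositive_rows_identified(self):
        x = np.array([0.5, -1.0, 0.7, 0.0])
        with pytest.raises(ValueError, match=r"rows: 1, 3"):
            fit_allometric(x, np.ones(4))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_allometric([1, 2], [1, 2])

    def test_constant_x_is_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_allometric([0.5] * 5, [1, 2, 3, 4, 5])

    def test_predict_rejects_nonpositive(self):
        res = fit_allometric([0.1, 0.5, 0.9], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            res.predict(-1.0)


class TestProperties:
    @given(c=st.floats(0.1, 10.0), b=st.floats(-2.0, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c, b):
        # fitting (c*x, y) multiplies a by c**(-b), leaves b unchanged
        x = np.linspace(0.2, 1.0, 12)
        y = 2.0 * x ** b
        base = fit_allometric(x, y)
        scaled = fit_allometric(c * x, y)
        assert scaled.b == pytest.approx(base.b, rel=1e-8, abs=1e-10)
        assert scaled.a == pytest.approx(base.a * c ** (-base.b),
                                         rel=1e-8)

    def test_predict_examples(self):
        x = np.linspace(0.1, 1.0, 10)
        res = fit_allometric(x, 2.92 * x ** 1.04)
        assert res.predict(1.0) == pytest.approx(2.92, rel=1e-9)
        res2 = fit_allometric(x, 2.0 * x ** 3.0)
        assert res2.predict(2.0) == pytest.approx(16.0, rel=1e-9)

    def test_summary_mentions_estimates(self):
        res = fit_allometric(np.linspace(0.1, 1, 10),
                             2 * np.linspace(0.1, 1, 10) ** 1.5)
        text = res.summary()
        assert "a = 2" in text and "R^2" in text


class TestCoverage:
    def test_ci_coverage_near_nominal(self, rng):
        """t-based 95% CIs cover truth at about the nominal rate.

        Lognormal multiplicative noise is exactly Gaussian in log space,
        so coverage should sit near 0.95; 60 replicates gives a loose
        but cheap check (the full 200-replicate study runs in the
        acceptance suite).
        """
        a_true, b_true, n = 4.87, 1.92, 120
        sigma = np.sqrt(np.log1p(0.1 ** 2))
        hits_a = hits_b = 0
        reps = 60
        for _ in range(reps):
            x = rng.uniform(0.1, 0.9, n)
            y = a_true * x ** b_true * np.exp(rng.normal(0, sigma, n))
            res = fit_allometric(x, y)
            hits_a += res.ci95_a[0] <= a_true <= res.ci95_a[1]
            hits_b += res.ci95_b[0] <= b_true <= res.ci95_b[1]
        assert 0.85 <= hits_a / reps <= 1.0
        assert 0.85 <= hits_b / reps <= 1.0
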