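"""Truncated exponential family: closed forms vs independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from aadfe.truncexp import (
    ConvergenceError,
    ScaleMap,
    TruncExpModel,
    fit_lambda_from_mean,
    tail_probability,
    to_target_scale,
)

LAMBDAS = [-10.0, -5.0, -2.0, -1.0, -0.3, 0.0, 1e-8, 0.3, 1.0, 2.0, 5.0, 10.0]


def numeric_mean(lam):
    """Oracle: mean by quadrature of x * c * exp(-lam x)."""
    m = TruncExpModel(lam)
    return quad(lambda x: x * m.pdf(x), 0, 1, epsabs=1e-13)[0]


def numeric_variance(lam):
    m = TruncExpModel(lam)
    mu = numeric_mean(lam)
    return quad(lambda x: (x - mu) ** 2 * m.pdf(x), 0, 1, epsabs=1e-13)[0]


class TestDensity:
    def test_uniform_limit(self):
        assert TruncExpModel(0.0).pdf(0.3) == pytest.approx(1.0)

    def test_normalizing_constant_at_origin(self):
        # c = 1/(1 - e^-1) for lambda = 1
        assert TruncExpModel(1.0).pdf(0.0) == pytest.approx(1.0 / (1.0 - math.exp(-1.0)))

    @pytest.mark.parametrize("lam", [-5.0, -1.0, 0.0, 1.0, 5.0])
    def test_integrates_to_one(self, lam):
        m = TruncExpModel(lam)
        total = quad(m.pdf, 0, 1, epsabs=1e-12)[0]
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("lam,direction", [(2.0, -1), (-2.0, 1), (0.0, 0)])
    def test_monotone_in_x(self, lam, direction):
        m = TruncExpModel(lam)
        vals = m.pdf(np.linspace(0, 1, 50))
        d = np.diff(vals)
        if direction < 0:
            assert np.all(d < 0)
        elif direction > 0:
            assert np.all(d > 0)
        else:
            assert np.allclose(d, 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            TruncExpModel(1.0).pdf(1.5)


class TestCdf:
    @pytest.mark.parametrize("lam", LAMBDAS)
    def test_boundaries(self, lam):
        m = TruncExpModel(lam)
        assert m.cdf(0.0) == pytest.approx(0.0, abs=1e-15)
        assert m.cdf(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_limit(self):
        assert TruncExpModel(0.0).cdf(0.42) == pytest.approx(0.42)

    def test_round_trip(self):
        m = TruncExpModel(2.7)
        for x in np.linspace(0.0, 1.0, 21):
            assert m.ppf(m.cdf(x)) == pytest.approx(x, abs=1e-10)

    def test_domain_error(self):
        m = TruncExpModel(1.0)
        with pytest.raises(ValueError):
            m.cdf(-0.1)
        with pytest.raises(ValueError):
            m.ppf(1.2)


class TestMoments:
    def test_uniform_mean_and_variance(self):
        m = TruncExpModel(0.0)
        assert m.mean() == pytest.approx(0.5)
        assert m.variance() == pytest.approx(1.0 / 12.0)

    def test_mean_symmetry(self):
        assert TruncExpModel(3.1).mean() + TruncExpModel(-3.1).mean() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_variance_even(self):
        assert TruncExpModel(2.0).variance() == pytest.approx(
            TruncExpModel(-2.0).variance(), abs=1e-14
        )

    @pytest.mark.parametrize("lam", LAMBDAS)
    def test_mean_matches_quadrature(self, lam):
        assert TruncExpModel(lam).mean() == pytest.approx(numeric_mean(lam), abs=1e-8)

    @pytest.mark.parametrize("lam", LAMBDAS)
    def test_variance_matches_quadrature(self, lam):
        assert TruncExpModel(lam).variance() == pytest.approx(
            numeric_variance(lam), abs=1e-8
        )

    def test_mean_example(self):
        # frozen from the quadrature oracle at lambda = 1.23
        assert TruncExpModel(1.23).mean() == pytest.approx(numeric_mean(1.23), abs=1e-10)
        assert TruncExpModel(1.23).mean() == pytest.approx(0.400, abs=5e-4)

    def test_mean_variance_curve_peaks_at_uniform(self):
        lams = np.linspace(-6, 6, 61)
        mus = np.array([TruncExpModel(l).mean() for l in lams])
        sig = np.array([TruncExpModel(l).variance() for l in lams])
        assert sig.max() == pytest.approx(1.0 / 12.0)
        assert mus[np.argmax(sig)] == pytest.approx(0.5)
        # symmetric about mean 0.5: variance at mu and 1-mu coincide
        assert np.allclose(sig, sig[::-1], atol=1e-12)


class TestFitLambdaFromMean:
    def test_uniform(self):
        assert fit_lambda_from_mean(0.5).lambda_ == pytest.approx(0.0, abs=1e-9)

    def test_against_bisection_oracle(self):
        # independent oracle: bisect the quadrature-based mean function
        lam_oracle = brentq(lambda l: numeric_mean(l) - 0.400, -500, 500, xtol=1e-10)
        assert fit_lambda_from_mean(0.400).lambda_ == pytest.approx(lam_oracle, abs=1e-6)
        assert lam_oracle == pytest.approx(1.230, abs=1e-3)

    @pytest.mark.parametrize("mu", [0.22, 0.5, 0.71, 0.003, 0.997])
    def test_round_trip(self, mu):
        model = fit_lambda_from_mean(mu, tol=1e-12)
        assert model.mean() == pytest.approx(mu, abs=1e-10)

    def test_monotone_decreasing(self):
        lams = [fit_lambda_from_mean(mu).lambda_ for mu in (0.2, 0.4, 0.6, 0.8)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.2, 1.4])
    def test_domain_error(self, mu):
        with pytest.raises(ValueError):
            fit_lambda_from_mean(mu)

    def test_unrepresentable_mean(self):
        with pytest.raises(ConvergenceError):
            fit_lambda_from_mean(1e-9)


class TestTailProbability:
    def test_uniform(self):
        assert tail_probability(TruncExpModel(0.0), 0.9) == pytest.approx(0.1)

    @pytest.mark.parametrize("lam", [-3.0, 0.0, 3.0])
    def test_full_mass_at_zero(self, lam):
        assert tail_probability(TruncExpModel(lam), 0.0) == pytest.approx(1.0)

    def test_threefold_amplification(self):
        # a 0.4 vs 0.6 difference in means -> >3-fold difference in P(X > 0.9)
        hi = fit_lambda_from_mean(0.6)
        lo = fit_lambda_from_mean(0.4)
        ratio = tail_probability(hi, 0.9) / tail_probability(lo, 0.9)
        assert ratio > 3.0
        assert ratio == pytest.approx(3.0, abs=0.05)


class TestScaleMap:
    def test_identity_composition(self):
        m = TruncExpModel(1.5)
        s = ScaleMap.identity()
        for u in (0.1, 0.5, 0.9):
            assert to_target_scale(m, s, u) == pytest.approx(m.ppf(u))

    def test_uniform_passes_through(self):
        from scipy.stats import norm

        probs = np.linspace(0.001, 0.999, 99)
        s = ScaleMap.from_table(probs, norm.ppf(probs))
        m = TruncExpModel(0.0)
        for u in (0.1, 0.5, 0.9):
            assert to_target_scale(m, s, u) == pytest.approx(s(u))

    def test_composition_monotone(self):
        from scipy.stats import norm

        probs = np.linspace(0.001, 0.999, 99)
        s = ScaleMap.from_table(probs, norm.ppf(probs))
        m = TruncExpModel(1.5)
        vals = [to_target_scale(m, s, u) for u in np.linspace(0.01, 0.99, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            ScaleMap(lambda u: np.sin(6 * np.asarray(u)))
        with pytest.raises(ValueError):
            ScaleMap.from_table([0.0, 0.5, 1.0], [0.0, 2.0, 1.0])

    def test_from_tsv(self, tmp_path):
        p = tmp_path / "scale.tsv"
        p.write_text("0.0\t-5.0\n0.5\t0.0\n1.0\t5.0\n")
        s = ScaleMap.from_tsv(p)
        assert s(0.25) == pytest.approx(-2.5)


@pytest.mark.parametrize("lam", [-2.0, 0.0, 2.0])
def test_sampling_oracle(lam):
    """1e5 inverse-CDF draws reproduce analytic mean and variance to 3 SE."""
    m = TruncExpModel(lam)
    rng = np.random.default_rng(42)
    x = m.rvs(100_000, rng)
    n = x.size
    se_mean = math.sqrt(m.variance() / n)
    assert abs(x.mean() - m.mean()) < 3 * se_mean
    # SE of the sample variance via the fourth central moment
    m4 = quad(lambda t: (t - m.mean()) ** 4 * m.pdf(t), 0, 1)[0]
    se_var = math.sqrt((m4 - m.variance() ** 2) / n)
    assert abs(x.var(ddof=1) - m.variance()) < 3 * se_var


@settings(derandomize=True, max_examples=60)
@given(lam=st.floats(-30, 30), u=st.floats(0, 1))
def test_ppf_cdf_round_trip_property(lam, u):
    m = TruncExpModel(lam)
    assert m.cdf(m.ppf(u)) == pytest.approx(u, abs=1e-9)


@settings(derandomize=True, max_examples=60)
@given(mu=st.floats(0.01, 0.99))
def test_fit_is_inverse_of_mean_property(mu):
    assert fit_lambda_from_mean(mu).mean() == pytest.approx(mu, abs=1e-9)
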