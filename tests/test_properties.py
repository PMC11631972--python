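"""Tests for moments, shape measures, reliability, order statistics, entropy.

Oracles are independent of the closed forms they check: adaptive quadrature
against the density (or scipy's burr-III implementation), Monte-Carlo
simulation, and finite limits.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import beta as beta_fn
from scipy.special import betainc

import nesbr3 as nb
from nesbr3 import (
    DivergentMomentError,
    DomainError,
    EntropySpec,
    NesBr3Params,
    OrderStatSpec,
)
from nesbr3.properties import PDF_CONSISTENT, UPSCALED, UPSCALED_INVERSE_ARGS


def quad_moment(p: NesBr3Params, r: int) -> float:
    """Independent quadrature of x^r against the density on (0, inf)."""
    val, _ = integrate.quad(
        lambda t: (t / (1 - t)) ** r * nb.pdf(t / (1 - t), p) / (1 - t) ** 2,
        0.0,
        1.0,
        limit=400,
    )
    return val


class TestRawMoment:
    def test_direct_beta_identity(self):
        from scipy.special import gamma

        m = nb.raw_moment(1, NesBr3Params(1.0, 3.0))
        assert m.value == pytest.approx(gamma(2 / 3) * gamma(4 / 3) / gamma(2))
        assert m.beta_args == pytest.approx((1 - 1 / 3, 1 + 1 / 3))

    def test_matches_quadrature(self):
        p = NesBr3Params(2.0, 4.0, 0.0)
        m = nb.raw_moment(1, p, PDF_CONSISTENT)
        assert m.value == pytest.approx(quad_moment(p, 1), rel=1e-6)

    def test_matches_quadrature_with_indeterminacy(self):
        p = NesBr3Params(2.0, 4.0, 0.3)
        for r in (1, 2, 3):
            m = nb.raw_moment(r, p, PDF_CONSISTENT)
            assert m.value == pytest.approx(quad_moment(p, r), rel=1e-6)

    def test_convention_prefactors(self):
        lo = NesBr3Params(1.0, 1.5, 0.0)
        hi = NesBr3Params(1.0, 1.5, 0.3)
        # r=2 does not exist for theta=1.5, so check the prefactor at r=1
        a0 = nb.raw_moment(1, lo, UPSCALED).value
        assert nb.raw_moment(1, hi, UPSCALED).value == pytest.approx(1.3 * a0)
        assert nb.raw_moment(1, hi, PDF_CONSISTENT).value == pytest.approx(a0 / 1.3)

    def test_classical_textbook_form(self, param_grid):
        # at I = 0 both conventions equal lam * B(lam + r/theta, 1 - r/theta)
        for p in param_grid:
            if p.indet != 0 or p.theta <= 1:
                continue
            expected = p.lam * beta_fn(p.lam + 1 / p.theta, 1 - 1 / p.theta)
            assert nb.raw_moment(1, p).value == pytest.approx(expected, rel=1e-12)

    def test_divergence_signal(self):
        with pytest.raises(DivergentMomentError):
            nb.raw_moment(2, NesBr3Params(1.0, 1.5))
        with pytest.raises(DomainError):
            nb.raw_moment(0, NesBr3Params(1.0, 3.0))


class TestNegativeMoment:
    def test_direct_substitution(self):
        m = nb.negative_moment(1, NesBr3Params(2.0, 2.0))
        assert m.value == pytest.approx(2.0 * beta_fn(1.5, 1.5))

    def test_matches_quadrature(self):
        p = NesBr3Params(3.0, 2.0, 0.0)
        val, _ = integrate.quad(lambda x: nb.pdf(x, p) / x, 0, np.inf, limit=400)
        assert nb.negative_moment(1, p).value == pytest.approx(val, rel=1e-6)

    def test_scales_up_with_indeterminacy(self):
        crisp = nb.negative_moment(1, NesBr3Params(3.0, 2.0)).value
        shifted = nb.negative_moment(1, NesBr3Params(3.0, 2.0, 0.5)).value
        assert shifted == pytest.approx(1.5 * crisp)

    def test_divergence_signal(self):
        with pytest.raises(DivergentMomentError):
            nb.negative_moment(1, NesBr3Params(0.5, 1.0))  # lam - r/theta = -0.5


class TestMeanVariance:
    def test_mean_is_first_moment(self):
        p = NesBr3Params(1.0, 3.0)
        mean, _ = nb.mean_variance(p)
        assert mean == pytest.approx(nb.raw_moment(1, p).value)

    def test_variance_matches_quadrature(self):
        p = NesBr3Params(2.0, 5.0, 0.0)
        mean, var = nb.mean_variance(p)
        val, _ = integrate.quad(
            lambda x: (x - mean) ** 2 * nb.pdf(x, p), 0, np.inf, limit=400
        )
        assert var == pytest.approx(val, rel=1e-6)

    def test_inverse_args_variant_differs(self):
        p = NesBr3Params(2.0, 5.0, 0.0)
        mean_default, var_default = nb.mean_variance(p, PDF_CONSISTENT)
        mean_alt, var_alt = nb.mean_variance(p, UPSCALED_INVERSE_ARGS)
        assert mean_alt != pytest.approx(mean_default, rel=1e-3)
        assert var_alt != pytest.approx(var_default, rel=1e-3)


class TestSkewnessKurtosis:
    def test_symmetric_reference_density(self):
        # oracle sanity: moment-ratio formula on a symmetric density gives C1 = 0
        mu = [stats.norm(loc=3.0, scale=0.5).moment(r) for r in (1, 2, 3, 4)]
        var = mu[1] - mu[0] ** 2
        c1 = (mu[2] - 3 * mu[0] * mu[1] + 2 * mu[0] ** 3) / var**1.5
        assert c1 == pytest.approx(0.0, abs=1e-9)

    def test_matches_quadrature_ratios(self):
        p = NesBr3Params(2.0, 6.0, 0.0)
        sm = nb.skewness_kurtosis(p)
        mu = [quad_moment(p, r) for r in (1, 2, 3, 4)]
        var = mu[1] - mu[0] ** 2
        c1 = (mu[2] - 3 * mu[0] * mu[1] + 2 * mu[0] ** 3) / var**1.5
        c2 = (mu[3] - 4 * mu[0] * mu[2] + 6 * mu[1] * mu[0] ** 2 - 3 * mu[0] ** 4) / var**2
        assert sm.skewness == pytest.approx(c1, rel=1e-6)
        assert sm.kurtosis == pytest.approx(c2, rel=1e-6)

    def test_invariant_under_indeterminacy(self):
        a = nb.skewness_kurtosis(NesBr3Params(2.0, 6.0, 0.0))
        b = nb.skewness_kurtosis(NesBr3Params(2.0, 6.0, 0.4))
        assert a.skewness == pytest.approx(b.skewness, rel=1e-12)
        assert a.kurtosis == pytest.approx(b.kurtosis, rel=1e-12)

    def test_divergence_signal(self):
        with pytest.raises(DivergentMomentError):
            nb.skewness_kurtosis(NesBr3Params(2.0, 3.5))


class TestStressStrength:
    def test_symmetry(self):
        assert nb.stress_strength(3.0, 3.0, 2.0) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self):
        lam1, lam2, theta = 2.0, 1.0, 3.0
        n = 1_000_000
        rng = np.random.default_rng(11)
        x1 = nb.rvs(n, NesBr3Params(lam1, theta, 0.0), rng)
        x2 = nb.rvs(n, NesBr3Params(lam2, theta, 0.0), rng)
        phat = np.mean(x2 < x1)
        se = math.sqrt(phat * (1 - phat) / n)
        assert nb.stress_strength(lam1, lam2, theta) == pytest.approx(2 / 3)
        assert abs(phat - 2 / 3) < 3 * se

    def test_independent_of_indeterminacy_and_theta(self):
        r0 = nb.stress_strength(2.0, 1.0, 3.0, indet=0.0)
        assert nb.stress_strength(2.0, 1.0, 3.0, indet=0.5) == r0
        assert nb.stress_strength(2.0, 1.0, 0.7, indet=0.0) == r0

    def test_bounds(self):
        for lam1, lam2 in [(0.1, 9.0), (5.0, 0.01), (1.0, 1.0)]:
            r = nb.stress_strength(lam1, lam2, 2.0)
            assert 0.0 < r < 1.0


class TestOrderStatistics:
    def test_reduces_to_pdf(self):
        p = NesBr3Params(2.0, 3.0, 0.05)
        spec = OrderStatSpec(j=1, n=1)
        x = np.geomspace(0.1, 10, 30)
        np.testing.assert_allclose(
            nb.order_statistic_pdf(x, spec, p), nb.pdf(x, p), rtol=1e-12
        )

    def test_normalization(self):
        p = NesBr3Params(2.0, 3.0, 0.0)
        spec = OrderStatSpec(j=2, n=3)
        val, _ = integrate.quad(
            lambda t: nb.order_statistic_pdf(t / (1 - t), spec, p) / (1 - t) ** 2,
            0,
            1,
            limit=400,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_median_density_against_simulation(self):
        # KS of 200k simulated sample medians (n=5) against the implied CDF
        p = NesBr3Params(2.0, 3.0, 0.0)
        rng = np.random.default_rng(5)
        draws = nb.rvs(200_000 * 5, p, rng).reshape(200_000, 5)
        medians = np.median(draws, axis=1)
        cdf_med = lambda x: betainc(3, 3, nb.cdf(x, p))  # noqa: E731
        d = stats.kstest(medians, cdf_med).statistic
        assert d < 1.628 / math.sqrt(200_000)

    def test_moment_reduces_to_raw_moment(self):
        p = NesBr3Params(2.0, 4.0, 0.1)
        spec = OrderStatSpec(j=1, n=1, r=1)
        assert nb.order_statistic_moment(spec, p) == pytest.approx(
            nb.raw_moment(1, p, PDF_CONSISTENT).value, rel=1e-6
        )

    def test_median_moment_against_simulation(self):
        p = NesBr3Params(2.0, 4.0, 0.0)
        rng = np.random.default_rng(17)
        draws = nb.rvs(200_000 * 5, p, rng).reshape(200_000, 5)
        medians = np.median(draws, axis=1)
        target = nb.order_statistic_moment(OrderStatSpec(j=3, n=5, r=1), p)
        mc_se = medians.std(ddof=1) / math.sqrt(medians.size)
        assert abs(medians.mean() - target) < 3 * mc_se

    def test_stochastic_ordering(self):
        p = NesBr3Params(2.0, 4.0, 0.0)
        means = [
            nb.order_statistic_moment(OrderStatSpec(j=j, n=3, r=1), p) for j in (1, 2, 3)
        ]
        assert means[0] < means[1] < means[2]

    def test_series_variant_flags_indeterminacy(self):
        p = NesBr3Params(2.0, 4.0, 0.05)
        spec = OrderStatSpec(j=2, n=3, r=1)
        with pytest.warns(RuntimeWarning):
            series = nb.order_statistic_moment(spec, p, method="series")
        assert series != pytest.approx(nb.order_statistic_moment(spec, p), rel=1e-3)

    def test_series_variant_matches_at_crisp(self):
        p = NesBr3Params(2.0, 4.0, 0.0)
        spec = OrderStatSpec(j=2, n=3, r=1)
        assert nb.order_statistic_moment(spec, p, method="series") == pytest.approx(
            nb.order_statistic_moment(spec, p), rel=1e-6
        )

    def test_invalid_rank(self):
        with pytest.raises(DomainError):
            OrderStatSpec(j=4, n=3)


class TestRenyiEntropy:
    def test_shannon_limit(self):
        p = NesBr3Params(2.0, 3.0, 0.0)
        shannon, _ = integrate.quad(
            lambda x: -nb.pdf(x, p) * nb.log_pdf(x, p), 0, np.inf, limit=400
        )
        near = np.mean(
            [
                nb.renyi_entropy(EntropySpec(1 + 1e-4), p),
                nb.renyi_entropy(EntropySpec(1 - 1e-4), p),
            ]
        )
        assert near == pytest.approx(shannon, abs=1e-3)

    def test_scale_shift_under_indeterminacy(self):
        spec = EntropySpec(2.0)
        h0 = nb.renyi_entropy(spec, NesBr3Params(2.0, 3.0, 0.0))
        h1 = nb.renyi_entropy(spec, NesBr3Params(2.0, 3.0, 0.4))
        assert h1 - h0 == pytest.approx(-math.log(1.4), abs=1e-7)

    def test_dual_quadrature_oracle(self):
        # same integral, different integration scheme (direct infinite-range
        # Gauss-Kronrod, no change of variables)
        p = NesBr3Params(2.0, 3.0, 0.0)
        val, _ = integrate.quad(lambda x: nb.pdf(x, p) ** 2, 0, np.inf, limit=400)
        direct = math.log(val) / (1 - 2.0)
        assert nb.renyi_entropy(EntropySpec(2.0), p) == pytest.approx(direct, abs=1e-6)

    def test_closed_form_matches_numeric(self, param_grid):
        spec = EntropySpec(2.0)
        for p in param_grid:
            try:
                closed = nb.renyi_entropy(spec, p, method="closed_form")
            except DivergentMomentError:
                continue
            assert closed == pytest.approx(
                nb.renyi_entropy(spec, p, method="numeric"), abs=1e-6
            ), p

    def test_legacy_variant_flagged(self):
        p = NesBr3Params(2.0, 3.0, 0.0)
        with pytest.warns(RuntimeWarning):
            legacy = nb.renyi_entropy(EntropySpec(2.0), p, method="legacy")
        assert legacy != pytest.approx(nb.renyi_entropy(EntropySpec(2.0), p), abs=1e-3)

    def test_bad_order(self):
        with pytest.raises(DomainError):
            EntropySpec(1.0)
        with pytest.raises(DomainError):
            EntropySpec(-2.0)


class TestPropertyTable:
    def test_layout_and_export(self, tmp_path):
        grid = [NesBr3Params(2.0, 6.0, i) for i in (0.0, 0.05)]
        table = nb.property_table(grid)
        assert list(table.columns) == [
            "lam", "theta", "indet", "mu1", "mu2", "mu3", "mu4", "V", "C1", "C2",
        ]
        assert len(table) == 2
        out = tmp_path / "props.csv"
        table.to_csv(out, index=False)
        import pandas as pd

        back = pd.read_csv(out)
        assert back.shape == table.shape

    def test_divergent_cells_are_nan(self):
        table = nb.property_table([NesBr3Params(1.0, 1.5, 0.0)])
        assert np.isnan(table.loc[0, "mu2"]) and np.isnan(table.loc[0, "C2"])
        assert np.isfinite(table.loc[0, "mu1"])


def test_quadrature_agreement_over_grid(param_grid):
    """Closed forms agree with quadrature to 1e-6 where theta > r + 1."""
    checked = 0
    for p in param_grid:
        for r in (1, 2):
            if p.theta <= r + 1:
                continue
            m = nb.raw_moment(r, p, PDF_CONSISTENT)
            assert m.value == pytest.approx(quad_moment(p, r), rel=1e-6), (p, r)
            checked += 1
    assert checked >= 20
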