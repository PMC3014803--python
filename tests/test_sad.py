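"""SAD likelihoods, profiles, ML fits and AIC selection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize, special, stats

from commstruct.sad import (
    LogSeries,
    RankProfile,
    aic,
    brokenstick_expected_props,
    fishers_alpha,
    fit_brokenstick,
    fit_logseries,
    fit_lognormal,
    fit_preemption,
    logseries_logpmf,
    logseries_mean,
    logseries_x_for_mean,
    multinomial_rank_logL,
    poisson_lognormal_logpmf,
    preemption_expected_props,
)
from commstruct.selection import FitSummary, select_model


class TestLogSeriesPmf:
    def test_closed_form_n1(self):
        assert logseries_logpmf(1, 0.5) == pytest.approx(math.log(0.5 / math.log(2)),
                                                         abs=1e-12)

    def test_matches_scipy_logser(self):
        n = np.arange(1, 50)
        for x in (0.1, 0.5, 0.9, 0.99):
            assert np.allclose(logseries_logpmf(n, x), stats.logser.logpmf(n, x),
                               atol=1e-12)

    def test_normalizes(self):
        n = np.arange(1, 10**6)
        assert np.exp(logseries_logpmf(n, 0.9)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_matches_brute_force_sum(self):
        n = np.arange(1, 10**6)
        brute = (n * np.exp(logseries_logpmf(n, 0.8))).sum()
        assert logseries_mean(0.8) == pytest.approx(brute, abs=1e-9)

    def test_mean_inversion(self):
        for m in (1.5, 6.34, 166.7):
            assert logseries_mean(logseries_x_for_mean(m)) == pytest.approx(m,
                                                                            rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            logseries_logpmf(3, bad)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            logseries_logpmf(0, 0.5)


class TestRankProfiles:
    def test_preemption_closed_form(self):
        p = preemption_expected_props(2, 0.5).expected_props
        assert np.allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_preemption_single_species(self):
        assert preemption_expected_props(1, 0.7).expected_props[0] == pytest.approx(1.0)

    def test_preemption_grid_nonincreasing_and_normalized(self):
        for S in np.linspace(2, 400, 50).astype(int):
            for k in np.linspace(0.01, 0.99, 50):
                p = preemption_expected_props(int(S), k).expected_props
                assert np.all(np.diff(p) <= 1e-15)
                assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_brokenstick_closed_forms(self):
        assert brokenstick_expected_props(1).expected_props[0] == pytest.approx(1.0)
        assert np.allclose(brokenstick_expected_props(2).expected_props,
                           [0.75, 0.25], atol=1e-12)

    def test_brokenstick_sums_to_one_up_to_500(self):
        for S in range(1, 501):
            assert brokenstick_expected_props(S).expected_props.sum() == \
                pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            preemption_expected_props(0, 0.5)
        with pytest.raises(ValueError):
            preemption_expected_props(5, 1.0)
        with pytest.raises(ValueError):
            brokenstick_expected_props(0)


class TestMultinomialBridge:
    def test_hand_computed_value(self):
        prof = RankProfile(2, np.array([0.75, 0.25]))
        assert multinomial_rank_logL([3, 1], prof) == pytest.approx(
            math.log(4 * 0.75**3 * 0.25), abs=1e-12)

    def test_single_rank_is_certain(self):
        assert multinomial_rank_logL([5], RankProfile(1, np.array([1.0]))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            multinomial_rank_logL([3, 2, 1], RankProfile(2, np.array([0.75, 0.25])))

    def test_profile_matching_counts_maximizes(self):
        counts = np.array([40, 30, 20, 10])
        best = None
        for k in np.linspace(0.05, 0.95, 50):
            ll = multinomial_rank_logL(counts, preemption_expected_props(4, k))
            best = max(best, ll) if best is not None else ll
        exact = multinomial_rank_logL(
            counts, RankProfile(4, counts / counts.sum()))
        assert exact >= best


class TestPoissonLognormal:
    def test_sigma_to_zero_limit_is_truncated_poisson(self):
        mu, lam = math.log(5), 5.0
        n = np.arange(1, 20)
        pl = np.exp(poisson_lognormal_logpmf(n, mu, 1e-4))
        tp = stats.poisson.pmf(n, lam) / (1 - stats.poisson.pmf(0, lam))
        assert np.abs(pl - tp).max() < 1e-4

    def test_normalizes(self):
        n = np.arange(1, 2001)
        assert np.exp(poisson_lognormal_logpmf(n, 1.0, 1.0)).sum() == \
            pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n,mu,sigma", [(3, 0.5, 0.8), (1, 1.0, 1.0),
                                            (100, 2.0, 1.5), (7, -3.0, 0.5)])
    def test_matches_adaptive_quadrature(self, n, mu, sigma):
        # independent oracle: adaptive quadrature around the integrand mode
        g = lambda z: n - math.exp(z) - (z - mu) / sigma**2
        zm = optimize.brentq(g, -60, 60)

        def logf(z):
            return (n * z - math.exp(z) - special.gammaln(n + 1)
                    - (z - mu) ** 2 / (2 * sigma**2)
                    - 0.5 * math.log(2 * math.pi * sigma**2))

        fm = logf(zm)
        val, _ = integrate.quad(lambda z: math.exp(logf(z) - fm),
                                zm - 30, zm + 30, limit=400)
        oracle_log_mass = fm + math.log(val)
        p0g = lambda z: -math.exp(z) - (z - mu) / sigma**2
        zm0 = optimize.brentq(p0g, -60, 60)
        f0 = lambda z: (-math.exp(z) - (z - mu) ** 2 / (2 * sigma**2)
                        - 0.5 * math.log(2 * math.pi * sigma**2))
        v0, _ = integrate.quad(lambda z: math.exp(f0(z) - f0(zm0)),
                               zm0 - 30, zm0 + 30, limit=400)
        log_p0 = f0(zm0) + math.log(v0)
        oracle = oracle_log_mass - math.log1p(-math.exp(log_p0))
        assert poisson_lognormal_logpmf(n, mu, sigma) == pytest.approx(
            oracle, abs=1e-8)

    def test_sigma_domain(self):
        with pytest.raises(ValueError):
            poisson_lognormal_logpmf(3, 0.0, -1.0)


class TestFits:
    def test_logseries_all_singletons_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            f = fit_logseries([1, 1, 1, 1])
        assert f.params["x"] < 1e-6

    def test_logseries_recovery_from_direct_pmf_draws(self):
        rng = np.random.default_rng(11)
        c = np.sort(stats.logser.rvs(0.97, size=200, random_state=rng))[::-1]
        f = fit_logseries(c)
        se = f.bse["x"]
        assert abs(f.params["x"] - 0.97) < 1.96 * se * 1.5 + 0.005
        assert f.derived["fishers_alpha"] == pytest.approx(
            fishers_alpha(200, f.params["x"]))

    def test_logseries_optimum_dominates_grid(self):
        rng = np.random.default_rng(5)
        c = np.sort(stats.logser.rvs(0.9, size=60, random_state=rng))[::-1]
        m = LogSeries(c)
        f = m.fit()
        grid = [m.loglike([x]) for x in np.linspace(0.01, 0.999, 100)]
        assert f.llf >= max(grid) - 1e-9

    def test_preemption_recovery(self):
        rng = np.random.default_rng(3)
        prof = preemption_expected_props(20, 0.3).expected_props
        c = np.sort(rng.multinomial(10**4, prof))[::-1]
        c = c[c > 0]
        f = fit_preemption(c)
        assert 0.28 < f.params["k"] < 0.32

    def test_preemption_geometric_counts_give_half(self):
        f = fit_preemption(np.array([64, 32, 16, 8, 4, 2, 1]) * 3)
        assert f.params["k"] == pytest.approx(0.5, abs=1e-3)

    def test_brokenstick_single_species(self):
        f = fit_brokenstick([9])
        assert f.llf == pytest.approx(0.0, abs=1e-12)
        assert f.aic == pytest.approx(0.0, abs=1e-12)

    def test_brokenstick_data_prefers_brokenstick_over_preemption(self):
        rng = np.random.default_rng(4)
        prof = brokenstick_expected_props(4).expected_props
        c = np.sort(rng.multinomial(4000, prof))[::-1]
        fb, fp = fit_brokenstick(c), fit_preemption(c)
        assert fb.aic < fp.aic  # 0-parameter model wins on its own data

    def test_brokenstick_aic_ordering_scale_invariant(self):
        rng = np.random.default_rng(9)
        prof = brokenstick_expected_props(10).expected_props
        c = np.sort(rng.multinomial(2000, prof))[::-1]
        c = c[c > 0]
        order1 = fit_brokenstick(c).aic < fit_preemption(c).aic
        order2 = fit_brokenstick(c * 10).aic < fit_preemption(c * 10).aic
        assert order1 == order2

    def test_lognormal_recovery(self):
        rng = np.random.default_rng(8)
        lam = np.exp(rng.normal(2.0, 1.2, 300))
        c = rng.poisson(lam)
        c = np.sort(c[c > 0])[::-1]
        f = fit_lognormal(c)
        assert abs(f.params["mu"] - 2.0) < 0.25
        assert abs(f.params["sigma"] - 1.2) < 0.25

    def test_lognormal_optimum_dominates_grid(self):
        rng = np.random.default_rng(2)
        lam = np.exp(rng.normal(1.0, 0.8, 60))
        c = rng.poisson(lam)
        c = np.sort(c[c > 0])[::-1]
        from commstruct.sad import PoissonLognormal

        m = PoissonLognormal(c)
        f = m.fit()
        grid = max(
            m.loglike([mu, s])
            for mu in np.linspace(-1, 3, 40)
            for s in np.linspace(0.05, 3, 40)
        )
        assert f.llf >= grid - 1e-9

    def test_lognormal_needs_three_counts(self):
        with pytest.raises(ValueError, match="S >= 3"):
            fit_lognormal([5, 3])

    def test_lognormal_equal_counts_sigma_floor(self):
        with pytest.warns(UserWarning, match="sigma"):
            f = fit_lognormal([7, 7, 7, 7, 7])
        assert f.params["sigma"] <= 1.1e-4

    def test_aic_invariant_identity(self):
        for f in (fit_logseries([8, 4, 2, 1, 1]),
                  fit_preemption([8, 4, 2, 1, 1]),
                  fit_brokenstick([8, 4, 2, 1, 1]),
                  fit_lognormal([8, 4, 2, 1, 1])):
            assert f.aic == pytest.approx(2 * f.k_params - 2 * f.llf, abs=1e-9)


class TestAIC:
    def test_arithmetic(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-65.0, 2) == 134.0

    def test_fewer_params_win_at_equal_likelihood(self):
        assert aic(-10.0, 0) < aic(-10.0, 1) < aic(-10.0, 2)

    def test_negative_param_count_rejected(self):
        with pytest.raises(ValueError):
            aic(-1.0, -1)


class TestSelectModel:
    def test_printed_aic_pair_is_equivalent(self):
        r = select_model([FitSummary("logseries", 41.318),
                          FitSummary("lognormal", 39.72)], delta_threshold=2.0)
        assert r.best == "lognormal"
        assert r.equivalent == (True, True)
        assert r.delta_aics[1] == pytest.approx(1.598, abs=1e-9)

    def test_clear_winner_not_equivalent_to_rest(self):
        r = select_model([FitSummary("logseries", 202.231),
                          FitSummary("lognormal", 250.0),
                          FitSummary("preemption", 300.0),
                          FitSummary("brokenstick", 310.0)])
        assert r.best == "logseries"
        assert r.equivalent == (True, False, False, False)

    def test_exact_tie_keeps_input_order(self):
        r = select_model([FitSummary("a", 100.0), FitSummary("b", 100.0)])
        assert r.names == ("a", "b") and r.equivalent == (True, True)

    def test_differing_data_lengths_rejected(self):
        with pytest.raises(ValueError, match="differing"):
            select_model([FitSummary("a", 10.0, nobs=5),
                          FitSummary("b", 12.0, nobs=7)])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=6, unique=True))
    def test_ranking_sorted_and_best_flagged(self, aics):
        fits = [FitSummary(f"m{i}", a) for i, a in enumerate(aics)]
        r = select_model(fits)
        assert list(r.aics) == sorted(aics)
        assert r.equivalent[0] is True or r.equivalent[0] == True  # noqa: E712
        assert r.delta_aics[0] == 0.0
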