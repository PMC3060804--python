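import numpy as np
import pytest
from scipy import stats

from sppgof import pvalues as P
from sppgof.discrepancy import get_discrepancy
from sppgof.exact import spp_exact_sup_deviation
from sppgof.models import (BetaPrior, BoundaryMLEError, DiracPrior,
                           GammaPrior, ThetaValue)


class TestCountExtremes:
    @pytest.mark.parametrize("d_obs, reps, u, expected", [
        (1.0, [2.0, 2.0, 0.0], 0.5, 2.0),
        (1.0, [1.0, 1.0], 0.5, 1.0),
        (5.0, [1.0, 2.0], 0.9, 0.0),
    ])
    def test_examples(self, d_obs, reps, u, expected):
        a, k = P.count_extremes(d_obs, np.array(reps), u)
        assert a == pytest.approx(expected)
        assert k == len(reps)

    def test_monotone_in_observed_discrepancy(self, rng):
        reps = rng.normal(size=200)
        a_vals = [P.count_extremes(d, reps, 0.3)[0]
                  for d in np.linspace(-3, 3, 25)]
        assert all(a1 >= a2 for a1, a2 in zip(a_vals, a_vals[1:]))

    def test_near_ties_use_relative_tolerance(self):
        d = 1.0
        reps = np.array([1.0 + 1e-15, 1.0 + 1e-9])
        a, _ = P.count_extremes(d, reps, 0.0)
        assert a == 1.0  # only the clearly-greater one counts

    def test_pairwise_vector_observed(self):
        a, k = P.count_extremes(np.array([0.0, 2.0]), np.array([1.0, 1.0]), 0.0)
        assert (a, k) == (1.0, 2)


class TestBetaDraw:
    def test_no_information_is_uniform(self, rng):
        draws = np.array([P.beta_draw_pvalue(0, 0, rng) for _ in range(2000)])
        assert stats.kstest(draws, "uniform").pvalue > 1e-3

    def test_mean_at_half(self, rng):
        draws = rng.beta(51, 51, size=20000)  # Beta(a*+1, K-a*+1), a*=50, K=100
        assert draws.mean() == pytest.approx(0.5, abs=3 * 0.05 / np.sqrt(20000))

    def test_all_extreme_mean(self, rng):
        draws = np.array([P.beta_draw_pvalue(5000, 5000, rng) for _ in range(2000)])
        assert draws.mean() == pytest.approx(5001 / 5002, abs=1e-3)
        assert np.all((draws > 0) & (draws < 1))

    def test_all_ties_recovers_tie_u(self, rng):
        # constant discrepancy: every replicate ties, a* = u*K
        for u in (0.1, 0.3, 0.8):
            a, k = P.count_extremes(2.0, np.full(5000, 2.0), u)
            draws = [P.beta_draw_pvalue(a, k, rng) for _ in range(200)]
            assert np.mean(draws) == pytest.approx(u, abs=0.02)

    def test_bounds_checked(self, rng):
        with pytest.raises(ValueError):
            P.beta_draw_pvalue(11, 10, rng)


class TestEngineContracts:
    def test_result_invariants_and_determinism(self, rng):
        x = rng.poisson(1.0, 30)
        res1 = P.gof_pvalue("spp", GammaPrior(2, 2), x,
                            get_discrepancy("variance"), K=200, seed=42)
        res2 = P.gof_pvalue("spp", GammaPrior(2, 2), x,
                            get_discrepancy("variance"), K=200, seed=42)
        assert res1 == res2
        assert 0 < res1.p < 1
        assert 0 <= res1.n_greater + res1.n_equal <= res1.K
        assert res1.seed == 42

    @pytest.mark.parametrize("engine", P.ENGINES)
    def test_every_engine_runs_on_poisson(self, engine, rng):
        x = rng.poisson(2.0, 25)
        disc = get_discrepancy("variance", "normalized") \
            if engine == "nspp" else get_discrepancy("variance")
        res = P.gof_pvalue(engine, GammaPrior(2, 1), x, disc, K=100, rng=rng)
        assert 0 < res.p < 1
        assert res.engine == engine

    def test_per_replicate_marker(self, rng):
        res = P.gof_pvalue("ppost", GammaPrior(2, 1), rng.poisson(1.0, 20),
                           get_discrepancy("meanc"), K=50, rng=rng)
        assert res.theta_used == "per-replicate"

    def test_naive_estimator_is_count_ratio(self, rng):
        res = P.gof_pvalue("spp", GammaPrior(2, 1), rng.poisson(1.0, 20),
                           get_discrepancy("mean"), K=100, rng=rng,
                           estimator="naive")
        assert res.p == pytest.approx((res.n_greater + res.n_equal) / res.K)

    def test_multi_shares_theta(self, rng):
        res = P.gof_pvalue_multi("spp", GammaPrior(2, 1), rng.poisson(1.0, 20),
                                 [get_discrepancy("mean"),
                                  get_discrepancy("variance")], K=50, rng=rng)
        assert res[0].theta_used == res[1].theta_used

    def test_dirac_prior_rejected_for_bayes_engines(self, rng):
        with pytest.raises(ValueError, match="Dirac"):
            P.gof_pvalue("spp", DiracPrior(ThetaValue.poisson(1.0)), [1, 2],
                         get_discrepancy("mean"), K=10, rng=rng)

    def test_nspp_requires_normalized_scale(self, rng):
        with pytest.raises(ValueError, match="normalized"):
            P.gof_pvalue("nspp", GammaPrior(2, 1), [1, 2],
                         get_discrepancy("mean"), K=10, rng=rng)

    def test_plugml_boundary_mle_errors(self, rng):
        with pytest.raises(BoundaryMLEError):
            P.gof_pvalue("plugml", GammaPrior(2, 1), [0, 0, 0],
                         get_discrepancy("mean"), K=10, rng=rng)

    def test_halfml_redraws_boundary_subsets(self, rng):
        # data with many zeros: some half-samples are all-zero, but an
        # interior half-sample exists and must eventually be found
        x = np.array([0.0] * 18 + [1.0, 2.0])
        res = P.gof_pvalue("halfml", GammaPrior(2, 1), x,
                           get_discrepancy("mean"), K=50, rng=rng)
        assert 0 < res.p < 1


class TestUniformity:
    def test_exact_enumeration_small_bernoulli(self):
        """Matched Beta(1,1) prior, mean discrepancy: exactly uniform."""
        for n in (1, 2, 3):
            assert spp_exact_sup_deviation(n, BetaPrior(1, 1)) < 0.01

    def test_spp_uniform_small_n_simulation(self):
        """Matched priors: SPP uniform even at n=5 (simulation check)."""
        master = np.random.SeedSequence(0)
        ps = []
        for child in master.spawn(800):
            r = np.random.default_rng(child)
            lam = r.gamma(2.0) / 2.0
            x = r.poisson(lam, 5)
            ps.append(P.gof_pvalue("spp", GammaPrior(2, 2), x,
                                   get_discrepancy("variance"), K=300,
                                   rng=r).p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_nspp_pivotal_at_n20(self):
        """NSPP is uniform at n=20, not just asymptotically."""
        master = np.random.SeedSequence(1)
        ps = []
        for child in master.spawn(800):
            r = np.random.default_rng(child)
            lam = r.gamma(2.0) / 2.0
            x = r.poisson(lam, 20)
            ps.append(P.gof_pvalue("nspp", GammaPrior(2, 2), x,
                                   get_discrepancy("skewness"), K=300,
                                   rng=r).p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestQuantileBand:
    def test_median_and_support(self, rng):
        x = rng.poisson(1.0, 30)
        q, ps = P.spp_quantile_band(GammaPrior(2, 1), x,
                                    get_discrepancy("variance"), K=100, M=11,
                                    q=0.5, rng=rng)
        assert q == pytest.approx(np.median(ps))
        assert ps.size == 11
        assert np.all((ps > 0) & (ps < 1))

    def test_m_lower_bound(self, rng):
        with pytest.raises(ValueError):
            P.spp_quantile_band(GammaPrior(2, 1), [1, 2],
                                get_discrepancy("mean"), M=1, rng=rng)
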