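import numpy as np
import pytest
from scipy import stats

from sppgof import models as M
from sppgof.models import (BetaPrior, BoundaryMLEError, DiracPrior,
                           GammaPrior, NormalInvGammaPrior, ThetaValue)


class TestConjugacy:
    @pytest.mark.parametrize("prior, x, expected", [
        (GammaPrior(2, 1), [1, 2], GammaPrior(5, 3)),
        (BetaPrior(1, 1), [1, 0, 1], BetaPrior(3, 2)),
        (GammaPrior(0.5, 2), [0, 0, 0], GammaPrior(0.5, 5)),
    ])
    def test_closed_form_updates(self, prior, x, expected):
        post = M.posterior_update(prior, x)
        assert type(post) is type(prior)
        assert post == expected

    def test_normal_inverse_gamma_update(self):
        # hand computation: n=2, xbar=2, ss=2
        post = M.posterior_update(NormalInvGammaPrior(0.0, 1.0, 2.0, 1.0), [1, 3])
        assert post.kappa0 == 3.0
        assert post.mu0 == pytest.approx(4.0 / 3.0)
        assert post.a0 == 3.0
        assert post.b0 == pytest.approx(1.0 + 1.0 + 2.0 * 4.0 / 6.0)

    def test_empty_data_returns_prior(self):
        prior = GammaPrior(2, 1)
        assert M.posterior_update(prior, np.array([])) is prior

    @pytest.mark.parametrize("prior, x", [
        (GammaPrior(2.5, 0.5), [3, 0, 1, 4, 2, 2]),
        (BetaPrior(0.7, 1.3), [1, 0, 0, 1, 1, 0]),
        (NormalInvGammaPrior(0.3, 2.0, 3.0, 2.0), [0.1, -1.2, 0.7, 2.3, 0.0, -0.4]),
    ])
    def test_sequential_update_equals_joint(self, prior, x):
        x = np.asarray(x, dtype=float)
        joint = M.posterior_update(prior, x)
        seq = M.posterior_update(M.posterior_update(prior, x[:3]), x[3:])
        for f, v in joint.__dict__.items():
            assert seq.__dict__[f] == pytest.approx(v, rel=1e-12)

    def test_dirac_prior_has_no_posterior(self):
        with pytest.raises(ValueError, match="Dirac"):
            M.posterior_update(DiracPrior(ThetaValue.poisson(2.0)), [1, 2])

    def test_family_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.posterior_update(BetaPrior(1, 1), [0, 3, 1])  # not 0/1 data


class TestSampling:
    def test_dirac_sampling_is_point_mass(self, rng):
        spec = DiracPrior(ThetaValue.poisson(2.0))
        assert all(M.sample_theta(spec, rng).lam == 2.0 for _ in range(5))

    def test_gamma_prior_mean(self, rng):
        draws = np.array([M.sample_theta(GammaPrior(3, 2), rng).lam
                          for _ in range(20000)])
        se = np.sqrt(3 / 4) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.5) < 3 * se

    def test_beta_prior_support(self, rng):
        th = M.sample_theta_matrix(BetaPrior(3, 2), 1000, rng)[0]
        assert np.all((th > 0) & (th < 1))

    def test_nig_prior_var_mean(self, rng):
        # E[sigma^2] = b0/(a0-1) = 2
        _, var = M.sample_theta_matrix(NormalInvGammaPrior(0, 1, 3, 4), 40000, rng)
        assert var.mean() == pytest.approx(2.0, rel=0.05)

    def test_degenerate_bernoulli_data(self, rng):
        x = M.sample_data("bernoulli", ThetaValue.bernoulli(1.0), 5, rng)
        assert np.array_equal(x, np.ones(5))

    def test_poisson_boundary_rate_rejected(self):
        with pytest.raises(ValueError):
            ThetaValue.poisson(0.0)

    def test_normal_sample_mean_lln(self, rng):
        x = M.sample_data("normal", ThetaValue.normal(0, 1), 100000, rng)
        assert abs(x.mean()) < 3 / np.sqrt(x.size)


class TestMLE:
    def test_poisson_full_and_subset(self):
        assert M.mle("poisson", [1, 2, 3]).theta.lam == pytest.approx(2.0)
        r = M.mle("poisson", [1, 3, 2, 4], subset=[0, 3])
        assert r.theta.lam == pytest.approx(2.5)
        assert not r.boundary

    def test_bernoulli_proportion_and_boundary_flag(self):
        assert M.mle("bernoulli", [1, 1, 0, 0]).theta.p == pytest.approx(0.5)
        assert M.mle("bernoulli", [1, 1, 1]).boundary
        assert M.mle("poisson", [0, 0]).boundary

    def test_normal_variance_denominator_is_m(self):
        r = M.mle("normal", [0.0, 2.0])
        assert r.theta.mu == pytest.approx(1.0)
        assert r.theta.var == pytest.approx(1.0)  # ((1)^2+(1)^2)/2

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            M.mle("poisson", [1, 2], subset=[])

    def test_half_sample_indices(self, rng):
        idx = M.half_sample_indices(9, rng)
        assert idx.size == 4 and np.unique(idx).size == 4


class TestRandomizedCDF:
    def test_normal_symmetry(self):
        th = ThetaValue.normal(0, 1)
        for u in (0.0, 0.5, 1.0):
            assert M.cdf_randomized("normal", th, 0.0, u) == pytest.approx(0.5)

    def test_poisson_atom_interpolation(self):
        th = ThetaValue.poisson(1.0)
        assert M.cdf_randomized("poisson", th, 0, 0.5) == pytest.approx(
            0.5 * np.exp(-1), rel=1e-12)
        assert M.cdf_randomized("poisson", th, 0, 1.0) == pytest.approx(
            np.exp(-1), rel=1e-12)

    def test_strictly_increasing_in_u_on_atoms(self):
        th = ThetaValue.poisson(2.0)
        vals = [M.cdf_randomized("poisson", th, 3, u) for u in (0.1, 0.5, 0.9)]
        assert vals[0] < vals[1] < vals[2]

    @pytest.mark.parametrize("family, theta", [
        ("poisson", ThetaValue.poisson(1.3)),
        ("bernoulli", ThetaValue.bernoulli(0.37)),
        ("normal", ThetaValue.normal(0.5, 2.0)),
    ])
    def test_pit_is_exactly_uniform(self, family, theta, rng):
        n = 100000
        x = M.sample_data(family, theta, n, rng)
        u = rng.random(n)
        c = M.cdf_randomized(family, theta, x, u)
        assert stats.kstest(c, "uniform").pvalue > 1e-3

    def test_invalid_u_rejected(self):
        with pytest.raises(ValueError):
            M.cdf_randomized("poisson", ThetaValue.poisson(1.0), 0, 1.5)


@pytest.mark.parametrize("family, theta, expected", [
    ("poisson", ThetaValue.poisson(2.0), (2.0, 2.0)),
    ("bernoulli", ThetaValue.bernoulli(0.5), (0.5, 0.25)),
    ("normal", ThetaValue.normal(1.0, 4.0), (1.0, 4.0)),
])
def test_model_moments(family, theta, expected):
    m, v = M.model_moments(family, theta)
    assert (float(m), float(v)) == pytest.approx(expected)


class TestFreqThetaDraw:
    def test_draws_positive_and_centered(self, rng):
        x = rng.poisson(2.0, 50)
        draws = np.log([M.freq_theta_draw("poisson", x, rng).lam
                        for _ in range(20000)])
        assert np.all(np.isfinite(draws))
        se = 1.0 / np.sqrt(x.sum())
        assert abs(draws.mean() - np.log(x.mean())) < 3 * se / np.sqrt(draws.size) + 1e-9

    def test_zero_sum_is_boundary_error(self, rng):
        with pytest.raises(BoundaryMLEError):
            M.freq_theta_draw("poisson", [0, 0, 0], rng)

    def test_other_families_unsupported(self, rng):
        with pytest.raises(ValueError):
            M.freq_theta_draw("bernoulli", [0, 1], rng)


class TestIO:
    @pytest.mark.parametrize("prior", [
        GammaPrior(2, 1), BetaPrior(0.5, 3),
        NormalInvGammaPrior(0.1, 2, 3, 4),
        DiracPrior(ThetaValue.normal(1.0, 2.0)),
    ])
    def test_model_json_roundtrip(self, prior):
        assert M.model_from_json(prior.to_json()) == prior

    def test_dataset_csv_roundtrip(self, tmp_path):
        x = np.array([1.0, 0.0, 3.0])
        path = tmp_path / "d.csv"
        M.write_dataset_csv(path, x)
        assert np.array_equal(M.read_dataset_csv(path), x)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            M.validate_dataset("bernoulli", [0, 2])
        with pytest.raises(ValueError):
            M.validate_dataset("poisson", [1.5])
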