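"""Goodness-of-fit p-value engines.

All engines share the same skeleton: a reference scheme proposes parameter
values and replicate datasets, a discrepancy d is evaluated on the observed
and replicated data, and the p-value estimates

    p = Pr( d(X, theta) >= d(x_obs, theta) )

with ties between observed and replicated discrepancies randomized by a
single uniform draw (the "ventilated" p-value, exact for discrete-valued
discrepancies).  Rather than the classical count/K estimate, the Monte
Carlo estimate is one draw from Beta(a*+1, K-a*+1) -- the posterior of the
underlying p under a uniform prior after observing a* "more extreme"
outcomes among K -- which keeps the pooled distribution of estimated
p-values faithful to the distribution of the exact p-value even for small
K.

Engines
-------
spp
    Sampled posterior p-value: all K replicates are simulated at a single
    parameter value drawn from the posterior.  Uniform under a matched
    proper prior for every discrepancy; asymptotically uniform otherwise.
nspp
    SPP on normalized data (randomized PIT + normal quantile), making the
    statistic pivotal: exactly uniform at any n under a matched prior.
ppost
    Posterior predictive: a fresh posterior draw per replicate, observed
    and replicated discrepancies compared pairwise.  Conservative for
    statistics whose mean depends on theta.
plugml
    Parametric bootstrap at the full-data MLE.
halfml
    Parametric bootstrap at the MLE of a random floor(n/2) half-sample.
prior
    Prior predictive: parameter drawn from the prior per replicate.
freqspp
    SPP with the posterior draw replaced by a frequentist draw of
    log(lambda) from its asymptotic normal distribution (Poisson only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .discrepancy import DiscrepancySpec, discrepancy_rows, normalize
from .models import (BoundaryMLEError, PriorSpec, ThetaValue, as_rng,
                     posterior_update, sample_theta)

ENGINES = ("spp", "nspp", "ppost", "plugml", "halfml", "prior", "freqspp")

_SINGLE_THETA = ("spp", "nspp", "plugml", "halfml", "freqspp")
_PER_REPLICATE = ("ppost", "prior")

#: relative tolerance declaring two float discrepancies tied
TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PValueResult:
    """One GOF p-value with its Monte Carlo bookkeeping."""

    p: float
    engine: str
    statistic: str
    input_scale: str
    n_greater: float
    n_equal: int
    K: int
    theta_used: ThetaValue | str
    tie_u: float
    seed: int | None = None

    def to_json(self) -> dict:
        th = self.theta_used
        if isinstance(th, ThetaValue):
            th = {k: v for k, v in th.__dict__.items() if v is not None}
        return {
            "p": self.p, "engine": self.engine, "statistic": self.statistic,
            "input_scale": self.input_scale, "n_greater": self.n_greater,
            "n_equal": self.n_equal, "K": self.K, "theta_used": th,
            "tie_u": self.tie_u, "seed": self.seed,
        }


def _tally(d_obs, d_reps, tie_u: float) -> tuple[float, float, int, int]:
    """(a*, n_greater, n_equal, K) for the ventilated comparison."""
    if not 0.0 <= tie_u <= 1.0:
        raise ValueError("tie_u must lie in [0, 1]")
    reps = np.atleast_1d(np.asarray(d_reps))
    obs = np.asarray(d_obs)
    if reps.dtype.kind in "iu" and obs.dtype.kind in "iu":
        tied = reps == obs
    else:
        reps = reps.astype(float)
        obs = obs.astype(float)
        tied = np.isclose(reps, obs, rtol=TIE_RTOL, atol=0.0)
    greater = (reps > obs) & ~tied
    n_eq = int(tied.sum())
    n_gt = float(greater.sum())
    return n_gt + tie_u * n_eq, n_gt, n_eq, int(reps.size)


def count_extremes(d_obs, d_reps, tie_u: float) -> tuple[float, int]:
    """a* = #{d_rep > d_obs} + tie_u * #{d_rep = d_obs}.

    Equality is exact for integer-valued statistics and within relative
    tolerance ``TIE_RTOL`` otherwise.  ``d_obs`` may be a scalar (single
    reference parameter) or a length-K vector (pairwise comparison for the
    predictive engines).  Returns (a*, K).
    """
    a_star, _, _, k = _tally(d_obs, d_reps, tie_u)
    return a_star, k


def beta_draw_pvalue(a_star: float, K: int, rng) -> float:
    """One draw from Beta(a*+1, K-a*+1), the posterior of the underlying p.

    Never returns exactly 0 or 1; expectation (a*+1)/(K+2).
    """
    if not 0.0 <= a_star <= K:
        raise ValueError("need 0 <= a_star <= K")
    return float(as_rng(rng).beta(a_star + 1.0, K - a_star + 1.0))


def _check_prior_for_engine(engine: str, prior: PriorSpec) -> None:
    if engine in ("spp", "nspp", "ppost", "prior") and prior.is_dirac:
        raise ValueError(f"{engine} needs a proper (non-Dirac) prior")


def _single_theta(engine: str, prior: PriorSpec, x: np.ndarray, rng) -> ThetaValue:
    family = prior.family
    if engine in ("spp", "nspp"):
        return sample_theta(posterior_update(prior, x), rng)
    if engine == "freqspp":
        return models.freq_theta_draw(family, x, rng)
    if engine == "plugml":
        r = models.mle(family, x)
        if r.boundary:
            raise BoundaryMLEError(
                "full-data MLE on the parameter-space boundary; "
                "use a Bayesian engine (spp/nspp/ppost)")
        return r.theta
    if engine == "halfml":
        full = models.mle(family, x)
        if full.boundary:
            raise BoundaryMLEError(
                "data admit only a boundary MLE; use a Bayesian engine")
        # a random half-sample may hit the boundary even when the full data
        # do not; redraw the subset rather than abort
        for _ in range(1000):
            idx = models.half_sample_indices(x.size, rng)
            r = models.mle(family, x, subset=idx)
            if not r.boundary:
                return r.theta
        raise BoundaryMLEError("could not find an interior half-sample MLE")
    raise ValueError(f"unknown engine {engine!r}")


def _validate_discs(engine: str, discs: list[DiscrepancySpec]) -> None:
    if engine == "nspp":
        bad = [d.label for d in discs if d.input_scale != "normalized"]
        if bad:
            raise ValueError(f"nspp requires normalized-scale statistics: {bad}")


def gof_pvalue_multi(
    engine: str,
    model: PriorSpec,
    x_obs,
    discs: list[DiscrepancySpec] | tuple[DiscrepancySpec, ...],
    K: int = 5000,
    rng=None,
    seed: int | None = None,
    estimator: str = "beta",
    u_obs: np.ndarray | None = None,
) -> list[PValueResult]:
    """Several discrepancies on one dataset, sharing theta and replicates.

    This is the batch workhorse: the reference parameter(s) and the K
    replicate datasets are drawn once and every requested discrepancy is
    evaluated on them, exactly as if each p-value had been computed alone
    (the marginal law of each result is unchanged; only the Monte Carlo
    noise is shared).

    ``estimator`` is "beta" (default, the Beta(a*+1, K-a*+1) draw) or
    "naive" (classical count{d_rep >= d_obs}/K, kept for the estimator
    -contrast diagnostic).
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; known: {ENGINES}")
    if K < 1:
        raise ValueError("K must be >= 1")
    if estimator not in ("beta", "naive"):
        raise ValueError("estimator must be 'beta' or 'naive'")
    rng = as_rng(rng if rng is not None else seed)
    discs = [d if isinstance(d, DiscrepancySpec) else DiscrepancySpec(*d)
             for d in discs]
    _validate_discs(engine, discs)
    _check_prior_for_engine(engine, model)
    family = model.family
    x = models.as_data(x_obs)
    n = x.size

    raw = [d for d in discs if d.input_scale == "raw"]
    norm = [d for d in discs if d.input_scale == "normalized"]
    need_u = bool(norm)

    out: dict[str, tuple] = {}

    if engine in _SINGLE_THETA:
        theta = _single_theta(engine, model, x, rng)
        th = models.theta_arrays(theta)
        if raw:
            reps = models.sample_data_matrix(family, th, (K, n), rng)
            for d in raw:
                d_o = discrepancy_rows(d, x, th, family)
                d_r = discrepancy_rows(d, reps, th, family)
                out[d.label] = (float(d_o), d_r, theta)
        if norm:
            u = rng.random(n) if u_obs is None else np.asarray(u_obs, float)
            y_obs = normalize(family, th, x, u)
            # replicates drawn at theta and normalized with theta are exact
            # i.i.d. N(0,1); simulate them directly
            y_reps = rng.standard_normal((K, n))
            for d in norm:
                d_o = discrepancy_rows(d, y_obs, th, family)
                d_r = discrepancy_rows(d, y_reps, th, family)
                out[d.label] = (float(d_o), d_r, theta)
    else:  # ppost, prior
        source = posterior_update(model, x) if engine == "ppost" else model
        th_k = models.sample_theta_matrix(source, K, rng)
        marker = "per-replicate"
        if raw:
            reps = models.sample_data_matrix(family, th_k, (K, n), rng)
            for d in raw:
                d_o = discrepancy_rows(d, x[None, :], th_k, family)
                d_o = np.broadcast_to(np.atleast_1d(d_o), (K,))
                d_r = discrepancy_rows(d, reps, th_k, family)
                out[d.label] = (d_o, d_r, marker)
        if norm:
            u = rng.random(n) if u_obs is None else np.asarray(u_obs, float)
            bth = tuple(v[:, None] for v in th_k)
            y_obs = normalize(family, bth, x[None, :], u[None, :])
            y_reps = rng.standard_normal((K, n))
            for d in norm:
                d_o = discrepancy_rows(d, y_obs, th_k, family)
                d_r = discrepancy_rows(d, y_reps, th_k, family)
                out[d.label] = (d_o, d_r, marker)

    results = []
    for d in discs:
        d_o, d_r, th_used = out[d.label]
        tie_u = float(rng.random())
        a_star, n_gt, n_eq, k = _tally(d_o, d_r, tie_u)
        if estimator == "beta":
            p = beta_draw_pvalue(a_star, k, rng)
        else:
            p = (n_gt + n_eq) / k
        results.append(PValueResult(
            p=p, engine=engine, statistic=d.name, input_scale=d.input_scale,
            n_greater=n_gt, n_equal=n_eq, K=k, theta_used=th_used,
            tie_u=tie_u, seed=seed))
    return results


def gof_pvalue(
    engine: str,
    model: PriorSpec,
    x_obs,
    disc: DiscrepancySpec,
    K: int = 5000,
    rng=None,
    seed: int | None = None,
    estimator: str = "beta",
) -> PValueResult:
    """One GOF p-value for one dataset, engine and discrepancy."""
    return gof_pvalue_multi(engine, model, x_obs, [disc], K=K, rng=rng,
                            seed=seed, estimator=estimator)[0]


def spp_quantile_band(
    model: PriorSpec,
    x_obs,
    disc: DiscrepancySpec,
    K: int = 5000,
    M: int = 20,
    q: float = 0.5,
    rng=None,
) -> tuple[float, np.ndarray]:
    """Empirical q-quantile of M independent-theta SPPs on one dataset.

    The SPP is random even for fixed data (a fresh posterior draw each
    time); reporting a quantile of M repetitions stabilizes the report.
    The observation-normalizing uniforms are drawn once and reused across
    the M draws so repetitions differ only through theta, which makes the
    procedure reproducible across analysts sharing the same u-vector.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    rng = as_rng(rng)
    x = models.as_data(x_obs)
    u_obs = rng.random(x.size) if disc.input_scale == "normalized" else None
    engine = "nspp" if disc.input_scale == "normalized" else "spp"
    ps = np.array([
        gof_pvalue_multi(engine, model, x, [disc], K=K, rng=rng,
                         u_obs=u_obs)[0].p
        for _ in range(M)
    ])
    return float(np.quantile(ps, q)), ps
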