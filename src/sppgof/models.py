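"""Conjugate model families shared by every p-value engine.

Three i.i.d. likelihood families are supported, each with its conjugate
prior so that posterior distributions are available in closed form:

* ``poisson``   -- rate lambda with a Gamma(shape, rate) prior;
* ``bernoulli`` -- success probability p with a Beta(a, b) prior;
* ``normal``    -- (mu, sigma^2) with a normal-inverse-gamma prior,
  sigma^2 ~ InvGamma(a0, b0) and mu | sigma^2 ~ Normal(mu0, sigma^2/kappa0).

A Dirac (point-mass) "prior" is also provided; it is only meaningful as a
data-generating law, never as an analysis prior.

Besides the priors, the module provides the primitives every engine needs:
posterior updates, prior/posterior sampling, data simulation, (subset)
maximum-likelihood estimation, the randomized CDF used by the probability
integral transform for discrete families, model moments, and a frequentist
log-scale parameter draw for the Poisson family.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import ClassVar, Sequence

import numpy as np
from scipy import special, stats

FAMILIES = ("poisson", "bernoulli", "normal")


class FamilyMismatchError(ValueError):
    """Prior/data/theta families do not agree."""


class BoundaryMLEError(ValueError):
    """The MLE sits on the boundary of the parameter space."""


# ---------------------------------------------------------------------------
# parameter points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThetaValue:
    """One point of a family's parameter space.

    Only the fields relevant to ``family`` are set: ``lam`` for Poisson,
    ``p`` for Bernoulli, ``mu``/``var`` for Normal.
    """

    family: str
    lam: float | None = None
    p: float | None = None
    mu: float | None = None
    var: float | None = None

    def __post_init__(self) -> None:
        if self.family == "poisson":
            if self.lam is None or not self.lam > 0:
                raise ValueError("poisson rate lambda must be > 0")
        elif self.family == "bernoulli":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("bernoulli p must lie in [0, 1]")
        elif self.family == "normal":
            if self.mu is None or self.var is None or not self.var > 0:
                raise ValueError("normal theta needs mu and var > 0")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def poisson(cls, lam: float) -> "ThetaValue":
        return cls("poisson", lam=float(lam))

    @classmethod
    def bernoulli(cls, p: float) -> "ThetaValue":
        return cls("bernoulli", p=float(p))

    @classmethod
    def normal(cls, mu: float, var: float) -> "ThetaValue":
        return cls("normal", mu=float(mu), var=float(var))

    def params(self) -> tuple[float, ...]:
        """Parameter tuple in the canonical order used internally."""
        if self.family == "poisson":
            return (self.lam,)
        if self.family == "bernoulli":
            return (self.p,)
        return (self.mu, self.var)


@dataclass(frozen=True)
class Dataset:
    """A vector of i.i.d. observations, optionally tagged with provenance.

    ``provenance`` records the ThetaValue or PriorSpec the data were
    generated from (None for user data).
    """

    x: np.ndarray
    provenance: object | None = None

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.x, dtype=float))
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("dataset must be a non-empty 1-d vector")
        object.__setattr__(self, "x", arr)

    @property
    def n(self) -> int:
        return int(self.x.size)


def as_data(data) -> np.ndarray:
    """Accept a Dataset, array-like or sequence; return a 1-d float array."""
    x = data.x if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    x = np.atleast_1d(x)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("data must be a non-empty 1-d vector")
    return x


def validate_dataset(family: str, data) -> np.ndarray:
    """Check support constraints (counts / binary entries) for a family."""
    x = as_data(data)
    if family == "poisson":
        if np.any(x < 0) or np.any(x != np.floor(x)):
            raise ValueError("poisson data must be nonnegative integers")
    elif family == "bernoulli":
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError("bernoulli data must be 0/1")
    elif family != "normal":
        raise ValueError(f"unknown family {family!r}")
    return x


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Base class for conjugate prior specifications."""

    family: ClassVar[str] = ""
    is_dirac: ClassVar[bool] = False

    def mean_theta(self) -> ThetaValue:  # pragma: no cover - abstract
        raise NotImplementedError

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return {"family": self.family, "prior": d}


@dataclass(frozen=True)
class GammaPrior(PriorSpec):
    """Gamma(shape, rate) prior on the Poisson rate."""

    shape: float
    rate: float
    family: ClassVar[str] = "poisson"

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma shape and rate must be > 0")

    def mean_theta(self) -> ThetaValue:
        return ThetaValue.poisson(self.shape / self.rate)

    def mean_var(self) -> tuple[float, float]:
        return self.shape / self.rate, self.shape / self.rate**2


@dataclass(frozen=True)
class BetaPrior(PriorSpec):
    """Beta(a, b) prior on the Bernoulli success probability."""

    a: float
    b: float
    family: ClassVar[str] = "bernoulli"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta shapes must be > 0")

    def mean_theta(self) -> ThetaValue:
        return ThetaValue.bernoulli(self.a / (self.a + self.b))

    def mean_var(self) -> tuple[float, float]:
        s = self.a + self.b
        m = self.a / s
        return m, m * (1 - m) / (s + 1)


@dataclass(frozen=True)
class NormalInvGammaPrior(PriorSpec):
    """Normal-inverse-gamma prior on (mu, sigma^2).

    sigma^2 ~ InvGamma(a0, b0), mu | sigma^2 ~ Normal(mu0, sigma^2/kappa0).
    """

    mu0: float
    kappa0: float
    a0: float
    b0: float
    family: ClassVar[str] = "normal"

    def __post_init__(self) -> None:
        if not (self.kappa0 > 0 and self.a0 > 0 and self.b0 > 0):
            raise ValueError("kappa0, a0, b0 must be > 0")

    def mean_theta(self) -> ThetaValue:
        if self.a0 <= 1:
            raise ValueError("prior mean of sigma^2 undefined for a0 <= 1")
        return ThetaValue.normal(self.mu0, self.b0 / (self.a0 - 1))

    def mu_marginal_sd(self) -> float:
        """Marginal prior standard deviation of mu (finite for a0 > 1)."""
        if self.a0 <= 1:
            raise ValueError("marginal sd of mu undefined for a0 <= 1")
        return math.sqrt(self.b0 / (self.kappa0 * (self.a0 - 1)))


@dataclass(frozen=True)
class DiracPrior(PriorSpec):
    """Point mass at a fixed parameter value (data-generating use only)."""

    theta: ThetaValue
    is_dirac: ClassVar[bool] = True

    @property
    def family(self) -> str:  # type: ignore[override]
        return self.theta.family

    def mean_theta(self) -> ThetaValue:
        return self.theta

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "prior": {"dirac": True, "theta": dataclasses.asdict(self.theta)},
        }


def model_from_json(obj: dict) -> PriorSpec:
    """Inverse of ``PriorSpec.to_json``."""
    family = obj["family"]
    prior = dict(obj["prior"])
    if prior.pop("dirac", False):
        th = {k: v for k, v in prior["theta"].items() if v is not None}
        return DiracPrior(ThetaValue(**th))
    cls = {"poisson": GammaPrior, "bernoulli": BetaPrior,
           "normal": NormalInvGammaPrior}[family]
    return cls(**prior)


# ---------------------------------------------------------------------------
# conjugate updating and sampling
# ---------------------------------------------------------------------------


def posterior_update(prior: PriorSpec, data) -> PriorSpec:
    """Closed-form conjugate posterior given i.i.d. data.

    Empty data returns the prior unchanged.  Dirac priors have no posterior
    here and raise.
    """
    if prior.is_dirac:
        raise ValueError("posterior undefined for a Dirac prior")
    x = np.asarray(getattr(data, "x", data), dtype=float)
    x = np.atleast_1d(x)
    n = x.size
    if n == 0:
        return prior
    x = validate_dataset(prior.family, x) if prior.family != "normal" else x
    if isinstance(prior, GammaPrior):
        return GammaPrior(prior.shape + float(x.sum()), prior.rate + n)
    if isinstance(prior, BetaPrior):
        s = float(x.sum())
        return BetaPrior(prior.a + s, prior.b + n - s)
    if isinstance(prior, NormalInvGammaPrior):
        xbar = float(x.mean())
        ss = float(((x - xbar) ** 2).sum())
        kn = prior.kappa0 + n
        mun = (prior.kappa0 * prior.mu0 + n * xbar) / kn
        an = prior.a0 + n / 2.0
        bn = prior.b0 + 0.5 * ss + prior.kappa0 * n * (xbar - prior.mu0) ** 2 / (2.0 * kn)
        return NormalInvGammaPrior(mun, kn, an, bn)
    raise FamilyMismatchError(f"unsupported prior {type(prior).__name__}")


def as_rng(rng) -> np.random.Generator:
    """Coerce None / int / SeedSequence / Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_theta(spec: PriorSpec, rng) -> ThetaValue:
    """One draw from a prior (or posterior) specification."""
    rng = as_rng(rng)
    if isinstance(spec, DiracPrior):
        return spec.theta
    tiny = np.finfo(float).tiny
    if isinstance(spec, GammaPrior):
        # tiny shapes make the variate underflow to 0.0; clamp to stay in
        # the open parameter space
        return ThetaValue.poisson(max(rng.gamma(spec.shape), tiny) / spec.rate)
    if isinstance(spec, BetaPrior):
        return ThetaValue.bernoulli(rng.beta(spec.a, spec.b))
    if isinstance(spec, NormalInvGammaPrior):
        var = spec.b0 / max(rng.gamma(spec.a0), tiny)
        if not np.isfinite(var):
            var = np.finfo(float).max / 4.0
        mu = rng.normal(spec.mu0, math.sqrt(var / spec.kappa0))
        return ThetaValue.normal(mu, var)
    raise FamilyMismatchError(f"unsupported prior {type(spec).__name__}")


def sample_theta_matrix(spec: PriorSpec, size: int, rng) -> tuple[np.ndarray, ...]:
    """``size`` i.i.d. prior/posterior draws as canonical parameter arrays."""
    rng = as_rng(rng)
    if isinstance(spec, DiracPrior):
        return tuple(np.full(size, v) for v in spec.theta.params())
    tiny = np.finfo(float).tiny
    if isinstance(spec, GammaPrior):
        g = np.maximum(rng.gamma(spec.shape, size=size), tiny)
        return (g / spec.rate,)
    if isinstance(spec, BetaPrior):
        return (rng.beta(spec.a, spec.b, size=size),)
    if isinstance(spec, NormalInvGammaPrior):
        var = spec.b0 / np.maximum(rng.gamma(spec.a0, size=size), tiny)
        var = np.minimum(var, np.finfo(float).max / 4.0)
        mu = rng.normal(spec.mu0, np.sqrt(var / spec.kappa0))
        return (mu, var)
    raise FamilyMismatchError(f"unsupported prior {type(spec).__name__}")


def theta_arrays(theta: ThetaValue) -> tuple[np.ndarray, ...]:
    """Canonical parameter tuple of scalars (broadcastable) for a theta."""
    return tuple(np.asarray(v, dtype=float) for v in theta.params())


def sample_data(family: str, theta: ThetaValue, n: int, rng) -> np.ndarray:
    """n i.i.d. draws from f(.|theta)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta.family != family:
        raise FamilyMismatchError(f"theta family {theta.family} != {family}")
    return sample_data_matrix(family, theta_arrays(theta), (int(n),), as_rng(rng))


def sample_data_matrix(family: str, th: tuple[np.ndarray, ...], shape, rng) -> np.ndarray:
    """Array of model draws; per-row parameters broadcast against ``shape``."""
    th = tuple(np.asarray(v, dtype=float) for v in th)
    bth = tuple(v[:, None] if v.ndim == 1 and len(shape) == 2 else v for v in th)
    if family == "poisson":
        return rng.poisson(np.broadcast_to(bth[0], shape)).astype(float)
    if family == "bernoulli":
        return (rng.random(shape) < bth[0]).astype(float)
    if family == "normal":
        mu, var = bth
        return rng.normal(0.0, 1.0, size=shape) * np.sqrt(var) + mu
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# estimation, CDFs and moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLEResult:
    """MLE together with a boundary flag callers must handle."""

    theta: ThetaValue
    boundary: bool


def mle(family: str, data, subset: Sequence[int] | np.ndarray | None = None) -> MLEResult:
    """Maximum-likelihood estimate, optionally on an index subset.

    Poisson: subset mean. Bernoulli: subset proportion. Normal: (mean,
    variance with denominator m).  Poisson mean 0 and Bernoulli proportions
    in {0,1} are boundary MLEs: the value is returned flagged, because a
    random half-sample may legitimately hit the boundary.
    """
    x = as_data(data)
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be non-empty")
        x = x[idx]
    m = x.size
    if family == "poisson":
        lam = float(x.mean())
        if lam <= 0:
            # lam=0 is outside the open parameter space; keep a usable object
            return MLEResult(ThetaValue("poisson", lam=np.nextafter(0, 1)), True)
        return MLEResult(ThetaValue.poisson(lam), False)
    if family == "bernoulli":
        p = float(x.mean())
        return MLEResult(ThetaValue.bernoulli(p), p in (0.0, 1.0))
    if family == "normal":
        if m < 2:
            raise ValueError("normal MLE needs at least 2 observations")
        mu = float(x.mean())
        var = float(((x - mu) ** 2).mean())
        if var <= 0:
            return MLEResult(ThetaValue.normal(mu, np.nextafter(0, 1)), True)
        return MLEResult(ThetaValue.normal(mu, var), False)
    raise ValueError(f"unknown family {family!r}")


def half_sample_indices(n: int, rng) -> np.ndarray:
    """A uniformly random floor(n/2)-subset of {0..n-1}, without replacement."""
    if n < 2:
        raise ValueError("half-sample needs n >= 2")
    return as_rng(rng).choice(n, size=n // 2, replace=False)


def cdf_randomized(family: str, th: tuple[np.ndarray, ...] | ThetaValue, x, u):
    """Randomized probability integral transform.

    Continuous families return F_theta(x).  Discrete families return
    F(x-1) + u * (F(x) - F(x-1)) with F(-1) = 0, which is exactly U(0,1)
    when x ~ f(.|theta) and u ~ U(0,1) independently.  Fully vectorized;
    ``th`` may hold per-row parameter arrays.
    """
    if isinstance(th, ThetaValue):
        th = theta_arrays(th)
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("u must lie in [0, 1]")
    if family == "poisson":
        lam = th[0]
        lo = stats.poisson.cdf(x - 1, lam)
        return lo + u * stats.poisson.pmf(x, lam)
    if family == "bernoulli":
        p = th[0]
        lo = np.where(x >= 1, 1.0 - p, 0.0) * (x >= 0)
        pm = np.where(x == 0, 1.0 - p, np.where(x == 1, p, 0.0))
        return lo + u * pm
    if family == "normal":
        mu, var = th
        return special.ndtr((x - mu) / np.sqrt(var))
    raise ValueError(f"unknown family {family!r}")


def model_moments(family: str, th: tuple[np.ndarray, ...] | ThetaValue):
    """(mean, variance) of one observation under f(.|theta); vectorized."""
    if isinstance(th, ThetaValue):
        th = theta_arrays(th)
    if family == "poisson":
        return th[0], th[0]
    if family == "bernoulli":
        return th[0], th[0] * (1.0 - th[0])
    if family == "normal":
        return th[0], th[1]
    raise ValueError(f"unknown family {family!r}")


def loglik_rows(family: str, th: tuple[np.ndarray, ...], data2d: np.ndarray) -> np.ndarray:
    """Row sums of log f(x_ij | theta_i); theta broadcast along rows."""
    x = np.asarray(data2d, dtype=float)
    bth = tuple(np.asarray(v, dtype=float) for v in th)
    bth = tuple(v[:, None] if v.ndim == 1 and x.ndim == 2 else v for v in bth)
    if family == "poisson":
        lam = bth[0]
        ll = x * np.log(lam) - lam - special.gammaln(x + 1.0)
    elif family == "bernoulli":
        p = bth[0]
        ll = np.where(x == 1.0, np.log(p), np.log1p(-p))
    elif family == "normal":
        mu, var = bth
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)
    else:
        raise ValueError(f"unknown family {family!r}")
    return ll.sum(axis=-1)


def freq_theta_draw(family: str, data, rng) -> ThetaValue:
    """Frequentist parameter draw on the log scale (Poisson only).

    log(lambda) ~ Normal(log(lambda_hat), se^2) with lambda_hat the sample
    mean and se = (sum x)^(-1/2), the standard error of the intercept of a
    log-link intercept-only Poisson GLM.
    """
    if family != "poisson":
        raise ValueError("freq_theta_draw supports the poisson family only")
    x = validate_dataset(family, data)
    total = float(x.sum())
    if total <= 0:
        raise BoundaryMLEError("all-zero data: frequentist draw undefined")
    lam_hat = total / x.size
    se = total ** -0.5
    return ThetaValue.poisson(float(np.exp(as_rng(rng).normal(np.log(lam_hat), se))))


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def read_dataset_csv(path) -> np.ndarray:
    """Read a one-column CSV with a header line into a float vector."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise ValueError("expected a one-column CSV with a header")
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_dataset_csv(path, x, column: str = "x") -> None:
    import pandas as pd

    pd.DataFrame({column: np.asarray(x)}).to_csv(path, index=False)
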