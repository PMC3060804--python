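"""Synthetic-data generation for the calibration and power studies.

Each simulated dataset is a *pair* of models: a probabilistic model
(likelihood + prior pi0) that generates the data and a statistical model
(likelihood + prior pi) used to analyze them.  Four scenarios probe the
calibration of the p-value engines as the two priors drift apart:

1. pi = pi0 (matched) -- the exact-uniformity regime;
2. same center, dispersion of pi rescaled by a sharpness multiplier
   mu_sigma0 (prior sd multiplied by mu_sigma0, mean fixed);
3. as 2, plus multiplicative off-centering of the prior mean by theta0
   (natural-parameter scale: mean for Poisson, log-odds for Bernoulli,
   prior-sd units of log(theta0) for the normal location);
4. pi0 a Dirac at the mean of the scenario-1 statistical prior (fixed-
   parameter data generation).

The base (scenario-1) prior is itself redrawn per dataset: its center is
fixed while its dispersion varies, emulating a population of analyses.
Sample sizes follow a two-component law favoring small studies.  The
bounded-support alternative for power studies is the Polya (beta-binomial)
distribution with moments matched to the Poisson being tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models
from .discrepancy import DiscrepancySpec, get_discrepancy
from .models import (BetaPrior, Dataset, DiracPrior, GammaPrior,
                     NormalInvGammaPrior, PriorSpec, as_rng)
from .pvalues import gof_pvalue_multi

__all__ = [
    "ScenarioConfig", "ScenarioPair", "PolyaParams", "BatchConfig",
    "draw_sample_size", "make_scenario_pair", "polya_moment_match",
    "sample_polya", "run_batch", "run_power_batch",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Laws of the redacted simulation quantities (study conditions).

    Dispersion hyper-laws are log-normal; fields ending in ``_sdlog`` are
    the sd of the underlying normal (meanlog 0 unless stated).
    """

    # Poisson: Gamma prior with fixed mean and random index of dispersion
    poisson_mean: float = 1.0
    poisson_dispersion_sdlog: float = 1.0
    # Bernoulli: Beta prior with fixed mean and random concentration a+b
    bernoulli_mean: float = 0.5
    bernoulli_conc_meanlog: float = math.log(4.0)
    bernoulli_conc_sdlog: float = 1.0
    # Normal: NIG prior, fixed center, random marginal prior sd of mu
    normal_mu0: float = 0.0
    normal_tau_sdlog: float = 1.0
    normal_ig_shape: float = 3.0
    normal_ig_scale: float = 2.0
    # scenario 2/3 covariate laws
    mu_sigma0_sdlog: float = 1.0
    theta0_sdlog: float = 0.5
    # sample-size law: "mixture" (20..1000), "small" (uniform 20..50),
    # or a fixed integer
    n_law: object = "mixture"


@dataclass(frozen=True)
class ScenarioPair:
    """One simulated dataset with its generating and analysis models."""

    scenario: int
    family: str
    probabilistic: PriorSpec
    statistical: PriorSpec
    mu_sigma0: float
    theta0: float
    n: int
    theta_true: models.ThetaValue
    dataset: Dataset


def draw_sample_size(rng) -> int:
    """Random dataset size in {20,...,1000}, favoring small studies.

    With probability 0.7, uniform on the multiples of ten in [20, 200];
    otherwise uniform on the multiples of one hundred in [300, 1000].
    """
    rng = as_rng(rng)
    if rng.random() < 0.7:
        return int(10 * rng.integers(2, 21))
    return int(100 * rng.integers(3, 11))


def _draw_base_prior(family: str, cfg: ScenarioConfig, rng) -> PriorSpec:
    """Scenario-1 prior: fixed center, dataset-specific dispersion."""
    if family == "poisson":
        phi = rng.lognormal(0.0, cfg.poisson_dispersion_sdlog)
        rate = 1.0 / phi
        return GammaPrior(cfg.poisson_mean * rate, rate)
    if family == "bernoulli":
        s = rng.lognormal(cfg.bernoulli_conc_meanlog, cfg.bernoulli_conc_sdlog)
        return BetaPrior(cfg.bernoulli_mean * s, (1.0 - cfg.bernoulli_mean) * s)
    if family == "normal":
        tau = rng.lognormal(0.0, cfg.normal_tau_sdlog)
        a0, b0 = cfg.normal_ig_shape, cfg.normal_ig_scale
        kappa0 = b0 / ((a0 - 1.0) * tau**2)  # marginal sd of mu equals tau
        return NormalInvGammaPrior(cfg.normal_mu0, kappa0, a0, b0)
    raise ValueError(f"unknown family {family!r}")


def scale_dispersion(prior: PriorSpec, mu_sigma0: float) -> PriorSpec:
    """Multiply the prior sd by mu_sigma0 at fixed center."""
    if isinstance(prior, GammaPrior):
        return GammaPrior(prior.shape / mu_sigma0**2, prior.rate / mu_sigma0**2)
    if isinstance(prior, BetaPrior):
        return BetaPrior(prior.a / mu_sigma0**2, prior.b / mu_sigma0**2)
    if isinstance(prior, NormalInvGammaPrior):
        return replace(prior, kappa0=prior.kappa0 / mu_sigma0**2)
    raise ValueError("cannot rescale this prior")


def off_center(prior: PriorSpec, theta0: float) -> PriorSpec:
    """Multiplicative shift of the prior center on the natural scale.

    Poisson: mean multiplied by theta0 at fixed variance.  Bernoulli:
    log-odds shifted by log(theta0) at fixed concentration.  Normal:
    location shifted by log(theta0) marginal-prior-sd units.
    """
    if isinstance(prior, GammaPrior):
        return GammaPrior(theta0**2 * prior.shape, theta0 * prior.rate)
    if isinstance(prior, BetaPrior):
        s = prior.a + prior.b
        logit = math.log(prior.a / prior.b) + math.log(theta0)
        p = 1.0 / (1.0 + math.exp(-logit))
        return BetaPrior(p * s, (1.0 - p) * s)
    if isinstance(prior, NormalInvGammaPrior):
        shift = math.log(theta0) * prior.mu_marginal_sd()
        return replace(prior, mu0=prior.mu0 + shift)
    raise ValueError("cannot off-center this prior")


def _draw_n(cfg: ScenarioConfig, rng) -> int:
    if cfg.n_law == "mixture":
        return draw_sample_size(rng)
    if cfg.n_law == "small":
        return int(rng.integers(20, 51))
    return int(cfg.n_law)


def make_scenario_pair(scenario: int, family: str, rng,
                       config: ScenarioConfig | None = None) -> ScenarioPair:
    """Draw one (probabilistic model, statistical model, dataset) triple."""
    if scenario not in (1, 2, 3, 4):
        raise ValueError("scenario must be 1, 2, 3 or 4")
    cfg = config or ScenarioConfig()
    rng = as_rng(rng)
    base = _draw_base_prior(family, cfg, rng)
    mu_sigma0 = 1.0
    theta0 = 1.0
    statistical = base
    if scenario in (2, 3):
        mu_sigma0 = float(rng.lognormal(0.0, cfg.mu_sigma0_sdlog))
        statistical = scale_dispersion(base, mu_sigma0)
    if scenario == 3:
        theta0 = float(rng.lognormal(0.0, cfg.theta0_sdlog))
        statistical = off_center(statistical, theta0)
    probabilistic: PriorSpec = base
    if scenario == 4:
        probabilistic = DiracPrior(base.mean_theta())
    n = _draw_n(cfg, rng)
    theta_true = models.sample_theta(probabilistic, rng)
    x = models.sample_data(family, theta_true, n, rng)
    return ScenarioPair(scenario, family, probabilistic, statistical,
                        mu_sigma0, theta0, n, theta_true,
                        Dataset(x, provenance=theta_true))


# ---------------------------------------------------------------------------
# Polya (beta-binomial) alternative
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolyaParams:
    """Beta-binomial on {0..m} with shape parameters (alpha, beta)."""

    m: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.m < 1 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("need m >= 1 and positive shapes")

    def mean_var(self) -> tuple[float, float]:
        s = self.alpha + self.beta
        p = self.alpha / s
        return self.m * p, self.m * p * (1 - p) * (s + self.m) / (s + 1)


def polya_moment_match(m: int, mean: float, var: float) -> PolyaParams:
    """Beta-binomial on {0..m} with the requested mean and variance.

    Solving mean = m*p and var = m*p*(1-p)*(s+m)/(s+1) for s = alpha+beta
    gives s = (m*p*q*m - var) / (var - m*p*q); feasible iff the target
    variance exceeds the binomial variance m*p*q and s > 0.
    """
    if not 0 < mean < m:
        raise ValueError("need 0 < mean < m")
    p = mean / m
    c = m * p * (1.0 - p)  # binomial variance floor
    if var <= c or var >= c * m:
        raise ValueError(
            f"variance {var} infeasible for beta-binomial on 0..{m} with "
            f"mean {mean}: need {c} < var < {c * m}")
    s = (c * m - var) / (var - c)
    return PolyaParams(m, p * s, (1.0 - p) * s)


def sample_polya(params: PolyaParams, n: int, rng) -> np.ndarray:
    """n i.i.d. beta-binomial draws (one Beta(p) per observation)."""
    rng = as_rng(rng)
    p = rng.beta(params.alpha, params.beta, size=n)
    return rng.binomial(params.m, p).astype(float)


# ---------------------------------------------------------------------------
# batch harness
# ---------------------------------------------------------------------------

#: output schema version written in the CSV header comment
BATCH_SCHEMA = "sppgof-batch-v1"

#: Poisson mean of the power study (the Polya alternative matches its
#: moments).  Larger than the calibration scenarios' prior mean 1 because
#: near mean 1 a beta-binomial on {0..5} with Poisson moments is all but
#: indistinguishable from the Poisson itself (every engine's power sits at
#: the nominal level); at mean 2.5 the bounded support genuinely bites.
POWER_POISSON_MEAN = 2.5

BATCH_COLUMNS = ("rep", "scenario", "family", "n", "mu_sigma0", "theta0",
                 "abs_log_theta0", "engine", "statistic", "input_scale", "p",
                 "seed")


@dataclass(frozen=True)
class BatchConfig:
    """One calibration batch: scenarios x engines x discrepancies."""

    scenario: int
    family: str
    reps: int
    K: int
    seed: int
    engines: tuple[str, ...] = ("spp",)
    discrepancies: tuple[str, ...] = ("variance",)
    estimator: str = "beta"
    scenario_config: ScenarioConfig = field(default_factory=ScenarioConfig)

    def __post_init__(self) -> None:
        if self.reps < 1 or self.K < 1:
            raise ValueError("reps and K must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "BatchConfig":
        d = dict(d)
        sc = d.pop("scenario_config", None)
        if isinstance(sc, dict):
            sc = ScenarioConfig(**sc)
        for key in ("engines", "discrepancies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d, **({"scenario_config": sc} if sc else {}))


def _resolve_discs(names) -> list[DiscrepancySpec]:
    return [d if isinstance(d, DiscrepancySpec) else get_discrepancy(str(d))
            for d in names]


def _discs_for_engine(engine: str, discs: list[DiscrepancySpec],
                      engines: tuple[str, ...]) -> list[DiscrepancySpec]:
    """Route a mixed-scale discrepancy list to a compatible subset.

    nspp takes the normalized-scale subset; when nspp is also in the batch,
    spp takes the raw subset (spp on normalized data *is* nspp, so running
    both would duplicate rows).  Other engines take the full list.
    """
    if engine == "nspp":
        return [d for d in discs if d.input_scale == "normalized"]
    if engine == "spp" and "nspp" in engines:
        return [d for d in discs if d.input_scale == "raw"]
    return list(discs)


def run_batch(config: BatchConfig | dict) -> pd.DataFrame:
    """Run a calibration batch; one row per (dataset, engine, discrepancy).

    Deterministic given the master seed: each replicate owns a child seed
    stream, split again per engine, so datasets are shared across engines
    and discrepancies within a replicate and any single replicate can be
    reproduced in isolation.
    """
    cfg = BatchConfig.from_dict(config) if isinstance(config, dict) else config
    discs = _resolve_discs(cfg.discrepancies)
    ss = np.random.SeedSequence(cfg.seed)
    rows: list[tuple] = []
    for i, child in enumerate(ss.spawn(cfg.reps)):
        streams = child.spawn(1 + len(cfg.engines))
        pair = make_scenario_pair(cfg.scenario, cfg.family,
                                  np.random.default_rng(streams[0]),
                                  cfg.scenario_config)
        for j, engine in enumerate(cfg.engines):
            ediscs = _discs_for_engine(engine, discs, cfg.engines)
            if not ediscs:
                continue
            erng = np.random.default_rng(streams[1 + j])
            res = gof_pvalue_multi(engine, pair.statistical, pair.dataset.x,
                                   ediscs, K=cfg.K, rng=erng,
                                   estimator=cfg.estimator)
            for r in res:
                rows.append((i, cfg.scenario, cfg.family, pair.n,
                             pair.mu_sigma0, pair.theta0,
                             abs(math.log(pair.theta0)), engine, r.statistic,
                             r.input_scale, r.p, cfg.seed))
    return pd.DataFrame(rows, columns=BATCH_COLUMNS)


def run_power_batch(
    reps: int,
    K: int,
    seed: int,
    sizes=(20, 50),
    m: int = 5,
    engines: tuple[str, ...] = ("spp", "halfml", "ppost"),
    discrepancies=(("skewness", "normalized"), ("kurtosis", "normalized"),
                   ("za", "normalized"), ("maximum", "normalized"),
                   ("maximum", "raw")),
    alternative: str = "polya",
    scenario_config: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Power-study batch under the Polya alternative (or the Poisson null).

    Data are drawn from a beta-binomial on {0..m} whose mean and variance
    match the Poisson implied by the statistical prior center (``polya``),
    or from that Poisson itself (``null``); the analysis model is the
    Poisson family with a scenario-1 statistical prior.  Sample sizes
    cycle deterministically through ``sizes`` so every cell gets
    reps/len(sizes) datasets.
    """
    if alternative not in ("polya", "null"):
        raise ValueError("alternative must be 'polya' or 'null'")
    cfg = scenario_config or ScenarioConfig(poisson_mean=POWER_POISSON_MEAN)
    lam = cfg.poisson_mean
    polya = polya_moment_match(m, lam, lam) if alternative == "polya" else None
    discs = [d if isinstance(d, DiscrepancySpec) else get_discrepancy(*(
        (d,) if isinstance(d, str) else d)) for d in discrepancies]
    ss = np.random.SeedSequence(seed)
    rows: list[tuple] = []
    for i, child in enumerate(ss.spawn(reps)):
        streams = child.spawn(1 + len(engines))
        drng = np.random.default_rng(streams[0])
        statistical = _draw_base_prior("poisson", cfg, drng)
        n = int(sizes[i % len(sizes)])
        if polya is not None:
            x = sample_polya(polya, n, drng)
        else:
            x = models.sample_data("poisson", models.ThetaValue.poisson(lam),
                                   n, drng)
        for j, engine in enumerate(engines):
            erng = np.random.default_rng(streams[1 + j])
            res = gof_pvalue_multi(engine, statistical, x, discs, K=K,
                                   rng=erng)
            for r in res:
                rows.append((i, alternative, "poisson", n, 1.0, 1.0, 0.0,
                             engine, r.statistic, r.input_scale, r.p, seed))
    return pd.DataFrame(rows, columns=BATCH_COLUMNS)


def write_batch_csv(df: pd.DataFrame, path) -> None:
    """Batch CSV with a schema-version header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# {BATCH_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_batch_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
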