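"""Discrepancy and test-statistic functions, and the normalization transform.

A discrepancy d(X, theta) measures model-data disagreement; a test
statistic t(X) is the special case that ignores theta.  Statistics can be
evaluated either on the raw data or on *normalized* data: the randomized
probability integral transform followed by the standard-normal quantile
function, which maps model-distributed data to exact i.i.d. N(0,1) values
and makes any statistic of them pivotal.

Registry
--------
========== ============== ============ =======================================
name       scales         needs theta  definition
========== ============== ============ =======================================
mean       raw,normalized no           sample mean
variance   raw,normalized no           sample variance (denominator n-1)
maximum    raw,normalized no           sample maximum
meanc      raw            yes          mean(x) - model mean(theta)
varc       raw            yes          var(x) - model variance(theta)
loglik     raw            yes          sum_i log f(x_i | theta)
skewness   normalized     no           biased standardized third moment
kurtosis   normalized     no           biased fourth moment (not excess)
za         normalized     no           Zhang's Z_A on the uniformized values
========== ============== ============ =======================================

Zhang's Z_A is ``-sum_i [log(U_(i))/(n-i+0.5) + log(1-U_(i))/(i-0.5)]``
on the ascending-sorted uniformized values U_(i) = Phi(y_(i)); large
values flag poor fit anywhere in the distribution, with sensitivity in
both tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from . import models

__all__ = [
    "DiscrepancySpec",
    "get_discrepancy",
    "list_discrepancies",
    "normalize",
    "compute_discrepancy",
    "discrepancy_rows",
]

#: statistic name -> scales it may be evaluated on (first entry is default)
ALLOWED_SCALES: dict[str, tuple[str, ...]] = {
    "mean": ("raw", "normalized"),
    "variance": ("raw", "normalized"),
    "maximum": ("raw", "normalized"),
    "meanc": ("raw",),
    "varc": ("raw",),
    "loglik": ("raw",),
    "skewness": ("normalized",),
    "kurtosis": ("normalized",),
    "za": ("normalized",),
}

NEEDS_THETA = frozenset({"meanc", "varc", "loglik"})

#: statistics undefined (or degenerate) for fewer than two observations
MIN_TWO = frozenset({"variance", "varc", "skewness", "kurtosis"})


@dataclass(frozen=True)
class DiscrepancySpec:
    """A named discrepancy plus the scale it is evaluated on."""

    name: str
    input_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.name not in ALLOWED_SCALES:
            raise KeyError(f"unknown discrepancy {self.name!r}; "
                           f"known: {sorted(ALLOWED_SCALES)}")
        if self.input_scale not in ALLOWED_SCALES[self.name]:
            raise ValueError(
                f"{self.name!r} cannot be evaluated on {self.input_scale!r} "
                f"data (allowed: {ALLOWED_SCALES[self.name]})")

    @property
    def needs_theta(self) -> bool:
        return self.name in NEEDS_THETA

    @property
    def label(self) -> str:
        return f"{self.name}@{self.input_scale}"


def get_discrepancy(name: str, scale: str | None = None) -> DiscrepancySpec:
    """Look up a discrepancy by name, optionally forcing the input scale."""
    if "@" in name and scale is None:
        name, scale = name.split("@", 1)
    return DiscrepancySpec(name, scale or ALLOWED_SCALES[name][0])


def list_discrepancies() -> list[dict]:
    """Registry contents, one dict per statistic (for the CLI)."""
    return [
        {"name": k, "scales": v, "needs_theta": k in NEEDS_THETA}
        for k, v in ALLOWED_SCALES.items()
    ]


def normalize(family: str, theta, x, u_vec) -> np.ndarray:
    """Map data to the standard-normal scale via the randomized PIT.

    y_i = Phi^{-1}( F_theta^rand(x_i, u_i) ).  If x ~ f(.|theta) and the
    u_i are independent U(0,1), the output is exactly i.i.d. N(0,1).
    CDF values of exactly 0 or 1 (possible only through floating-point
    underflow) are clamped with a warning.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u_vec, dtype=float)
    c = models.cdf_randomized(family, theta, x, u)
    tiny = np.finfo(float).tiny
    eps = np.finfo(float).epsneg
    if np.any(c <= 0.0) or np.any(c >= 1.0):
        warnings.warn("randomized CDF hit 0 or 1; clamping before Phi^-1",
                      RuntimeWarning, stacklevel=2)
        c = np.clip(c, tiny, 1.0 - eps)
    return special.ndtri(c)


# --- vectorized statistic kernels (last axis = observations) ---------------


def _var(y: np.ndarray) -> np.ndarray:
    return y.var(axis=-1, ddof=1)


def _central_moments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = y - y.mean(axis=-1, keepdims=True)
    c2 = c * c
    m2 = c2.mean(axis=-1)
    m3 = (c2 * c).mean(axis=-1)
    m4 = (c2 * c2).mean(axis=-1)
    return m2, m3, m4


def _za(y: np.ndarray) -> np.ndarray:
    u = special.ndtr(y)
    # finite y gives u in (0,1) mathematically; guard the float boundary
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    u = np.sort(u, axis=-1)
    n = y.shape[-1]
    i = np.arange(1, n + 1, dtype=float)
    return -(np.log(u) / (n - i + 0.5) + np.log1p(-u) / (i - 0.5)).sum(axis=-1)


def discrepancy_rows(spec: DiscrepancySpec, data, th=None, family: str | None = None):
    """Evaluate a discrepancy along the last axis of ``data``.

    ``data`` may be (n,) or (K, n); ``th`` is a canonical parameter tuple
    (see :func:`sppgof.models.theta_arrays`) whose entries broadcast
    against rows, enabling per-replicate parameters for the predictive
    engines.  Returns a scalar for 1-d input, a length-K vector otherwise.
    """
    y = np.asarray(data, dtype=float)
    if y.shape[-1] < 2 and spec.name in MIN_TWO:
        raise ValueError(f"{spec.name} needs at least 2 observations")
    name = spec.name
    if spec.needs_theta:
        if th is None or family is None:
            raise ValueError(f"{name} requires theta and family")
    if name == "mean":
        return y.mean(axis=-1)
    if name == "variance":
        return _var(y)
    if name == "maximum":
        return y.max(axis=-1)
    if name == "meanc":
        m, _ = models.model_moments(family, th)
        return y.mean(axis=-1) - m
    if name == "varc":
        _, v = models.model_moments(family, th)
        return _var(y) - v
    if name == "loglik":
        return models.loglik_rows(family, th, y)
    if name == "skewness":
        m2, m3, _ = _central_moments(y)
        return m3 / m2**1.5
    if name == "kurtosis":
        m2, _, m4 = _central_moments(y)
        return m4 / m2**2
    if name == "za":
        return _za(y)
    raise KeyError(name)  # pragma: no cover - guarded by DiscrepancySpec


def compute_discrepancy(spec: DiscrepancySpec, data, theta=None) -> float:
    """Scalar discrepancy d(data, theta) for a single dataset.

    ``data`` must already be on ``spec.input_scale`` (use :func:`normalize`
    for the normalized scale).  ``theta`` is a ThetaValue, required iff
    ``spec.needs_theta``.
    """
    x = models.as_data(data)
    th = fam = None
    if theta is not None:
        th, fam = models.theta_arrays(theta), theta.family
    elif spec.needs_theta:
        raise ValueError(f"{spec.name} requires a theta value")
    return float(discrepancy_rows(spec, x, th, fam))
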