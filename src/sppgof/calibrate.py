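"""Uniformity and power diagnostics for batches of p-values.

A calibrated GOF p-value should be uniform on (0,1) when the analysis
model matches the data-generating model.  This module measures departures
three ways:

* a one-sample Kolmogorov-Smirnov test against U(0,1);
* the frequency of p-values in the two-sided ``level`` extremities of the
  unit interval (below level/2 or above 1-level/2), with a *randomized*
  two-sided binomial test whose own p-value is exactly uniform under the
  null despite the discreteness of the count;
* a band code classifying the Beta(count+1, N-count+1) posterior of the
  underlying tail proportion against negligibility intervals around the
  nominal level (at 5%: inner band 0.04-0.06, outer band 0.03-0.07; at
  1% the same cutoffs divided by 5).

Band codes: ``zero_zero``/``zero`` -- the 95% credible interval sits
inside the inner/outer band (departure negligible); ``plus``/``plus_plus``
-- the interval sits wholly above 0.06/0.07 (tail excess); ``minus``/
``minus_minus`` mirror below 0.04/0.03 (conservative); ``none`` otherwise.

Power against an alternative is simply the extremity frequency at the
chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import as_rng

__all__ = [
    "ks_uniformity", "tail_frequency_test", "band_code", "estimate_power",
    "TailTest", "calibrate_batch", "render_table",
    "MU_SIGMA0_BINS", "OFFCENTER_BINS", "assign_bins",
]

#: stratification edges for the prior-sharpness multiplier
MU_SIGMA0_BINS = (0.0, 0.40, 1.01, 2.59, np.inf)
#: stratification edges for |log theta0| (off-centering)
OFFCENTER_BINS = (0.0, 0.14, 0.28, 0.47, 1.73, np.inf)

#: negligibility cutoffs at the 5% level; divided by 5 at the 1% level
INNER_BAND = (0.04, 0.06)
OUTER_BAND = (0.03, 0.07)

_BAND_SIGN = {"minus_minus": -2, "minus": -1, "zero_zero": 0, "zero": 0,
              "none": 0, "plus": 1, "plus_plus": 2}


def ks_uniformity(pvals) -> tuple[float, float]:
    """One-sample KS statistic against U(0,1) and its asymptotic p-value."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    res = stats.kstest(p, "uniform", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _extreme_mask(pvals: np.ndarray, level: float) -> np.ndarray:
    return (pvals < level / 2.0) | (pvals > 1.0 - level / 2.0)


def band_code(count: int, N: int, level: float) -> str:
    """Negligibility band from the beta posterior of the tail proportion."""
    scale = level / 0.05
    inner = (INNER_BAND[0] * scale, INNER_BAND[1] * scale)
    outer = (OUTER_BAND[0] * scale, OUTER_BAND[1] * scale)
    lo, hi = stats.beta.ppf((0.025, 0.975), count + 1, N - count + 1)
    if hi <= outer[0]:
        return "minus_minus"
    if hi <= inner[0]:
        return "minus"
    if lo >= outer[1]:
        return "plus_plus"
    if lo >= inner[1]:
        return "plus"
    if inner[0] < lo and hi < inner[1]:
        return "zero_zero"
    if outer[0] < lo and hi < outer[1]:
        return "zero"
    return "none"


def band_sign(code: str) -> int:
    """-2..2 ordering of band codes (for monotonicity checks/reports)."""
    return _BAND_SIGN[code]


@dataclass(frozen=True)
class TailTest:
    """Extremity-frequency diagnostic at one nominal level."""

    level: float
    N: int
    count: int
    freq: float
    binom_p: float
    beta_shape1: float
    beta_shape2: float
    band: str


def tail_frequency_test(pvals, level: float = 0.05, rng=None) -> TailTest:
    """Tail frequency with a randomized binomial test and band code.

    The extremity region is two-sided with total nominal mass ``level``.
    The test p-value is 2*min(V, 1-V) where V is the randomized binomial
    PIT of the count, hence exactly U(0,1) under the null.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = int(p.size)
    count = int(_extreme_mask(p, level).sum())
    u = float(as_rng(rng).random())
    v = stats.binom.cdf(count - 1, n, level) + u * stats.binom.pmf(count, n, level)
    binom_p = 2.0 * min(v, 1.0 - v)
    return TailTest(level=level, N=n, count=count, freq=count / n,
                    binom_p=float(binom_p), beta_shape1=count + 1.0,
                    beta_shape2=n - count + 1.0,
                    band=band_code(count, n, level))


def estimate_power(pvals, level: float = 0.05) -> float:
    """Fraction of p-values in the two-sided ``level`` extremities."""
    if level >= 1.0:
        return 1.0
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(_extreme_mask(p, level).mean())


# ---------------------------------------------------------------------------
# batch-level reports
# ---------------------------------------------------------------------------


def assign_bins(df: pd.DataFrame) -> pd.DataFrame:
    """Add sharpness / off-centering stratum labels to a batch frame."""
    out = df.copy()
    out["mu_bin"] = pd.cut(out["mu_sigma0"], MU_SIGMA0_BINS, right=False)
    if "abs_log_theta0" in out:
        out["offc_bin"] = pd.cut(out["abs_log_theta0"], OFFCENTER_BINS,
                                 right=False)
    return out


def calibrate_batch(df: pd.DataFrame, by=("engine", "statistic"),
                    rng=None) -> pd.DataFrame:
    """Per-stratum calibration report for a batch of p-values.

    Groups ``df`` by the columns in ``by`` and reports N, the KS distance
    and p-value, and the 5%/1% tail frequencies with their randomized
    binomial p-values and band codes.
    """
    rng = as_rng(rng)
    rows = []
    for key, g in df.groupby(list(by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        p = g["p"].to_numpy()
        D, ksp = ks_uniformity(p)
        t5 = tail_frequency_test(p, 0.05, rng)
        t1 = tail_frequency_test(p, 0.01, rng)
        rows.append((*key, p.size, D, ksp, t5.freq, t5.binom_p, t5.band,
                     t1.freq, t1.binom_p, t1.band))
    cols = [*by, "N", "ks_D", "ks_p", "freq5", "binom_p5", "band5",
            "freq1", "binom_p1", "band1"]
    return pd.DataFrame(rows, columns=cols)


_SIG = ((1e-4, "***"), (0.01, "**"), (0.05, "*"), (0.10, "(*)"))
_BAND_MARK = {"zero_zero": "00", "zero": "0", "plus_plus": "++", "plus": "+",
              "minus_minus": "--", "minus": "-", "none": ""}


def _annotate(freq: float, test_p: float, band: str) -> str:
    sig = next((m for cut, m in _SIG if test_p < cut), "")
    marks = ",".join(m for m in (sig, _BAND_MARK[band]) if m)
    return f"{freq:.3f}" + (f"^{marks}" if marks else "")


def render_table(df: pd.DataFrame, rows: str = "mu_bin",
                 cols: str | None = "offc_bin", value: str = "freq5",
                 test: str = "binom_p5", band: str = "band5") -> str:
    """Plain-text stratified frequency table with significance/band marks.

    ``df`` is a calibrated batch (see :func:`calibrate_batch` with the
    stratum columns in ``by``).  Significance marks: ``(*)`` p in
    (.05,.1], ``*`` (.01,.05], ``**`` (.0001,.01], ``***`` <= .0001; band
    marks as in :func:`band_code`.
    """
    d = df.copy()
    d["cell"] = [_annotate(f, t, b)
                 for f, t, b in zip(d[value], d[test], d[band])]
    if cols is None or cols not in d:
        table = d.set_index(rows)[["N", "cell"]]
        return table.to_string()
    pivot = d.pivot_table(index=rows, columns=cols, values="cell",
                          aggfunc="first", observed=True)
    return pivot.to_string()
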