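"""Manipulation-check statistics: paired t tests and Cohen's d_z.

d_z is the one-sample standardized effect for paired data — the mean of the
difference scores divided by their standard deviation — and satisfies
t = d_z * sqrt(n) exactly.  Its confidence interval comes from inverting the
noncentral-t distribution of the observed t statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PairedResult", "paired_t", "cohens_dz", "manipulation_checks"]


@dataclass(frozen=True)
class PairedResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    d_z: float
    d_z_ci: tuple[float, float]


def _validate_diffs(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least 2 paired observations")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    if np.std(d, ddof=1) == 0:
        raise ValueError("degenerate data: zero variance of difference scores")
    return d


def cohens_dz(differences, confidence: float = 0.95) -> tuple[float, float, float]:
    """Cohen's d_z with a noncentral-t confidence interval.

    The CI bounds are the noncentrality parameters delta_lo, delta_hi for
    which the observed t is the (1 -/+ alpha/2) quantile of t'(df, delta),
    rescaled by sqrt(n).
    """
    d = _validate_diffs(np.asarray(differences))
    n = d.size
    dz = float(np.mean(d) / np.std(d, ddof=1))
    t_obs = dz * math.sqrt(n)
    df = n - 1
    alpha = 1.0 - confidence

    def _cdf(delta: float) -> float:
        v = stats.nct.cdf(t_obs, df, delta)
        if math.isnan(v):
            # Johnson-Kotz normal approximation, used only where scipy's
            # noncentral-t CDF underflows to NaN
            num = t_obs * (1.0 - 1.0 / (4.0 * df)) - delta
            den = math.sqrt(1.0 + t_obs**2 / (2.0 * df))
            v = stats.norm.cdf(num / den)
        return v

    def _bound(prob: float) -> float:
        # find delta with P(T'_{df, delta} <= t_obs) = prob
        f = lambda delta: _cdf(delta) - prob
        span = 10.0 + 10.0 * abs(t_obs)
        lo, hi = t_obs - span, t_obs + span
        while f(lo) < 0:
            lo -= span
        while f(hi) > 0:
            hi += span
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    delta_lo = _bound(1.0 - alpha / 2.0)
    delta_hi = _bound(alpha / 2.0)
    return dz, delta_lo / math.sqrt(n), delta_hi / math.sqrt(n)


def paired_t(x, y) -> PairedResult:
    """Two-sided paired t test of x vs y with Cohen's d_z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = _validate_diffs(x - y)
    n = d.size
    res = stats.ttest_rel(x, y)
    dz, lo, hi = cohens_dz(d)
    return PairedResult(
        n=n,
        mean_diff=float(np.mean(d)),
        sd_diff=float(np.std(d, ddof=1)),
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        d_z=dz,
        d_z_ci=(lo, hi),
    )


def manipulation_checks(wide) -> dict[str, PairedResult]:
    """Paired CS+ vs CS- tests for every measure present in a wide table.

    Expects columns ``cs_plus_<measure>`` / ``cs_minus_<measure>`` (e.g.
    fear, disgust, valence) keyed by participant.
    """
    results = {}
    for col in wide.columns:
        if col.startswith("cs_plus_"):
            measure = col[len("cs_plus_"):]
            minus = f"cs_minus_{measure}"
            if minus in wide.columns:
                results[measure] = paired_t(wide[col].to_numpy(), wide[minus].to_numpy())
    if not results:
        raise ValueError("no cs_plus_*/cs_minus_* column pairs found")
    return results
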