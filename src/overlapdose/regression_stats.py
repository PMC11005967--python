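"""Statistical comparison of the two overlap parameters.

For each dose level x in a 1-Gy sweep (default 20-75 Gy) the per-case
V_xGy values of one OAR are regressed on COPP and on POPP, giving two
Pearson correlation series r_COPP(x) and r_POPP(x).  Two questions follow:

* At which levels do the parameters differ significantly?  The default test
  is the Williams/Steiger comparison of two dependent correlations sharing
  the variable V_xGy (the predictors COPP and POPP are themselves strongly
  correlated, which the test accounts for through their inter-correlation).
  A windowed paired t-test over neighbouring 1-Gy levels is available as an
  alternative reading of "paired-samples t-test" applied to correlation
  series; both are reported side by side, with a Holm-corrected column for
  transparency (the per-level 5% decisions themselves are uncorrected).
* Where do the two series cross?  The threshold dose Dth is the level at
  which the correlations are equal - below it POPP predicts better, above
  it COPP does.  It is located by linear interpolation of
  ``delta(x) = r_POPP(x) - r_COPP(x)`` at its first positive-to-negative
  sign change scanning upward in dose; multiple crossings are logged as a
  warning and the first is reported.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "CorrelationSweep",
    "DegeneratePredictorError",
    "linear_fit",
    "pearson_r",
    "williams_test",
    "sweep_correlations",
    "compare_correlations",
    "significant_ranges",
    "threshold_dose",
]


class DegeneratePredictorError(ValueError):
    """Regression input is constant or too small to fit."""


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit of a metric on a predictor."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    residual_sd: float


def linear_fit(x, y) -> RegressionResult:
    """OLS fit with the sample Pearson correlation.

    Requires n >= 3 and a non-constant predictor; the sign of ``pearson_r``
    equals the sign of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DegeneratePredictorError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor is constant")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(n - 2, 1)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=n,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def pearson_r(x, y) -> float:
    """Sample Pearson correlation (convenience wrapper)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclasses.dataclass
class CorrelationSweep:
    """Per-dose-level correlations of V_xGy with COPP and with POPP."""

    oar: str
    dose_levels: np.ndarray
    r_copp: np.ndarray
    r_popp: np.ndarray
    n: int
    r_predictors: np.ndarray  # COPP-POPP inter-correlation per level's sample
    p_values: np.ndarray | None = None          # default (Williams) method
    p_paired_window: np.ndarray | None = None   # windowed paired-t variant
    p_holm: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.dose_levels)
        if len(self.r_copp) != k or len(self.r_popp) != k:
            raise ValueError("correlation series must align with dose_levels")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "dose_gy": self.dose_levels,
                "r_copp": self.r_copp,
                "r_popp": self.r_popp,
            }
        )
        if self.p_values is not None:
            out["p_williams"] = self.p_values
            out["significant"] = self.p_values < 0.05
        if self.p_paired_window is not None:
            out["p_paired_window"] = self.p_paired_window
        if self.p_holm is not None:
            out["p_holm"] = self.p_holm
        return out


def _metric_column(oar: str, level: float) -> str:
    return f"{oar}_v{level:g}gy"


def sweep_correlations(
    table: pd.DataFrame,
    oar: str = "rectum",
    dose_range: tuple[float, float] = (20.0, 75.0),
    step: float = 1.0,
) -> CorrelationSweep:
    """Correlate V_xGy with COPP and POPP at every level of a 1-Gy sweep.

    ``table`` holds one row per case with columns ``{oar}_copp``,
    ``{oar}_popp`` and ``{oar}_v{x}gy`` for every level of the sweep.
    """
    n = len(table)
    if n < 3:
        raise DegeneratePredictorError(f"need at least 3 cases, got {n}")
    copp = table[f"{oar}_copp"].to_numpy(dtype=float)
    popp = table[f"{oar}_popp"].to_numpy(dtype=float)
    levels = np.arange(dose_range[0], dose_range[1] + 0.5 * step, step)
    r_c = np.empty(levels.size)
    r_p = np.empty(levels.size)
    r_cp = np.full(levels.size, pearson_r(copp, popp))
    for i, lev in enumerate(levels):
        v = table[_metric_column(oar, lev)].to_numpy(dtype=float)
        r_c[i] = pearson_r(copp, v)
        r_p[i] = pearson_r(popp, v)
    return CorrelationSweep(
        oar=oar, dose_levels=levels, r_copp=r_c, r_popp=r_p, n=n, r_predictors=r_cp
    )


def williams_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' t for equality of two dependent overlapping correlations.

    Variable 1 is shared (here V_xGy); ``r12`` and ``r13`` are its
    correlations with the two predictors and ``r23`` the predictors'
    inter-correlation.  Returns ``(t, two-sided p)`` with ``n - 3`` degrees
    of freedom.
    """
    if n < 4:
        raise DegeneratePredictorError("Williams test needs n >= 4")
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        return np.inf if r12 != r13 else 0.0, 0.0 if r12 != r13 else 1.0
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def compare_correlations(
    sweep: CorrelationSweep,
    table: pd.DataFrame | None = None,
    method: str = "dependent-correlation",
    window: int = 5,
    alpha: float = 0.05,
) -> CorrelationSweep:
    """Attach per-level p-values for r_COPP vs r_POPP to a sweep.

    ``method="dependent-correlation"`` (default) applies the Williams test
    per level using the COPP-POPP inter-correlation.  ``"paired-t-window"``
    runs a paired t-test of the two correlation series over a sliding window
    of ``window`` neighbouring 1-Gy levels (windows are truncated at the
    sweep edges; at least 3 level pairs are required).  Both columns are
    populated; ``method`` selects which one feeds ``p_values`` consumers.
    A Holm-corrected copy of the default p-series is attached as well.
    """
    if method not in ("dependent-correlation", "paired-t-window"):
        raise ValueError(f"unknown method {method!r}")
    k = sweep.dose_levels.size
    p_w = np.empty(k)
    for i in range(k):
        _, p_w[i] = williams_test(
            sweep.r_copp[i], sweep.r_popp[i], sweep.r_predictors[i], sweep.n
        )

    half = window // 2
    p_t = np.full(k, np.nan)
    for i in range(k):
        lo, hi = max(0, i - half), min(k, i + half + 1)
        rc, rp = sweep.r_copp[lo:hi], sweep.r_popp[lo:hi]
        if rc.size >= 3 and np.ptp(rc - rp) > 0:
            p_t[i] = stats.ttest_rel(rc, rp).pvalue
        elif rc.size >= 3:
            p_t[i] = 1.0 if np.allclose(rc, rp) else 0.0

    from statsmodels.stats.multitest import multipletests

    sweep.p_values = p_w if method == "dependent-correlation" else p_t
    sweep.p_paired_window = p_t
    sweep.p_holm = multipletests(p_w, alpha=alpha, method="holm")[1]
    return sweep


def significant_ranges(
    levels: np.ndarray, p: np.ndarray, alpha: float = 0.05
) -> list[tuple[float, float]]:
    """Contiguous dose-level runs with p < alpha, as (low, high) pairs."""
    levels = np.asarray(levels, dtype=float)
    sig = np.asarray(p) < alpha
    ranges: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = levels[i]
        elif not flag and start is not None:
            ranges.append((start, levels[i - 1]))
            start = None
    if start is not None:
        ranges.append((start, levels[-1]))
    return ranges


def threshold_dose(sweep: CorrelationSweep) -> float | None:
    """Dth: the dose at which the COPP and POPP correlations are equal.

    Linear interpolation of ``delta = r_POPP - r_COPP`` at its first
    positive-to-negative sign change scanning upward in dose; ``None`` when
    the series never crosses.  An exact zero at a grid level is returned as
    that level.
    """
    delta = sweep.r_popp - sweep.r_copp
    levels = sweep.dose_levels
    crossings = []
    for i in range(levels.size):
        if delta[i] == 0.0 and (i == 0 or delta[i - 1] > 0):
            crossings.append(float(levels[i]))
        elif i + 1 < levels.size and delta[i] > 0 and delta[i + 1] < 0:
            frac = delta[i] / (delta[i] - delta[i + 1])
            crossings.append(float(levels[i] + frac * (levels[i + 1] - levels[i])))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"{sweep.oar}: multiple correlation crossings at {crossings}; "
            "reporting the first",
            stacklevel=2,
        )
    return crossings[0]
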