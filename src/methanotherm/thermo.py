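"""Arrhenius analysis of temperature sensitivity.

The temperature dependence of a rate P is characterized by

    ln P = E * (-1 / (R * T)) + M

with T the absolute temperature (K), R the Boltzmann constant in eV/K, E the
apparent activation energy (eV) and M the intercept (the theoretical log-rate
in the absence of an activation barrier). E is the OLS slope of ln P on
-1/(R*T) and is invariant to any positive rescaling of the rates, so the
(arbitrary) rate unit never matters.

A community whose composition shifts with temperature can show *two* regimes:
a steep slope (high E) below a break temperature and a shallower one above.
``fit_segmented`` searches every admissible cut between consecutive distinct
temperatures, fits two independent OLS lines (no continuity constraint), and
keeps the cut minimizing the pooled residual sum of squares; ``select_model``
arbitrates one vs two regimes with an extra-sum-of-squares F-test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import RateEstimate

logger = logging.getLogger(__name__)

#: Boltzmann constant in eV/K as conventionally printed in the source field
#: (CODATA value is 8.617333e-5; the difference moves fitted E by < 0.1%).
BOLTZMANN_EV_PER_K = 8.623e-5

_RSS_ATOL = 1e-12


class ThermoError(ValueError):
    pass


class FTestUndefinedError(ThermoError):
    """Extra-sum-of-squares test needs more points than parameters (n > 4)."""


@dataclass(frozen=True)
class ArrheniusPoint:
    """One (temperature, rate) observation in Arrhenius coordinates."""

    temperature_K: float
    rate: float
    x: float  # -1/(R*T)
    y: float  # ln(rate)


@dataclass
class ArrheniusFit:
    """OLS fit of y = E*x + M over a set of Arrhenius points."""

    E: float
    M: float
    se_E: float | None
    r2: float
    n: int
    rss: float

    def ci_E(self, level: float = 0.95) -> tuple[float, float] | None:
        """Two-sided t confidence interval on E; None when the SE is undefined."""
        if self.se_E is None or self.n <= 2:
            return None
        tq = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.E - tq * self.se_E, self.E + tq * self.se_E)


@dataclass
class SegmentedFit:
    """Two independent Arrhenius regimes split at a temperature cut.

    ``break_after_temperature_C`` is the highest temperature assigned to the
    low-temperature segment.
    """

    break_after_temperature_C: float
    low: ArrheniusFit
    high: ArrheniusFit
    pooled_rss: float
    f_stat: float | None = None
    p_value: float | None = None


def arrhenius_transform(
    temperature_C: float, rate: float, boltzmann_eV_per_K: float = BOLTZMANN_EV_PER_K
) -> ArrheniusPoint:
    """Map (degC, rate) to the (x, y) = (-1/(R*T_K), ln rate) plane."""
    if rate <= 0:
        raise ThermoError(f"rate must be > 0 for log transform, got {rate}")
    t_k = temperature_C + 273.15
    if t_k <= 0:
        raise ThermoError("absolute temperature must be positive")
    return ArrheniusPoint(
        temperature_K=t_k,
        rate=float(rate),
        x=-1.0 / (boltzmann_eV_per_K * t_k),
        y=math.log(rate),
    )


def transform_rates(
    rates: Iterable[RateEstimate], boltzmann_eV_per_K: float = BOLTZMANN_EV_PER_K
) -> list[ArrheniusPoint]:
    """Transform rate estimates, excluding non-positive rates with a warning."""
    pts = []
    for r in rates:
        if r.p_max <= 0:
            logger.warning(
                "excluding non-positive rate at %.1f degC from Arrhenius fit",
                r.temperature_C,
            )
            continue
        pts.append(arrhenius_transform(r.temperature_C, r.p_max, boltzmann_eV_per_K))
    return pts


def fit_single(points: Sequence[ArrheniusPoint]) -> ArrheniusFit:
    """OLS of y on x. E = slope, M = intercept; se_E is None when n = 2."""
    if len(points) < 2:
        raise ThermoError("need at least 2 points")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0:
        raise ThermoError("need at least 2 distinct temperatures")
    n = len(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # linregress warns on n=2 perfect fits
        res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    se = None if n == 2 else float(res.stderr)
    return ArrheniusFit(E=float(res.slope), M=float(res.intercept), se_E=se, r2=r2, n=n, rss=rss)


def fit_segmented(points: Sequence[ArrheniusPoint], min_points: int = 2) -> SegmentedFit:
    """Exhaustive breakpoint search over cuts between distinct temperatures.

    Every cut leaving >= min_points on each side is scored by the pooled RSS of
    two independent OLS fits; ties go to the more balanced split, then to the
    lower break temperature.
    """
    if len(points) < 2 * min_points:
        raise ThermoError(
            f"need at least {2 * min_points} points for a segmented fit"
        )
    pts = sorted(points, key=lambda p: p.temperature_K)
    temps = np.array([p.temperature_K for p in pts])
    distinct = np.unique(temps)
    best: SegmentedFit | None = None
    best_key: tuple | None = None
    for cut_temp in distinct[:-1]:
        low_idx = temps <= cut_temp
        n_low = int(low_idx.sum())
        n_high = len(pts) - n_low
        if n_low < min_points or n_high < min_points:
            continue
        low_pts = [p for p, m in zip(pts, low_idx) if m]
        high_pts = [p for p, m in zip(pts, low_idx) if not m]
        try:
            low_fit = fit_single(low_pts)
            high_fit = fit_single(high_pts)
        except ThermoError:
            continue  # a side with a single distinct temperature
        pooled = low_fit.rss + high_fit.rss
        # tie-break: smaller pooled RSS, then more balanced split, then lower cut
        key = (pooled, abs(n_low - n_high), cut_temp)
        if best_key is None or key < best_key:
            best_key = key
            best = SegmentedFit(
                break_after_temperature_C=float(cut_temp - 273.15),
                low=low_fit,
                high=high_fit,
                pooled_rss=pooled,
            )
    if best is None:
        raise ThermoError("no admissible cut (too few points per side)")
    return best


def select_model(
    single: ArrheniusFit, segmented: SegmentedFit, alpha: float = 0.05
) -> str:
    """Extra-sum-of-squares F-test between one and two Arrhenius regimes.

    F = ((rss1 - rss2)/2) / (rss2/(n-4)) with n the shared point count.
    Returns "segmented" iff p < alpha. Degenerate zero-RSS cases short-circuit:
    both zero -> "single" (the simpler model explains everything); only the
    segmented RSS zero -> "segmented". Raises :class:`FTestUndefinedError`
    when n <= 4; the caller should then report the single fit with a warning.
    """
    n = single.n
    rss1, rss2 = single.rss, segmented.pooled_rss
    scale = max(rss1, rss2, 1.0)
    if rss2 <= _RSS_ATOL * scale or rss2 <= _RSS_ATOL:
        if rss1 <= _RSS_ATOL * scale or rss1 <= _RSS_ATOL:
            segmented.f_stat, segmented.p_value = 0.0, 1.0
            return "single"
        if n > 4:
            segmented.f_stat, segmented.p_value = math.inf, 0.0
            return "segmented"
    if n <= 4:
        raise FTestUndefinedError(
            f"F-test undefined with n={n} points and 4 segmented parameters"
        )
    f = ((rss1 - rss2) / 2.0) / (rss2 / (n - 4))
    f = max(f, 0.0)
    p = float(stats.f.sf(f, 2, n - 4))
    segmented.f_stat, segmented.p_value = float(f), p
    return "segmented" if p < alpha else "single"


# ---------------------------------------------------------------------------
# qPCR table and rate normalization

@dataclass
class QpcrTable:
    """mcrA copy numbers (x1e6 copies per bottle) by day x temperature.

    ``means`` and ``ses`` are DataFrames indexed by day with temperature (degC)
    columns; not-detected cells are NaN and are *ignored* (never treated as
    zero) when taking column maxima.
    """

    means: pd.DataFrame
    ses: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.means.index.is_monotonic_increasing:
            self.means = self.means.sort_index()
            self.ses = self.ses.sort_index()
        if (self.means.fillna(0) < 0).any().any():
            raise ThermoError("mcrA copy numbers must be >= 0")

    @property
    def temperatures_C(self) -> list[float]:
        return [float(c) for c in self.means.columns]

    def column_max(self, temperature_C: float) -> float:
        """Maximum detected abundance over days at one temperature."""
        col = None
        for c in self.means.columns:
            if math.isclose(float(c), temperature_C):
                col = c
                break
        if col is None:
            raise ThermoError(f"no qPCR column for {temperature_C} degC")
        vals = self.means[col].dropna()
        if vals.empty:
            raise ThermoError(
                f"qPCR column at {temperature_C} degC is entirely not-detected"
            )
        return float(vals.max())


def normalize_rates(
    rates: Iterable[RateEstimate], qpcr: QpcrTable
) -> list[RateEstimate]:
    """Divide each maximal rate by the peak detected mcrA abundance at its
    temperature, yielding a per-capita rate (units/day per 1e6 copies)."""
    out = []
    for r in rates:
        divisor = qpcr.column_max(r.temperature_C)
        out.append(
            RateEstimate(
                temperature_C=r.temperature_C,
                gas=r.gas,
                p_max=r.p_max / divisor,
                window=r.window,
                window_r2=r.window_r2,
                lag_days=r.lag_days,
                se=None if r.se is None else r.se / divisor,
                floored=r.floored,
                n_replicates=r.n_replicates,
            )
        )
    return out
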