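"""Extraction of maximal production rates and lag times from cumulative gas curves.

An anaerobic soil incubation accumulates CH4 (after a temperature-dependent
lag) and CO2 (immediately) in the bottle headspace. The quantity entering the
Arrhenius analysis is the *maximal* slope of the cumulative curve, which
approximates the substrate-unlimited production rate. It is estimated as the
maximum over all contiguous windows of ``window_points`` observations of the
ordinary-least-squares slope of amount vs time within the window; the lag is
the time-axis intercept of the tangent line through that window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

GAS_LABELS = ("ch4", "co2", "h2")


class KineticsError(ValueError):
    """Invalid input to a rate/lag extraction."""


class LagUndefinedError(KineticsError):
    """Signalled when the maximal rate is zero and no tangent intercept exists."""


@dataclass(frozen=True)
class GasTimeSeries:
    """Cumulative headspace gas observations for one temperature x replicate.

    Times are in days and must be strictly increasing; gas amounts are
    cumulative, non-negative, in any consistent unit (the Arrhenius slope is
    invariant to the unit choice).
    """

    temperature_C: float
    replicate: str
    times: np.ndarray
    ch4: np.ndarray
    co2: np.ndarray
    h2: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("times", "ch4", "co2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.h2 is not None:
            object.__setattr__(self, "h2", np.asarray(self.h2, dtype=float))
        t = self.times
        if t.ndim != 1 or len(t) < 2:
            raise KineticsError("need at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise KineticsError(
                f"times must be strictly increasing (temperature {self.temperature_C}, "
                f"replicate {self.replicate})"
            )
        for name in ("ch4", "co2"):
            v = getattr(self, name)
            if v.shape != t.shape:
                raise KineticsError(f"{name} length does not match times")
            if np.any(v < 0):
                raise KineticsError(f"negative {name} values")

    def gas(self, label: str) -> np.ndarray:
        label = label.lower()
        if label not in GAS_LABELS:
            raise KineticsError(f"unknown gas label {label!r}; expected one of {GAS_LABELS}")
        v = getattr(self, label)
        if v is None:
            raise KineticsError(f"series has no {label} observations")
        return v


@dataclass
class RateEstimate:
    """Maximal production rate P (gas units / day) and lag for one series.

    ``window`` is the (start, stop) index span (inclusive) of the best window;
    ``floored`` flags a negative best slope floored at zero.
    """

    temperature_C: float
    gas: str
    p_max: float
    window: tuple[int, int]
    window_r2: float
    lag_days: float | None = None
    se: float | None = None
    floored: bool = False
    n_replicates: int = 1


def _window_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and r^2 on one window; r^2 of a 2-point window is 1 by convention."""
    if len(t) == 2:
        return float((y[1] - y[0]) / (t[1] - t[0])), 1.0
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return float(res.slope), r2


def max_rate(series: GasTimeSeries, gas: str, window_points: int = 3) -> RateEstimate:
    """Maximal sliding-window OLS slope of the cumulative curve.

    Negative window slopes compete as candidates but the returned ``p_max``
    is floored at 0 (with ``floored`` set) because a production rate cannot
    be negative.
    """
    if window_points < 2:
        raise KineticsError("window_points must be >= 2")
    y = series.gas(gas)
    t = series.times
    if window_points > len(t):
        raise KineticsError(
            f"window_points={window_points} exceeds series length {len(t)}"
        )
    best_slope = -math.inf
    best = (0, window_points - 1)
    best_r2 = 0.0
    for i in range(len(t) - window_points + 1):
        sl = slice(i, i + window_points)
        slope, r2 = _window_slope(t[sl], y[sl])
        if slope > best_slope:
            best_slope, best, best_r2 = slope, (i, i + window_points - 1), r2
    floored = best_slope < 0
    est = RateEstimate(
        temperature_C=series.temperature_C,
        gas=gas.lower(),
        p_max=max(best_slope, 0.0),
        window=best,
        window_r2=best_r2,
        floored=floored,
    )
    return est


def lag_time(series: GasTimeSeries, gas: str, window_points: int = 3) -> float:
    """Lag: time-axis intercept of the tangent through the maximal-rate window.

    The tangent has slope ``p_max`` and passes through the best window's
    centroid; the intercept is clamped to [0, last time]. Raises
    :class:`LagUndefinedError` when ``p_max`` is zero.
    """
    est = max_rate(series, gas, window_points)
    if est.p_max <= 0:
        raise LagUndefinedError(
            f"lag undefined: zero maximal rate at {series.temperature_C} degC"
        )
    i0, i1 = est.window
    t_c = float(np.mean(series.times[i0 : i1 + 1]))
    y_c = float(np.mean(series.gas(gas)[i0 : i1 + 1]))
    lag = t_c - y_c / est.p_max
    return float(min(max(lag, 0.0), series.times[-1]))


def rates_by_temperature(
    dataset: Iterable[GasTimeSeries], gas: str, window_points: int = 3
) -> list[RateEstimate]:
    """One aggregated RateEstimate per temperature.

    Replicates are independent bottles: the per-temperature rate is the mean of
    per-replicate maxima, with the standard error of that mean recorded (None
    for a single replicate). The lag is likewise the replicate mean, taken over
    replicates where it is defined.
    """
    dataset = list(dataset)
    if not dataset:
        raise KineticsError("empty dataset")
    by_temp: dict[float, list[GasTimeSeries]] = {}
    for s in dataset:
        by_temp.setdefault(float(s.temperature_C), []).append(s)
    out: list[RateEstimate] = []
    for temp in sorted(by_temp):
        group = by_temp[temp]
        ests = [max_rate(s, gas, window_points) for s in group]
        p = np.array([e.p_max for e in ests])
        lags = []
        for s in group:
            try:
                lags.append(lag_time(s, gas, window_points))
            except LagUndefinedError:
                pass
        n = len(p)
        se = float(np.std(p, ddof=1) / math.sqrt(n)) if n > 1 else None
        rep = ests[int(np.argmax(p))]
        out.append(
            RateEstimate(
                temperature_C=temp,
                gas=gas.lower(),
                p_max=float(np.mean(p)),
                window=rep.window,
                window_r2=rep.window_r2,
                lag_days=float(np.mean(lags)) if lags else None,
                se=se,
                floored=any(e.floored for e in ests),
                n_replicates=n,
            )
        )
    return out
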