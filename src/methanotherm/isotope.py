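"""Apparent carbon-isotope fractionation and methanogenic pathway classification.

CH4 produced by CO2 reduction (hydrogenotrophic methanogenesis) is strongly
depleted in 13C relative to CH4 from acetate cleavage, so the apparent
fractionation factor between coexisting CO2 and CH4,

    alpha_app = (d13C-CO2 + 1000) / (d13C-CH4 + 1000),

tracks the balance of the two pathways: values below about 1.03 indicate
aceticlastic dominance, values of 1.04 and above a substantial
hydrogenotrophic contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

LABEL_ACETICLASTIC = "aceticlastic-dominated"
LABEL_MIXED = "mixed/hydrogenotrophic-enriched"
LABEL_INDETERMINATE = "indeterminate"

#: physical lower bound of the delta scale (per mil): all 13C removed
DELTA_FLOOR = -1000.0


class IsotopeError(ValueError):
    pass


@dataclass
class IsotopeRecord:
    """Paired d13C of CH4 and CO2 (per mil vs VPDB) at one temperature and day."""

    temperature_C: float
    day: float
    d13c_ch4: float
    d13c_co2: float
    alpha_app: float | None = None

    def __post_init__(self) -> None:
        if self.d13c_ch4 <= DELTA_FLOOR or self.d13c_co2 <= DELTA_FLOOR:
            raise IsotopeError("d13C values must exceed -1000 per mil")


def alpha_app(d13c_co2: float, d13c_ch4: float) -> float:
    """Apparent fractionation factor (d13C-CO2 + 1000)/(d13C-CH4 + 1000)."""
    num = d13c_co2 + 1000.0
    den = d13c_ch4 + 1000.0
    if den <= 0 or num <= 0:
        raise IsotopeError("d13C values must exceed -1000 per mil")
    return num / den


def annotate_alpha(records: Iterable[IsotopeRecord]) -> list[IsotopeRecord]:
    """Fill the alpha_app field of each record in place; returns the list."""
    records = list(records)
    for r in records:
        r.alpha_app = alpha_app(r.d13c_co2, r.d13c_ch4)
    return records


def classify_pathway(
    series: Iterable[IsotopeRecord],
    active_from_day: float = 20.0,
    lower_threshold: float = 1.03,
    mixed_threshold: float = 1.04,
) -> dict[float, str]:
    """Label the dominant pathway per temperature from the active-phase alpha_app.

    The median alpha_app over records at or after ``active_from_day`` (the
    window where CH4 production is most active) is compared against the two
    thresholds: below ``lower_threshold`` -> aceticlastic-dominated, at or
    above ``mixed_threshold`` -> mixed/hydrogenotrophic-enriched, in between
    -> indeterminate.
    """
    by_temp: dict[float, list[float]] = {}
    for r in series:
        if r.day >= active_from_day:
            a = r.alpha_app if r.alpha_app is not None else alpha_app(r.d13c_co2, r.d13c_ch4)
            by_temp.setdefault(float(r.temperature_C), []).append(a)
    if not by_temp:
        raise IsotopeError(
            f"no records at or after day {active_from_day}: empty active window"
        )
    labels: dict[float, str] = {}
    for temp, alphas in sorted(by_temp.items()):
        med = float(np.median(alphas))
        if med < lower_threshold:
            labels[temp] = LABEL_ACETICLASTIC
        elif med >= mixed_threshold:
            labels[temp] = LABEL_MIXED
        else:
            labels[temp] = LABEL_INDETERMINATE
    return labels


def mixing_delta(f_h: float, delta_h: float, delta_a: float) -> float:
    """Two-endmember d13C-CH4 mixture: f_h from CO2 reduction, 1-f_h from acetate."""
    if not 0.0 <= f_h <= 1.0:
        raise IsotopeError(f"hydrogenotrophic fraction must be in [0, 1], got {f_h}")
    return f_h * delta_h + (1.0 - f_h) * delta_a
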