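"""Degree-day phenology from estimated thermal requirements.

Daily heat accumulation above the lower developmental threshold is computed
with the single-sine method: the diurnal temperature course is approximated
by a sine wave between the daily minimum and maximum, and the area above
the threshold is integrated in closed form.  Accumulating the daily
day-degrees until the sum of effective temperatures is reached predicts the
completion date of a developmental stage.  The crossing temperature of two
species' linear rate lines identifies where a higher-threshold but
lower-SET species starts to develop faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .thermal import ThermalRequirement


@dataclass(frozen=True)
class DailyTemperature:
    """Daily minimum/maximum temperature record."""

    date: Date
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValidationError(
                f"{self.date}: t_min ({self.t_min}) exceeds t_max ({self.t_max})"
            )


@dataclass(frozen=True)
class DegreeDaySeries:
    """Accumulated day-degrees above a threshold, with stage completion."""

    table: pd.DataFrame  # columns: date, daily_dd, cumulative_dd
    ldt: float
    set_dd: float
    completion_date: Date | None


@dataclass(frozen=True)
class CrossingResult:
    """Intersection of two linear development-rate lines."""

    t_c: float  # °C
    faster_above: str  # species_id developing faster above t_c


def daily_degree_days_single_sine(day: DailyTemperature, ldt: float) -> float:
    """Day-degrees above ``ldt`` for one day via the single-sine method.

    With m = (t_max + t_min)/2 and w = (t_max - t_min)/2 the diurnal course
    is m + w sin(2 pi tau); integrating its part above the threshold gives

        D = (1/pi) [ (m - ldt)(pi/2 - theta) + w cos(theta) ],
        theta = arcsin((ldt - m)/w),

    reducing to m - ldt when the whole day is above the threshold and to 0
    when it stays below.
    """
    m = 0.5 * (day.t_max + day.t_min)
    w = 0.5 * (day.t_max - day.t_min)
    if day.t_min >= ldt:
        return m - ldt
    if day.t_max <= ldt:
        return 0.0
    theta = math.asin((ldt - m) / w)
    return ((m - ldt) * (math.pi / 2 - theta) + w * math.cos(theta)) / math.pi


def daily_degree_days_average(day: DailyTemperature, ldt: float) -> float:
    """Simple-average method: max(0, mean temperature - ldt)."""
    return max(0.0, 0.5 * (day.t_max + day.t_min) - ldt)


def accumulate_to_completion(
    series: Sequence[DailyTemperature],
    tr: ThermalRequirement,
    method: str = "single_sine",
) -> DegreeDaySeries:
    """Accumulate day-degrees above ``tr.ldt`` until ``tr.set_dd`` is reached.

    The completion date is the first day on which the cumulative sum meets
    the thermal sum (day granularity), or None if it is never reached.
    """
    if not series:
        raise ValidationError("empty temperature series")
    dates = [d.date for d in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError("temperature series must be strictly chronological")
    fn = {"single_sine": daily_degree_days_single_sine,
          "average": daily_degree_days_average}.get(method)
    if fn is None:
        raise ValidationError(f"unknown accumulation method {method!r}")

    daily = np.array([fn(d, tr.ldt) for d in series])
    cumulative = np.cumsum(daily)
    reached = np.flatnonzero(cumulative >= tr.set_dd)
    completion = dates[int(reached[0])] if reached.size else None
    table = pd.DataFrame({"date": dates, "daily_dd": daily, "cumulative_dd": cumulative})
    return DegreeDaySeries(table=table, ldt=tr.ldt, set_dd=tr.set_dd,
                           completion_date=completion)


def crossing_temperature(
    inv: ThermalRequirement, noninv: ThermalRequirement
) -> CrossingResult:
    """Temperature at which the two linear rate lines intersect.

    Solving (T - ldt_I)/SET_I = (T - ldt_N)/SET_N gives

        T_c = (ldt_I SET_N - ldt_N SET_I) / (SET_N - SET_I).

    Above T_c the species with the smaller SET (steeper rate line) develops
    faster; equal SETs mean parallel lines with no finite crossing.
    """
    if inv.set_dd == noninv.set_dd:
        raise ValidationError("parallel rate lines, no finite crossing")
    t_c = (inv.ldt * noninv.set_dd - noninv.ldt * inv.set_dd) / (
        noninv.set_dd - inv.set_dd
    )
    faster = inv if inv.set_dd < noninv.set_dd else noninv
    return CrossingResult(t_c=float(t_c), faster_above=faster.species_id)
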