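"""MSU dispatch decision: operating hours, catchment, single-unit busy logic.

A chronological sweep over the eligible alarms decides, for each one,
whether the mobile unit goes out: the alarm must fall inside the daily
operating window, the patient's zone must lie within the catchment driving
time from the MSU base, and a unit must be free.  Dispatched missions make
the unit busy for the drive out, the on-scene workup and (by default) the
escort to hospital and return to base.  The availability fraction follows
the reporting convention of dispatch studies: dispatches divided by
eligible alarms inside the catchment (alarms outside the catchment are not
offered to the unit at all).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import MIN_PER_DAY, ParameterError, TimeParams
from .cohort import Patient
from .region import RegionSpec
from .times import msu_busy_interval, patient_time_draws

REASONS = ("outside_hours", "outside_catchment", "busy", "strategy_ems_alone")


@dataclass
class ScenarioSpec:
    """One dispatch scenario: base site, daily operating window(s) in clock
    hours, catchment driving-time limit (None = entire region) and strategy."""

    msu_site_id: str
    operating_window: list = field(default_factory=lambda: [(7.0, 23.0)])  # hours of day
    catchment_limit: float | None = None  # minutes; None = unlimited
    strategy: str = "msu_plus_ems"  # or "ems_alone"
    n_units: int = 1
    scenario_id: str = "base"

    def validate(self) -> None:
        for lo, hi in self.operating_window:
            if not (0.0 <= lo <= 24.0 and 0.0 <= hi <= 24.0 and lo < hi):
                raise ParameterError(f"bad operating window ({lo}, {hi})")
        if self.catchment_limit is not None and self.catchment_limit <= 0:
            raise ParameterError("catchment_limit must be positive or None")
        if self.strategy not in ("msu_plus_ems", "ems_alone"):
            raise ParameterError(f"unknown strategy {self.strategy!r}")
        if self.n_units < 1:
            raise ParameterError("n_units must be >= 1")

    def in_window(self, alarm_time_min: float) -> bool:
        hour = (alarm_time_min % MIN_PER_DAY) / 60.0
        return any(lo <= hour < hi for lo, hi in self.operating_window)


@dataclass
class DispatchResult:
    patient_id: int
    msu_dispatched: bool
    reason_if_not: str | None = None


def in_catchment(region: RegionSpec, scenario: ScenarioSpec, zone_id: str) -> bool:
    """True iff the MSU base-to-zone driving time is within the catchment
    limit (inclusive boundary) or the catchment is unlimited."""
    if scenario.catchment_limit is None:
        return True
    return region.travel_time(scenario.msu_site_id, zone_id) <= scenario.catchment_limit


def simulate_availability(
    cohort: list[Patient],
    region: RegionSpec,
    scenario: ScenarioSpec,
    time_params: TimeParams,
    seed: int = 0,
) -> tuple[dict[int, DispatchResult], float]:
    """Chronological sweep over eligible alarms.

    Returns (results keyed by patient_id, availability fraction).  Only
    eligible patients (onset-to-alarm < 6 h) appear in the results.  Reason
    precedence for non-dispatch: outside_hours, outside_catchment, busy.
    Availability = dispatched / eligible alarms inside the catchment (zero
    when no alarm falls inside the catchment).
    """
    scenario.validate()
    eligible = sorted((p for p in cohort if p.eligible), key=lambda p: (p.alarm_time, p.patient_id))
    results: dict[int, DispatchResult] = {}

    if scenario.strategy == "ems_alone":
        for p in eligible:
            results[p.patient_id] = DispatchResult(p.patient_id, False, "strategy_ems_alone")
        return results, 0.0

    free_at = [float("-inf")] * scenario.n_units
    n_dispatched = 0
    n_in_catchment = 0
    for p in eligible:
        inside = in_catchment(region, scenario, p.zone_id)
        n_in_catchment += inside
        if not scenario.in_window(p.alarm_time):
            results[p.patient_id] = DispatchResult(p.patient_id, False, "outside_hours")
            continue
        if not inside:
            results[p.patient_id] = DispatchResult(p.patient_id, False, "outside_catchment")
            continue
        unit = min(range(scenario.n_units), key=lambda u: free_at[u])
        if free_at[unit] > p.alarm_time:
            results[p.patient_id] = DispatchResult(p.patient_id, False, "busy")
            continue
        draws = patient_time_draws(seed, p.patient_id, time_params)
        busy = msu_busy_interval(p, region, scenario.msu_site_id, time_params, draws=draws)
        free_at[unit] = p.alarm_time + busy
        results[p.patient_id] = DispatchResult(p.patient_id, True)
        n_dispatched += 1

    frac = n_dispatched / n_in_catchment if n_in_catchment else 0.0
    return results, frac


def dispatch_log_frame(results: dict[int, DispatchResult]) -> pd.DataFrame:
    rows = sorted(results.values(), key=lambda r: r.patient_id)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "msu_dispatched": [r.msu_dispatched for r in rows],
            "reason": [r.reason_if_not or "" for r in rows],
        }
    )
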