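"""Virtual one-year cohort of suspected-stroke presentations.

Counts per (zone, age band) are Poisson with mean population x age-specific
suspected-stroke rate.  Each presentation gets an age (uniform within its
band), a diagnosis (mimic / TIA / ICH / ischemic with or without large
vessel occlusion), an onset-to-alarm delay and a clock alarm time over the
year.  Patients are eligible for the model when onset-to-alarm < 6 h.

Diagnosis and conditional-LVO assignment are stored as latent uniform draws
(``dx_u``, ``lvo_u``) alongside the realised labels so sensitivity analyses
can re-threshold the same cohort under perturbed case-mix probabilities with
common random numbers.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AGE_BAND_EDGES,
    ELIGIBILITY_WINDOW_MIN,
    MIN_PER_YEAR,
    N_AGE_BANDS,
    EpidemiologyParams,
)
from .region import RegionSpec

DIAGNOSES = ("mimic", "tia", "ich", "ischemic_nonlvo", "ischemic_lvo")


@dataclass
class Patient:
    patient_id: int
    age: float
    zone_id: str
    diagnosis: str
    onset_to_alarm: float  # minutes
    alarm_time: float  # minutes since year start
    dx_u: float  # latent uniform behind the diagnosis label
    lvo_u: float  # latent uniform behind the LVO assignment

    @property
    def eligible(self) -> bool:
        return self.onset_to_alarm < ELIGIBILITY_WINDOW_MIN

    @property
    def ischemic(self) -> bool:
        return self.diagnosis in ("ischemic_nonlvo", "ischemic_lvo")


def classify(dx_u: float, lvo_u: float, epi: EpidemiologyParams) -> str:
    """Map the latent uniforms to a diagnosis under the given case-mix.

    Threshold order: mimic, TIA, ICH, remainder ischemic; among ischemic,
    LVO iff lvo_u < p_lvo_given_ischemic.
    """
    c1 = epi.p_mimic
    c2 = c1 + epi.p_tia
    c3 = c2 + epi.p_ich
    if dx_u < c1:
        return "mimic"
    if dx_u < c2:
        return "tia"
    if dx_u < c3:
        return "ich"
    return "ischemic_lvo" if lvo_u < epi.p_lvo_given_ischemic else "ischemic_nonlvo"


def _sample_alarm_times(rng: np.random.Generator, n: int, epi: EpidemiologyParams) -> np.ndarray:
    """Alarm clock times over the year; uniform by default, optionally
    weighted by a 24-hour diurnal profile."""
    if epi.diurnal_weights is None:
        return rng.uniform(0.0, MIN_PER_YEAR, n)
    w = np.asarray(epi.diurnal_weights, dtype=float)
    w = w / w.sum()
    day = rng.integers(0, 365, n)
    hour = rng.choice(24, size=n, p=w)
    within = rng.uniform(0.0, 60.0, n)
    return day * 1440.0 + hour * 60.0 + within


def generate_cohort(
    region: RegionSpec, epi: EpidemiologyParams, seed: int = 0
) -> list[Patient]:
    """Draw the one-year virtual cohort; deterministic given seed."""
    epi.validate()
    rng = np.random.default_rng(seed)
    rates = np.asarray(epi.incidence_by_age, dtype=float)

    patients: list[Patient] = []
    pid = 0
    for z in region.zones:
        counts = rng.poisson(z.population_by_age * rates)
        for band, n in enumerate(counts):
            if n == 0:
                continue
            lo = AGE_BAND_EDGES[band]
            hi = lo + 5 if band < N_AGE_BANDS - 1 else lo + 10  # open-ended 95+
            ages = rng.uniform(lo, hi, n)
            dx_u = rng.random(n)
            lvo_u = rng.random(n)
            oa = epi.onset_to_alarm.sample(rng, n)
            alarm = _sample_alarm_times(rng, n, epi)
            for j in range(n):
                patients.append(
                    Patient(
                        patient_id=pid,
                        age=float(ages[j]),
                        zone_id=z.zone_id,
                        diagnosis=classify(float(dx_u[j]), float(lvo_u[j]), epi),
                        onset_to_alarm=float(oa[j]),
                        alarm_time=float(alarm[j]),
                        dx_u=float(dx_u[j]),
                        lvo_u=float(lvo_u[j]),
                    )
                )
                pid += 1
    return patients


def expected_cohort_size(region: RegionSpec, epi: EpidemiologyParams) -> float:
    """Analytic expectation: sum over zones and bands of population x rate."""
    rates = np.asarray(epi.incidence_by_age, dtype=float)
    return float(sum((z.population_by_age * rates).sum() for z in region.zones))


def summarize_cohort(cohort: list[Patient]) -> dict:
    """Counts by diagnosis and eligibility plus median age with IQR
    (order-statistic definition via linear-interpolation percentiles)."""
    n = len(cohort)
    counts = {d: 0 for d in DIAGNOSES}
    n_eligible = 0
    for p in cohort:
        counts[p.diagnosis] += 1
        n_eligible += p.eligible
    out = {
        "n_total": n,
        "n_eligible": n_eligible,
        "eligible_fraction": (n_eligible / n) if n else 0.0,
        "counts_by_diagnosis": counts,
    }
    if n:
        ages = np.array([p.age for p in cohort])
        q25, q50, q75 = np.percentile(ages, [25, 50, 75])
        out.update(median_age=float(q50), age_iqr=(float(q25), float(q75)))
    else:
        out.update(median_age=None, age_iqr=None)
    return out


def cohort_to_frame(cohort: list[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "age": [p.age for p in cohort],
            "zone_id": [p.zone_id for p in cohort],
            "diagnosis": [p.diagnosis for p in cohort],
            "onset_to_alarm_min": [p.onset_to_alarm for p in cohort],
            "alarm_time_min": [p.alarm_time for p in cohort],
            "eligible": [p.eligible for p in cohort],
            "dx_u": [p.dx_u for p in cohort],
            "lvo_u": [p.lvo_u for p in cohort],
        }
    )


def write_cohort(cohort: list[Patient], path) -> None:
    # %.17g keeps the write->read round trip bit-exact for float64 columns
    cohort_to_frame(cohort).to_csv(Path(path), index=False, float_format="%.17g")


def read_cohort(path) -> list[Patient]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        Patient(
            patient_id=int(r["patient_id"]),
            age=float(r["age"]),
            zone_id=str(r["zone_id"]),
            diagnosis=str(r["diagnosis"]),
            onset_to_alarm=float(r["onset_to_alarm_min"]),
            alarm_time=float(r["alarm_time_min"]),
            dx_u=float(r["dx_u"]),
            lvo_u=float(r["lvo_u"]),
        )
        for _, r in df.iterrows()
    ]
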