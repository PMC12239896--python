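"""Onset-to-treatment time composition under both dispatch strategies.

Timeline per arm (minutes from stroke onset):

MSU arm (prehospital workup, IVT on scene):
  ott_ivt = onset_to_alarm + (mobilisation + drive site->zone) + scene-to-needle
  ott_evt = onset_to_alarm + dispatch_to_arrival + total on-scene
            + drive zone->nearest TSC + door-to-groin (pre-notification factor)

EMS arm (workup in hospital):
  ott_ivt = onset_to_alarm + dispatch_to_arrival + on-scene
            + drive zone->nearest hospital + door-to-needle
  ott_evt, nearest hospital thrombectomy-capable:
            ... arrival + door-to-groin
  ott_evt, nearest hospital primary (drip-and-ship):
            ... arrival at PSC + door-in-door-out + transfer drive
            + handover + door-to-groin at the TSC

Per-patient stochastic components (mobilisation, on-scene times) are drawn
from a patient-keyed stream so the two strategies and the dispatch
availability sweep see identical draws (common random numbers).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TimeParams
from .cohort import Patient
from .region import ConfigurationError, RegionSpec, nearest_hospital, nearest_site

ROUTINGS = ("msu_direct_tsc", "msu_to_psc", "ems_direct_tsc", "ems_via_psc", "ems_to_psc")


@dataclass
class TimeBreakdown:
    """Per-patient time components for one strategy arm (minutes).

    ``ott_evt`` fields describe the endovascular pathway as it would run for
    a large-vessel occlusion; they are None when the region has no
    thrombectomy-capable center.  ``routing`` reflects the patient's
    realised diagnosis.
    """

    patient_id: int
    msu_dispatched: bool
    onset_to_alarm: float
    dispatch_to_arrival: float
    on_scene: float
    scene_to_hospital: float
    dtn: float | None
    dido: float | None
    transfer: float | None
    dtg: float | None
    ott_ivt: float
    ott_evt: float | None
    routing: str
    hospital_id: str
    evt_hospital_id: str | None


def patient_time_draws(seed: int, patient_id: int, params: TimeParams) -> dict:
    """Common-random-number component draws for one patient.

    The stream is keyed by (seed, patient_id) only, never by strategy, so a
    patient's mobilisation and on-scene draws are identical across arms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, patient_id]))
    return {
        "ems_mob": float(params.ems_mobilization.sample(rng)),
        "msu_mob": float(params.msu_mobilization.sample(rng)),
        "ems_on_scene": float(params.ems_on_scene.sample(rng)),
        "msu_needle": float(params.msu_on_scene_to_needle.sample(rng)),
        "msu_post": float(params.msu_post_needle_on_scene.sample(rng)),
        "u_ivt": float(rng.random()),
        "u_evt": float(rng.random()),
    }


def pathway_times(
    patient: Patient,
    msu_dispatched: bool,
    region: RegionSpec,
    msu_site_id: str,
    params: TimeParams,
    seed: int = 0,
    draws: dict | None = None,
) -> TimeBreakdown:
    """Compose the full time breakdown for one patient in one arm."""
    d = draws if draws is not None else patient_time_draws(seed, patient.patient_id, params)
    oa = patient.onset_to_alarm
    zid = patient.zone_id
    has_tsc = any(h.tsc for h in region.hospitals)
    if patient.diagnosis == "ischemic_lvo" and not has_tsc:
        raise ConfigurationError("LVO pathway requires a thrombectomy-capable center")

    ems_site = nearest_site(region, zid)
    ems_d2a = d["ems_mob"] + region.travel_time(ems_site.site_id, zid)

    if msu_dispatched:
        d2a = d["msu_mob"] + region.travel_time(msu_site_id, zid)
        needle = d["msu_needle"]
        on_scene_total = needle + d["msu_post"]
        ott_ivt = oa + d2a + needle
        depart_base = max(d2a, ems_d2a) if params.sync_transport_with_ems else d2a

        nearest = nearest_hospital(region, zid, require_tsc=False)
        if has_tsc:
            tsc = nearest_hospital(region, zid, require_tsc=True)
            drive_tsc = region.travel_time(zid, tsc.hospital_id)
            dtg = tsc.door_to_groin * params.msu_dtg_factor
            ott_evt = oa + depart_base + on_scene_total + drive_tsc + dtg
            evt_hosp = tsc.hospital_id
        else:
            drive_tsc = dtg = ott_evt = evt_hosp = None

        lvo = patient.diagnosis == "ischemic_lvo"
        routing = "msu_direct_tsc" if lvo else "msu_to_psc"
        dest = evt_hosp if lvo else nearest.hospital_id
        scene_to_hosp = drive_tsc if lvo else region.travel_time(zid, nearest.hospital_id)
        return TimeBreakdown(
            patient_id=patient.patient_id,
            msu_dispatched=True,
            onset_to_alarm=oa,
            dispatch_to_arrival=d2a,
            on_scene=on_scene_total,
            scene_to_hospital=float(scene_to_hosp),
            dtn=None,
            dido=None,
            transfer=None,
            dtg=None if dtg is None else float(dtg),
            ott_ivt=float(ott_ivt),
            ott_evt=None if ott_evt is None else float(ott_evt),
            routing=routing,
            hospital_id=dest,
            evt_hospital_id=evt_hosp,
        )

    # EMS-only pathway
    nearest = nearest_hospital(region, zid, require_tsc=False)
    drive = region.travel_time(zid, nearest.hospital_id)
    arrival = oa + ems_d2a + d["ems_on_scene"] + drive
    ott_ivt = arrival + nearest.door_to_needle

    dido = transfer = dtg = ott_evt = None
    evt_hosp = None
    if has_tsc:
        if nearest.tsc:
            dtg = nearest.door_to_groin
            ott_evt = arrival + dtg
            evt_hosp = nearest.hospital_id
            evt_routing = "ems_direct_tsc"
        else:
            tsc = nearest_hospital(region, zid, require_tsc=True)
            dido = nearest.door_in_door_out
            transfer = region.transfer_time(nearest.hospital_id, tsc.hospital_id) + params.transfer_handover
            dtg = tsc.door_to_groin
            ott_evt = arrival + dido + transfer + dtg
            evt_hosp = tsc.hospital_id
            evt_routing = "ems_via_psc"
    else:
        evt_routing = "ems_to_psc"

    lvo = patient.diagnosis == "ischemic_lvo"
    routing = evt_routing if lvo else "ems_to_psc"
    return TimeBreakdown(
        patient_id=patient.patient_id,
        msu_dispatched=False,
        onset_to_alarm=oa,
        dispatch_to_arrival=ems_d2a,
        on_scene=d["ems_on_scene"],
        scene_to_hospital=float(drive),
        dtn=float(nearest.door_to_needle),
        dido=None if dido is None else float(dido),
        transfer=None if transfer is None else float(transfer),
        dtg=None if dtg is None else float(dtg),
        ott_ivt=float(ott_ivt),
        ott_evt=None if ott_evt is None else float(ott_evt),
        routing=routing,
        hospital_id=nearest.hospital_id,
        evt_hospital_id=evt_hosp,
    )


def msu_busy_interval(
    patient: Patient,
    region: RegionSpec,
    msu_site_id: str,
    params: TimeParams,
    seed: int = 0,
    draws: dict | None = None,
) -> float:
    """Minutes the unit is unavailable after dispatch: drive to scene,
    total on-scene time, and (when the unit escorts the transport) the legs
    to the receiving hospital and back to base.  The return leg retraces
    hospital->zone->base because the travel matrix only covers site<->zone
    and zone<->hospital pairs."""
    d = draws if draws is not None else patient_time_draws(seed, patient.patient_id, params)
    to_scene = d["msu_mob"] + region.travel_time(msu_site_id, patient.zone_id)
    on_scene = d["msu_needle"] + d["msu_post"]
    busy = to_scene + on_scene
    if params.msu_escorts_to_hospital:
        if patient.diagnosis == "ischemic_lvo" and any(h.tsc for h in region.hospitals):
            dest = nearest_hospital(region, patient.zone_id, require_tsc=True)
        else:
            dest = nearest_hospital(region, patient.zone_id, require_tsc=False)
        leg = region.travel_time(patient.zone_id, dest.hospital_id)
        busy += 2.0 * leg + region.travel_time(msu_site_id, patient.zone_id)
    else:
        busy += region.travel_time(msu_site_id, patient.zone_id)  # straight back to base
    return float(busy)


def time_savings_summary(
    ems: dict[int, TimeBreakdown],
    msu: dict[int, TimeBreakdown],
    cohort: list[Patient],
    dispatched: set[int],
) -> dict:
    """Median onset-to-treatment advantage (EMS minus MSU, minutes) among
    MSU-dispatched ischemic patients, by subgroup: non-LVO (thrombolysis
    clock), LVO with EMS routing direct to a thrombectomy-capable center,
    and LVO that EMS would have routed drip-and-ship via a primary center.
    Empty subgroups are reported as None."""
    nonlvo, lvo_direct, lvo_via = [], [], []
    for p in cohort:
        if p.patient_id not in dispatched or not p.ischemic:
            continue
        e, m = ems[p.patient_id], msu[p.patient_id]
        if p.diagnosis == "ischemic_nonlvo":
            nonlvo.append(e.ott_ivt - m.ott_ivt)
        elif e.ott_evt is not None and m.ott_evt is not None:
            (lvo_direct if e.routing == "ems_direct_tsc" else lvo_via).append(e.ott_evt - m.ott_evt)

    def med(v):
        return float(np.median(v)) if v else None

    return {
        "nonlvo_ivt_saving_min": med(nonlvo),
        "lvo_direct_tsc_evt_saving_min": med(lvo_direct),
        "lvo_via_psc_evt_saving_min": med(lvo_via),
        "n_nonlvo": len(nonlvo),
        "n_lvo_direct": len(lvo_direct),
        "n_lvo_via_psc": len(lvo_via),
    }


def count_avoided_transfers(
    cohort: list[Patient], region: RegionSpec, dispatched: set[int]
) -> int:
    """LVO patients with an MSU dispatch whose nearest hospital is a primary
    center: each avoids one drip-and-ship interhospital transfer."""
    n = 0
    for p in cohort:
        if p.patient_id in dispatched and p.diagnosis == "ischemic_lvo":
            if not nearest_hospital(region, p.zone_id, require_tsc=False).tsc:
                n += 1
    return n
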