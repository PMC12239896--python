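import numpy as np
import pytest

from msu_cea import ConfigurationError, pathway_times, patient_time_draws
from msu_cea.times import count_avoided_transfers, time_savings_summary

from conftest import fixed_times, make_patient, toy_via_psc_region, zero_time_region


def _zeroed_times():
    from msu_cea.config import fixed

    return fixed_times(
        ems_mobilization=fixed(0.0),
        msu_mobilization=fixed(0.0),
        ems_on_scene=fixed(0.0),
        msu_on_scene_to_needle=fixed(0.0),
        msu_post_needle_on_scene=fixed(0.0),
        transfer_handover=0.0,
    )


def test_all_zero_components_reduce_ott_to_onset_to_alarm():
    region = zero_time_region()
    p = make_patient(onset_to_alarm=77.0)
    for msu in (False, True):
        bd = pathway_times(p, msu, region, "S0", _zeroed_times())
        assert bd.ott_ivt == pytest.approx(77.0)


def test_via_psc_timeline_matches_hand_trace():
    """EMS drip-and-ship: alarm 60 + mob 2 + drive-out 5 + scene 15 +
    drive 20 -> PSC arrival 102; needle 122 (DTN 20); DIDO 30 + transfer 5 +
    handover 10 -> groin at 177 (DTG 30)."""
    region = toy_via_psc_region()
    p = make_patient(diagnosis="ischemic_lvo", onset_to_alarm=60.0)
    bd = pathway_times(p, False, region, "S0", fixed_times())
    assert bd.routing == "ems_via_psc"
    assert bd.ott_ivt == pytest.approx(60 + 2 + 5 + 15 + 20 + 20)
    assert bd.ott_evt == pytest.approx(60 + 2 + 5 + 15 + 20 + 30 + 5 + 10 + 30)
    # component-sum identity re-added from the parts
    assert bd.ott_evt == pytest.approx(
        bd.onset_to_alarm + bd.dispatch_to_arrival + bd.on_scene
        + bd.scene_to_hospital + bd.dido + bd.transfer + bd.dtg
    )
    assert bd.ott_ivt == pytest.approx(
        bd.onset_to_alarm + bd.dispatch_to_arrival + bd.on_scene
        + bd.scene_to_hospital + bd.dtn
    )


def test_msu_direct_to_tsc_timeline_matches_hand_trace():
    """MSU arm: alarm 60 + mob 3 + drive 5 -> scene at 68; needle at 98;
    departure at 108 (total on-scene 40); TSC arrival 148; groin 178."""
    region = toy_via_psc_region()
    p = make_patient(diagnosis="ischemic_lvo", onset_to_alarm=60.0)
    bd = pathway_times(p, True, region, "S0", fixed_times())
    assert bd.routing == "msu_direct_tsc"
    assert bd.ott_ivt == pytest.approx(60 + 3 + 5 + 30)
    assert bd.ott_evt == pytest.approx(60 + 3 + 5 + 40 + 40 + 30)


def test_msu_ivt_faster_when_scene_needle_beats_hospital_path():
    """With identical mobilisation draws, the MSU thrombolysis clock beats
    EMS whenever scene-to-needle < on-scene + drive + door-to-needle."""
    region = toy_via_psc_region()
    p = make_patient(diagnosis="ischemic_nonlvo", onset_to_alarm=60.0)
    params = fixed_times()
    d = patient_time_draws(0, p.patient_id, params)
    ems = pathway_times(p, False, region, "S0", params, draws=d)
    msu = pathway_times(p, True, region, "S0", params, draws=d)
    # 30 < 15 + 20 + 20, minus the 1-minute dispatch handicap of the MSU
    assert msu.ott_ivt < ems.ott_ivt


def test_removing_dido_and_transfer_shrinks_saving_by_exactly_those_parts():
    region = toy_via_psc_region()
    p = make_patient(diagnosis="ischemic_lvo", onset_to_alarm=60.0)
    full = fixed_times()
    ems_full = pathway_times(p, False, region, "S0", full)
    region2 = toy_via_psc_region()
    region2.hospitals[0].door_in_door_out = 0.0
    region2.travel[("H_PSC", "H_TSC")] = 0.0
    nodido = fixed_times(transfer_handover=0.0)
    ems_cut = pathway_times(p, False, region2, "S0", nodido)
    assert ems_full.ott_evt - ems_cut.ott_evt == pytest.approx(30 + 5 + 10)


def test_lvo_without_tsc_raises():
    region = zero_time_region()
    region.hospitals = [h for h in region.hospitals if not h.tsc]
    p = make_patient(diagnosis="ischemic_lvo")
    with pytest.raises(ConfigurationError):
        pathway_times(p, False, region, "S0", fixed_times())


def test_common_random_numbers_shared_across_strategies(region_small, default_cfg):
    p = make_patient(zone_id=region_small.zones[0].zone_id)
    d = patient_time_draws(5, p.patient_id, default_cfg.times)
    ems = pathway_times(p, False, region_small, "S00", default_cfg.times, draws=d)
    msu = pathway_times(p, True, region_small, "S00", default_cfg.times, draws=d)
    assert ems.onset_to_alarm == msu.onset_to_alarm
    # and the draw stream itself is strategy-independent
    assert patient_time_draws(5, p.patient_id, default_cfg.times) == d


class TestSavingsSummary:
    def _breakdowns(self, region, cohort, params, seed=0):
        ems, msu = {}, {}
        for p in cohort:
            d = patient_time_draws(seed, p.patient_id, params)
            ems[p.patient_id] = pathway_times(p, False, region, "S0", params, draws=d)
            msu[p.patient_id] = pathway_times(p, True, region, "S0", params, draws=d)
        return ems, msu

    def test_identical_arms_give_zero_savings(self):
        """If the MSU pathway is parameterised to mimic EMS exactly (same
        mobilisation, needle clock equal to scene + drive + DTN, neutral
        DTG factor), all subgroup savings vanish."""
        from msu_cea.config import fixed

        region = toy_via_psc_region()
        params = fixed_times(
            msu_mobilization=fixed(2.0),
            msu_on_scene_to_needle=fixed(15.0 + 20.0 + 20.0),
            msu_post_needle_on_scene=fixed(0.0),
        )
        cohort = [make_patient(0, diagnosis="ischemic_nonlvo")]
        ems, msu = self._breakdowns(region, cohort, params)
        s = time_savings_summary(ems, msu, cohort, {0})
        assert s["nonlvo_ivt_saving_min"] == pytest.approx(0.0)

    def test_savings_independent_of_cohort_ordering(self, region_small, default_cfg):
        zones = [z.zone_id for z in region_small.zones]
        cohort = [
            make_patient(i, zone_id=zones[i % len(zones)],
                         diagnosis="ischemic_nonlvo" if i % 2 else "ischemic_lvo")
            for i in range(12)
        ]
        ems, msu = {}, {}
        for p in cohort:
            d = patient_time_draws(1, p.patient_id, default_cfg.times)
            ems[p.patient_id] = pathway_times(p, False, region_small, "S00", default_cfg.times, draws=d)
            msu[p.patient_id] = pathway_times(p, True, region_small, "S00", default_cfg.times, draws=d)
        disp = {p.patient_id for p in cohort}
        s1 = time_savings_summary(ems, msu, cohort, disp)
        s2 = time_savings_summary(ems, msu, list(reversed(cohort)), disp)
        assert s1 == s2

    def test_empty_subgroup_reported_as_missing(self):
        region = toy_via_psc_region()
        cohort = [make_patient(0, diagnosis="ischemic_nonlvo")]
        ems, msu = self._breakdowns(region, cohort, fixed_times())
        s = time_savings_summary(ems, msu, cohort, {0})
        assert s["lvo_direct_tsc_evt_saving_min"] is None
        assert s["n_lvo_via_psc"] == 0


def test_avoided_transfer_count_is_dispatched_lvo_nearest_psc():
    region = toy_via_psc_region()
    cohort = [
        make_patient(0, diagnosis="ischemic_lvo"),
        make_patient(1, diagnosis="ischemic_lvo"),
        make_patient(2, diagnosis="ischemic_nonlvo"),
    ]
    # only dispatched LVO patients whose nearest hospital is the PSC count
    assert count_avoided_transfers(cohort, region, {0, 2}) == 1
    assert count_avoided_transfers(cohort, region, {0, 1}) == 2
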