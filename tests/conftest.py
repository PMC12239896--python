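import numpy as np
import pytest

from msu_cea import (
    DispatchSite,
    Hospital,
    Patient,
    RegionSpec,
    TimeParams,
    Zone,
    default_config,
    generate_cohort,
    generate_synthetic_region,
)
from msu_cea.config import N_AGE_BANDS, fixed


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def region_small():
    """Small synthetic region: 3 primary + 2 thrombectomy-capable centers."""
    return generate_synthetic_region(
        n_zones=15, n_psc=3, n_tsc=2, n_sites=2, total_population=120_000,
        area_km2=400.0, seed=11,
    )


@pytest.fixture(scope="session")
def cohort_small(region_small, default_cfg):
    return generate_cohort(region_small, default_cfg.epidemiology, seed=12)


def make_zone(zone_id="Z0", x=0.0, y=0.0, pop_total=1000.0, band=15):
    pops = np.zeros(N_AGE_BANDS)
    pops[band] = pop_total
    return Zone(zone_id, x, y, pops)


def make_patient(pid=0, age=74.0, zone_id="Z0", diagnosis="ischemic_nonlvo",
                 onset_to_alarm=60.0, alarm_time=600.0, dx_u=0.9, lvo_u=0.9):
    return Patient(pid, age, zone_id, diagnosis, onset_to_alarm, alarm_time, dx_u, lvo_u)


def fixed_times(**overrides) -> TimeParams:
    """Deterministic time parameters for hand-traceable timelines."""
    base = dict(
        ems_mobilization=fixed(2.0),
        msu_mobilization=fixed(3.0),
        ems_on_scene=fixed(15.0),
        msu_on_scene_to_needle=fixed(30.0),
        msu_post_needle_on_scene=fixed(10.0),
        transfer_handover=10.0,
        msu_dtg_factor=1.0,
    )
    base.update(overrides)
    return TimeParams(**base)


def toy_via_psc_region() -> RegionSpec:
    """One zone, one PSC 20 min away, one TSC 40 min away, explicit 5-min
    interhospital transfer leg; dispatch site 5 min from the zone."""
    zone = make_zone("Z0", 0.0, 0.0, 1000.0)
    psc = Hospital("H_PSC", 1.0, 0.0, False, door_to_needle=20.0, door_in_door_out=30.0)
    tsc = Hospital("H_TSC", 2.0, 0.0, True, door_to_needle=20.0, door_to_groin=30.0)
    site = DispatchSite("S0", 0.5, 0.0, msu_capable=True)
    travel = {
        ("S0", "Z0"): 5.0,
        ("Z0", "H_PSC"): 20.0,
        ("Z0", "H_TSC"): 40.0,
        ("H_PSC", "H_TSC"): 5.0,
    }
    region = RegionSpec([zone], [psc, tsc], [site], travel)
    region.validate()
    return region


def zero_time_region() -> RegionSpec:
    """Degenerate region where every leg and workflow time is zero."""
    zone = make_zone("Z0", 0.0, 0.0, 100.0)
    psc = Hospital("H0", 0.0, 0.0, False, door_to_needle=0.0, door_in_door_out=0.0)
    tsc = Hospital("H1", 0.0, 0.0, True, door_to_needle=0.0, door_to_groin=0.0)
    site = DispatchSite("S0", 0.0, 0.0, msu_capable=True)
    travel = {("S0", "Z0"): 0.0, ("Z0", "H0"): 0.0, ("Z0", "H1"): 0.0}
    region = RegionSpec([zone], [psc, tsc], [site], travel)
    region.validate()
    return region
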