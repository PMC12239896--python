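"""Strategy evaluation, probabilistic sensitivity analysis, scenario grid,
tornado analysis and result export.

The evaluation engine compares the MSU+EMS strategy with EMS-alone on the
same virtual cohort with common random numbers: identical onset-to-alarm
delays, time-component draws, diagnosis latents and treatment-receipt
uniforms in both arms, so the strategies differ only through dispatch,
routing and the resulting treatment times.  Per-patient lifetime value is
taken in expectation over the 90-day mRS distribution (probability-weighted
table lookup), which removes first-order Monte-Carlo noise from the
strategy deltas; the drawn-state microsimulation path exists in
``lifetime_econ`` and is validated against this expectation in the tests.

The PSA redraws uncertain parameters per iteration (beta for
probabilities, gamma for costs and normal for treatment-effect log-odds by
default), holds the cohort fixed, and pools iterations across independent
runs; 95% intervals are 2.5/97.5 percentiles of the pooled draws.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Patient
from .config import ModelConfig, ParameterError
from .dispatch import ScenarioSpec, simulate_availability
from .lifetime_econ import (
    lifetime_value_table,
    lifetime_value_year_profiles,
    program_cost,
)
from .outcomes import shift_distribution
from .region import RegionSpec, nearest_hospital
from .times import pathway_times, patient_time_draws


def inmb(delta_qaly: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit: delta_QALY x WTP - delta_cost,
    with delta_cost = (MSU strategy cost) - (EMS strategy cost), so cost
    savings (negative delta_cost) increase the benefit."""
    return delta_qaly * wtp - delta_cost


# ---------------------------------------------------------------------------
# cohort precomputation (fixed across PSA iterations)


@dataclass
class PrecomputedCohort:
    """Per-eligible-patient arrays that do not change across parameter
    draws: ages, latent uniforms, and onset-to-treatment times under both
    arms (EVT times computed along the large-vessel-occlusion routing)."""

    patients: list[Patient]
    age: np.ndarray
    age_idx: np.ndarray  # index into unique_ages
    unique_ages: np.ndarray
    dx_u: np.ndarray
    lvo_u: np.ndarray
    u_ivt: np.ndarray
    u_evt: np.ndarray
    ott_ivt_ems: np.ndarray
    ott_evt_ems: np.ndarray  # nan when no TSC
    ott_ivt_msu: np.ndarray
    ott_evt_msu: np.ndarray
    ems_via_psc: np.ndarray  # nearest hospital is a primary center
    msu_site_id: str


def precompute_cohort(
    region: RegionSpec,
    cohort: list[Patient],
    cfg: ModelConfig,
    msu_site_id: str,
    seed: int,
) -> PrecomputedCohort:
    pts = [p for p in cohort if p.eligible]
    n = len(pts)
    a = np.array([p.age for p in pts])
    age_int = np.floor(a).astype(int)
    unique_ages, age_idx = np.unique(age_int, return_inverse=True)
    arrs = {k: np.full(n, np.nan) for k in ("ott_ivt_ems", "ott_evt_ems", "ott_ivt_msu", "ott_evt_msu")}
    via = np.zeros(n, dtype=bool)
    u_ivt = np.empty(n)
    u_evt = np.empty(n)
    dx_u = np.array([p.dx_u for p in pts])
    lvo_u = np.array([p.lvo_u for p in pts])
    for i, p in enumerate(pts):
        d = patient_time_draws(seed, p.patient_id, cfg.times)
        u_ivt[i], u_evt[i] = d["u_ivt"], d["u_evt"]
        be = pathway_times(p, False, region, msu_site_id, cfg.times, draws=d)
        bm = pathway_times(p, True, region, msu_site_id, cfg.times, draws=d)
        arrs["ott_ivt_ems"][i] = be.ott_ivt
        arrs["ott_ivt_msu"][i] = bm.ott_ivt
        if be.ott_evt is not None:
            arrs["ott_evt_ems"][i] = be.ott_evt
        if bm.ott_evt is not None:
            arrs["ott_evt_msu"][i] = bm.ott_evt
        via[i] = not nearest_hospital(region, p.zone_id, require_tsc=False).tsc
    return PrecomputedCohort(
        patients=pts,
        age=a,
        age_idx=age_idx,
        unique_ages=unique_ages,
        dx_u=dx_u,
        lvo_u=lvo_u,
        u_ivt=u_ivt,
        u_evt=u_evt,
        ems_via_psc=via,
        msu_site_id=msu_site_id,
        **arrs,
    )


# ---------------------------------------------------------------------------
# vectorised strategy evaluation


def _arm_totals(pre, dispatched, cfg, qtab, ctab, is_cat, year_tables=None):
    """Total QALYs and costs for one arm given the dispatch mask."""
    is_mimic, is_tia, is_ich, is_isch, is_lvo = is_cat
    om, econ = cfg.outcome, cfg.economics
    n = len(pre.patients)

    ott_ivt = np.where(dispatched, pre.ott_ivt_msu, pre.ott_ivt_ems)
    ott_evt = np.where(dispatched, pre.ott_evt_msu, pre.ott_evt_ems)

    treated_ivt = is_isch & (ott_ivt < om.ivt_window) & (pre.u_ivt < om.p_ivt_given_eligible)
    evt_ok = ~np.isnan(ott_evt) & (ott_evt < om.evt_window)
    treated_evt = is_lvo & evt_ok & (pre.u_evt < om.p_evt_given_lvo_eligible)

    d_ivt = np.where(treated_ivt, np.maximum(0.0, om.beta_ivt + om.beta_ivt_decay * ott_ivt), 0.0)
    d_evt = np.where(treated_evt, np.maximum(0.0, om.beta_evt + om.beta_evt_decay * np.nan_to_num(ott_evt)), 0.0)
    if om.additive_lvo_effects:
        delta = np.where(is_lvo, d_ivt + d_evt, d_ivt)
    else:
        delta = np.where(is_lvo, np.where(treated_evt, d_evt, d_ivt), d_ivt)

    base = np.empty((n, 7))
    base[is_isch & ~is_lvo] = np.asarray(om.mrs_untreated_nonlvo, float)
    base[is_lvo] = np.asarray(om.mrs_untreated_lvo, float)
    base[is_ich] = np.asarray(om.mrs_ich, float)
    e0 = np.zeros(7)
    e0[0] = 1.0
    base[is_tia] = e0
    base[is_mimic] = e0  # placeholder row; mimics use the nonstroke column below

    dist = shift_distribution(base, np.asarray(delta)[:, None])

    q_states = qtab[pre.age_idx]  # (n, 8)
    c_states = ctab[pre.age_idx]
    qaly = np.where(is_mimic, q_states[:, 7], np.einsum("ij,ij->i", dist, q_states[:, :7]))
    lt_cost = np.where(is_mimic, c_states[:, 7], np.einsum("ij,ij->i", dist, c_states[:, :7]))

    transfer = is_lvo & ~dispatched & pre.ems_via_psc & treated_evt
    acute = (
        econ.acute_ems_ride
        + econ.acute_msu_ride * dispatched
        + econ.acute_ivt * treated_ivt
        + econ.acute_evt * treated_evt
        + econ.acute_interhospital_transfer * transfer
        - econ.acute_ed_visit_deduction * (dispatched & treated_ivt)
    )
    out = {
        "qaly": float(qaly.sum()),
        "cost": float(lt_cost.sum() + acute.sum()),
        "n_treated_ivt": int(treated_ivt.sum()),
        "n_treated_evt": int(treated_evt.sum()),
    }
    if year_tables is not None:
        qy, cy = year_tables  # (n_ages, 8, years)
        w = np.zeros((n, 8))
        w[np.arange(n), 7] = is_mimic
        w[:, :7] = dist * (~is_mimic)[:, None]
        qaly_y = np.einsum("is,isy->y", w, qy[pre.age_idx])
        cost_y = np.einsum("is,isy->y", w, cy[pre.age_idx])
        cost_y[0] += acute.sum()
        out["qaly_by_year"] = qaly_y
        out["cost_by_year"] = cost_y
    return out


def evaluate_strategies(
    pre: PrecomputedCohort,
    dispatched: np.ndarray,
    cfg: ModelConfig,
    tables=None,
    year_tables=None,
    horizon_years: float = 1.0,
) -> dict:
    """Evaluate MSU+EMS vs EMS-alone on the precomputed cohort under one
    parameter set; returns totals, deltas and the net monetary benefit."""
    epi = cfg.epidemiology
    c1 = epi.p_mimic
    c2 = c1 + epi.p_tia
    c3 = c2 + epi.p_ich
    if c3 > 1.0 + 1e-12:
        raise ParameterError("diagnosis probabilities exceed 1")
    is_mimic = pre.dx_u < c1
    is_tia = (pre.dx_u >= c1) & (pre.dx_u < c2)
    is_ich = (pre.dx_u >= c2) & (pre.dx_u < c3)
    is_isch = pre.dx_u >= c3
    is_lvo = is_isch & (pre.lvo_u < epi.p_lvo_given_ischemic)
    is_cat = (is_mimic, is_tia, is_ich, is_isch, is_lvo)

    if tables is None:
        tables = lifetime_value_table(pre.unique_ages, cfg.economics, cfg.mortality)
    qtab, ctab = tables

    msu = _arm_totals(pre, np.asarray(dispatched, bool), cfg, qtab, ctab, is_cat, year_tables)
    ems = _arm_totals(pre, np.zeros(len(pre.patients), bool), cfg, qtab, ctab, is_cat, year_tables)

    prog = program_cost(cfg.economics, horizon_years)
    delta_qaly = msu["qaly"] - ems["qaly"]
    delta_cost = (msu["cost"] + prog) - ems["cost"]
    res = {
        "qaly_msu": msu["qaly"],
        "qaly_ems": ems["qaly"],
        "cost_msu": msu["cost"] + prog,
        "cost_ems": ems["cost"],
        "delta_qaly": delta_qaly,
        "delta_cost": delta_cost,
        "inmb": inmb(delta_qaly, delta_cost, cfg.economics.wtp),
        "n_treated_ivt_msu": msu["n_treated_ivt"],
        "n_treated_ivt_ems": ems["n_treated_ivt"],
        "n_treated_evt_msu": msu["n_treated_evt"],
        "n_treated_evt_ems": ems["n_treated_evt"],
    }
    if year_tables is not None:
        dq = msu["qaly_by_year"] - ems["qaly_by_year"]
        dc = msu["cost_by_year"] - ems["cost_by_year"]
        dc[0] += prog
        res["delta_qaly_by_year"] = dq
        res["delta_cost_by_year"] = dc
        res["cum_inmb_by_year"] = np.cumsum(dq * cfg.economics.wtp - dc)
    return res


def inmb_trajectory(
    pre: PrecomputedCohort, dispatched: np.ndarray, cfg: ModelConfig, n_years: int = 101
) -> pd.DataFrame:
    """Cumulative incremental net monetary benefit by model year at base
    parameter values (programme and acute costs land in year 0)."""
    ytab = lifetime_value_year_profiles(pre.unique_ages, cfg.economics, cfg.mortality, n_years)
    res = evaluate_strategies(pre, dispatched, cfg, year_tables=ytab)
    return pd.DataFrame(
        {
            "year": np.arange(n_years),
            "delta_qaly": res["delta_qaly_by_year"],
            "delta_cost": res["delta_cost_by_year"],
            "cum_inmb": res["cum_inmb_by_year"],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class ScenarioResult:
    scenario_id: str
    n_dispatches: int
    availability_fraction: float
    delta_qaly_mean: float
    delta_qaly_ci: tuple
    delta_cost_mean: float
    delta_cost_ci: tuple
    inmb_mean: float
    inmb_ci: tuple
    draws: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "n_dispatches": self.n_dispatches,
            "availability_fraction": self.availability_fraction,
            "delta_qaly_mean": self.delta_qaly_mean,
            "delta_qaly_ci": list(self.delta_qaly_ci),
            "delta_cost_mean": self.delta_cost_mean,
            "delta_cost_ci": list(self.delta_cost_ci),
            "inmb_mean": self.inmb_mean,
            "inmb_ci": list(self.inmb_ci),
        }


def draw_parameter_configs(cfg: ModelConfig, n: int, seed: int) -> list[ModelConfig]:
    """n parameter sets from the PSA distributions (deterministic given
    seed).  Sets violating the case-mix simplex are redrawn."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    out = []
    for _ in range(n):
        for _attempt in range(100):
            c = cfg.copy()
            for _name, (path, dist) in cfg.psa.items():
                c.set_path(path, float(dist.sample(rng)))
            epi = c.epidemiology
            if epi.p_mimic + epi.p_tia + epi.p_ich <= 1.0:
                break
        out.append(c)
    return out


def _aggregate(scenario_id, n_disp, avail, rows) -> ScenarioResult:
    df = pd.DataFrame(rows)
    run_means = df.groupby("run")[["delta_qaly", "delta_cost", "inmb"]].mean()

    def ci(col):
        return tuple(np.percentile(df[col], [2.5, 97.5]))

    return ScenarioResult(
        scenario_id=scenario_id,
        n_dispatches=n_disp,
        availability_fraction=avail,
        delta_qaly_mean=float(run_means["delta_qaly"].mean()),
        delta_qaly_ci=ci("delta_qaly"),
        delta_cost_mean=float(run_means["delta_cost"].mean()),
        delta_cost_ci=ci("delta_cost"),
        inmb_mean=float(run_means["inmb"].mean()),
        inmb_ci=ci("inmb"),
        draws=df,
    )


def run_psa(
    region: RegionSpec,
    cohort: list[Patient],
    scenario: ScenarioSpec,
    cfg: ModelConfig,
    n_iterations: int = 3000,
    n_runs: int = 10,
    seed: int = 0,
) -> ScenarioResult:
    """Probabilistic sensitivity analysis for one scenario: per iteration a
    parameter set is drawn and both strategies are evaluated on the fixed
    cohort with common random numbers.  Means are averaged over runs; 95%
    intervals are percentiles of the pooled iteration draws."""
    pre = precompute_cohort(region, cohort, cfg, scenario.msu_site_id, seed)
    results, avail = simulate_availability(cohort, region, scenario, cfg.times, seed)
    mask = np.array([results[p.patient_id].msu_dispatched for p in pre.patients])
    n_disp = int(mask.sum())

    rows = []
    for run in range(n_runs):
        params = draw_parameter_configs(cfg, n_iterations, seed + 7919 * (run + 1))
        for it, c in enumerate(params):
            r = evaluate_strategies(pre, mask, c)
            rows.append(
                {
                    "run": run,
                    "iteration": it,
                    "delta_qaly": r["delta_qaly"],
                    "delta_cost": r["delta_cost"],
                    "inmb": r["inmb"],
                }
            )
    return _aggregate(scenario.scenario_id, n_disp, avail, rows)


#: canonical operating windows (hours of day)
WINDOWS = {"12h": [(9.0, 21.0)], "16h": [(7.0, 23.0)], "24h": [(0.0, 24.0)]}
#: canonical catchment limits (minutes; None = entire region)
CATCHMENTS = {"entire": None, "25min": 25.0, "20min": 20.0, "15min": 15.0}


def run_scenario_grid(
    region: RegionSpec,
    cohort: list[Patient],
    cfg: ModelConfig,
    sites: list[str] | None = None,
    windows: dict | None = None,
    catchments: dict | None = None,
    n_iterations: int = 300,
    n_runs: int = 2,
    seed: int = 0,
) -> list[ScenarioResult]:
    """Evaluate every (site, operating window, catchment) combination.

    The EMS-alone comparator and the parameter draws are shared across the
    grid: the same drawn parameter sets are applied to every scenario, and
    the comparator is evaluated once per draw."""
    windows = windows if windows is not None else WINDOWS
    catchments = catchments if catchments is not None else CATCHMENTS
    if sites is None:
        sites = [s.site_id for s in region.sites if s.msu_capable]

    param_sets = []
    for run in range(n_runs):
        for c in draw_parameter_configs(cfg, n_iterations, seed + 7919 * (run + 1)):
            param_sets.append((run, c))

    out = []
    for site in sites:
        pre = precompute_cohort(region, cohort, cfg, site, seed)
        # value tables depend on the draw, not the scenario: build once per
        # draw and share across the whole window x catchment grid
        tables = [
            lifetime_value_table(pre.unique_ages, c.economics, c.mortality)
            for _run, c in param_sets
        ]
        for wname, window in windows.items():
            for cname, limit in catchments.items():
                scen = ScenarioSpec(
                    msu_site_id=site,
                    operating_window=window,
                    catchment_limit=limit,
                    scenario_id=f"{site}_{wname}_{cname}",
                )
                results, avail = simulate_availability(cohort, region, scen, cfg.times, seed)
                mask = np.array([results[p.patient_id].msu_dispatched for p in pre.patients])
                rows = []
                for it, (run, c) in enumerate(param_sets):
                    r = evaluate_strategies(pre, mask, c, tables=tables[it])
                    rows.append(
                        {
                            "run": run,
                            "iteration": it,
                            "delta_qaly": r["delta_qaly"],
                            "delta_cost": r["delta_cost"],
                            "inmb": r["inmb"],
                        }
                    )
                out.append(_aggregate(scen.scenario_id, int(mask.sum()), avail, rows))
    return out


# ---------------------------------------------------------------------------
# tornado analysis


def tornado(
    region: RegionSpec,
    cohort: list[Patient],
    scenario: ScenarioSpec,
    cfg: ModelConfig,
    ranges: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """One-way sensitivity: each parameter in ``ranges`` (name ->
    (config path, low, high)) is set to its low and high value with all
    other parameters at base values; rows are sorted by the swing of the
    net monetary benefit."""
    paths = [p for p, _lo, _hi in ranges.values()]
    if len(set(paths)) != len(paths):
        raise ParameterError("overlapping parameter paths in tornado ranges")
    pre = precompute_cohort(region, cohort, cfg, scenario.msu_site_id, seed)
    results, avail = simulate_availability(cohort, region, scenario, cfg.times, seed)
    mask = np.array([results[p.patient_id].msu_dispatched for p in pre.patients])

    base = evaluate_strategies(pre, mask, cfg)
    rows = []
    for name, (path, lo, hi) in ranges.items():
        vals = {}
        for end, v in (("low", lo), ("high", hi)):
            c = cfg.copy()
            c.set_path(path, v)
            vals[end] = evaluate_strategies(pre, mask, c)
        rows.append(
            {
                "parameter": name,
                "path": path,
                "low_value": lo,
                "high_value": hi,
                "delta_qaly_low": vals["low"]["delta_qaly"],
                "delta_qaly_high": vals["high"]["delta_qaly"],
                "delta_cost_low": vals["low"]["delta_cost"],
                "delta_cost_high": vals["high"]["delta_cost"],
                "inmb_low": vals["low"]["inmb"],
                "inmb_high": vals["high"]["inmb"],
                "inmb_base": base["inmb"],
                "inmb_swing": abs(vals["high"]["inmb"] - vals["low"]["inmb"]),
            }
        )
    return pd.DataFrame(rows).sort_values("inmb_swing", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# export


def results_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Scenario table mirroring the published layout: dispatches with
    availability, QALY gain, cost savings (million EUR) and iNMB (million
    EUR), each with 95% intervals."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario_id,
                "n_dispatches": r.n_dispatches,
                "availability": round(r.availability_fraction, 3),
                "qaly_gain": r.delta_qaly_mean,
                "qaly_gain_ci_low": r.delta_qaly_ci[0],
                "qaly_gain_ci_high": r.delta_qaly_ci[1],
                "cost_savings_meur": -r.delta_cost_mean / 1e6,
                "cost_savings_meur_ci_low": -r.delta_cost_ci[1] / 1e6,
                "cost_savings_meur_ci_high": -r.delta_cost_ci[0] / 1e6,
                "inmb_meur": r.inmb_mean / 1e6,
                "inmb_meur_ci_low": r.inmb_ci[0] / 1e6,
                "inmb_meur_ci_high": r.inmb_ci[1] / 1e6,
            }
        )
    return pd.DataFrame(rows)


def export_results(results: list[ScenarioResult], outdir, trajectory: pd.DataFrame | None = None) -> dict:
    """Write results_table.csv, psa_draws.csv, scatter.csv, summary.json and
    optionally the cumulative-iNMB trajectory; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = results_table(results)
    paths["results_table"] = outdir / "results_table.csv"
    table.to_csv(paths["results_table"], index=False)

    draws = pd.concat(
        [r.draws.assign(scenario=r.scenario_id) for r in results if r.draws is not None],
        ignore_index=True,
    )
    paths["psa_draws"] = outdir / "psa_draws.csv"
    draws.to_csv(paths["psa_draws"], index=False)

    scatter = draws[["scenario", "delta_qaly", "delta_cost"]]
    paths["scatter"] = outdir / "scatter.csv"
    scatter.to_csv(paths["scatter"], index=False)

    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump({"scenarios": [r.to_dict() for r in results]}, fh, indent=2)

    if trajectory is not None:
        paths["trajectory"] = outdir / "inmb_trajectory.csv"
        trajectory.to_csv(paths["trajectory"], index=False)
    return paths


def read_results_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
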