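import json

import numpy as np
import pandas as pd
import pytest

from msu_cea import (
    ScenarioSpec,
    default_config,
    evaluate_strategies,
    export_results,
    generate_cohort,
    generate_synthetic_region,
    inmb,
    inmb_trajectory,
    precompute_cohort,
    results_table,
    run_psa,
    run_scenario_grid,
    tornado,
)
from msu_cea.config import ParameterError, fixed
from msu_cea.dispatch import simulate_availability
from msu_cea.psa_scenarios import read_results_json


@pytest.fixture(scope="module")
def setup():
    region = generate_synthetic_region(
        n_zones=20, n_psc=3, n_tsc=1, n_sites=2, total_population=150_000,
        area_km2=600.0, seed=21,
    )
    cfg = default_config()
    cohort = generate_cohort(region, cfg.epidemiology, seed=22)
    scen = ScenarioSpec(msu_site_id="S00", scenario_id="test")
    return region, cohort, cfg, scen


def _mask(region, cohort, scen, cfg, seed=0):
    pre = precompute_cohort(region, cohort, cfg, scen.msu_site_id, seed)
    res, avail = simulate_availability(cohort, region, scen, cfg.times, seed)
    return pre, np.array([res[p.patient_id].msu_dispatched for p in pre.patients]), avail


class TestInmb:
    def test_definition(self):
        assert inmb(0.0, 0.0, 50_000.0) == 0.0
        assert inmb(2.0, -100.0, 50_000.0) == pytest.approx(100_100.0)

    def test_published_row_12h_entire_region(self):
        # QALY gain 394.8, cost savings 3.99 MEUR at WTP 50k -> 23.73 MEUR
        assert inmb(394.8, -3.99e6, 50_000.0) / 1e6 == pytest.approx(23.73, abs=0.005)

    def test_published_row_24h_15min(self):
        assert inmb(438.2, -3.91e6, 50_000.0) / 1e6 == pytest.approx(25.82, abs=0.005)


class TestPsa:
    def test_fixed_distributions_collapse_interval(self, setup):
        region, cohort, cfg, scen = setup
        c = cfg.copy()
        c.psa = {"wtp": ("economics.wtp", fixed(50_000.0))}
        r = run_psa(region, cohort, scen, c, n_iterations=5, n_runs=2, seed=1)
        assert r.inmb_ci[0] == pytest.approx(r.inmb_ci[1])
        assert r.draws["inmb"].nunique() == 1

    def test_single_iteration_single_run_is_one_deterministic_evaluation(self, setup):
        region, cohort, cfg, scen = setup
        r1 = run_psa(region, cohort, scen, cfg, n_iterations=1, n_runs=1, seed=5)
        r2 = run_psa(region, cohort, scen, cfg, n_iterations=1, n_runs=1, seed=5)
        assert len(r1.draws) == 1
        assert r1.inmb_mean == r2.inmb_mean

    def test_per_draw_identity_links_inmb_to_deltas(self, setup):
        region, cohort, cfg, scen = setup
        r = run_psa(region, cohort, scen, cfg, n_iterations=20, n_runs=2, seed=3)
        wtp = cfg.economics.wtp
        np.testing.assert_allclose(
            r.draws["inmb"], r.draws["delta_qaly"] * wtp - r.draws["delta_cost"], rtol=1e-12
        )

    def test_interval_width_shrinks_with_sqrt_iterations(self, setup):
        """The Monte-Carlo standard error of the mean iNMB over parameter
        draws scales like 1/sqrt(n)."""
        region, cohort, cfg, scen = setup
        ses = []
        for n in (50, 200):
            r = run_psa(region, cohort, scen, cfg, n_iterations=n, n_runs=1, seed=2)
            ses.append(r.draws["inmb"].std(ddof=1) / np.sqrt(n))
        ratio = ses[0] / ses[1]
        assert 1.3 < ratio < 3.1  # expect ~2 with stochastic slack

    def test_null_effect_config_gives_zero_deltas(self, setup):
        """Zero treatment effects, no routing-dependent costs and no
        programme cost: both strategies are economically identical and
        every draw has zero QALY and cost difference."""
        region, cohort, cfg, scen = setup
        c = cfg.copy()
        for path in (
            "outcome.beta_ivt", "outcome.beta_evt",
            "economics.acute_msu_ride", "economics.acute_ed_visit_deduction",
            "economics.acute_ivt", "economics.acute_evt",
            "economics.acute_interhospital_transfer",
            "economics.msu_investment_total", "economics.msu_operational_annual",
            "economics.msu_personnel_annual",
        ):
            c.set_path(path, 0.0)
        c.psa = {k: v for k, v in c.psa.items() if k.startswith("p_")}
        r = run_psa(region, cohort, scen, c, n_iterations=50, n_runs=2, seed=4)
        assert abs(r.delta_qaly_mean) < 1e-9
        assert abs(r.delta_cost_mean) < 1e-9
        assert r.inmb_ci[0] <= 0.0 <= r.inmb_ci[1]

    def test_positive_effects_dominate_on_favourable_config(self, setup):
        """With positive treatment effects, decaying with time, and a
        drip-and-ship share, the QALY delta is positive in (almost) every
        draw."""
        region, cohort, cfg, scen = setup
        r = run_psa(region, cohort, scen, cfg, n_iterations=60, n_runs=1, seed=6)
        assert (r.draws["delta_qaly"] > 0).mean() > 0.95


class TestGrid:
    def test_grid_of_one_matches_run_psa(self, setup):
        region, cohort, cfg, scen = setup
        grid = run_scenario_grid(
            region, cohort, cfg, sites=["S00"],
            windows={"16h": [(7.0, 23.0)]}, catchments={"entire": None},
            n_iterations=10, n_runs=1, seed=9,
        )
        solo = run_psa(region, cohort, scen, cfg, n_iterations=10, n_runs=1, seed=9)
        assert len(grid) == 1
        assert grid[0].inmb_mean == pytest.approx(solo.inmb_mean)
        assert grid[0].n_dispatches == solo.n_dispatches

    def test_availability_non_increasing_as_window_shrinks(self, setup):
        region, cohort, cfg, _ = setup
        grid = run_scenario_grid(
            region, cohort, cfg, sites=["S00"],
            windows={"24h": [(0.0, 24.0)], "16h": [(7.0, 23.0)], "12h": [(9.0, 21.0)]},
            catchments={"entire": None},
            n_iterations=2, n_runs=1, seed=10,
        )
        disp = {r.scenario_id: r.n_dispatches for r in grid}
        assert disp["S00_24h_entire"] >= disp["S00_16h_entire"] >= disp["S00_12h_entire"]

    def test_catchment_patient_counts_nest(self, setup):
        region, cohort, cfg, _ = setup
        counts = []
        for limit in (None, 25.0, 20.0, 15.0):
            scen = ScenarioSpec(msu_site_id="S00", catchment_limit=limit)
            _, mask, _ = _mask(region, cohort, scen, cfg)
            res, _ = simulate_availability(cohort, region, scen, cfg.times, 0)
            n_in = sum(
                1 for r in res.values() if r.msu_dispatched or r.reason_if_not in ("busy", "outside_hours")
            )
            counts.append(n_in)
        assert counts == sorted(counts, reverse=True)


class TestTornado:
    ranges = {
        "p_mimic": ("epidemiology.p_mimic", 0.15, 0.35),
        "p_tia": ("epidemiology.p_tia", 0.10, 0.22),
        "beta_evt": ("outcome.beta_evt", 1.4, 2.6),
        "msu_personnel": ("economics.msu_personnel_annual", 450_000.0, 850_000.0),
    }

    def test_zero_width_range_gives_zero_swing(self, setup):
        region, cohort, cfg, scen = setup
        df = tornado(region, cohort, scen, cfg, {"p": ("outcome.beta_ivt", 1.0, 1.0)})
        assert df.loc[0, "inmb_swing"] == 0.0

    def test_duplicate_paths_rejected(self, setup):
        region, cohort, cfg, scen = setup
        bad = {"a": ("outcome.beta_ivt", 0.5, 1.0), "b": ("outcome.beta_ivt", 0.5, 1.5)}
        with pytest.raises(ParameterError, match="overlap"):
            tornado(region, cohort, scen, cfg, bad)

    def test_mimic_and_tia_raise_effectiveness_and_lower_costs_in_both_arms(self, setup):
        """More mimics/TIAs means more patients landing in benign states:
        total effectiveness rises and total costs fall in each strategy."""
        region, cohort, cfg, scen = setup
        pre, mask, _ = _mask(region, cohort, scen, cfg)
        for path in ("epidemiology.p_mimic", "epidemiology.p_tia"):
            lo_cfg, hi_cfg = cfg.copy(), cfg.copy()
            lo_cfg.set_path(path, 0.10)
            hi_cfg.set_path(path, 0.35)
            lo = evaluate_strategies(pre, mask, lo_cfg)
            hi = evaluate_strategies(pre, mask, hi_cfg)
            for arm in ("msu", "ems"):
                assert hi[f"qaly_{arm}"] > lo[f"qaly_{arm}"]
                assert hi[f"cost_{arm}"] < lo[f"cost_{arm}"]

    def test_msu_only_parameter_does_not_move_the_comparator_arm(self, setup):
        region, cohort, cfg, scen = setup
        pre, mask, _ = _mask(region, cohort, scen, cfg)
        lo_cfg, hi_cfg = cfg.copy(), cfg.copy()
        lo_cfg.set_path("economics.acute_msu_ride", 0.0)
        hi_cfg.set_path("economics.acute_msu_ride", 2000.0)
        lo = evaluate_strategies(pre, mask, lo_cfg)
        hi = evaluate_strategies(pre, mask, hi_cfg)
        assert hi["cost_ems"] == pytest.approx(lo["cost_ems"])
        assert hi["cost_msu"] > lo["cost_msu"]

    def test_rows_sorted_by_swing(self, setup):
        region, cohort, cfg, scen = setup
        df = tornado(region, cohort, scen, cfg, self.ranges)
        swings = df["inmb_swing"].to_numpy()
        assert (swings[:-1] >= swings[1:]).all()


class TestExport:
    def test_files_written_with_expected_shapes(self, setup, tmp_path):
        region, cohort, cfg, scen = setup
        r = run_psa(region, cohort, scen, cfg, n_iterations=8, n_runs=2, seed=11)
        pre, mask, _ = _mask(region, cohort, scen, cfg, seed=11)
        traj = inmb_trajectory(pre, mask, cfg)
        paths = export_results([r], tmp_path, trajectory=traj)
        table = pd.read_csv(paths["results_table"])
        assert list(table["scenario"]) == ["test"]
        for col in ("n_dispatches", "availability", "qaly_gain", "cost_savings_meur", "inmb_meur"):
            assert col in table.columns
        scatter = pd.read_csv(paths["scatter"])
        assert len(scatter) == 8 * 2  # iterations x runs
        summary = read_results_json(paths["summary"])
        assert summary["scenarios"][0] == r.to_dict()

    def test_trajectory_cumulative_inmb_non_decreasing_after_program_year(self, setup):
        region, cohort, cfg, scen = setup
        pre, mask, _ = _mask(region, cohort, scen, cfg)
        traj = inmb_trajectory(pre, mask, cfg)
        assert (traj["delta_qaly"] >= -1e-9).all()
        after = traj["cum_inmb"].to_numpy()[1:]
        assert (np.diff(after) >= -1e-6).all()

    def test_end_to_end_seeded_determinism(self, setup, tmp_path):
        region, cohort, cfg, scen = setup
        for d in ("a", "b"):
            r = run_psa(region, cohort, scen, cfg, n_iterations=5, n_runs=1, seed=77)
            export_results([r], tmp_path / d)
        for name in ("results_table.csv", "psa_draws.csv", "scatter.csv", "summary.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
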