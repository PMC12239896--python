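# msu-cea

Lifetime cost-effectiveness microsimulation of **mobile stroke unit (MSU)
dispatch** in a regionally adaptable ambulance catchment.

An MSU is an ambulance with an on-board CT/CTA scanner and a crew that can
start intravenous thrombolysis (IVT) at the scene and triage large vessel
occlusions (LVO) straight to a thrombectomy-capable stroke center (TSC),
bypassing the drip-and-ship detour via a primary stroke center (PSC).
Whether that is worth the investment depends heavily on regional geography:
population density, hospital distribution, driving times, and the dispatch
scenario (operating hours, catchment size, base location).  This package is
for health-economic modellers and stroke-care planners who want to evaluate
that question for *their* region from plain tabular inputs, without GIS
software or patient-level data.

## Model

A state-transition microsimulation compares two strategies on the same
virtual one-year cohort of suspected-stroke presentations:

* **MSU + EMS** — MSU and regular ambulance dispatched together when the
  alarm falls inside the operating window and catchment and the unit is
  free;
* **EMS alone** — standard of care.

For each patient the model composes the onset-to-treatment time (OTT) from
onset-to-alarm, dispatch-to-arrival, on-scene, driving, and in-hospital
workflow components (door-to-needle DTN, door-to-groin DTG,
door-in-door-out DIDO, interhospital transfer).  Treatment shifts the
7-category modified Rankin Scale (mRS) distribution at 90 days by a
proportional-odds effect that decays per minute of delay:

```
logit P'(mRS <= k) = logit P(mRS <= k) + delta(t),    k = 0..5
delta(t) = max(0, beta + beta_decay * t)   for t inside the treatment window
```

with separate `beta`/`beta_decay` for IVT (4.5 h window) and endovascular
thrombectomy (EVT, 6 h window).  The 90-day state then accrues utilities
and long-term care costs over the remaining lifetime (3-month, 9-month,
then annual Markov cycles up to 100, half-cycle corrected, discounted at
1.5 % for effects and 4.0 % for costs), with mortality from an age life
table multiplied by mRS-specific hazard ratios on the hazard scale.

The primary outcome is the **incremental net monetary benefit**

```
iNMB = dQALY x WTP - dCost,        WTP = EUR 50,000 / QALY
```

estimated by probabilistic sensitivity analysis (PSA) over parameter
distributions (beta for probabilities, gamma for costs, normal for
treatment-effect log-odds) with common random numbers across the two
strategies.  A scenario grid (operating windows x catchment limits x
dispatch sites) and a one-way tornado analysis are built in.

Because real regional inputs (postal-code demographics, road-network
driving times, registry workflow times) are usually proprietary, the
package ships a **synthetic-region generator** that emulates a mixed
urban/suburban region — by default 1.77 million inhabitants on ~1,600 km²
with 7 PSCs and 2 TSCs — and every epidemiological, time, outcome and cost
parameter is a documented, replaceable config value (see
`docs/methods.md` for what the defaults represent and what they are not).

## Worked example

```python
from msu_cea import (ScenarioSpec, default_config, generate_cohort,
                     generate_synthetic_region, run_psa, summarize_cohort)

region = generate_synthetic_region(seed=1)          # 1.77M people, 7 PSC + 2 TSC
cfg = default_config()
cohort = generate_cohort(region, cfg.epidemiology, seed=2)

scen = ScenarioSpec(msu_site_id="S00")              # 16 h/day, entire region
result = run_psa(region, cohort, scen, cfg, n_iterations=300, n_runs=2, seed=3)
```

prints (via the obvious f-strings):

```
5411 suspected strokes; 3551 with onset-to-alarm < 6 h
dispatches: 1708  availability: 48.1%
dQALY: 99.0 (95% CI 64.3-134.4)
dCost: EUR -0.51 million
iNMB:  EUR +5.46 million (95% CI 3.01 to 7.86)
```

Read: of ~5,400 suspected-stroke alarms in the synthetic year, 3,551 ring
within 6 h of onset; the MSU reaches 1,708 of them (48 % of in-catchment
eligible alarms — the rest fall outside the 07:00–23:00 window or hit a
busy unit).  One year of MSU operation buys ~99 lifetime QALYs *and* saves
about EUR 0.5 million (better outcomes need less long-term care), so the
MSU strategy dominates: iNMB ≈ EUR +5.5 million at EUR 50,000/QALY.  The
magnitudes are properties of the synthetic defaults, not of any real
region.

The same pipeline is scriptable from the shell:

```
msu-cea synth-region --outdir region --seed 1
msu-cea cohort --region-dir region --out cohort.csv --seed 2
msu-cea run --region-dir region --cohort-file cohort.csv \
            --window 16h --catchment entire --psa-iters 3000 --runs 10 \
            --seed 3 --outdir out
msu-cea grid --region-dir region --cohort-file cohort.csv --outdir grid_out
msu-cea tornado --region-dir region --cohort-file cohort.csv --out tornado.csv
```

`out/` contains `results_table.csv` (one scenario row: dispatches,
availability, QALY gain, cost savings and iNMB with 95 % intervals),
`psa_draws.csv` / `scatter.csv` (per-iteration dCost vs dQALY), the
cumulative `inmb_trajectory.csv` by model year, and `summary.json`.

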