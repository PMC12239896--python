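# Methods

This note documents the model implemented in `msu_cea`: its structure and
assumptions, what each parameter block means, what the synthetic-data
generator does and does not emulate, the numerical conventions, and the
design choices that were genuinely open.

## Model structure

Every suspected-stroke presentation enters as a "suspected stroke" and,
after the prehospital pathway, transitions at 90 days to one of nine
states: mRS 0–6, or a non-stroke state (stroke mimics).  TIAs enter mRS 0;
intracerebral haemorrhage (ICH) draws from its own 90-day distribution;
mimics, TIAs and ICH are unaffected by the dispatch strategy by
construction, so they cancel exactly in strategy comparisons.  Patients
remain in their 90-day state until death — no recurrent events, no state
migration — which is a deliberate simplification shared by both arms.

The comparison is MSU+EMS versus EMS-alone on the **same** cohort with
common random numbers: each patient's onset-to-alarm delay, mobilisation
and on-scene draws, diagnosis latents, and treatment-receipt uniforms are
keyed by `(seed, patient_id)` only.  The arms therefore differ exclusively
through dispatch, routing and times, which removes almost all first-order
Monte-Carlo noise from the deltas.

### Dispatch

A chronological sweep over eligible alarms (onset-to-alarm < 6 h).  The
unit goes out iff the alarm is inside the daily operating window, the zone
is within the catchment driving-time limit (boundary inclusive), and a
unit is free (n_units >= 1, first-free assignment; 1 by default).  The
busy interval is mobilisation + drive to scene + total on-scene time +
return; by default the regular ambulance transports the patient and the
MSU returns from the scene (`msu_escorts_to_hospital` adds the escort and
retrace legs — the travel matrix only covers site<->zone and
zone<->hospital pairs, so the return is modelled as retracing them).
Window membership is decided on the alarm time alone, with no look-ahead
to whether the mission ends after closing.  The reported availability
fraction is dispatches divided by eligible alarms **inside the catchment**,
matching how dispatch studies tabulate "% available" across catchment
scenarios.

### Times

OTT composition per arm is given in the README.  Conventions worth
stating:

* dispatch-to-arrival = stochastic mobilisation draw + deterministic
  driving time from the dispatch site (MSU base, or nearest EMS site);
* the MSU needle happens on scene (`msu_on_scene_to_needle`); departure
  adds `msu_post_needle_on_scene`;
* after MSU assessment the receiving TSC's door-to-groin is multiplied by
  `msu_dtg_factor` (default 0.6): the CTA is already acquired and the
  centre pre-notified, emulating direct-to-angio workflows that shorten
  DTG by roughly 20–30 minutes.  Set 1.0 for no in-hospital advantage;
* EMS routing is always to the nearest hospital (no prehospital triage
  instrument); an LVO whose nearest hospital is a PSC follows drip-and-ship
  (DIDO + transfer drive + handover + TSC door-to-groin);
* by default the transport clock in the MSU arm starts from the MSU
  arrival; `sync_transport_with_ems=True` makes it wait for the later of
  the two arrivals;
* interhospital transfer legs between named hospitals use an explicit
  travel-matrix row when present and otherwise the Euclidean-detour
  estimate between hospital coordinates.

### Outcomes

Proportional-odds shift on all six cumulative cuts of the mRS
distribution, death included (treatment reduces mortality).  The net
effect `max(0, beta + beta_decay * OTT)` is floored at zero — late
treatment is modelled as ineffective, never harmful — and is identically
zero at or beyond the window (270 min IVT, 360 min EVT).  For LVO patients
receiving both treatments the two deltas add on the log-odds scale
(`additive_lvo_effects=False` lets the EVT effect dominate instead).
Treatment receipt is Bernoulli — 0.55 for IVT given an ischemic stroke
inside 4.5 h, 0.85 for EVT given an LVO inside 6 h — drawn once per
patient and shared across arms, so a "treatment taker" is one in both
strategies and only the timing differs.  Cumulative probabilities are
clamped to [1e-12, 1-1e-12] before the logit so degenerate distributions
(e.g. the TIA point mass) remain well defined.

### Lifetime accrual

Cycle 1 is 3 months (the acute quarter, accruing the 90-day state's
utility and long-term cost pro-rata; its mortality is already embedded in
the mRS-6 entry probability), cycle 2 is 9 months, cycles 3+ are annual,
100 cycles in total after which everyone is assumed dead.  Note the 100
cycles therefore span 99 years.  Annual death probability combines the
age-specific background probability q with the state hazard ratio HR as
`1 - (1-q)^HR` (hazard-scale application), fractionally exponentiated for
the 9-month cycle; ages above the life-table range die with certainty.
Death in a cycle earns half that cycle's accrual (half-cycle correction);
all accrual is discounted at the **mid-cycle time** with separate rates
for effects (1.5 %) and costs (4.0 %) — including the sub-annual first
cycles, which keeps one uniform convention rather than a special
first-year rule.  `lifetime_value` exposes both a closed-form
survival-weighted expectation and a drawn-death-year microsimulation; the
test suite verifies their agreement at 10^4 draws per state.

Acute event costs (rides, IVT/EVT, transfer, emergency-department
deduction when IVT was already given in the MSU) are incurred at t = 0
undiscounted.  Programme costs (straight-line 5-year depreciation of the
investment plus operational and personnel costs) are added once to the
MSU+EMS strategy for the implementation horizon, never per patient.

### Sensitivity analyses

The PSA draws one parameter set per iteration (beta for probabilities,
gamma for costs and times, normal for treatment-effect log-odds; sets
violating the case-mix simplex are redrawn), evaluates both strategies on
the fixed cohort, and pools iterations across runs that differ only by
sub-seed; point estimates are means of run-means and 95 % intervals are
2.5/97.5 percentiles of the pooled draws.  Per-patient lifetime value is
taken **in expectation over the 90-day mRS distribution** (a
probability-weighted lookup in a per-draw age x state value table) rather
than by drawing the state: with a fixed cohort this is the exact
conditional mean of the microsimulation and makes the intervals pure
parameter uncertainty.  Diagnosis labels are re-thresholded from stored
latent uniforms when case-mix probabilities are perturbed, so the same
patient flips category coherently across draws and arms.  Dispatch
availability is computed once per scenario at base time parameters (the
published per-scenario availability is likewise a single figure).  The
scenario grid shares the drawn parameter sets and the EMS comparator
across all window x catchment combinations; the tornado analysis is
one-at-a-time low/high substitution at base values, sorted by iNMB swing.

## Synthetic region and cohort

The generator emulates the study setting the model was built for — a
mixed urban/suburban ambulance region of 1.77 million inhabitants on
~1,592 km² with 7 primary and 2 thrombectomy-capable stroke centers —
without reproducing any real geography:

* zones are scattered on a plane, half clustered in an urban core;
  populations follow an exponential density decay (e-folding
  `density_profile` = 10 km) with log-normal zone noise, summing exactly
  to the configured total;
* age structure is a western-European national pyramid with
  Dirichlet-perturbed zone shares;
* hospitals occupy ranked population centres with a minimum-separation
  rule; thrombectomy capability is spread over the ranking (not simply the
  two largest centres) so that most zones are nearest to a primary centre
  and the drip-and-ship share among LVO (~75–80 %) resembles a
  multi-PSC region;
* travel time = Euclidean distance x 1.3 detour factor / 65 km/h, the
  standard road-network approximation; no triangle inequality is assumed
  for user-supplied matrices;
* age-band incidence rates are calibrated once so the default region
  yields ≈ 5,500 suspected-stroke alarms per year (crude rate ≈ 3.1 per
  1,000 person-years) with median age in the mid-70s;
* onset-to-alarm is a mixture of a witnessed-onset spike (weight 0.25,
  uniform 5–35 min) and a log-normal solved so the overall median is
  150 min and 66 % of alarms ring within 6 h; alarm clock-times are
  uniform over the year (an optional 24-hour diurnal weight vector exists
  for sensitivity work).

What the generator does **not** emulate: real road networks (ferries,
bridges, congestion — travel times violating the triangle inequality can
only enter via user matrices), diurnal and seasonal incidence structure,
socio-economic gradients in onset-to-alarm behaviour, hospital-level
workflow heterogeneity beyond random draws, and EMS fleet capacity (EMS is
always available).  Passing tests on synthetic regions therefore
demonstrates the *mechanics* of the model — routing, time composition,
outcome shifts, accounting identities, monotonicities — not the
cost-effectiveness of any real deployment.

## Default parameter values

All defaults are placeholders in the families practitioners would
recognise, and none is an authoritative regional estimate:

| block | defaults represent | key values |
|---|---|---|
| case mix | prehospital triage-study proportions | mimic 0.25, TIA 0.16, ICH 0.07, LVO&#124;ischemic 0.23 |
| times | national stroke-audit-like workflows | DTN ≈ 25, DTG ≈ 60, DIDO ≈ 60 min; EMS scene 15; MSU scene-to-needle 32, +8 to departure |
| outcomes | RCT-control-arm-shaped mRS vectors | `beta_ivt` 1.0, decay −0.0025/min; `beta_evt` 2.0, decay −0.005/min |
| utilities | literature mRS utilities | 0.95, 0.93, 0.83, 0.62, 0.42, 0.11, 0 |
| long-term costs | Dutch-style annual care costs | EUR 1.5k → 75k/yr from mRS 0 to 5 |
| mortality | Gompertz life-table shape, mRS hazard ratios | HR 1.0 → 4.5 |
| programme | one MSU | EUR 1.0M investment / 5 y + 0.25M + 0.65M per year |

The treatment-effect decays were chosen so the model's marginal value of
treatment delay matches the magnitudes the reperfusion literature reports
— roughly 1.8 days of healthy life per minute of thrombolysis delay and
most of a week per minute of thrombectomy delay — given that one unit of
log-odds shift is worth ≈ 2 lifetime QALYs at the cohort's median age.
With these defaults the MSU strategy dominates (more QALYs, lower costs)
on the default synthetic region, qualitatively matching what regional MSU
evaluations with lifetime horizons report; the magnitudes scale with the
region and are not reproduction targets.

## Numerical conventions and degenerate inputs

* Ties in nearest-hospital and nearest-site selection break on
  lexicographic id, for determinism.
* Catchment membership is boundary-inclusive (travel == limit is inside).
* Truncated PSA distributions redraw up to 100 times, then clip with a
  warning.
* Value tables index patients by integer (floored) age.
* `%.17g` formatting plus round-trip float parsing keeps region and
  cohort CSV round-trips bit-exact.
* Empty subgroups in time-savings summaries report `None`, never 0.
* Problem sizes in the test suite are scaled for a laptop-class single
  CPU: small synthetic regions (10–60 zones, 10^4–10^6 population),
  10^4-draw oracle comparisons, and a 100k-person end-to-end pipeline at
  300 x 2 PSA draws; when a region is scaled down, programme fixed costs
  are scaled by the same population ratio, since a miniature region would
  operate a proportionally smaller service.

## Known limitations

* No diagnostic-error model (MSU and in-hospital CT are assumed equally
  accurate) and no treatment effect for ICH in the MSU.
* No recurrent stroke or post-90-day state transitions; health-care
  perspective only (no productivity or informal-care costs).
* A single region-wide onset-to-alarm distribution; no per-zone behaviour.
* The availability model treats the MSU as a single M/G/1-style server
  with deterministic-given-draws service times; no re-dispatch, diversion,
  or multi-alarm prioritisation.
* The decay of treatment effect is linear in time on the log-odds scale
  and floored at zero; if the underlying effect turns harmful late, this
  model will not show it.
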