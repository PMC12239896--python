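"""Lifetime QALY and cost accrual from the 90-day health state.

Patients stay in their 90-day state until death.  The cycle structure is:
a 3-month first cycle (the acute quarter, accruing the 90-day state's
utility and long-term cost pro-rata), a 9-month second cycle completing the
first year, then annual cycles up to 100 cycles in total, after which
everyone is assumed dead.  Death within a cycle earns half the cycle's
accrual (half-cycle correction) and all accrual is discounted at the
mid-cycle time, with separate rates for effects and costs.

Annual death probability combines the age-specific background probability
with an mRS-specific hazard ratio on the hazard scale:
q' = 1 - exp(-HR * (-ln(1 - q_age))) = 1 - (1 - q_age)^HR.

``lifetime_value`` has two modes: ``expected`` evaluates the
survival-weighted closed-form sum (the deterministic oracle used by the
probabilistic sensitivity analysis), ``microsim`` draws an individual death
cycle.  Acute event costs are incurred at time zero and are undiscounted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EconomicParams, MortalityParams, ParameterError

NONSTROKE_STATE = 7  # index used in value tables: mRS 0..6, then nonstroke
STATES = list(range(7)) + ["nonstroke"]


@dataclass
class PatientValue:
    qaly_discounted: float
    cost_discounted: float


def annual_death_probability(age: float, hr: float, mortality: MortalityParams) -> float:
    """Background annual death probability adjusted by a hazard ratio on
    the hazard scale."""
    q = mortality.q_at(age)
    if q >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q) ** hr


def survival_probability(age: float, mrs, mortality: MortalityParams) -> float:
    """Annual survival probability for a patient of given age and state
    (mRS 0-5, or "nonstroke"; mRS 6 returns 0)."""
    if mrs == 6:
        return 0.0
    hr = mortality.hr_nonstroke if mrs == "nonstroke" else float(np.asarray(mortality.hr_by_mrs)[mrs])
    return 1.0 - annual_death_probability(age, hr, mortality)


def _state_u_c_hr(state, econ: EconomicParams, mortality: MortalityParams):
    if state == "nonstroke" or state == NONSTROKE_STATE:
        return econ.utility_nonstroke, econ.annual_cost_nonstroke, mortality.hr_nonstroke
    state = int(state)
    if not 0 <= state <= 6:
        raise ParameterError(f"invalid health state {state!r}")
    if state == 6:
        return 0.0, 0.0, np.inf
    return (
        float(np.asarray(econ.utility_by_mrs)[state]),
        float(np.asarray(econ.annual_cost_by_mrs)[state]),
        float(np.asarray(mortality.hr_by_mrs)[state]),
    )


def _cycle_schedule(age: float, hr: float, mortality: MortalityParams):
    """Durations (years), mid-cycle times and within-cycle death
    probabilities for the full cycle sequence."""
    n = mortality.max_cycles
    dur = np.concatenate([[0.25, 0.75], np.ones(n - 2)])
    t_start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    t_mid = t_start + dur / 2.0
    # age at cycle start: a0 for cycles 1-2, then advancing one year per cycle
    ages = np.concatenate([[age, age], age + 1.0 + np.arange(n - 2)])
    table_ages = np.asarray(mortality.ages, float)
    q = np.interp(ages, table_ages, np.asarray(mortality.annual_mortality_by_age, float))
    q[ages > table_ages[-1]] = 1.0  # beyond the life table: certain death
    q_hr = np.where(q >= 1.0, 1.0, 1.0 - (1.0 - q) ** hr)
    p_die = 1.0 - (1.0 - q_hr) ** dur
    p_die[0] = 0.0  # 90-day mortality is captured by the mRS-6 entry state
    return dur, t_mid, p_die


def _expected_profiles(
    state, age: float, econ: EconomicParams, mortality: MortalityParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle discounted expected QALY and cost contributions, plus the
    cycle mid-times (for year-resolved accounting)."""
    u, c, hr = _state_u_c_hr(state, econ, mortality)
    if u == 0.0 and c == 0.0 and np.isinf(hr):  # dead at entry
        n = mortality.max_cycles
        return np.zeros(n), np.zeros(n), np.zeros(n)
    dur, t_mid, p_die = _cycle_schedule(age, hr, mortality)
    s_prev = np.concatenate([[1.0], np.cumprod(1.0 - p_die)[:-1]])
    credit = s_prev * ((1.0 - p_die) * dur + p_die * dur / 2.0)
    qaly = credit * u / (1.0 + econ.discount_effects) ** t_mid
    cost = credit * c / (1.0 + econ.discount_costs) ** t_mid
    return qaly, cost, t_mid


def lifetime_value(
    state,
    age: float,
    econ: EconomicParams,
    mortality: MortalityParams,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
) -> PatientValue:
    """Discounted lifetime QALYs and long-term costs from model entry for a
    patient entering at ``age`` in ``state`` (mRS 0-6 or "nonstroke")."""
    if mode == "expected":
        qaly, cost, _ = _expected_profiles(state, age, econ, mortality)
        return PatientValue(float(qaly.sum()), float(cost.sum()))
    if mode != "microsim":
        raise ParameterError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    u, c, hr = _state_u_c_hr(state, econ, mortality)
    if u == 0.0 and c == 0.0 and np.isinf(hr):
        return PatientValue(0.0, 0.0)
    dur, t_mid, p_die = _cycle_schedule(age, hr, mortality)
    df_e = (1.0 + econ.discount_effects) ** -t_mid
    df_c = (1.0 + econ.discount_costs) ** -t_mid
    qaly = cost = 0.0
    for i in range(len(dur)):
        died = rng.random() < p_die[i]
        frac = 0.5 if died else 1.0
        qaly += frac * dur[i] * u * df_e[i]
        cost += frac * dur[i] * c * df_c[i]
        if died:
            break
    return PatientValue(float(qaly), float(cost))


def lifetime_value_table(
    ages: np.ndarray, econ: EconomicParams, mortality: MortalityParams
) -> tuple[np.ndarray, np.ndarray]:
    """Expected discounted (QALY, cost) for every (age, state) pair.

    Returns two arrays of shape (len(ages), 8); state order mRS 0..6 then
    nonstroke.  Used by the sensitivity analyses to evaluate cohorts by
    table lookup."""
    ages = np.asarray(ages, dtype=float)
    qaly = np.zeros((len(ages), 8))
    cost = np.zeros((len(ages), 8))
    for i, a in enumerate(ages):
        for j, state in enumerate(STATES):
            q, c, _ = _expected_profiles(state, float(a), econ, mortality)
            qaly[i, j] = q.sum()
            cost[i, j] = c.sum()
    return qaly, cost


def lifetime_value_year_profiles(
    ages: np.ndarray, econ: EconomicParams, mortality: MortalityParams, n_years: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Expected discounted QALY / cost accrual binned by model year since
    entry, shape (len(ages), 8, n_years).  Supports cumulative
    net-benefit-over-time accounting."""
    ages = np.asarray(ages, dtype=float)
    qaly = np.zeros((len(ages), 8, n_years))
    cost = np.zeros((len(ages), 8, n_years))
    for i, a in enumerate(ages):
        for j, state in enumerate(STATES):
            q, c, t_mid = _expected_profiles(state, float(a), econ, mortality)
            years = np.minimum(np.floor(t_mid).astype(int), n_years - 1)
            np.add.at(qaly[i, j], years, q)
            np.add.at(cost[i, j], years, c)
    return qaly, cost


def acute_cost(
    econ: EconomicParams,
    msu_dispatched: bool,
    treated_ivt: bool,
    treated_evt: bool,
    interhospital_transfer: bool,
) -> float:
    """Acute-phase event cost: the EMS ride always runs; the MSU ride adds
    when dispatched; treatment costs when given; the drip-and-ship transfer
    when it happens; and the emergency-department visit is deducted when
    thrombolysis was already delivered in the MSU (the ED is bypassed)."""
    total = econ.acute_ems_ride
    if msu_dispatched:
        total += econ.acute_msu_ride
    if treated_ivt:
        total += econ.acute_ivt
    if treated_evt:
        total += econ.acute_evt
    if interhospital_transfer:
        total += econ.acute_interhospital_transfer
    if msu_dispatched and treated_ivt:
        total -= econ.acute_ed_visit_deduction
    return float(total)


def program_cost(econ: EconomicParams, horizon_years: float = 1.0) -> float:
    """Programme-level MSU cost for the implementation horizon: straight-line
    depreciation of the investment plus operational and personnel costs.
    Added once to the MSU+EMS strategy, not per patient."""
    if horizon_years <= 0:
        raise ParameterError("horizon_years must be positive")
    annual = (
        econ.msu_investment_total / econ.msu_depreciation_years
        + econ.msu_operational_annual
        + econ.msu_personnel_annual
    )
    return float(annual * horizon_years)
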