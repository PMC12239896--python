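"""90-day outcome model: proportional-odds mRS shift with time decay.

Treatment moves the whole 7-category mRS distribution toward better
outcomes by adding a delta to every cumulative log-odds
logit P(mRS <= k), k = 0..5 (a positive delta favours lower mRS, including
lower mortality since mRS 6 participates in the shift).  The delta for a
treatment is its time-zero log-odds effect plus a per-minute decay times
the onset-to-treatment time, floored at zero so late treatment is modelled
as ineffective rather than harmful, and zero outside the treatment window.

Mimic, TIA and ICH presentations are unaffected by treatment: mimics enter
a non-stroke state, TIAs enter mRS 0, ICH draws from its own distribution.
"""
from __future__ import annotations

import numpy as np

from .config import OutcomeModel, ParameterError
from .cohort import Patient

NONSTROKE = "nonstroke"
_EPS = 1e-12


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def shift_distribution(base: np.ndarray, delta: float) -> np.ndarray:
    """Proportional-odds shift of a 7-category mRS distribution.

    Each cumulative cut k = 0..5 moves by ``delta`` on the logit scale;
    category probabilities are recovered by differencing.  Cumulative
    probabilities of exactly 0 or 1 are clamped to [1e-12, 1 - 1e-12]
    before the logit so degenerate distributions stay well-defined.
    """
    base = np.asarray(base, dtype=float)
    if base.shape[-1] != 7:
        raise ParameterError("mRS distribution must have 7 categories")
    cum = np.cumsum(base, axis=-1)[..., :6]
    shifted = 1.0 / (1.0 + np.exp(-(_logit(cum) + delta)))  # monotone in cum, so still a CDF
    full = np.concatenate([shifted, np.ones_like(base[..., :1])], axis=-1)
    out = np.diff(full, axis=-1, prepend=0.0)
    return np.clip(out, 0.0, 1.0)


def treatment_delta(beta: float, beta_decay: float, ott: float, window: float) -> float:
    """Net log-odds treatment effect at onset-to-treatment time ``ott``:
    max(0, beta + beta_decay * ott) inside the window, 0 at or beyond it."""
    if ott < 0:
        raise ParameterError("onset-to-treatment time must be >= 0")
    if ott >= window:
        return 0.0
    return max(0.0, beta + beta_decay * ott)


def outcome_distribution(
    patient: Patient,
    treated_ivt: bool,
    treated_evt: bool,
    ott_ivt: float | None,
    ott_evt: float | None,
    model: OutcomeModel,
):
    """90-day outcome for one patient: the string ``"nonstroke"`` for a
    mimic, else a 7-probability mRS vector."""
    dx = patient.diagnosis
    if treated_evt and dx != "ischemic_lvo":
        raise ParameterError("EVT flag on a non-LVO patient")
    if dx == "mimic":
        return NONSTROKE
    if dx == "tia":
        out = np.zeros(7)
        out[0] = 1.0
        return out
    if dx == "ich":
        return np.asarray(model.mrs_ich, dtype=float).copy()

    delta = 0.0
    if treated_ivt:
        delta_ivt = treatment_delta(model.beta_ivt, model.beta_ivt_decay, ott_ivt, model.ivt_window)
    else:
        delta_ivt = 0.0
    if dx == "ischemic_nonlvo":
        base = model.mrs_untreated_nonlvo
        delta = delta_ivt
    else:
        base = model.mrs_untreated_lvo
        delta_evt = (
            treatment_delta(model.beta_evt, model.beta_evt_decay, ott_evt, model.evt_window)
            if treated_evt
            else 0.0
        )
        if model.additive_lvo_effects:
            delta = delta_ivt + delta_evt
        else:
            delta = delta_evt if treated_evt else delta_ivt
    if delta == 0.0:
        return np.asarray(base, dtype=float).copy()
    return shift_distribution(base, delta)


def draw_mrs(dist: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw of the realised mRS from a 7-probability vector."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (7,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
        raise ParameterError("invalid mRS distribution")
    return int(rng.choice(7, p=dist / dist.sum()))


def decide_treatments(
    patient: Patient,
    ott_ivt: float | None,
    ott_evt: float | None,
    model: OutcomeModel,
    u_ivt: float,
    u_evt: float,
) -> tuple[bool, bool]:
    """Treatment receipt: IVT for ischemic strokes inside the 4.5-h clock
    with probability p_ivt; EVT for LVO inside the 6-h clock with
    probability p_evt.  The Bernoulli uniforms come from the patient's
    common-random-number stream so the same patient is a treatment taker in
    both strategies and the arms differ only through time."""
    ivt = (
        patient.ischemic
        and ott_ivt is not None
        and ott_ivt < model.ivt_window
        and u_ivt < model.p_ivt_given_eligible
    )
    evt = (
        patient.diagnosis == "ischemic_lvo"
        and ott_evt is not None
        and ott_evt < model.evt_window
        and u_evt < model.p_evt_given_lvo_eligible
    )
    return bool(ivt), bool(evt)
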