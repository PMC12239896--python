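"""Model configuration: parameter blocks, distributions, YAML round-trip.

All default values for epidemiology, times, outcomes, utilities, mortality
and costs are documented placeholders drawn from the published literature
families (registry workflow times, trial control-arm outcome distributions,
national life tables, Dutch long-term care cost studies).  They are NOT
authoritative regional estimates; any real application must replace them
with region-specific values through the YAML config.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# constants

#: 5-year age bands 0-4 ... 90-94, 95+
AGE_BAND_EDGES = list(range(0, 100, 5))  # lower edges; last band is 95+
N_AGE_BANDS = len(AGE_BAND_EDGES)
AGE_BAND_LABELS = [f"{lo:02d}_{lo + 4:02d}" for lo in AGE_BAND_EDGES[:-1]] + ["95plus"]

MIN_PER_DAY = 1440.0
MIN_PER_YEAR = 525600.0
ELIGIBILITY_WINDOW_MIN = 360.0  # onset-to-alarm gate: < 6 h


class ParameterError(ValueError):
    """Invalid parameter value or distribution specification."""


# ---------------------------------------------------------------------------
# distributions


@dataclass
class Distribution:
    """A scalar sampling distribution, used both for per-patient time
    components and for probabilistic-sensitivity parameter uncertainty.

    kind: one of fixed, lognormal, normal, beta, gamma, uniform.
    params by kind:
      fixed     -> value
      lognormal -> median, sigma (sd on the log scale)
      normal    -> mu, sd
      beta      -> a, b
      gamma     -> shape, scale
      uniform   -> low, high
    bounds: optional (low, high) truncation; draws outside are rejected and
    redrawn, capped at 100 rejections after which the draw is clipped (a
    warning is emitted once).
    """

    kind: str
    params: dict = field(default_factory=dict)
    bounds: tuple | None = None

    _KINDS = ("fixed", "lognormal", "normal", "beta", "gamma", "uniform")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.bounds is not None:
            self.bounds = tuple(self.bounds)

    def _draw(self, rng: np.random.Generator, size):
        p = self.params
        if self.kind == "fixed":
            val = p["value"]
            return np.full(size, val) if size is not None else float(val)
        if self.kind == "lognormal":
            return rng.lognormal(np.log(p["median"]), p["sigma"], size)
        if self.kind == "normal":
            return rng.normal(p["mu"], p["sd"], size)
        if self.kind == "beta":
            return rng.beta(p["a"], p["b"], size)
        if self.kind == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        raise AssertionError(self.kind)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution, honouring truncation bounds."""
        x = self._draw(rng, size)
        if self.bounds is None or self.kind == "fixed":
            return x
        lo, hi = self.bounds
        if size is None:
            for _ in range(100):
                if lo <= x <= hi:
                    return float(x)
                x = self._draw(rng, None)
            warnings.warn(
                f"distribution {self.kind}{self.params} exceeded 100 rejections; clipping",
                stacklevel=2,
            )
            return float(np.clip(x, lo, hi))
        bad = (x < lo) | (x > hi)
        tries = 0
        while bad.any() and tries < 100:
            x[bad] = self._draw(rng, int(bad.sum()))
            bad = (x < lo) | (x > hi)
            tries += 1
        if bad.any():
            warnings.warn("truncated distribution exceeded 100 rejections; clipping", stacklevel=2)
            x = np.clip(x, lo, hi)
        return x

    def mean(self) -> float:
        p = self.params
        if self.kind == "fixed":
            return float(p["value"])
        if self.kind == "lognormal":
            return float(p["median"] * np.exp(p["sigma"] ** 2 / 2.0))
        if self.kind == "normal":
            return float(p["mu"])
        if self.kind == "beta":
            return float(p["a"] / (p["a"] + p["b"]))
        if self.kind == "gamma":
            return float(p["shape"] * p["scale"])
        if self.kind == "uniform":
            return float((p["low"] + p["high"]) / 2.0)
        raise AssertionError(self.kind)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "params": dict(self.params)}
        if self.bounds is not None:
            d["bounds"] = list(self.bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Distribution":
        return cls(kind=d["kind"], params=dict(d["params"]), bounds=d.get("bounds"))


def fixed(value: float) -> Distribution:
    return Distribution("fixed", {"value": float(value)})


def lognormal(median: float, sigma: float) -> Distribution:
    return Distribution("lognormal", {"median": float(median), "sigma": float(sigma)})


def beta_mean_k(mean: float, k: float) -> Distribution:
    """Beta distribution parameterised by mean and concentration a+b=k."""
    return Distribution("beta", {"a": mean * k, "b": (1.0 - mean) * k})


def gamma_mean_cv(mean: float, cv: float) -> Distribution:
    """Gamma distribution parameterised by mean and coefficient of variation."""
    shape = 1.0 / cv**2
    return Distribution("gamma", {"shape": shape, "scale": mean / shape})


# ---------------------------------------------------------------------------
# onset-to-alarm model


@dataclass
class OnsetToAlarmModel:
    """Mixture model for the onset-to-alarm delay (minutes).

    A fraction ``spike_weight`` of patients alarm quickly (uniform on
    [spike_lo, spike_hi], the witnessed-onset spike); the remainder follow a
    log-normal whose parameters are solved so the overall distribution has
    the configured median and P(delay < 6 h).
    """

    median_min: float = 150.0
    p_lt_6h: float = 0.66
    spike_weight: float = 0.25
    spike_lo: float = 5.0
    spike_hi: float = 35.0

    def lognormal_params(self) -> tuple[float, float]:
        """Solve (mu, sigma) of the log-normal component from the two
        overall constraints.  Requires spike_hi <= median_min < 360."""
        from scipy.stats import norm

        w = self.spike_weight
        if not (0.0 <= w < 1.0):
            raise ParameterError("spike_weight must be in [0, 1)")
        if not (self.spike_hi <= self.median_min < ELIGIBILITY_WINDOW_MIN):
            raise ParameterError("need spike_hi <= median_min < 360")
        if not (0.5 < self.p_lt_6h < 1.0):
            raise ParameterError("p_lt_6h must be in (0.5, 1)")
        p_med = (0.5 - w) / (1.0 - w)
        p_6h = (self.p_lt_6h - w) / (1.0 - w)
        if p_med <= 0.0 or p_6h <= p_med:
            raise ParameterError("spike_weight incompatible with median / p_lt_6h")
        z1 = norm.ppf(p_med)
        z2 = norm.ppf(p_6h)
        sigma = np.log(ELIGIBILITY_WINDOW_MIN / self.median_min) / (z2 - z1)
        mu = np.log(self.median_min) - sigma * z1
        return float(mu), float(sigma)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu, sigma = self.lognormal_params()
        spike = rng.random(size) < self.spike_weight
        out = rng.lognormal(mu, sigma, size)
        out[spike] = rng.uniform(self.spike_lo, self.spike_hi, int(spike.sum()))
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OnsetToAlarmModel":
        return cls(**d)


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class EpidemiologyParams:
    """Suspected-stroke incidence and case-mix.

    incidence_by_age: suspected-stroke alarms per person-year per 5-year
    age band (includes mimics, TIA, ICH and ischemic stroke).
    Diagnosis split: mimic / TIA / ICH, remainder ischemic; LVO is a
    conditional probability among ischemic strokes.
    """

    incidence_by_age: np.ndarray = field(
        default_factory=lambda: np.array(
            # per person-year; bands 0-4 ... 95+; calibrated so a ~1.77M
            # population with a western-European pyramid yields ~5,500
            # suspected-stroke alarms per year with median age mid-70s
            [0.00015] * 8
            + [0.0003, 0.0007, 0.0011, 0.0019, 0.0034, 0.0060, 0.0095,
               0.0130, 0.0190, 0.0240, 0.0320, 0.0400]
        )
    )
    p_mimic: float = 0.25
    p_tia: float = 0.16
    p_ich: float = 0.07
    p_lvo_given_ischemic: float = 0.23
    onset_to_alarm: OnsetToAlarmModel = field(default_factory=OnsetToAlarmModel)
    #: optional 24-vector of relative alarm weights per clock hour (uniform if None)
    diurnal_weights: np.ndarray | None = None

    def validate(self) -> None:
        r = np.asarray(self.incidence_by_age, dtype=float)
        if r.shape != (N_AGE_BANDS,) or (r < 0).any():
            raise ParameterError("incidence_by_age must be 20 non-negative rates")
        for name in ("p_mimic", "p_tia", "p_ich", "p_lvo_given_ischemic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.p_mimic + self.p_tia + self.p_ich > 1.0 + 1e-12:
            raise ParameterError("p_mimic + p_tia + p_ich exceeds 1")
        if self.diurnal_weights is not None:
            w = np.asarray(self.diurnal_weights, dtype=float)
            if w.shape != (24,) or (w < 0).any() or w.sum() <= 0:
                raise ParameterError("diurnal_weights must be 24 non-negative weights")

    def to_dict(self) -> dict:
        return {
            "incidence_by_age": np.asarray(self.incidence_by_age, float).tolist(),
            "p_mimic": self.p_mimic,
            "p_tia": self.p_tia,
            "p_ich": self.p_ich,
            "p_lvo_given_ischemic": self.p_lvo_given_ischemic,
            "onset_to_alarm": self.onset_to_alarm.to_dict(),
            "diurnal_weights": None
            if self.diurnal_weights is None
            else np.asarray(self.diurnal_weights, float).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpidemiologyParams":
        return cls(
            incidence_by_age=np.asarray(d["incidence_by_age"], float),
            p_mimic=d["p_mimic"],
            p_tia=d["p_tia"],
            p_ich=d["p_ich"],
            p_lvo_given_ischemic=d["p_lvo_given_ischemic"],
            onset_to_alarm=OnsetToAlarmModel.from_dict(d["onset_to_alarm"]),
            diurnal_weights=None
            if d.get("diurnal_weights") is None
            else np.asarray(d["diurnal_weights"], float),
        )


@dataclass
class TimeParams:
    """Prehospital and in-hospital time components (minutes).

    dispatch-to-arrival = mobilisation draw + driving time from the
    dispatch site to the patient's zone (driving times come from the
    region's travel matrix).
    """

    ems_mobilization: Distribution = field(default_factory=lambda: lognormal(2.5, 0.40))
    msu_mobilization: Distribution = field(default_factory=lambda: lognormal(3.0, 0.40))
    ems_on_scene: Distribution = field(default_factory=lambda: lognormal(15.0, 0.30))
    #: MSU arrival to needle: examination, CT/CTA, IVT start on scene
    msu_on_scene_to_needle: Distribution = field(default_factory=lambda: lognormal(32.0, 0.20))
    #: extra on-scene minutes after the needle before departure
    msu_post_needle_on_scene: Distribution = field(default_factory=lambda: lognormal(8.0, 0.30))
    transfer_handover: float = 10.0
    #: multiplier on the receiving TSC door-to-groin after MSU assessment
    #: (prehospital CTA + pre-notification shortens the in-hospital pathway)
    msu_dtg_factor: float = 0.6
    #: if True, the scene-departure clock in the MSU arm waits for the later
    #: of the MSU and EMS arrivals (EMS performs the transport)
    sync_transport_with_ems: bool = False
    #: if True, the MSU escorts the patient to the receiving hospital before
    #: returning to base (busy-interval composition); by default the regular
    #: ambulance performs the transport and the MSU returns from the scene
    msu_escorts_to_hospital: bool = False

    def validate(self) -> None:
        if self.transfer_handover < 0:
            raise ParameterError("transfer_handover must be >= 0")
        if not 0 < self.msu_dtg_factor <= 1.5:
            raise ParameterError("msu_dtg_factor must be in (0, 1.5]")

    _DISTS = (
        "ems_mobilization",
        "msu_mobilization",
        "ems_on_scene",
        "msu_on_scene_to_needle",
        "msu_post_needle_on_scene",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k).to_dict() for k in self._DISTS}
        d.update(
            transfer_handover=self.transfer_handover,
            msu_dtg_factor=self.msu_dtg_factor,
            sync_transport_with_ems=self.sync_transport_with_ems,
            msu_escorts_to_hospital=self.msu_escorts_to_hospital,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TimeParams":
        kw = {k: Distribution.from_dict(d[k]) for k in cls._DISTS}
        for k in (
            "transfer_handover",
            "msu_dtg_factor",
            "sync_transport_with_ems",
            "msu_escorts_to_hospital",
        ):
            kw[k] = d[k]
        return cls(**kw)


@dataclass
class OutcomeModel:
    """90-day mRS outcome model: baseline distributions and
    proportional-odds treatment effects with per-minute decay.

    Baseline vectors follow the shape of control arms of the thrombolysis
    and thrombectomy randomised trials (placeholders, not trial data).
    ``beta_*`` are log-odds shifts toward better outcome at time zero;
    ``beta_*_decay`` (per minute, expected <= 0) erodes them with
    onset-to-treatment time; the net effect is floored at zero.
    """

    mrs_untreated_nonlvo: np.ndarray = field(
        default_factory=lambda: np.array([0.20, 0.18, 0.16, 0.16, 0.13, 0.07, 0.10])
    )
    mrs_untreated_lvo: np.ndarray = field(
        default_factory=lambda: np.array([0.02, 0.09, 0.13, 0.16, 0.23, 0.15, 0.22])
    )
    mrs_ich: np.ndarray = field(
        default_factory=lambda: np.array([0.06, 0.09, 0.11, 0.13, 0.15, 0.16, 0.30])
    )
    beta_ivt: float = 1.0
    beta_ivt_decay: float = -0.0025
    beta_evt: float = 2.0
    beta_evt_decay: float = -0.005
    ivt_window: float = 270.0
    evt_window: float = 360.0
    p_ivt_given_eligible: float = 0.55
    p_evt_given_lvo_eligible: float = 0.85
    #: LVO patients receiving both treatments: add the two log-odds deltas
    #: (False: EVT delta alone dominates)
    additive_lvo_effects: bool = True

    def validate(self) -> None:
        for name in ("mrs_untreated_nonlvo", "mrs_untreated_lvo", "mrs_ich"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (7,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ParameterError(f"{name} must be a 7-probability vector summing to 1")
        if self.ivt_window <= 0 or self.evt_window <= 0:
            raise ParameterError("treatment windows must be positive")
        for name in ("p_ivt_given_eligible", "p_evt_given_lvo_eligible"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")

    _VECS = ("mrs_untreated_nonlvo", "mrs_untreated_lvo", "mrs_ich")
    _SCALARS = (
        "beta_ivt",
        "beta_ivt_decay",
        "beta_evt",
        "beta_evt_decay",
        "ivt_window",
        "evt_window",
        "p_ivt_given_eligible",
        "p_evt_given_lvo_eligible",
        "additive_lvo_effects",
    )

    def to_dict(self) -> dict:
        d = {k: np.asarray(getattr(self, k), float).tolist() for k in self._VECS}
        d.update({k: getattr(self, k) for k in self._SCALARS})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeModel":
        kw = {k: np.asarray(d[k], float) for k in cls._VECS}
        kw.update({k: d[k] for k in cls._SCALARS})
        return cls(**kw)


@dataclass
class EconomicParams:
    """Utilities, costs (2021-indexed euros), discounting and the WTP
    threshold.  Long-term annual costs per mRS state rise steeply with
    disability (rehabilitation, long-term care, institutionalisation)."""

    utility_by_mrs: np.ndarray = field(
        default_factory=lambda: np.array([0.95, 0.93, 0.83, 0.62, 0.42, 0.11, 0.0])
    )
    utility_nonstroke: float = 0.95
    annual_cost_by_mrs: np.ndarray = field(
        default_factory=lambda: np.array(
            [1500.0, 4000.0, 11000.0, 22000.0, 48000.0, 75000.0, 0.0]
        )
    )
    annual_cost_nonstroke: float = 1500.0
    acute_ems_ride: float = 700.0
    acute_msu_ride: float = 300.0
    acute_ivt: float = 1100.0
    acute_evt: float = 9500.0
    acute_ed_visit_deduction: float = 400.0
    acute_interhospital_transfer: float = 800.0
    msu_investment_total: float = 1_000_000.0
    msu_depreciation_years: float = 5.0
    msu_operational_annual: float = 250_000.0
    msu_personnel_annual: float = 650_000.0
    discount_effects: float = 0.015
    discount_costs: float = 0.04
    wtp: float = 50_000.0

    def validate(self) -> None:
        u = np.asarray(self.utility_by_mrs, dtype=float)
        if u.shape != (7,) or (u < -0.2).any() or (u > 1.0).any():
            raise ParameterError("utility_by_mrs must be 7 values in [-0.2, 1]")
        if abs(u[6]) > 1e-12:
            raise ParameterError("utility of mRS 6 (death) must be 0")
        for name in ("discount_effects", "discount_costs"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1)")
        if self.msu_depreciation_years <= 0:
            raise ParameterError("msu_depreciation_years must be positive")

    _VECS = ("utility_by_mrs", "annual_cost_by_mrs")

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = np.asarray(v, float).tolist() if f.name in self._VECS else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EconomicParams":
        kw = dict(d)
        for k in cls._VECS:
            kw[k] = np.asarray(kw[k], float)
        return cls(**kw)


def _gompertz_mortality(ages: np.ndarray) -> np.ndarray:
    """Gompertz-shaped annual death probabilities emulating a western-European
    all-cause life table (placeholder, not an official table)."""
    q = 2.0e-5 * np.exp(0.097 * ages)
    return np.clip(q, 0.0, 1.0)


@dataclass
class MortalityParams:
    """Age-dependent background mortality with mRS-specific hazard ratios."""

    ages: np.ndarray = field(default_factory=lambda: np.arange(0, 111, dtype=float))
    annual_mortality_by_age: np.ndarray = field(
        default_factory=lambda: _gompertz_mortality(np.arange(0, 111, dtype=float))
    )
    #: hazard ratio vs the general population, per mRS 0-5
    hr_by_mrs: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.16, 1.52, 2.1, 3.1, 4.5])
    )
    hr_nonstroke: float = 1.0
    max_cycles: int = 100

    def validate(self) -> None:
        a = np.asarray(self.ages, float)
        q = np.asarray(self.annual_mortality_by_age, float)
        if a.shape != q.shape or (q < 0).any() or (q > 1).any():
            raise ParameterError("mortality table malformed")
        if np.asarray(self.hr_by_mrs, float).shape != (6,):
            raise ParameterError("hr_by_mrs must have 6 entries (mRS 0-5)")
        if self.max_cycles < 2:
            raise ParameterError("max_cycles must be >= 2")

    def q_at(self, age: float) -> float:
        """Baseline annual death probability; 1.0 above the table range."""
        a = np.asarray(self.ages, float)
        if age > a[-1]:
            return 1.0
        if age < a[0]:
            raise ParameterError(f"age {age} below mortality table range")
        return float(np.interp(age, a, np.asarray(self.annual_mortality_by_age, float)))

    def to_dict(self) -> dict:
        return {
            "ages": np.asarray(self.ages, float).tolist(),
            "annual_mortality_by_age": np.asarray(self.annual_mortality_by_age, float).tolist(),
            "hr_by_mrs": np.asarray(self.hr_by_mrs, float).tolist(),
            "hr_nonstroke": self.hr_nonstroke,
            "max_cycles": self.max_cycles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MortalityParams":
        return cls(
            ages=np.asarray(d["ages"], float),
            annual_mortality_by_age=np.asarray(d["annual_mortality_by_age"], float),
            hr_by_mrs=np.asarray(d["hr_by_mrs"], float),
            hr_nonstroke=d["hr_nonstroke"],
            max_cycles=d["max_cycles"],
        )


# ---------------------------------------------------------------------------
# top-level config


@dataclass
class ModelConfig:
    epidemiology: EpidemiologyParams = field(default_factory=EpidemiologyParams)
    times: TimeParams = field(default_factory=TimeParams)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    economics: EconomicParams = field(default_factory=EconomicParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    #: PSA parameter distributions: name -> (config path, Distribution)
    psa: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.epidemiology.validate()
        self.times.validate()
        self.outcome.validate()
        self.economics.validate()
        self.mortality.validate()

    def copy(self) -> "ModelConfig":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- parameter paths (used by the PSA and the tornado analysis) --------

    def get_path(self, path: str):
        obj, attr, idx = self._resolve(path)
        v = getattr(obj, attr)
        return v[idx] if idx is not None else v

    def set_path(self, path: str, value) -> None:
        obj, attr, idx = self._resolve(path)
        if idx is not None:
            arr = getattr(obj, attr)
            arr[idx] = value
        else:
            setattr(obj, attr, value)

    def _resolve(self, path: str):
        parts = path.split(".")
        obj = self
        for p in parts[:-1]:
            obj = getattr(obj, p)
        last = parts[-1]
        idx = None
        if "[" in last:
            last, rest = last.split("[", 1)
            idx = int(rest.rstrip("]"))
        if not hasattr(obj, last):
            raise ParameterError(f"unknown parameter path {path!r}")
        return obj, last, idx

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "epidemiology": self.epidemiology.to_dict(),
            "times": self.times.to_dict(),
            "outcome": self.outcome.to_dict(),
            "economics": self.economics.to_dict(),
            "mortality": self.mortality.to_dict(),
            "psa": {k: {"path": p, "dist": d.to_dict()} for k, (p, d) in self.psa.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            epidemiology=EpidemiologyParams.from_dict(d["epidemiology"]),
            times=TimeParams.from_dict(d["times"]),
            outcome=OutcomeModel.from_dict(d["outcome"]),
            economics=EconomicParams.from_dict(d["economics"]),
            mortality=MortalityParams.from_dict(d["mortality"]),
            psa={
                k: (v["path"], Distribution.from_dict(v["dist"]))
                for k, v in d.get("psa", {}).items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_psa_distributions() -> dict:
    """Standard PSA set: beta for probabilities, gamma for costs, normal for
    treatment-effect log-odds."""
    return {
        "p_mimic": ("epidemiology.p_mimic", beta_mean_k(0.25, 200)),
        "p_tia": ("epidemiology.p_tia", beta_mean_k(0.16, 200)),
        "p_ich": ("epidemiology.p_ich", beta_mean_k(0.07, 200)),
        "p_lvo_given_ischemic": ("epidemiology.p_lvo_given_ischemic", beta_mean_k(0.23, 150)),
        "beta_ivt": ("outcome.beta_ivt", Distribution("normal", {"mu": 1.0, "sd": 0.12})),
        "beta_evt": ("outcome.beta_evt", Distribution("normal", {"mu": 2.0, "sd": 0.25})),
        "p_ivt": ("outcome.p_ivt_given_eligible", beta_mean_k(0.55, 80)),
        "p_evt": ("outcome.p_evt_given_lvo_eligible", beta_mean_k(0.85, 80)),
        "cost_msu_ride": ("economics.acute_msu_ride", gamma_mean_cv(300.0, 0.20)),
        "cost_mrs3": ("economics.annual_cost_by_mrs[3]", gamma_mean_cv(22000.0, 0.15)),
        "cost_mrs4": ("economics.annual_cost_by_mrs[4]", gamma_mean_cv(48000.0, 0.15)),
        "cost_mrs5": ("economics.annual_cost_by_mrs[5]", gamma_mean_cv(75000.0, 0.15)),
        "msu_personnel": ("economics.msu_personnel_annual", gamma_mean_cv(650_000.0, 0.10)),
    }


def default_config(psa: bool = True) -> ModelConfig:
    cfg = ModelConfig()
    if psa:
        cfg.psa = default_psa_distributions()
    cfg.validate()
    return cfg
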