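"""Study-region representation and synthetic-region generation.

A region is a set of postal-code-like zones (planar km coordinates,
population per 5-year age band), stroke centers (primary or
thrombectomy-capable, each with its in-hospital workflow times), ambulance
dispatch sites, and a travel-time matrix in minutes covering every
(site, zone) and (zone, hospital) pair.  Travel times are supplied, never
computed from a road network; synthetic regions derive them from Euclidean
distance with a detour factor, which is the standard road-network
approximation.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_BAND_LABELS, N_AGE_BANDS, ParameterError


class RegionValidationError(ValueError):
    """Region file contents violate an invariant."""


class ConfigurationError(ValueError):
    """Region lacks a facility the requested operation needs."""


@dataclass
class Zone:
    zone_id: str
    x_km: float
    y_km: float
    population_by_age: np.ndarray  # counts per 5-year band, 0-4 ... 95+

    def __post_init__(self) -> None:
        p = np.asarray(self.population_by_age, dtype=float)
        if p.shape != (N_AGE_BANDS,):
            raise RegionValidationError(
                f"zone {self.zone_id}: expected {N_AGE_BANDS} age bands, got {p.shape}"
            )
        if (p < 0).any():
            raise RegionValidationError(f"zone {self.zone_id}: negative population count")
        self.population_by_age = p

    @property
    def population(self) -> float:
        return float(self.population_by_age.sum())


@dataclass
class Hospital:
    hospital_id: str
    x_km: float
    y_km: float
    tsc: bool
    door_to_needle: float
    door_to_groin: float | None = None  # TSC only
    door_in_door_out: float | None = None  # non-TSC only

    def __post_init__(self) -> None:
        if self.tsc and self.door_to_groin is None:
            raise RegionValidationError(f"hospital {self.hospital_id}: TSC requires door_to_groin")
        if not self.tsc and self.door_to_groin is not None:
            raise RegionValidationError(
                f"hospital {self.hospital_id}: door_to_groin set on a non-TSC"
            )
        if not self.tsc and self.door_in_door_out is None:
            raise RegionValidationError(
                f"hospital {self.hospital_id}: non-TSC requires door_in_door_out"
            )
        for name in ("door_to_needle", "door_to_groin", "door_in_door_out"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RegionValidationError(f"hospital {self.hospital_id}: {name} < 0")


@dataclass
class DispatchSite:
    site_id: str
    x_km: float
    y_km: float
    msu_capable: bool = False


@dataclass
class RegionSpec:
    """Zones, hospitals, dispatch sites and the travel-time lookup.

    ``travel`` maps (from_id, to_id) -> minutes for every (site, zone) and
    (zone, hospital) pair.  The triangle inequality is NOT assumed.
    Hospital-to-hospital transfer legs fall back to a coordinate-based
    estimate (Euclidean x detour / speed) unless an explicit row exists.
    """

    zones: list[Zone]
    hospitals: list[Hospital]
    sites: list[DispatchSite]
    travel: dict = field(default_factory=dict)
    speed_kmh: float = 65.0
    detour_factor: float = 1.3

    def __post_init__(self) -> None:
        self._zone_by_id = {z.zone_id: z for z in self.zones}
        self._hosp_by_id = {h.hospital_id: h for h in self.hospitals}
        self._site_by_id = {s.site_id: s for s in self.sites}

    def validate(self) -> None:
        if not self.sites:
            raise RegionValidationError("at least one dispatch site is required")
        missing = []
        for s in self.sites:
            for z in self.zones:
                if (s.site_id, z.zone_id) not in self.travel:
                    missing.append((s.site_id, z.zone_id))
        for z in self.zones:
            for h in self.hospitals:
                if (z.zone_id, h.hospital_id) not in self.travel:
                    missing.append((z.zone_id, h.hospital_id))
        if missing:
            raise RegionValidationError(f"travel matrix missing pairs: {missing[:10]}")
        for k, v in self.travel.items():
            if v < 0:
                raise RegionValidationError(f"negative travel time for pair {k}")

    # -- lookups -----------------------------------------------------------

    def zone(self, zone_id: str) -> Zone:
        return self._zone_by_id[zone_id]

    def hospital(self, hospital_id: str) -> Hospital:
        return self._hosp_by_id[hospital_id]

    def site(self, site_id: str) -> DispatchSite:
        return self._site_by_id[site_id]

    def travel_time(self, from_id: str, to_id: str) -> float:
        return float(self.travel[(from_id, to_id)])

    def transfer_time(self, from_hospital: str, to_hospital: str) -> float:
        """Interhospital driving time; explicit matrix row if present, else
        the Euclidean-detour estimate between hospital coordinates."""
        key = (from_hospital, to_hospital)
        if key in self.travel:
            return float(self.travel[key])
        a = self._hosp_by_id[from_hospital]
        b = self._hosp_by_id[to_hospital]
        d = float(np.hypot(a.x_km - b.x_km, a.y_km - b.y_km))
        return d * self.detour_factor / self.speed_kmh * 60.0

    @property
    def total_population(self) -> float:
        return float(sum(z.population for z in self.zones))

    def summary(self) -> dict:
        return {
            "n_zones": len(self.zones),
            "n_psc": sum(not h.tsc for h in self.hospitals),
            "n_tsc": sum(h.tsc for h in self.hospitals),
            "n_sites": len(self.sites),
            "total_population": self.total_population,
        }


# ---------------------------------------------------------------------------
# routing


def nearest_hospital(region: RegionSpec, zone: Zone | str, require_tsc: bool = False) -> Hospital:
    """Hospital minimising zone->hospital travel time among qualifying
    hospitals (all, or thrombectomy-capable only); ties broken by
    lexicographic hospital_id."""
    zid = zone if isinstance(zone, str) else zone.zone_id
    candidates = [h for h in region.hospitals if h.tsc or not require_tsc]
    if not candidates:
        raise ConfigurationError(
            "no thrombectomy-capable hospital in region" if require_tsc else "no hospitals in region"
        )
    return min(candidates, key=lambda h: (region.travel_time(zid, h.hospital_id), h.hospital_id))


def nearest_site(region: RegionSpec, zone: Zone | str) -> DispatchSite:
    """EMS dispatch site minimising site->zone travel time (ties by id)."""
    zid = zone if isinstance(zone, str) else zone.zone_id
    return min(region.sites, key=lambda s: (region.travel_time(s.site_id, zid), s.site_id))


# ---------------------------------------------------------------------------
# synthetic generation

#: western-European national age pyramid, share of population per 5-year band
_PYRAMID = np.array(
    [5.0, 5.3, 5.6, 5.8, 6.2, 6.5, 6.4, 6.0, 5.9, 6.5, 7.0, 6.9, 6.3, 5.6, 5.3, 4.0, 2.6, 1.5, 0.6, 0.15]
)
_PYRAMID = _PYRAMID / _PYRAMID.sum()


def generate_synthetic_region(
    n_zones: int = 60,
    n_psc: int = 7,
    n_tsc: int = 2,
    n_sites: int = 5,
    total_population: int = 1_770_000,
    area_km2: float = 1592.0,
    density_profile: float = 10.0,
    speed_kmh: float = 65.0,
    detour_factor: float = 1.3,
    seed: int = 0,
) -> RegionSpec:
    """Generate a synthetic region emulating a mixed urban/suburban ambulance
    catchment: zones scattered on a plane with population density decaying
    away from an urban core, a national-style age pyramid with zone-level
    noise, primary and thrombectomy-capable stroke centers placed in
    population centres, and EMS dispatch sites (the first is MSU-capable).

    density_profile is the e-folding distance (km) of the urban-core density
    decay; travel time = Euclidean distance x detour_factor / speed.
    Deterministic given seed.
    """
    if n_zones < 1:
        raise ParameterError("n_zones must be >= 1")
    if n_psc < 0 or n_tsc < 0 or n_psc + n_tsc < 1:
        raise ParameterError("need at least one hospital")
    if n_sites < 1:
        raise ParameterError("need at least one dispatch site")
    if speed_kmh <= 0 or detour_factor <= 0:
        raise ParameterError("speed and detour factor must be positive")
    if total_population < 0 or area_km2 <= 0:
        raise ParameterError("population must be >= 0 and area positive")

    rng = np.random.default_rng(seed)
    side = float(np.sqrt(area_km2))
    centre = np.array([side / 2.0, side / 2.0])

    # zone locations: mixture of a clustered urban core and a uniform spread
    n_core = max(1, int(round(0.5 * n_zones)))
    core = centre + rng.normal(scale=density_profile * 0.6, size=(n_core, 2))
    rest = rng.uniform(0.0, side, size=(n_zones - n_core, 2))
    xy = np.clip(np.vstack([core, rest]), 0.0, side)

    # population weights: exponential decay from the core plus zone noise
    r = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
    w = np.exp(-r / density_profile) + 0.05
    w = w * rng.lognormal(0.0, 0.35, n_zones)
    w = w / w.sum()
    zone_pops = rng.multinomial(int(total_population), w)

    zones = []
    for i in range(n_zones):
        # zone-level age-structure noise around the national pyramid
        alpha = np.maximum(_PYRAMID * 300.0, 1e-3)
        shares = rng.dirichlet(alpha)
        ages = rng.multinomial(int(zone_pops[i]), shares)
        zones.append(Zone(f"Z{i:03d}", float(xy[i, 0]), float(xy[i, 1]), ages.astype(float)))

    # hospitals near population mass, kept apart from one another
    n_hosp = n_psc + n_tsc
    order = np.argsort(-zone_pops)
    chosen: list[int] = []
    min_sep = side / max(2.0, np.sqrt(n_hosp) + 1.0)
    for idx in order:
        if len(chosen) == n_hosp:
            break
        if all(np.hypot(*(xy[idx] - xy[j])) >= min_sep for j in chosen):
            chosen.append(int(idx))
    k = 0
    while len(chosen) < n_hosp:  # relax separation if the region is tiny
        if k >= len(order):  # more hospitals than zones: reuse (jittered)
            chosen.append(int(order[k % len(order)]))
        elif int(order[k]) not in chosen:
            chosen.append(int(order[k]))
        k += 1

    hospitals = []
    # thrombectomy capability is spread over the ranked centres (not simply
    # the largest ones), so most zones' nearest hospital is a primary center
    # and the drip-and-ship share resembles a multi-PSC region
    tsc_positions = set(
        int(round(x)) for x in np.linspace(1, n_hosp - 1, n_tsc)
    ) if n_hosp > n_tsc else set(range(n_tsc))
    while len(tsc_positions) < n_tsc:
        tsc_positions.add(min(set(range(n_hosp)) - tsc_positions))
    for j, idx in enumerate(chosen):
        pos = xy[idx] + rng.normal(scale=1.0, size=2)
        tsc = j in tsc_positions
        if tsc:
            hospitals.append(
                Hospital(
                    f"H{j:02d}", float(pos[0]), float(pos[1]), True,
                    door_to_needle=max(10.0, float(rng.normal(25.0, 3.0))),
                    door_to_groin=max(20.0, float(rng.normal(60.0, 8.0))),
                )
            )
        else:
            hospitals.append(
                Hospital(
                    f"H{j:02d}", float(pos[0]), float(pos[1]), False,
                    door_to_needle=max(10.0, float(rng.normal(25.0, 3.0))),
                    door_in_door_out=max(20.0, float(rng.normal(60.0, 10.0))),
                )
            )

    # dispatch sites near population mass; site S00 is MSU-capable
    sites = []
    seen: list[int] = []
    for idx in [chosen[0]] + [int(i) for i in order]:
        if idx not in seen:
            seen.append(idx)
        if len(seen) == n_sites:
            break
    while len(seen) < n_sites:  # more sites than zones: reuse zones (jittered)
        seen.append(int(order[len(seen) % len(order)]))
    for j, idx in enumerate(seen):
        pos = xy[idx] + rng.normal(scale=0.8, size=2)
        sites.append(DispatchSite(f"S{j:02d}", float(pos[0]), float(pos[1]), msu_capable=j == 0))

    def _tt(ax, ay, bx, by) -> float:
        return float(np.hypot(ax - bx, ay - by) * detour_factor / speed_kmh * 60.0)

    travel: dict = {}
    for s in sites:
        for z in zones:
            travel[(s.site_id, z.zone_id)] = _tt(s.x_km, s.y_km, z.x_km, z.y_km)
    for z in zones:
        for h in hospitals:
            travel[(z.zone_id, h.hospital_id)] = _tt(z.x_km, z.y_km, h.x_km, h.y_km)

    region = RegionSpec(zones, hospitals, sites, travel, speed_kmh=speed_kmh, detour_factor=detour_factor)
    region.validate()
    return region


# ---------------------------------------------------------------------------
# file I/O

_POP_COLS = [f"pop_{lbl}" for lbl in AGE_BAND_LABELS]


def write_region(region: RegionSpec, outdir) -> None:
    """Write zones.csv, hospitals.csv, sites.csv, travel.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    zrows = []
    for z in region.zones:
        row = {"zone_id": z.zone_id, "x_km": z.x_km, "y_km": z.y_km}
        row.update({c: int(p) for c, p in zip(_POP_COLS, z.population_by_age)})
        zrows.append(row)
    pd.DataFrame(zrows).to_csv(outdir / "zones.csv", index=False)

    hrows = [
        {
            "hospital_id": h.hospital_id,
            "x_km": h.x_km,
            "y_km": h.y_km,
            "tsc": int(h.tsc),
            "dtn_min": h.door_to_needle,
            "dtg_min": "" if h.door_to_groin is None else h.door_to_groin,
            "dido_min": "" if h.door_in_door_out is None else h.door_in_door_out,
        }
        for h in region.hospitals
    ]
    pd.DataFrame(hrows).to_csv(outdir / "hospitals.csv", index=False)

    srows = [
        {"site_id": s.site_id, "x_km": s.x_km, "y_km": s.y_km, "msu_capable": int(s.msu_capable)}
        for s in region.sites
    ]
    pd.DataFrame(srows).to_csv(outdir / "sites.csv", index=False)

    trows = [{"from_id": a, "to_id": b, "minutes": m} for (a, b), m in sorted(region.travel.items())]
    pd.DataFrame(trows).to_csv(outdir / "travel.csv", index=False)


def _require_cols(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RegionValidationError(f"{fname}: missing columns {missing}")


def read_region(indir, speed_kmh: float = 65.0, detour_factor: float = 1.3) -> RegionSpec:
    """Read a region from zones.csv / hospitals.csv / sites.csv / travel.csv,
    validating schemas, invariants and travel-matrix completeness."""
    indir = Path(indir)
    zdf = pd.read_csv(indir / "zones.csv")
    _require_cols(zdf, ["zone_id", "x_km", "y_km"] + _POP_COLS, "zones.csv")
    zones = [
        Zone(str(r["zone_id"]), float(r["x_km"]), float(r["y_km"]),
             np.array([float(r[c]) for c in _POP_COLS]))
        for _, r in zdf.iterrows()
    ]

    hdf = pd.read_csv(indir / "hospitals.csv")
    _require_cols(hdf, ["hospital_id", "x_km", "y_km", "tsc", "dtn_min", "dtg_min", "dido_min"], "hospitals.csv")
    hospitals = []
    for _, r in hdf.iterrows():
        dtg = None if pd.isna(r["dtg_min"]) else float(r["dtg_min"])
        dido = None if pd.isna(r["dido_min"]) else float(r["dido_min"])
        hospitals.append(
            Hospital(str(r["hospital_id"]), float(r["x_km"]), float(r["y_km"]),
                     bool(int(r["tsc"])), float(r["dtn_min"]), dtg, dido)
        )

    sdf = pd.read_csv(indir / "sites.csv")
    _require_cols(sdf, ["site_id", "x_km", "y_km", "msu_capable"], "sites.csv")
    sites = [
        DispatchSite(str(r["site_id"]), float(r["x_km"]), float(r["y_km"]), bool(int(r["msu_capable"])))
        for _, r in sdf.iterrows()
    ]

    tdf = pd.read_csv(indir / "travel.csv")
    _require_cols(tdf, ["from_id", "to_id", "minutes"], "travel.csv")
    known = {z.zone_id for z in zones} | {h.hospital_id for h in hospitals} | {s.site_id for s in sites}
    travel: dict = {}
    for i, r in tdf.iterrows():
        a, b, m = str(r["from_id"]), str(r["to_id"]), float(r["minutes"])
        if a not in known or b not in known:
            raise RegionValidationError(f"travel.csv row {i}: dangling id ({a}, {b})")
        if m < 0:
            raise RegionValidationError(f"travel.csv row {i}: negative minutes for ({a}, {b})")
        travel[(a, b)] = m

    region = RegionSpec(zones, hospitals, sites, travel, speed_kmh=speed_kmh, detour_factor=detour_factor)
    region.validate()
    return region


def region_fingerprint(region: RegionSpec) -> str:
    """Stable content digest of a region (determinism checks)."""
    import hashlib

    buf = io.StringIO()
    for z in region.zones:
        buf.write(f"{z.zone_id},{z.x_km:.9f},{z.y_km:.9f},{','.join(str(int(p)) for p in z.population_by_age)}\n")
    for h in region.hospitals:
        buf.write(f"{h.hospital_id},{h.x_km:.9f},{h.y_km:.9f},{h.tsc},{h.door_to_needle:.9f},{h.door_to_groin},{h.door_in_door_out}\n")
    for s in region.sites:
        buf.write(f"{s.site_id},{s.x_km:.9f},{s.y_km:.9f},{s.msu_capable}\n")
    for (a, b), m in sorted(region.travel.items()):
        buf.write(f"{a},{b},{m:.9f}\n")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
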