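"""Synthetic multi-track Sentinel-1-like scene generator.

Emulates the statistical structure the retrieval pipeline assumes: two
descending relative orbits observed at distinct local incidence angles
(path 141 near 33°, path 68 near 43°), 6/12-day acquisition calendars,
dual-polarization γ0 backscatter driven by a double-logistic winter-wheat
LAI curve through a water-cloud-style forward model with multiplicative
gamma speckle, irrigation-driven soil-moisture pulses, and in situ LAI
sampling as the average of n replicate noisy observations per 10 m ESU.

Every stochastic output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Polygon, box, mapping

from .raster import Raster, polygon_mask, write_ascii

# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------


@dataclass
class PhenologyParams:
    """Double-logistic seasonal LAI course (day indices are day-of-season).

    The curve is the product of a rising and a falling logistic, scaled so
    its interior maximum equals ``peak_lai``, clamped to zero before
    emergence and from harvest onward.  The rising inflection sits one
    third of the way from emergence to senescence onset.
    """

    emergence_day: int = 5
    peak_lai: float = 4.1           # m² m⁻², seasonal maximum
    growth_rate: float = 0.085      # d⁻¹
    senescence_onset_day: int = 88  # falling-logistic midpoint
    senescence_rate: float = 0.12   # d⁻¹
    harvest_day: int = 130

    def __post_init__(self) -> None:
        if self.peak_lai <= 0:
            raise ValueError("peak_lai must be positive")
        if not (self.emergence_day < self.senescence_onset_day < self.harvest_day):
            raise ValueError("need emergence < senescence onset < harvest")
        if self.growth_rate <= 0 or self.senescence_rate <= 0:
            raise ValueError("rates must be positive")

    @property
    def rise_midpoint(self) -> float:
        return self.emergence_day + (self.senescence_onset_day
                                     - self.emergence_day) / 3.0

    def _raw(self, t: np.ndarray) -> np.ndarray:
        up = 1.0 / (1.0 + np.exp(-self.growth_rate * (t - self.rise_midpoint)))
        down = 1.0 / (1.0 + np.exp(
            self.senescence_rate * (t - self.senescence_onset_day)))
        return up * down

    def peak_day(self) -> float:
        """Analytic argmax of the double-logistic (root of d log f / dt)."""
        rg, rs = self.growth_rate, self.senescence_rate

        def dlogf(t: float) -> float:
            su = 1.0 / (1.0 + np.exp(-rg * (t - self.rise_midpoint)))
            sd = 1.0 / (1.0 + np.exp(rs * (t - self.senescence_onset_day)))
            return rg * (1.0 - su) - rs * (1.0 - sd)

        return brentq(dlogf, self.emergence_day - 50, self.harvest_day + 50)


def simulate_lai(params: PhenologyParams, days: np.ndarray) -> np.ndarray:
    """LAI (m² m⁻²) at the given day-of-season values, ascending order."""
    t = np.asarray(days, dtype=np.float64)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("days must be 1-D and sorted ascending")
    scale = params.peak_lai / params._raw(np.array([params.peak_day()]))[0]
    lai = scale * params._raw(t)
    lai[(t < params.emergence_day) | (t >= params.harvest_day)] = 0.0
    return lai


# ---------------------------------------------------------------------------
# forward backscatter model
# ---------------------------------------------------------------------------


@dataclass
class PolCoeffs:
    A: float    # vegetation volume-scattering amplitude, linear power
    B: float    # two-way canopy attenuation per unit LAI
    C: float    # dry-soil backscatter level, dB
    D: float    # backscatter gain per unit volumetric soil moisture, dB


@dataclass
class ForwardModelParams:
    """Water-cloud-style two-term γ0 model, summed in linear power.

    γ0_lin = A·cosθ·(1 − e^(−2B·LAI/cosθ)) + cos²θ·S(mv)·e^(−2B·LAI/cosθ)
    with S(mv) = 10^((C + D·mv)/10).  Monotone non-decreasing in LAI while
    A ≥ cosθ·S(mv) (true for the defaults at volumetric moisture ≤ 0.45),
    and strictly decreasing in the local incidence angle θ.
    """

    vh: PolCoeffs = field(default_factory=lambda: PolCoeffs(0.12, 0.35, -24.0, 15.0))
    vv: PolCoeffs = field(default_factory=lambda: PolCoeffs(0.25, 0.25, -17.0, 18.0))

    def __post_init__(self) -> None:
        for c in (self.vh, self.vv):
            if c.A <= 0 or c.B <= 0 or c.D <= 0:
                raise ValueError("A, B, D must be positive")

    def coeffs(self, pol: str) -> PolCoeffs:
        try:
            return {"VH": self.vh, "VV": self.vv}[pol.upper()]
        except KeyError:
            raise ValueError(f"unknown polarization {pol!r}") from None


def simulate_backscatter(lai, lia, soil_moisture, pol: str,
                         fm: ForwardModelParams | None = None,
                         enl: float | None = None,
                         rng: np.random.Generator | None = None):
    """γ0 in dB for given LAI, local incidence angle (deg) and moisture.

    With ``enl`` finite, multiplicative unit-mean gamma speckle of shape
    ENL is applied in linear power before dB conversion (seeded ``rng``
    required); with ``enl`` None/inf the output is deterministic.
    """
    fm = fm or ForwardModelParams()
    lai = np.asarray(lai, dtype=np.float64)
    lia = np.asarray(lia, dtype=np.float64)
    sm = np.asarray(soil_moisture, dtype=np.float64)
    if np.any(lai < 0):
        raise ValueError("lai must be non-negative")
    if np.any((lia <= 0) | (lia >= 90)):
        raise ValueError("local incidence angle must lie in (0, 90) degrees")
    if np.any((sm < 0) | (sm > 1)):
        raise ValueError("soil moisture must lie in [0, 1]")
    c = fm.coeffs(pol)
    cos_t = np.cos(np.deg2rad(lia))
    atten = np.exp(-2.0 * c.B * lai / cos_t)
    soil_lin = 10.0 ** ((c.C + c.D * sm) / 10.0)
    power = c.A * cos_t * (1.0 - atten) + cos_t ** 2 * soil_lin * atten
    if enl is not None and np.isfinite(enl):
        if enl <= 0:
            raise ValueError("enl must be positive")
        if rng is None:
            raise ValueError("speckled simulation requires a seeded rng")
        power = power * rng.gamma(enl, 1.0 / enl, size=np.shape(power))
    return 10.0 * np.log10(power)


def soil_moisture_at(day: float, base: float,
                     events: list[tuple[int, float, float]]) -> float:
    """Volumetric soil moisture: base + exponential-decay pulses."""
    mv = base
    for ev_day, amp, decay in events:
        if day >= ev_day:
            mv += amp * np.exp(-(day - ev_day) / decay)
    return float(np.clip(mv, 0.0, 1.0))


# ---------------------------------------------------------------------------
# scene configuration
# ---------------------------------------------------------------------------


@dataclass
class TrackSpec:
    platform: str              # "S1A" | "S1B"
    orbit: int                 # relative orbit number
    pass_direction: str        # "DESC" | "ASC"
    revisit_days: int          # per-platform cadence
    first_date: date
    mean_lia: float            # degrees
    lia_sd: float              # spatial SD, degrees

    @property
    def tag(self) -> str:
        return f"{self.platform}-{self.orbit}"


def default_tracks() -> list[TrackSpec]:
    # path 141: S1-A only (12-day); path 68: S1-A + S1-B interleaved (6-day)
    return [
        TrackSpec("S1A", 141, "DESC", 12, date(2020, 9, 1), 33.0, 0.5),
        TrackSpec("S1A", 68, "DESC", 12, date(2020, 9, 8), 43.0, 0.5),
        TrackSpec("S1B", 68, "DESC", 12, date(2020, 9, 2), 43.0, 0.5),
    ]


def default_sampling_dates() -> list[date]:
    # field campaign dates inside the green-up window used for training
    # (later senescence-stage visits are excluded from the sample database)
    return [date(2020, 9, 3), date(2020, 9, 17), date(2020, 10, 2),
            date(2020, 10, 19), date(2020, 11, 2)]


@dataclass
class SceneConfig:
    rows: int = 60
    cols: int = 60
    cell: float = 10.0
    x_min: float = 500_000.0
    y_max: float = 5_640_000.0
    crs: str = "EPSG:32720"
    tracks: list[TrackSpec] = field(default_factory=default_tracks)
    season_start: date = date(2020, 8, 27)
    season_end: date = date(2021, 1, 12)
    # irrigation / rain pulses: (day-of-season, amplitude, decay days)
    soil_events: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(1, 0.20, 10.0), (20, 0.20, 10.0),
                                 (90, 0.20, 10.0)])
    soil_moisture_base: float = 0.08
    enl: float = 10.0                  # equivalent number of looks
    esu_noise_sd: float = 0.5          # per-replicate LAI noise, m² m⁻²
    n_replicates: int = 6
    n_esus_per_paddock: int = 3
    n_nonveg: int = 12
    sampling_dates: list[date] = field(default_factory=default_sampling_dates)
    pixel_scale_sd: float = 0.10       # lognormal SD of per-pixel peak scaling
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    forward: ForwardModelParams = field(default_factory=ForwardModelParams)
    seed: int = 12345

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("at least one track required")
        for t in self.tracks:
            if t.revisit_days not in (6, 12):
                raise ValueError("revisit days must be 6 or 12")
        if self.enl <= 0:
            raise ValueError("ENL must be positive")
        if self.rows < 4 or self.cols < 4:
            raise ValueError("grid too small")

    def day_of(self, d: date) -> int:
        return (d - self.season_start).days

    def grid_raster(self, fill: float = 0.0) -> Raster:
        return Raster(np.full((self.rows, self.cols), fill), self.x_min,
                      self.y_max, self.cell, self.crs)


def default_paddocks(config: SceneConfig) -> list[tuple[str, Polygon]]:
    """Three axis-aligned rectangular paddocks inside the scene."""
    w = config.cols * config.cell
    h = config.rows * config.cell
    x0, y0 = config.x_min, config.y_max - h

    def rect(fx0, fy0, fx1, fy1):
        return box(x0 + fx0 * w, y0 + fy0 * h, x0 + fx1 * w, y0 + fy1 * h)

    return [("321", rect(0.08, 0.55, 0.42, 0.92)),
            ("322", rect(0.52, 0.50, 0.92, 0.90)),
            ("323", rect(0.10, 0.08, 0.46, 0.42))]


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


@dataclass
class TrackData:
    spec: TrackSpec
    lia: Raster
    dates: list[date]
    vh: dict[date, Raster]
    vv: dict[date, Raster]

    @property
    def tag(self) -> str:
        return self.spec.tag


@dataclass
class Scene:
    config: SceneConfig
    tracks: list[TrackData]
    esu_table: pd.DataFrame          # esu_id, x, y, date, lai, n_obs
    nonveg_table: pd.DataFrame       # bare-soil augmentation rows, label 0
    paddocks: list[tuple[str, Polygon]]
    lai_scale: Raster                # per-pixel peak multiplier, 0 off-paddock

    def truth_lai(self, d: date) -> Raster:
        day = self.config.day_of(d)
        base = simulate_lai(self.config.phenology, np.array([float(day)]))[0]
        return self.lai_scale.copy_with(self.lai_scale.data * base)

    def track(self, tag: str) -> TrackData:
        for t in self.tracks:
            if t.tag == tag:
                return t
        raise KeyError(f"no track {tag!r} in scene")

    def calendars(self) -> dict[str, list[date]]:
        return {t.tag: list(t.dates) for t in self.tracks}

    def union_dates(self) -> list[date]:
        out: set[date] = set()
        for t in self.tracks:
            out.update(t.dates)
        return sorted(out)


def _track_calendar(spec: TrackSpec, start: date, end: date) -> list[date]:
    dates = []
    d = spec.first_date
    while d <= end:
        if d >= start:
            dates.append(d)
        d += timedelta(days=spec.revisit_days)
    if not dates:
        raise ValueError(f"track {spec.tag} has no acquisitions in season")
    return dates


def generate_scene(config: SceneConfig,
                   paddocks: list[tuple[str, Polygon]] | None = None) -> Scene:
    """Build the full synthetic world; bit-identical for identical seeds."""
    paddocks = paddocks if paddocks is not None else default_paddocks(config)
    for pid, poly in paddocks:
        if poly.area <= 0:
            raise ValueError(f"paddock {pid} has zero area")
    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_lia, rng_speckle, rng_esu, rng_pts = (
        np.random.default_rng(s) for s in ss.spawn(5))

    grid = config.grid_raster()
    crop_mask = polygon_mask(grid, [p for _, p in paddocks])

    # per-pixel peak-LAI multiplier (lognormal, unit median), 0 off-paddock
    scale = np.exp(rng_field.normal(0.0, config.pixel_scale_sd,
                                    size=(config.rows, config.cols)))
    scale[~crop_mask] = 0.0
    lai_scale = grid.copy_with(scale)

    # one LIA raster per relative orbit, shared between platforms
    lia_by_orbit: dict[int, Raster] = {}
    for spec in config.tracks:
        if spec.orbit not in lia_by_orbit:
            field_ = spec.mean_lia + rng_lia.normal(
                0.0, spec.lia_sd, size=(config.rows, config.cols))
            lia_by_orbit[spec.orbit] = grid.copy_with(field_)

    scene_days = lambda d: float(config.day_of(d))
    tracks: list[TrackData] = []
    for spec in config.tracks:
        cal = _track_calendar(spec, config.season_start, config.season_end)
        lia = lia_by_orbit[spec.orbit]
        vh: dict[date, Raster] = {}
        vv: dict[date, Raster] = {}
        for d in cal:
            day = scene_days(d)
            lai = lai_scale.data * simulate_lai(
                config.phenology, np.array([day]))[0]
            mv = soil_moisture_at(day, config.soil_moisture_base,
                                  config.soil_events)
            for pol, store in (("VH", vh), ("VV", vv)):
                g0 = simulate_backscatter(lai, lia.data, mv, pol,
                                          config.forward, config.enl,
                                          rng_speckle)
                store[d] = grid.copy_with(g0)
        tracks.append(TrackData(spec, lia, cal, vh, vv))

    # ESU locations: pixel centers inside paddocks, drawn without replacement
    xg, yg = grid.pixel_centers()
    esu_rows = []
    esu_id = 0
    for pid, poly in paddocks:
        mask = polygon_mask(grid, [poly])
        flat = np.flatnonzero(mask)
        if flat.size == 0:
            raise ValueError(f"paddock {pid} covers no pixel centers")
        take = min(config.n_esus_per_paddock, flat.size)
        chosen = rng_pts.choice(flat, size=take, replace=False)
        for idx in chosen:
            esu_id += 1
            r, c = np.unravel_index(idx, mask.shape)
            esu_rows.append((f"ESU{esu_id:02d}", float(xg[r, c]),
                             float(yg[r, c]), r, c))

    records = []
    for name, x, y, r, c in esu_rows:
        for d in config.sampling_dates:
            truth = lai_scale.data[r, c] * simulate_lai(
                config.phenology, np.array([scene_days(d)]))[0]
            reps = truth + rng_esu.normal(0.0, config.esu_noise_sd,
                                          size=config.n_replicates)
            records.append({"esu_id": name, "x": x, "y": y,
                            "date": d.isoformat(),
                            "lai": max(0.0, float(np.mean(reps))),
                            "n_obs": config.n_replicates})
    esu_table = pd.DataFrame.from_records(records)

    # non-vegetated augmentation samples from bare (off-paddock) pixels
    bare = np.flatnonzero(~crop_mask)
    n_nv = min(config.n_nonveg, bare.size)
    chosen = rng_pts.choice(bare, size=n_nv, replace=False)
    nv_records = []
    for i, idx in enumerate(chosen):
        r, c = np.unravel_index(idx, crop_mask.shape)
        d = config.sampling_dates[i % len(config.sampling_dates)]
        nv_records.append({"esu_id": f"NV{i + 1:02d}", "x": float(xg[r, c]),
                           "y": float(yg[r, c]), "date": d.isoformat(),
                           "lai": 0.0, "n_obs": config.n_replicates})
    nonveg_table = pd.DataFrame.from_records(nv_records)

    return Scene(config, tracks, esu_table, nonveg_table, paddocks, lai_scale)


# ---------------------------------------------------------------------------
# config (de)serialization and on-disk layout
# ---------------------------------------------------------------------------


def config_to_dict(cfg: SceneConfig) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    d["season_start"] = cfg.season_start.isoformat()
    d["season_end"] = cfg.season_end.isoformat()
    d["sampling_dates"] = [x.isoformat() for x in cfg.sampling_dates]
    d["tracks"] = [{**t, "first_date": t["first_date"].isoformat()}
                   for t in d["tracks"]]
    return d


def config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    d["season_start"] = date.fromisoformat(d["season_start"])
    d["season_end"] = date.fromisoformat(d["season_end"])
    d["sampling_dates"] = [date.fromisoformat(x) for x in d["sampling_dates"]]
    d["tracks"] = [TrackSpec(**{**t, "first_date":
                                date.fromisoformat(t["first_date"])})
                   for t in d["tracks"]]
    d["soil_events"] = [tuple(e) for e in d["soil_events"]]
    ph = d["phenology"]
    d["phenology"] = ph if isinstance(ph, PhenologyParams) else PhenologyParams(**ph)
    fm = d["forward"]
    if not isinstance(fm, ForwardModelParams):
        d["forward"] = ForwardModelParams(PolCoeffs(**fm["vh"]),
                                          PolCoeffs(**fm["vv"]))
    return SceneConfig(**d)


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, str]:
    """Write rasters (.asc), ESU CSV and paddock GeoJSON; returns path map."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for t in scene.tracks:
        tag = f"{t.spec.platform}_{t.spec.orbit}"
        lia_path = out / f"LIA_{tag}.asc"
        write_ascii(t.lia, lia_path)
        paths[f"lia_{tag}"] = str(lia_path)
        for d in t.dates:
            for pol, store in (("VH", t.vh), ("VV", t.vv)):
                p = out / f"{tag}_{d.strftime('%Y%m%d')}_{pol}.asc"
                write_ascii(store[d], p)
                paths[f"{tag}_{d.isoformat()}_{pol}"] = str(p)
    esu_path = out / "esu_samples.csv"
    scene.esu_table.to_csv(esu_path, index=False)
    paths["esu_table"] = str(esu_path)
    nv_path = out / "nonveg_samples.csv"
    scene.nonveg_table.to_csv(nv_path, index=False)
    paths["nonveg_table"] = str(nv_path)
    gj = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"paddock": pid},
         "geometry": mapping(poly)} for pid, poly in scene.paddocks]}
    pad_path = out / "paddocks.geojson"
    pad_path.write_text(json.dumps(gj))
    paths["paddocks"] = str(pad_path)
    for d in scene.config.sampling_dates:
        p = out / f"truth_lai_{d.strftime('%Y%m%d')}.asc"
        write_ascii(scene.truth_lai(d), p)
        paths[f"truth_{d.isoformat()}"] = str(p)
    scale_path = out / "lai_scale.asc"
    write_ascii(scene.lai_scale, scale_path)
    paths["lai_scale"] = str(scale_path)
    meta = {"format": "s1lai-scene", "config": config_to_dict(scene.config)}
    (out / "scene.json").write_text(json.dumps(meta, indent=1))
    paths["scene_meta"] = str(out / "scene.json")
    return paths


def read_scene(indir: str | Path) -> Scene:
    """Reload a scene written by :func:`write_scene`."""
    import json

    from shapely.geometry import shape

    from .raster import read_ascii

    ind = Path(indir)
    meta = json.loads((ind / "scene.json").read_text())
    if meta.get("format") != "s1lai-scene":
        raise ValueError(f"{indir} does not contain a scene")
    cfg = config_from_dict(meta["config"])
    tracks = []
    for spec in cfg.tracks:
        tag = f"{spec.platform}_{spec.orbit}"
        lia = read_ascii(ind / f"LIA_{tag}.asc", cfg.crs)
        cal = _track_calendar(spec, cfg.season_start, cfg.season_end)
        vh, vv = {}, {}
        for d in cal:
            stem = f"{tag}_{d.strftime('%Y%m%d')}"
            vh[d] = read_ascii(ind / f"{stem}_VH.asc", cfg.crs)
            vv[d] = read_ascii(ind / f"{stem}_VV.asc", cfg.crs)
        tracks.append(TrackData(spec, lia, cal, vh, vv))
    esu = pd.read_csv(ind / "esu_samples.csv")
    nonveg = pd.read_csv(ind / "nonveg_samples.csv")
    gj = json.loads((ind / "paddocks.geojson").read_text())
    paddocks = [(f["properties"]["paddock"], shape(f["geometry"]))
                for f in gj["features"]]
    lai_scale = read_ascii(ind / "lai_scale.asc", cfg.crs)
    return Scene(cfg, tracks, esu, nonveg, paddocks, lai_scale)
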