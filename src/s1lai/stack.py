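"""Per-track backscatter time-series assembly and feature construction.

Builds the 2-band (single track) or 6-band (merged multi-incidence-angle)
feature vectors used by the regressor, either from raw nearest-acquisition
values or from Whittaker-smoothed daily-interpolated series evaluated at
the field sampling date.  Band order is fixed: for each track in
(S1A-141, S1A-68, S1B-68) the VH band precedes the VV band.

All pixels of one track share the acquisition calendar, so smoothing of a
whole raster stack factorizes: one banded factorization per λ serves every
pixel, and the V-curve / GCV criterion is evaluated per pixel in vectorized
form.  ESU feature extraction runs the same code path on the ESU pixels
only, which guarantees sample/cube consistency to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .raster import Raster
from .scene import Scene, TrackData
from .whittaker import (DEFAULT_LOG_GRID, _lambda_grid, difference_matrix,
                        smooth_fixed_multi, _system_banded)
from scipy.linalg import solveh_banded

DEFAULT_TRACK_ORDER = ("S1A-141", "S1A-68", "S1B-68")
POLS = ("VH", "VV")

# 2020 winter-wheat field campaign: sampling dates and the Sentinel-1
# acquisition used per track (relative orbits 141 and 68, descending)
FIELD_CAMPAIGN_2020: list[tuple[date, dict[str, date]]] = [
    (date(2020, 9, 3), {"S1A-141": date(2020, 9, 1),
                        "S1A-68": date(2020, 9, 8),
                        "S1B-68": date(2020, 9, 2)}),
    (date(2020, 9, 17), {"S1A-141": date(2020, 9, 13),
                         "S1A-68": date(2020, 9, 20),
                         "S1B-68": date(2020, 9, 26)}),
    (date(2020, 10, 2), {"S1A-141": date(2020, 10, 7),
                         "S1A-68": date(2020, 10, 2),
                         "S1B-68": date(2020, 10, 8)}),
    (date(2020, 10, 19), {"S1A-141": date(2020, 10, 19),
                          "S1A-68": date(2020, 10, 14),
                          "S1B-68": date(2020, 10, 20)}),
    (date(2020, 11, 2), {"S1A-141": date(2020, 10, 31),
                         "S1A-68": date(2020, 11, 7),
                         "S1B-68": date(2020, 11, 1)}),
    (date(2020, 11, 16), {"S1A-141": date(2020, 11, 12),
                          "S1A-68": date(2020, 11, 19),
                          "S1B-68": date(2020, 11, 13)}),
]


def band_names(track_tags: tuple[str, ...] | list[str]) -> list[str]:
    return [f"{tag}-{pol}" for tag in track_tags for pol in POLS]


# ---------------------------------------------------------------------------
# acquisition pairing (raw scenario, field-campaign table)
# ---------------------------------------------------------------------------


def pair_acquisitions(sampling_date: date,
                      calendars: dict[str, list[date]],
                      ) -> tuple[dict[str, date], int]:
    """Nearest acquisition per track and the rounded mean absolute offset.

    Ties between equally distant acquisitions go to the earlier date; the
    day offset Δ is the mean of per-track absolute offsets rounded half-up.
    """
    nearest: dict[str, date] = {}
    offsets = []
    for tag, cal in calendars.items():
        if not cal:
            raise ValueError(f"empty acquisition calendar for track {tag}")
        best = min(cal, key=lambda d: (abs((d - sampling_date).days), d))
        nearest[tag] = best
        offsets.append(abs((best - sampling_date).days))
    delta = int(math.floor(np.mean(offsets) + 0.5))
    return nearest, delta


# ---------------------------------------------------------------------------
# pixel series
# ---------------------------------------------------------------------------


@dataclass
class PixelSeries:
    track: str
    pol: str
    dates: list[date]
    values: np.ndarray     # γ0 dB at the track's acquisition dates


def extract_pixel_series(track: TrackData, location: tuple[float, float],
                         ) -> dict[str, PixelSeries]:
    """Per-polarization series at the pixel containing ``location``.

    Values are read from the pixel as stored (no resampling); the series
    length equals the track calendar length.
    """
    x, y = location
    r, c = track.lia.rowcol(x, y)
    out: dict[str, PixelSeries] = {}
    for pol, store in (("VH", track.vh), ("VV", track.vv)):
        vals = np.array([store[d].data[r, c] for d in track.dates])
        nodata = store[track.dates[0]].nodata
        if np.all(vals == nodata):
            raise ValueError(f"all-nodata pixel at ({x}, {y})")
        vals = np.where(vals == nodata, np.nan, vals)
        out[pol] = PixelSeries(track.tag, pol, list(track.dates), vals)
    return out


# ---------------------------------------------------------------------------
# vectorized smoothing of one track/band over many pixels
# ---------------------------------------------------------------------------


def _daily_design(track: TrackData, scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    """(grid day indices, observation weight vector) on the season window."""
    cfg = scene.config
    n_days = cfg.day_of(cfg.season_end) + 1
    grid = np.arange(n_days)
    w = np.zeros(n_days)
    w[[cfg.day_of(d) for d in track.dates]] = 1.0
    return grid, w


def smoothed_band_at_day(scene: Scene, track: TrackData, pol: str,
                         pixel_rows: np.ndarray, pixel_cols: np.ndarray,
                         target_day: int, p: int = 2, method: str = "vcurve",
                         log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
                         ) -> np.ndarray:
    """Smoothed/interpolated γ0 at ``target_day`` for the given pixels.

    Selects λ per pixel (V-curve by default, GCV optionally) over the
    log₁₀ grid, exploiting the shared weight pattern of the track.
    """
    grid, w = _daily_design(track, scene)
    if not (grid[0] <= target_day <= grid[-1]):
        raise ValueError("target day outside the smoothed grid")
    cfg = scene.config
    store = track.vh if pol == "VH" else track.vv
    npix = pixel_rows.size
    Y = np.zeros((grid.size, npix))
    for d in track.dates:
        Y[cfg.day_of(d), :] = store[d].data[pixel_rows, pixel_cols]

    exps = _lambda_grid(log_grid)
    n_obs = int(np.count_nonzero(w))
    M = difference_matrix(grid.size, p)

    if method == "vcurve":
        best_dist = np.full(npix, np.inf)
        best_idx = np.zeros(npix, dtype=int)
        prev_psi = prev_phi = None
        with np.errstate(divide="ignore"):
            for i, e in enumerate(exps):
                X = smooth_fixed_multi(Y, w, 10.0 ** e, p)
                psi = np.log(np.sum(w[:, None] * (Y - X) ** 2, axis=0))
                phi = np.log(np.sum((M @ X) ** 2, axis=0))
                if prev_psi is not None:
                    dist = np.hypot(psi - prev_psi, phi - prev_phi)
                    dist = np.where(np.isfinite(dist), dist, np.inf)
                    better = dist < best_dist
                    best_dist[better] = dist[better]
                    best_idx[better] = i - 1
                prev_psi, prev_phi = psi, phi
        lam_exp = (exps[best_idx] + exps[best_idx + 1]) / 2.0
        lam_exp[~np.isfinite(best_dist)] = exps[-1]   # fidelity-end fallback
    elif method == "gcv":
        best_score = np.full(npix, np.inf)
        best_i = np.zeros(npix, dtype=int)
        for i, e in enumerate(exps):
            lam = 10.0 ** e
            X = smooth_fixed_multi(Y, w, lam, p)
            ab = _system_banded(w, lam, p)
            Ainv_diag = np.diag(solveh_banded(ab, np.eye(grid.size)))
            tr = lam * np.sum(Ainv_diag * w)
            denom = 1.0 - tr / n_obs
            if denom <= 0:
                continue
            score = np.sum(w[:, None] * ((Y - X) / denom) ** 2, axis=0) / n_obs
            better = score < best_score
            best_score[better] = score[better]
            best_i[better] = i
        lam_exp = exps[best_i]
    else:
        raise ValueError(f"unknown selection method {method!r}")

    # second pass: solve only at each distinct selected λ
    out = np.empty(npix)
    for e in np.unique(lam_exp):
        sel = lam_exp == e
        X = smooth_fixed_multi(Y[:, sel], w, 10.0 ** e, p)
        out[sel] = X[target_day, :]
    return out


# ---------------------------------------------------------------------------
# feature samples and feature cubes
# ---------------------------------------------------------------------------


def _sample_table(scene: Scene, include_nonveg: bool) -> pd.DataFrame:
    tables = [scene.esu_table]
    if include_nonveg and len(scene.nonveg_table):
        tables.append(scene.nonveg_table)
    return pd.concat(tables, ignore_index=True)


def build_feature_samples(scene: Scene,
                          track_tags: tuple[str, ...] = DEFAULT_TRACK_ORDER,
                          smoothed: bool = True, method: str = "vcurve",
                          p: int = 2,
                          log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
                          include_nonveg: bool = True) -> pd.DataFrame:
    """Feature table: one row per sample, one column per band, plus label.

    Smoothing on: features are the Whittaker-interpolated values at the
    sampling date itself.  Smoothing off: features are the raw values at
    the nearest acquisition of each track (ties to the earlier date), with
    the per-band day offset recorded in the provenance column.
    """
    samples = _sample_table(scene, include_nonveg)
    cfg = scene.config
    tracks = [scene.track(tag) for tag in track_tags]
    names = band_names(track_tags)
    feats = {name: np.empty(len(samples)) for name in names}
    provenance = [[] for _ in range(len(samples))]

    rows = np.empty(len(samples), dtype=int)
    cols = np.empty(len(samples), dtype=int)
    for i, rec in samples.iterrows():
        rows[i], cols[i] = tracks[0].lia.rowcol(rec.x, rec.y)
    dates = [date.fromisoformat(d) for d in samples["date"]]

    for track in tracks:
        for pol in POLS:
            name = f"{track.tag}-{pol}"
            if smoothed:
                for d in sorted(set(dates)):
                    idx = np.array([j for j, dd in enumerate(dates) if dd == d])
                    vals = smoothed_band_at_day(
                        scene, track, pol, rows[idx], cols[idx],
                        cfg.day_of(d), p, method, log_grid)
                    feats[name][idx] = vals
                    for j in idx:
                        provenance[j].append(f"{name}:smoothed-at-date")
            else:
                store = track.vh if pol == "VH" else track.vv
                for j, d in enumerate(dates):
                    nearest, _ = pair_acquisitions(d, {track.tag: track.dates})
                    ad = nearest[track.tag]
                    feats[name][j] = store[ad].data[rows[j], cols[j]]
                    provenance[j].append(
                        f"{name}:nearest{abs((ad - d).days):+d}d")

    out = samples.copy()
    for name in names:
        out[name] = feats[name]
    out["provenance"] = [";".join(pr) for pr in provenance]
    if not np.all(np.isfinite(out[names].to_numpy())):
        raise ValueError("non-finite features produced")
    return out


@dataclass
class FeatureCube:
    """Multi-band feature raster stack for one map date."""

    date: date
    band_names: list[str]
    data: np.ndarray        # (B, rows, cols)
    template: Raster
    valid: np.ndarray       # bool (rows, cols)

    def extract(self, x: float, y: float) -> np.ndarray:
        r, c = self.template.rowcol(x, y)
        return self.data[:, r, c]


def assemble_feature_cube(scene: Scene, map_date: date,
                          track_tags: tuple[str, ...] = DEFAULT_TRACK_ORDER,
                          smoothed: bool = True, method: str = "vcurve",
                          p: int = 2,
                          log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
                          ) -> FeatureCube:
    """Per-pixel features for one map date, same code path as the samples.

    No extrapolation: the map date must fall inside every track's
    acquisition span.
    """
    cfg = scene.config
    tracks = [scene.track(tag) for tag in track_tags]
    for t in tracks:
        if not (t.dates[0] <= map_date <= t.dates[-1]):
            raise ValueError(
                f"map date {map_date} outside acquisition span of {t.tag}")
    names = band_names(track_tags)
    template = cfg.grid_raster()
    nr, nc = template.shape
    rows, cols = np.indices((nr, nc))
    rows, cols = rows.ravel(), cols.ravel()
    data = np.empty((len(names), nr, nc))
    valid = np.ones((nr, nc), dtype=bool)
    day = cfg.day_of(map_date)

    b = 0
    for track in tracks:
        for pol in POLS:
            store = track.vh if pol == "VH" else track.vv
            for d in track.dates:
                valid &= store[d].mask_valid()
            if smoothed:
                vals = smoothed_band_at_day(scene, track, pol, rows, cols,
                                            day, p, method, log_grid)
                data[b] = vals.reshape(nr, nc)
            else:
                nearest, _ = pair_acquisitions(map_date,
                                               {track.tag: track.dates})
                data[b] = store[nearest[track.tag]].data
            b += 1
    data[:, ~valid] = template.nodata
    return FeatureCube(map_date, names, data, template, valid)
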