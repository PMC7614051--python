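"""Goodness-of-fit metrics, hold-out and k-fold cross-validation, and the
scenario comparison table.

Metrics: R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², MAE, RMSE and NRMSE = 100·RMSE/(y_max −
y_min) in percent.  Cross-validation partitions the samples into k seeded
near-equal folds (the first N mod k folds receive one extra sample) and
pools the out-of-fold predictions into a single report; per-fold reports
are retained.  The scenario table compares single-track 2-band against
merged 6-band feature sets, raw against smoothed, plus a 10-fold CV row
for the merged smoothed model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import gpr
from .scene import Scene
from .stack import DEFAULT_TRACK_ORDER, band_names, build_feature_samples


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    nrmse: float            # percent; NaN when the label range is zero
    r2: float
    n: int
    scenario: str = ""
    elapsed_s: float = float("nan")   # informational only


def compute_metrics(y: np.ndarray, y_hat: np.ndarray, scenario: str = "",
                    elapsed_s: float = float("nan")) -> MetricsReport:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("need equal-length 1-D arrays with >= 2 samples")
    resid = y - y_hat
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    rng = float(y.max() - y.min())
    nrmse = 100.0 * rmse / rng if rng > 0 else float("nan")
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else float("nan")
    report = MetricsReport(mae, rmse, nrmse, r2, y.size, scenario, elapsed_s)
    assert report.mae <= report.rmse + 1e-12
    return report


@dataclass
class CVResult:
    fold_of: np.ndarray             # fold index per sample
    y: np.ndarray
    pred_mean: np.ndarray           # pooled out-of-fold predictions
    pred_sd: np.ndarray
    fold_reports: list[MetricsReport]
    pooled: MetricsReport


def _default_fit(X, y, seed):
    return gpr.fit(X, y, seed=seed)


def _default_predict(model, X):
    p = gpr.predict(model, X)
    return p.mean, p.sd


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0,
             fit_fn: Callable = _default_fit,
             predict_fn: Callable = _default_predict,
             scenario: str = "") -> CVResult:
    """Seeded k-fold CV with pooled out-of-fold metrics."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1                 # first N mod k folds get one extra
    fold_of = np.empty(n, dtype=int)
    stop = np.cumsum(sizes)
    start = np.concatenate([[0], stop[:-1]])
    for f in range(k):
        fold_of[perm[start[f]:stop[f]]] = f

    pred = np.empty(n)
    sd = np.empty(n)
    fold_reports = []
    t0 = time.perf_counter()
    for f in range(k):
        test = fold_of == f
        model = fit_fn(X[~test], y[~test], seed=seed + f)
        m, s = predict_fn(model, X[test])
        pred[test], sd[test] = m, s
        if test.sum() >= 2:
            fold_reports.append(compute_metrics(y[test], m,
                                                f"{scenario}/fold{f}"))
    elapsed = time.perf_counter() - t0
    pooled = compute_metrics(y, pred, scenario, elapsed)
    return CVResult(fold_of, y, pred, sd, fold_reports, pooled)


def holdout_eval(X: np.ndarray, y: np.ndarray, train_fraction: float = 0.7,
                 seed: int = 0, fit_fn: Callable = _default_fit,
                 predict_fn: Callable = _default_predict,
                 scenario: str = "") -> MetricsReport:
    """Seeded shuffle split; metrics on the held-out fraction.

    Train size is floor(N · train_fraction); both splits must keep at
    least 2 samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    n_train = int(np.floor(n * train_fraction))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("degenerate train/test split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    t0 = time.perf_counter()
    model = fit_fn(X[tr], y[tr], seed=seed)
    m, _ = predict_fn(model, X[te])
    elapsed = time.perf_counter() - t0
    return compute_metrics(y[te], m, scenario, elapsed)


# ---------------------------------------------------------------------------
# scenario matrix
# ---------------------------------------------------------------------------

SINGLE_TRACKS = (("S1A-141",), ("S1A-68",), ("S1B-68",))


def _scenario_tag(tracks: tuple[str, ...], smoothed: bool, cv: bool) -> str:
    if len(tracks) == 1:
        plat, orbit = tracks[0].split("-")
        data = f"{plat}-P{orbit}"
        model = "GPR[2B]"
    else:
        data = "S1AB-P141-68"
        model = "GPR_CV[6B]" if cv else "GPR[6B]"
    return f"{data} {model} {'smoothed' if smoothed else 'raw'}"


def scenario_table(scene: Scene, seed: int = 0, k: int = 10,
                   train_fraction: float = 0.7, n_restarts: int = 5,
                   method: str = "vcurve") -> pd.DataFrame:
    """One row per scenario: {each single track, merged 6B} × {raw,
    smoothed} hold-out rows plus the merged-6B smoothed k-fold CV row.
    """
    rows = []
    for smoothed in (False, True):
        table = build_feature_samples(scene, DEFAULT_TRACK_ORDER,
                                      smoothed=smoothed, method=method)
        y = table["lai"].to_numpy()
        for tracks in (*SINGLE_TRACKS, DEFAULT_TRACK_ORDER):
            names = band_names(tracks)
            X = table[names].to_numpy()
            fit_fn = lambda Xa, ya, seed: gpr.fit(Xa, ya, n_restarts, seed,
                                                  band_names=names)
            tag = _scenario_tag(tracks, smoothed, cv=False)
            rep = holdout_eval(X, y, train_fraction, seed, fit_fn,
                               scenario=tag)
            rows.append(rep)
            if smoothed and len(tracks) > 1:
                tag = _scenario_tag(tracks, smoothed, cv=True)
                cvres = kfold_cv(X, y, k, seed, fit_fn, scenario=tag)
                rows.append(cvres.pooled)
    return pd.DataFrame([{
        "scenario": r.scenario, "n": r.n, "mae": r.mae, "rmse": r.rmse,
        "nrmse_pct": r.nrmse, "r2": r.r2, "elapsed_s": r.elapsed_s,
    } for r in rows])
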