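"""Weighted Whittaker smoothing with automatic selection of λ.

The smoother minimizes

    λ Σ_j ω_j (y_j − x_j)²  +  Σ_j (Δᵖ x_j)²

over the sequence x on an implicit unit grid.  Note the convention: λ
multiplies the *fidelity* term, so λ → ∞ reproduces the data and λ → 0⁺
tends to the weighted least-squares polynomial of degree p − 1.  The more
common penalty-side convention is obtained through λ_penalty = 1/λ.

Zero weights mark missing samples, which makes the same solver perform
gap interpolation onto a daily grid.  λ is chosen automatically either by
generalized cross-validation (GCV) or by the V-curve: the grid-λ pair of
consecutive points of the (log-fidelity, log-roughness) curve at minimal
Euclidean distance, with λ reported at the log₁₀ midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.special import comb

DEFAULT_LOG_GRID = (-4.0, 4.0, 0.1)


@dataclass
class WeightedSeries:
    """One time sequence y with per-sample weights ω ∈ [0, 1] (0 = missing)."""

    y: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.w is None:
            self.w = np.ones_like(self.y)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.y.ndim != 1 or self.y.shape != self.w.shape:
            raise ValueError("y and w must be 1-D of equal length")
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if not np.all(np.isfinite(self.y[self.w > 0])):
            raise ValueError("non-finite values at positive-weight slots")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.w))


@dataclass
class SmoothResult:
    x_hat: np.ndarray
    lam: float
    method: str                       # fixed | gcv | vcurve
    curve: pd.DataFrame | None = None  # per-grid-λ criterion records
    warnings: list[str] = field(default_factory=list)


def difference_matrix(n: int, p: int) -> sparse.csr_matrix:
    """(n − p) × n forward-difference matrix of order p.

    Row j carries the signed binomial coefficients of Δᵖ applied at j:
    for p = 2 and n = 6 the rows are (1, −2, 1, 0, 0, 0) … (0, 0, 0, 1, −2, 1).
    """
    if not (1 <= p < n):
        raise ValueError(f"need 1 <= p < n, got p={p}, n={n}")
    k = np.arange(p + 1)
    coeffs = ((-1.0) ** (p - k)) * comb(p, k)
    diags = [np.full(n - p, c) for c in coeffs]
    return sparse.diags(diags, offsets=list(range(p + 1)),
                        shape=(n - p, n)).tocsr()


def _system_banded(w: np.ndarray, lam: float, p: int) -> np.ndarray:
    """Upper-banded form of A = λW + MᵀM for solveh_banded."""
    n = w.size
    M = difference_matrix(n, p)
    A = (sparse.diags(lam * w) + M.T @ M).todia()
    ab = np.zeros((p + 1, n))
    for off, diag in zip(A.offsets, A.data):
        if 0 <= off <= p:
            ab[p - off, :] = diag
    return ab


def _check_series(series: WeightedSeries, p: int) -> None:
    if series.n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} samples, got {series.n}")
    if series.n_observed < p + 1:
        raise ValueError(
            f"need at least p+1={p + 1} positive-weight samples, "
            f"got {series.n_observed}")


def smooth_fixed(series: WeightedSeries, lam: float, p: int = 2) -> SmoothResult:
    """Solve (λW + MᵀM) x̂ = λW y by symmetric banded factorization."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    _check_series(series, p)
    ab = _system_banded(series.w, lam, p)
    x_hat = solveh_banded(ab, lam * series.w * series.y)
    return SmoothResult(x_hat=x_hat, lam=float(lam), method="fixed")


def smooth_fixed_multi(Y: np.ndarray, w: np.ndarray, lam: float,
                       p: int = 2) -> np.ndarray:
    """Vectorized smoother: one factorization, many series (columns of Y).

    All columns share the weight pattern w (e.g. every pixel of one track
    observes the same acquisition calendar).  Y is (n, m); missing slots
    (w == 0) may hold any finite value, zeros conventionally.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    w = np.asarray(w, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    ab = _system_banded(w, lam, p)
    return solveh_banded(ab, lam * w[:, None] * np.where(w[:, None] > 0, Y, 0.0))


def _hat_trace(w: np.ndarray, lam: float, p: int) -> float:
    """trace of the effective hat matrix H = λ(λW + MᵀM)⁻¹W."""
    n = w.size
    ab = _system_banded(w, lam, p)
    Ainv = solveh_banded(ab, np.eye(n))
    return float(lam * np.sum(np.diag(Ainv) * w))


def gcv_score(series: WeightedSeries, lam: float, p: int = 2) -> float:
    """Generalized cross-validation score at λ.

    n⁻¹ Σ ω_j ((y_j − x̂_j) / (1 − n⁻¹ tr H))² with n the number of observed
    samples; with uniform weights H = λ(λI + MᵀM)⁻¹ is the classical hat
    matrix and the expression reduces to the textbook GCV formula.
    """
    res = smooth_fixed(series, lam, p)
    n_obs = series.n_observed
    tr = _hat_trace(series.w, lam, p)
    denom = 1.0 - tr / n_obs
    if denom <= 0:
        raise ValueError("degenerate smoother: effective dof equals n")
    resid = series.y - res.x_hat
    return float(np.sum(series.w * (resid / denom) ** 2) / n_obs)


def _lambda_grid(log_grid: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = log_grid
    if step <= 0 or hi <= lo:
        raise ValueError("invalid log grid")
    exps = np.arange(lo, hi + step / 2, step)
    if exps.size < 3:
        raise ValueError("λ grid needs at least 3 points")
    return exps


def gcv_select(series: WeightedSeries, p: int = 2,
               log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
               ) -> SmoothResult:
    """Pick λ minimizing the GCV score over the log₁₀ grid."""
    exps = _lambda_grid(log_grid)
    scores = np.array([gcv_score(series, 10.0 ** e, p) for e in exps])
    # ties broken toward the smoother (smaller-λ) side
    best = int(np.argmin(scores))
    lam = 10.0 ** exps[best]
    res = smooth_fixed(series, lam, p)
    curve = pd.DataFrame({"log10_lam": exps, "gcv": scores})
    return SmoothResult(res.x_hat, lam, "gcv", curve)


def vcurve_points(series: WeightedSeries, p: int,
                  exps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ψ, φ) coordinates: log weighted fidelity and log roughness per λ."""
    M = difference_matrix(series.n, p)
    psi = np.empty(exps.size)
    phi = np.empty(exps.size)
    for i, e in enumerate(exps):
        x_hat = smooth_fixed(series, 10.0 ** e, p).x_hat
        with np.errstate(divide="ignore"):
            psi[i] = np.log(np.sum(series.w * (series.y - x_hat) ** 2))
            phi[i] = np.log(np.sum((M @ x_hat) ** 2))
    return psi, phi


def vcurve_select(series: WeightedSeries, p: int = 2,
                  log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
                  ) -> SmoothResult:
    """V-curve selection of λ.

    Evaluates (ψ, φ) on the log₁₀-λ grid and selects the pair of adjacent
    grid points with the minimal Euclidean distance in the (ψ, φ) plane;
    λ is taken at the log midpoint of that pair.  Non-finite curve
    coordinates (e.g. exact interpolation leaving zero residual) trigger a
    fallback to the fidelity-dominant (largest-λ) grid end, recorded as a
    warning.
    """
    exps = _lambda_grid(log_grid)
    psi, phi = vcurve_points(series, p, exps)
    dist = np.hypot(np.diff(psi), np.diff(phi))
    warnings: list[str] = []
    finite = np.isfinite(dist)
    if not finite.any():
        lam = 10.0 ** exps[-1]
        warnings.append("non-finite V-curve; fell back to fidelity-dominant λ")
    else:
        dist_masked = np.where(finite, dist, np.inf)
        best = int(np.argmin(dist_masked))  # argmin takes first = smaller λ
        lam = 10.0 ** ((exps[best] + exps[best + 1]) / 2.0)
    res = smooth_fixed(series, lam, p)
    curve = pd.DataFrame({
        "log10_lam": exps, "psi": psi, "phi": phi,
        "dist_to_next": np.append(dist, np.nan),
    })
    return SmoothResult(res.x_hat, lam, "vcurve", curve, warnings)


def smooth_interpolate(obs_positions: np.ndarray, obs_values: np.ndarray,
                       grid_positions: np.ndarray, p: int = 2,
                       method: str = "vcurve", lam: float | None = None,
                       log_grid: tuple[float, float, float] = DEFAULT_LOG_GRID,
                       ) -> SmoothResult:
    """Expand sparse observations onto a grid (ω = 1 observed, 0 elsewhere),
    select λ, and smooth; the result is defined at every grid position.
    """
    grid = np.asarray(grid_positions)
    obs = np.asarray(obs_positions)
    vals = np.asarray(obs_values, dtype=np.float64)
    if obs.size != vals.size:
        raise ValueError("positions/values length mismatch")
    idx = np.searchsorted(grid, obs)
    if np.any(idx >= grid.size) or np.any(grid[np.clip(idx, 0, grid.size - 1)] != obs):
        raise ValueError("observation position outside the grid")
    y = np.zeros(grid.size)
    w = np.zeros(grid.size)
    y[idx] = vals
    w[idx] = 1.0
    series = WeightedSeries(y, w)
    if method == "fixed":
        if lam is None:
            raise ValueError("fixed method requires lam")
        return smooth_fixed(series, lam, p)
    if method == "gcv":
        return gcv_select(series, p, log_grid)
    if method == "vcurve":
        return vcurve_select(series, p, log_grid)
    raise ValueError(f"unknown selection method {method!r}")
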