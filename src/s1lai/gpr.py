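"""Gaussian process regression with an ARD squared-exponential kernel.

Model:  y* = Σ_i α_i k_θ(x_i, x*) + α₀  with

    k_θ(x_i, x_j) = v exp(−Σ_b (x_i^b − x_j^b)² / (2 σ_b²)) + σ_n² δ_ij,

θ = [v, σ_n, σ_1 … σ_B].  α₀ is a constant prior mean fixed at the
training-label mean; the dual weights solve (K + σ_n² I) α = y − α₀.
Hyperparameters maximize the log marginal likelihood over log-parameters
with analytic gradients and seeded multi-restart L-BFGS.  The predictive
variance is the standard GP posterior variance v + σ_n² − k*ᵀ(K + σ_n²I)⁻¹k*.

Features are centered and scaled by training statistics before entering
the kernel (ARD length scales are otherwise unit-dependent); the
transform is stored in the model.  1/σ_b ranks feature relevance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize

log = logging.getLogger(__name__)

_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


@dataclass
class Hyperparams:
    """θ = [v, σ_n, σ_1 … σ_B]; all strictly positive."""

    v: float                # signal variance scaling factor
    sigma_n: float          # noise standard deviation
    sigma_b: np.ndarray     # per-feature length scales

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, dtype=np.float64)
        if self.v <= 0 or self.sigma_n <= 0 or np.any(self.sigma_b <= 0):
            raise ValueError("hyperparameters must be strictly positive")


def ard_kernel(xi: np.ndarray, xj: np.ndarray, theta: Hyperparams,
               same_index: bool = False) -> float:
    """ARD kernel between two feature vectors; δ_ij applied if same_index."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("feature vectors must be 1-D of equal length")
    if xi.size != theta.sigma_b.size:
        raise ValueError("feature length does not match length scales")
    expo = np.sum((xi - xj) ** 2 / (2.0 * theta.sigma_b ** 2))
    val = theta.v * np.exp(-expo)
    if same_index:
        val += theta.sigma_n ** 2
    return float(val)


def _kernel_matrix(Xa: np.ndarray, Xb: np.ndarray,
                   theta: Hyperparams) -> np.ndarray:
    """Noise-free v·exp(−½ Σ d²/σ²) between rows of Xa and Xb."""
    Za = Xa / theta.sigma_b
    Zb = Xb / theta.sigma_b
    d2 = (np.sum(Za ** 2, axis=1)[:, None] + np.sum(Zb ** 2, axis=1)[None, :]
          - 2.0 * Za @ Zb.T)
    np.maximum(d2, 0.0, out=d2)
    return theta.v * np.exp(-0.5 * d2)


@dataclass
class GPRModel:
    theta: Hyperparams
    alpha: np.ndarray            # dual weights, solve (K + σ_n²I)α = y − α₀
    alpha_0: float               # constant prior mean (training-label mean)
    X_train: np.ndarray          # raw training features, N × B
    x_mean: np.ndarray
    x_scale: np.ndarray
    band_names: list[str]
    y_train: np.ndarray
    log_marginal_likelihood: float = np.nan
    degenerate: bool = False     # zero-variance target
    jitter: float = 0.0
    _chol: tuple | None = field(default=None, repr=False)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_scale

    def _factor(self):
        if self._chol is None:
            Z = self._standardize(self.X_train)
            C = _kernel_matrix(Z, Z, self.theta)
            C[np.diag_indices_from(C)] += self.theta.sigma_n ** 2
            self._chol, self.jitter = _chol_with_jitter(C)
        return self._chol


@dataclass
class Prediction:
    mean: np.ndarray
    sd: np.ndarray


def _chol_with_jitter(C: np.ndarray):
    """Cholesky with escalating relative jitter on failure (logged)."""
    scale = float(np.mean(np.diag(C)))
    jitter = 0.0
    rel = _JITTER_START
    while True:
        try:
            return cho_factor(C + jitter * np.eye(C.shape[0]), lower=True), jitter
        except LinAlgError:
            jitter = rel * scale
            log.warning("kernel factorization failed; escalating jitter to %g",
                        jitter)
            rel *= 10.0
            if rel > _JITTER_MAX * 10.0:
                raise


def _nll_and_grad(log_theta: np.ndarray, Z: np.ndarray, r: np.ndarray):
    """Negative log marginal likelihood and gradient w.r.t. log θ."""
    n, B = Z.shape
    v = np.exp(2.0 * log_theta[0])          # parameterized as log sqrt(v)
    sigma_n = np.exp(log_theta[1])
    sigma_b = np.exp(log_theta[2:])
    theta = Hyperparams(v, sigma_n, sigma_b)
    K = _kernel_matrix(Z, Z, theta)
    C = K + (sigma_n ** 2) * np.eye(n)
    try:
        # reject numerically indefinite trials outright; jitter repair is
        # reserved for the final factorization of the selected model
        chol = cho_factor(C, lower=True)
    except LinAlgError:
        return np.inf, np.zeros_like(log_theta)
    alpha = cho_solve(chol, r)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    nll = 0.5 * (r @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2.0 * np.pi)
    Cinv = cho_solve(chol, np.eye(n))
    A = np.outer(alpha, alpha) - Cinv        # dLML/dθ = ½ tr(A ∂C/∂θ)
    grad = np.empty_like(log_theta)
    grad[0] = -0.5 * np.sum(A * K) * 2.0          # ∂C/∂log√v = 2K
    grad[1] = -0.5 * np.trace(A) * 2.0 * sigma_n ** 2
    for b in range(B):
        Db = (Z[:, b][:, None] - Z[:, b][None, :]) ** 2
        grad[2 + b] = -0.5 * np.sum(A * (K * Db / sigma_b[b] ** 2))
    return float(nll), grad


def fit(X: np.ndarray, y: np.ndarray, n_restarts: int = 5, seed: int = 0,
        band_names: list[str] | None = None) -> GPRModel:
    """Fit hyperparameters by maximizing the log marginal likelihood.

    Multi-restart from seeded log-normal perturbations of a moment-based
    initial guess; deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    N, B = X.shape
    if N < 2:
        raise ValueError("need at least 2 training samples")
    if y.shape != (N,):
        raise ValueError("label shape mismatch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    names = list(band_names) if band_names is not None else [
        f"band{b}" for b in range(B)]
    if len(names) != B:
        raise ValueError("band_names length mismatch")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    alpha_0 = float(y.mean())
    y_sd = float(y.std())

    if y_sd < 1e-12:
        # zero-variance target: constant predictor, relevance degenerate
        theta = Hyperparams(1e-12, 1e-6, np.ones(B))
        return GPRModel(theta, np.zeros(N), alpha_0, X, x_mean, x_scale,
                        names, y, degenerate=True)

    Z = (X - x_mean) / x_scale
    r = y - alpha_0
    rng = np.random.default_rng(seed)
    base = np.concatenate([[np.log(y_sd)], [np.log(0.1 * y_sd)], np.zeros(B)])
    bounds = [(-10.0, 10.0)] * (B + 2)

    best = None
    for k in range(max(1, n_restarts)):
        x0 = base if k == 0 else base + rng.normal(0.0, 0.7, size=base.size)
        res = minimize(_nll_and_grad, x0, args=(Z, r), jac=True,
                       method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("GPR fit failed: non-finite likelihood at all restarts")

    lt = best.x
    theta = Hyperparams(np.exp(2.0 * lt[0]), np.exp(lt[1]), np.exp(lt[2:]))
    C = _kernel_matrix(Z, Z, theta)
    C[np.diag_indices_from(C)] += theta.sigma_n ** 2
    chol, jitter = _chol_with_jitter(C)
    alpha = cho_solve(chol, r)
    model = GPRModel(theta, alpha, alpha_0, X, x_mean, x_scale, names, y,
                     log_marginal_likelihood=-float(best.fun), jitter=jitter)
    model._chol = chol
    return model


def predict(model: GPRModel, X_star: np.ndarray) -> Prediction:
    """Posterior mean and standard deviation at the query points."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=np.float64))
    if X_star.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension mismatch with training data")
    if model.degenerate:
        m = X_star.shape[0]
        return Prediction(np.full(m, model.alpha_0), np.zeros(m))
    Zs = model._standardize(X_star)
    Z = model._standardize(model.X_train)
    Ks = _kernel_matrix(Zs, Z, model.theta)          # M × N
    mean = Ks @ model.alpha + model.alpha_0
    chol = model._factor()
    V = cho_solve(chol, Ks.T)                        # N × M
    q = np.einsum("nm,nm->m", Ks.T, V)
    var = model.theta.v + model.theta.sigma_n ** 2 - q
    return Prediction(mean, np.sqrt(np.maximum(var, 0.0)))


def feature_relevance(model: GPRModel) -> list[tuple[str, float]]:
    """Bands ranked by 1/σ_b, descending; ties broken by band order."""
    rel = 1.0 / model.theta.sigma_b
    if model.degenerate:
        log.warning("relevance ranking is degenerate (constant target)")
    order = np.lexsort((np.arange(rel.size), -rel))
    return [(model.band_names[i], float(rel[i])) for i in order]


# -- serialization (self-describing JSON container) -----------------------

def save_model(model: GPRModel, path: str | Path) -> None:
    payload = {
        "format": "s1lai-gpr-model",
        "version": 1,
        "theta": {"v": model.theta.v, "sigma_n": model.theta.sigma_n,
                  "sigma_b": model.theta.sigma_b.tolist()},
        "alpha": model.alpha.tolist(),
        "alpha_0": model.alpha_0,
        "X_train": model.X_train.tolist(),
        "y_train": model.y_train.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "band_names": model.band_names,
        "log_marginal_likelihood": model.log_marginal_likelihood,
        "degenerate": model.degenerate,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> GPRModel:
    d = json.loads(Path(path).read_text())
    if d.get("format") != "s1lai-gpr-model":
        raise ValueError(f"{path} is not a GPR model file")
    theta = Hyperparams(d["theta"]["v"], d["theta"]["sigma_n"],
                        np.array(d["theta"]["sigma_b"]))
    return GPRModel(theta, np.array(d["alpha"]), d["alpha_0"],
                    np.array(d["X_train"]), np.array(d["x_mean"]),
                    np.array(d["x_scale"]), d["band_names"],
                    np.array(d["y_train"]),
                    d.get("log_marginal_likelihood", np.nan),
                    d.get("degenerate", False))
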