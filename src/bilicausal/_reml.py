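"""Restricted maximum likelihood for the single-kinship variance-component
model Var(y) = sigma_g^2 K + sigma_e^2 I.

One eigendecomposition of K rotates the problem so the restricted likelihood
is a scalar function of the variance ratio delta = sigma_e^2 / sigma_g^2
(equivalently of h^2 = 1/(1+delta)); it is maximized by a deterministic
coarse-grid scan followed by Brent refinement and a Newton polish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class RemlFit:
    sigma_g2: float
    sigma_e2: float
    h2: float
    delta: float
    loglik: float
    n_iter: int
    boundary: bool
    grad: float
    beta: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    loglik_path: list


def _restricted_ll(log_delta: float, lam: np.ndarray, y_rot: np.ndarray,
                   x_rot: np.ndarray, logdet_xtx: float):
    """Profile restricted log-likelihood at a given log variance ratio."""
    delta = math.exp(log_delta)
    w = lam + delta
    wi = 1.0 / w
    xtwx = x_rot.T @ (x_rot * wi[:, None])
    xtwy = x_rot.T @ (y_rot * wi)
    beta = np.linalg.solve(xtwx, xtwy)
    r = y_rot - x_rot @ beta
    n, p = y_rot.size, x_rot.shape[1]
    rss = float(r @ (r * wi))
    sigma_g2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - p) * (_LOG2PI + math.log(sigma_g2) + 1.0)
        + float(np.log(w).sum())
        + logdet_xtwx
        - logdet_xtx
    )
    return ll, sigma_g2, beta


def profile_rll(h2: float, lam: np.ndarray, y_rot: np.ndarray,
                x_rot: np.ndarray) -> float:
    """Restricted log-likelihood profiled over the scale, as a function of h2.

    Exposed so tests can compare the optimizer against a brute-force grid.
    """
    h2 = min(max(h2, 1e-12), 1 - 1e-12)
    sign, logdet_xtx = np.linalg.slogdet(x_rot.T @ x_rot)
    ll, _, _ = _restricted_ll(math.log((1.0 - h2) / h2), lam, y_rot, x_rot, logdet_xtx)
    return ll


def reml_fit(y: np.ndarray, x: np.ndarray, k: np.ndarray | None = None,
             eig: tuple[np.ndarray, np.ndarray] | None = None,
             log_delta_bounds: tuple[float, float] = (-12.0, 12.0),
             n_grid: int = 64, max_newton: int = 25) -> RemlFit:
    """Fit sigma_g^2, sigma_e^2 by REML given kinship K (or its eigenpair).

    Raises ``RuntimeError`` with the likelihood trace if the Newton polish
    fails to reduce the score gradient at an interior optimum.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if eig is None:
        if k is None:
            raise ValueError("supply either k or its eigendecomposition")
        lam, u = np.linalg.eigh(k)
    else:
        lam, u = eig
    lam = np.maximum(lam, 0.0)  # clip tiny negative eigenvalues (PSD noise)
    y_rot = u.T @ y
    x_rot = u.T @ x
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)

    path = []
    evals = 0

    def nll(t):
        nonlocal evals
        evals += 1
        ll, _, _ = _restricted_ll(t, lam, y_rot, x_rot, logdet_xtx)
        path.append(max(ll, path[-1]) if path else ll)  # best-so-far trace
        return -ll

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([nll(t) for t in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    t = float(res.x)

    # Newton polish on the numeric score so interior optima are sharp
    h = 1e-5
    grad = 0.0
    boundary = t <= lo + 1e-6 or t >= hi - 1e-6
    if not boundary:
        for _ in range(max_newton):
            f0, fp, fm = nll(t), nll(t + h), nll(t - h)
            grad = (fp - fm) / (2 * h)
            hess = (fp - 2 * f0 + fm) / h**2
            if abs(grad) < 1e-9 or hess <= 0:
                break
            step = np.clip(grad / hess, -0.5, 0.5)
            t_new = float(np.clip(t - step, lo, hi))
            if nll(t_new) > f0 + 1e-12:
                break
            t = t_new
        if not math.isfinite(grad):
            raise RuntimeError(f"REML polish diverged; trace tail: {path[-5:]}")

    ll, sigma_g2, beta = _restricted_ll(t, lam, y_rot, x_rot, logdet_xtx)
    delta = math.exp(t)
    sigma_e2 = sigma_g2 * delta
    h2 = 1.0 / (1.0 + delta)
    boundary = boundary or h2 < 1e-5 or h2 > 1 - 1e-5
    return RemlFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=h2,
        delta=delta,
        loglik=ll,
        n_iter=evals,
        boundary=boundary,
        grad=abs(grad),
        beta=beta,
        eigvals=lam,
        eigvecs=u,
        loglik_path=path,
    )
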