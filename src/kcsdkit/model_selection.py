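"""Selection of the regularization parameter λ and basis radius R.

Two selectors are provided:

* leave-one-out cross-validation — for each electrode i, refit on the
  remaining N−1 measurements (drop row/column i of K) and predict the
  held-out potential; the prediction error is
  ``err(λ) = Σ_i (V'ᵢ_λ(x_i) − V_i)²`` and the minimizing λ wins;
* the L-curve — plot the model norm ``η_λ = |β_λᵀ K β_λ|`` against the
  residual ``ρ_λ = Σ_i (V_λ(x_i) − V_i)²`` in log-log scale and pick the λ
  of maximal curvature, measured as the signed area of the triangle joining
  each curve point with the two curve ends (clockwise negative).

Joint (R, λ) selection scans a grid: kernels are rebuilt per R and the
global minimum error / maximum curvature wins.  Default grids follow the
kernel spectrum: λ from the smallest eigenvalue of K up to the standard
deviation of the eigenvalues; R from the minimum interelectrode distance to
half the maximum interelectrode distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kernels import KernelModel, build_kernels, default_basis, fit
from .setups import ElectrodeSetup, EstimationSpace, PotentialRecord

__all__ = [
    "CVScan",
    "LCurveScan",
    "loo_prediction",
    "cv_error",
    "default_lambda_range",
    "default_R_range",
    "lcurve_point",
    "triangle_curvature",
    "select_parameters",
]

#: floor used before taking log10 of ρ or η
LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class CVScan:
    """Cross-validation error surface over an (R, λ) grid."""

    lambdas: np.ndarray
    Rs: np.ndarray
    error: np.ndarray        # |Rs| × |lambdas|
    R_best: float
    lambda_best: float
    boundary_flag: bool

    @property
    def argmin(self):
        return self.R_best, self.lambda_best


@dataclass(frozen=True)
class LCurveScan:
    """L-curve coordinates and triangle curvature over an (R, λ) grid."""

    lambdas: np.ndarray
    Rs: np.ndarray
    rho: np.ndarray          # |Rs| × |lambdas|
    eta: np.ndarray
    curvature: np.ndarray
    R_best: float
    lambda_best: float
    boundary_flag: bool

    @property
    def argmax(self):
        return self.R_best, self.lambda_best


def _as_vector(V):
    if isinstance(V, PotentialRecord):
        V = V.values
    V = np.asarray(V, dtype=float)
    if V.ndim == 2:
        if V.shape[1] != 1:
            raise ValueError("parameter selection expects a single time sample")
        V = V[:, 0]
    return V


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loo_prediction(model: KernelModel, V, lam: float, i: int) -> float:
    """Predict the potential at electrode ``i`` from the other N−1.

    Removing row/column i of K is exactly the kernel of the reduced setup,
    so this equals physically rebuilding and refitting without electrode i.
    """
    V = _as_vector(V)
    n = model.n_electrodes
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 electrodes")
    keep = np.arange(n) != i
    K_red = model.K[np.ix_(keep, keep)]
    sub = KernelModel(K=K_red, Ktilde=model.K[i:i + 1, keep],
                      Ktilde_pot=model.K[i:i + 1, keep], lam=lam)
    beta, _ = sub.solve_regularized(V[keep][:, None], lam)
    return float(model.K[i, keep] @ beta[:, 0])


def cv_error(model: KernelModel, V, lam: float) -> float:
    """Sum of squared leave-one-out prediction residuals at λ."""
    V = _as_vector(V)
    preds = np.array([loo_prediction(model, V, lam, i)
                      for i in range(model.n_electrodes)])
    return float(np.sum((preds - V) ** 2))


# ---------------------------------------------------------------------------
# default scan ranges
# ---------------------------------------------------------------------------

def default_lambda_range(model: KernelModel, n_points: int = 25):
    """λ grid spanning the kernel spectrum: from the smallest eigenvalue of
    K to the standard deviation of the eigenvalues, log-spaced.

    When K is numerically singular its smallest eigenvalue is round-off
    noise; the lower end is then floored at 1e-10 of the largest eigenvalue
    so that K + λI never exceeds condition 1e10 along the grid.
    """
    w = model.eigvals
    floor = 1e-10 * max(w[0], 1e-300)
    lam_min = max(float(w[-1]), floor)
    lam_max = float(np.std(w))
    if lam_max <= lam_min:
        warnings.warn("degenerate kernel spectrum; widening lambda range",
                      RuntimeWarning, stacklevel=2)
        lam_max = lam_min * 1e6
    grid = np.logspace(np.log10(lam_min), np.log10(lam_max), n_points)
    return lam_min, lam_max, grid


def default_R_range(setup: ElectrodeSetup, n_points: int = 9) -> np.ndarray:
    """R grid from the minimum interelectrode distance to half the maximum,
    log-spaced; collapses to a single value when the range is empty."""
    d = setup.pairwise_distances()
    r_min = float(d.min())
    r_max = float(d.max()) / 2.0
    if r_min >= r_max:
        return np.array([r_min])
    return np.logspace(np.log10(r_min), np.log10(r_max), n_points)


# ---------------------------------------------------------------------------
# L-curve
# ---------------------------------------------------------------------------

def lcurve_point(model: KernelModel, V, lam: float) -> tuple[float, float]:
    """Residual ``ρ_λ`` and model norm ``η_λ = |β_λᵀ K β_λ|`` at one λ.

    Evaluated spectrally on the kernel eigendecomposition with round-off
    eigenvalues (below the numerical-rank cutoff) clipped to zero, so the
    ridge path is exactly monotone: ρ non-decreasing and η non-increasing
    in λ.  A Cholesky solve would inject noise-amplified null-space modes
    into η at small λ on rank-deficient kernels.
    """
    from .kernels import PINV_RCOND

    V = _as_vector(V)
    w = np.maximum(model.eigvals, 0.0)
    w[w <= PINV_RCOND * max(w[0], 1e-300)] = 0.0
    c = model._eigvecs.T @ V
    with np.errstate(divide="ignore", invalid="ignore"):
        filt = np.where(w > 0, w / (w + lam), 0.0)
        coef = np.where(w > 0, c / (w + lam), 0.0)
    if lam == 0.0:
        filt = (w > 0).astype(float)
    rho = float(np.sum(((filt - 1.0) * c) ** 2))
    eta = float(abs(np.sum(coef * coef * w)))
    return rho, eta


def triangle_curvature(log_rho, log_eta) -> np.ndarray:
    """Signed triangle-area curvature along an L-curve in log coordinates.

    For each interior point P the curvature is the signed area of the
    triangle (first point, P, last point); positive for counter-clockwise
    traversal, negative for clockwise.  Endpoints get 0.
    """
    x = np.asarray(log_rho, dtype=float)
    y = np.asarray(log_eta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log_rho and log_eta must be equal-length vectors")
    if x.size < 3:
        raise ValueError("triangle curvature needs at least 3 points")
    ax, ay = x[0], y[0]
    cx, cy = x[-1], y[-1]
    area = 0.5 * ((x - ax) * (cy - ay) - (y - ay) * (cx - ax))
    area[0] = 0.0
    area[-1] = 0.0
    return area


def _lcurve_scan_1R(model: KernelModel, V, lambdas):
    pts = [lcurve_point(model, V, lam) for lam in lambdas]
    rho = np.array([p[0] for p in pts])
    eta = np.array([p[1] for p in pts])
    curv = triangle_curvature(np.log10(np.maximum(rho, LOG_FLOOR)),
                              np.log10(np.maximum(eta, LOG_FLOOR)))
    return rho, eta, curv


# ---------------------------------------------------------------------------
# joint scans
# ---------------------------------------------------------------------------

def select_parameters(setup: ElectrodeSetup, V, space: EstimationSpace,
                      method: str = "cv", family: str = "gaussian",
                      h: float | None = None, R_grid=None, lambda_grid=None,
                      n_lambdas: int = 25, n_Rs: int = 9):
    """Joint (R, λ) selection by grid scan.

    Rebuilds the kernel per R and returns the global argmin of the CV error
    (``method="cv"``) or argmax of the L-curve curvature
    (``method="lcurve"``) together with the full scan.  When no λ grid is
    supplied, a common default grid is derived from the kernel at the median
    R of the R grid.  ``boundary_flag`` is set when the winner lies on the
    edge of the scanned plane (consider extending the ranges).
    """
    if method not in ("cv", "lcurve"):
        raise ValueError("method must be 'cv' or 'lcurve'")
    V = _as_vector(V)
    if h is None:
        h = float(setup.pairwise_distances().min()) / 2.0
    Rs = (default_R_range(setup, n_Rs) if R_grid is None
          else np.asarray(R_grid, dtype=float))
    if Rs.size == 0:
        raise ValueError("R grid must be non-empty")

    models = {}

    def model_for(R: float) -> KernelModel:
        if R not in models:
            basis = default_basis(setup, R=R, h=h, family=family)
            models[R] = build_kernels(setup, basis, space)
        return models[R]

    if lambda_grid is None:
        mid = float(Rs[len(Rs) // 2])
        _, _, lambdas = default_lambda_range(model_for(mid), n_lambdas)
    else:
        lambdas = np.asarray(lambda_grid, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")

    if method == "cv":
        err = np.full((Rs.size, lambdas.size), np.nan)
        for a, R in enumerate(Rs):
            m = model_for(float(R))
            err[a] = [cv_error(m, V, float(lam)) for lam in lambdas]
        if np.all(np.isnan(err)):
            raise ValueError("cross-validation scan produced no finite errors")
        a, b = np.unravel_index(np.nanargmin(err), err.shape)
        flag = _on_boundary(a, b, err.shape)
        return CVScan(lambdas=lambdas, Rs=Rs, error=err,
                      R_best=float(Rs[a]), lambda_best=float(lambdas[b]),
                      boundary_flag=flag), model_for(float(Rs[a]))

    rho = np.full((Rs.size, lambdas.size), np.nan)
    eta = np.full_like(rho, np.nan)
    curv = np.full_like(rho, np.nan)
    for a, R in enumerate(Rs):
        m = model_for(float(R))
        rho[a], eta[a], curv[a] = _lcurve_scan_1R(m, V, lambdas)
    if np.all(np.isnan(curv)):
        raise ValueError("L-curve scan produced no finite curvatures")
    # argmax of curvature; ties broken toward larger λ (more regularization)
    best = np.nanmax(curv)
    cand = np.argwhere(curv >= best - 0.0)
    a, b = max(cand.tolist(), key=lambda ab: (ab[1], -ab[0]))
    flag = _on_boundary(a, b, curv.shape)
    return LCurveScan(lambdas=lambdas, Rs=Rs, rho=rho, eta=eta,
                      curvature=curv, R_best=float(Rs[a]),
                      lambda_best=float(lambdas[b]), boundary_flag=flag), \
        model_for(float(Rs[a]))


def _on_boundary(a: int, b: int, shape) -> bool:
    edge_R = shape[0] > 1 and a in (0, shape[0] - 1)
    edge_l = shape[1] > 1 and b in (0, shape[1] - 1)
    return edge_R or edge_l
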