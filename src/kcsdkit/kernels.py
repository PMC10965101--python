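"""Kernel construction and regularized kCSD estimation.

Given basis sources b̃_m with potential counterparts b_m, the method builds

* the kernel matrix       ``K_ij  = Σ_m b_m(x_i) b_m(x_j)`` (electrodes),
* the CSD cross-kernel    ``K̃_pj = Σ_m b̃_m(x_p) b_m(x_j)`` (estimation pts),
* the potential cross-kernel ``K_pj = Σ_m b_m(x_p) b_m(x_j)``,

fits ``β = (K + λI)⁻¹ V`` per time sample, and reads out the CSD
``C* = K̃ β`` and the interpolated potential ``V* = K_pot β``.  λ is the
ridge regularization parameter; λ = 0 means trusting the data exactly
(kernel interpolation), large λ shrinks the estimate toward zero.

The slice variant for planar MEA recordings replaces the infinite-medium 2D
layer kernel by a method-of-images ladder handling the conductivity jump at
the tissue–saline interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .basis import (BasisConfig, csd_design_matrix, get_radial_potential,
                    place_basis_regular)
from .setups import ElectrodeSetup, EstimationSpace, PotentialRecord

__all__ = [
    "KernelModel",
    "CSDEstimate",
    "SliceGeometry",
    "default_basis",
    "build_kernels",
    "okcsd_model",
    "fit",
    "moi_potential_basis",
]

#: relative eigenvalue cutoff for the λ=0 pseudo-inverse solve
PINV_RCOND = 1e-12

#: condition-number threshold beyond which the Cholesky path falls back
COND_LIMIT = 1e14

#: default per-axis refinement of the basis grid over the electrode grid
BASIS_REFINEMENT = 4


@dataclass(frozen=True)
class SliceGeometry:
    """Slice-on-MEA geometry for the method-of-images forward model.

    The electrode plane and the source layer sit at the bottom of a slice of
    given ``thickness``, with saline of conductivity ``sigma_saline`` above.
    The image ladder is truncated after ``n_images`` reflection pairs; each
    pair carries a weight ``W^n`` with
    ``W = (σ_tissue − σ_saline) / (σ_tissue + σ_saline)``.
    """

    thickness: float
    sigma_tissue: float
    sigma_saline: float
    n_images: int = 20

    def __post_init__(self):
        if not self.thickness > 0:
            raise ValueError("slice thickness must be positive")
        if not (self.sigma_tissue > 0 and self.sigma_saline > 0):
            raise ValueError("conductivities must be positive")
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")

    @property
    def W(self) -> float:
        return ((self.sigma_tissue - self.sigma_saline)
                / (self.sigma_tissue + self.sigma_saline))


@dataclass
class KernelModel:
    """Kernel matrices plus the spectral data needed by the solver."""

    K: np.ndarray              # N×N
    Ktilde: np.ndarray         # P×N, CSD read-out
    Ktilde_pot: np.ndarray     # P×N, potential read-out
    lam: float = 0.0
    setup: ElectrodeSetup | None = None
    basis: BasisConfig | None = None
    space: EstimationSpace | None = None
    eigvals: np.ndarray = field(init=False, repr=False)
    _eigvecs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        scale = max(np.abs(K).max(), 1e-300)
        if np.abs(K - K.T).max() > 1e-10 * scale:
            raise ValueError("kernel matrix K must be symmetric")
        self.K = 0.5 * (K + K.T)
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        w, U = linalg.eigh(self.K)
        order = np.argsort(w)[::-1]
        self.eigvals = w[order]
        self._eigvecs = U[:, order]
        if self.eigvals[-1] < -1e-8 * max(self.eigvals[0], 0.0):
            raise ValueError("kernel matrix is not positive semi-definite")

    @property
    def n_electrodes(self) -> int:
        return self.K.shape[0]

    def with_lambda(self, lam: float) -> "KernelModel":
        out = KernelModel.__new__(KernelModel)
        out.__dict__.update(self.__dict__)
        out.lam = float(lam)
        return out

    def solve_regularized(self, B: np.ndarray, lam: float | None = None):
        """Solve ``(K + λI) X = B`` (symmetric solve, never an explicit
        inverse).  Returns ``(X, method)`` with ``method`` in
        ``{"cholesky", "pinv"}``.

        λ = 0 always goes through the eigendecomposition pseudo-inverse
        (relative cutoff ``PINV_RCOND``): the kernel of an oversampled basis
        is routinely numerically singular and the pseudo-inverse makes
        interpolation well defined on the data range.
        """
        lam = self.lam if lam is None else float(lam)
        B = np.asarray(B, dtype=float)
        w1 = max(self.eigvals[0], 0.0)
        if lam > 0:
            cond = (w1 + lam) / (max(self.eigvals[-1], 0.0) + lam)
            if cond < COND_LIMIT:
                try:
                    c, low = linalg.cho_factor(
                        self.K + lam * np.eye(self.n_electrodes))
                    return linalg.cho_solve((c, low), B), "cholesky"
                except linalg.LinAlgError:
                    pass
            warnings.warn("ill-conditioned K + lambda*I; falling back to "
                          "pseudo-inverse", RuntimeWarning, stacklevel=2)
        w = self.eigvals + lam
        keep = w > PINV_RCOND * max(w[0], 1e-300)
        U = self._eigvecs[:, keep]
        X = U @ ((U.T @ B).T / w[keep]).T
        return X, "pinv"


@dataclass(frozen=True)
class CSDEstimate:
    """Result of a kCSD fit: coefficients plus CSD/potential read-outs."""

    beta: np.ndarray   # N×T
    csd: np.ndarray    # P×T
    pot: np.ndarray    # P×T
    lam: float
    solver: str        # "cholesky" or "pinv"


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def default_basis(setup: ElectrodeSetup, R: float, h: float | None = None,
                  family: str = "gaussian",
                  refinement: int = BASIS_REFINEMENT) -> BasisConfig:
    """Basis centers on a regular grid over the electrode bounding box,
    ``refinement`` times denser per axis than the electrode grid."""
    box = setup.bounding_box()
    n_axis = max(2, int(np.ceil(setup.n_electrodes ** (1.0 / setup.dim))))
    counts = [max(2, n_axis * refinement) if hi > lo else 1 for lo, hi in box]
    centers = place_basis_regular(box, counts)
    return BasisConfig(family=family, R=R, h=h, centers=centers)


def _medium_for(dim: int, geometry: SliceGeometry | None) -> str:
    if geometry is not None:
        return "moi"
    return {1: "1d_cylinder", 2: "2d_layer", 3: "3d_infinite"}[dim]


def _moi_kernel2d(h: float, geometry: SliceGeometry):
    """Vertical line-integral kernel for the MoI slice, in the arsinh
    convention of the infinite-medium 2D layer (effective half-thickness
    H = 2h reproduces the printed layer formula at W = 0)."""
    H = 2.0 * h
    d = geometry.thickness
    W = geometry.W

    def kernel(rho):
        val = np.arcsinh(H / rho)
        for n in range(1, geometry.n_images + 1):
            Z = 2.0 * n * d
            val = val + W**n * (np.arcsinh((Z + H) / rho)
                                - np.arcsinh((Z - H) / rho))
        return val

    return kernel


def _potential_matrix(basis: BasisConfig, points: np.ndarray, sigma: float,
                      geometry: SliceGeometry | None, d_max: float) -> np.ndarray:
    """M×P matrix of potential basis values b_m(points)."""
    pts = np.atleast_2d(points)
    diff = basis.centers[:, None, :] - pts[None, :, :]
    dists = np.linalg.norm(diff, axis=2)
    medium = _medium_for(basis.dim, geometry)
    if medium == "moi":
        kernel2d = _moi_kernel2d(basis.h, geometry)
        table = get_radial_potential(
            2, basis.family, basis.R, basis.h, geometry.sigma_tissue, d_max,
            kernel2d=kernel2d,
            cache_key_extra=("moi", geometry.thickness, geometry.sigma_saline,
                             geometry.n_images))
    else:
        table = get_radial_potential(basis.dim, basis.family, basis.R,
                                     basis.h, sigma, d_max)
    return table(dists)


def _reach(setup: ElectrodeSetup, basis: BasisConfig,
           space: EstimationSpace) -> float:
    pts = np.vstack([setup.positions, space.points])
    lo = np.minimum(pts.min(axis=0), basis.centers.min(axis=0))
    hi = np.maximum(pts.max(axis=0), basis.centers.max(axis=0))
    return float(np.linalg.norm(hi - lo)) + 6.0 * basis.R + 1e-9


def build_kernels(setup: ElectrodeSetup, basis: BasisConfig,
                  space: EstimationSpace, lam: float = 0.0,
                  geometry: SliceGeometry | None = None) -> KernelModel:
    """Assemble K, K̃ and the potential cross-kernel for a setup."""
    if not (setup.dim == basis.dim == space.dim):
        raise ValueError(
            f"dimensionality mismatch: electrodes {setup.dim}D, basis "
            f"{basis.dim}D, estimation space {space.dim}D")
    if geometry is not None and setup.dim != 2:
        raise ValueError("the slice (MoI) forward model is 2D only")
    d_max = _reach(setup, basis, space)
    phi_el = _potential_matrix(basis, setup.positions, setup.sigma,
                               geometry, d_max)           # M×N
    phi_est = _potential_matrix(basis, space.points, setup.sigma,
                                geometry, d_max)          # M×P
    btil_est = csd_design_matrix(basis, space.points)     # M×P
    for name, mat in (("potential basis", phi_el), ("csd basis", btil_est)):
        if not np.all(np.isfinite(mat)):
            m = int(np.argwhere(~np.isfinite(mat))[0][0])
            raise ValueError(f"non-finite {name} evaluation for basis {m}")
    K = phi_el.T @ phi_el
    Ktilde = btil_est.T @ phi_el
    Ktilde_pot = phi_est.T @ phi_el
    return KernelModel(K=K, Ktilde=Ktilde, Ktilde_pot=Ktilde_pot, lam=lam,
                       setup=setup, basis=basis, space=space)


def okcsd_model(setup: ElectrodeSetup, centers, estimation_points,
                R: float, h: float | None = None, family: str = "gaussian",
                lam: float = 0.0) -> KernelModel:
    """kCSD with explicitly placed (possibly irregular) basis centers and
    estimation points; identical math to :func:`build_kernels`."""
    basis = BasisConfig(family=family, R=R, h=h, centers=np.atleast_2d(centers))
    space = EstimationSpace(np.atleast_2d(estimation_points))
    return build_kernels(setup, basis, space, lam=lam)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit(model: KernelModel, V, lam: float | None = None) -> CSDEstimate:
    """Ridge-regularized kCSD estimate ``C* = K̃ (K + λI)⁻¹ V``.

    ``V`` may be a :class:`PotentialRecord`, an N-vector, or an N×T matrix;
    time samples are solved as columns of one symmetric solve.
    """
    if isinstance(V, PotentialRecord):
        V = V.values
    V = np.asarray(V, dtype=float)
    squeeze = V.ndim == 1
    if squeeze:
        V = V[:, None]
    if V.shape[0] != model.n_electrodes:
        raise ValueError(
            f"potential rows ({V.shape[0]}) do not match electrode count "
            f"({model.n_electrodes})")
    lam = model.lam if lam is None else float(lam)
    beta, solver = model.solve_regularized(V, lam)
    csd = model.Ktilde @ beta
    pot = model.Ktilde_pot @ beta
    if squeeze:
        beta, csd, pot = beta[:, 0], csd[:, 0], pot[:, 0]
    return CSDEstimate(beta=beta, csd=csd, pot=pot, lam=lam, solver=solver)


def moi_potential_basis(center, R, h, geometry: SliceGeometry, xy_points,
                        family: str = "gaussian"):
    """Potential basis for the slice-on-MEA model at in-plane points.

    With ``n_images = 0`` or ``σ_saline = σ_tissue`` (W = 0) this reduces to
    the infinite-medium 2D layer basis.
    """
    from .basis import _as_distances, _pot2d_radial  # quadrature path
    kernel = _moi_kernel2d(float(h), geometry)
    d = _as_distances(xy_points, center)
    return np.array([
        _pot2d_radial(di, float(R), float(h), geometry.sigma_tissue, family,
                      kernel=kernel)
        for di in d])
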