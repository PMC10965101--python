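"""CSD-space basis sources and their potential-space counterparts.

The reconstruction space is spanned by elementary CSD profiles ("basis
sources"): isotropic Gaussians or step (top-hat) functions of radius ``R``
placed on a grid of centers.  Each CSD basis source ``b̃_i`` has a potential
counterpart ``b_i`` obtained by solving the forward problem for the assumed
tissue model:

* 1D (laminar probe): the source is a Gaussian along the probe axis spread
  over a cylindrical sheath of radius ``h``; the potential on the axis is
  ``b(z) = (1/2σ) ∫ dz' (sqrt((z-z')² + h²) - |z-z'|) b̃(z')``.
* 2D (planar probe): the source occupies a tissue layer of thickness ``2h``
  around the electrode plane; the in-plane potential is
  ``b(x,y) = (1/2πσ) ∫∫ dx'dy' arsinh(2h / r) b̃(x',y')``.
* 3D: the plain Coulomb integral ``b = (1/4πσ) ∫ b̃(x')/|x-x'| d³x'``; for a
  normalized Gaussian this has the closed form
  ``b(r) = erf(r / (√2 R)) / (4πσ r)``.

All potentials here assume an infinite homogeneous medium of conductivity
``σ``; the method-of-images slice variant lives in :mod:`kcsdkit.kernels`.

Evaluation strategy: every supported basis family is isotropic, so each
potential basis function depends only on the distance to its center.  Public
operations evaluate the 1D/2D transforms by adaptive quadrature; kernel
construction uses a cubic-spline lookup table over distance (built once per
parameter set by the same quadrature) so that N×M kernel assembly stays
cheap.  Table resolution is chosen so the interpolation error is below 1e-6
relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special
from scipy.interpolate import CubicSpline

__all__ = [
    "BasisConfig",
    "place_basis_regular",
    "csd_basis",
    "csd_design_matrix",
    "potential_basis_1d",
    "potential_basis_2d",
    "potential_basis_3d_gaussian",
    "potential_basis_3d_general",
    "RadialPotential",
]

#: Gaussian support truncation, in units of R.
GAUSS_SUPPORT = 6.0

#: Absolute quadrature tolerance for potential-basis integrals.
QUAD_TOL = 1e-10


# ---------------------------------------------------------------------------
# configuration and placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisConfig:
    """Family, scale and placement of the CSD basis sources.

    Parameters
    ----------
    family
        ``"gaussian"`` or ``"step"``.
    R
        Basis radius: Gaussian scale (std) or step support radius. Same
        length unit as the electrode coordinates.
    h
        1D: radius of the cylindrical sheath; 2D: half-thickness of the
        contributing tissue layer (the layer spans ``-h..h``). Unused in 3D.
    centers
        ``M×k`` array of basis-source centers.
    """

    family: str
    R: float
    centers: np.ndarray
    h: float | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "step"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if not self.R > 0:
            raise ValueError("basis radius R must be positive")
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 2 or centers.shape[0] < 1:
            raise ValueError("centers must be an M×k array with M >= 1")
        if self.dim in (1, 2):
            if self.h is None or not self.h > 0:
                raise ValueError("h must be positive for 1D/2D bases")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @property
    def n_bases(self) -> int:
        return self.centers.shape[0]


def place_basis_regular(bounds, counts) -> np.ndarray:
    """Regular grid of basis centers covering axis-aligned ``bounds``.

    ``bounds`` is a sequence of ``(min, max)`` per axis, ``counts`` the
    number of centers per axis.  A single center on an axis is placed at the
    axis midpoint.  Expansion is row-major with the last axis fastest.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    counts = [int(c) for c in np.atleast_1d(counts)]
    if len(counts) != len(bounds):
        raise ValueError("counts and bounds must have matching length")
    axes = []
    for (lo, hi), c in zip(bounds, counts):
        if lo > hi:
            raise ValueError(f"axis bounds reversed: {lo} > {hi}")
        if c < 1:
            raise ValueError("counts must be >= 1 per axis")
        axes.append(np.array([(lo + hi) / 2.0]) if c == 1 else np.linspace(lo, hi, c))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


# ---------------------------------------------------------------------------
# CSD-space profiles
# ---------------------------------------------------------------------------

def _radial_csd(r, R: float, dim: int, family: str):
    """Unit-integral isotropic profile value at distance ``r`` from center."""
    r = np.asarray(r, dtype=float)
    if family == "gaussian":
        norm = (2.0 * np.pi * R * R) ** (-dim / 2.0)
        return norm * np.exp(-0.5 * (r / R) ** 2)
    if family == "step":
        vol = {1: 2.0 * R, 2: np.pi * R * R, 3: 4.0 / 3.0 * np.pi * R**3}[dim]
        return np.where(r <= R, 1.0 / vol, 0.0)
    raise ValueError(f"unknown basis family {family!r}")


def csd_basis(points, center, R: float, family: str = "gaussian"):
    """CSD basis source values at ``points`` (unit spatial integral)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.atleast_1d(np.asarray(center, dtype=float))
    r = np.linalg.norm(pts - center[None, :], axis=1)
    return _radial_csd(r, R, center.size, family)


def csd_design_matrix(cfg: BasisConfig, points) -> np.ndarray:
    """``M×P`` matrix of b̃_m evaluated at ``points``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    diff = cfg.centers[:, None, :] - pts[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    return _radial_csd(r, cfg.R, cfg.dim, cfg.family)


# ---------------------------------------------------------------------------
# radial quadrature engines (potential of a unit-integral source at distance d)
# ---------------------------------------------------------------------------

def _source_half_width(R: float, family: str) -> float:
    return GAUSS_SUPPORT * R if family == "gaussian" else R


def _pot1d_radial(u: float, R: float, h: float, sigma: float, family: str) -> float:
    """1D sheath potential at axial distance ``u`` from the source center."""
    w = _source_half_width(R, family)

    def integrand(t):
        dz = u - t
        return (np.sqrt(dz * dz + h * h) - abs(dz)) * _radial_csd(abs(t), R, 1, family)

    pts = [u] if -w < u < w else None
    val, _ = integrate.quad(integrand, -w, w, points=pts,
                            epsabs=QUAD_TOL, epsrel=1e-10, limit=200)
    return val / (2.0 * sigma)


def _angular_average(rho, d: float, R: float, family: str):
    """Average of the source profile over a circle of radius rho centered
    at distance d from the source center (2D)."""
    rho = np.asarray(rho, dtype=float)
    if family == "gaussian":
        # closed form via the scaled Bessel function I0
        z = d * rho / (R * R)
        return ((2.0 * np.pi * R * R) ** -1
                * np.exp(-0.5 * ((d - rho) / R) ** 2) * special.ive(0, z))
    # step: fraction of the circle inside the disk of radius R
    full = 1.0 / (np.pi * R * R)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosarg = (d * d + rho * rho - R * R) / (2.0 * d * rho)
    frac = np.where(rho + d <= R, 1.0,
                    np.where(np.abs(d - rho) >= R, 0.0,
                             np.arccos(np.clip(cosarg, -1.0, 1.0)) / np.pi))
    if d == 0.0:
        frac = np.where(rho <= R, 1.0, 0.0)
    return full * frac


def _pot2d_radial(d: float, R: float, h: float, sigma: float, family: str,
                  kernel=None) -> float:
    """In-plane layer potential at distance ``d`` from the source center.

    ``kernel`` maps in-plane distance rho to the vertical line integral in
    the arsinh convention; default is the infinite-medium layer kernel
    ``arsinh(2h/rho)``.
    """
    if kernel is None:
        kernel = lambda rho: np.arcsinh(2.0 * h / rho)
    w = _source_half_width(R, family)
    if family == "step":
        lo, hi = max(0.0, d - R), d + R
    else:
        lo, hi = 0.0, d + w

    def integrand(rho):
        return rho * kernel(rho) * _angular_average(rho, d, R, family)

    pts = [d] if lo < d < hi else None
    val, _ = integrate.quad(integrand, lo, hi, points=pts,
                            epsabs=QUAD_TOL, epsrel=1e-10, limit=200)
    # 2π from the angular integral cancels the 1/2π of the layer kernel
    return val / sigma


def _pot3d_radial(r: float, R: float, sigma: float, family: str) -> float:
    """Infinite-medium 3D potential of a unit isotropic source at distance r.

    Uses the exact spherical-shell reduction of the Coulomb integral:
    ``V(r) = (1/σ) [ (1/r) ∫_0^r s² b̃(s) ds + ∫_r^∞ s b̃(s) ds ]``.
    """
    w = _source_half_width(R, family)

    def inner(s):
        return s * s * _radial_csd(s, R, 3, family) * 4.0 * np.pi

    def outer(s):
        return s * _radial_csd(s, R, 3, family) * 4.0 * np.pi

    if r <= 0.0:
        tail, _ = integrate.quad(outer, 0.0, w, epsabs=QUAD_TOL, epsrel=1e-10)
        return tail / (4.0 * np.pi * sigma)
    hi = min(r, w)
    q_in, _ = integrate.quad(inner, 0.0, hi, epsabs=QUAD_TOL, epsrel=1e-10)
    if r < w:
        tail, _ = integrate.quad(outer, r, w, epsabs=QUAD_TOL, epsrel=1e-10)
    else:
        tail = 0.0
    return (q_in / r + tail) / (4.0 * np.pi * sigma)


# ---------------------------------------------------------------------------
# public potential-basis operations (quadrature path)
# ---------------------------------------------------------------------------

def _as_distances(points, center):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.atleast_1d(np.asarray(center, dtype=float))
    if pts.shape[1] != c.size:
        raise ValueError("points and center dimensionality mismatch")
    return np.linalg.norm(pts - c[None, :], axis=1)


def potential_basis_1d(center, R, h, sigma, z_points, family="gaussian"):
    """Potential basis b(z) for a 1D source in a cylindrical sheath."""
    _check_pos(R=R, h=h, sigma=sigma)
    c = float(np.atleast_1d(center)[0])
    z = np.atleast_1d(np.asarray(z_points, dtype=float)).ravel()
    return np.array([_pot1d_radial(abs(zi - c), R, h, sigma, family) for zi in z])


def potential_basis_2d(center, R, h, sigma, xy_points, family="gaussian"):
    """In-plane potential basis b(x, y) for a 2D source layer of span -h..h."""
    _check_pos(R=R, h=h, sigma=sigma)
    d = _as_distances(xy_points, center)
    return np.array([_pot2d_radial(di, R, h, sigma, family) for di in d])


def potential_basis_3d_gaussian(center, R, sigma, points):
    """Closed-form potential of a normalized 3D Gaussian source.

    ``b(r) = erf(r / (√2 R)) / (4πσ r)`` with the analytic center limit
    ``√(2/π) / (4πσR)``.
    """
    _check_pos(R=R, sigma=sigma)
    r = _as_distances(points, center)
    out = np.empty_like(r)
    small = r < 1e-12 * R
    out[small] = np.sqrt(2.0 / np.pi) / (4.0 * np.pi * sigma * R)
    rs = r[~small]
    out[~small] = special.erf(rs / (np.sqrt(2.0) * R)) / (4.0 * np.pi * sigma * rs)
    return out


def potential_basis_3d_general(center, R, sigma, points, family="step"):
    """3D potential of a unit isotropic source by quadrature of the Coulomb
    integral (exact spherical-shell radial reduction)."""
    _check_pos(R=R, sigma=sigma)
    r = _as_distances(points, center)
    return np.array([_pot3d_radial(ri, R, sigma, family) for ri in r])


def _check_pos(**params):
    for name, val in params.items():
        if not float(val) > 0:
            raise ValueError(f"{name} must be positive, got {val}")


# ---------------------------------------------------------------------------
# lookup-table evaluation for kernel assembly
# ---------------------------------------------------------------------------

@dataclass
class RadialPotential:
    """Cubic-spline lookup table of a potential basis over distance.

    Built once per (dim, family, R, h, sigma, medium) by the quadrature
    engines above; evaluation then costs a spline lookup.  The node spacing
    resolves the smaller of R and h so cubic interpolation error stays below
    1e-6 relative to the peak.
    """

    dim: int
    family: str
    R: float
    h: float | None
    sigma: float
    d_max: float
    kernel2d: object = None  # optional override of the 2D layer kernel (MoI)
    _spline: CubicSpline = field(init=False, repr=False, default=None)

    #: hard cap on table size; spacing is widened if d_max is very large
    MAX_NODES = 6000

    def __post_init__(self):
        scale = self.R if self.h is None else min(self.R, self.h)
        du = scale / 16.0
        n = int(np.ceil(self.d_max / du)) + 1
        if n > self.MAX_NODES:
            n = self.MAX_NODES
        n = max(n, 64)
        d = np.linspace(0.0, self.d_max, n)
        if self.dim == 1:
            vals = [_pot1d_radial(di, self.R, self.h, self.sigma, self.family)
                    for di in d]
        elif self.dim == 2:
            vals = [_pot2d_radial(di, self.R, self.h, self.sigma, self.family,
                                  kernel=self.kernel2d) for di in d]
        elif self.dim == 3 and self.family == "gaussian":
            vals = potential_basis_3d_gaussian(
                np.zeros(3), self.R, self.sigma,
                np.column_stack([d, np.zeros_like(d), np.zeros_like(d)]))
        elif self.dim == 3:
            vals = [_pot3d_radial(di, self.R, self.sigma, self.family) for di in d]
        else:
            raise ValueError("dim must be 1, 2 or 3")
        # isotropic potential is even in distance: clamp slope at the origin
        self._spline = CubicSpline(d, np.asarray(vals, dtype=float),
                                   bc_type=((1, 0.0), "not-a-knot"))

    def __call__(self, dists):
        dists = np.asarray(dists, dtype=float)
        if np.any(dists > self.d_max * (1 + 1e-9)):
            raise ValueError("distance beyond lookup-table range; rebuild with "
                             f"larger d_max (have {self.d_max})")
        return self._spline(np.clip(dists, 0.0, self.d_max))


_TABLE_CACHE: dict = {}


def get_radial_potential(dim, family, R, h, sigma, d_max, kernel2d=None,
                         cache_key_extra=None) -> RadialPotential:
    """Cached :class:`RadialPotential` lookup (tables are expensive to build).

    ``d_max`` is quantized upward so near-identical requests share a table.
    """
    d_key = float(np.ceil(d_max / max(R, 1e-30)) * R)
    key = (dim, family, round(float(R), 12), None if h is None else round(float(h), 12),
           round(float(sigma), 12), round(d_key, 9), cache_key_extra)
    if key not in _TABLE_CACHE:
        if len(_TABLE_CACHE) > 256:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = RadialPotential(dim, family, float(R),
                                            None if h is None else float(h),
                                            float(sigma), d_key, kernel2d=kernel2d)
    return _TABLE_CACHE[key]
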