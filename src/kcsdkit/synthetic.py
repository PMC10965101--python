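"""Synthetic ground truth, forward modeling and noise injection.

Ground-truth CSD profiles are Gaussian mixtures.  Families are defined
relative to a reference interelectrode spacing ``d_ref``:

* ``small``  — dipole of Gaussians with radii uniform in [0.1, 0.5]·d_ref,
* ``large``  — dipole with radii uniform in [1, 2]·d_ref,
* ``dipole`` — dipole with radii uniform in [0.5, 1.5]·d_ref,
* ``dipole_split_sink`` — 1D only: one positive Gaussian plus two nearby
  negative Gaussians of half the amplitude (a dipolar source whose sink is
  split in two), the standard 1D demonstration profile.

Component amplitudes alternate ±1 so every profile is charge balanced.
Potentials at the electrodes are forward-modeled per component: the 3D
model uses the erf closed form, the 1D sheath and 2D layer models the same
quadrature transforms as the basis module.  All randomness flows from one
seed through ``numpy.random.SeedSequence`` spawning, so the profile, noise
and electrode-removal substreams are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import _pot1d_radial, _pot2d_radial, potential_basis_3d_gaussian
from .setups import ElectrodeSetup, NoiseModel, PotentialRecord

__all__ = [
    "GroundTruthProfile",
    "make_profile",
    "forward_potentials",
    "add_noise",
    "demo_1d_fixture",
]

FAMILIES = ("small", "large", "dipole", "dipole_split_sink", "custom")

#: radius ranges per family, in units of the reference spacing
RADIUS_RANGE = {"small": (0.1, 0.5), "large": (1.0, 2.0), "dipole": (0.5, 1.5)}

#: default uniform-noise amplitude, relative to the peak |V|
NOISE_REL_AMPLITUDE = 0.05


@dataclass(frozen=True)
class GroundTruthProfile:
    """Analytic CSD ground truth: a mixture of isotropic Gaussians."""

    centers: np.ndarray    # n_components × k
    radii: np.ndarray      # n_components
    amplitudes: np.ndarray  # n_components
    family: str = "custom"
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "centers",
                           np.atleast_2d(np.asarray(self.centers, dtype=float)))
        object.__setattr__(self, "radii",
                           np.atleast_1d(np.asarray(self.radii, dtype=float)))
        object.__setattr__(self, "amplitudes",
                           np.atleast_1d(np.asarray(self.amplitudes, dtype=float)))
        if not (len(self.radii) == len(self.amplitudes) == len(self.centers)):
            raise ValueError("component arrays must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("component radii must be positive")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @property
    def n_components(self) -> int:
        return self.centers.shape[0]

    def evaluate(self, points) -> np.ndarray:
        """CSD values at ``points`` (each component has unit integral before
        scaling by its amplitude)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = self.dim
        out = np.zeros(pts.shape[0])
        for c, R, a in zip(self.centers, self.radii, self.amplitudes):
            r2 = np.sum((pts - c[None, :]) ** 2, axis=1)
            norm = (2.0 * np.pi * R * R) ** (-k / 2.0)
            out += a * norm * np.exp(-0.5 * r2 / (R * R))
        return out


def _spawn(seed, *labels):
    """Independent substream of the master seed, keyed by integer labels."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=labels))


def make_profile(family: str, dim: int, bounds, seed: int,
                 spacing: float = 1.0) -> GroundTruthProfile:
    """Seeded ground-truth profile of a named family.

    ``bounds`` is the bounding box (per-axis (min, max)) in which component
    centers are drawn; ``spacing`` the reference interelectrode distance
    that sets the component radii.
    """
    if family not in FAMILIES or family == "custom":
        raise ValueError(f"unknown profile family {family!r}")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != dim:
        raise ValueError("bounds length must equal dim")
    rng = _spawn(seed, 0)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if family == "dipole_split_sink":
        if dim != 1:
            raise ValueError("dipole_split_sink is a 1D profile")
        L = hi[0] - lo[0]
        centers = lo[0] + L * np.array([[0.35], [0.60], [0.78]])
        radii = np.full(3, 0.05 * L)
        amps = np.array([1.0, -0.5, -0.5])
        return GroundTruthProfile(centers, radii, amps, family=family, seed=seed)
    r_lo, r_hi = RADIUS_RANGE[family]
    radii = rng.uniform(r_lo * spacing, r_hi * spacing, size=2)
    centers = rng.uniform(lo, hi, size=(2, dim))
    amps = np.array([1.0, -1.0])
    return GroundTruthProfile(centers, radii, amps, family=family, seed=seed)


# ---------------------------------------------------------------------------
# forward modeling
# ---------------------------------------------------------------------------

def forward_potentials(profile: GroundTruthProfile, setup: ElectrodeSetup,
                       h: float | None = None) -> np.ndarray:
    """Exact potentials of the profile at the electrodes.

    The physical model follows the setup dimensionality: 1D cylindrical
    sheath of radius ``h``, 2D layer of half-thickness ``h``, 3D infinite
    medium (closed form).  Components superpose linearly.
    """
    if profile.dim != setup.dim:
        raise ValueError("profile and setup dimensionality differ")
    if setup.dim in (1, 2):
        if h is None or not h > 0:
            raise ValueError("the 1D/2D forward model needs a positive h")
    V = np.zeros(setup.n_electrodes)
    for c, R, a in zip(profile.centers, profile.radii, profile.amplitudes):
        if a == 0.0:
            continue
        if setup.dim == 3:
            V += a * potential_basis_3d_gaussian(c, R, setup.sigma,
                                                 setup.positions)
        elif setup.dim == 1:
            d = np.abs(setup.positions[:, 0] - c[0])
            V += a * np.array([_pot1d_radial(di, R, h, setup.sigma, "gaussian")
                               for di in d])
        else:
            d = np.linalg.norm(setup.positions - c[None, :], axis=1)
            V += a * np.array([_pot2d_radial(di, R, h, setup.sigma, "gaussian")
                               for di in d])
    return V


def add_noise(potentials, kind: str = "uniform", seed: int = 0,
              amplitude: float | None = None,
              noise_model: NoiseModel | None = None):
    """Seeded additive electrode noise.

    ``kind="uniform"`` draws i.i.d. values from ``U(−a, a)`` with
    ``a = amplitude`` (absolute; defaults to 5% of the peak |V|);
    ``kind="gaussian"`` draws from ``N(0, Σ_V)`` given by ``noise_model``.
    Returns ``(noisy, noise)`` so tests can inspect the realization.
    """
    V = np.asarray(potentials, dtype=float)
    rng = _spawn(seed, 1)
    if kind == "uniform":
        a = (NOISE_REL_AMPLITUDE * np.abs(V).max()
             if amplitude is None else float(amplitude))
        noise = rng.uniform(-a, a, size=V.shape)
    elif kind == "gaussian":
        if noise_model is None:
            raise ValueError("gaussian noise needs a NoiseModel")
        n = V.shape[0]
        cov = noise_model.full_covariance(n)
        flat = rng.multivariate_normal(np.zeros(n), cov,
                                       size=V.shape[1:][::-1] or 1,
                                       method="cholesky" if np.all(
                                           np.linalg.eigvalsh(cov) > 0)
                                       else "svd")
        noise = flat.T.reshape(V.shape) if V.ndim > 1 else flat[0]
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return V + noise, noise


# ---------------------------------------------------------------------------
# end-to-end demo fixture
# ---------------------------------------------------------------------------

def demo_1d_fixture(seed: int, n_electrodes: int = 32, h: float = 0.1,
                    sigma: float = 1.0, noise: bool = True,
                    noise_amplitude: float | None = None):
    """Standard 1D demonstration: a regular laminar probe on [0, 1] records
    a dipolar source with a split sink, plus uniform electrode noise.

    Returns a dict with the setup, the ground-truth profile, clean and
    noisy potentials and the noise realization.
    """
    positions = np.linspace(0.0, 1.0, n_electrodes)[:, None]
    setup = ElectrodeSetup(positions, sigma=sigma)
    profile = make_profile("dipole_split_sink", 1, [(0.0, 1.0)], seed)
    clean = forward_potentials(profile, setup, h=h)
    if noise:
        noisy, eps = add_noise(clean, "uniform", seed=seed,
                               amplitude=noise_amplitude)
    else:
        noisy, eps = clean.copy(), np.zeros_like(clean)
    return {
        "setup": setup,
        "profile": profile,
        "h": h,
        "clean": PotentialRecord(clean),
        "potentials": PotentialRecord(noisy),
        "noise": eps,
    }
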