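"""Quality control for kCSD estimates.

Everything here exploits the linearity of the estimation operator
(the resolvent) ``E = K̃ (K + λI)⁻¹``:

* columns of E are *error propagation maps* — the CSD response to a unit
  potential at one electrode;
* measurement noise ``ε ~ N(0, Σ_V)`` propagates to the estimate as
  ``C* ~ N(E V_exact, E Σ_V Eᵀ)``, whose diagonal is the *measurement
  uncertainty map*;
* the eigenvectors of K map through K̃ to *eigensources*, the perfectly
  recoverable CSD fields spanning everything the setup can see;
* *reliability maps* average a point-wise relative-difference error over a
  seeded family of test ground truths pushed through the full pipeline, and
  the *broken-electrode study* repeats them with contacts removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (KernelModel, build_kernels, default_basis, fit)
from .model_selection import cv_error, default_R_range, default_lambda_range
from .setups import ElectrodeSetup, EstimationSpace, NoiseModel
from .synthetic import _spawn, forward_potentials, make_profile

__all__ = [
    "Resolvent",
    "UncertaintyMap",
    "ReliabilityResult",
    "resolvent",
    "error_propagation_maps",
    "uncertainty_map",
    "eigensources",
    "rdm_pointwise_error",
    "reliability_map",
    "broken_electrode_study",
]


@dataclass(frozen=True)
class Resolvent:
    """The linear map from measured potentials to estimated CSD."""

    E: np.ndarray  # P×N
    lam: float


@dataclass(frozen=True)
class UncertaintyMap:
    """Per-point variance of the CSD estimate under measurement noise."""

    variance: np.ndarray  # P
    noise: NoiseModel
    lam: float


@dataclass(frozen=True)
class ReliabilityResult:
    """Point-wise reconstruction errors over a family of test sources."""

    per_profile_error: np.ndarray  # n_profiles × P
    mean_map: np.ndarray           # P
    family: str
    seed: int
    selected_R: np.ndarray         # per profile
    space: EstimationSpace


def resolvent(model: KernelModel, lam: float | None = None) -> Resolvent:
    """Compute ``E = K̃ (K+λI)⁻¹`` via N symmetric solves."""
    lam = model.lam if lam is None else float(lam)
    X, _ = model.solve_regularized(model.Ktilde.T, lam)
    return Resolvent(E=X.T, lam=lam)


def error_propagation_maps(model: KernelModel,
                           lam: float | None = None) -> np.ndarray:
    """P×N stack: column i is the CSD response to a unit potential at
    electrode i."""
    return resolvent(model, lam).E


def uncertainty_map(model: KernelModel, noise: NoiseModel,
                    lam: float | None = None) -> UncertaintyMap:
    """Diagonal of ``E Σ_V Eᵀ``; scalar noise uses ``σ²·diag(EEᵀ)``."""
    res = resolvent(model, lam)
    E = res.E
    if noise.covariance is None:
        var = noise.variance * np.einsum("pn,pn->p", E, E)
    else:
        cov = noise.full_covariance(model.n_electrodes)
        var = np.einsum("pn,nm,pm->p", E, cov, E)
    return UncertaintyMap(variance=np.maximum(var, 0.0), noise=noise,
                          lam=res.lam)


def eigensources(model: KernelModel, rcond: float = 1e-12):
    """Eigensource fields on the estimation points.

    Eigendecomposition ``K = U Λ Uᵀ`` (eigenvalues descending, relative
    cutoff ``rcond``); eigensource j is the CSD field ``K̃ u_j`` of the
    unit-norm coefficient vector ``u_j``.  Returns ``(fields P×r,
    eigenvalues r, coefficients N×r)``.
    """
    w = model.eigvals
    if w[0] <= 0:
        raise ValueError("kernel matrix has no positive eigenvalues")
    keep = w > rcond * w[0]
    U = model._eigvecs[:, keep]
    fields = model.Ktilde @ U
    return fields, w[keep], U


def rdm_pointwise_error(truth: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Point-wise relative-difference error between two CSD fields.

    ``err(x) = | Ĉ(x)/‖Ĉ‖ − C(x)/‖C‖ | · ‖C‖ / max|C|`` with ‖·‖ the
    Euclidean norm over the estimation points.  Scale-invariant in the
    estimate; zero iff the estimate is a positive multiple of the truth.
    """
    C = np.asarray(truth, dtype=float).ravel()
    Chat = np.asarray(estimate, dtype=float).ravel()
    if C.shape != Chat.shape:
        raise ValueError("truth and estimate must share estimation points")
    nC = np.linalg.norm(C)
    if nC == 0:
        raise ValueError("ground-truth field has zero norm")
    nChat = np.linalg.norm(Chat)
    unit_hat = Chat / nChat if nChat > 0 else Chat
    return np.abs(unit_hat - C / nC) * nC / np.abs(C).max()


# ---------------------------------------------------------------------------
# reliability maps
# ---------------------------------------------------------------------------

def _profile_families(family: str):
    if family == "both":
        return ("small", "large")
    if family in ("small", "large"):
        return (family,)
    raise ValueError("profile family must be 'small', 'large' or 'both'")


def _grid_symmetry_orders(space: EstimationSpace):
    """Index permutations realizing the 8 mirror symmetries of a square
    2D grid (identity, flips, transposes)."""
    if space.grid is None or space.dim != 2:
        raise ValueError("symmetrization needs a regular 2D grid")
    (lo0, hi0, n0), (lo1, hi1, n1) = space.grid
    if n0 != n1 or (hi0 - lo0) != (hi1 - lo1):
        raise ValueError("symmetrization needs a square grid")
    n = n0
    idx = np.arange(n * n).reshape(n, n)
    mats = [idx, idx[::-1], idx[:, ::-1], idx[::-1, ::-1],
            idx.T, idx.T[::-1], idx.T[:, ::-1], idx.T[::-1, ::-1]]
    return [m.ravel() for m in mats]


def reliability_map(setup: ElectrodeSetup, space: EstimationSpace,
                    family: str = "both", n_profiles: int = 20,
                    seed: int = 0, h: float | None = None,
                    basis_family: str = "gaussian", R_grid=None,
                    symmetrize: bool = False,
                    profile_box=None, profile_spacing: float | None = None,
                    _estimator=None) -> ReliabilityResult:
    """Average point-wise reconstruction error over seeded test sources.

    For each profile: forward-model noise-free potentials, select R by
    leave-one-out cross-validation (λ pinned at the bottom of its default
    range — the noise-free convention), reconstruct, and score with
    :func:`rdm_pointwise_error`; the reliability map is the profile mean.
    ``symmetrize`` additionally averages each error map over the eight
    mirror symmetries of a square grid.  ``profile_box`` and
    ``profile_spacing`` override the geometry the test sources are drawn
    from (used by the broken-electrode study so removals do not change the
    source family).  ``_estimator`` is a test hook mapping
    (profile, space) to a CSD field, bypassing the pipeline.
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    families = _profile_families(family)
    spacing = (float(setup.pairwise_distances().min())
               if profile_spacing is None else float(profile_spacing))
    if h is None:
        h = spacing / 2.0
    Rs = default_R_range(setup) if R_grid is None else np.asarray(R_grid, float)
    box = setup.bounding_box() if profile_box is None else list(profile_box)

    models = {}

    def model_for(R: float) -> KernelModel:
        if R not in models:
            basis = default_basis(setup, R=R, h=h, family=basis_family)
            models[R] = build_kernels(setup, basis, space)
        return models[R]

    sym_orders = _grid_symmetry_orders(space) if symmetrize else None

    errors = np.empty((n_profiles, space.n_points))
    selected_R = np.empty(n_profiles)
    for p in range(n_profiles):
        fam = families[p % len(families)]
        prof_seed = int(_spawn(seed, 2, p).integers(0, 2**31 - 1))
        profile = make_profile(fam, setup.dim, box, prof_seed, spacing=spacing)
        truth = profile.evaluate(space.points)
        if _estimator is not None:
            est_csd = _estimator(profile, space)
            selected_R[p] = np.nan
        else:
            V = forward_potentials(profile, setup, h=h)
            best, best_err = None, np.inf
            for R in Rs:
                m = model_for(float(R))
                lam_min, _, _ = default_lambda_range(m)
                e = cv_error(m, V, lam_min)
                if e < best_err:
                    best, best_err = float(R), e
            m = model_for(best)
            lam_min, _, _ = default_lambda_range(m)
            est_csd = fit(m, V, lam=lam_min).csd
            selected_R[p] = best
        err = rdm_pointwise_error(truth, est_csd)
        if sym_orders is not None:
            err = np.mean([err[o] for o in sym_orders], axis=0)
        errors[p] = err
    return ReliabilityResult(per_profile_error=errors,
                             mean_map=errors.mean(axis=0), family=family,
                             seed=seed, selected_R=selected_R, space=space)


def broken_electrode_study(setup: ElectrodeSetup, space: EstimationSpace,
                           n_broken=(5, 10, 20), family: str = "both",
                           n_profiles: int = 20, seed: int = 0,
                           h: float | None = None, R_grid=None):
    """Reliability change when contacts fail.

    Removes seeded random electrode subsets, nested across counts
    (5 ⊂ 10 ⊂ 20 within one seed), recomputes the reliability map on the
    same estimation space with the same profile set, and returns
    (broken − intact) difference maps.

    Returns a dict with the intact result, per-count results, difference
    maps and the removal order.
    """
    counts = sorted(int(c) for c in n_broken)
    if counts and counts[-1] >= setup.n_electrodes:
        raise ValueError("cannot break all electrodes")
    if any(c < 0 for c in counts):
        raise ValueError("broken counts must be non-negative")
    order = _spawn(seed, 3).permutation(setup.n_electrodes)
    box = setup.bounding_box()
    spacing = float(setup.pairwise_distances().min())
    if h is None:
        h = spacing / 2.0
    intact = reliability_map(setup, space, family=family,
                             n_profiles=n_profiles, seed=seed, h=h,
                             R_grid=R_grid, profile_box=box,
                             profile_spacing=spacing)
    results, diffs = {}, {}
    for c in counts:
        if c == 0:
            results[c] = intact
            diffs[c] = np.zeros_like(intact.mean_map)
            continue
        keep = np.setdiff1d(np.arange(setup.n_electrodes), order[:c])
        sub = setup.subset(keep)
        res = reliability_map(sub, space, family=family,
                              n_profiles=n_profiles, seed=seed, h=h,
                              R_grid=R_grid, profile_box=box,
                              profile_spacing=spacing)
        results[c] = res
        diffs[c] = res.mean_map - intact.mean_map
    return {"intact": intact, "per_count": results, "difference": diffs,
            "removal_order": order}
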