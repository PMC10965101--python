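# Methods

## Model

The package estimates current source density C from potentials V measured
at N electrode positions x₁…x_N (1D, 2D or 3D coordinates). The tissue is
assumed ohmic, homogeneous and isotropic with conductivity σ, so potential
and CSD are linked by the Coulomb integral
`V(x) = (1/4πσ) ∫ C(x′)/|x−x′| d³x′`. The estimation space is spanned by M
basis sources b̃ᵢ with potential counterparts bᵢ; kernel ridge regression
with kernel `K(x,x′) = Σᵢ bᵢ(x)bᵢ(x′)` interpolates the measurements and
the cross-kernel `K̃(x,y) = Σᵢ b̃ᵢ(x)bᵢ(y)` maps the fitted coefficients
`β = (K+λI)⁻¹V` to the CSD estimate `C* = K̃β`. Time samples are columns of
one symmetric solve.

### Basis families and forward models

Gaussians `b̃(r) = (2πR²)^{-k/2} exp(−r²/2R²)` (k the dimensionality) and
unit-integral step functions on a ball of radius R. Both are normalized to
unit spatial integral so the families are interchangeable; the estimate is
invariant to the normalization choice since it is absorbed by the fitted
coefficients.

Dimension-reduced forward models:

- 1D (laminar probe): sources occupy a cylindrical sheath of radius h
  around the probe axis; on the axis
  `b(z) = (1/2σ) ∫ dz′ (√((z−z′)²+h²) − |z−z′|) b̃(z′)`.
- 2D (planar): sources occupy a tissue layer around the electrode plane;
  in-plane `b(x,y) = (1/2πσ) ∫∫ arsinh(2h/ρ) b̃ dx′dy′` with ρ the
  in-plane distance. (This printed kernel corresponds to a layer of
  effective half-thickness 2h; the method-of-images terms below use the
  same convention so the no-contrast limit is exact.)
- 3D: the Coulomb integral; for Gaussian bases the closed form
  `b(r) = erf(r/(√2R)) / (4πσr)` with center limit `√(2/π)/(4πσR)`.

For the slice-on-MEA geometry the 2D vertical kernel is replaced by a
method-of-images ladder: the insulating MEA plane is folded into the
symmetric layer, the tissue–saline boundary at the slice thickness d
contributes image pairs at heights 2nd weighted by
`Wⁿ, W = (σ_t−σ_s)/(σ_t+σ_s)`, truncated after `n_images` pairs (geometric
tail ≲ |W|^{n+1}/(1−|W|)). With W = 0 or n_images = 0 this reduces exactly
to the infinite-medium layer kernel.

### Numerics

All supported bases are isotropic, so every potential basis is a radial
function. Public operations evaluate the 1D/2D transforms by adaptive
quadrature (absolute tolerance 1e-10, Gaussian support truncated at 6R;
the 2D angular integral is reduced analytically — Bessel I₀ for Gaussians,
arc fractions for steps — leaving one radial quadrature with the
integrable log singularity handled under the ρ dρ measure). The 3D general
family uses the exact spherical-shell reduction of the Coulomb integral.
Kernel assembly evaluates bases through a cubic-spline lookup table over
distance, nodes spaced at min(R, h)/16 (interpolation error below 1e-6
relative, verified against quadrature in tests), cached per parameter set.

`(K+λI)β = V` is solved by Cholesky factorization for λ > 0. At λ = 0 the
solver always uses the eigendecomposition pseudo-inverse with relative
cutoff 1e-12: kernels built from oversampled bases (M > N is the default)
are routinely numerically singular, and the pseudo-inverse makes λ = 0
interpolation and eigensource round-trips well defined. The resolvent
`E = K̃(K+λI)⁻¹` is computed by N solves of the same system, never an
explicit inverse.

## Parameter selection

- λ grid: log-spaced, 25 points by default, from the smallest eigenvalue
  of K — floored at 1e-10 of the largest so the condition number along the
  grid never exceeds 1e10 — to the standard deviation of the eigenvalues.
- R grid: log-spaced, 9 points, from the minimum interelectrode distance
  to half the maximum; collapses to the minimum when the range is empty.
  For single-R analyses (the 1D demo) the convention is R = minimum
  interelectrode distance, the lower end of this rule.
- Cross-validation: full leave-one-out; deleting row/column i of K is
  identical to rebuilding the reduced setup, which the tests exploit as an
  independent oracle. The global (R, λ) minimizer wins; a winner on a grid
  edge sets `boundary_flag`.
- L-curve: `ρ_λ = Σᵢ(V_λ(xᵢ)−Vᵢ)²` against `η_λ = |β_λᵀKβ_λ|` in log₁₀
  coordinates (floored at 1e-300). Both are evaluated spectrally on the
  kernel eigendecomposition with round-off eigenvalues clipped at the
  numerical rank — algebraically identical to the β-based definitions but
  keeps the ridge path exactly monotone (ρ non-decreasing, η
  non-increasing) on rank-deficient kernels, where a direct solve injects
  noise-amplified null-space modes into η. Curvature per point is the
  signed area of the triangle joining it with the two curve endpoints
  (clockwise negative); the maximum wins, ties broken toward larger λ.
  When the joint scan is given no λ grid, one common grid is derived from
  the kernel at the median R so the error surface is rectangular.

## Diagnostics

- Error propagation maps are the columns of E; the uncertainty map is
  `diag(E Σ_V Eᵀ)` (scalar shorthand `σ²·diag(EEᵀ)`), validated against
  Monte-Carlo variance of refits under sampled noise.
- Eigensources: `K = UΛUᵀ` (descending, relative cutoff 1e-12); source j
  is the field `K̃u_j` of the unit-norm coefficient vector u_j, reported
  unnormalized in CSD units. Forward-modeling source j gives electrode
  potentials `Ku_j`; re-estimation at λ = 0 returns it exactly, which is
  the recoverability test.
- Point-wise reconstruction error between truth C and estimate Ĉ:
  `err(x) = |Ĉ(x)/‖Ĉ‖ − C(x)/‖C‖| · ‖C‖/max|C|`, with ‖·‖ the Euclidean
  norm over the estimation points (the discrete proxy for the function
  norm). The measure is invariant to positive rescaling of the estimate
  and equals `2|C(x)|/max|C|` for a sign-flipped estimate.
- Reliability maps average this error over seeded test-source families
  pushed through the full pipeline with noise-free potentials; R is
  selected per profile by cross-validation with λ pinned at the bottom of
  its default range (the noise-free convention). Optional symmetrization
  averages each profile's error over the eight mirror images of a square
  grid. The broken-electrode study removes seeded random contact subsets,
  nested across counts within one seed, and reports (broken − intact)
  difference maps computed on the same estimation space with the same
  profiles (profile geometry is pinned to the intact grid so removals do
  not change the source family).

## Synthetic data

Ground truths are Gaussian mixtures. Families are defined relative to the
minimum interelectrode spacing d: "small" sources draw radii uniformly
from [0.1, 0.5]·d, "large" from [1, 2]·d, "dipole" from [0.5, 1.5]·d; each
profile is a ±1 pair with centers uniform in the electrode bounding box,
so every profile is charge balanced. The 1D demonstration profile is a
dipole whose sink is split in two: components (+1, −0.5, −0.5) at
(0.35, 0.60, 0.78)·L with width 0.05·L on a probe of length L — chosen so
a 32-contact probe resolves the split sink. Forward modeling reuses the
basis-module transforms component-wise (closed form in 3D), and uniform
electrode noise defaults to ±5% of the peak potential. All randomness
flows from one seed through `numpy.random.SeedSequence` spawning, so the
profile, noise and contact-removal substreams are independently
reproducible.

What the generator does *not* emulate: temporal structure, correlated or
heteroscedastic electrode noise, electrode position errors, conductivity
inhomogeneity or anisotropy, and sources outside the Gaussian-mixture
family. Passing tests therefore certify the estimator's algebra, its
noise propagation and its behavior on smooth compact sources — not
performance on data violating those assumptions.

## Problem sizes and defaults

Basis placement defaults to a regular grid 4× denser per axis than the
electrode grid over the electrode bounding box (M ≥ N oversampling;
estimates stabilize well before this density). Reliability and
broken-electrode studies default to 20 test profiles; map studies in the
test suite and acceptance script use a 10×10 electrode grid with a 20×20
estimation grid and removal counts (5, 10, 20), sizes at which the full
study completes in about two minutes on one core. The Monte-Carlo check of
the uncertainty map uses 10⁴ noise draws (sampling error ≈ 1.4%,
comfortably inside the 5% comparison tolerance).

## Known limitations

- Reduced-dimensional models inherit the classic 1D/2D CSD assumptions
  (rotational symmetry around the probe; a uniform source layer); h is a
  modeling parameter, not a measured quantity.
- The L-curve corner and CV minimum can sit in a shallow valley where
  (R, λ) trade off; disagreement beyond an order of magnitude usually
  means the landscape is flat, not that either selector failed.
- Broken-electrode reliability differences at 20 test profiles carry
  sampling noise of order 1e-3; single-seed differences between nearby
  removal counts can invert even though the trend over many seeds is
  monotone.
- The MoI ladder assumes the slice is thin relative to its planar extent
  and the recording is far from the slice edge; no FEM fallback is
  provided.
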