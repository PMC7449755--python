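# Methods

## The imaging model

In a scanning micro-endoscope built on a step-index multimode fiber (MMF),
wavefront control forms a focus at the distal plane whose effective
numerical aperture decays from the core center outward. The point spread
function (PSF) therefore depends on the absolute position of the source
point, and image formation is a superposition integral rather than a
convolution:

    I(x, y) = ∬ S(u, v) · P(u, v, x − u, y − v) du dv .

`svmpsf` makes this operator tractable by a modal (eigen-PSF) expansion.
Focal spots are recorded on a calibration grid across the field of view
(FOV), a square patch is cropped around each focus peak, and the patches'
second-moment matrix

    M = (1/J) Σ_j vec(patch_j) vec(patch_j)ᵀ

is eigendecomposed. The eigenvectors, reshaped to patches, form an
orthonormal basis of spatially invariant "eigen-PSFs" p_i ordered by
eigenvalue; the local PSF is

    P(u, v, x, y) = Σ_i a_i(u, v) · p_i(x, y),

with coefficients a_i sampled at the grid points by orthogonal projection
and interpolated bicubically in between. Image formation becomes a sum of
ordinary convolutions, I = Σ_i p_i ∗ (a_i ⊙ S), evaluated with zero-padded
FFTs, and its cost grows linearly with the number of retained modes.

No mean subtraction is applied before the decomposition (M is the second
moment, not the covariance proper). This is deliberate: keeping the mean
makes mode 1 the average PSF and its coefficient map uniform, which is the
natural leading term of the expansion. With mean subtraction mode 1 could
not play that role.

### Patch normalization

Each crop is normalized to **unit L2 norm** ("unit energy") before the
decomposition, and the applied scale is recorded per patch. With an
orthonormal basis and inner-product coefficients this is the unique
normalization for which the mode-1 coefficient is ≈ 1 uniformly across the
FOV (a₁ is then the cosine between the local focus shape and the leading
principal direction). Unit-sum normalization — superficially attractive
because PSFs conserve flux — cannot produce a₁ ≈ 1: for a unit-sum Gaussian
focus of σ ≈ 1.5 px, ⟨patch, p₁⟩ ≤ ‖patch‖₂ ≈ 0.19.

A consequence worth knowing: the reconstructed local kernels carry a
position-dependent flux scale κ(u) = Σ_i a_i(u) · Σ_{x,y} p_i(x, y)
(≈ 5–8 for the default study). Richardson-Lucy deconvolution is invariant
to this scale at its fixed point (the ratio and correction steps cancel
it), but quantitative flux comparisons on the forward model should divide
by κ.

## Deconvolution

The modified Richardson-Lucy iteration evaluates, per iteration k:

    TV_k    = 1 / (1 − λ_TV · div(∇S_k / |∇S_k|))
    I_k     = Σ_i p_i ∗ (a_i ⊙ S_k)
    R_k     = I / I_k
    E_k     = Σ_i p̂_i ∗ (a_i ⊙ R_k)          (p̂ = 180°-rotated kernel)
    S_{k+1} = TV_k ⊙ E_k ⊙ S_k ,  clipped at 0,

so the spatially variant model enters both the blur and the correction.
The multiplicative TV factor is the l1 total-variation regularizer of the
RL-TV scheme (Dey et al.); λ_TV defaults to 0.002 (bead/grid-type data;
0.02 suits noisier biological images). A single Gaussian filter of 2/3 px
is applied after the last iteration to suppress pixelation.

Numerical choices (the continuous equations are silent on all of these):

- **Initialization** S₀ = I, the observed image: nonnegative by
  construction and close to the solution in flux.
- **Ratio floor**: the denominator I_k is floored at 10⁻¹² × max(I_k);
  floor hits are counted in the diagnostics.
- **TV discretization**: forward differences for ∇, backward differences
  (the negative adjoint) for div, |∇S| floored at 10⁻⁸ × max|S|, and the
  final denominator clamped away from zero at 10⁻⁶ with a warning.
- **Correction step**: a_i weights R_k *before* the convolution with the
  flipped kernel, exactly as the update is usually written. This is not
  the exact adjoint of the forward step (that would weight *after* the
  convolution); the exact-adjoint variant is available via
  `DeconvConfig(exact_adjoint=True)` and behaves almost identically on the
  synthetic studies (slightly faster edge convergence).
- **Convolution boundary**: zero-padded linear convolution with the patch
  center as kernel origin; nothing wraps around the frame.
- **Nonnegativity**: the TV factor can overshoot; negative pixels are
  clipped to zero each iteration and counted. Runaway bright pixels
  (the failure mode of under-parameterized models) are detected from the
  intensity record and reported as a warning, never suppressed.

Two structural properties to be aware of. First, the update has no ML-EM
sensitivity normalization (no division by the operator's column sums), so
for sources near the frame border — where zero-padding truncates the blur —
the data-fit residual converges to a small nonzero floor instead of
decreasing monotonically. Second, convergence speed scales with the local
kernel width: after a fixed number of iterations, broad edge foci are
deconvolved less completely than narrow central ones (see "Known
limitations").

## The synthetic study

The generator emulates the NA-0.22, 50-µm-core configuration on which the
modeling analysis is easiest to interpret: 120×120-px frames at
0.435 µm/px, a 13×13 calibration grid (169 foci), and a ground-truth PSF
field that is an anisotropic Gaussian rotated to the local radial
direction with

    σ_radial(r) = σ₀ · (1 + b · r / R_core),   σ_tangential = σ₀ ,

with σ₀ = 1.5 px (≈ the diffraction-limited 1/e² radius 0.61λ/NA at
λ = 488 nm), R_core = 57.5 px (25 µm) and b = 1.1, which makes the
outermost grid foci ≈ 1.9× radially elongated — the qualitative geometry
of an MMF focus grid. `radial_broadening = 0` yields a bit-identical,
isotropic focus everywhere (the shift-invariant control). Noise, when
enabled, is additive zero-mean Gaussian clipped at zero, standing in for
averaged camera frames; the default study is noiseless. Bead phantoms are
non-overlapping anti-aliased disks placed inside both the core disk and
the calibrated (grid-covered) region, with centers returned as ground
truth.

What the generator does *not* emulate: optical wave propagation and mode
structure of real fibers, speckle background, calibration drift, detector
noise statistics, or the NA-0.66 bead-imaging configuration (where the
PSF is narrower than a 1-µm bead). Passing tests on this synthetic study
therefore validate the algorithmic chain — decomposition, interpolation,
forward model, deconvolution, metrics — not any specific fiber's optics.

## Validation metrics

- **1/e² radius**: intensity profile through an object's peak along the
  radial (from the FOV center) or tangential direction, sampled by cubic
  spline at 0.05-px steps; the first crossing of peak/e² is located by
  linear interpolation between samples and the two half-profiles are
  averaged. The peak is located on a 3×3-mean-smoothed image (noise
  robustness) but its *value* is read from the raw image at the sub-pixel
  refined position — normalizing by the smoothed value would bias the
  radius by ~0.2σ for σ ≈ 1 px. Exact on analytic Gaussians to < 0.05 px
  for σ ∈ [1, 5].
- **Edge-to-center ratio**: mean radial 1/e² radius of objects beyond 75%
  of the core radius over that of objects within 25%. Objects outside the
  core disk are excluded — the core is the FOV. The FOV center defaults to
  the object centroid.
- **Normalized RMS error vs. modes**: RMS(measured − reconstructed) /
  RMS(measured) per grid point, averaged in radial bins; nonincreasing in
  the mode count by construction (projection residual).
- **FOV enhancement**: each deconvolved point-response peak-intensity map
  is normalized to its own maximum and azimuthally averaged; the usable
  FOV is the largest centered circle where the profile stays ≥ 0.8, and
  the enhancement is the area ratio (multi-mode over single-mode).

## Known limitations

- At 500 iterations the noiseless study does not fully equalize the point
  response: textbook RL with the *exact* local kernel still leaves a
  σ_r = 2.8 px focus at a 1.63-px radial 1/e² radius versus 1.37 px for
  the central focus (intrinsic ratio ≈ 1.19; the full pipeline measures
  ≈ 1.29 at 500 iterations, decreasing monotonically with further
  iterations). Real recordings reach a noise/regularization resolution
  floor that equalizes both sooner.
- Coefficient maps outside the calibration grid's hull are clamped to the
  nearest in-hull value; the model is an extrapolation there and beads/
  objects outside the calibrated region deconvolve with a biased kernel.
- Sub-pixel-centered point-like objects develop the usual RL spike
  splitting at high iteration counts; localization from the deconvolved
  response is accurate to ~1.5 px worst-case (0.2–0.5 px on average) on
  the default study.
- The pipeline is strictly 2-D; axially extended sources are out of scope.
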