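# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Forward model

The substrate is a homogeneous, isotropic, linear elastic half-space with
Young's modulus E (Pa) and Poisson ratio ν. Only tangential (in-plane)
tractions and in-plane surface displacements are modeled; out-of-plane
components and finite-thickness corrections are out of scope. The surface
response to a tangential point force is the Boussinesq Green's tensor

    G_ij(x) = (1 + ν)/(πE) [ (1 − ν) δ_ij / r + ν x_i x_j / r³ ],  r = |x|.

The traction field is discretized on a regular grid (mesh constant a) and
interpolated with pyramidal shape functions h (bilinear hats of half-width
a). The operator entry for sample i and node j is the convolution
T(x_i − x_j) = ∫ G(x_i − x_j − x′) h(x′) d²x′, which depends only on the
separation.

Numerical choices:

- **Kernel assembly.** G is sampled on a grid oversampled 8× relative to
  the mesh and convolved with the sampled h by FFT. The convolution is an
  exact *linear* convolution (the kernel is sampled over the full range of
  offsets the operator needs), so there is no periodic wrap-around from the
  long-ranged 1/r kernel — zero-padding questions do not arise. Samples
  within one mesh constant of the singularity are replaced by exact cell
  averages of G, computed with a polar edge-fan rule that exploits the fact
  that G(r e) · r depends only on the direction e, making the radial
  integral exact. Agreement with direct quadrature is ≈0.5% in Frobenius
  norm on a 16×16 grid (tested at 1%).
- **Irregular samples.** Rows for off-lattice sample points are obtained by
  multiplying the kernel spectrum by the shift-theorem phase factor
  exp(i k·δ) (with a cosine factor on the Nyquist bins so shifted kernels
  stay exactly real) and reading the shifted lattice off the inverse FFT.
  Samples coincident with nodes reproduce the regular assembly to machine
  precision; half-mesh offsets agree with quadrature to ≈0.1%.
- **Direct quadrature reference.** Tensor Gauss–Legendre per support cell
  for far entries; the polar edge-fan scheme around the sample point for
  entries whose sample lies inside or within half a mesh of the support.
  Deterministic, with self-convergence <0.1% under order doubling; used
  only as the oracle for the fast routes.
- **Self-term.** The displacement at a loaded node always comes from the
  shape-function convolution; G is never evaluated at zero separation.
- **Storage.** Dense float64; the benchmark scale (5000×5000) needs
  ~200 MB.
- **Units.** Containers and operators carry a length-unit tag (μm or pix,
  with an explicit pixel size, default 0.1 μm/pix) and refuse mixed-unit
  algebra. Matrix entries are length/stress and scale with the unit.

## Synthetic benchmark

The generator emulates the standard artificial-data protocol: a
25 μm × 25 μm plane on a 10 kPa, ν = 0.3 substrate with 9 spots of 100 Pa
or 15 spots of 2 μm diameter whose magnitudes are evenly spaced over
[0, 250] Pa and shuffled per seed (so weak spots always exist, including
one at exactly 0 Pa, which the metrics exclude from patch averages). Spot
centers are rejection-sampled with at least one diameter of separation and
a 2-radius margin to the edge; traction directions are uniform random.
Displacements are sampled at uniform random positions (the reference
density, 2500 samples, corresponds to one sample per 0.5 μm on average) and
noise is i.i.d. Gaussian per component, specified either as a percentage of
the maximum displacement magnitude or as an inverse variance β (pix⁻²);
σ = 1/√β.

Disc displacements are computed semi-analytically: in polar coordinates
around the query point, G(r e)·r is independent of r, so the radial
integral over each chord through the disc is exact and only a 256-node
Gauss–Legendre quadrature over the angle remains. This is validated against
the point-force far-field limit (<1% at 10 radii) and, end to end, against
the assembled forward operator applied to the rasterized traction (<2% RMS
on a mesh that resolves the spots; an area-weighted rasterization option
preserves the interpolated field's total force for this purpose).

What the generator does *not* emulate: bead images and tracking errors
(noise is exactly Gaussian and spatially independent, which real PIV/PTV
output is not), displacement gradients within a tracking window, drift, or
spatially correlated noise. Passing benchmarks therefore demonstrate
correctness of the inference machinery under the stated noise model, not
performance on microscope data.

## Penalized solvers

All five solvers minimize ‖Mf − u‖₂² + λ₁‖R₁f‖₁ + λ₂‖R₂f‖₂²:

- **L2 (ridge)**: normal equations, Cholesky; exact and unique.
- **L1 (Lasso)** and **Elastic Net**: coordinate descent
  (scikit-learn backend, penalty weights mapped exactly onto the objective
  above); an independent split-variable bound-constrained solver verifies
  the optima in the tests. Coefficients below 1e-9 of the peak are reported
  as exact zeros. The elastic-net estimate is by default the de-biased
  (1 + λ₂) × naive minimizer — the standard correction the f → f/(1 + λ₂)
  substitution encodes; a flag switches to the naive convention.
- **PGL / PGEN (proximal gradient)**: ISTA with step 1/L (L = largest
  squared singular value, by power iteration), soft-thresholding the
  orthonormal wavelet coefficients of each traction component plane.
  Basis: Daubechies-4, periodized, full decomposition depth — the math
  only requires orthonormality; this choice is fixed for reproducibility.
  The factor 2 in R₁ folds into the threshold level (2λ₁/L); the quadratic
  wavelet penalty of PGEN becomes the shrinkage 1/(1 + 2λ₂/L).
  Approximation (DC) coefficients are thresholded like details by default
  (switchable). Stops when the relative objective change falls below 1e-6
  (the objective is monotone and asserted so) or after 5000 iterations.

## Bayesian regularization (BL2 / ABL2)

A Gaussian traction prior p(f|α) ∝ exp(−α‖f‖²/2) and Gaussian noise
p(u|f, β) ∝ exp(−β‖Mf − u‖²/2) give the posterior maximizer = ridge at
λ = α/β, and an exact Gaussian evidence

    log p(u|α, β) = −αE_f − βE_u − ½ log det A + n log α + m log β
                    − m log 2π,       A = αI + βM̃ᵀM̃,

with n traction nodes and m samples (half-dimensions; the prior and noise
normalizers are (2π/α)ⁿ and (2π/β)ᵐ for the 2n- and 2m-dimensional
vectors). Inference runs on the standardized problem: u is centered, each
column of M is centered and scaled by its sample standard deviation (2m−1
denominator), and the traction is de-standardized as f_j = f̃_j/ω_j. The
hyperprior on (α, β) is uniform, so evidence maximization is the whole
story. Reported λ̂ refers to the standardized problem; the de-standardized
traction is the physical output.

Numerical choices:

- `log_evidence` computes log det A from an explicit Cholesky factor
  (2Σ log L_ii). The optimizers use an algebraically identical fast path:
  one symmetric eigendecomposition of M̃ᵀM̃ makes every (α, β) evaluation
  O(n) (log det A = Σ log(α + βs_i), Tr A⁻¹ = Σ 1/(α + βs_i), exact —
  no stochastic trace estimation). Both routes agree to 1e-9 in tests.
  Eigenvalues at the roundoff floor (below 1e-15 of the largest) are
  treated as exact null space together with their data projections.
- **BL2**: β is measured (e.g. `estimate_beta_background` pools the
  component variance of displacements far from the cell, after mean
  removal). α is scanned on a 200-point log grid (default 1e-6…1e6),
  refined by bounded scalar minimization to 1e-4 relative tolerance. A
  boundary maximum triggers one bound expansion and is flagged.
- **ABL2**: coarse 40×40 log grid over (α, β) — β bounds derived from the
  data variance — then alternating bounded 1-D refinement. Only an
  *interior* local maximum of the grid is accepted: the evidence also rises
  toward the degenerate corner (α → 0, β → ∞) where a full-rank problem
  can interpolate the data, and that corner is a boundary phenomenon, not a
  hyperparameter estimate. If no interior maximum exists after one bound
  expansion, the boundary maximizer is returned with a flag. The implicit
  stationarity equations (2α̂E_f = 2n − α̂TrA⁻¹ etc.) are implemented as a
  fixed-point iteration and agree with the scan optimum within 1% on test
  problems.

Behavior on the benchmark: at the reduced scale used in the test suite
(1 μm mesh, 625 nodes, 800 samples), ABL2 recovers the generating β within
a few percent (median over seeds) and BL2/ABL2 λ̂ agree within 10%. At the
full 0.5 μm / 2500-node / 2500-sample scale the evidence maximum
systematically overestimates β by ~10–15%: the true traction (sharp sparse
spots) is far from a draw of the isotropic Gaussian prior, and at this
conditioning the misspecification inflates the apparent noise precision.
This bias is a property of the model at that problem scale, reproduced —
not hidden — by the acceptance script.

## Parameter selection baselines

- **L-curve**: residual norm vs penalty norm over a log-spaced λ grid
  (≥10 points). The corner is the maximum-curvature point of the smoothed
  log-log curve, with curvature from cubic-spline derivatives (raw finite
  differences are noise-dominated on the flat stretches). If no interior
  curvature maximum exists, or several candidates come within 10% of the
  best, no corner is declared and all candidates are reported — corners do
  not always exist, and pretending otherwise is the failure mode the
  Bayesian route avoids.
- **GCV**: GCV(λ) = 2m‖(I − H)u‖²/tr(I − H)² with H the ridge hat matrix,
  evaluated via SVD; the score is ∞ when tr(I − H) = 0 (square invertible
  M at λ → 0). GCV and the L-curve rarely agree, which the tests assert as
  an inequality.

## Error metrics

DTMA (per-patch mean magnitude error, averaged over patches), DTMB
(background magnitude error normalized by the mean patch magnitude), SNR
(mean patch magnitude over background spread), DMA (per-patch peak error).
Two definitional ambiguities are resolved as defaults and kept switchable:
the SNR denominator is the standard deviation over all background vector
*components* (alternative: over magnitudes), and the DMA normalizer is the
number of patches (same set as DTMA). Patches whose true traction is zero
are excluded with a warning rather than poisoning the averages. Node/patch
assignment is center-in-disc, boundary inclusive.

## Problem sizes

The test suite runs everything at desk scale — 8×8 to 25×25 grids, up to
800 samples — chosen so the full suite finishes in about a minute and a
half while preserving the undersampling ratio and noise calibration of the
benchmark; the acceptance script runs the full 2500-node protocol
(~1 minute per realization). Known limitations beyond those noted above:
no FISTA acceleration for the proximal solvers, no L1-residual
formulations, and no hierarchical (per-node) priors — the global-prior
evidence scheme is the point of the package.
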