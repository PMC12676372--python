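# Methods

## Problem setting

Quantitative MRI estimates physical tissue parameters (here: the
effective transverse relaxation rate R2\*, pool fractions, or a complex
image in reconstruction) by fitting a forward signal model to
multi-dimensional measurements.  The conventional route fits each voxel
independently by nonlinear least squares (NLLS),

    argmin_theta || w (s_meas(phi) - s(phi, theta)) ||_2^2 ,

looped sequentially over the volume.  This package instead poses **one
global objective over all masked voxels**,

    argmin_theta || M W (S_meas(phi) - S(phi, theta)) ||_{L1|L2} + sum_k lambda_k R_k(theta),

so all parameters are updated simultaneously by a first-order optimiser,
and regularisers R_k can couple voxels spatially.  A second solver
samples the per-voxel posterior by MCMC under a Gaussian likelihood,
yielding posterior mean and SD maps.  Both solvers consume the same
forward-model contract: a deterministic map from named, box-bounded
parameter arrays plus acquisition parameters (echo times, b-values) to a
predicted-signal array shaped like the data.

## Automatic differentiation

No autodiff framework is a dependency: `qmrifit.autodiff` is a compact
tape-based reverse-mode engine over numpy arrays covering exactly the
operations the models, losses and regularisers need (elementwise
arithmetic, exp/log/sigmoid, |x| with subgradient 0 at ties, reductions,
slicing/fancy indexing, and unitary FFTs).  Complex arrays follow the
packed-gradient convention (`grad = dL/dx + i dL/dy` for `z = x + iy`),
so the adjoint of a complex-linear operator is its conjugate transpose
and a gradient-descent step on a real loss is well defined.  The engine
is verified against central finite differences for every op family,
including an FFT-based complex pipeline.

## Gradient solver

* **Bounds.** Parameters are optimised in unconstrained space through a
  scaled logit, `theta = lb + (ub - lb) * sigmoid(z)`: differentiable,
  and bounds hold at every iterate.  The reconstruction unknown (a
  complex image, carried as real/imaginary maps) is unbounded and uses
  the identity parametrisation.
* **Loss.** Mean (not sum) of |W r| or (W r)^2 over masked elements, so
  `tol` and regularisation weights are insensitive to mask size.
  Complex residuals use the modulus.  Note the consequence: lambda
  scales with the *square* (L2) or magnitude (L1) of the signal units,
  so unnormalised signals (~10^3) need lambda ~10^3–10^4 for TV terms
  on order-one parameter maps.
* **Optimisers.** Adam (beta1 0.9, beta2 0.999, eps 1e-8), SGD+momentum
  (0.9), RMSProp (decay 0.9) — the standard constants of those methods.
  Execution is full-batch and deterministic; there is no voxel
  subsampling, so repeated runs are bit-identical.
* **Stopping.** Checked each iteration in the order: loss < `tol`; max
  `iteration`; |OLS slope of the last `convergence_window` (default 20)
  losses| < `convergence_value`.  The slope is compared in absolute
  value.
* **Memory path.** Voxels are gathered to a flat list (column-major
  spatial order, fixed and documented) before model evaluation; when a
  spatial regulariser is active the parameters are scattered back to
  volume layout each iteration so TV sees true neighbourhoods.
* **Defaults.** Learn rate 0.001 is conservative; the worked examples
  use 0.01 with 3000–4000 iterations, which drives the noiseless R2*
  demo below 1e-5 relative error.  Recon runs use lr 0.02 and 1200
  iterations.

## Regularisers

* **Volumetric TV** is anisotropic (L1 of axis-wise forward
  differences), normalised as a mean over valid differences; a
  difference is dropped if either endpoint leaves the mask (no
  smoothing across tissue/air boundaries).  The 2D variant differences
  only the first two axes, slice-wise.  Verified against a
  brute-force nested-loop oracle to 1e-12.
* **Graph TV** over a vertex adjacency (e.g. a cortical mesh read from
  a 0-based two-column edge list) is the per-vertex double sum, so each
  undirected edge contributes twice; a triangle with values (0, 1, 2)
  evaluates to 8.
* **Prior penalty**: mean |theta - mu| / sigma against per-voxel prior
  mean/SD maps (e.g. ROI statistics from a high-SNR cohort).
* **Composition**: weighted sums, with custom callables accepted if
  they return a finite scalar; lambda = 0 terms contribute exactly 0.

## MCMC

Gaussian likelihood with a **fixed, user-supplied noise SD** (scalar or
per-voxel map); sigma is not sampled, keeping the likelihood identical
across both algorithms and testable against closed forms.  Bounds act
as a truncated-uniform prior: out-of-bounds proposals are rejected,
preserving proposal symmetry.

* **Metropolis-Hastings**: per voxel, `n_proposals` (default 4)
  independent chains with symmetric normal proposals of per-parameter SD
  `x_step_size`.
* **Ensemble**: Goodman–Weare stretch moves with stretch parameter
  a = `step_size` (default 2); walkers split into two halves updated
  alternately; z drawn with density ∝ 1/sqrt(z) on [1/a, a] via
  z = ((a-1)u + 1)^2 / a; log-acceptance (d-1) log z + delta
  log-likelihood.  Walkers start at the user init plus uniform jitter of
  1% of the bound range, clipped strictly inside bounds.
* **Chain accounting**: per chain, discard the first
  floor(burnin * iteration) states and keep every thinning-th of the
  rest: floor((1-burnin) * iteration / thinning) samples.  With 10%
  burn-in and thinning 100, both 4x25000 (MH) and 50x2000 (ensemble)
  retain exactly 900 samples per voxel.
* **Reproducibility**: one master seed spawns an independent
  `SeedSequence` substream per voxel, each consumed in a fixed block
  order (documented in `qmrifit.mcmc`).  The vectorised lockstep
  implementation is therefore bit-identical to a per-voxel sequential
  loop — asserted in the tests, the package's analogue of identical
  CPU/GPU chains.  Random blocks are pre-generated per voxel; memory is
  ~(voxels x iterations x chains x (params + 1)) doubles, which at the
  desk scales used here stays below ~100 MB.
* **Summaries**: per-voxel sample mean and SD (ddof 1), optional IQR.

## Synthetic data

Generators are pure functions of seed and settings.  Noise is additive
Gaussian on the magnitude signal, matching the samplers' likelihood; a
Rician option exists but is off by default (magnitude data at moderate
SNR is near-Gaussian, and the Gaussian choice keeps the sampler
validation exact).  SNR is defined at the reference measurement:
noise SD = mean first-echo signal inside the mask / SNR.  Phantoms are
piecewise constant (nested boxes), giving TV a truthful target; smooth
variants are available.

The conjugate-Gaussian toy (identity forward model, flat prior in wide
bounds) has the closed-form posterior N(ybar, sigma^2/n) used to
calibrate both samplers: with n = 100 and sigma = 1 the posterior SD is
0.1 exactly.

## Reconstruction

The SENSE/CAIPI encoding operator maps a complex multi-echo image to
multi-coil undersampled k-space: per coil c and echo e,
`k = M_u[e] * FFT(C_c * I_e)` with a **unitary** FFT, so the adjoint is
exactly the masked inverse FFT followed by conjugate-coil summation.
Synthetic coil sensitivities are normalised to sum |C_c|^2 = 1 per
voxel, making fully-sampled reconstruction exactly invertible.  The
CAIPI mask samples kz at stride Rz with a ky-dependent offset
(z-shift per ky row) rotated across echoes (z-TE-shift); the default
phantom uses Rz = 9, z-shift 3, z-TE-shift 2, 6 echoes with
TE1/dTE = 3/5 ms.

Geometry note: the aliasing distance is nz/Rz voxels, so the default
phantom uses nz = 36 (aliases 4 voxels apart, spread further in y by the
CAIPI shift), ny divisible by 3 so the shift pattern tiles, and
localised coil profiles — broad coils cannot disambiguate 9-fold
aliasing at any matrix size.

Two solvers share the operator: a conjugate-gradient normal-equations
baseline (optionally Tikhonov-damped) and the gradient solver minimising
the same objective (mean-normalised, with optional 2D TV on the
real/imaginary parts and a mean-normalised Tikhonov term).  At Rz = 9
the unregularised problem has weakly-encoded directions where
first-order methods converge arbitrarily slowly, so the solver-agreement
check compares the **matched Tikhonov** problems (sum-normalised
lambda 1e-3, converted by the element-count ratio for the
mean-normalised loss); both solvers then agree to ~0.3% NRMSE.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
every property is still sharply testable: 8x8x8 volumes with 12 (R2*) or
24 (two-pool) echoes; 50–100 voxel toys for the samplers with the full
4x25000 and 50x2000 chain settings; a 6x18x36, 12-coil, 6-echo
reconstruction phantom.

## Known limitations

* The synthetic phantoms have no partial-volume ramps, B0/B1 artefacts,
  or spatially correlated noise; passing tests show solver correctness,
  not robustness to those real-data effects.
* Anisotropic TV is not rotation-invariant; the original formulation's
  isotropy, normalisation and boundary rule are design choices here
  (documented above) rather than reproductions.
* The MH stall warning and the ensemble degenerate-geometry warning are
  heuristics; no further convergence diagnostics (R-hat, ESS beyond
  thinning) are provided.
* Likelihood noise SD must be supplied; a residual-based estimate from
  an NLLS pre-fit is a reasonable source but is not automated into the
  samplers.
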