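# Methods

## Problem setting

Sparse-view CT reconstructs a 2-D attenuation map x from line-integral
measurements y = T x taken at few view angles (here 9–120 equidistant views
over [0°, 180°)).  With few views the linear system is severely
underdetermined and filtered back-projection (FBP) produces streak artifacts;
all the iterative methods in this package differ only in the prior they place
on the image.

The package's core method is conditioned generative latent optimization
(cGLO): all K slices of one subject are reconstructed *jointly* by optimizing

    min_{Z, θ}  (1/K) Σ_i ‖ T f_θ(z_i) − y_i ‖²   s.t.  ‖z_i‖₂ = 1,

where f_θ is a shared convolutional generator and z_i a per-slice latent code
on the unit sphere.  The regularization is implicit: the generator's
architecture biases outputs toward natural images, and the shared weights
couple the slices so every view of every slice informs all reconstructions.
The stack is optionally enlarged by inserting artificial sinograms linearly
interpolated between vertically adjacent measured ones (interpolation factor
f; the inserted profiles are dropped from the result).  The decoder may be
GLO-pretrained on full slices — the same objective with T replaced by the
identity — with pretraining latents discarded afterwards.

## Forward operator

Parallel-beam geometry, square images, rotation center at
((side−1)/2, (side−1)/2), detector bins at 1-pixel pitch spanning the image
diagonal: n_bins = ceil(side·√2), which gives 453 bins for 320-pixel slices
and 725 for 512-pixel slices.  Angles are equidistant with the 180° endpoint
excluded; an optional per-slice start-angle offset in [0, 180/N) supports
random-start acquisitions.

The discretization is rotate-and-sum: bilinear sampling of the image on a
detector-aligned grid, summed along the ray at unit steps.  The operator is
materialized once per geometry as a sparse CSR matrix (cached), so

* the adjoint is exactly the transpose (the adjoint test holds to machine
  precision), and
* gradients through the projection are exact — reconstruction loops simply
  backproject the residual.

FBP uses the discrete ramp kernel (value 1/4 at lag 0, −1/(πk)² at odd lags)
applied in the frequency domain after zero-padding rows to the next power of
two ≥ 2·n_bins, optional Hann/Hamming apodization, and the π/n_angles angular
weight.  The ramp filter is the default because the reference pipelines name
FBP without an apodization.

## Generator

A DCGAN-style decoder: a linear block maps the latent vector to a 2×2×C
feature map; each stage doubles the spatial size and halves the channel count
until the output side is reached (a non-power-of-two side is reached by an
exact bilinear resize in the last stage, e.g. 256 → 320 is a ×1.25 upscale);
the final stage produces one channel through a sigmoid so slices live in
[0, 1].  Hidden stages use batch normalization and ReLU; weights are
initialized N(0, 0.02²) from a seeded generator.  The reference configuration
is C = 8192 with latent dimension equal to the slice side (320 or 512).

Upsampling is bilinear-resize + 3×3 convolution by default rather than the
kernel-4 stride-2 transposed convolution (also available as
`upsample_mode="convtranspose"`).  In development the transposed-convolution
generator fitted sinograms well but filled the unmeasured null space with
checkerboard texture (at 9 views: ~16 dB PSNR, SSIM ~0.25 despite a small
data residual); the resize-conv generator reached ~22–23 dB and SSIM ~0.67 on
the same tasks.  Checkerboard artifacts are a known failure mode of strided
transposed convolutions, and here the architecture *is* the prior, so the
smoother parameterization is the default.

Batch normalization is essential in this stack: without it the 5–8-stage
generator failed to move off its initialization under Adam.

## Optimization

Adam (β = 0.9, 0.999) with separate learning-rate groups for latent codes and
weights; codes are re-projected onto the unit sphere after every step.  Batch
sizes grow along a schedule instead of decaying learning rates; the default
schedule starts at 8 and doubles at 25/50/75% of the iteration budget
(schedules are not prescribed by the reference pipeline, so this is a package
default), capped at the (augmented) stack size.  Minibatches are drawn
without replacement from a reshuffled queue, seeded.

Reference learning rates are (1e-3, 1e-3) for pretraining and (1e-2, 1e-4)
for (codes, weights) during reconstruction.  The pretraining rates transfer
to desk scale unchanged.  The reconstruction weight rate does not: it was
chosen for a ~5·10⁸-parameter generator at 320²–512², and at the package's
desk scale (64² slices, C = 128–256, ~2·10⁵ parameters) the data loss is
still falling steeply at any budget that fits on one CPU.  Desk-scale runs
therefore default to lr_weights = 1e-2, chosen by running the budget-doubling
convergence rule (converged when doubling the iteration count improves the
loss by < 1%) on pilot phantom tasks; both rates remain configurable.

Convergence bookkeeping follows the same rule everywhere: `check_convergence`
returns true iff (L_n − L_2n)/L_n < 0.01.

## Baselines

**TV-Reg** solves min_x ‖Tx − y‖² + λ·TV(x) with Chambolle-Pock from a zero
slice, τ = σ = 0.75/‖L‖ with ‖L‖ the power-iteration spectral norm of the
stacked operator (T, ∇) (verified against dense SVD on small instances).
TV is anisotropic by default (the literal L1 norm of the forward-difference
gradient, Neumann boundary); isotropic TV is available.  λ is selected by
maximizing reconstruction PSNR on simulated sinograms of a validation slice
set over a log-spaced grid.  The grid must bracket the maximum for the data
scale at hand; on [0,1]-normalized 64² phantoms the optimum sits near 1e-2,
orders of magnitude above the values tuned for 320²/512² CT slices (those
reference values ship in `REFERENCE_LAMBDAS` for documentation).

**DIP** reparameterizes a single slice through a U-Net with a fixed seeded
noise input: stage 1 fits the network output to the FBP image (5000
iterations at reference scale), stage 2 minimizes the sinogram residual plus
α·TV (10⁴ iterations at reference scale).  The U-Net (scales, base channels,
LeakyReLU, batch norm, bilinear upsampling, skip concatenations, sigmoid
output) is a package design choice — the reference defers to prior work and
prints no topology.  Desk-scale defaults are 3 scales × 16 channels and
400 + 800 iterations so a slice reconstructs in roughly a minute on one CPU.

## Poisson degradation and PNLL reconstruction

Measurement simulation deliberately breaks the inverse crime: the slice is
bilinearly upsampled (reference: 320 → 1000 pixels, factor 3.125) and
projected with the *same* detector (bin count and 1-original-pixel pitch), so
the data come from a finer discretization than the reconstruction projector.
Line integrals are rescaled to original-pixel units (divide by the upsampling
ratio), multiplied by an attenuation scale, and counts are drawn as
y_δ ~ Poisson(N₀·e^(−y)) with N₀ = 10⁵ by default.

The attenuation scale maps [0,1] slice values to physical attenuation; by
default it is chosen per stack so the largest line integral is ≈ 5
(transmission e⁻⁵ ≈ 0.7%), keeping counts informative at N₀ = 10⁵.  The
reference pipeline does not state its slice units, so this is a package
convention, configurable through `NoiseModel`.

Reconstruction from counts replaces the squared residual by the Poisson
negative log-likelihood, PNLL(ŷ, y_δ) = ŷ − y_δ·log ŷ + C(y_δ) with
ŷ = N₀·exp(−scale·T f_θ(Z)) and C the Stirling approximation of log(y_δ!)
(0 at y_δ = 0); the noisy counts are used as-is, with no log transformation.
The loss is averaged over bins, matching the L2 pipeline's convention, and
its gradient with respect to the line integrals is scale·(y_δ − ŷ)/m.

## Synthetic phantoms

`generate_phantom_stack` emulates one subject's slice stack: a fixed soft
body ellipse plus n_ellipses random ellipses whose centers, axes, rotation
and intensity follow a Gaussian random walk along z smoothed by a moving
average of width `smoothness` (the correlation length in slices), clipped to
[0, 1].  This reproduces the one property the interpolation augmentation
relies on — sinograms of adjacent slices interpolate to a good approximation
of the intermediate slice's sinogram — and is seeded and fully deterministic.

What it does *not* emulate matters for interpreting results: real CT slices
carry soft-tissue texture and acquisition noise, while these phantoms are
piecewise-constant.  Piecewise-constant images are exactly total variation's
favored class, so on this generator a PSNR-tuned TV-Reg is close to an oracle
prior and outperforms every learned/implicit prior (TV ≈ 28 dB at 9 views
versus ≈ 23 dB for both DIP and cGLO at 64²).  On real CT the reference
results show the opposite ordering with a thin margin (+0.26 dB for cGLO over
TV-Reg at 9 views).  Passing or failing a TV comparison on these phantoms
therefore says little about real data; the cross-method tests in this package
treat FBP and DIP orderings as the transferable signal.

## Metrics

PSNR = 10·log₁₀(range²/MSE), capped at 100 dB for exact matches, with
data_range fixed at 1.0 for normalized slices (the convention shifts absolute
dB, so it is stated rather than inferred).  SSIM uses a Gaussian window
(σ = 1.5, width 11) and constants (0.01·range)², (0.03·range)².  Stacks are
summarized as median ± half the interquartile range with linear-interpolation
quantiles.

## Numerical choices and problem sizes

* All neural-network computation is float32 (parameters, activations,
  gradients); the forward operator and Chambolle-Pock run in float64.
  Gradient correctness is verified in float64 against central differences.
* Every stochastic component (weight init, latent init, batch shuffling,
  Poisson draws, random offsets) draws from an explicit numpy Generator seed;
  identical seeds give bit-identical runs.
* Desk-scale study sizes used throughout the tests and the acceptance script:
  64×64 slices, stacks of 8, C = 128, latent dimension 64, interpolation
  factor 2, 2000 reconstruction iterations (the point where reconstruction
  quality saturates on pilot runs; the loss-based doubling rule favors longer
  runs but buys < 0.5 dB), 50 GLO-pretraining epochs on 64 slices.  These sizes
  reconstruct a stack in a few minutes on one CPU core.
* Divergence (non-finite loss or iterate) raises a dedicated error carrying
  the iteration index; degenerate inputs (zero latent rows, empty grids,
  mismatched shapes) raise ValueError before any computation.

## Known limitations

* 2-D parallel beam only; no fan/cone beam, no 3-D coupling between slices
  beyond the shared decoder and sinogram interpolation.
* The desk-scale generator is ~3 orders of magnitude smaller than the
  reference configuration; absolute dB values are not comparable to
  full-scale results, only orderings and trends within the package.
* TV-Reg comparisons on piecewise-constant phantoms favor TV structurally
  (see above).
* The Poisson pipeline assumes ideal counting statistics: no beam hardening,
  scatter, or detector cross-talk.
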