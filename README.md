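# cglo — conditioned generative latent optimization for sparse-view CT

`cglo` reconstructs stacks of CT slices from sparse-view sinograms (few
projection angles, e.g. 9–50 views over 180°), a severely ill-posed inverse
problem where filtered back-projection produces heavy streak artifacts.  It
is aimed at researchers studying learned and implicit image priors for
tomography who want a small, fully seeded, CPU-friendly testbed.

## Method

All K slices of one subject are reconstructed jointly by optimizing a shared
convolutional generator f_θ and one unit-norm latent code per slice:

    X̂ = f_θ*(Z*),   (Z*, θ*) = argmin_{Z,θ} (1/K) Σᵢ ‖T f_θ(zᵢ) − yᵢ‖₂²
                                s.t. ‖zᵢ‖₂ = 1,

where T is the discrete parallel-beam Radon transform and yᵢ the measured
sinogram of slice i.  No adversary and no pretraining are required — the
generator architecture itself is the prior, and the shared weights couple all
slices into one objective.  Three optional ingredients strengthen it:

* **profile interpolation** — artificial sinograms linearly interpolated
  between vertically adjacent slices enlarge the joint objective (and are
  discarded from the result);
* **GLO pretraining** — the decoder can first memorize a corpus of full
  slices (same objective with T = identity), giving a warm start θ₀;
* **Poisson likelihood** — for photon-count data y_δ ~ Poisson(N₀e^{−y}) the
  L2 residual is replaced by the Poisson negative log-likelihood of
  N₀·exp(−T f_θ(Z)), with no log-preprocessing of the counts.

Training-free baselines ship alongside: FBP (ramp filter), TV-regularized
least squares ‖Tx−y‖² + λ·TV(x) solved by Chambolle-Pock
(τ = σ = 0.75/‖(T, ∇)‖), and a U-Net deep image prior initialized on the FBP
image.  The forward operator is materialized as a sparse matrix, so its
adjoint is exact and gradients propagate exactly; everything is seeded and
reproducible bit-for-bit.  See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

```python
import numpy as np
from cglo import (PhantomSpec, generate_phantom_stack, make_parallel_geometry,
                  simulate_sinogram_stack, CGLOReconstructor,
                  FBPReconstructor, psnr)

stack = generate_phantom_stack(PhantomSpec(side=64, n_slices=8, seed=1))
geom = make_parallel_geometry(64, 9)          # 9 views, 91 detector bins
sinos = simulate_sinogram_stack(stack, geom)

fbp = FBPReconstructor().transform(sinos)
cglo = CGLOReconstructor(latent_dim=64, first_channels=128,
                         interpolation_factor=2, lr_latent=1e-2,
                         lr_weights=1e-2, n_iterations=2000,
                         seed=0).transform(sinos)

for name, rec in [("FBP", fbp), ("cGLO", cglo)]:
    print(name, round(float(np.mean([psnr(r, t) for r, t in
                                     zip(rec, stack.slices)])), 2), "dB")
```

Output (a few minutes on one CPU core):

```
FBP 19.62 dB
cGLO 22.39 dB
```

At 9 views FBP is streak-limited (~19.6 dB on this phantom family) while the
joint generator prior removes most null-space artifacts (~22.4 dB, SSIM 0.67
vs 0.40).  `CGLOReconstructor.fit(slices)` pretrains the decoder first;
`cglo.reconstruct_cglo_poisson` handles photon-count data.

A command-line interface mirrors the library
(`cglo phantom | simulate | pretrain | reconstruct | baseline | evaluate |
experiment`); `cglo experiment --config cfg.yaml` runs a full seeded
phantom-to-report comparison and writes a JSON manifest sufficient to
reproduce it.

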