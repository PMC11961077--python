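"""Joint latent/decoder optimization: GLO pretraining and cGLO reconstruction.

Two closely related optimizations share the machinery here:

* **Pretraining** — given full slices, jointly fit decoder weights theta and
  one unit-norm latent code per slice by minimizing the mean squared
  image-domain error.  The trained weights theta_0 are kept; the latent codes
  are discarded.

* **Reconstruction** — given per-slice sinograms of one subject (optionally
  augmented with linearly interpolated artificial profiles along z), jointly
  optimize fresh latent codes and the decoder weights so that projections of
  the decoded slices match the measurements (mean squared sinogram-domain
  residual by default; a Poisson likelihood variant lives in
  :mod:`cglo.degradation`).  Slices decoded from artificial profiles are
  discarded from the result.

Both loops use Adam with separate learning rates for codes and weights,
re-project every updated code onto the unit sphere, and grow the minibatch
size along a schedule instead of decaying learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .decoder import Decoder
from .geometry import ProjectionGeometry, Sinogram, projector_matrix
from .latent import LatentCodes, init_latent_codes, project_to_sphere

__all__ = [
    "TrainConfig", "SliceStack", "SinogramStack", "ReconstructionTask",
    "ReconstructionResult", "DivergedOptimizationError", "pretrain_glo",
    "augment_profiles", "reconstruct_cglo", "check_convergence",
    "simulate_sinogram_stack",
]


class DivergedOptimizationError(RuntimeError):
    """Raised when an iterate or loss becomes non-finite."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class TrainConfig:
    """Optimization hyper-parameters.

    Reference values: learning rates (1e-3, 1e-3) for pretraining and
    (1e-2, 1e-4) for (latents, weights) during reconstruction; 1000
    reconstruction iterations; batch size 8 doubling at 25/50/75% of the run.
    ``n_iterations`` counts optimizer steps during reconstruction and epochs
    during pretraining.
    """

    lr_latent: float = 1e-2
    lr_weights: float = 1e-4
    n_iterations: int = 1000
    batch_schedule: list[tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self):
        # lr_latent 0 freezes the codes (DIP-style single-image fits);
        # frozen weights would make the optimization vacuous
        if self.lr_latent < 0 or self.lr_weights <= 0:
            raise ValueError("learning rates must be positive"
                             " (lr_latent may be 0)")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be nonnegative")
        if self.batch_schedule is not None:
            starts = [s for s, _ in self.batch_schedule]
            sizes = [b for _, b in self.batch_schedule]
            if starts != sorted(starts) or sizes != sorted(sizes):
                raise ValueError("batch_schedule must be nondecreasing")

    def resolved_schedule(self) -> list[tuple[int, int]]:
        if self.batch_schedule is not None:
            return list(self.batch_schedule)
        n = self.n_iterations
        return [(0, 8), (n // 4, 16), (n // 2, 32), (3 * n // 4, 64)]


def _batch_size_at(schedule: list[tuple[int, int]], it: int) -> int:
    size = schedule[0][1]
    for start, b in schedule:
        if it >= start:
            size = b
    return size


@dataclass
class SliceStack:
    """Ordered slices of one subject; index 0 is the bottom of the stack."""

    slices: np.ndarray  # (K, side, side), values in [0, 1]

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[1] != self.slices.shape[2]:
            raise ValueError("slices must be a (K, side, side) array")

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def side(self) -> int:
        return self.slices.shape[1]


class SinogramStack:
    """Ordered per-slice measurements.  All entries share the bin count,
    angle count and image side; the angle offset may vary per slice (random
    start-angle acquisitions)."""

    def __init__(self, sinograms: list[Sinogram]):
        if not sinograms:
            raise ValueError("empty sinogram stack")
        g0 = sinograms[0].geometry
        for s in sinograms:
            g = s.geometry
            if (g.side, g.n_angles, g.n_bins) != (g0.side, g0.n_angles, g0.n_bins):
                raise ValueError("all sinograms must share side/angles/bins")
        self.sinograms = list(sinograms)

    def __len__(self) -> int:
        return len(self.sinograms)

    def __getitem__(self, i: int) -> Sinogram:
        return self.sinograms[i]

    @property
    def geometry(self) -> ProjectionGeometry:
        return self.sinograms[0].geometry

    @property
    def values(self) -> np.ndarray:
        return np.stack([s.values for s in self.sinograms])

    @property
    def is_interpolated(self) -> np.ndarray:
        return np.array([s.is_interpolated for s in self.sinograms])

    def shares_geometry(self) -> bool:
        g0 = self.geometry
        return all(s.geometry.angle_offset == g0.angle_offset
                   for s in self.sinograms)


def simulate_sinogram_stack(stack: SliceStack,
                            geometry: ProjectionGeometry,
                            angle_offsets: np.ndarray | None = None
                            ) -> SinogramStack:
    """Project every slice; optional per-slice start angles."""
    from .geometry import radon_forward, with_offset

    sinos = []
    for i, img in enumerate(stack.slices):
        g = geometry if angle_offsets is None \
            else with_offset(geometry, float(angle_offsets[i]))
        sinos.append(radon_forward(img, g))
    return SinogramStack(sinos)


def augment_profiles(stack: SinogramStack, factor: int) -> SinogramStack:
    """Insert ``factor - 1`` linearly interpolated artificial profiles between
    each vertically adjacent pair, multiplying the profile count by roughly
    ``factor``.  Interpolated entries are flagged so reconstruction can
    discard them."""
    if factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    if factor == 1:
        return stack
    if len(stack) < 2:
        raise ValueError("need at least two profiles to interpolate between")
    out: list[Sinogram] = []
    for i in range(len(stack) - 1):
        a, b = stack[i], stack[i + 1]
        out.append(a)
        for j in range(1, factor):
            t = j / factor
            vals = (1 - t) * a.values + t * b.values
            off = (1 - t) * a.geometry.angle_offset + t * b.geometry.angle_offset
            geom = replace(a.geometry, angle_offset=off)
            out.append(Sinogram(values=vals, geometry=geom, is_interpolated=True))
    out.append(stack[len(stack) - 1])
    return SinogramStack(out)


@dataclass
class ReconstructionTask:
    sinograms: SinogramStack
    decoder_init: Decoder
    interpolation_factor: int = 1
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def geometry(self) -> ProjectionGeometry:
        return self.sinograms.geometry


@dataclass
class ReconstructionResult:
    slices: SliceStack          # artificial entries already discarded
    final_loss: float           # full-stack data-fidelity loss after training
    initial_loss: float         # same quantity before the first update
    loss_history: np.ndarray    # per-iteration minibatch losses
    latents: LatentCodes        # codes of the retained slices


def check_convergence(loss_at_n: float, loss_at_2n: float) -> bool:
    """Budget-doubling convergence rule: converged when doubling the number of
    iterations reduces the loss by less than 1%."""
    if loss_at_n <= 0 or loss_at_2n <= 0 or not np.isfinite(loss_at_n) \
            or not np.isfinite(loss_at_2n):
        raise ValueError("losses must be positive and finite")
    return (loss_at_n - loss_at_2n) / loss_at_n < 0.01


def pretrain_glo(decoder: Decoder, slices: SliceStack,
                 config: TrainConfig | None = None) -> Decoder:
    """Unsupervised GLO pretraining: memorize the slice set through the
    decoder.  Returns the decoder with trained weights theta_0; the per-slice
    latent codes are discarded.  The epoch-mean loss curve is stored on the
    decoder as ``pretrain_history_``."""
    if config is None:
        config = TrainConfig(lr_latent=1e-3, lr_weights=1e-3, n_iterations=50)
    side = decoder.config.out_side
    x = slices.slices
    if x.shape[1] != side:
        raise ValueError(f"slice side {x.shape[1]} != decoder out_side {side}")
    n = len(slices)
    d = decoder.config.latent_dim

    codes = init_latent_codes(n, d, config.seed)
    z = codes.vectors
    opt_w = nn.Adam([(decoder.params(), config.lr_weights)])
    opt_z = nn.AdamRows(z, config.lr_latent)
    rng = np.random.default_rng(config.seed + 1)
    schedule = config.batch_schedule or [(0, 8)]

    history = []
    for epoch in range(config.n_iterations):
        perm = rng.permutation(n)
        b = min(_batch_size_at(schedule, epoch), n)
        epoch_losses = []
        for start in range(0, n, b):
            idx = perm[start:start + b]
            out = decoder.forward(z[idx], train=True)
            diff = out - x[idx]
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise DivergedOptimizationError(
                    f"non-finite pretraining loss at epoch {epoch}", epoch)
            opt_w.zero_grad()
            gz = decoder.backward(2.0 * diff / diff.size)
            opt_w.step()
            opt_z.step_rows(idx, gz)
            z[idx] = project_to_sphere(z[idx])
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    decoder.pretrain_history_ = np.asarray(history)
    return decoder


def _project_batch(images: np.ndarray, geoms: list[ProjectionGeometry]
                   ) -> np.ndarray:
    """Forward-project a batch where each image may carry its own geometry."""
    out = np.empty((images.shape[0],) + geoms[0].shape)
    for i, (img, g) in enumerate(zip(images, geoms)):
        out[i] = (projector_matrix(g) @ img.ravel()).reshape(g.shape)
    return out


def _backproject_batch(grads: np.ndarray, geoms: list[ProjectionGeometry]
                       ) -> np.ndarray:
    side = geoms[0].side
    out = np.empty((grads.shape[0], side, side))
    for i, (g_s, g) in enumerate(zip(grads, geoms)):
        out[i] = (projector_matrix(g).T @ g_s.ravel()).reshape(side, side)
    return out


def _l2_loss_grad(pred: np.ndarray, target: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def _optimize_conditioned(decoder: Decoder, stack: SinogramStack,
                          config: TrainConfig, loss_grad_fn,
                          measured=None) -> tuple[np.ndarray, dict]:
    """Shared minibatch loop for conditioned reconstruction.

    ``loss_grad_fn(pred_line_integrals, targets) -> (loss, d loss / d pred)``;
    ``measured`` overrides the per-slice optimization targets (used by the
    Poisson variant, whose targets are photon counts, not line integrals).
    """
    geoms = [s.geometry for s in stack.sinograms]
    targets = stack.values if measured is None else measured
    k = len(stack)
    d = decoder.config.latent_dim

    codes = init_latent_codes(k, d, config.seed)
    z = codes.vectors
    opt_w = nn.Adam([(decoder.params(), config.lr_weights)])
    opt_z = nn.AdamRows(z, config.lr_latent)
    rng = np.random.default_rng(config.seed + 1)
    schedule = config.resolved_schedule()

    def full_loss() -> float:
        imgs = decoder.forward(z, train=True)
        pred = _project_batch(imgs, geoms)
        return loss_grad_fn(pred, targets)[0]

    initial_loss = full_loss()
    history = []
    queue: list[int] = []
    for it in range(config.n_iterations):
        b = min(_batch_size_at(schedule, it), k)
        if len(queue) < b:
            queue = list(rng.permutation(k))
        idx = np.array([queue.pop() for _ in range(b)])
        imgs = decoder.forward(z[idx], train=True)
        pred = _project_batch(imgs, [geoms[i] for i in idx])
        loss, g_pred = loss_grad_fn(pred, targets[idx])
        if not np.isfinite(loss):
            raise DivergedOptimizationError(
                f"non-finite reconstruction loss at iteration {it}", it)
        g_imgs = _backproject_batch(g_pred, [geoms[i] for i in idx])
        opt_w.zero_grad()
        gz = decoder.backward(g_imgs)
        opt_w.step()
        opt_z.step_rows(idx, gz)
        z[idx] = project_to_sphere(z[idx])
        history.append(loss)

    final_loss = full_loss()
    info = {
        "initial_loss": initial_loss,
        "final_loss": final_loss,
        "loss_history": np.asarray(history),
    }
    return z, info


def reconstruct_cglo(task: ReconstructionTask) -> ReconstructionResult:
    """Conditioned GLO reconstruction of one slice stack from its sinograms."""
    decoder = task.decoder_init
    if decoder.config.out_side != task.geometry.side:
        raise ValueError(
            f"decoder out_side {decoder.config.out_side} != geometry side "
            f"{task.geometry.side}")
    stack = augment_profiles(task.sinograms, task.interpolation_factor)
    z, info = _optimize_conditioned(decoder, stack, task.config, _l2_loss_grad)
    imgs = decoder.forward(z, train=False)
    keep = ~stack.is_interpolated
    return ReconstructionResult(
        slices=SliceStack(imgs[keep]),
        final_loss=info["final_loss"],
        initial_loss=info["initial_loss"],
        loss_history=info["loss_history"],
        latents=LatentCodes(project_to_sphere(z[keep])),
    )
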