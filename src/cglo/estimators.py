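"""Scikit-learn-style reconstruction estimators.

Each reconstructor is a ``BaseEstimator`` whose ``transform`` maps a stack of
sinograms — a ``(K, n_angles, n_bins)`` array or a :class:`~cglo.core.SinogramStack`
— to a ``(K, side, side)`` stack of reconstructed slices.  ``CGLOReconstructor``
additionally supports ``fit(X)`` with a ``(N, side, side)`` stack of training
slices, which runs unsupervised GLO pretraining of the decoder; the other
methods are training-free and ``fit`` is a no-op.  Fitted state lives in
trailing-underscore attributes, so the estimators compose with sklearn
pipelines and ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .baselines import (DIPConfig, TVRegConfig, dip_reconstruct,
                        estimate_operator_norm, tv_reg_reconstruct)
from .core import (ReconstructionTask, SinogramStack, SliceStack, TrainConfig,
                   pretrain_glo, reconstruct_cglo)
from .decoder import Decoder, DecoderConfig
from .geometry import ProjectionGeometry, Sinogram, fbp_reconstruct

__all__ = ["FBPReconstructor", "TVRegReconstructor", "DIPReconstructor",
           "CGLOReconstructor", "as_sinogram_stack"]


def as_sinogram_stack(X, geometry: ProjectionGeometry) -> SinogramStack:
    """Accept a SinogramStack, a list of Sinograms, or a raw (K, A, B) array."""
    if isinstance(X, SinogramStack):
        return X
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], Sinogram):
        return SinogramStack(list(X))
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return SinogramStack([Sinogram(values=v, geometry=geometry) for v in arr])


class _ReconstructorBase(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        return self

    def _stack(self, X) -> SinogramStack:
        if self.geometry is None and not isinstance(X, SinogramStack) \
                and not (isinstance(X, (list, tuple)) and X
                         and isinstance(X[0], Sinogram)):
            raise ValueError("geometry must be set to transform raw arrays")
        return as_sinogram_stack(X, self.geometry)


class FBPReconstructor(_ReconstructorBase):
    """Filtered back-projection, slice by slice."""

    def __init__(self, geometry: ProjectionGeometry | None = None,
                 filter_name: str = "ramp"):
        self.geometry = geometry
        self.filter_name = filter_name

    def transform(self, X) -> np.ndarray:
        stack = self._stack(X)
        return np.stack([fbp_reconstruct(s, self.filter_name)
                         for s in stack.sinograms])


class TVRegReconstructor(_ReconstructorBase):
    """TV-regularized least squares via Chambolle-Pock, slice by slice."""

    def __init__(self, geometry: ProjectionGeometry | None = None,
                 lam: float = 1e-5, n_iterations: int = 600,
                 step_scale: float = 0.75, tv_flavor: str = "anisotropic"):
        self.geometry = geometry
        self.lam = lam
        self.n_iterations = n_iterations
        self.step_scale = step_scale
        self.tv_flavor = tv_flavor

    def transform(self, X) -> np.ndarray:
        stack = self._stack(X)
        cfg = TVRegConfig(lam=self.lam, n_iterations=self.n_iterations,
                          step_scale=self.step_scale, tv_flavor=self.tv_flavor)
        self.op_norm_ = estimate_operator_norm(stack.geometry)
        return np.stack([
            tv_reg_reconstruct(s, cfg, op_norm=self.op_norm_)
            for s in stack.sinograms])


class DIPReconstructor(_ReconstructorBase):
    """Deep image prior, one U-Net optimization per slice."""

    def __init__(self, geometry: ProjectionGeometry | None = None,
                 alpha: float = 1e-6, n_init_iterations: int = 400,
                 n_recon_iterations: int = 800, lr: float = 1e-3,
                 scales: int = 3, base_channels: int = 16, seed: int = 0):
        self.geometry = geometry
        self.alpha = alpha
        self.n_init_iterations = n_init_iterations
        self.n_recon_iterations = n_recon_iterations
        self.lr = lr
        self.scales = scales
        self.base_channels = base_channels
        self.seed = seed

    def transform(self, X) -> np.ndarray:
        stack = self._stack(X)
        out = []
        for i, s in enumerate(stack.sinograms):
            cfg = DIPConfig(
                alpha=self.alpha, n_init_iterations=self.n_init_iterations,
                n_recon_iterations=self.n_recon_iterations, lr=self.lr,
                scales=self.scales, base_channels=self.base_channels,
                seed=self.seed + i)
            out.append(dip_reconstruct(s, cfg))
        return np.stack(out)


class CGLOReconstructor(_ReconstructorBase):
    """Conditioned generative latent optimization.

    ``fit(X)`` pretrains the decoder on full slices (optional);
    ``transform(Y)`` jointly reconstructs a stack of sinograms.  Fitted
    attributes: ``decoder_`` (pretrained or randomly initialized weights),
    ``latents_``, ``loss_history_``, ``result_``.
    """

    def __init__(self, geometry: ProjectionGeometry | None = None,
                 latent_dim: int = 64, first_channels: int = 128,
                 interpolation_factor: int = 2,
                 lr_latent: float = 1e-2, lr_weights: float = 1e-4,
                 n_iterations: int = 1000,
                 pretrain_lr: float = 1e-3, pretrain_epochs: int = 50,
                 batch_schedule: list | None = None, seed: int = 0):
        self.geometry = geometry
        self.latent_dim = latent_dim
        self.first_channels = first_channels
        self.interpolation_factor = interpolation_factor
        self.lr_latent = lr_latent
        self.lr_weights = lr_weights
        self.n_iterations = n_iterations
        self.pretrain_lr = pretrain_lr
        self.pretrain_epochs = pretrain_epochs
        self.batch_schedule = batch_schedule
        self.seed = seed

    def _build_decoder(self, side: int) -> Decoder:
        return Decoder(DecoderConfig(
            latent_dim=self.latent_dim, first_channels=self.first_channels,
            out_side=side, seed=self.seed))

    def fit(self, X, y=None):
        """GLO-pretrain the decoder on a (N, side, side) stack of slices.
        ``fit(None)`` skips pretraining (training-free reconstruction)."""
        if X is None:
            return self
        slices = X if isinstance(X, SliceStack) \
            else SliceStack(np.asarray(X, dtype=np.float64))
        decoder = self._build_decoder(slices.side)
        cfg = TrainConfig(lr_latent=self.pretrain_lr,
                          lr_weights=self.pretrain_lr,
                          n_iterations=self.pretrain_epochs,
                          seed=self.seed)
        self.decoder_ = pretrain_glo(decoder, slices, cfg)
        self.pretrain_history_ = self.decoder_.pretrain_history_
        return self

    def transform(self, X) -> np.ndarray:
        import copy

        stack = self._stack(X)
        decoder = getattr(self, "decoder_", None)
        if decoder is None:
            decoder = self._build_decoder(stack.geometry.side)
        else:
            # reconstruction updates weights in place; keep the fitted
            # (pretrained) decoder intact for later transforms
            decoder = copy.deepcopy(decoder)
        cfg = TrainConfig(lr_latent=self.lr_latent,
                          lr_weights=self.lr_weights,
                          n_iterations=self.n_iterations,
                          batch_schedule=self.batch_schedule, seed=self.seed)
        task = ReconstructionTask(
            sinograms=stack, decoder_init=decoder,
            interpolation_factor=self.interpolation_factor, config=cfg)
        result = reconstruct_cglo(task)
        self.result_ = result
        self.latents_ = result.latents
        self.loss_history_ = result.loss_history
        return result.slices.slices
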