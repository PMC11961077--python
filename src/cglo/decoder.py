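"""DCGAN-style convolutional generator mapping unit latent vectors to slices.

The latent code passes through a linear block onto a 2x2xC feature map; each
upsampling stage doubles the spatial size and halves the channel count
(transposed convolution, kernel 4, stride 2, padding 1, batch norm, ReLU).
The final stage produces one channel through a sigmoid so outputs live in
[0, 1], matching slices normalized as attenuation maps.  When the target side
is not a power of two the last stage uses an exact bilinear resize followed by
a 3x3 convolution (e.g. 256 -> 320 is an upscale factor of 1.25).

The image side, the latent dimension and C (first-stage channels) fully
determine the architecture; the reference configuration uses C = 8192 with
latent dimension 320 (320x320 slices) or 512 (512x512 slices).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .latent import _NORM_TOL

__all__ = ["DecoderConfig", "Decoder", "build_decoder", "decode",
           "save_decoder", "load_decoder"]


@dataclass(frozen=True)
class DecoderConfig:
    latent_dim: int
    first_channels: int  # C: channels of the 2x2 feature map
    out_side: int
    seed: int = 0
    batchnorm: bool = True  # batch norm in hidden stages (DCGAN recipe)
    # "resize-conv" (bilinear x2 + 3x3 conv, avoids checkerboard artifacts)
    # or "convtranspose" (kernel-4 stride-2 transposed convolution)
    upsample_mode: str = "resize-conv"

    @property
    def n_stages(self) -> int:
        """Number of upsampling stages from the 2x2 map to the output side."""
        return max(1, math.ceil(math.log2(self.out_side / 2)))

    def channel_sequence(self) -> list[int]:
        """Feature channels entering each stage, halving per stage."""
        return [self.first_channels // (2 ** i) for i in range(self.n_stages)]

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.out_side < 4:
            raise ValueError("out_side must be >= 4")
        n_halvings = self.n_stages - 1
        if self.first_channels < 2 or self.first_channels % (2 ** n_halvings):
            raise ValueError(
                f"first_channels={self.first_channels} must be divisible by "
                f"2^{n_halvings} for {self.n_stages} stages"
            )


class Decoder:
    """Generator f_theta; holds the layer graph and exposes decode/backward."""

    def __init__(self, config: DecoderConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.first_channels
        side = config.out_side
        chans = config.channel_sequence()

        def maybe_bn(ch):
            return [nn.BatchNorm2d(ch)] if config.batchnorm else []

        layers: list[nn.Layer] = [
            nn.Linear(config.latent_dim, 2 * 2 * c, rng),
            nn.Reshape((c, 2, 2)),
            *maybe_bn(c),
            nn.ReLU(),
        ]
        if config.upsample_mode not in ("resize-conv", "convtranspose"):
            raise ValueError(f"unknown upsample_mode {config.upsample_mode!r}")
        resize_conv = config.upsample_mode == "resize-conv"

        def up_block(c_in, c_out, out_size):
            if resize_conv:
                return [nn.BilinearResize(out_size, out_size),
                        nn.Conv2d(c_in, c_out, 3, rng)]
            return [nn.ConvTranspose2d(c_in, c_out, rng)]

        size = 2
        for i in range(config.n_stages - 1):
            size *= 2
            layers += [
                *up_block(chans[i], chans[i + 1], size),
                *maybe_bn(chans[i + 1]),
                nn.ReLU(),
            ]
        # final stage to one channel; a fractional upscale (e.g. x1.25 for
        # 256 -> 320) always goes through the resize + 3x3 conv path
        if side == 2 * size and not resize_conv:
            layers.append(nn.ConvTranspose2d(chans[-1], 1, rng))
        else:
            layers += [
                nn.BilinearResize(side, side),
                nn.Conv2d(chans[-1], 1, 3, rng),
            ]
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, latents: np.ndarray, train: bool = True) -> np.ndarray:
        """(K, latent_dim) unit vectors -> (K, out_side, out_side) images."""
        out = self.net.forward(np.asarray(latents, dtype=nn.DTYPE), train)
        return out[:, 0]

    def backward(self, grad_images: np.ndarray) -> np.ndarray:
        """Backpropagate (K, side, side) output sensitivities; accumulates
        weight gradients and returns the latent gradient (K, latent_dim)."""
        return self.net.backward(np.asarray(grad_images, dtype=nn.DTYPE)[:, None])


def build_decoder(config: DecoderConfig) -> Decoder:
    return Decoder(config)


def decode(decoder: Decoder, latents: np.ndarray, train: bool = False) -> np.ndarray:
    """Decode a batch of unit latent vectors into [0, 1] slices."""
    latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    if latents.shape[1] != decoder.config.latent_dim:
        raise ValueError(
            f"latent length {latents.shape[1]} != latent_dim "
            f"{decoder.config.latent_dim}"
        )
    norms = np.linalg.norm(latents, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-5):
        raise ValueError("latents must be unit vectors; project to the sphere first")
    return decoder.forward(latents, train=train)


def save_decoder(decoder: Decoder, path: str) -> None:
    """Checkpoint: an .npz of all weight arrays plus a JSON config sidecar.
    Round trips are bit exact."""
    arrays = {f"p{i}": p.value for i, p in enumerate(decoder.params())}
    bn_i = 0
    for layer in decoder.net.layers:
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"bn{bn_i}_mean"] = layer.running_mean
            arrays[f"bn{bn_i}_var"] = layer.running_var
            bn_i += 1
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(asdict(decoder.config), fh, indent=2)


def load_decoder(path: str) -> Decoder:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        config = DecoderConfig(**json.load(fh))
    decoder = Decoder(config)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    if not os.path.exists(npz_path):
        raise FileNotFoundError(npz_path)
    with np.load(npz_path) as data:
        for i, p in enumerate(decoder.params()):
            p.value[...] = data[f"p{i}"]
        bn_i = 0
        for layer in decoder.net.layers:
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = data[f"bn{bn_i}_mean"]
                layer.running_var[...] = data[f"bn{bn_i}_var"]
                bn_i += 1
    return decoder
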