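"""Seeded synthetic slice stacks: Shepp-Logan and vertically coherent
random-ellipse volumes.

The random-ellipse generator emulates the property of real CT stacks that the
interpolation augmentation relies on: anatomy varies smoothly from slice to
slice, so linearly interpolating two adjacent sinograms approximates the
sinogram of the slice in between.  Ellipse centers, axes, rotations and
intensities follow a smoothed Gaussian random walk along z with a controllable
correlation length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .core import SliceStack

__all__ = ["PhantomSpec", "shepp_logan", "generate_phantom_stack"]


def shepp_logan(side: int) -> np.ndarray:
    """The standard 10-ellipse Shepp-Logan phantom, resampled to ``side`` and
    scaled to [0, 1]."""
    if side < 16:
        raise ValueError("side must be >= 16")
    img = shepp_logan_phantom()  # 400x400, values in [0, 1]
    if side != img.shape[0]:
        img = resize(img, (side, side), anti_aliasing=True)
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    side: int = 64
    n_slices: int = 8
    n_ellipses: int = 6
    smoothness: float = 4.0  # correlation length along z, in slices
    seed: int = 0

    def validate(self) -> None:
        if min(self.side, self.n_slices, self.n_ellipses) < 1:
            raise ValueError("side, n_slices and n_ellipses must be >= 1")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def _smooth_walk(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Gaussian random walk smoothed by a moving average of the given width."""
    steps = rng.standard_normal(n + width)
    walk = np.cumsum(steps)
    kernel = np.ones(width) / width
    sm = np.convolve(walk, kernel, mode="valid")[:n]
    return sm - sm.mean()


def generate_phantom_stack(spec: PhantomSpec) -> SliceStack:
    """Sum of random ellipses per slice, parameters drifting smoothly along z;
    values clipped to [0, 1]."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    side, nz = spec.side, spec.n_slices
    width = max(1, int(round(spec.smoothness)))
    yy, xx = np.mgrid[0:side, 0:side]
    yy = (yy - (side - 1) / 2) / (side / 2)
    xx = (xx - (side - 1) / 2) / (side / 2)

    stack = np.zeros((nz, side, side))
    # body outline: a large soft ellipse shared by all slices of the subject
    body = ((xx / 0.9) ** 2 + (yy / 0.92) ** 2) <= 1.0
    stack += 0.2 * body

    for _ in range(spec.n_ellipses):
        cx0, cy0 = rng.uniform(-0.5, 0.5, size=2)
        a0 = rng.uniform(0.08, 0.35)
        b0 = rng.uniform(0.08, 0.35)
        th0 = rng.uniform(0, np.pi)
        v0 = rng.uniform(0.15, 0.6)
        cx = cx0 + 0.08 * _smooth_walk(rng, nz, width)
        cy = cy0 + 0.08 * _smooth_walk(rng, nz, width)
        aa = np.clip(a0 * (1 + 0.15 * _smooth_walk(rng, nz, width)), 0.03, 0.6)
        bb = np.clip(b0 * (1 + 0.15 * _smooth_walk(rng, nz, width)), 0.03, 0.6)
        th = th0 + 0.1 * _smooth_walk(rng, nz, width)
        vv = v0 * (1 + 0.1 * _smooth_walk(rng, nz, width))
        for k in range(nz):
            ct, st = np.cos(th[k]), np.sin(th[k])
            u = (xx - cx[k]) * ct + (yy - cy[k]) * st
            w = -(xx - cx[k]) * st + (yy - cy[k]) * ct
            mask = (u / aa[k]) ** 2 + (w / bb[k]) ** 2 <= 1.0
            stack[k] += vv[k] * mask
    return SliceStack(np.clip(stack, 0.0, 1.0))
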