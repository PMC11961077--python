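"""Unit-sphere latent codes.

The generator's inputs are constrained to the unit n-sphere: codes are drawn
from a standard normal and normalized, and re-normalized (projected back onto
the sphere) after every gradient update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatentCodes", "init_latent_codes", "project_to_sphere"]

_NORM_TOL = 1e-6


@dataclass
class LatentCodes:
    """K unit-norm latent vectors, one per slice."""

    vectors: np.ndarray  # (K, latent_dim)
    seed: int | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=_NORM_TOL):
            raise ValueError("latent codes must have unit L2 norm")

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.vectors.shape[1]


def project_to_sphere(vectors: np.ndarray) -> np.ndarray:
    """Normalize each row to unit L2 norm.  Idempotent; zero rows are rejected."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
        squeeze = True
    else:
        squeeze = False
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("cannot project a zero vector onto the unit sphere")
    out = vectors / norms
    return out[0] if squeeze else out


def init_latent_codes(k: int, latent_dim: int, seed: int) -> LatentCodes:
    """Draw K codes from N(0, I) and project them onto the unit sphere."""
    if k < 1 or latent_dim < 1:
        raise ValueError("K and latent_dim must be positive")
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((k, latent_dim))
    return LatentCodes(vectors=project_to_sphere(vecs), seed=seed)
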