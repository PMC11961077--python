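"""Discrete parallel-beam projection geometry, Radon transform, adjoint and FBP.

Conventions
-----------
Images are square ``side x side`` arrays indexed ``[row, col]`` with the rotation
center at pixel ``((side - 1) / 2, (side - 1) / 2)``.  A view at angle ``phi``
(degrees) integrates along rays perpendicular to the detector; detector bins sit
at 1-pixel pitch, centered on the image center, and there are
``ceil(side * sqrt(2))`` of them so the detector spans the image diagonal.
Angles are equidistant on ``[0, 180)`` degrees: ``angle_offset + k * 180 / n_angles``.

The discretization is rotate-and-sum: the image is resampled with bilinear
interpolation onto a grid aligned with the detector (one axis along the detector,
one along the ray) and summed along the ray axis at unit step.  Because every
output entry is a fixed linear combination of input pixels, the whole operator is
materialized once per geometry as a sparse matrix; the adjoint is its transpose
and gradients propagate exactly through both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "make_parallel_geometry",
    "radon_forward",
    "radon_adjoint",
    "fbp_reconstruct",
    "projector_matrix",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam acquisition geometry for square slices.

    Attributes
    ----------
    side : int
        Pixels per image edge.
    n_angles : int
        Number of views, equidistant on [0, 180) degrees.
    n_bins : int
        Detector bins, ``ceil(side * sqrt(2))`` at 1-pixel pitch.
    angle_offset : float
        Degrees added to every angle, in ``[0, 180 / n_angles)``.
    bin_spacing : float
        Detector pitch in pixel units (1 for standard geometries).
    """

    side: int
    n_angles: int
    angle_offset: float = 0.0
    n_bins: int = field(default=0)
    bin_spacing: float = 1.0

    @property
    def angles(self) -> np.ndarray:
        """View angles in degrees, endpoint 180 excluded."""
        return self.angle_offset + np.arange(self.n_angles) * (180.0 / self.n_angles)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_bins)


@dataclass
class Sinogram:
    """Line-integral measurements of one slice: ``n_angles x n_bins``."""

    values: np.ndarray
    geometry: ProjectionGeometry
    is_interpolated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


def make_parallel_geometry(
    side: int, n_angles: int, angle_offset: float = 0.0
) -> ProjectionGeometry:
    """Build the standard geometry: equidistant angles, diagonal-spanning detector.

    ``n_bins = ceil(side * sqrt(2))`` reproduces 453 bins for 320-pixel slices and
    725 bins for 512-pixel slices.
    """
    if side < 1 or n_angles < 1:
        raise ValueError("side and n_angles must be positive")
    max_offset = 180.0 / n_angles
    if not 0.0 <= angle_offset < max_offset:
        raise ValueError(
            f"angle_offset must lie in [0, {max_offset}) degrees, got {angle_offset}"
        )
    n_bins = math.ceil(side * math.sqrt(2.0))
    return ProjectionGeometry(
        side=side, n_angles=n_angles, angle_offset=float(angle_offset), n_bins=n_bins
    )


# One sparse matrix per geometry; keyed by the geometry's value fields.
_PROJECTOR_CACHE: dict[tuple, sp.csr_matrix] = {}


def _build_projector(geom: ProjectionGeometry, step: float) -> sp.csr_matrix:
    """Materialize the forward operator as a CSR matrix of shape
    ``(n_angles * n_bins, side * side)``.

    For each view the image is sampled with bilinear interpolation at points
    ``center + s * (cos a, sin a) + t * (-sin a, cos a)`` for detector offsets
    ``s`` (bin positions) and ray parameters ``t`` (unit steps spanning the
    diagonal), and summed over ``t``.
    """
    side, n_bins = geom.side, geom.n_bins
    center = (side - 1) / 2.0
    offsets = (np.arange(n_bins) - (n_bins - 1) / 2.0) * geom.bin_spacing
    n_steps = int(math.ceil(n_bins * geom.bin_spacing / step))
    ts = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step

    rows_all, cols_all, vals_all = [], [], []
    for k, ang in enumerate(np.deg2rad(geom.angles)):
        ca, sa = math.cos(ang), math.sin(ang)
        # sample coordinates, x = column axis, y = row axis
        xs = center + offsets[:, None] * ca - ts[None, :] * sa
        ys = center + offsets[:, None] * sa + ts[None, :] * ca
        x0 = np.floor(xs).astype(np.int64)
        y0 = np.floor(ys).astype(np.int64)
        fx = xs - x0
        fy = ys - y0
        row_idx = (k * n_bins + np.arange(n_bins))[:, None]
        for dy, dx, w in (
            (0, 0, (1 - fx) * (1 - fy)),
            (0, 1, fx * (1 - fy)),
            (1, 0, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            xi = x0 + dx
            yi = y0 + dy
            ok = (xi >= 0) & (xi < side) & (yi >= 0) & (yi < side) & (w > 0)
            rows_all.append(np.broadcast_to(row_idx, xs.shape)[ok])
            cols_all.append((yi * side + xi)[ok])
            vals_all.append((w * step)[ok])

    mat = sp.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(geom.n_angles * n_bins, side * side),
    )
    return mat.tocsr()


def projector_matrix(geom: ProjectionGeometry, step: float = 1.0) -> sp.csr_matrix:
    """Sparse matrix of the forward operator (cached per geometry)."""
    key = (geom.side, geom.n_angles, geom.n_bins, geom.angle_offset,
           geom.bin_spacing, step)
    mat = _PROJECTOR_CACHE.get(key)
    if mat is None:
        mat = _build_projector(geom, step)
        _PROJECTOR_CACHE[key] = mat
    return mat


def radon_forward(image: np.ndarray, geom: ProjectionGeometry) -> Sinogram:
    """Project a slice to its sinogram of line integrals.

    Linear in the input; the exact adjoint is :func:`radon_adjoint`, so callers
    implementing gradient descent through the projection can use
    ``grad_image = radon_adjoint(grad_sinogram)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (geom.side, geom.side):
        raise ValueError(
            f"image shape {image.shape} does not match geometry side {geom.side}"
        )
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    mat = projector_matrix(geom)
    vals = (mat @ image.ravel()).reshape(geom.shape)
    return Sinogram(values=vals, geometry=geom)


def radon_forward_many(images: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """Vectorized projection of a ``(K, side, side)`` batch; returns raw values."""
    images = np.asarray(images, dtype=np.float64)
    k = images.shape[0]
    mat = projector_matrix(geom)
    flat = images.reshape(k, -1).T
    return (mat @ flat).T.reshape(k, *geom.shape)


def radon_adjoint(sinogram: Sinogram | np.ndarray,
                  geom: ProjectionGeometry | None = None) -> np.ndarray:
    """Adjoint (unfiltered backprojection): ``<T x, y> = <x, T^T y>`` exactly."""
    if isinstance(sinogram, Sinogram):
        values, geom = sinogram.values, sinogram.geometry
    else:
        if geom is None:
            raise ValueError("geometry required when passing a raw array")
        values = np.asarray(sinogram, dtype=np.float64)
    if values.shape != geom.shape:
        raise ValueError(
            f"sinogram shape {values.shape} does not match geometry {geom.shape}"
        )
    mat = projector_matrix(geom)
    return (mat.T @ values.ravel()).reshape(geom.side, geom.side)


def radon_adjoint_many(values: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """Vectorized adjoint of a ``(K, n_angles, n_bins)`` batch."""
    values = np.asarray(values, dtype=np.float64)
    k = values.shape[0]
    mat = projector_matrix(geom)
    flat = values.reshape(k, -1).T
    return (mat.T @ flat).T.reshape(k, geom.side, geom.side)


_FILTERS = ("ramp", "hann", "hamming")


def _ramp_filter(n: int, filter_name: str) -> np.ndarray:
    """Frequency response of the discrete ramp filter (Ram-Lak), optionally
    apodized.  Built from the space-domain kernel so the DC term is handled
    correctly on finite, zero-padded signals."""
    # space-domain ramp kernel h[k]: 1/4 at k=0, -1/(pi k)^2 for odd k, 0 even
    ks = np.concatenate([np.arange(n // 2 + 1), np.arange(-(n // 2) + 1, 0)])
    h = np.zeros(n)
    h[0] = 0.25
    odd = ks % 2 == 1
    h[odd] = -1.0 / (np.pi * ks[odd]) ** 2
    resp = 2.0 * np.real(np.fft.fft(h))
    if filter_name == "ramp":
        return resp
    freqs = np.fft.fftfreq(n)
    if filter_name == "hann":
        return resp * (0.5 + 0.5 * np.cos(2 * np.pi * freqs))
    if filter_name == "hamming":
        return resp * (0.54 + 0.46 * np.cos(2 * np.pi * freqs))
    raise ValueError(f"unknown filter {filter_name!r}; supported: {_FILTERS}")


def fbp_reconstruct(sinogram: Sinogram | np.ndarray,
                    filter_name: str = "ramp",
                    geom: ProjectionGeometry | None = None) -> np.ndarray:
    """Filtered back-projection: ramp-filter each view, backproject, scale.

    Rows are zero-padded to the next power of two (at least twice the bin count)
    before frequency-domain filtering.  Linear in the sinogram.
    """
    if isinstance(sinogram, Sinogram):
        values, geom = sinogram.values, sinogram.geometry
    else:
        if geom is None:
            raise ValueError("geometry required when passing a raw array")
        values = np.asarray(sinogram, dtype=np.float64)
    if filter_name not in _FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; supported: {_FILTERS}")
    if values.shape != geom.shape:
        raise ValueError("sinogram shape does not match geometry")

    n_bins = geom.n_bins
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n_bins))))
    resp = _ramp_filter(n_pad, filter_name)
    padded = np.zeros((geom.n_angles, n_pad))
    padded[:, :n_bins] = values
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * resp, axis=1))
    filtered = filtered[:, :n_bins]
    # pi / n_angles approximates the angular integral over [0, pi)
    back = radon_adjoint(filtered, geom)
    return back * (np.pi / (2.0 * geom.n_angles))


def with_offset(geom: ProjectionGeometry, angle_offset: float) -> ProjectionGeometry:
    """Same geometry with a different start angle (Appendix-style random starts)."""
    max_offset = 180.0 / geom.n_angles
    if not 0.0 <= angle_offset < max_offset:
        raise ValueError(f"angle_offset must lie in [0, {max_offset})")
    return replace(geom, angle_offset=float(angle_offset))
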