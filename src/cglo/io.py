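"""Serialization: dense arrays with JSON geometry sidecars, PNG export."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .geometry import ProjectionGeometry, Sinogram

__all__ = ["save_slices", "load_slices", "save_sinograms", "load_sinograms",
           "save_png"]


def save_slices(directory: str | Path, slices: np.ndarray) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(np.asarray(slices)):
        np.save(directory / f"slice_{i:04d}.npy", img)


def load_slices(directory: str | Path) -> np.ndarray:
    files = sorted(Path(directory).glob("slice_*.npy"))
    if not files:
        raise FileNotFoundError(f"no slice_*.npy files in {directory}")
    return np.stack([np.load(f) for f in files])


def _geometry_to_dict(geom: ProjectionGeometry) -> dict:
    return asdict(geom)


def save_sinograms(directory: str | Path, sinograms: list[Sinogram]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(sinograms):
        np.save(directory / f"sino_{i:04d}.npy", s.values)
        meta = {"geometry": _geometry_to_dict(s.geometry),
                "is_interpolated": bool(s.is_interpolated)}
        (directory / f"sino_{i:04d}.json").write_text(json.dumps(meta))


def load_sinograms(directory: str | Path) -> list[Sinogram]:
    files = sorted(Path(directory).glob("sino_*.npy"))
    if not files:
        raise FileNotFoundError(f"no sino_*.npy files in {directory}")
    out = []
    for f in files:
        meta = json.loads(f.with_suffix(".json").read_text())
        geom = ProjectionGeometry(**meta["geometry"])
        out.append(Sinogram(values=np.load(f), geometry=geom,
                            is_interpolated=meta["is_interpolated"]))
    return out


def save_png(path: str | Path, image: np.ndarray) -> None:
    """8-bit grayscale export for visual inspection."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 255).astype(np.uint8))
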