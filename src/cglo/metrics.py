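"""PSNR / SSIM evaluation and median +/- half-IQR aggregation.

``data_range`` defaults to 1.0 everywhere because slices are normalized
attenuation maps in [0, 1]; absolute dB values shift with this convention, so
it is fixed and documented rather than inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim", "aggregate", "MetricReport", "evaluate_stack"]

PSNR_CAP_DB = 100.0


def psnr(x: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 100 dB for identical images."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range ** 2 / mse))


def ssim(x: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity with a Gaussian window (sigma 1.5, width 11)
    and constants C1 = (0.01 L)^2, C2 = (0.03 L)^2."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    if min(x.shape) < 11:
        raise ValueError("image smaller than the 11-pixel SSIM window")
    return float(structural_similarity(
        x, ref, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False))


def aggregate(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Median and half the interquartile range, linear-interpolation quantiles."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float((q3 - q1) / 2.0)


@dataclass
class MetricReport:
    per_slice_psnr: list[float]
    per_slice_ssim: list[float]
    median_psnr: float
    half_iqr_psnr: float
    median_ssim: float
    half_iqr_ssim: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_stack(recon: np.ndarray, truth: np.ndarray,
                   data_range: float = 1.0) -> MetricReport:
    """Per-slice PSNR/SSIM of a (K, side, side) reconstruction and their
    median +/- half-IQR summary."""
    recon = np.asarray(recon)
    truth = np.asarray(truth)
    if recon.shape != truth.shape:
        raise ValueError("reconstruction and truth shapes differ")
    ps = [psnr(r, t) for r, t in zip(recon, truth)]
    ss = [ssim(r, t) for r, t in zip(recon, truth)]
    mp, hp = aggregate(ps)
    ms, hs = aggregate(ss)
    return MetricReport(ps, ss, mp, hp, ms, hs)
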