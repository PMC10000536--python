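"""Segmentation quality metrics: MSE, PSNR, SSIM, Dice, rerun statistics."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["mse", "psnr", "ssim", "mask_ssim", "dice", "rerun_stats", "MetricsReport"]

PEAK = 255.0


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared intensity difference between two same-shape images."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio ``10 log10(255^2 / MSE)`` in dB.

    Identical images return ``inf``.
    """
    e = mse(a, b)
    if e == 0:
        return float("inf")
    return float(10.0 * np.log10(PEAK**2 / e))


def ssim(a, b, win_size: int = 11) -> float:
    """Mean structural similarity with the canonical parameterization.

    11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, dynamic range 255.
    """
    a, b = _pair(a, b)
    if min(a.shape) < win_size:
        raise ValueError(
            f"image min dimension {min(a.shape)} is smaller than the {win_size}-pixel "
            "window; pass a smaller odd win_size"
        )
    return float(
        structural_similarity(
            a,
            b,
            win_size=win_size,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=PEAK,
        )
    )


def mask_ssim(a, b, win_size: int = 11) -> float:
    """SSIM between two binary masks scaled to {0, 255}."""
    a, b = _pair(a, b)
    return ssim(a * PEAK, b * PEAK, win_size=win_size)


def dice(a, b) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)``; two empty masks give 1."""
    a, b = _pair(a, b)
    a = a > 0
    b = b > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def rerun_stats(fitness_list) -> tuple[float, float, float]:
    """(best, mean, population std) of a list of per-rerun best fitnesses."""
    f = np.asarray(fitness_list, dtype=float)
    if f.size == 0:
        raise ValueError("fitness list must be non-empty")
    return float(f.max()), float(f.mean()), float(f.std(ddof=0))


class MetricsReport(dict):
    """Plain dict of metric name -> value with a stable key order."""

    @classmethod
    def compare(cls, reference, test, ground_truth_mask=None, test_mask=None) -> "MetricsReport":
        rep = cls()
        rep["mse"] = mse(reference, test)
        rep["psnr"] = psnr(reference, test)
        rep["ssim"] = ssim(reference, test)
        if ground_truth_mask is not None and test_mask is not None:
            rep["dice"] = dice(ground_truth_mask, test_mask)
            rep["mask_ssim"] = mask_ssim(ground_truth_mask, test_mask)
        return rep
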