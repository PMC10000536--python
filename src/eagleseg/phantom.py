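"""Synthetic test images ("phantoms") and histogram landscapes.

The phantom emulates the qualitative structure of a contrast-enhanced
T1 brain slice as seen by a histogram method: a dark surround, concentric
mid-gray tissue bands, and one bright compact blob (the "tumor") plus a few
bright specks and additive Gaussian intensity noise.  It makes every stage
of the pipeline testable against a known ground-truth mask without any
external data.  It does not model MRI physics (bias fields, partial
volume, anatomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histogram import N_LEVELS

__all__ = ["PhantomSpec", "make_phantom", "make_mixture_histogram"]


@dataclass
class PhantomSpec:
    """Geometry and noise of a synthetic multi-class image.

    ``class_means`` are the strictly increasing gray levels of the classes;
    the background is laid out as concentric rings at the first ``c - 1``
    means (dark outermost) and the tumor disk is painted at the brightest
    mean.  ``noise_sigma`` is the additive Gaussian intensity noise in gray
    levels (default 8, a moderately noisy acquisition); ``speck_count``
    bright 2-px specks act as clutter the post-processing must remove.
    """

    size: tuple[int, int] = (256, 256)
    class_means: tuple[int, ...] = (20, 90, 160, 230)
    tumor_center: tuple[int, int] | None = None  # default: (5H/8, 3W/8)
    tumor_radius: int | None = None  # default: ~min(H,W)/6
    speck_count: int = 5
    speck_radius: int = 2
    noise_sigma: float = 8.0
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        h, w = self.size
        if h < 16 or w < 16:
            raise ValueError("phantom must be at least 16x16")
        means = np.asarray(self.class_means)
        if means.size < 2 or np.any(np.diff(means) <= 0):
            raise ValueError("class_means must be strictly increasing with >= 2 entries")
        if means.min() < 0 or means.max() > 255:
            raise ValueError("class_means must lie in [0, 255]")
        if self.tumor_center is None:
            self.tumor_center = (5 * h // 8, 3 * w // 8)
        if self.tumor_radius is None:
            self.tumor_radius = max(4, min(h, w) // 6)
        cy, cx = self.tumor_center
        r = self.tumor_radius
        if r < 1:
            raise ValueError("tumor_radius must be >= 1")
        if not (r <= cy < h - r and r <= cx < w - r):
            raise ValueError("tumor disk must lie fully inside the image")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.speck_count < 0 or self.speck_radius < 1:
            raise ValueError("invalid speck parameters")
        return self


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_phantom(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom image and its ground-truth tumor mask.

    Returns ``(image, gt)``: a uint8 image and a uint8 {0, 1} mask of the
    tumor disk.  Same spec (incl. seed) -> bit-identical output.
    """
    spec = (spec or PhantomSpec()).validate()
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    means = list(spec.class_means)
    n_bands = len(means) - 1

    # concentric tissue bands: dark outermost ring at means[0], brightening inward
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    rmax = float(rad.max())
    band = np.minimum((n_bands * (1.0 - rad / (rmax + 1e-9))).astype(int), n_bands - 1)
    image = np.asarray(means)[band].astype(float)

    gt = _disk_mask((h, w), spec.tumor_center, spec.tumor_radius)
    image[gt] = means[-1]

    # bright clutter specks, kept clear of the tumor
    placed = 0
    guard = 0
    while placed < spec.speck_count and guard < 1000:
        guard += 1
        y = int(rng.integers(spec.speck_radius, h - spec.speck_radius))
        x = int(rng.integers(spec.speck_radius, w - spec.speck_radius))
        d = np.hypot(y - spec.tumor_center[0], x - spec.tumor_center[1])
        if d < spec.tumor_radius + 6 * spec.speck_radius:
            continue
        image[_disk_mask((h, w), (y, x), spec.speck_radius)] = means[-1]
        placed += 1

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    return image, gt.astype(np.uint8)


def make_mixture_histogram(weights, means, sigmas, bins: int = N_LEVELS) -> np.ndarray:
    """Discretized Gaussian-mixture histogram over the gray axis.

    ``weights`` must be non-negative and sum to 1; a component with sigma 0
    becomes a point mass at its rounded mean.  The result is renormalized
    over ``bins`` levels and sums to 1.
    """
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(means, dtype=float)
    sg = np.asarray(sigmas, dtype=float)
    if not (w.shape == mu.shape == sg.shape) or w.ndim != 1 or w.size == 0:
        raise ValueError("weights, means and sigmas must be equal-length 1-D sequences")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    if np.any(sg < 0):
        raise ValueError("sigmas must be >= 0")
    levels = np.arange(bins, dtype=float)
    p = np.zeros(bins)
    for wi, mi, si in zip(w, mu, sg):
        if si == 0:
            p[int(np.clip(np.floor(mi + 0.5), 0, bins - 1))] += wi
        else:
            comp = np.exp(-0.5 * ((levels - mi) / si) ** 2)
            p += wi * comp / comp.sum()
    return p / p.sum()
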