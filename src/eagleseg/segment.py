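"""From thresholds to images: quantized "threshold image" and binary mask.

A threshold set assigns each pixel a class index (a threshold belongs to
the class below it).  ``quantize`` replaces each pixel by its class
representative; ``binarize`` marks a chosen subset of classes (by default
the brightest) as foreground.
"""

from __future__ import annotations

import numpy as np

from .histogram import _as_image, _as_thresholds, _interval_bounds, N_LEVELS

__all__ = ["class_indices", "quantize", "binarize"]


def class_indices(image, thresholds) -> np.ndarray:
    """Class index of every pixel under the lower-inclusive convention.

    A pixel with value v falls in class ``searchsorted(t, v, 'left')``:
    class 0 is ``[0..t_1]``, duplicated thresholds skip their empty class.
    """
    arr = _as_image(image)
    t = _as_thresholds(thresholds)
    return np.searchsorted(t, arr, side="left")


def _representatives(image: np.ndarray, t: np.ndarray, mode: str) -> np.ndarray:
    counts = np.bincount(image.ravel(), minlength=N_LEVELS).astype(float)
    levels = np.arange(N_LEVELS, dtype=float)
    reps = np.empty(t.size + 1, dtype=np.int64)
    for i, (lo, hi) in enumerate(_interval_bounds(t)):
        if mode == "class_floor":
            reps[i] = min(lo, N_LEVELS - 1)
            continue
        mass = counts[lo : hi + 1].sum() if lo <= hi else 0.0
        if mass > 0:
            mean = (counts[lo : hi + 1] * levels[lo : hi + 1]).sum() / mass
        else:
            mean = (lo + hi) / 2.0  # empty or zero-mass class: interval midpoint
        reps[i] = int(np.floor(mean + 0.5))
    return np.clip(reps, 0, N_LEVELS - 1)


def quantize(image, thresholds, mode: str = "class_mean") -> np.ndarray:
    """Replace each pixel by its class representative gray level.

    ``class_mean`` uses the rounded intensity-weighted mean of the class's
    own histogram mass (the minimum-MSE per-class constant); ``class_floor``
    uses the lowest level of the class interval.
    """
    if mode not in ("class_mean", "class_floor"):
        raise ValueError(f"unknown quantization mode {mode!r}")
    arr = _as_image(image)
    t = _as_thresholds(thresholds)
    reps = _representatives(arr, t, mode)
    return reps[class_indices(arr, t)].astype(np.uint8)


def binarize(image, thresholds, foreground=None) -> np.ndarray:
    """Binary mask of the pixels whose class index is in ``foreground``.

    ``foreground`` is a set of class indices in ``0..k``; the default is the
    single highest-intensity class ``{k}``.  Returns a uint8 array of {0, 1}.
    """
    arr = _as_image(image)
    t = _as_thresholds(thresholds)
    k = t.size
    if foreground is None:
        foreground = {k}
    fg = sorted(int(c) for c in np.atleast_1d(list(foreground)).ravel())
    if not fg:
        raise ValueError("foreground class set must be non-empty")
    if fg[0] < 0 or fg[-1] > k:
        raise ValueError(f"foreground class indices must lie in [0, {k}]")
    cls = class_indices(arr, t)
    return np.isin(cls, fg).astype(np.uint8)
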