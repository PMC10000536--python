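"""Gray-level histograms, class partitions and the Kapur entropy objective.

Multilevel thresholding places ``k`` integer cut points ``t_1 <= ... <= t_k``
on the 8-bit gray axis, splitting ``[0, 255]`` into ``k + 1`` classes.
Kapur's criterion scores a threshold set by the sum of Shannon entropies of
the class-normalized histogram segments,

    F(t) = sum_i H_i,    H_i = -sum_{j in class i} (p_j / A_i) ln(p_j / A_i),

where ``p_j`` is the probability of gray level ``j`` and ``A_i`` the total
probability mass of class ``i``.  The best threshold set maximizes ``F``.

Conventions (fixed here so printed optima containing duplicates and endpoint
values are representable): a threshold belongs to the class *below* it, i.e.
class 0 is ``[0 .. t_1]``, class i is ``[t_i + 1 .. t_{i+1}]`` and class k is
``[t_k + 1 .. 255]``; duplicated thresholds produce empty classes, which
contribute zero entropy; ``0 * ln 0 := 0``; natural logarithm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

N_LEVELS = 256

__all__ = [
    "N_LEVELS",
    "ClassPartition",
    "compute_histogram",
    "partition_classes",
    "kapur_fitness",
    "exhaustive_optimum",
    "KapurObjective",
]


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("image intensities must be integers in [0, 255]")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return arr.astype(np.int64, copy=False)


def _as_histogram(hist) -> np.ndarray:
    p = np.asarray(hist, dtype=float)
    if p.shape != (N_LEVELS,):
        raise ValueError(f"histogram must have exactly {N_LEVELS} bins, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("histogram probabilities must be non-negative")
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"histogram must sum to 1, sums to {total!r}")
    return p


def _as_thresholds(thresholds, k: int | None = None) -> np.ndarray:
    t = np.asarray(thresholds)
    if t.ndim != 1:
        raise ValueError("thresholds must be a flat sequence")
    if t.size and not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValueError("thresholds must be integers")
    t = t.astype(np.int64, copy=False) if t.size else t.astype(np.int64)
    if t.size:
        if t.min() < 0 or t.max() > 255:
            raise ValueError("thresholds must lie in [0, 255]")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be sorted non-decreasing")
    if k is not None and t.size != k:
        raise ValueError(f"expected {k} thresholds, got {t.size}")
    return t


def compute_histogram(image) -> np.ndarray:
    """Normalized 256-bin gray-level histogram of an 8-bit image.

    Returns an array ``p`` with ``p[j]`` the fraction of pixels equal to
    gray level ``j``; always 256 bins regardless of the observed range.
    """
    arr = _as_image(image)
    counts = np.bincount(arr.ravel(), minlength=N_LEVELS)
    return counts / arr.size


@dataclass(frozen=True)
class ClassPartition:
    """Gray-level intervals and probability masses induced by a threshold set.

    ``intervals[i] = (lo, hi)`` is inclusive; an empty class has ``lo > hi``
    and mass 0.  The intervals tile ``[0, 255]``.
    """

    intervals: tuple[tuple[int, int], ...]
    masses: tuple[float, ...]


def _interval_bounds(t: np.ndarray) -> list[tuple[int, int]]:
    k = t.size
    bounds = []
    for i in range(k + 1):
        lo = 0 if i == 0 else int(t[i - 1]) + 1
        hi = int(t[i]) if i < k else 255
        bounds.append((lo, hi))
    return bounds


def partition_classes(thresholds, hist=None) -> ClassPartition:
    """Split ``[0, 255]`` into the k+1 classes induced by a threshold set.

    With ``hist`` given, class masses are the summed probabilities; without,
    masses are reported as 0 for empty intervals and NaN otherwise.
    """
    t = _as_thresholds(thresholds)
    bounds = _interval_bounds(t)
    if hist is not None:
        p = _as_histogram(hist)
        masses = tuple(float(p[lo : hi + 1].sum()) if lo <= hi else 0.0 for lo, hi in bounds)
    else:
        masses = tuple(0.0 if lo > hi else float("nan") for lo, hi in bounds)
    return ClassPartition(intervals=tuple(bounds), masses=masses)


def _cumulants(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums of ``p`` and of ``p ln p`` (0 ln 0 := 0), length 257."""
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    cum_a = np.concatenate(([0.0], np.cumsum(p)))
    cum_s = np.concatenate(([0.0], np.cumsum(plogp)))
    return cum_a, cum_s


def _fitness_from_sorted(T: np.ndarray, cum_a: np.ndarray, cum_s: np.ndarray) -> np.ndarray:
    """Kapur fitness for a batch of sorted integer threshold rows (B, k)."""
    B, k = T.shape
    edges = np.empty((B, k + 2), dtype=np.int64)
    edges[:, 0] = 0
    edges[:, 1:-1] = T + 1
    edges[:, -1] = N_LEVELS
    A = cum_a[edges[:, 1:]] - cum_a[edges[:, :-1]]
    S = cum_s[edges[:, 1:]] - cum_s[edges[:, :-1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(A > 0, np.log(np.maximum(A, 1e-300)) - S / np.maximum(A, 1e-300), 0.0)
    return H.sum(axis=1)


def kapur_fitness(hist, thresholds) -> float:
    """Kapur entropy of the class partition induced by ``thresholds``.

    Sum over classes of the Shannon entropy of the class-normalized
    histogram segment; empty classes and zero-probability bins contribute 0.
    Always ``>= 0``.
    """
    p = _as_histogram(hist)
    t = _as_thresholds(thresholds)
    cum_a, cum_s = _cumulants(p)
    return float(_fitness_from_sorted(t[None, :], cum_a, cum_s)[0])


class KapurObjective:
    """Reusable Kapur-entropy evaluator for one histogram.

    Precomputes prefix sums so each evaluation of a batch of candidate
    threshold vectors is O(batch * k).  Accepts real-valued positions and
    repairs them (round half-up, sort) to integer threshold sets, matching
    how a continuous-space optimizer probes the discrete search domain.
    """

    def __init__(self, hist):
        self.p = _as_histogram(hist)
        self._cum_a, self._cum_s = _cumulants(self.p)

    def from_sorted_int(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=np.int64)
        squeeze = T.ndim == 1
        if squeeze:
            T = T[None, :]
        out = _fitness_from_sorted(T, self._cum_a, self._cum_s)
        return out[0] if squeeze else out

    def __call__(self, positions) -> np.ndarray:
        from .optimizer import repair_to_thresholds

        pos = np.asarray(positions, dtype=float)
        squeeze = pos.ndim == 1
        if squeeze:
            pos = pos[None, :]
        T = repair_to_thresholds(pos)
        out = _fitness_from_sorted(T, self._cum_a, self._cum_s)
        return float(out[0]) if squeeze else out


def exhaustive_optimum(
    hist, k: int, max_level: int = 255, max_candidates: int = 5_000_000
) -> tuple[np.ndarray, float]:
    """Brute-force best threshold set by full enumeration.

    Enumerates every non-decreasing k-tuple over ``[0, max_level]`` and
    returns the lexicographically smallest maximizer together with its
    fitness.  Intended as a ground-truth oracle for small ``k``; refuses
    instances whose candidate count exceeds ``max_candidates``.
    """
    p = _as_histogram(hist)
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0 <= max_level <= 255:
        raise ValueError("max_level must be in [0, 255]")
    n_cand = math.comb(max_level + 1 + k - 1, k) if k > 0 else 1
    if n_cand > max_candidates:
        raise ValueError(
            f"exhaustive search would evaluate {n_cand} candidates, "
            f"above the limit of {max_candidates}"
        )
    cum_a, cum_s = _cumulants(p)
    if k == 0:
        T0 = np.empty((1, 0), dtype=np.int64)
        return np.empty(0, dtype=np.int64), float(_fitness_from_sorted(T0, cum_a, cum_s)[0])

    from itertools import combinations_with_replacement, islice

    best_t: np.ndarray | None = None
    best_f = -np.inf
    it = combinations_with_replacement(range(max_level + 1), k)
    chunk_size = 65536
    while True:
        chunk = np.array(list(islice(it, chunk_size)), dtype=np.int64)
        if chunk.size == 0:
            break
        f = _fitness_from_sorted(chunk, cum_a, cum_s)
        i = int(np.argmax(f))
        # strict ">" keeps the lexicographically first maximizer overall
        if f[i] > best_f:
            best_f = float(f[i])
            best_t = chunk[i].copy()
    assert best_t is not None
    return best_t, best_f
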