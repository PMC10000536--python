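"""Scikit-learn style estimators wrapping the thresholding pipeline.

:class:`MultilevelThresholder` is a transformer that *fits* a set of gray-level
thresholds to an image (or a pre-computed 256-bin histogram) by maximizing
Kapur's entropy with the eagle-search optimizer, then *transforms* images into
their quantized or binarized form.  :class:`TumorRegionExtractor` is a
stateless transformer applying the morphology post-processing chain to binary
masks.  The two compose into a standard ``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import morphology as morph
from .histogram import N_LEVELS, compute_histogram, exhaustive_optimum, kapur_fitness
from .optimizer import OptimizerConfig, run_bes, run_dobes
from .segment import binarize, quantize

__all__ = ["MultilevelThresholder", "TumorRegionExtractor", "segment_image"]


def _fit_input_to_histogram(X) -> np.ndarray:
    arr = np.asarray(X)
    if arr.ndim == 1:
        if arr.shape != (N_LEVELS,):
            raise ValueError(f"1-D fit input must be a {N_LEVELS}-bin histogram")
        p = arr.astype(float)
        if p.sum() <= 0:
            raise ValueError("histogram must have positive mass")
        return p / p.sum()  # counts or probabilities both accepted
    if arr.ndim == 2:
        return compute_histogram(arr)
    raise ValueError(f"fit input must be a 2-D image or 256-bin histogram, got shape {arr.shape}")


class MultilevelThresholder(TransformerMixin, BaseEstimator):
    """Kapur-entropy multilevel thresholding fitted by eagle search.

    Parameters
    ----------
    n_thresholds : int, default 3
        Number of gray-level cut points ``k`` (giving ``k + 1`` classes).
    method : {"dobes", "bes", "exhaustive"}, default "dobes"
        Optimizer: dynamic-opposite eagle search, the plain eagle-search
        baseline, or brute-force enumeration (small ``k`` only).
    population_size, max_iterations, reruns : int
        Search budget; the defaults (30, 100, 10) follow the standard
        benchmark protocol.
    quantize_mode : {"class_mean", "class_floor"}, default "class_mean"
        Class representative used by :meth:`transform`.
    output : {"quantized", "mask"}, default "quantized"
        What :meth:`transform` returns; "mask" yields the binary
        foreground mask of the ``foreground`` classes.
    foreground : set of int or None
        Class indices treated as foreground (default: brightest class).
    random_state : int, default 0
        Base seed; rerun ``j`` uses ``random_state + j``.

    Attributes
    ----------
    thresholds_ : (k,) int array — fitted gray-level thresholds.
    fitness_ : float — Kapur entropy of the fitted thresholds.
    convergence_ : array — best-so-far fitness per iteration (best rerun).
    rerun_fitness_ : array — per-rerun best fitness.
    histogram_ : (256,) array — the histogram the fit used.
    """

    def __init__(
        self,
        n_thresholds: int = 3,
        method: str = "dobes",
        population_size: int = 30,
        max_iterations: int = 100,
        reruns: int = 10,
        alpha_select: float = 2.0,
        alpha_spiral: float = 10.0,
        R: float = 1.5,
        c1: float = 2.0,
        c2: float = 2.0,
        dol_weight: float = 3.0,
        quantize_mode: str = "class_mean",
        output: str = "quantized",
        foreground=None,
        random_state: int = 0,
    ):
        self.n_thresholds = n_thresholds
        self.method = method
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.reruns = reruns
        self.alpha_select = alpha_select
        self.alpha_spiral = alpha_spiral
        self.R = R
        self.c1 = c1
        self.c2 = c2
        self.dol_weight = dol_weight
        self.quantize_mode = quantize_mode
        self.output = output
        self.foreground = foreground
        self.random_state = random_state

    def _config(self) -> OptimizerConfig:
        return OptimizerConfig(
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            reruns=self.reruns,
            alpha_select=self.alpha_select,
            alpha_spiral=self.alpha_spiral,
            R=self.R,
            c1=self.c1,
            c2=self.c2,
            dol_weight=self.dol_weight,
            seed=self.random_state,
        ).validate()

    def fit(self, X, y=None):
        """Fit thresholds to a 2-D gray image or a 256-bin histogram."""
        if not isinstance(self.n_thresholds, numbers.Integral) or self.n_thresholds < 1:
            raise ValueError("n_thresholds must be a positive integer")
        hist = _fit_input_to_histogram(X)
        if self.method in ("dobes", "bes"):
            runner = run_dobes if self.method == "dobes" else run_bes
            result = runner(hist, int(self.n_thresholds), self._config())
            self.thresholds_ = result.best_thresholds
            self.fitness_ = result.best_fitness
            self.convergence_ = result.convergence
            self.rerun_fitness_ = result.rerun_fitness
            self.result_ = result
        elif self.method == "exhaustive":
            t, f = exhaustive_optimum(hist, int(self.n_thresholds))
            self.thresholds_ = t
            self.fitness_ = f
            self.convergence_ = np.array([f])
            self.rerun_fitness_ = np.array([f])
            self.result_ = None
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.histogram_ = hist
        return self

    def transform(self, X) -> np.ndarray:
        """Quantize an image to class representatives, or binarize it."""
        check_is_fitted(self, "thresholds_")
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("transform expects a single 2-D gray image")
        if self.output == "quantized":
            return quantize(arr, self.thresholds_, mode=self.quantize_mode)
        if self.output == "mask":
            return self.binarize(arr)
        raise ValueError(f"unknown output {self.output!r}")

    def binarize(self, X, foreground=None) -> np.ndarray:
        """Binary mask of the foreground classes (default: brightest)."""
        check_is_fitted(self, "thresholds_")
        fg = foreground if foreground is not None else self.foreground
        return binarize(np.asarray(X), self.thresholds_, foreground=fg)

    def score(self, X, y=None) -> float:
        """Kapur entropy of the fitted thresholds on ``X``'s histogram."""
        check_is_fitted(self, "thresholds_")
        return kapur_fitness(_fit_input_to_histogram(X), self.thresholds_)


class TumorRegionExtractor(TransformerMixin, BaseEstimator):
    """Morphology post-processing chain as a stateless transformer.

    Applies edge detection, dilation, boundary tracing, small-region
    removal, hole filling and target-region selection to a binary mask.
    Parameters mirror :class:`eagleseg.morphology.MorphologyConfig`.
    """

    def __init__(
        self,
        canny_sigma: float = 1.0,
        canny_low: float = 0.1,
        canny_high: float = 0.2,
        dilation_radius: int = 2,
        min_area: int | None = None,
        connectivity: int = 8,
        selection: str = "largest",
    ):
        self.canny_sigma = canny_sigma
        self.canny_low = canny_low
        self.canny_high = canny_high
        self.dilation_radius = dilation_radius
        self.min_area = min_area
        self.connectivity = connectivity
        self.selection = selection

    def _config(self) -> morph.MorphologyConfig:
        return morph.MorphologyConfig(
            canny_sigma=self.canny_sigma,
            canny_low=self.canny_low,
            canny_high=self.canny_high,
            dilation_radius=self.dilation_radius,
            min_area=self.min_area,
            connectivity=self.connectivity,
            selection=self.selection,
        ).validate()

    def fit(self, X=None, y=None):
        self._config()  # parameter validation only; nothing is learned
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        return morph.postprocess(np.asarray(X), self._config())


def segment_image(
    image,
    n_thresholds: int = 3,
    method: str = "dobes",
    random_state: int = 0,
    thresholder: MultilevelThresholder | None = None,
    extractor: TumorRegionExtractor | None = None,
):
    """One-call pipeline: fit thresholds, binarize, post-process.

    Returns a dict with the fitted thresholder and the intermediate and
    final products (quantized image, binary mask, final region mask).
    """
    thr = thresholder or MultilevelThresholder(
        n_thresholds=n_thresholds, method=method, random_state=random_state
    )
    ext = extractor or TumorRegionExtractor()
    thr.fit(image)
    quantized = thr.transform(image)
    mask = thr.binarize(image)
    final = ext.fit().transform(mask)
    return {
        "thresholder": thr,
        "thresholds": thr.thresholds_,
        "fitness": thr.fitness_,
        "quantized": quantized,
        "mask": mask,
        "region": final,
    }
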