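"""Bald eagle search (BES) and its dynamic-opposite variant (DOBES).

BES is a population metaheuristic with three movement phases per iteration:

* **select** — each agent moves from the best-known position toward the
  population centroid, ``P_new = P_best + alpha * r * (P_mean - P_i)``;
* **search** — agents spiral around their neighbourhood,
  ``P_new = P_i + m_i (P_i - P_{i+1}) + l_i (P_i - P_mean)`` with ``l, m``
  normalized polar-spiral coordinates;
* **swoop** — agents dive toward the best solution using a hyperbolic
  spiral, ``P_new = u P_best + l1_i (P_i - c1 P_mean) + m1_i (P_i - c2 P_best)``.

DOBES augments BES with dynamic-opposite learning (DOL): for a point ``x``
with bounds ``[lo, hi]`` the opposite is ``x_o = lo + hi - x`` and the
dynamic opposite is ``x + w r1 (r2 x_o - x)`` with fresh uniform draws
``r1, r2``.  DOL is applied at initialization (the fittest N of the 2N
union of agents and their opposites survive) and inside the search phase
(each agent keeps the best of its current position, spiral candidate and
the candidate's dynamic opposite).

Candidates are accepted per agent only when fitter, and the best position
ever evaluated is recorded, so the convergence curve is non-decreasing.
Positions live in a continuous box (default ``[0, 255]^k``) and are
repaired to sorted integer gray levels at evaluation time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .histogram import KapurObjective, N_LEVELS

__all__ = [
    "OptimizerConfig",
    "SpiralDraws",
    "OptimizerResult",
    "repair_to_thresholds",
    "dynamic_opposite",
    "init_population",
    "dol_initialization",
    "select_candidates",
    "spiral_draws",
    "search_candidates",
    "swoop_candidates",
    "run_dobes",
    "run_bes",
    "minimal_config",
]


@dataclass
class OptimizerConfig:
    """Tunable parameters of the eagle-search optimizer.

    Defaults follow the standard benchmark protocol: population 30, 100
    iterations, 10 independent reruns.  ``alpha_select`` scales the select
    step (valid range [1.5, 2]); ``alpha_spiral`` and ``R`` shape the search
    spiral (ranges [5, 10] and [0.5, 2]); ``c1, c2`` weight the swoop pull
    toward centroid/best (range [1, 2]); ``dol_weight`` is the ``w`` of the
    dynamic-opposite step.  ``bounds`` is the per-dimension search box.
    """

    population_size: int = 30
    max_iterations: int = 100
    reruns: int = 10
    alpha_select: float = 2.0
    alpha_spiral: float = 10.0
    R: float = 1.5
    c1: float = 2.0
    c2: float = 2.0
    dol_weight: float = 3.0
    seed: int = 0
    bounds: tuple[float, float] = (0.0, 255.0)

    def validate(self) -> "OptimizerConfig":
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.reruns < 1:
            raise ValueError("reruns must be >= 1")
        if not 1.5 <= self.alpha_select <= 2.0:
            raise ValueError("alpha_select must lie in [1.5, 2]")
        if not 5.0 <= self.alpha_spiral <= 10.0:
            raise ValueError("alpha_spiral must lie in [5, 10]")
        if not 0.5 <= self.R <= 2.0:
            raise ValueError("R must lie in [0.5, 2]")
        if not 1.0 <= self.c1 <= 2.0 or not 1.0 <= self.c2 <= 2.0:
            raise ValueError("c1 and c2 must lie in [1, 2]")
        if self.dol_weight <= 0:
            raise ValueError("dol_weight must be > 0")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lower < upper")
        return self


def minimal_config(**overrides) -> OptimizerConfig:
    """A small, fast configuration for smoke runs; keyword overrides applied."""
    base = dict(population_size=10, max_iterations=20, reruns=1)
    base.update(overrides)
    return OptimizerConfig(**base).validate()


@dataclass(frozen=True)
class SpiralDraws:
    """Per-agent spiral coordinates used by the search and swoop phases."""

    theta: np.ndarray
    r: np.ndarray
    lr: np.ndarray
    mr: np.ndarray
    l: np.ndarray
    m: np.ndarray


@dataclass
class OptimizerResult:
    """Outcome of a multi-rerun optimization.

    ``convergence`` is the best-so-far fitness after each iteration of the
    best rerun (non-decreasing; last entry equals ``best_fitness``).
    """

    best_thresholds: np.ndarray
    best_fitness: float
    convergence: np.ndarray
    rerun_fitness: np.ndarray
    rerun_thresholds: np.ndarray
    config: OptimizerConfig
    algorithm: str

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_thresholds": [int(v) for v in self.best_thresholds],
            "best_fitness": float(self.best_fitness),
            "convergence": [float(v) for v in self.convergence],
            "rerun_fitness": [float(v) for v in self.rerun_fitness],
            "rerun_thresholds": [[int(v) for v in row] for row in self.rerun_thresholds],
            "config": asdict(self.config),
        }


def repair_to_thresholds(position) -> np.ndarray:
    """Map continuous positions to valid threshold sets.

    Round half-up to integers, clip to [0, 255], sort non-decreasing
    (duplicates kept).  Accepts a single vector or a (B, k) batch.
    """
    pos = np.asarray(position, dtype=float)
    T = np.clip(np.floor(pos + 0.5), 0, N_LEVELS - 1).astype(np.int64)
    return np.sort(T, axis=-1)


def _bounds_arrays(bounds, k: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = bounds
    return np.full(k, float(lo)), np.full(k, float(hi))


def dynamic_opposite(position, bounds, w: float, rng=None, *, r1=None, r2=None) -> np.ndarray:
    """Dynamic-opposite point(s) of ``position`` within ``bounds``.

    Per dimension: ``x_o = lo + hi - x`` and ``x_do = x + w r1 (r2 x_o - x)``
    with independent uniform(0, 1) draws ``r1, r2`` (supplied explicitly or
    drawn from ``rng``); the result is clipped back into the box.
    """
    if w <= 0:
        raise ValueError("dol weight w must be > 0")
    pos = np.asarray(position, dtype=float)
    lo, hi = bounds
    if r1 is None or r2 is None:
        if rng is None:
            raise ValueError("either rng or explicit draws r1, r2 are required")
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
    opp = lo + hi - pos
    out = pos + w * np.asarray(r1) * (np.asarray(r2) * opp - pos)
    return np.clip(out, lo, hi)


def init_population(config: OptimizerConfig, k: int, rng) -> np.ndarray:
    """Uniform random positions, shape (N, k), within the configured box."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = _bounds_arrays(config.bounds, k)
    return rng.uniform(lo, hi, size=(config.population_size, k))


def dol_initialization(positions, fitness, fitness_fn, config: OptimizerConfig, rng):
    """Opposition-refined initialization: keep the N fittest of agents + opposites.

    Ties favour the original agents (stable ranking with originals listed
    first), so the refined population is never worse than the raw one.
    """
    pos = np.asarray(positions, dtype=float)
    opp = dynamic_opposite(pos, config.bounds, config.dol_weight, rng)
    opp_fit = np.asarray(fitness_fn(opp), dtype=float)
    all_pos = np.vstack([pos, opp])
    all_fit = np.concatenate([np.asarray(fitness, dtype=float), opp_fit])
    order = np.argsort(-all_fit, kind="stable")[: pos.shape[0]]
    return all_pos[order], all_fit[order], opp, opp_fit


def select_candidates(positions, best, mean, alpha: float, r) -> np.ndarray:
    """Select-phase candidates ``P_best + alpha * r_i * (P_mean - P_i)`` (unclipped)."""
    pos = np.asarray(positions, dtype=float)
    r = np.asarray(r, dtype=float).reshape(-1, 1)
    return np.asarray(best) + alpha * r * (np.asarray(mean) - pos)


def _normalize(raw: np.ndarray) -> np.ndarray:
    denom = np.max(np.abs(raw))
    if denom == 0:
        return np.zeros_like(raw)
    return raw / denom


def spiral_draws(
    n: int, alpha_spiral: float, R: float, hyperbolic: bool, rng, *, u=None, v=None
) -> SpiralDraws:
    """Polar (circular) or hyperbolic spiral coordinates for ``n`` agents.

    Circular: ``theta = alpha * pi * u``, ``r = theta + R * v``,
    ``lr = r sin(theta)``, ``mr = r cos(theta)``.  Hyperbolic: ``r = theta``
    with sinh/cosh.  ``l, m`` are ``lr, mr`` scaled by the maximum absolute
    raw value (all-zero raw coordinates map to zeros).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if u is None:
        u = rng.random(n)
    if v is None and not hyperbolic:
        v = rng.random(n)
    theta = alpha_spiral * np.pi * np.asarray(u, dtype=float)
    if hyperbolic:
        r = theta.copy()
        lr = r * np.sinh(theta)
        mr = r * np.cosh(theta)
    else:
        r = theta + R * np.asarray(v, dtype=float)
        lr = r * np.sin(theta)
        mr = r * np.cos(theta)
    return SpiralDraws(theta=theta, r=r, lr=lr, mr=mr, l=_normalize(lr), m=_normalize(mr))


def search_candidates(positions, mean, draws: SpiralDraws) -> np.ndarray:
    """Search-phase candidates with wrap-around neighbour pairing (unclipped)."""
    pos = np.asarray(positions, dtype=float)
    nxt = np.roll(pos, -1, axis=0)
    l = draws.l.reshape(-1, 1)
    m = draws.m.reshape(-1, 1)
    return pos + m * (pos - nxt) + l * (pos - np.asarray(mean))


def swoop_candidates(positions, best, mean, draws: SpiralDraws, u, c1: float, c2: float) -> np.ndarray:
    """Swoop-phase candidates diving toward the best position (unclipped)."""
    pos = np.asarray(positions, dtype=float)
    u = np.asarray(u, dtype=float).reshape(-1, 1)
    l1 = draws.l.reshape(-1, 1)
    m1 = draws.m.reshape(-1, 1)
    best = np.asarray(best)
    return u * best + l1 * (pos - c1 * np.asarray(mean)) + m1 * (pos - c2 * best)


class _BestTracker:
    """Elitist record of the best position ever evaluated."""

    def __init__(self):
        self.fitness = -np.inf
        self.position: np.ndarray | None = None

    def update(self, positions: np.ndarray, fitness: np.ndarray) -> None:
        i = int(np.argmax(fitness))
        if fitness[i] > self.fitness:
            self.fitness = float(fitness[i])
            self.position = positions[i].copy()


def _single_run(fitness_fn, k: int, config: OptimizerConfig, seed: int, use_dol: bool):
    rng = np.random.default_rng(seed)
    lo, hi = config.bounds
    N = config.population_size
    pos = init_population(config, k, rng)
    fit = np.asarray(fitness_fn(pos), dtype=float)
    best = _BestTracker()
    best.update(pos, fit)
    if use_dol:
        pos, fit, opp, opp_fit = dol_initialization(pos, fit, fitness_fn, config, rng)
        best.update(opp, opp_fit)

    curve = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        # --- select: explore toward the centroid from the best-known point
        mean = pos.mean(axis=0)
        r = rng.random(N)
        cand = np.clip(select_candidates(pos, best.position, mean, config.alpha_select, r), lo, hi)
        cf = np.asarray(fitness_fn(cand), dtype=float)
        adopt = cf > fit
        pos[adopt], fit[adopt] = cand[adopt], cf[adopt]
        best.update(cand, cf)

        # --- search: spiral exploitation, optionally widened by DOL
        mean = pos.mean(axis=0)
        draws = spiral_draws(N, config.alpha_spiral, config.R, False, rng)
        cand = np.clip(search_candidates(pos, mean, draws), lo, hi)
        cf = np.asarray(fitness_fn(cand), dtype=float)
        best.update(cand, cf)
        if use_dol:
            opp = dynamic_opposite(cand, config.bounds, config.dol_weight, rng)
            of = np.asarray(fitness_fn(opp), dtype=float)
            best.update(opp, of)
            # per-agent argmax of {current, candidate, opposite}; ties keep current
            stacked = np.stack([fit, cf, of])
            choice = np.argmax(stacked, axis=0)
            pos = np.where((choice == 1)[:, None], cand, np.where((choice == 2)[:, None], opp, pos))
            fit = stacked[choice, np.arange(N)]
        else:
            adopt = cf > fit
            pos[adopt], fit[adopt] = cand[adopt], cf[adopt]

        # --- swoop: hyperbolic dive toward the best solution
        mean = pos.mean(axis=0)
        draws = spiral_draws(N, config.alpha_spiral, config.R, True, rng)
        u = rng.random(N)
        cand = np.clip(
            swoop_candidates(pos, best.position, mean, draws, u, config.c1, config.c2), lo, hi
        )
        cf = np.asarray(fitness_fn(cand), dtype=float)
        adopt = cf > fit
        pos[adopt], fit[adopt] = cand[adopt], cf[adopt]
        best.update(cand, cf)

        curve[it] = best.fitness

    return best.position, best.fitness, curve


def _run(hist, k: int, config: OptimizerConfig, use_dol: bool, name: str) -> OptimizerResult:
    config.validate()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > N_LEVELS:
        raise ValueError(f"k must be <= {N_LEVELS}")
    objective = KapurObjective(hist)
    rerun_fit = np.empty(config.reruns)
    rerun_pos = []
    curves = []
    for j in range(config.reruns):
        p, f, c = _single_run(objective, k, config, config.seed + j, use_dol)
        rerun_fit[j] = f
        rerun_pos.append(p)
        curves.append(c)
    best_j = int(np.argmax(rerun_fit))
    rerun_thresholds = repair_to_thresholds(np.asarray(rerun_pos))
    return OptimizerResult(
        best_thresholds=rerun_thresholds[best_j],
        best_fitness=float(rerun_fit[best_j]),
        convergence=curves[best_j],
        rerun_fitness=rerun_fit,
        rerun_thresholds=rerun_thresholds,
        config=config,
        algorithm=name,
    )


def run_dobes(hist, k: int, config: OptimizerConfig | None = None) -> OptimizerResult:
    """Maximize Kapur entropy over k thresholds with the dynamic-opposite variant.

    Runs ``config.reruns`` independent searches seeded ``seed, seed+1, ...``
    and returns the overall best threshold set, the best rerun's convergence
    curve, and per-rerun records.
    """
    return _run(hist, k, config or OptimizerConfig(), use_dol=True, name="dobes")


def run_bes(hist, k: int, config: OptimizerConfig | None = None) -> OptimizerResult:
    """Plain bald-eagle-search baseline: identical loop with DOL disabled."""
    return _run(hist, k, config or OptimizerConfig(), use_dol=False, name="bes")
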