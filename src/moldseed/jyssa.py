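"""Sparrow search optimizer with an elite reverse (opposition) strategy.

Minimizes a fitness function over a bounded box.  Each iteration the
population is ranked and split into roles:

* producers (best ``producer_fraction`` of the population) move by
  ``X * exp(-i / (alpha * max_iter))`` while the alarm value stays below the
  safety threshold, and by a normal-noise step otherwise;
* followers either jump toward the worst position scaled by their hunger
  rank (worse half) or crowd the best producer's position (better half);
* scouts (a fresh random 10-20% each iteration) step toward the global
  best when they are not at it, or jitter away from the worst when they
  are the current optimum.

The elite reverse step then mirrors the top ``elite_fraction`` individuals
through the center of the elite set's dynamic bounding box and keeps each
mirrored candidate only when it is strictly fitter.  The same opposition is
applied once at initialization.  Best-so-far fitness is tracked separately,
so the reported history is monotonically non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "JyssaConfig",
    "Population",
    "init_population",
    "producer_update",
    "follower_update",
    "scout_update",
    "elite_reverse",
    "optimize",
    "OptimizeResult",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass
class JyssaConfig:
    """Optimizer settings.

    ``lower`` / ``upper`` are per-dimension box bounds.  ``safety_threshold``
    (ST) gates the producers' alarm branch; ``scout_fraction`` must lie in
    [0.10, 0.20].  ``beta_mean`` defaults to 1 (step-control parameter drawn
    from a normal with mean and variance 1); set 0 for the classical choice.
    ``elite_reverse_enabled=False`` gives the plain sparrow search.
    """

    lower: Sequence[float]
    upper: Sequence[float]
    pop_size: int = 30
    max_iter: int = 50
    safety_threshold: float = 0.8
    producer_fraction: float = 0.2
    scout_fraction: float = 0.15
    elite_fraction: float = 0.10
    epsilon: float = 1e-10
    beta_mean: float = 1.0
    tol: float = 1e-6
    patience: int = 20
    rng_seed: int = 0
    elite_reverse_enabled: bool = True

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("bounds must satisfy lower < upper per dimension")
        if not 0.0 < self.producer_fraction < 1.0:
            raise ValueError("producer_fraction must be in (0, 1)")
        if not 0.10 <= self.scout_fraction <= 0.20:
            raise ValueError("scout_fraction must be in [0.10, 0.20]")
        if not 0.5 < self.safety_threshold <= 1.0:
            raise ValueError("safety_threshold must be in (0.5, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")

    @property
    def n_dim(self) -> int:
        return int(self.lower.size)

    @property
    def n_producers(self) -> int:
        return max(1, int(round(self.producer_fraction * self.pop_size)))

    @property
    def n_scouts(self) -> int:
        return max(1, int(round(self.scout_fraction * self.pop_size)))

    @property
    def n_elite(self) -> int:
        return max(1, math.ceil(self.elite_fraction * self.pop_size))


@dataclass
class Population:
    """Positions, fitness, and best/worst tracking (minimization)."""

    X: np.ndarray                 # (n, d) positions
    f: np.ndarray                 # (n,) current fitness
    xbest: np.ndarray             # best-so-far position
    fg: float                     # best-so-far fitness (non-increasing)
    xworst: np.ndarray            # current worst position
    fw: float                     # current worst fitness
    t: int = 0
    roles: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def refresh_best_worst(self) -> None:
        i_best = int(np.argmin(self.f))
        i_worst = int(np.argmax(self.f))
        if self.f[i_best] < self.fg:
            self.fg = float(self.f[i_best])
            self.xbest = self.X[i_best].copy()
        self.fw = float(self.f[i_worst])
        self.xworst = self.X[i_worst].copy()


def _evaluate(fitness_fn: FitnessFn, X: np.ndarray) -> np.ndarray:
    f = np.empty(X.shape[0])
    for i, x in enumerate(X):
        val = float(fitness_fn(x))
        if not math.isfinite(val):
            raise ValueError(f"non-finite fitness {val!r} at position {x.tolist()}")
        f[i] = val
    return f


def _clamp(X: np.ndarray, config: JyssaConfig) -> np.ndarray:
    return np.clip(X, config.lower, config.upper)


def _assign_roles(pop: Population, config: JyssaConfig) -> None:
    order = np.argsort(pop.f, kind="stable")
    roles = np.full(pop.X.shape[0], "follower", dtype=object)
    roles[order[: config.n_producers]] = "producer"
    pop.roles = roles


def _opposition(
    X_elite: np.ndarray,
    f_elite: np.ndarray,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Dynamic-boundary opposition on an elite set; greedy acceptance.

    Candidate X' = k*(da + db) - X with k ~ U(0,1) per individual; da/db are
    the per-dimension min/max of the elite positions.  Out-of-box components
    are resampled uniformly inside [da, db].
    """
    da = X_elite.min(axis=0)
    db = X_elite.max(axis=0)
    X_new = X_elite.copy()
    f_new = f_elite.copy()
    n_accepted = 0
    for i in range(X_elite.shape[0]):
        k = rng.uniform(0.0, 1.0)
        cand = k * (da + db) - X_elite[i]
        out = (cand < da) | (cand > db)
        if np.any(out):
            resampled = da + rng.uniform(0.0, 1.0, size=cand.shape) * (db - da)
            cand = np.where(out, resampled, cand)
        f_cand = float(fitness_fn(cand))
        if not math.isfinite(f_cand):
            raise ValueError(f"non-finite fitness at position {cand.tolist()}")
        if f_cand < f_new[i]:
            X_new[i] = cand
            f_new[i] = f_cand
            n_accepted += 1
    return X_new, f_new, n_accepted


def init_population(
    config: JyssaConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator | None = None,
) -> Population:
    """Uniform initialization plus elite opposition on the best fraction."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, d = config.pop_size, config.n_dim
    X = config.lower + rng.uniform(0.0, 1.0, size=(n, d)) * (config.upper - config.lower)
    f = _evaluate(fitness_fn, X)

    if config.elite_reverse_enabled:
        order = np.argsort(f, kind="stable")
        elite_idx = order[: config.n_elite]
        X_e, f_e, _ = _opposition(X[elite_idx], f[elite_idx], fitness_fn, rng)
        X[elite_idx] = X_e
        f[elite_idx] = f_e

    i_best = int(np.argmin(f))
    i_worst = int(np.argmax(f))
    pop = Population(
        X=X, f=f,
        xbest=X[i_best].copy(), fg=float(f[i_best]),
        xworst=X[i_worst].copy(), fw=float(f[i_worst]),
        t=0,
    )
    _assign_roles(pop, config)
    return pop


def producer_update(
    pop: Population,
    config: JyssaConfig,
    rng: np.random.Generator,
) -> Population:
    """Producer move: exponential contraction under safety, noise otherwise.

    One alarm value R2 ~ U[0,1) is drawn per iteration; per producer of
    fitness rank i (1-based), alpha ~ U(0,1] and Q ~ N(0,1).
    """
    order = np.argsort(pop.f, kind="stable")
    r2 = rng.uniform(0.0, 1.0)
    for rank, idx in enumerate(order[: config.n_producers], start=1):
        if r2 < config.safety_threshold:
            alpha = 1.0 - rng.uniform(0.0, 1.0)  # uniform on (0, 1]
            pop.X[idx] = pop.X[idx] * math.exp(-rank / (alpha * config.max_iter))
        else:
            q = rng.standard_normal()
            pop.X[idx] = pop.X[idx] + q
    pop.X = _clamp(pop.X, config)
    return pop


def follower_update(
    pop: Population,
    config: JyssaConfig,
    rng: np.random.Generator,
    xp: np.ndarray | None = None,
) -> Population:
    """Follower move: starvation jump for the worse half, plunder otherwise.

    ``xp`` is the best producer's (already updated) position; defaults to
    the position of the fitness-rank-1 individual.  The plunder step adds
    the scalar ``sum(|X - xp| * A) / d`` (A a random +/-1 row) to every
    dimension — the Moore-Penrose form A^T (A A^T)^-1 L collapses to it.
    """
    order = np.argsort(pop.f, kind="stable")
    n, d = pop.X.shape
    if xp is None:
        xp = pop.X[order[0]]
    xp = np.asarray(xp, dtype=float)
    for rank, idx in enumerate(order[config.n_producers:], start=config.n_producers + 1):
        if rank > n / 2:
            q = rng.standard_normal()
            pop.X[idx] = q * np.exp((pop.xworst - pop.X[idx]) / float(rank) ** 2)
        else:
            A = rng.integers(0, 2, size=d) * 2 - 1
            step = float(np.sum(np.abs(pop.X[idx] - xp) * A)) / d
            pop.X[idx] = xp + step
    pop.X = _clamp(pop.X, config)
    return pop


def scout_update(
    pop: Population,
    config: JyssaConfig,
    rng: np.random.Generator,
) -> Population:
    """Danger-aware move for a fresh random subset of the population.

    Individuals worse than the global best step toward it with step control
    beta ~ N(beta_mean, 1); an individual already at the best fitness
    jitters away from the worst with K ~ U[-1, 1], guarded by epsilon.
    """
    n = pop.X.shape[0]
    scouts = rng.choice(n, size=min(config.n_scouts, n), replace=False)
    for idx in scouts:
        fi = pop.f[idx]
        if fi > pop.fg:
            beta = config.beta_mean + rng.standard_normal()
            pop.X[idx] = pop.xbest + beta * np.abs(pop.X[idx] - pop.xbest)
        else:
            K = rng.uniform(-1.0, 1.0)
            pop.X[idx] = pop.X[idx] + K * (
                np.abs(pop.X[idx] - pop.xworst) / ((fi - pop.fw) + config.epsilon)
            )
    pop.X = _clamp(pop.X, config)
    return pop


def elite_reverse(
    pop: Population,
    config: JyssaConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
) -> Population:
    """Opposition step on the current elite set with greedy acceptance."""
    order = np.argsort(pop.f, kind="stable")
    elite_idx = order[: config.n_elite]
    X_e, f_e, _ = _opposition(pop.X[elite_idx], pop.f[elite_idx], fitness_fn, rng)
    pop.X[elite_idx] = X_e
    pop.f[elite_idx] = f_e
    pop.refresh_best_worst()
    return pop


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    history: np.ndarray           # best-so-far fitness per iteration
    n_iter: int
    converged: bool


def optimize(fitness_fn: FitnessFn, config: JyssaConfig) -> OptimizeResult:
    """Run the full loop: init, role updates, elite reversal, tracking.

    Stops at ``max_iter`` or when the best fitness fails to improve by
    ``tol`` for ``patience`` consecutive iterations.
    """
    rng = np.random.default_rng(config.rng_seed)
    pop = init_population(config, fitness_fn, rng)
    history: list[float] = []
    stall = 0
    converged = False

    for t in range(1, config.max_iter + 1):
        pop.t = t
        _assign_roles(pop, config)
        order = np.argsort(pop.f, kind="stable")
        best_producer = int(order[0])

        producer_update(pop, config, rng)
        follower_update(pop, config, rng, xp=pop.X[best_producer])
        scout_update(pop, config, rng)

        pop.f = _evaluate(fitness_fn, pop.X)
        pop.refresh_best_worst()
        if config.elite_reverse_enabled:
            elite_reverse(pop, config, fitness_fn, rng)

        prev = history[-1] if history else math.inf
        history.append(pop.fg)
        if prev - pop.fg < config.tol:
            stall += 1
            if stall >= config.patience:
                converged = True
                break
        else:
            stall = 0

    return OptimizeResult(
        x=pop.xbest.copy(),
        fun=pop.fg,
        history=np.asarray(history),
        n_iter=len(history),
        converged=converged,
    )
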