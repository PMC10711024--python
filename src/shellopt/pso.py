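"""Standard particle swarm optimization (maximization) on box bounds.

Velocity and position updates follow the classic inertia-weight form

    v <- w v + c1 r1 (p_best - x) + c2 r2 (g_best - x),    x <- x + v,

with independent uniform(0, 1) draws r1, r2 per particle and per dimension.
The inertia weight follows a linear schedule across generations — by default
increasing from 0.4 to 0.6, as in the study protocol this package
reimplements — and the acceleration constants default to c1 = c2 = 0.5 with
40 particles. Positions are clamped to the bounds after each move, zeroing
the velocity on any clamped dimension. The only stopping rule is the
generation budget.

With these weak acceleration constants the swarm contracts quickly, and on
multimodal objectives (the extraction response surfaces have distinct
corner and interior maxima over the factor box) a purely random swarm often
collapses into the wrong basin. Two mitigations are built in: the initial
swarm is seeded with the 3^M factorial lattice of the bounds (corners,
edge and face midpoints, center) so every corner basin contributes to the
initial global best, and :func:`optimize` can run several independently
seeded restarts, reporting the best (``restarts`` in the config).

Objectives are batched: they take an (n, M) array of positions and return n
fitness values. Use :func:`batched` to wrap a scalar function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["PsoConfig", "SwarmState", "SwarmResult", "batched", "pso_step", "optimize"]


def batched(scalar_objective: Callable) -> Callable:
    """Wrap f(x: (M,)) -> float into the batched form pso expects."""

    def wrapped(X: np.ndarray) -> np.ndarray:
        return np.array([scalar_objective(row) for row in np.atleast_2d(X)])

    return wrapped


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyperparameters and bounds.

    ``bounds`` is an (M, 2) array-like of per-dimension (low, high).
    ``inertia`` is the (start, end) of the linear schedule over generations.
    """

    bounds: tuple
    swarm_size: int = 40
    c1: float = 0.5
    c2: float = 0.5
    inertia: tuple[float, float] = (0.4, 0.6)
    max_generations: int = 2000
    restarts: int = 5
    lattice_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        b = self.bounds_array()
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must be (M, 2)")
        if not np.all(b[:, 1] > b[:, 0]):
            raise ValueError("each bound must satisfy low < high")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration constants must be >= 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)

    def inertia_at(self, generation: int) -> float:
        w0, w1 = self.inertia
        if self.max_generations == 1:
            return w0
        return w0 + (w1 - w0) * generation / (self.max_generations - 1)

    def to_dict(self) -> dict:
        return {
            "bounds": self.bounds_array().tolist(),
            "swarm_size": self.swarm_size,
            "c1": self.c1,
            "c2": self.c2,
            "inertia": list(self.inertia),
            "max_generations": self.max_generations,
            "restarts": self.restarts,
            "lattice_init": self.lattice_init,
            "seed": self.seed,
            "boundary_handling": "clamp, velocity zeroed on clamped dimension",
            "initialization": (
                "3^M factorial lattice of the bounds, remainder uniform"
                if self.lattice_init
                else "positions uniform in bounds"
            )
            + "; velocities uniform in +/-0.2*range",
        }


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of the swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    generation: int = 0


@dataclass
class SwarmResult:
    """Outcome of a PSO run (maximization)."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    n_evaluations: int
    config: dict = field(default_factory=dict)


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    f = np.asarray(objective(X), dtype=float)
    if f.shape != (len(X),):
        raise ValueError(
            f"objective returned shape {f.shape}, expected ({len(X)},)"
        )
    if not np.all(np.isfinite(f)):
        bad = X[~np.isfinite(f)][0]
        raise ValueError(f"objective returned a non-finite value at {bad}")
    return f


def init_state(objective, config: PsoConfig, rng: np.random.Generator) -> SwarmState:
    b = config.bounds_array()
    lo, hi = b[:, 0], b[:, 1]
    n, m = config.swarm_size, len(b)
    positions = rng.uniform(lo, hi, size=(n, m))
    if config.lattice_init:
        from itertools import product

        lattice = np.array(
            list(product(*[(b[d, 0], b[d].mean(), b[d, 1]) for d in range(m)]))
        )
        k = min(len(lattice), n)
        positions[:k] = lattice[:k]
    velocities = rng.uniform(-0.2, 0.2, size=(n, m)) * (hi - lo)
    fitness = _evaluate(objective, positions)
    g = int(np.argmax(fitness))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        gbest_position=positions[g].copy(),
        gbest_fitness=float(fitness[g]),
    )


def pso_step(
    state: SwarmState,
    objective,
    w: float,
    rng: np.random.Generator,
    config: PsoConfig,
) -> SwarmState:
    """Advance the swarm one generation in place and return it."""
    b = config.bounds_array()
    lo, hi = b[:, 0], b[:, 1]
    shape = state.positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    state.velocities = (
        w * state.velocities
        + config.c1 * r1 * (state.pbest_positions - state.positions)
        + config.c2 * r2 * (state.gbest_position - state.positions)
    )
    state.positions = state.positions + state.velocities
    below = state.positions < lo
    above = state.positions > hi
    state.velocities[below | above] = 0.0
    state.positions = np.clip(state.positions, lo, hi)

    fitness = _evaluate(objective, state.positions)
    improved = fitness > state.pbest_fitness
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitness[improved] = fitness[improved]
    g = int(np.argmax(state.pbest_fitness))
    if state.pbest_fitness[g] > state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[g])
        state.gbest_position = state.pbest_positions[g].copy()
    state.generation += 1
    return state


def _optimize_once(objective, config: PsoConfig, seed) -> SwarmResult:
    rng = np.random.default_rng(seed)
    state = init_state(objective, config, rng)
    history = np.empty(config.max_generations)
    for g in range(config.max_generations):
        pso_step(state, objective, config.inertia_at(g), rng, config)
        history[g] = state.gbest_fitness
    return SwarmResult(
        best_position=state.gbest_position.copy(),
        best_fitness=state.gbest_fitness,
        history=history,
        n_evaluations=config.swarm_size * (config.max_generations + 1),
        config=config.to_dict(),
    )


def optimize(objective, config: PsoConfig) -> SwarmResult:
    """Maximize a batched objective over the configured bounds.

    Runs ``config.restarts`` independently seeded swarms — each for exactly
    ``config.max_generations`` generations, the sole per-swarm stopping
    rule — and returns the best run's result with the total evaluation
    count. Fully reproducible from ``config.seed``.
    """
    best: SwarmResult | None = None
    n_evals = 0
    for r in range(config.restarts):
        seed = np.random.SeedSequence([config.seed, r])
        result = _optimize_once(objective, config, seed)
        n_evals += result.n_evaluations
        if best is None or result.best_fitness > best.best_fitness:
            best = result
    assert best is not None
    best.n_evaluations = n_evals
    return best
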