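"""The base fox-hunting optimizer (FOX).

A population of agents mimics a red fox hunting by sound.  Each iteration
an agent either *exploits* — it estimates the distance to the prey from the
incumbent best position and a random sound-travel time, computes a pounce
height from gravity, and jumps — or *explores*, taking a random walk scaled
by the best position, the minimum mean travel time across the pack and a
factor that decays over the run.  The branch is picked by a uniform draw
``r`` against a 0.5 threshold, and within exploitation a second draw ``p``
against 0.18 selects the jump direction (northeast scales by ``c1``,
opposite by ``c2``).

The distance bookkeeping deliberately follows the hunt metaphor step by
step: the sound speed is the best position divided by the travel time, the
sound distance multiplies that speed back by the time, and the fox–prey
distance halves it.  Algebraically the chain collapses to half the best
position; the intermediates are kept so each stage is testable on its own.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np

from .types import Bounds, FoxConfig, FoxState, OptResult

__all__ = [
    "init_population",
    "compute_sound_speed",
    "compute_distances",
    "compute_jump",
    "exploitation_move",
    "compute_min_t",
    "compute_a",
    "exploration_move",
    "clamp_to_bounds",
    "fox_step",
    "fox_optimize",
]

logger = logging.getLogger(__name__)

#: Floor applied to sound-travel times before division.
TIME_EPS = 1e-12

Objective = Callable[[np.ndarray], float]


def _evaluate(
    objective: Objective, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate each row; returns (fitness, non-finite mask)."""
    fit = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        fit[i] = objective(np.asarray(x, dtype=float))
    bad = ~np.isfinite(fit)
    if np.any(bad):
        logger.warning(
            "objective returned non-finite values for %d agent(s)",
            int(bad.sum()),
        )
    return fit, bad


def init_population(
    bounds: Bounds, config: FoxConfig, rng: np.random.Generator,
    objective: Objective | None = None,
) -> FoxState:
    """Sample the pack uniformly within the box and score it.

    When ``objective`` is omitted, fitness is set to +inf and the caller is
    expected to evaluate before stepping.
    """
    n, d = config.n_agents, bounds.dim
    positions = rng.uniform(bounds.lower, bounds.upper, size=(n, d))
    time_matrix = rng.uniform(0.0, 1.0, size=(n, d))
    if objective is not None:
        fitness, bad = _evaluate(objective, positions)
        fitness[bad] = np.inf
        n_evals = n
    else:
        fitness = np.full(n, np.inf)
        n_evals = 0
    ibest = int(np.argmin(fitness))
    return FoxState(
        positions=positions,
        fitness=fitness,
        time_matrix=time_matrix,
        best_x=positions[ibest].copy(),
        best_fitness=float(fitness[ibest]),
        iteration=0,
        n_evals=n_evals,
    )


def compute_sound_speed(best_x: np.ndarray, time_row: np.ndarray) -> np.ndarray:
    """Per-dimension sound speed: the best position over the travel time.

    Times are floored at ``TIME_EPS`` so a zero draw never divides by zero.
    """
    best_x = np.asarray(best_x, dtype=float)
    time_row = np.maximum(np.asarray(time_row, dtype=float), TIME_EPS)
    return best_x / time_row


def compute_distances(
    sp_s: np.ndarray, time_row: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sound distance (speed x time) and fox-prey distance (half of it)."""
    sp_s = np.asarray(sp_s, dtype=float)
    time_row = np.asarray(time_row, dtype=float)
    if sp_s.shape != time_row.shape:
        raise ValueError(
            f"speed and time vectors must have equal shape, "
            f"got {sp_s.shape} and {time_row.shape}"
        )
    dist_s_t = sp_s * time_row
    return dist_s_t, 0.5 * dist_s_t


def compute_jump(time_row: np.ndarray, gravity: float = 9.81) -> float:
    """Pounce height 0.5·g·t² with t = (mean travel time)/2.

    The mean time is halved because the sound makes a round trip; the jump
    squares it because the pounce goes up and comes down.
    """
    time_row = np.asarray(time_row, dtype=float)
    if time_row.size == 0:
        raise ValueError("time_row must be non-empty")
    t = time_row.mean() / 2.0
    return 0.5 * gravity * t * t


def exploitation_move(
    dist_fox_prey: np.ndarray, jump: float, p: float, config: FoxConfig
) -> np.ndarray:
    """New position from a pounce: distance x jump x (c1 or c2).

    ``p > p_threshold`` means the fox jumps northeast (scale ``c1``),
    otherwise it jumps the opposite way (scale ``c2``).
    """
    dist_fox_prey = np.asarray(dist_fox_prey, dtype=float)
    scale = config.c1 if p > config.p_threshold else config.c2
    return dist_fox_prey * jump * scale


def compute_min_t(time_matrix: np.ndarray) -> float:
    """Minimum over agents of the mean sound-travel time."""
    time_matrix = np.asarray(time_matrix, dtype=float)
    if time_matrix.size == 0:
        raise ValueError("time_matrix must be non-empty")
    return float(time_matrix.mean(axis=1).min())


def compute_a(it: int, max_iter: int, literal: bool = False) -> float:
    """Exploration scale, decaying from ~2 to 0 over the run.

    The decaying form ``2·(1 − it/max_iter)`` is the default; ``literal``
    selects the alternative increasing form ``2·(it − 1/max_iter)`` for
    comparison, which grows with ``it`` and is kept only for archaeology.
    """
    if not 1 <= it <= max_iter:
        raise ValueError(f"it must lie in [1, {max_iter}], got {it}")
    if literal:
        return 2.0 * (it - 1.0 / max_iter)
    return 2.0 * (1.0 - it / max_iter)


def exploration_move(
    best_x: np.ndarray, min_t: float, a: float, rng: np.random.Generator
) -> np.ndarray:
    """Random walk around the incumbent: best_x ⊙ U[0,1]^d · (min_t · a)."""
    best_x = np.asarray(best_x, dtype=float)
    u = rng.uniform(0.0, 1.0, size=best_x.shape)
    return best_x * u * (min_t * a)


def clamp_to_bounds(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Project every coordinate back onto its box interval."""
    return np.clip(np.asarray(position, dtype=float), bounds.lower, bounds.upper)


def fox_step(
    state: FoxState,
    objective: Objective,
    bounds: Bounds,
    config: FoxConfig,
    rng: np.random.Generator,
    exploration: Callable[..., np.ndarray] | None = None,
) -> FoxState:
    """Advance the pack one iteration (in place) and return the state.

    Every agent resamples its travel-time row, then draws ``r``: with
    ``r >= r_threshold`` it exploits (pounce toward the prey inferred from
    the incumbent best), otherwise it explores.  Moves are computed from the
    best-so-far at the start of the iteration; positions are replaced
    unconditionally, while the global best is an elite archive and never
    worsens.  ``exploration`` may substitute a different random-walk move
    with the same ``(best_x, min_t, a, rng)`` signature.
    """
    if exploration is None:
        exploration = exploration_move
    n, d = state.n_agents, state.dim
    it = state.iteration + 1

    state.time_matrix = rng.uniform(0.0, 1.0, size=(n, d))
    min_t = compute_min_t(state.time_matrix)
    a = compute_a(it, config.max_iter, literal=config.literal_a)
    best_x = state.best_x.copy()

    r = rng.uniform(0.0, 1.0, size=n)
    new_positions = np.empty_like(state.positions)
    for i in range(n):
        time_row = state.time_matrix[i]
        if r[i] >= config.r_threshold:
            p = rng.uniform(0.0, 1.0)
            sp_s = compute_sound_speed(best_x, time_row)
            _, dist_fox_prey = compute_distances(sp_s, time_row)
            jump = compute_jump(time_row, config.gravity)
            new_positions[i] = exploitation_move(dist_fox_prey, jump, p, config)
        else:
            new_positions[i] = exploration(best_x, min_t, a, rng)
        new_positions[i] = clamp_to_bounds(new_positions[i], bounds)

    new_fitness, bad = _evaluate(objective, new_positions)
    # a non-finite evaluation keeps the previous position/fitness pair
    ok = ~bad
    state.positions[ok] = new_positions[ok]
    state.fitness[ok] = new_fitness[ok]
    state.n_evals += n
    state.iteration = it

    ibest = int(np.argmin(state.fitness))
    if state.fitness[ibest] < state.best_fitness:
        state.best_fitness = float(state.fitness[ibest])
        state.best_x = state.positions[ibest].copy()
    return state


def fox_optimize(
    objective: Objective, bounds: Bounds, config: FoxConfig | None = None
) -> OptResult:
    """Run the full FOX loop: init + ``max_iter`` steps.

    Deterministic under ``config.seed``; the evaluation budget is exactly
    ``n_agents * (max_iter + 1)``.
    """
    if config is None:
        config = FoxConfig()
    rng = np.random.default_rng(config.seed)
    state = init_population(bounds, config, rng, objective=objective)
    history = np.empty(config.max_iter)
    for k in range(config.max_iter):
        fox_step(state, objective, bounds, config, rng)
        history[k] = state.best_fitness
    return OptResult(
        best_x=state.best_x.copy(),
        best_fitness=state.best_fitness,
        best_history=history,
        n_evals=state.n_evals,
    )
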