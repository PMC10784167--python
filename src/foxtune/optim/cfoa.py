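"""Contracted Fox Optimization Algorithm (CFOA).

Two modifications of the base fox optimizer:

* **Lévy-flight exploration** — the uniform random-walk factor of the
  exploration move is replaced by a heavy-tailed Lévy step (Mantegna
  construction, index ``xi`` = 3/2 by default).  Occasional long jumps let
  the pack escape local optima.
* **Elimination phase** — every ``ep`` iterations the ``et`` worst agents
  are culled and resampled uniformly in the (possibly expanded) box.  A
  dimension's bounds expand by ``expand_factor`` about zero whenever a
  surviving agent sits beyond ``th`` percent of that dimension's absolute
  magnitude, widening the realm of investigation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fox import (
    Objective,
    _evaluate,
    clamp_to_bounds,
    fox_step,
    init_population,
)
from .types import Bounds, FoxConfig, FoxState, OptResult

__all__ = [
    "LevyParams",
    "EliminationConfig",
    "CfoaConfig",
    "levy_sigma",
    "levy_step",
    "cfoa_exploration_move",
    "expand_bounds",
    "elimination_phase",
    "cfoa_optimize",
    "cfoa_config_from_dict",
]

#: Floor on |B| in the Mantegna ratio so steps stay finite.
_B_EPS = 1e-300


def levy_sigma(xi: float) -> float:
    """Step-scale sigma of the Mantegna Lévy-step construction.

    sigma = [Γ(1+ξ)·sin(πξ/2) / (Γ((1+ξ)/2)·ξ·2^((ξ−1)/2))]^(1/ξ)

    At ξ=1 every factor reduces to 1, so sigma is exactly 1.
    """
    if not 0.0 < xi <= 2.0:
        raise ValueError(f"xi must lie in (0, 2], got {xi}")
    num = math.gamma(1.0 + xi) * math.sin(math.pi * xi / 2.0)
    den = math.gamma((1.0 + xi) / 2.0) * xi * 2.0 ** ((xi - 1.0) / 2.0)
    return (num / den) ** (1.0 / xi)


@dataclass(frozen=True)
class LevyParams:
    """Lévy-flight step parameters: tail index ``xi`` and derived scale."""

    xi: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.xi <= 2.0:
            raise ValueError(f"xi must lie in (0, 2], got {self.xi}")

    @property
    def sigma(self) -> float:
        return levy_sigma(self.xi)


@dataclass(frozen=True)
class EliminationConfig:
    """Schedule and scope of the periodic cull.

    ``ep`` — period in iterations; ``et`` — number of worst agents replaced
    per event; ``th`` — percent of a dimension's absolute magnitude beyond
    which a surviving agent triggers bound expansion; ``expand_factor`` —
    multiplicative widening applied about zero.
    """

    ep: int = 40
    et: int = 30
    th: float = 60.0
    expand_factor: float = 1.25

    def __post_init__(self) -> None:
        if self.ep < 1:
            raise ValueError("ep must be >= 1")
        if self.et < 1:
            raise ValueError("et must be >= 1")
        if not 0.0 < self.th <= 100.0:
            raise ValueError("th must lie in (0, 100]")
        if self.expand_factor <= 1.0:
            raise ValueError("expand_factor must exceed 1")


@dataclass
class CfoaConfig:
    """Full CFOA configuration: base fox knobs + Lévy + elimination."""

    fox: FoxConfig = field(default_factory=FoxConfig)
    levy: LevyParams = field(default_factory=LevyParams)
    elimination: EliminationConfig = field(default_factory=EliminationConfig)

    def __post_init__(self) -> None:
        if self.elimination.et >= self.fox.n_agents:
            raise ValueError(
                f"et ({self.elimination.et}) must be below the population "
                f"size ({self.fox.n_agents})"
            )


def cfoa_config_from_dict(doc: dict) -> CfoaConfig:
    """Build a config from a nested mapping (YAML/JSON); unknown keys rejected."""
    if not isinstance(doc, dict):
        raise TypeError("config document must be a mapping")
    known = {"fox", "levy", "elimination"}
    extra = set(doc) - known
    if extra:
        raise ValueError(f"unknown config section(s): {sorted(extra)}")

    def build(cls, section):
        fields = {f for f in cls.__dataclass_fields__}
        extra = set(section) - fields
        if extra:
            raise ValueError(
                f"unknown key(s) in {cls.__name__}: {sorted(extra)}"
            )
        return cls(**section)

    return CfoaConfig(
        fox=build(FoxConfig, doc.get("fox", {})),
        levy=build(LevyParams, doc.get("levy", {})),
        elimination=build(EliminationConfig, doc.get("elimination", {})),
    )


def levy_step(
    dim: int, params: LevyParams, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed step vector w = A / |B|^(1/xi), A~N(0, sigma²), B~N(0,1)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    a = rng.normal(0.0, params.sigma, size=dim)
    b = rng.normal(0.0, 1.0, size=dim)
    return a / np.maximum(np.abs(b), _B_EPS) ** (1.0 / params.xi)


def cfoa_exploration_move(
    best_x: np.ndarray,
    min_t: float,
    a: float,
    params: LevyParams,
    rng: np.random.Generator,
    levy_vec: np.ndarray | None = None,
) -> np.ndarray:
    """Exploration with a Lévy factor in place of the uniform draw.

    ``levy_vec`` lets callers stub the Lévy stream (tests).
    """
    best_x = np.asarray(best_x, dtype=float)
    if levy_vec is None:
        levy_vec = levy_step(best_x.size, params, rng)
    return best_x * levy_vec * (min_t * a)


def expand_bounds(
    state: FoxState, bounds: Bounds, cfg: EliminationConfig,
    survivors: np.ndarray | None = None,
) -> Bounds:
    """Widen a dimension's box when survivors press against its magnitude.

    A dimension expands by ``expand_factor`` about zero when any surviving
    agent's |coordinate| exceeds ``th``% of max(|lower|, |upper|) there.
    """
    pos = state.positions if survivors is None else state.positions[survivors]
    mag = np.maximum(np.abs(bounds.lower), np.abs(bounds.upper))
    trigger = np.any(np.abs(pos) > (cfg.th / 100.0) * mag, axis=0)
    if not np.any(trigger):
        return bounds
    lower = bounds.lower.copy()
    upper = bounds.upper.copy()
    lower[trigger] *= cfg.expand_factor
    upper[trigger] *= cfg.expand_factor
    return Bounds(lower, upper)


def elimination_phase(
    state: FoxState,
    bounds: Bounds,
    cfg: EliminationConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> tuple[FoxState, Bounds]:
    """Cull the ``et`` worst agents and resample them in the revised box.

    Survivors are untouched; the global best is an elite archive and never
    worsens.  Replacement fitness counts toward the evaluation tally.
    """
    n = state.n_agents
    if cfg.et >= n:
        raise ValueError(f"et ({cfg.et}) must be below population size ({n})")
    order = np.argsort(state.fitness, kind="stable")
    worst = order[n - cfg.et:]
    survivors = order[: n - cfg.et]

    new_bounds = expand_bounds(state, bounds, cfg, survivors=survivors)
    replacements = rng.uniform(
        new_bounds.lower, new_bounds.upper, size=(cfg.et, new_bounds.dim)
    )
    fit, bad = _evaluate(objective, replacements)
    fit[bad] = np.inf
    state.positions[worst] = replacements
    state.fitness[worst] = fit
    state.n_evals += cfg.et

    ibest = int(np.argmin(state.fitness))
    if state.fitness[ibest] < state.best_fitness:
        state.best_fitness = float(state.fitness[ibest])
        state.best_x = state.positions[ibest].copy()
    return state, new_bounds


def cfoa_optimize(
    objective: Objective, bounds: Bounds, config: CfoaConfig | None = None
) -> OptResult:
    """Full CFOA run: fox loop with Lévy exploration + periodic elimination.

    Elimination fires after every ``ep``-th iteration, so a run triggers
    exactly ``floor(max_iter / ep)`` events.  Deterministic under
    ``config.fox.seed``.
    """
    if config is None:
        config = CfoaConfig()
    fox_cfg = config.fox
    rng = np.random.default_rng(fox_cfg.seed)
    state = init_population(bounds, fox_cfg, rng, objective=objective)

    def levy_exploration(best_x, min_t, a, rng_):
        return cfoa_exploration_move(best_x, min_t, a, config.levy, rng_)

    cur_bounds = bounds
    history = np.empty(fox_cfg.max_iter)
    for k in range(fox_cfg.max_iter):
        fox_step(
            state, objective, cur_bounds, fox_cfg, rng,
            exploration=levy_exploration,
        )
        if state.iteration % config.elimination.ep == 0:
            state, cur_bounds = elimination_phase(
                state, cur_bounds, config.elimination, objective, rng
            )
        history[k] = state.best_fitness
    return OptResult(
        best_x=state.best_x.copy(),
        best_fitness=state.best_fitness,
        best_history=history,
        n_evals=state.n_evals,
    )
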