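"""Shared containers for the fox-family optimizers.

All optimizers minimize; a maximization problem is handled by negating the
objective before passing it in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Bounds", "FoxConfig", "FoxState", "OptResult"]


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints for a continuous search space.

    Parameters
    ----------
    lower, upper
        Arrays of equal length; ``lower[d] < upper[d]`` must hold strictly
        in every dimension.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower, upper):
        lower = np.atleast_1d(np.asarray(lower, dtype=float))
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError(
                f"lower and upper must be 1-D arrays of equal length, "
                f"got shapes {lower.shape} and {upper.shape}"
            )
        if not np.all(lower < upper):
            bad = np.nonzero(~(lower < upper))[0]
            raise ValueError(
                f"lower must be strictly below upper in every dimension; "
                f"violated at dimension(s) {bad.tolist()}"
            )
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def cube(cls, lo: float, hi: float, dim: int) -> "Bounds":
        """Symmetric box ``[lo, hi]^dim``."""
        return cls(np.full(dim, float(lo)), np.full(dim, float(hi)))

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass
class FoxConfig:
    """Knobs of the base fox optimizer.

    ``c1``/``c2`` scale the exploitation jump depending on the jump
    direction draw ``p`` (northeast vs. opposite); ``sound_speed_air`` is
    the physical 343 m/s constant the hunt metaphor quotes and is carried
    for reference only — the position update derives the speed from the
    incumbent best instead.
    """

    n_agents: int = 60
    max_iter: int = 200
    c1: float = 0.18
    c2: float = 0.82
    p_threshold: float = 0.18
    r_threshold: float = 0.5
    sound_speed_air: float = 343.0
    gravity: float = 9.81
    seed: int | None = None
    literal_a: bool = False  # keep the (increasing) printed form of the decay

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not 0.0 <= self.c1 <= 0.18:
            raise ValueError("c1 must lie in [0, 0.18]")
        if not 0.19 <= self.c2 <= 1.0:
            raise ValueError("c2 must lie in [0.19, 1]")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")


@dataclass
class FoxState:
    """Mutable optimizer population state.

    ``time_matrix`` holds the per-agent, per-dimension sound-travel times in
    [0, 1] that drive the distance and jump computations; it is resampled
    every iteration.
    """

    positions: np.ndarray
    fitness: np.ndarray
    time_matrix: np.ndarray
    best_x: np.ndarray
    best_fitness: float
    iteration: int = 0
    n_evals: int = 0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass
class OptResult:
    """Outcome of a full optimization run."""

    best_x: np.ndarray
    best_fitness: float
    best_history: np.ndarray
    n_evals: int

    def to_dict(self) -> dict:
        return {
            "best_x": np.asarray(self.best_x).tolist(),
            "best_fitness": float(self.best_fitness),
            "best_history": np.asarray(self.best_history).tolist(),
            "n_evals": int(self.n_evals),
        }
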