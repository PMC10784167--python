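"""Baseline optimizers for comparison harnesses.

Only uniform random search ships built in; anything conforming to the
optimizer-callable contract ``(objective, bounds, seed, n_evals) ->
OptResult`` can be plugged into the trial harness.
"""

from __future__ import annotations

import numpy as np

from .fox import Objective, _evaluate
from .types import Bounds, OptResult

__all__ = ["random_search"]


def random_search(
    objective: Objective,
    bounds: Bounds,
    seed: int | None = None,
    n_evals: int = 12_060,
    batch: int = 60,
) -> OptResult:
    """Uniform i.i.d. sampling in the box, tracking the running best.

    ``best_history`` records the incumbent after each batch so histories
    are comparable with population optimizers at an equal evaluation
    budget (default 60·201, the fox budget at population 60 / 200
    iterations).
    """
    rng = np.random.default_rng(seed)
    best_f = np.inf
    best_x = None
    history = []
    done = 0
    while done < n_evals:
        m = min(batch, n_evals - done)
        xs = rng.uniform(bounds.lower, bounds.upper, size=(m, bounds.dim))
        fit, bad = _evaluate(objective, xs)
        fit[bad] = np.inf
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f = float(fit[i])
            best_x = xs[i].copy()
        history.append(best_f)
        done += m
    return OptResult(
        best_x=best_x,
        best_fitness=best_f,
        best_history=np.asarray(history),
        n_evals=done,
    )
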