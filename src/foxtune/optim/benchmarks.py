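"""Classical benchmark objectives and the repeated-trial harness.

The suite is the standard analytic set (sphere, rosenbrock, rastrigin,
ackley, griewank, schwefel-2.21, levy-surface, zakharov), each with its
documented box and known minimum.  The harness runs an optimizer callable
over consecutive seeds and reports Best / Mean / StD of the per-run final
fitness, mirroring the usual metaheuristic comparison table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .types import Bounds, OptResult

__all__ = ["BenchmarkFunction", "TrialStats", "registry", "get_function",
           "run_trials", "stats_table", "parse_stats_table"]


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dim: int
    bounds: Bounds
    evaluate: Callable[[np.ndarray], float]
    known_minimum: float
    argmin: np.ndarray


def _sphere(x):
    return float(np.sum(x * x))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x):
    n = x.size
    s1 = np.sum(x * x) / n
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / n
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _schwefel_2_21(x):
    return float(np.max(np.abs(x)))


def _levy_surface(x):
    w = 1.0 + (x - 1.0) / 4.0
    term1 = np.sin(np.pi * w[0]) ** 2
    term3 = (w[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[-1]) ** 2)
    wm = w[:-1]
    mid = np.sum((wm - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * wm + 1.0) ** 2))
    return float(term1 + mid + term3)


def _zakharov(x):
    i = np.arange(1, x.size + 1)
    s = np.sum(0.5 * i * x)
    return float(np.sum(x * x) + s ** 2 + s ** 4)


_SUITE = {
    # name: (fn, box half-width or (lo, hi), argmin builder)
    "sphere": (_sphere, (-100.0, 100.0), lambda d: np.zeros(d)),
    "rosenbrock": (_rosenbrock, (-30.0, 30.0), lambda d: np.ones(d)),
    "rastrigin": (_rastrigin, (-5.12, 5.12), lambda d: np.zeros(d)),
    "ackley": (_ackley, (-32.0, 32.0), lambda d: np.zeros(d)),
    "griewank": (_griewank, (-600.0, 600.0), lambda d: np.zeros(d)),
    "schwefel_2_21": (_schwefel_2_21, (-100.0, 100.0), lambda d: np.zeros(d)),
    "levy_surface": (_levy_surface, (-10.0, 10.0), lambda d: np.ones(d)),
    "zakharov": (_zakharov, (-10.0, 10.0), lambda d: np.zeros(d)),
}


def registry(dim: int = 10) -> list[BenchmarkFunction]:
    """All benchmark functions instantiated at the given dimension."""
    out = []
    for name, (fn, (lo, hi), argmin) in _SUITE.items():
        out.append(
            BenchmarkFunction(
                name=name,
                dim=dim,
                bounds=Bounds.cube(lo, hi, dim),
                evaluate=fn,
                known_minimum=0.0,
                argmin=argmin(dim),
            )
        )
    return out


def get_function(name: str, dim: int = 10) -> BenchmarkFunction:
    for f in registry(dim):
        if f.name == name:
            return f
    raise KeyError(
        f"unknown benchmark {name!r}; available: {sorted(_SUITE)}"
    )


@dataclass
class TrialStats:
    """Best / Mean / StD of final fitness over repeated seeded runs."""

    function_name: str
    algo_name: str
    n_runs: int
    best: float
    mean: float
    std: float
    per_run_finals: np.ndarray


# Optimizer-callable contract: (objective, bounds, seed) -> OptResult
Optimizer = Callable[..., OptResult]


def run_trials(
    algo: Optimizer,
    fn: BenchmarkFunction,
    n_runs: int = 25,
    base_seed: int = 0,
    algo_name: str = "optimizer",
) -> TrialStats:
    """Run ``algo`` with seeds base_seed..base_seed+n_runs−1 and aggregate.

    A run that raises is logged and excluded from the aggregate; StD uses
    the sample (n−1) convention and is 0 for a single run.
    """
    import logging

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    finals = []
    for k in range(n_runs):
        try:
            res = algo(fn.evaluate, fn.bounds, seed=base_seed + k)
            finals.append(res.best_fitness)
        except Exception:  # noqa: BLE001 - one bad seed must not sink the table
            logging.getLogger(__name__).warning(
                "optimizer run failed on %s with seed %d; excluded",
                fn.name, base_seed + k, exc_info=True,
            )
            finals.append(np.nan)
    finals = np.asarray(finals, dtype=float)
    valid = finals[np.isfinite(finals)]
    std = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0
    return TrialStats(
        function_name=fn.name,
        algo_name=algo_name,
        n_runs=n_runs,
        best=float(np.min(valid)),
        mean=float(np.mean(valid)),
        std=std,
        per_run_finals=finals,
    )


def stats_table(stats: Sequence[TrialStats]) -> pd.DataFrame:
    """Long-to-wide table: rows (function, indicator), one column per algorithm."""
    rows = []
    for s in stats:
        for indicator, value in (("Best", s.best), ("Mean", s.mean), ("StD", s.std)):
            rows.append(
                {"function": s.function_name, "indicator": indicator,
                 "algorithm": s.algo_name, "value": value}
            )
    if not rows:
        return pd.DataFrame(columns=["function", "indicator"])
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["function", "indicator"], columns="algorithm", values="value",
        sort=False,
    ).reset_index()
    wide.columns.name = None
    return wide


def parse_stats_table(csv_text: str) -> pd.DataFrame:
    """Round-trip reader for :func:`stats_table` CSV output."""
    return pd.read_csv(io.StringIO(csv_text))
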