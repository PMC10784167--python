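"""Class-imbalance-aware loss family and convolution cost formulas.

Cross entropy, weighted cross entropy and focal loss over softmax
probability vectors and one-hot targets, all using the *sum* convention
over samples (a mean reduction is available via ``reduction="mean"``).
The weighted variant's class weights can be rescheduled each training
repetition from the per-class error rates Er = 1 − TPR through a monotone
transform ρ (identity, cube, or exponentials e^y, e^{10y}, e^{100y}),
normalized to sum to one — upweighting the classes currently hardest to
recall.

Also included: the cost ratio between a conventional convolution and its
depthwise-separable factorization.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "RHO_KINDS",
    "cross_entropy",
    "weighted_cross_entropy",
    "focal_loss",
    "class_error_rates",
    "update_class_weights",
    "conv_costs",
]

logger = logging.getLogger(__name__)

#: Floor applied to probabilities before the logarithm.
PROB_FLOOR = 1e-12

RHO_KINDS = {
    "identity": lambda y: y,
    "cube": lambda y: y ** 3,
    "exp1": lambda y: np.exp(y),
    "exp10": lambda y: np.exp(10.0 * y),
    "exp100": lambda y: np.exp(100.0 * y),
}


def _check_pairs(probs: np.ndarray, targets: np.ndarray):
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if probs.shape != targets.shape:
        raise ValueError(
            f"probs and targets must align, got {probs.shape} vs {targets.shape}"
        )
    if probs.shape[0] < 1:
        raise ValueError("need at least one sample")
    if np.any(probs < -1e-9) or np.any(
        np.abs(probs.sum(axis=1) - 1.0) > 1e-9
    ):
        raise ValueError("each probability row must be non-negative and sum to 1")
    if np.any((targets != 0) & (targets != 1)) or np.any(
        targets.sum(axis=1) != 1
    ):
        raise ValueError("targets must be one-hot rows")
    return probs, targets


def _log_probs(probs: np.ndarray) -> np.ndarray:
    floored = np.maximum(probs, PROB_FLOOR)
    if np.any(probs < PROB_FLOOR):
        logger.warning("probability below floor %.0e; clamped before log", PROB_FLOOR)
    return np.log(floored)


def _reduce(per_sample: np.ndarray, reduction: str) -> float:
    if reduction == "sum":
        return float(per_sample.sum())
    if reduction == "mean":
        return float(per_sample.mean())
    raise ValueError("reduction must be 'sum' or 'mean'")


def cross_entropy(probs, targets, reduction: str = "sum") -> float:
    """−Σ_i z_i · ln P(y_i) over samples; 0 for perfect predictions."""
    probs, targets = _check_pairs(probs, targets)
    per_sample = -(targets * _log_probs(probs)).sum(axis=1)
    return _reduce(per_sample, reduction)


def weighted_cross_entropy(probs, targets, weights, reduction: str = "sum") -> float:
    """−Σ_i z_i · [w ⊙ ln P(y_i)]; unit weights recover plain cross entropy."""
    probs, targets = _check_pairs(probs, targets)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (probs.shape[1],):
        raise ValueError(
            f"weights must have one entry per class ({probs.shape[1]}), "
            f"got shape {weights.shape}"
        )
    if np.any(weights < 0):
        raise ValueError("class weights must be non-negative")
    per_sample = -(targets * (weights * _log_probs(probs))).sum(axis=1)
    return _reduce(per_sample, reduction)


def focal_loss(probs, targets, delta: float = 2.0, reduction: str = "sum") -> float:
    """−Σ_i z_i · [(1−P(y_i))^δ ⊙ ln P(y_i)]; δ=0 recovers cross entropy.

    The (1−p)^δ factor decays the contribution of samples the model already
    classifies confidently.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    probs, targets = _check_pairs(probs, targets)
    decay = (1.0 - probs) ** delta
    per_sample = -(targets * (decay * _log_probs(probs))).sum(axis=1)
    return _reduce(per_sample, reduction)


def class_error_rates(cm: np.ndarray) -> np.ndarray:
    """Per-class error rate Er_i = 1 − TPR_i from a confusion matrix.

    A class with no true samples has an undefined recall; its rate is
    reported as 0 with a warning.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_totals = cm.sum(axis=1)
    empty = row_totals == 0
    if np.any(empty):
        logger.warning(
            "class(es) %s have no true samples; error rate set to 0",
            np.nonzero(empty)[0].tolist(),
        )
    tpr = np.divide(
        np.diag(cm), row_totals, out=np.ones(cm.shape[0]), where=~empty
    )
    return 1.0 - tpr


def update_class_weights(er: np.ndarray, rho: str = "identity") -> np.ndarray:
    """Class weights w_i = ρ(Er_i) / Σ_j ρ(Er_j), summing to one.

    With identity ρ the weights track the error rates directly; the
    exponential kinds act as increasingly sharp softmaxes over them.  An
    all-zero denominator (possible under identity/cube) falls back to
    uniform weights with a warning.
    """
    er = np.asarray(er, dtype=np.float64)
    if np.any(er < 0) or np.any(er > 1):
        raise ValueError("error rates must lie in [0, 1]")
    if rho not in RHO_KINDS:
        raise ValueError(f"rho must be one of {sorted(RHO_KINDS)}")
    vals = RHO_KINDS[rho](er)
    total = vals.sum()
    if total <= 0:
        logger.warning("all-zero rho transform; using uniform class weights")
        return np.full(er.size, 1.0 / er.size)
    return vals / total


def conv_costs(
    hi: int, wi: int, di: int, dj: int, k: int
) -> tuple[float, float, float]:
    """Conventional vs depthwise-separable convolution cost and their ratio.

    C_nor = hi·wi·di·dj·k², C_sep = hi·wi·di·(dj+k²); the advantage ratio
    dj·k²/(dj+k²) is independent of the spatial extent and input depth.
    """
    for name, v in (("hi", hi), ("wi", wi), ("di", di), ("dj", dj), ("k", k)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    c_nor = float(hi * wi * di * dj * k * k)
    c_sep = float(hi * wi * di * (dj + k * k))
    ratio = float(dj * k * k) / float(dj + k * k)
    return c_nor, c_sep, ratio
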