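"""CFOA-driven hyperparameter tuning.

Encodes the four MobileNet-style scaling knobs — depth multiplier, width
multiplier, input resolution and dropout rate — as a 4-D box, with the
resolution snapped onto a declared grid, and minimizes an objective over
that box with the contracted fox optimizer.  The shipped objective is a
deliberately desk-scale toy classifier: pooled intensity/edge features on
the synthetic phantoms, a closed-form ridge-penalized linear classifier
with a softmax readout, and 1 − validation accuracy as the fitness.  Any
callable ``HyperParams × seed → fitness`` can replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .optim import Bounds, CfoaConfig, OptResult, cfoa_optimize
from .preprocessing import resize_to_input
from .synthetic import DatasetRecord

__all__ = [
    "HyperParams",
    "SearchSpace",
    "SplitResult",
    "decode_position",
    "split_dataset",
    "toy_classifier_objective",
    "tune",
]

logger = logging.getLogger(__name__)

#: Working-resolution cap inside the toy objective (keeps it desk-scale).
_TOY_MAX_RES = 64


@dataclass(frozen=True)
class HyperParams:
    """MobileNet-style scaling knobs."""

    depth_multiplier: float = 0.5
    width_multiplier: float = 0.75
    input_resolution: int = 512
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.depth_multiplier <= 1.0:
            raise ValueError("depth_multiplier must lie in (0, 1]")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_resolution < 1:
            raise ValueError("input_resolution must be positive")

    def to_dict(self) -> dict:
        return {
            "depth_multiplier": self.depth_multiplier,
            "width_multiplier": self.width_multiplier,
            "input_resolution": self.input_resolution,
            "dropout_rate": self.dropout_rate,
        }


@dataclass(frozen=True)
class SearchSpace:
    """Continuous intervals + resolution grid defining the encoded box.

    Positions live in the zero-centered unit box ``[-1, 1]^4`` with layout
    [depth, width, resolution_code, dropout]; each coordinate maps
    affinely onto its hyperparameter interval, and the resolution code
    snaps to the nearest grid index.  Centering the encoding on zero
    matters for the fox-family optimizers: their moves scale the incumbent
    best multiplicatively about the origin, and the elimination phase
    expands bounds about zero — a one-sided (all-positive) encoding would
    drift the resampling box away from any interior optimum.
    """

    depth: tuple[float, float] = (0.25, 1.0)
    width: tuple[float, float] = (0.25, 1.0)
    dropout: tuple[float, float] = (0.0, 0.5)
    resolution_grid: tuple[int, ...] = (128, 227, 256, 384, 512)

    def bounds(self) -> Bounds:
        return Bounds.cube(-1.0, 1.0, 4)

    def _intervals(self) -> np.ndarray:
        return np.array(
            [self.depth, self.width,
             (0.0, float(len(self.resolution_grid) - 1)), self.dropout]
        )

    def encode(self, hp: HyperParams) -> np.ndarray:
        if hp.input_resolution not in self.resolution_grid:
            raise ValueError(
                f"resolution {hp.input_resolution} not on the grid "
                f"{self.resolution_grid}"
            )
        idx = self.resolution_grid.index(hp.input_resolution)
        raw = np.array(
            [hp.depth_multiplier, hp.width_multiplier, float(idx),
             hp.dropout_rate]
        )
        iv = self._intervals()
        return 2.0 * (raw - iv[:, 0]) / (iv[:, 1] - iv[:, 0]) - 1.0


def decode_position(x: np.ndarray, space: SearchSpace) -> HyperParams:
    """Map an encoded position to hyperparameters (resolution snapped).

    Positions outside the unit box are clamped first with a warning (the
    optimizer's bound expansion can push resampled agents beyond it).
    """
    x = np.asarray(x, dtype=float)
    b = space.bounds()
    if not b.contains(x):
        logger.warning("position outside the search box; clamped before decode")
        x = np.clip(x, b.lower, b.upper)
    iv = space._intervals()
    raw = iv[:, 0] + (x + 1.0) / 2.0 * (iv[:, 1] - iv[:, 0])
    idx = int(round(raw[2]))
    return HyperParams(
        depth_multiplier=float(raw[0]),
        width_multiplier=float(raw[1]),
        input_resolution=space.resolution_grid[idx],
        dropout_rate=float(raw[3]),
    )


@dataclass
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_train_counts: dict[int, int] = field(default_factory=dict)


def split_dataset(
    labels, train_frac: float = 0.8, rng: np.random.Generator | None = None
) -> SplitResult:
    """Stratified split: per class, round(frac·n) samples go to training.

    Nearest-integer rounding per class reproduces MATLAB's
    ``splitEachLabel`` bookkeeping on the usual class-size tables.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    train, test = [], []
    per_class = {}
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size == 0:
            raise ValueError(f"class {cls} has no samples")
        k = int(np.rint(train_frac * idx.size))
        chosen = rng.permutation(idx.size)
        train.extend(idx[chosen[:k]])
        test.extend(idx[chosen[k:]])
        per_class[int(cls)] = k
    return SplitResult(
        train_indices=np.sort(np.asarray(train, dtype=np.int64)),
        test_indices=np.sort(np.asarray(test, dtype=np.int64)),
        per_class_train_counts=per_class,
    )


def _features(img: np.ndarray, hp: HyperParams) -> np.ndarray:
    """Pooled intensity + edge features scaled by the width/depth knobs."""
    res = min(hp.input_resolution, _TOY_MAX_RES)
    x = resize_to_input(img, target=res, channels=1)
    x = x / 255.0

    g = max(2, int(round(8 * hp.width_multiplier)))
    # trim to a multiple of the pooling grid, then block-mean
    side = (res // g) * g
    core = x[:side, :side].reshape(g, side // g, g, side // g)
    pooled = core.mean(axis=(1, 3)).ravel()

    gy, gx = np.gradient(x)
    grad = np.sqrt(gy * gy + gx * gx)
    edge_core = grad[:side, :side].reshape(g, side // g, g, side // g)
    edges = hp.depth_multiplier * edge_core.mean(axis=(1, 3)).ravel()

    mu, sd = float(x.mean()), float(x.std())
    bright = float((x > mu + sd).mean())
    return np.concatenate([pooled, edges, [mu, sd, bright]])


def toy_classifier_objective(
    dataset: list[DatasetRecord], hp: HyperParams, seed: int = 0
) -> float:
    """1 − validation accuracy of a ridge-penalized linear classifier.

    Features are dropout-masked (inverted scaling) with a seed-derived
    stream, so the fitness is deterministic given (dataset, hp, seed).
    """
    labels = np.asarray([r.label for r in dataset])
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("dataset must contain at least two classes")
    rng = np.random.default_rng(seed)

    feats = np.stack([_features(r.image, hp) for r in dataset])
    if hp.dropout_rate > 0:
        keep = rng.random(feats.shape[1]) >= hp.dropout_rate
        if not np.any(keep):
            keep[rng.integers(feats.shape[1])] = True
        feats = feats[:, keep] / (1.0 - hp.dropout_rate)

    split = split_dataset(labels, 0.8, rng)
    tr, te = split.train_indices, split.test_indices
    mu = feats[tr].mean(axis=0)
    sd = feats[tr].std(axis=0)
    sd[sd == 0] = 1.0
    X = (feats - mu) / sd
    Xtr = np.hstack([X[tr], np.ones((tr.size, 1))])
    Xte = np.hstack([X[te], np.ones((te.size, 1))])

    onehot = (labels[tr][:, None] == classes[None, :]).astype(float)
    lam = 1e-2
    A = Xtr.T @ Xtr + lam * np.eye(Xtr.shape[1])
    W = np.linalg.solve(A, Xtr.T @ onehot)
    scores = Xte @ W
    pred = classes[np.argmax(scores, axis=1)]
    acc = float(np.mean(pred == labels[te]))
    return 1.0 - acc


def tune(
    space: SearchSpace | None = None,
    dataset: list[DatasetRecord] | None = None,
    cfoa_cfg: CfoaConfig | None = None,
    objective=None,
    seed: int | None = None,
) -> tuple[HyperParams, OptResult]:
    """Minimize an objective over the encoded hyperparameter box with CFOA.

    ``objective`` takes (HyperParams, seed) and returns a fitness; it
    defaults to :func:`toy_classifier_objective` over ``dataset``.  The
    default budget (population 60, 200 iterations, elimination every 5
    replacing 40 agents) suits cheap objectives; the dense elimination
    schedule matters because uniform resampling is the mechanism by which
    the fox-family dynamics reach optima away from the encoded origin.
    Pass a smaller ``cfoa_cfg`` for expensive objectives.
    """
    from .optim import EliminationConfig, FoxConfig, LevyParams

    if space is None:
        space = SearchSpace()
    if cfoa_cfg is None:
        cfoa_cfg = CfoaConfig(
            fox=FoxConfig(n_agents=60, max_iter=200, seed=seed),
            levy=LevyParams(),
            elimination=EliminationConfig(ep=5, et=40),
        )
    elif seed is not None:
        cfoa_cfg.fox.seed = seed
    obj_seed = cfoa_cfg.fox.seed if cfoa_cfg.fox.seed is not None else 0

    if objective is None:
        if dataset is None:
            raise ValueError("provide a dataset or an explicit objective")
        cache: dict[tuple, float] = {}

        def objective(hp: HyperParams, seed: int) -> float:
            key = (round(hp.depth_multiplier, 6), round(hp.width_multiplier, 6),
                   hp.input_resolution, round(hp.dropout_rate, 6))
            if key not in cache:
                cache[key] = toy_classifier_objective(dataset, hp, seed)
            return cache[key]

    b = space.bounds()

    def encoded_objective(x: np.ndarray) -> float:
        # expansion can push resampled agents past the unit box; that is
        # expected, so clip quietly before decoding
        hp = decode_position(np.clip(x, b.lower, b.upper), space)
        return float(objective(hp, obj_seed))

    result = cfoa_optimize(encoded_objective, b, cfoa_cfg)
    best_hp = decode_position(np.clip(result.best_x, b.lower, b.upper), space)
    return best_hp, result
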