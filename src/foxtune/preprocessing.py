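"""Grayscale MRI-style preprocessing.

Implements the classic contrast-limited adaptive histogram equalization
(CLAHE) pipeline stage by stage — tile partition, per-tile histogram,
clipping at a limit T, cumulative distribution, redistribution over the L
intensity levels, and tile merging by bilinear interpolation — plus
min-max normalization to [0, 1], resizing to a square network input with
channel replication, and the random affine augmentation family (rotation,
shear, translation, scale, optional reflection).

The CLAHE clipping step is available in two modes: the *literal* mode
simply truncates each histogram bin at T (clipped mass is discarded), and
the *redistribute* mode spreads the clipped excess uniformly over all bins
so the total count is conserved, as most CLAHE implementations do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage.transform import ProjectiveTransform, resize, warp

__all__ = [
    "ClaheConfig",
    "AugmentConfig",
    "partition_tiles",
    "tile_histogram",
    "clip_histogram",
    "histogram_cdf",
    "redistribute_cdf",
    "clahe",
    "min_max_normalize",
    "resize_to_input",
    "sample_augment_params",
    "augment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE parameters.

    ``clip_limit`` is interpreted per ``clip_unit``: ``"count"`` is an
    absolute per-bin count T, ``"fraction"`` scales T by the tile pixel
    count.  ``redistribute_excess`` False keeps the literal truncation.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 40.0
    clip_unit: str = "count"
    redistribute_excess: bool = False
    merge: str = "bilinear"
    levels: int = 256

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if self.clip_unit not in ("count", "fraction"):
            raise ValueError("clip_unit must be 'count' or 'fraction'")
        if self.merge not in ("bilinear", "nearest"):
            raise ValueError("merge must be 'bilinear' or 'nearest'")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def _pad_to_grid(img: np.ndarray, tile_rows: int, tile_cols: int):
    """Reflect-pad so both axes divide evenly into the tile grid."""
    m, n = img.shape
    th = -(-m // tile_rows)  # ceil
    tw = -(-n // tile_cols)
    pad_r = th * tile_rows - m
    pad_c = tw * tile_cols - n
    if pad_r or pad_c:
        img = np.pad(img, ((0, pad_r), (0, pad_c)), mode="reflect")
    return img, (th, tw)


def partition_tiles(img: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    """Split into a (tile_rows, tile_cols, H, W) array of non-overlapping tiles.

    Ragged edges are reflect-padded up to a grid multiple first, so every
    tile has the same H×W and together the tiles cover each (padded) pixel
    exactly once.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    padded, (th, tw) = _pad_to_grid(img, cfg.tile_rows, cfg.tile_cols)
    return (
        padded.reshape(cfg.tile_rows, th, cfg.tile_cols, tw)
        .transpose(0, 2, 1, 3)
    )


def tile_histogram(tile: np.ndarray, levels: int = 256) -> np.ndarray:
    """Count of each intensity value k in [0, levels)."""
    tile = np.asarray(tile)
    if not np.issubdtype(tile.dtype, np.integer):
        if not np.allclose(tile, np.round(tile)):
            raise ValueError("tile must hold integer intensity values")
        tile = np.round(tile).astype(np.int64)
    if tile.size and (tile.min() < 0 or tile.max() >= levels):
        raise ValueError(
            f"intensity values must lie in [0, {levels - 1}], "
            f"got range [{tile.min()}, {tile.max()}]"
        )
    return np.bincount(tile.ravel(), minlength=levels).astype(np.int64)


def clip_histogram(
    hist: np.ndarray, clip_limit: float, redistribute: bool = False
) -> np.ndarray:
    """Truncate bins at T; optionally spread the clipped excess uniformly.

    In redistribute mode the excess is dealt ``excess // L`` to every bin
    plus one extra to the first ``excess % L`` bins (round-robin), so the
    total count is conserved exactly.  Bins may then exceed T again; no
    second pass is made.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    hist = np.asarray(hist)
    clipped = np.minimum(hist, clip_limit)
    if not redistribute:
        return clipped
    excess = int(round(float(hist.sum() - clipped.sum())))
    if excess <= 0:
        return clipped
    L = hist.size
    out = clipped.astype(np.float64) + excess // L
    out[: excess % L] += 1
    if np.issubdtype(hist.dtype, np.integer) and float(clip_limit).is_integer():
        out = out.astype(np.int64)
    return out


def histogram_cdf(hist: np.ndarray) -> np.ndarray:
    """Cumulative counts C(k) = sum of H(j) for j <= k."""
    return np.cumsum(np.asarray(hist), dtype=np.float64)


def redistribute_cdf(cdf: np.ndarray, levels: int, n_pixels: int) -> np.ndarray:
    """Spread the cumulative distribution over [0, L−1]: (L−1)·C(k)/count.

    ``n_pixels`` is the pixel count the CDF was accumulated over (the tile's
    H·W when used per tile).
    """
    if n_pixels <= 0:
        raise ValueError("pixel count must be positive")
    return (levels - 1) * np.asarray(cdf, dtype=np.float64) / n_pixels


def _tile_mapping(tile: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    """Intensity LUT for one tile: histogram → clip → CDF → redistribution."""
    hist = tile_histogram(tile, cfg.levels)
    limit = cfg.clip_limit
    if cfg.clip_unit == "fraction":
        limit = cfg.clip_limit * tile.size
    clipped = clip_histogram(hist, limit, cfg.redistribute_excess)
    cdf = histogram_cdf(clipped)
    total = float(cdf[-1])
    if total <= 0:
        # fully clipped-away tile: identity mapping
        return np.arange(cfg.levels, dtype=np.float64)
    return redistribute_cdf(cdf, cfg.levels, int(round(total)))


def clahe(img: np.ndarray, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile LUTs are built from clipped histograms; pixels are remapped by
    bilinear interpolation between the four neighboring tile LUTs (or by
    their own tile's LUT with ``merge="nearest"``).  Output has the input's
    shape and dtype with values in [0, L−1].
    """
    if cfg is None:
        cfg = ClaheConfig()
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    orig_dtype = img.dtype
    m, n = img.shape
    padded, (th, tw) = _pad_to_grid(img, cfg.tile_rows, cfg.tile_cols)
    tiles = (
        padded.reshape(cfg.tile_rows, th, cfg.tile_cols, tw)
        .transpose(0, 2, 1, 3)
    )
    maps = np.empty((cfg.tile_rows, cfg.tile_cols, cfg.levels))
    for i in range(cfg.tile_rows):
        for j in range(cfg.tile_cols):
            maps[i, j] = _tile_mapping(tiles[i, j], cfg)

    pix = padded
    if not np.issubdtype(pix.dtype, np.integer):
        pix = np.round(pix).astype(np.int64)
    pix = pix.astype(np.intp)

    rows = np.arange(padded.shape[0])
    cols = np.arange(padded.shape[1])
    ty = (rows - (th - 1) / 2.0) / th
    tx = (cols - (tw - 1) / 2.0) / tw
    if cfg.merge == "nearest":
        i0 = np.clip(np.round(ty).astype(int), 0, cfg.tile_rows - 1)
        j0 = np.clip(np.round(tx).astype(int), 0, cfg.tile_cols - 1)
        out = maps[i0[:, None], j0[None, :], pix]
    else:
        ty = np.clip(ty, 0.0, cfg.tile_rows - 1.0)
        tx = np.clip(tx, 0.0, cfg.tile_cols - 1.0)
        i0 = np.floor(ty).astype(int)
        j0 = np.floor(tx).astype(int)
        i1 = np.minimum(i0 + 1, cfg.tile_rows - 1)
        j1 = np.minimum(j0 + 1, cfg.tile_cols - 1)
        fy = (ty - i0)[:, None]
        fx = (tx - j0)[None, :]
        v00 = maps[i0[:, None], j0[None, :], pix]
        v01 = maps[i0[:, None], j1[None, :], pix]
        v10 = maps[i1[:, None], j0[None, :], pix]
        v11 = maps[i1[:, None], j1[None, :], pix]
        out = (
            (1 - fy) * ((1 - fx) * v00 + fx * v01)
            + fy * ((1 - fx) * v10 + fx * v11)
        )
    out = np.clip(out[:m, :n], 0, cfg.levels - 1)
    if np.issubdtype(orig_dtype, np.integer):
        out = np.round(out).astype(orig_dtype)
    return out


def min_max_normalize(x: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (x − min) / (max − min).

    A constant input has no spread to normalize; it maps to all zeros with
    a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("constant input to min_max_normalize; returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def resize_to_input(
    img: np.ndarray, target: int = 227, channels: int = 3
) -> np.ndarray:
    """Bilinear resize to target×target, replicating grayscale channels.

    ``channels=1`` returns a 2-D array (identity when already the right
    size).
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.shape != (target, target):
        img = resize(
            img, (target, target), order=1, preserve_range=True,
            anti_aliasing=False,
        )
    if channels == 1:
        return img
    return np.repeat(img[:, :, None], channels, axis=2)


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling intervals for the random affine augmentation family.

    Defaults follow common MRI augmentation practice: rotation ±7°, shear
    ±0.03, translation ±35 px, anisotropic scale 0.4–3, no reflection.
    """

    rotation_deg: tuple[float, float] = (-7.0, 7.0)
    shear_xy: tuple[float, float] = (-0.03, 0.03)
    translation_px: tuple[float, float] = (-35.0, 35.0)
    scale_xy: tuple[float, float] = (0.4, 3.0)
    reflect_x: bool = False
    reflect_y: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "shear_xy", "translation_px", "scale_xy"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is inverted: ({lo}, {hi})")


def sample_augment_params(
    cfg: AugmentConfig, rng: np.random.Generator
) -> dict[str, float | bool]:
    """Draw one parameter set; every value falls inside its interval."""
    u = lambda iv: float(rng.uniform(iv[0], iv[1])) if iv[0] < iv[1] else float(iv[0])
    return {
        "rotation_deg": u(cfg.rotation_deg),
        "shear_x": u(cfg.shear_xy),
        "shear_y": u(cfg.shear_xy),
        "translate_x": u(cfg.translation_px),
        "translate_y": u(cfg.translation_px),
        "scale_x": u(cfg.scale_xy),
        "scale_y": u(cfg.scale_xy),
        "reflect_x": bool(cfg.reflect_x),
        "reflect_y": bool(cfg.reflect_y),
    }


def _affine_matrix(params: dict, shape: tuple[int, int]) -> np.ndarray:
    """Forward 3×3 matrix in (x, y) convention: scale→shear→rotate→translate
    composed about the image center; reflections applied innermost."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(params["rotation_deg"])

    refl = np.diag([
        -1.0 if params["reflect_x"] else 1.0,
        -1.0 if params["reflect_y"] else 1.0,
        1.0,
    ])
    scale = np.diag([params["scale_x"], params["scale_y"], 1.0])
    shear = np.array(
        [[1.0, params["shear_x"], 0.0],
         [params["shear_y"], 1.0, 0.0],
         [0.0, 0.0, 1.0]]
    )
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0.0],
         [np.sin(theta), np.cos(theta), 0.0],
         [0.0, 0.0, 1.0]]
    )
    to_center = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    from_center = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    trans = np.array(
        [[1, 0, params["translate_x"]], [0, 1, params["translate_y"]],
         [0, 0, 1.0]]
    )
    return trans @ from_center @ rot @ shear @ scale @ refl @ to_center


def augment(
    img: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one randomly sampled affine transform.

    Bilinear resampling with zero fill; the output shape equals the input
    shape.  Deterministic given the generator (or ``cfg.seed``).
    """
    if cfg is None:
        cfg = AugmentConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    img = np.asarray(img, dtype=np.float64)
    params = sample_augment_params(cfg, rng)
    fwd = _affine_matrix(params, img.shape)
    tform = ProjectiveTransform(matrix=np.linalg.inv(fwd))
    return warp(
        img, tform, order=1, cval=0.0, preserve_range=True,
        output_shape=img.shape,
    )
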