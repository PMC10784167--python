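"""Synthetic 3-class grayscale tumor-phantom generator and dataset I/O.

Emulates the structure of the public Figshare brain-tumor MRI collection
— three classes (meningioma-like, pituitary-like, glioma-like) of
grayscale images with a bright head-shaped background and a
class-conditional bright lesion — so every pipeline stage can run and be
tested without downloading data:

* class 1 (meningioma-like): one round blob near the head periphery;
* class 2 (pituitary-like): one small blob near the center;
* class 3 (glioma-like): a large irregular multi-lobed blob.

Records carry the image (uint8, [0, 255]), the integer label in {1, 2, 3}
and a boolean lesion mask.  Datasets round-trip through one ``.mat``
container per record (legacy scipy dialect written; legacy, HDF5/v7.3 and
Figshare-style ``cjdata`` field names all readable) plus a manifest CSV.
The phantoms are deliberately simple: classes are separable from
mean-intensity and lesion-area style features, which real MRI data is not.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
from PIL import Image

__all__ = [
    "SyntheticSpec",
    "DatasetRecord",
    "generate_image",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "export_png",
]

CLASS_NAMES = {1: "meningioma_like", 2: "pituitary_like", 3: "glioma_like"}

#: Figshare-style per-class image counts (meningioma, pituitary, glioma).
FIGSHARE_CLASS_SIZES = (708, 930, 1426)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.

    ``n_per_class`` orders counts as (class 1, class 2, class 3);
    ``noise_sd`` is the additive Gaussian noise level in 8-bit intensity
    units.  ``blobs`` may disable lesions entirely (background-only
    phantoms for degenerate tests).
    """

    n_per_class: tuple[int, int, int] = (50, 50, 50)
    image_size: int = 128
    noise_sd: float = 8.0
    blobs: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be three non-negative counts")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DatasetRecord:
    image: np.ndarray
    label: int
    mask: np.ndarray | None = None


def _head_background(size: int, rng: np.random.Generator, noise_sd: float):
    """Elliptical bright 'head' on a dark field, plus Gaussian noise."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ry, rx = 0.46 * size, 0.38 * size
    d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    # smooth falloff at the skull edge
    head = 90.0 / (1.0 + np.exp(np.clip((d - 1.0) * 12.0, -60.0, 60.0)))
    img = 10.0 + head
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img, d


def _add_blob(img, mask, cy, cx, ry, rx, angle, intensity):
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    ca, sa = np.cos(angle), np.sin(angle)
    dy, dx = yy - cy, xx - cx
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    d = u * u + v * v
    blob = intensity / (1.0 + np.exp(np.clip((d - 1.0) * 10.0, -60.0, 60.0)))
    img += blob
    mask |= d <= 1.0
    return img, mask


def generate_image(
    class_label: int, spec: SyntheticSpec, rng: np.random.Generator
) -> DatasetRecord:
    """One phantom of the requested class; deterministic under the stream."""
    if class_label not in (1, 2, 3):
        raise ValueError("class_label must be 1, 2 or 3")
    size = spec.image_size
    img, d_head = _head_background(size, rng, spec.noise_sd)
    mask = np.zeros((size, size), dtype=bool)
    c = (size - 1) / 2.0

    if spec.blobs:
        if class_label == 1:
            # single round blob toward the head periphery
            ang = rng.uniform(0, 2 * np.pi)
            rad = 0.26 * size
            cy, cx = c + rad * np.sin(ang), c + 0.85 * rad * np.cos(ang)
            r = rng.uniform(0.055, 0.085) * size
            img, mask = _add_blob(img, mask, cy, cx, r, r, 0.0, 130.0)
        elif class_label == 2:
            # small central blob
            cy = c + rng.uniform(-0.03, 0.03) * size
            cx = c + rng.uniform(-0.03, 0.03) * size
            r = rng.uniform(0.030, 0.050) * size
            img, mask = _add_blob(img, mask, cy, cx, r, r, 0.0, 130.0)
        else:
            # large irregular multi-lobed blob
            n_lobes = int(rng.integers(2, 5))
            cy = c + rng.uniform(-0.12, 0.12) * size
            cx = c + rng.uniform(-0.12, 0.12) * size
            for _ in range(n_lobes):
                oy = cy + rng.uniform(-0.06, 0.06) * size
                ox = cx + rng.uniform(-0.06, 0.06) * size
                ry = rng.uniform(0.08, 0.14) * size
                rx = rng.uniform(0.08, 0.14) * size
                ang = rng.uniform(0, np.pi)
                img, mask = _add_blob(img, mask, oy, ox, ry, rx, ang, 110.0)

    img = np.clip(img, 0.0, 255.0).astype(np.uint8)
    return DatasetRecord(image=img, label=class_label, mask=mask)


def generate_dataset(spec: SyntheticSpec) -> list[DatasetRecord]:
    """All records with exact per-class counts, shuffled by the seeded stream."""
    rng = np.random.default_rng(spec.seed)
    records: list[DatasetRecord] = []
    for label, n in zip((1, 2, 3), spec.n_per_class):
        for _ in range(n):
            records.append(generate_image(label, spec, rng))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def write_dataset(records, path) -> None:
    """One legacy .mat container per record + a manifest CSV.

    Fields: ``image`` (uint8), ``label`` (int), ``mask`` (uint8, optional).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        name = f"record_{i:05d}.mat"
        doc = {"image": rec.image, "label": int(rec.label)}
        if rec.mask is not None:
            doc["mask"] = rec.mask.astype(np.uint8)
        scipy.io.savemat(path / name, doc)
        rows.append((name, int(rec.label)))
    with open(path / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)


def _read_mat_record(file: Path) -> DatasetRecord:
    """Read one container; tolerates our dialect, cjdata, and v7.3 HDF5."""
    try:
        doc = scipy.io.loadmat(file, simplify_cells=True)
    except NotImplementedError:  # MATLAB v7.3 = HDF5
        import h5py

        doc = {}
        with h5py.File(file, "r") as fh:
            def pull(group, out):
                for k in group:
                    item = group[k]
                    if hasattr(item, "keys"):
                        out[k] = {}
                        pull(item, out[k])
                    else:
                        out[k] = np.asarray(item)
            pull(fh, doc)
    if "cjdata" in doc:
        doc = doc["cjdata"]
    image = None
    for key in ("image",):
        if key in doc:
            image = np.asarray(doc[key])
    if image is None:
        raise ValueError(f"{file.name}: missing required field 'image'")
    if "label" not in doc:
        raise ValueError(f"{file.name}: missing required field 'label'")
    label = int(np.asarray(doc["label"]).ravel()[0])
    mask = None
    for key in ("mask", "tumorMask"):
        if key in doc:
            mask = np.asarray(doc[key]).astype(bool)
    return DatasetRecord(image=image, label=label, mask=mask)


def read_dataset(path) -> list[DatasetRecord]:
    """Read every .mat container under ``path`` (manifest order if present)."""
    path = Path(path)
    manifest = path / "manifest.csv"
    if manifest.exists():
        with open(manifest, newline="") as fh:
            names = [row["filename"] for row in csv.DictReader(fh)]
        files = [path / n for n in names]
    else:
        files = sorted(path.glob("*.mat"))
    return [_read_mat_record(f) for f in files]


def export_png(records, path) -> list[Path]:
    """8-bit grayscale PNG per record; returns the written paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i, rec in enumerate(records):
        p = path / f"record_{i:05d}_class{rec.label}.png"
        Image.fromarray(rec.image.astype(np.uint8), mode="L").save(p)
        out.append(p)
    return out
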