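"""Point annotations, dataset manifests, and density-map containers.

Conventions: coordinates are 0-based and real-valued, ``x`` is the column and
``y`` the row, origin at the top-left — the same raster convention used
everywhere else in the package.  Annotations travel as JSON
(``{"image_id": ..., "points": [[x, y], ...]}``) or CSV with an ``x,y``
header; manifests as CSV; density maps as an HDF5 dataset named ``density``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PointAnnotationSet", "ManifestEntry", "DatasetManifest",
    "read_points", "write_points", "split_dataset", "select_labeled",
    "read_manifest", "write_manifest", "read_density", "write_density",
]


@dataclass(frozen=True)
class PointAnnotationSet:
    """Per-image shoot coordinates; ``len(points)`` is the ground-truth count."""

    image_id: str
    points: np.ndarray  # (n, 2) float array, columns (x, y)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    @property
    def count(self) -> int:
        return len(self.points)

    def validate_bounds(self, height: int, width: int) -> None:
        p = self.points
        if len(p) and ((p[:, 0] < 0).any() or (p[:, 0] >= width).any()
                       or (p[:, 1] < 0).any() or (p[:, 1] >= height).any()):
            raise ValueError(
                f"{self.image_id}: point outside image bounds {width}x{height}")


@dataclass(frozen=True)
class ManifestEntry:
    image_path: str
    annotation_path: str | None
    split: str            # train | val | test
    labeled: bool


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    labeled_percentage: float = 1.0
    split_seed: int = 0

    def subset(self, split: str | None = None, labeled: bool | None = None):
        out = self.entries
        if split is not None:
            out = [e for e in out if e.split == split]
        if labeled is not None:
            out = [e for e in out if e.labeled == labeled]
        return out

    @property
    def n_labeled_train(self) -> int:
        return len(self.subset("train", labeled=True))

    @property
    def n_unlabeled_train(self) -> int:
        return len(self.subset("train", labeled=False))


# ---------------------------------------------------------------------------
# point annotations
# ---------------------------------------------------------------------------

def read_points(path) -> PointAnnotationSet:
    """Read a point annotation file (JSON or CSV, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        image_id = payload.get("image_id", path.stem)
        raw = payload.get("points", [])
    else:
        frame = pd.read_csv(path)
        if not {"x", "y"} <= set(frame.columns):
            raise ValueError(f"{path}: CSV annotations need an x,y header")
        image_id = path.stem
        raw = frame[["x", "y"]].to_numpy().tolist()
    points = []
    for row_idx, row in enumerate(raw):
        try:
            x, y = float(row[0]), float(row[1])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric coordinate in row {row_idx}") from exc
        if not np.isfinite([x, y]).all() or x < 0 or y < 0:
            raise ValueError(f"{path}: invalid coordinate in row {row_idx}: ({x}, {y})")
        points.append((x, y))
    return PointAnnotationSet(image_id=image_id, points=np.asarray(points).reshape(-1, 2))


def write_points(annotations: PointAnnotationSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"image_id": annotations.image_id,
                   "points": [[float(x), float(y)] for x, y in annotations.points]}
        path.write_text(json.dumps(payload))
    else:
        pd.DataFrame(annotations.points, columns=["x", "y"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splits and labeled-percentage selection
# ---------------------------------------------------------------------------

def split_dataset(image_ids, ratios=(0.7, 0.2, 0.1), seed: int = 0) -> DatasetManifest:
    """Assign ids to train/val/test by a seeded shuffle of the sorted id list.

    Sizes are ``floor(n * ratio)`` for train and val, remainder to test, so a
    313-image dataset at 7:2:1 yields 219 / 62 / 32.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    ids = sorted(str(i) for i in image_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate image ids")
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.floor(n * ratios[1]))
    entries = []
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
        image_id = ids[idx]
        entries.append(ManifestEntry(
            image_path=image_id, annotation_path=None, split=split, labeled=True))
    entries.sort(key=lambda e: e.image_path)
    return DatasetManifest(entries=entries, labeled_percentage=1.0, split_seed=seed)


def select_labeled(manifest: DatasetManifest, percentage: float, seed: int = 0) -> DatasetManifest:
    """Flag ``floor(percentage * train size)`` train entries as labeled.

    The rest of the train split becomes the unlabeled pool; val/test stay
    labeled (they carry ground truth for evaluation).  A 313-image dataset
    split 7:2:1 at 5% keeps exactly 10 labeled training images.
    """
    if not 0 < percentage <= 1:
        raise ValueError("percentage must lie in (0, 1]")
    train = [e for e in manifest.entries if e.split == "train"]
    n_keep = int(np.floor(percentage * len(train)))
    if n_keep == 0:
        raise ValueError(
            f"percentage {percentage} on {len(train)} train images selects 0 labeled "
            "images; training is impossible")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(len(train), size=n_keep, replace=False).tolist())
    train_sorted = sorted(train, key=lambda e: e.image_path)
    labeled_paths = {train_sorted[i].image_path for i in keep}
    entries = []
    for e in manifest.entries:
        if e.split == "train":
            entries.append(replace(e, labeled=e.image_path in labeled_paths))
        else:
            entries.append(replace(e, labeled=True))
    return DatasetManifest(entries=entries, labeled_percentage=float(percentage),
                           split_seed=manifest.split_seed)


def write_manifest(manifest: DatasetManifest, path) -> None:
    frame = pd.DataFrame(
        [(e.image_path, e.annotation_path or "", e.split, int(e.labeled))
         for e in manifest.entries],
        columns=["image_path", "annotation_path", "split", "labeled"])
    frame.attrs["labeled_percentage"] = manifest.labeled_percentage
    frame.to_csv(path, index=False)


def read_manifest(path) -> DatasetManifest:
    frame = pd.read_csv(path, keep_default_na=False)
    entries = [ManifestEntry(image_path=str(r.image_path),
                             annotation_path=(str(r.annotation_path) or None),
                             split=str(r.split), labeled=bool(int(r.labeled)))
               for r in frame.itertuples()]
    return DatasetManifest(entries=entries)


# ---------------------------------------------------------------------------
# density-map container
# ---------------------------------------------------------------------------

def write_density(values: np.ndarray, path, scale: int = 1) -> None:
    """Store a density map as HDF5 dataset 'density' (float32, row-major)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError("density map must be 2-D")
    if not np.isfinite(values).all():
        raise ValueError("density map contains non-finite values")
    if (values < 0).any():
        raise ValueError("density map contains negative values")
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("density", data=values)
        ds.attrs["height"], ds.attrs["width"] = values.shape
        ds.attrs["scale"] = int(scale)


def read_density(path) -> tuple[np.ndarray, int]:
    try:
        with h5py.File(path, "r") as fh:
            if "density" not in fh:
                raise ValueError(f"{path}: no 'density' dataset")
            ds = fh["density"]
            values = np.asarray(ds, dtype=np.float32)
            scale = int(ds.attrs.get("scale", 1))
    except OSError as exc:
        raise OSError(f"{path}: not a readable HDF5 density container") from exc
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError(f"{path}: corrupt density values")
    return values, scale
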