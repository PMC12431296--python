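"""Structured scene features from object-detection outputs.

A per-image detection list (category, bounding box, confidence) over the 80
COCO categories is turned into four interpretable blocks:

* ``f_pres``  in {0,1}^C  — category presence indicators,
* ``f_cnt``   in N^C      — per-category instance counts,
* ``f_conf``  in [0,1]^C  — per-category mean detection confidence (0 if absent),
* ``f_grid``  in R^(C*N^2) — per-category sums of confidences over an N x N
  uniform partition of the image (box-center assignment), flattened row-major.

The concatenation ``f_scene = [f_pres | f_cnt | f_conf | f_grid]`` has length
3C + C*N^2 (960 at C=80, N=3) and feeds the scene classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

N_CATEGORIES = 80
DEFAULT_GRID = 3


def coco_category_names() -> list[str]:
    """The 80 COCO category names, index-aligned with category ids 0..79."""
    with resources.files("neurointent.data").joinpath(
            "coco_categories.json").open() as fh:
        return json.load(fh)


@dataclass
class Detection:
    category: int
    bbox: tuple[float, float, float, float]  # (x, y, w, h), top-left origin, px
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.category < 0:
            raise ValueError("category id must be non-negative")


@dataclass
class DetectionSet:
    """All detections of one image."""

    image_id: int | str
    image_size: tuple[float, float]  # (width, height) px
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image size must be positive")


def build_presence_count(ds: DetectionSet,
                         n_categories: int = N_CATEGORIES
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Presence indicator and instance count per category."""
    pres = np.zeros(n_categories)
    cnt = np.zeros(n_categories)
    for d in ds.detections:
        if d.category >= n_categories:
            raise ValueError(f"category id {d.category} >= C={n_categories}")
        cnt[d.category] += 1
    pres[cnt > 0] = 1.0
    return pres, cnt


def mean_confidence(ds: DetectionSet,
                    n_categories: int = N_CATEGORIES) -> np.ndarray:
    """Arithmetic mean of detection scores per category; 0 where absent."""
    total = np.zeros(n_categories)
    cnt = np.zeros(n_categories)
    for d in ds.detections:
        if d.category >= n_categories:
            raise ValueError(f"category id {d.category} >= C={n_categories}")
        total[d.category] += d.score
        cnt[d.category] += 1
    out = np.zeros(n_categories)
    nz = cnt > 0
    out[nz] = total[nz] / cnt[nz]
    return out


def grid_confidence_map(ds: DetectionSet, n_grid: int = DEFAULT_GRID,
                        n_categories: int = N_CATEGORIES) -> np.ndarray:
    """Per-category confidence mass over an N x N image partition.

    Each detection goes to exactly one cell by its box center:
    ``col = clip(floor(N * cx / W), 0, N-1)`` and likewise for the row, so a
    center sitting exactly on a cell boundary belongs to the higher cell.
    Per-category (row, col) maps are flattened row-major and concatenated.
    """
    if n_grid < 1:
        raise ValueError("grid size must be at least 1")
    w, h = ds.image_size
    grid = np.zeros((n_categories, n_grid, n_grid))
    for d in ds.detections:
        if d.category >= n_categories:
            raise ValueError(f"category id {d.category} >= C={n_categories}")
        x, y, bw, bh = d.bbox
        cx, cy = x + bw / 2.0, y + bh / 2.0
        col = min(max(int(np.floor(n_grid * cx / w)), 0), n_grid - 1)
        row = min(max(int(np.floor(n_grid * cy / h)), 0), n_grid - 1)
        grid[d.category, row, col] += d.score
    return grid.reshape(n_categories * n_grid * n_grid)


def build_scene_vector(ds: DetectionSet, n_grid: int = DEFAULT_GRID,
                       n_categories: int = N_CATEGORIES) -> np.ndarray:
    """Full feature vector ``[f_pres | f_cnt | f_conf | f_grid]``."""
    pres, cnt = build_presence_count(ds, n_categories)
    conf = mean_confidence(ds, n_categories)
    grid = grid_confidence_map(ds, n_grid, n_categories)
    return np.concatenate([pres, cnt, conf, grid])


class SceneFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping DetectionSets to scene feature rows.

    Parameters
    ----------
    n_grid : int, default=3
        Side of the spatial grid.
    score_threshold : float, default=0.25
        Detections below this confidence are dropped before featurization.
    blocks : tuple of str
        Which blocks to emit, in fixed order; subsets support the
        feature-combination ablation (e.g. ``("pres", "cnt")`` is 160-d).
    """

    BLOCK_ORDER = ("pres", "cnt", "conf", "grid")

    def __init__(self, n_grid: int = DEFAULT_GRID,
                 n_categories: int = N_CATEGORIES,
                 score_threshold: float = 0.25,
                 blocks: tuple[str, ...] = BLOCK_ORDER):
        self.n_grid = n_grid
        self.n_categories = n_categories
        self.score_threshold = score_threshold
        self.blocks = blocks

    def fit(self, X=None, y=None) -> "SceneFeaturizer":
        unknown = set(self.blocks) - set(self.BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
        if not self.blocks:
            raise ValueError("at least one feature block is required")
        return self

    def _filter(self, ds: DetectionSet) -> DetectionSet:
        kept = [d for d in ds.detections if d.score >= self.score_threshold]
        return DetectionSet(ds.image_id, ds.image_size, kept)

    def transform_one(self, ds: DetectionSet) -> np.ndarray:
        ds = self._filter(ds)
        pres, cnt = build_presence_count(ds, self.n_categories)
        parts = {
            "pres": pres, "cnt": cnt,
            "conf": mean_confidence(ds, self.n_categories),
            "grid": grid_confidence_map(ds, self.n_grid, self.n_categories),
        }
        return np.concatenate([parts[b] for b in self.BLOCK_ORDER
                               if b in self.blocks])

    def transform(self, X: list[DetectionSet]) -> np.ndarray:
        self.fit()
        return np.stack([self.transform_one(ds) for ds in X])

    @property
    def n_features_out(self) -> int:
        per = {"pres": self.n_categories, "cnt": self.n_categories,
               "conf": self.n_categories,
               "grid": self.n_categories * self.n_grid ** 2}
        return sum(per[b] for b in self.BLOCK_ORDER if b in self.blocks)


def read_coco_detections(path, image_sizes: dict | None = None,
                         default_size: tuple[float, float] = (640.0, 480.0),
                         ) -> list[DetectionSet]:
    """Read COCO detection-results JSON (list of
    ``{image_id, category_id, bbox, score}``) into per-image DetectionSets.

    ``image_sizes`` maps image_id to (width, height); ids without an entry use
    ``default_size``.  Malformed records raise with the offending index.
    """
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError("COCO detection results must be a JSON list")
    per_image: dict = {}
    for i, rec in enumerate(records):
        try:
            img = rec["image_id"]
            det = Detection(int(rec["category_id"]), tuple(rec["bbox"]),
                            float(rec["score"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed detection record #{i}: {exc}") from exc
        per_image.setdefault(img, []).append(det)
    sizes = image_sizes or {}
    return [DetectionSet(img, tuple(sizes.get(img, default_size)), dets)
            for img, dets in per_image.items()]


def write_coco_detections(path, sets: list[DetectionSet]) -> None:
    records = [{"image_id": ds.image_id, "category_id": d.category,
                "bbox": list(d.bbox), "score": d.score}
               for ds in sets for d in ds.detections]
    with open(path, "w") as fh:
        json.dump(records, fh)
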