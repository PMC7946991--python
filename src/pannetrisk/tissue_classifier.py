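"""Five-class tissue annotation: training, whole-slide maps, Jaccard.

Tiles are classified into cancer, cancer/stroma (stroma-rich cancer),
stroma, normal parenchyma and fat.  A slide's classification is a
per-grid-cell 5-class probability map with background cells masked out.
Agreement with pathologist-style ground-truth polygons is measured by the
Jaccard index of the cancer region (argmax in {CANCER, CANCER_STROMA} by
default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from ._nnet import SoftmaxNet, TrainingSchedule, tile_features
from .tiling import CLASS_ORDER, AnnotationRegion, TileImage, TilingResult, tile_slide

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSchedule",
    "ClassProbabilityMap",
    "TissueModel",
    "train_tissue_classifier",
    "classify_tiles",
    "annotate_slide",
    "cancer_region_jaccard",
]

CANCER_CLASSES = ("CANCER", "CANCER_STROMA")


@dataclass
class ClassProbabilityMap:
    """rows×cols×5 tile-class probabilities with a background mask.

    Background cells carry NaN probabilities and must never be read by
    downstream stages.
    """

    grid: np.ndarray  # rows x cols x 5
    background_mask: np.ndarray  # rows x cols, True = background
    class_order: tuple[str, ...] = CLASS_ORDER
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.grid.ndim != 3 or self.grid.shape[2] != len(self.class_order):
            raise ValueError("grid must be rows×cols×n_classes")
        if self.background_mask.shape != self.grid.shape[:2]:
            raise ValueError("mask shape mismatch")
        fg = self.grid[~self.background_mask]
        if fg.size and not np.allclose(fg.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("foreground probabilities must sum to 1")

    @property
    def argmax_classes(self) -> np.ndarray:
        """Per-cell winning class name (object array; background -> None)."""
        out = np.full(self.grid.shape[:2], None, dtype=object)
        fg = ~self.background_mask
        idx = np.nanargmax(np.where(fg[..., None], self.grid, -np.inf), axis=2)
        for i, cls in enumerate(self.class_order):
            out[fg & (idx == i)] = cls
        return out


@dataclass
class TissueModel:
    """Trained 5-class tile classifier: featurizer scaling + softmax net."""

    net: SoftmaxNet
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    class_order: tuple[str, ...]
    tile_size: int
    schedule: TrainingSchedule

    def _featurize(self, tiles: list[TileImage]) -> np.ndarray:
        X = np.stack([tile_features(t.pixels) for t in tiles])
        return (X - self.feature_mean) / self.feature_sd

    def predict_proba(self, tiles: list[TileImage]) -> np.ndarray:
        for t in tiles:
            if t.tile_size != self.tile_size:
                raise ValueError(
                    f"tile size {t.tile_size} does not match training size {self.tile_size}"
                )
        return self.net.predict_proba(self._featurize(tiles))

    def penultimate(self, tiles: list[TileImage]) -> np.ndarray:
        return self.net.penultimate(self._featurize(tiles))


def train_tissue_classifier(
    tiles: list[TileImage],
    labels: list[str],
    schedule: TrainingSchedule | None = None,
    hidden_dims: tuple[int, ...] = (64,),
) -> TissueModel:
    """Train the 5-class tissue classifier on labeled tiles.

    Training runs momentum SGD with per-epoch reshuffling, stopping at the
    first epoch where every class's training accuracy reaches the
    schedule's per-class threshold, else at ``max_epochs`` with a warning.
    """
    schedule = schedule or TrainingSchedule()
    if len(tiles) != len(labels):
        raise ValueError("tiles and labels length mismatch")
    classes = tuple(c for c in CLASS_ORDER if c in set(labels))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    unknown = set(labels) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown labels: {unknown}")
    X = np.stack([tile_features(t.pixels) for t in tiles])
    mean = X.mean(axis=0)
    sd = np.where(X.std(axis=0) < 1e-9, 1.0, X.std(axis=0))
    Xs = (X - mean) / sd
    y = np.array([classes.index(lbl) for lbl in labels])
    net = SoftmaxNet(
        input_dim=X.shape[1],
        n_classes=len(classes),
        hidden_dims=hidden_dims,
        seed=schedule.seed,
    )
    net.fit(Xs, y, schedule)
    return TissueModel(
        net=net,
        feature_mean=mean,
        feature_sd=sd,
        class_order=classes,
        tile_size=tiles[0].tile_size,
        schedule=schedule,
    )


def classify_tiles(model: TissueModel, tiles: list[TileImage]) -> np.ndarray:
    """Per-tile class probability vectors (rows sum to 1)."""
    if not tiles:
        return np.zeros((0, len(model.class_order)))
    return model.predict_proba(tiles)


def annotate_slide(
    model: TissueModel,
    slide: np.ndarray,
    slide_id: str = "",
    downsample: int = 1,
    tiling: TilingResult | None = None,
) -> ClassProbabilityMap:
    """Tile a slide and classify every foreground tile.

    A pre-computed :class:`TilingResult` can be passed to skip re-tiling.
    Probabilities are placed on the tile grid; background cells are masked.
    The map is always emitted over the full 5-class canonical order even
    when the model was trained on fewer classes (missing classes get 0).
    """
    if tiling is None:
        tiling = tile_slide(
            slide, tile_size=model.tile_size, downsample=downsample, slide_id=slide_id
        )
    rows, cols = tiling.grid_shape
    grid = np.full((rows, cols, len(CLASS_ORDER)), np.nan)
    mask = np.ones((rows, cols), dtype=bool)
    if tiling.tiles:
        probs = model.predict_proba(tiling.tiles)
        for tile, p in zip(tiling.tiles, probs):
            full = np.zeros(len(CLASS_ORDER))
            for j, cls in enumerate(model.class_order):
                full[CLASS_ORDER.index(cls)] = p[j]
            grid[tile.grid_row, tile.grid_col] = full
            mask[tile.grid_row, tile.grid_col] = False
    return ClassProbabilityMap(grid=grid, background_mask=mask, slide_id=slide_id)


def rasterize_truth_grid(
    annotations: list[AnnotationRegion],
    grid_shape: tuple[int, int],
    tile_size: int,
    downsample: int = 1,
) -> np.ndarray:
    """Predominant ground-truth class per grid cell (object array, None = uncovered).

    Polygons are given in level-0 pixel coordinates; the grid lives on the
    downsampled slide, so cell windows are scaled back up by ``downsample``.
    """
    rows, cols = grid_shape
    out = np.full((rows, cols), None, dtype=object)
    step = tile_size * downsample
    polys = [(a.shapely, a.tissue_class) for a in annotations]
    for r in range(rows):
        for c in range(cols):
            window = box(c * step, r * step, (c + 1) * step, (r + 1) * step)
            areas: dict[str, float] = {}
            for poly, cls in polys:
                a = poly.intersection(window).area
                if a > 0:
                    areas[cls] = areas.get(cls, 0.0) + a
            if areas:
                best = max(areas.values())
                winners = sorted(
                    (c_ for c_, a in areas.items() if abs(a - best) < 1e-9),
                    key=CLASS_ORDER.index,
                )
                out[r, c] = winners[0]
    return out


def cancer_region_jaccard(
    cls_map: ClassProbabilityMap,
    truth: list[AnnotationRegion],
    tile_size: int | None = None,
    downsample: int = 1,
    cancer_classes: tuple[str, ...] = CANCER_CLASSES,
) -> float:
    """Jaccard index of predicted vs true cancer regions over grid cells.

    Predicted cancer = foreground cells whose argmax class is in
    ``cancer_classes``; true cancer = cells whose predominant annotation
    class is in ``cancer_classes``.  Background cells are excluded from
    both sets.  Empty union is defined as 1 when both sets are empty.
    """
    if tile_size is None:
        tile_size = 150
    truth_grid = rasterize_truth_grid(truth, cls_map.grid.shape[:2], tile_size, downsample)
    fg = ~cls_map.background_mask
    pred_cls = cls_map.argmax_classes
    pred_cancer = fg & np.isin(pred_cls, cancer_classes)
    true_cancer = fg & np.isin(truth_grid, cancer_classes)
    union = np.logical_or(pred_cancer, true_cancer).sum()
    if union == 0:
        logger.info("empty prediction and truth cancer regions: Jaccard defined as 1")
        return 1.0
    inter = np.logical_and(pred_cancer, true_cancer).sum()
    return float(inter / union)
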