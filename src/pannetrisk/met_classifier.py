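"""Metastasis-association tile scoring.

Tiles confidently annotated (≥95% class probability) as cancer or as
cancer-adjacent stroma are relabeled with their patient's distant
metastasis status — a deliberately noisy, patient-level label — and a
binary classifier per compartment is trained under grouped five-fold
cross-validation (all slides of a patient share a fold).  Each validation
tile receives a softmax metastasis probability; diagnostics include
confusion-matrix sweeps over output-probability thresholds, UMAP embedding
of penultimate activations, and Gaussian-kernel bivariate density surfaces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from ._nnet import SoftmaxNet, TrainingSchedule, tile_features
from .eval_survival import ConfusionCounts, confusion_metrics
from .tiling import CLASS_ORDER, TileImage
from .tissue_classifier import ClassProbabilityMap

logger = logging.getLogger(__name__)

__all__ = [
    "MetScoreMap",
    "FoldAssignment",
    "MetModel",
    "MET_TRAINING_SCHEDULE",
    "DEFAULT_SWEEP_THRESHOLDS",
    "select_high_confidence_tiles",
    "grouped_kfold",
    "train_met_classifier",
    "score_tiles",
    "threshold_sweep",
    "embed_umap",
    "kde_density",
]

COMPARTMENTS = ("CANCER", "STROMA")

# Reference schedule for the metastasis classifier: exactly 15 epochs,
# lr 1e-4 decayed ×0.1 after epoch 5, momentum 0.9, L2 1e-4.
MET_TRAINING_SCHEDULE = TrainingSchedule(
    learning_rate=1e-4,
    momentum=0.9,
    batch_size=35,
    max_epochs=15,
    per_class_accuracy_stop=None,
    lr_decay_factor=0.1,
    lr_decay_after_epochs=5,
    l2_penalty=1e-4,
)

DEFAULT_SWEEP_THRESHOLDS = (0.5, 0.9, 0.99, 0.999, 0.9999, 0.99999)


@dataclass
class MetScoreMap:
    """Per-tile metastasis probability grid for one compartment."""

    scores: np.ndarray  # rows x cols floats in [0, 1]
    valid_mask: np.ndarray  # rows x cols bool
    compartment: str
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError("compartment must be CANCER or STROMA")
        if self.scores.shape != self.valid_mask.shape:
            raise ValueError("scores and valid_mask shape mismatch")
        vals = self.scores[self.valid_mask]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("scores must be in [0, 1]")

    @property
    def valid_scores(self) -> np.ndarray:
        return self.scores[self.valid_mask]


@dataclass
class FoldAssignment:
    """Patient-grouped fold ids per slide."""

    fold_of_slide: dict[str, int]
    patient_of_slide: dict[str, str]
    k: int

    def validation_slides(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_slide.items() if f == fold]

    def training_slides(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_slide.items() if f != fold]


def select_high_confidence_tiles(
    cls_map: ClassProbabilityMap,
    compartment: str,
    threshold: float = 0.95,
    adjacency_radius: int = 10,
) -> np.ndarray:
    """Boolean mask of grid cells eligible for metastasis scoring.

    CANCER compartment: cells with p(CANCER) ≥ threshold.  STROMA
    compartment: cells with p(STROMA) ≥ threshold that lie within
    Chebyshev distance ``adjacency_radius`` of a cancer cell (argmax in
    {CANCER, CANCER_STROMA}) — only cancer-adjacent stroma is informative.
    The confidence filter uses the compartment class's own probability.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError("compartment must be CANCER or STROMA")
    fg = ~cls_map.background_mask
    prob = np.where(fg, cls_map.grid[..., CLASS_ORDER.index(compartment)], np.nan)
    with np.errstate(invalid="ignore"):
        selected = fg & (prob >= threshold)
    if compartment == "STROMA":
        cancer_cells = np.isin(cls_map.argmax_classes, ("CANCER", "CANCER_STROMA"))
        if adjacency_radius > 0:
            size = 2 * adjacency_radius + 1
            near_cancer = ndimage.maximum_filter(
                cancer_cells.astype(np.uint8), size=size, mode="constant", cval=0
            ).astype(bool)
        else:
            near_cancer = cancer_cells
        selected &= near_cancer
    if not selected.any():
        warnings.warn(
            f"no high-confidence {compartment} tiles at threshold {threshold}", stacklevel=2
        )
    return selected


def grouped_kfold(
    patient_ids: list[str],
    slides_of_patient: dict[str, list[str]],
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Partition patients into k folds balanced within ±1 patient.

    All slides of a patient share a fold, so no patient's tiles ever
    appear on both sides of a train/validation split.
    """
    patients = list(patient_ids)
    if k > len(patients):
        raise ValueError("k cannot exceed the number of patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_slide: dict[str, int] = {}
    patient_of_slide: dict[str, str] = {}
    for pos, idx in enumerate(order):
        pid = patients[idx]
        fold = pos % k
        for sid in slides_of_patient[pid]:
            fold_of_slide[sid] = fold
            patient_of_slide[sid] = pid
    return FoldAssignment(fold_of_slide=fold_of_slide, patient_of_slide=patient_of_slide, k=k)


@dataclass
class MetModel:
    """Binary metastasis-association tile classifier."""

    net: SoftmaxNet
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    schedule: TrainingSchedule

    def _featurize(self, tiles: list[TileImage]) -> np.ndarray:
        X = np.stack([tile_features(t.pixels) for t in tiles])
        return (X - self.feature_mean) / self.feature_sd

    def score(self, tiles: list[TileImage]) -> np.ndarray:
        """p(metastasis) per tile."""
        return self.net.predict_proba(self._featurize(tiles))[:, 1]

    def penultimate(self, tiles: list[TileImage]) -> np.ndarray:
        return self.net.penultimate(self._featurize(tiles))


def train_met_classifier(
    tiles: list[TileImage],
    patient_labels: list[int],
    schedule: TrainingSchedule = MET_TRAINING_SCHEDULE,
    hidden_dims: tuple[int, ...] = (1024,),
    class_balanced: bool = True,
) -> MetModel:
    """Train a metastasis-association classifier on compartment tiles.

    Labels are the (noisy) patient-level metastasis statuses of the tiles'
    patients.  By default the loss is class-balanced (inverse-frequency
    sample weights): the cohort is ~20% metastatic, and balancing
    calibrates the softmax so a score ≥ 0.5 means the tile's appearance
    favors metastasis rather than that the posterior beats a 4:1 prior.
    The default hidden layer is 1024-dim so the penultimate activations
    match the embedding contract; tests use smaller layers.
    """
    if schedule.max_epochs <= 0:
        raise ValueError("schedule must run at least one epoch")
    y = np.asarray(patient_labels, dtype=int)
    if len(tiles) != y.size:
        raise ValueError("tiles and labels length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("both metastasis labels must be present in training data")
    X = np.stack([tile_features(t.pixels) for t in tiles])
    mean = X.mean(axis=0)
    sd = np.where(X.std(axis=0) < 1e-9, 1.0, X.std(axis=0))
    net = SoftmaxNet(
        input_dim=X.shape[1], n_classes=2, hidden_dims=hidden_dims, seed=schedule.seed
    )
    weight = None
    if class_balanced:
        freq = np.bincount(y, minlength=2) / y.size
        weight = 1.0 / freq[y]
    net.fit((X - mean) / sd, y, schedule, sample_weight=weight)
    return MetModel(net=net, feature_mean=mean, feature_sd=sd, schedule=schedule)


def score_tiles(
    model: MetModel,
    tiles: list[TileImage],
    grid_shape: tuple[int, int],
    compartment: str,
    slide_id: str = "",
) -> MetScoreMap:
    """Score tiles and assemble them into a MetScoreMap fragment.

    Cells without a scored tile are invalid; the tile's label is
    p(metastasis) ≥ 0.5 (ties classify as metastasis).
    """
    scores = np.zeros(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    if tiles:
        p = model.score(tiles)
        for tile, s in zip(tiles, p):
            scores[tile.grid_row, tile.grid_col] = s
            mask[tile.grid_row, tile.grid_col] = True
    return MetScoreMap(scores=scores, valid_mask=mask, compartment=compartment, slide_id=slide_id)


def threshold_sweep(
    scores: np.ndarray,
    true_labels: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_SWEEP_THRESHOLDS,
) -> pd.DataFrame:
    """Confusion counts and metrics per output-probability threshold.

    At threshold τ only tiles whose winning-class probability
    ``max(p, 1-p)`` is ≥ τ are retained; predictions are p ≥ 0.5.
    Thresholds retaining zero tiles produce a row of null metrics.
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    for t in thresholds:
        if not (0.5 <= t < 1.0):
            raise ValueError("thresholds must lie in [0.5, 1)")
    rows = []
    conf = np.maximum(scores, 1.0 - scores)
    pred = (scores >= 0.5).astype(int)
    for t in thresholds:
        keep = conf >= t
        row: dict = {"threshold": t, "retained": int(keep.sum())}
        if keep.sum() == 0:
            logger.info("threshold %.5f retains zero tiles", t)
            row.update({k: np.nan for k in ("tp", "fp", "tn", "fn")})
            rows.append(row)
            continue
        yt, yp = true_labels[keep], pred[keep]
        c = ConfusionCounts(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )
        row.update({"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn})
        row.update(confusion_metrics(c).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def embed_umap(
    activations: np.ndarray, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
) -> np.ndarray:
    """UMAP reduction of penultimate activations (n×D) to n×2."""
    import umap

    X = np.asarray(activations, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("activations must be an n×D matrix with D ≥ 2")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples to embed")
    if X.shape[0] <= n_neighbors:
        raise ValueError("n must exceed the n_neighbors parameter")
    reducer = umap.UMAP(n_components=2, random_state=seed, n_neighbors=n_neighbors, min_dist=min_dist)
    return reducer.fit_transform(X)


def kde_density(
    embedding: np.ndarray, grid_resolution: int = 100, padding: float = 0.15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel bivariate density over a regular grid.

    Returns (x_grid, y_grid, density); the numeric integral over the grid
    is within 2% of 1 for non-degenerate samples.  Degenerate (collinear)
    samples fall back to a jittered fit with a warning.
    """
    pts = np.asarray(embedding, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("embedding must be n×2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    try:
        kde = gaussian_kde(pts.T)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate sample: falling back to jittered bandwidth", stacklevel=2)
        rng = np.random.default_rng(0)
        scale = max(pts.std(), 1e-3)
        kde = gaussian_kde((pts + rng.normal(0, 1e-3 * scale, pts.shape)).T)
    span_x = pts[:, 0].max() - pts[:, 0].min()
    span_y = pts[:, 1].max() - pts[:, 1].min()
    # pad by a fraction of the span plus several kernel bandwidths so the
    # grid captures essentially all of the density mass
    pad_x = padding * span_x + 5.0 * kde.factor * max(pts[:, 0].std(), 1e-3)
    pad_y = padding * span_y + 5.0 * kde.factor * max(pts[:, 1].std(), 1e-3)
    xs = np.linspace(pts[:, 0].min() - pad_x, pts[:, 0].max() + pad_x, grid_resolution)
    ys = np.linspace(pts[:, 1].min() - pad_y, pts[:, 1].max() + pad_y, grid_resolution)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return xx, yy, dens
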