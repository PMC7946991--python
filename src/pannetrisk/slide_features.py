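"""Whole-slide feature extraction from metastasis score maps.

A slide's cancer and stroma score maps are reduced to an ordered vector of
150 named features (75 per compartment, cancer block first):

* 4 whole-distribution moments (mean, sd, skewness, excess kurtosis);
* 12 probability bands × {count, proportion} = 24;
* 8 tail-restricted moments (scores > 0.9 and < 0.1, 4 moments each);
* 1 valid-tile count;
* 4 extremes (min, max, median, IQR);
* 4 moments of per-block mean scores over complete 10×10 blocks;
* 30 spatial cluster-histogram counts: per 10×10 block, tiles above a
  score threshold are counted and the per-block counts histogrammed into
  width-2 bins {0-1, 2-3, ..., 16-17, ≥18}, at thresholds 0.5/0.9/0.99.

Before extraction, isolated tiles are removed by the neighbor artifact
filter (a tile survives only with enough same-compartment valid
8-neighbors; defaults 8 for cancer, 3 for stroma).  Missing values
(moments of degenerate distributions, empty compartments) are imputed
across slides by chained equations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .met_classifier import MetScoreMap

__all__ = [
    "PROBABILITY_BANDS",
    "CLUSTER_BINS",
    "CLUSTER_THRESHOLDS",
    "ClusterBinSpec",
    "feature_schema",
    "reduced_feature_names",
    "neighbor_filter",
    "block_cluster_histogram",
    "extract_slide_features",
    "impute_missing",
    "NEIGHBOR_THRESHOLDS",
]

BLOCK = 10  # spatial aggregation block, in tiles

# Narrow high bands mirror the published feature naming
# ("Prob >=0.9999 and <0.99999"); the last band is closed at 1.
PROBABILITY_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 1e-5),
    (1e-5, 1e-4),
    (1e-4, 1e-3),
    (1e-3, 1e-2),
    (1e-2, 0.1),
    (0.1, 0.5),
    (0.5, 0.9),
    (0.9, 0.99),
    (0.99, 0.999),
    (0.999, 0.9999),
    (0.9999, 0.99999),
    (0.99999, 1.0),
)

# width-2 count bins over positives per 10×10 block: 0-1, 2-3, ..., 16-17, >=18
CLUSTER_BINS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 1) for lo in range(0, 18, 2)
) + ((18, BLOCK * BLOCK),)

CLUSTER_THRESHOLDS: tuple[float, ...] = (0.5, 0.9, 0.99)

NEIGHBOR_THRESHOLDS = {"CANCER": 8, "STROMA": 3}


@dataclass(frozen=True)
class ClusterBinSpec:
    """Score threshold plus count bins for the spatial cluster histogram."""

    score_threshold: float
    bins: tuple[tuple[int, int], ...] = CLUSTER_BINS

    def __post_init__(self) -> None:
        covered = sorted(r for b in self.bins for r in range(b[0], b[1] + 1))
        if covered != list(range(0, BLOCK * BLOCK + 1)):
            raise ValueError("bins must partition {0..100}")


def _band_name(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})" if hi < 1.0 else f"[{lo:g},1]"


def feature_schema() -> list[dict]:
    """The versioned 150-feature registry (ordered; cancer block first)."""
    schema: list[dict] = []
    for comp in ("cancer", "stroma"):
        for m in ("mean", "sd", "skewness", "kurtosis"):
            schema.append({"name": f"{comp}_{m}", "compartment": comp, "category": "moment"})
        for lo, hi in PROBABILITY_BANDS:
            schema.append(
                {
                    "name": f"{comp}_count_{_band_name(lo, hi)}",
                    "compartment": comp,
                    "category": "band_count",
                    "band": [lo, hi],
                }
            )
            schema.append(
                {
                    "name": f"{comp}_prop_{_band_name(lo, hi)}",
                    "compartment": comp,
                    "category": "band_proportion",
                    "band": [lo, hi],
                }
            )
        for tail in ("high", "low"):
            for m in ("mean", "sd", "skewness", "kurtosis"):
                schema.append(
                    {
                        "name": f"{comp}_{tail}_tail_{m}",
                        "compartment": comp,
                        "category": "tail_moment",
                        "tail": tail,
                    }
                )
        schema.append({"name": f"{comp}_n_valid", "compartment": comp, "category": "count"})
        for m in ("min", "max", "median", "iqr"):
            schema.append({"name": f"{comp}_{m}", "compartment": comp, "category": "extreme"})
        for m in ("mean", "sd", "skewness", "kurtosis"):
            schema.append(
                {"name": f"{comp}_blockmean_{m}", "compartment": comp, "category": "block_moment"}
            )
        for thr in CLUSTER_THRESHOLDS:
            for lo, hi in CLUSTER_BINS:
                schema.append(
                    {
                        "name": f"{comp}_clusters_t{thr:g}_bin{lo}_{hi}",
                        "compartment": comp,
                        "category": "cluster_histogram",
                        "threshold": thr,
                        "bin": [lo, hi],
                    }
                )
    assert len(schema) == 150
    return schema


FEATURE_NAMES: list[str] = [f["name"] for f in feature_schema()]


def reduced_feature_names() -> list[str]:
    """The reduced schema for the generalization analysis.

    Only binary (score ≥ 0.5) counts/proportions and one broad high
    (> 0.9) and low (< 0.1) representation per compartment.
    """
    names = []
    for comp in ("cancer", "stroma"):
        names += [
            f"{comp}_count_ge_0.5",
            f"{comp}_prop_ge_0.5",
            f"{comp}_count_gt_0.9",
            f"{comp}_prop_gt_0.9",
            f"{comp}_count_lt_0.1",
            f"{comp}_prop_lt_0.1",
        ]
    return names


def reduced_feature_table(full: pd.DataFrame) -> pd.DataFrame:
    """Derive the reduced schema from a full 150-feature table.

    Band counts/proportions aggregate exactly onto the broad cut points
    (0.1, 0.5, 0.9 are all band edges).
    """
    out = pd.DataFrame(index=full.index)
    for comp in ("cancer", "stroma"):
        def _sum(kind: str, bands) -> pd.Series:
            cols = [f"{comp}_{kind}_{_band_name(lo, hi)}" for lo, hi in bands]
            return full[cols].sum(axis=1)

        ge_half = [b for b in PROBABILITY_BANDS if b[0] >= 0.5]
        gt_high = [b for b in PROBABILITY_BANDS if b[0] >= 0.9]
        lt_low = [b for b in PROBABILITY_BANDS if b[1] <= 0.1]
        out[f"{comp}_count_ge_0.5"] = _sum("count", ge_half)
        out[f"{comp}_prop_ge_0.5"] = _sum("prop", ge_half)
        out[f"{comp}_count_gt_0.9"] = _sum("count", gt_high)
        out[f"{comp}_prop_gt_0.9"] = _sum("prop", gt_high)
        out[f"{comp}_count_lt_0.1"] = _sum("count", lt_low)
        out[f"{comp}_prop_lt_0.1"] = _sum("prop", lt_low)
    return out


# --------------------------------------------------------------------------
# Neighbor artifact filter
# --------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def neighbor_filter(score_map: MetScoreMap, min_same_neighbors: int | None = None) -> MetScoreMap:
    """Remove tiles without enough same-compartment valid 8-neighbors.

    Single pass: neighbor counts are computed on the input mask, not
    iterated to a fixpoint.  Defaults: 8 neighbors for cancer, 3 for
    stroma.
    """
    if min_same_neighbors is None:
        min_same_neighbors = NEIGHBOR_THRESHOLDS[score_map.compartment]
    if not (0 <= min_same_neighbors <= 8):
        raise ValueError("min_same_neighbors must be in [0, 8]")
    counts = ndimage.convolve(
        score_map.valid_mask.astype(np.int64), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )
    survivors = score_map.valid_mask & (counts >= min_same_neighbors)
    if score_map.valid_mask.any() and not survivors.any():
        warnings.warn("neighbor filter removed every valid tile", stacklevel=2)
    return MetScoreMap(
        scores=np.where(survivors, score_map.scores, 0.0),
        valid_mask=survivors,
        compartment=score_map.compartment,
        slide_id=score_map.slide_id,
    )


# --------------------------------------------------------------------------
# Spatial cluster histogram
# --------------------------------------------------------------------------


def _block_positive_counts(score_map: MetScoreMap, threshold: float) -> np.ndarray:
    """Positives per complete 10×10 block anchored at the grid origin."""
    rows, cols = score_map.scores.shape
    br, bc = rows // BLOCK, cols // BLOCK
    if br == 0 or bc == 0:
        return np.zeros(0, dtype=int)
    pos = score_map.valid_mask & (score_map.scores >= threshold)
    trimmed = pos[: br * BLOCK, : bc * BLOCK]
    return (
        trimmed.reshape(br, BLOCK, bc, BLOCK).sum(axis=(1, 3)).ravel().astype(int)
    )


def block_cluster_histogram(score_map: MetScoreMap, spec: ClusterBinSpec) -> np.ndarray:
    """Histogram of per-block positive-tile counts over the spec's bins."""
    counts = _block_positive_counts(score_map, spec.score_threshold)
    if counts.size == 0:
        warnings.warn("grid smaller than one 10×10 block: all-zero histogram", stacklevel=2)
        return np.zeros(len(spec.bins), dtype=int)
    hist = np.zeros(len(spec.bins), dtype=int)
    for i, (lo, hi) in enumerate(spec.bins):
        hist[i] = int(((counts >= lo) & (counts <= hi)).sum())
    return hist


# --------------------------------------------------------------------------
# Feature extraction
# --------------------------------------------------------------------------


def _moments(x: np.ndarray) -> dict[str, float]:
    out = {"mean": np.nan, "sd": np.nan, "skewness": np.nan, "kurtosis": np.nan}
    if x.size >= 1:
        out["mean"] = float(np.mean(x))
    if x.size >= 2:
        out["sd"] = float(np.std(x, ddof=1))
    if x.size >= 3 and np.std(x) > 0:
        out["skewness"] = float(sps.skew(x))
    if x.size >= 4 and np.std(x) > 0:
        out["kurtosis"] = float(sps.kurtosis(x))
    return out


def _compartment_features(score_map: MetScoreMap) -> dict[str, float]:
    comp = score_map.compartment.lower()
    vals = score_map.valid_scores
    n = int(vals.size)
    feats: dict[str, float] = {}
    for m, v in _moments(vals).items():
        feats[f"{comp}_{m}"] = v
    for lo, hi in PROBABILITY_BANDS:
        if hi < 1.0:
            cnt = int(((vals >= lo) & (vals < hi)).sum())
        else:
            cnt = int(((vals >= lo) & (vals <= hi)).sum())
        feats[f"{comp}_count_{_band_name(lo, hi)}"] = cnt
        feats[f"{comp}_prop_{_band_name(lo, hi)}"] = cnt / n if n else np.nan
    for tail, sel in (("high", vals[vals > 0.9]), ("low", vals[vals < 0.1])):
        for m, v in _moments(sel).items():
            feats[f"{comp}_{tail}_tail_{m}"] = v
    feats[f"{comp}_n_valid"] = n
    feats[f"{comp}_min"] = float(vals.min()) if n else np.nan
    feats[f"{comp}_max"] = float(vals.max()) if n else np.nan
    feats[f"{comp}_median"] = float(np.median(vals)) if n else np.nan
    feats[f"{comp}_iqr"] = (
        float(np.percentile(vals, 75) - np.percentile(vals, 25)) if n else np.nan
    )
    # per-block mean scores over complete blocks (blocks with no valid tile skipped)
    rows, cols = score_map.scores.shape
    br, bc = rows // BLOCK, cols // BLOCK
    block_means = []
    for i in range(br):
        for j in range(bc):
            m = score_map.valid_mask[i * BLOCK : (i + 1) * BLOCK, j * BLOCK : (j + 1) * BLOCK]
            s = score_map.scores[i * BLOCK : (i + 1) * BLOCK, j * BLOCK : (j + 1) * BLOCK]
            if m.any():
                block_means.append(float(s[m].mean()))
    for m, v in _moments(np.asarray(block_means)).items():
        feats[f"{comp}_blockmean_{m}"] = v
    for thr in CLUSTER_THRESHOLDS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hist = block_cluster_histogram(score_map, ClusterBinSpec(thr))
        for (lo, hi), h in zip(CLUSTER_BINS, hist):
            feats[f"{comp}_clusters_t{thr:g}_bin{lo}_{hi}"] = int(h)
    return feats


def extract_slide_features(
    cancer_map: MetScoreMap, stroma_map: MetScoreMap
) -> pd.Series:
    """The ordered 150-feature vector for one slide.

    Maps are expected to be neighbor-filtered.  Features undefined on
    degenerate input (moments of too-few or constant tiles, statistics of
    an empty compartment) are emitted as NaN and flagged for imputation.
    """
    if cancer_map.compartment != "CANCER" or stroma_map.compartment != "STROMA":
        raise ValueError("expected (cancer_map, stroma_map) in that order")
    if not cancer_map.valid_mask.any() and not stroma_map.valid_mask.any():
        warnings.warn("both compartments empty: all-missing feature vector", stacklevel=2)
    feats = {}
    feats.update(_compartment_features(cancer_map))
    feats.update(_compartment_features(stroma_map))
    vec = pd.Series(feats, dtype=float).reindex(FEATURE_NAMES)
    assert vec.index.tolist() == FEATURE_NAMES
    return vec


def schema_json() -> str:
    """The feature registry as JSON (name, compartment, category, params)."""
    return json.dumps(feature_schema(), indent=1)


# --------------------------------------------------------------------------
# Chained-equation imputation
# --------------------------------------------------------------------------


def impute_missing(
    feature_table: pd.DataFrame, iterations: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Multivariate imputation by chained equations (default 10 iterations).

    Observed entries are left unchanged; the result has no missing values
    and is deterministic per seed.  A fully missing column is an error.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    fully_missing = [c for c in feature_table.columns if feature_table[c].isna().all()]
    if fully_missing:
        raise ValueError(f"fully missing feature(s): {fully_missing}")
    if not feature_table.isna().any().any():
        return feature_table.copy()
    imputer = IterativeImputer(max_iter=iterations, random_state=seed, keep_empty_features=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = imputer.fit_transform(feature_table.to_numpy(dtype=float))
    out = pd.DataFrame(values, index=feature_table.index, columns=feature_table.columns)
    observed = ~feature_table.isna()
    out[observed] = feature_table[observed]
    return out
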