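"""Synthetic slides, annotations, cohorts and score maps.

Real PanNET whole-slide images cannot be redistributed, so every pipeline
stage is exercised on synthetic material that reproduces the *statistical
structure* the method relies on rather than H&E appearance:

* five visually distinct tissue textures (blob-noise fields on hue-tinted
  backgrounds) that a linear classifier on pixel statistics separates,
  guaranteeing the tissue classifier has learnable signal;
* mosaic slides whose ground truth is carried as tile-aligned polygons,
  mimicking pathologist region annotations;
* a patient cohort matching the study marginals (89 patients, 104 slides,
  75 single-slide patients, 20% metastatic) with exponential
  metastasis-free-survival times under a planted hazard ratio;
* a planted texture shift (higher blob density) in the cancer/stroma
  regions of metastatic patients, which the metastasis-association
  classifier downstream must recover;
* direct score-map constructions for exercising the spatial feature
  extractor against known hotspot counts.

All generators are pure functions of their seed and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .tiling import AnnotationRegion, TileImage, CLASS_ORDER

__all__ = [
    "TextureParams",
    "CohortConfig",
    "PatientRecord",
    "DEFAULT_TEXTURES",
    "make_texture_tile",
    "shifted_textures",
    "make_synthetic_slide",
    "make_cohort",
    "cohort_to_frame",
    "make_score_map",
    "write_slide",
    "write_annotations",
]


@dataclass(frozen=True)
class TextureParams:
    """Rendering parameters of one synthetic tissue class.

    ``blob_density`` is expressed as blobs per 100×100 px.  For metastatic
    patients ``outcome_shift`` is added to ``blob_density`` in cancer and
    stroma regions — this is the planted, recoverable outcome signal.
    """

    tissue_class: str
    base_hue: float  # degrees in [0, 360)
    blob_density: float  # blobs per 100x100 px
    blob_radius_px: float
    noise_sd: float  # gray levels
    outcome_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue_class not in CLASS_ORDER:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if not (0 <= self.base_hue < 360):
            raise ValueError("base_hue must be in [0, 360)")
        if self.blob_density < 0:
            raise ValueError("blob_density must be non-negative")
        if self.blob_radius_px <= 0:
            raise ValueError("blob_radius_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Default texture set: hue-separated classes; metastatic shift concentrated
# in the cancer/stroma compartments (roughly +50% blob density).
DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "CANCER": TextureParams("CANCER", 300.0, 12.0, 6.0, 6.0, outcome_shift=6.0),
    "CANCER_STROMA": TextureParams("CANCER_STROMA", 330.0, 8.0, 4.0, 6.0, outcome_shift=3.0),
    "STROMA": TextureParams("STROMA", 20.0, 4.0, 5.0, 6.0, outcome_shift=2.0),
    "NORMAL": TextureParams("NORMAL", 270.0, 6.0, 3.0, 6.0),
    "FAT": TextureParams("FAT", 60.0, 1.0, 8.0, 4.0),
}


def shifted_textures(
    textures: dict[str, TextureParams], metastatic: bool
) -> dict[str, TextureParams]:
    """Texture set for one patient: apply ``outcome_shift`` if metastatic."""
    if not metastatic:
        return dict(textures)
    return {
        name: replace(p, blob_density=p.blob_density + p.outcome_shift)
        for name, p in textures.items()
    }


def _base_color(params: TextureParams) -> np.ndarray:
    """Background RGB (0-255 floats) for a texture class."""
    rgb = hsv_to_rgb([params.base_hue / 360.0, 0.45, 0.85])
    return np.asarray(rgb) * 255.0


def make_texture_tile(
    params: TextureParams, size: int = 150, seed: int = 0
) -> TileImage:
    """Render one square blob-noise texture tile.

    Gaussian blobs (count Poisson with mean ``blob_density`` scaled to the
    tile area) darken a hue-tinted background; i.i.d. Gaussian pixel noise
    of ``noise_sd`` gray levels is added.  Deterministic per (params, seed).
    """
    if size < 16:
        raise ValueError("tile size must be at least 16 px")
    rng = np.random.default_rng(seed)
    img = np.tile(_base_color(params), (size, size, 1))
    mean_blobs = params.blob_density * (size * size) / 1e4
    n_blobs = int(rng.poisson(mean_blobs)) if mean_blobs > 0 else 0
    if n_blobs > 0:
        yy, xx = np.mgrid[0:size, 0:size]
        bump = np.zeros((size, size))
        centers = rng.uniform(0, size, size=(n_blobs, 2))
        r2 = 2.0 * params.blob_radius_px**2
        for cy, cx in centers:
            bump += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / r2)
        # blobs darken the tile toward a deeper shade of the same hue
        img -= np.clip(bump, 0, 1.5)[..., None] * np.array([60.0, 80.0, 40.0])
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return TileImage(pixels=pixels, grid_row=0, grid_col=0, slide_id="synthetic")


def _layout_class_grid(
    rows: int, cols: int, classes: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Tile-aligned rectangular layout with every class present.

    Emulates a tumor-dominant resection slide: the upper ~2/3 band holds
    the tumor compartments (cancer on the widest strip, roughly 60% of
    the band, flanked by stroma-rich cancer and stroma), the lower band
    normal parenchyma and fat.  Strip boundaries are jittered by the
    seed.
    """
    grid = np.empty((rows, cols), dtype=object)
    split = int(round(rows * 2 / 3)) + int(rng.integers(-1, 2))
    split = int(np.clip(split, 1, rows - 1))
    order = list(classes)
    top, bottom = order[:3], order[3:]
    # cancer strip ~60% of width, the rest split between the other two
    w_cancer = max(1, int(round(cols * 0.6)) + int(rng.integers(-1, 2)))
    w_cancer = min(w_cancer, cols - 2)
    w_rest = cols - w_cancer
    w_mid = max(1, w_rest // 2 + int(rng.integers(0, 2)))
    w_mid = min(w_mid, w_rest - 1)
    widths = [w_cancer, w_mid, w_rest - w_mid]
    start = 0
    for cls, w in zip(top, widths):
        grid[:split, start : start + w] = cls
        start += w
    cut = int(rng.integers(1, cols))
    grid[split:, :cut] = bottom[0]
    grid[split:, cut:] = bottom[1] if len(bottom) > 1 else bottom[0]
    return grid


def _rect_polygon(r0: int, c0: int, r1: int, c1: int, tile_px: int) -> list[tuple[float, float]]:
    """Pixel-coordinate rectangle (x, y vertex order) for a tile-index box."""
    x0, y0 = c0 * tile_px, r0 * tile_px
    x1, y1 = c1 * tile_px, r1 * tile_px
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


def make_synthetic_slide(
    layout_seed: int,
    texture_set: dict[str, TextureParams] | None = None,
    grid: tuple[int, int] = (8, 8),
    tile_px: int = 150,
    slide_id: str = "synthetic",
    layout: np.ndarray | None = None,
) -> tuple[np.ndarray, list[AnnotationRegion], np.ndarray]:
    """Render a mosaic slide and its ground-truth region polygons.

    Returns ``(slide_pixels, annotations, class_grid)`` where
    ``class_grid`` is the generator's internal per-tile class map (exposed
    for self-consistency checks).  Polygons are tile-aligned rectangles
    that partition the foreground; each carries one tissue class, and
    every pixel inside a polygon was rendered from that class's texture.
    An explicit ``layout`` (rows×cols array of class names) overrides the
    default 5-region layout, e.g. a single-class slide.
    """
    rows, cols = grid
    texture_set = texture_set or DEFAULT_TEXTURES
    rng = np.random.default_rng(layout_seed)
    if layout is None:
        if rows < 4 or cols < 4:
            raise ValueError("grid must be at least 4×4 tiles to host 5 regions")
        missing = [c for c in CLASS_ORDER if c not in texture_set]
        if missing:
            raise ValueError(f"texture_set missing classes: {missing}")
        layout = _layout_class_grid(rows, cols, list(CLASS_ORDER), rng)
    else:
        layout = np.asarray(layout, dtype=object)
        if layout.shape != (rows, cols):
            raise ValueError("layout shape must match grid")
    slide = np.zeros((rows * tile_px, cols * tile_px, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            params = texture_set[layout[r, c]]
            tile_seed = int(rng.integers(0, 2**31 - 1))
            tile = make_texture_tile(params, size=tile_px, seed=tile_seed)
            slide[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px] = tile.pixels
    annotations = _grid_to_regions(layout, tile_px)
    return slide, annotations, layout


def _grid_to_regions(layout: np.ndarray, tile_px: int) -> list[AnnotationRegion]:
    """Decompose the class grid into maximal same-class rectangles.

    Greedy row-major sweep: grow each unclaimed cell rightward then
    downward while the class is uniform.  The rectangles partition the
    grid exactly.
    """
    rows, cols = layout.shape
    claimed = np.zeros((rows, cols), dtype=bool)
    regions: list[AnnotationRegion] = []
    for r in range(rows):
        for c in range(cols):
            if claimed[r, c]:
                continue
            cls = layout[r, c]
            c1 = c
            while c1 + 1 < cols and not claimed[r, c1 + 1] and layout[r, c1 + 1] == cls:
                c1 += 1
            r1 = r
            while r1 + 1 < rows and all(
                not claimed[r1 + 1, cc] and layout[r1 + 1, cc] == cls
                for cc in range(c, c1 + 1)
            ):
                r1 += 1
            claimed[r : r1 + 1, c : c1 + 1] = True
            regions.append(
                AnnotationRegion(
                    polygon=_rect_polygon(r, c, r1 + 1, c1 + 1, tile_px),
                    tissue_class=cls,
                )
            )
    return regions


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Cohort marginals and survival-process parameters.

    Defaults reproduce the study's table of characteristics: 89 patients,
    104 slides, 75 single-slide patients, 20% metastatic.  Survival times
    are exponential with the baseline hazard multiplied by
    ``planted_hazard_ratio`` for metastatic patients, administratively
    censored at ``censoring_horizon`` months.
    """

    n_patients: int = 89
    n_slides: int = 104
    n_single_slide_patients: int = 75
    metastasis_fraction: float = 0.20
    planted_hazard_ratio: float = 4.0
    baseline_hazard_per_month: float = 0.008
    censoring_horizon: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_single_slide_patients > self.n_patients:
            raise ValueError("n_single_slide_patients cannot exceed n_patients")
        if self.n_slides < self.n_patients:
            raise ValueError("need at least one slide per patient")
        if not (0.0 <= self.metastasis_fraction <= 1.0):
            raise ValueError("metastasis_fraction must be in [0, 1]")
        if self.planted_hazard_ratio <= 0:
            raise ValueError("planted_hazard_ratio must be positive")
        n_multi = self.n_patients - self.n_single_slide_patients
        extra = self.n_slides - self.n_patients
        if n_multi == 0 and extra > 0:
            raise ValueError("extra slides but no multi-slide patients")
        if extra < n_multi:
            raise ValueError(
                "infeasible slide allocation: every multi-slide patient needs ≥2 slides"
            )


@dataclass
class PatientRecord:
    patient_id: str
    slide_ids: list[str]
    metastasis: bool
    time_months: float
    event: bool
    age: float
    sex: str
    size_cm: float
    grade: int


def make_cohort(config: CohortConfig = CohortConfig()) -> list[PatientRecord]:
    """Draw a deterministic synthetic cohort from ``config``.

    Slide allocation: the first ``n_single_slide_patients`` (after a seeded
    shuffle) receive one slide; the extra ``n_slides - n_patients`` slides
    are dealt round-robin over the multi-slide patients.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_met = int(round(config.metastasis_fraction * n))
    met_flags = np.zeros(n, dtype=bool)
    met_flags[rng.choice(n, size=n_met, replace=False)] = True

    # slide allocation
    slide_counts = np.ones(n, dtype=int)
    n_multi = n - config.n_single_slide_patients
    extra = config.n_slides - n
    if n_multi > 0:
        multi_idx = rng.choice(n, size=n_multi, replace=False)
        for i in range(extra):
            slide_counts[multi_idx[i % n_multi]] += 1

    lam0 = config.baseline_hazard_per_month
    records: list[PatientRecord] = []
    slide_counter = 0
    for i in range(n):
        lam = lam0 * (config.planted_hazard_ratio if met_flags[i] else 1.0)
        t_event = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        event = t_event <= config.censoring_horizon
        time = float(min(t_event, config.censoring_horizon))
        age = float(np.clip(rng.normal(56.0, 13.0), 19, 82))
        sex = "M" if rng.random() < 0.44 else "F"
        size_cm = float(np.clip(rng.lognormal(np.log(3.0), 0.5), 0.6, 11.0))
        grade = int(rng.choice([1, 2, 3], p=[0.70, 0.25, 0.05]))
        slide_ids = [
            f"P{i:03d}_S{j}" for j in range(slide_counts[i])
        ]
        slide_counter += slide_counts[i]
        records.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                slide_ids=slide_ids,
                metastasis=bool(met_flags[i]),
                time_months=time,
                event=bool(event),
                age=age,
                sex=sex,
                size_cm=size_cm,
                grade=grade,
            )
        )
    assert slide_counter == config.n_slides
    return records


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort to the CSV schema (one row per patient)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "slide_ids": [";".join(p.slide_ids) for p in cohort],
            "metastasis": [int(p.metastasis) for p in cohort],
            "time_months": [p.time_months for p in cohort],
            "event": [int(p.event) for p in cohort],
            "age": [p.age for p in cohort],
            "sex": [p.sex for p in cohort],
            "size_cm": [p.size_cm for p in cohort],
            "grade": [p.grade for p in cohort],
        }
    )


# --------------------------------------------------------------------------
# Direct score-map construction
# --------------------------------------------------------------------------

_BLOCK = 10  # hotspot blocks are 10×10 tiles


def make_score_map(
    rows: int,
    cols: int,
    hotspot_spec: list[tuple[tuple[int, int], int, float]] | None = None,
    background_score: float = 0.1,
    seed: int = 0,
    compartment: str = "CANCER",
    slide_id: str = "synthetic",
):
    """Construct a metastasis score map with planted hotspot counts.

    ``hotspot_spec`` is a list of ``((block_row0, block_col0),
    positive_count, score_level)``: inside each 10×10 block anchored at the
    given origin, exactly ``positive_count`` randomly placed tiles are set
    to ``score_level``; all other tiles carry ``background_score``.
    Blocks must be disjoint and inside the grid.
    """
    from .met_classifier import MetScoreMap

    hotspot_spec = hotspot_spec or []
    if not (0.0 <= background_score <= 1.0):
        raise ValueError("background_score must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.full((rows, cols), background_score, dtype=np.float64)
    occupied = np.zeros((rows, cols), dtype=bool)
    for (r0, c0), count, level in hotspot_spec:
        if r0 < 0 or c0 < 0 or r0 + _BLOCK > rows or c0 + _BLOCK > cols:
            raise ValueError("hotspot block does not fit inside the grid")
        if not (0.0 <= level <= 1.0):
            raise ValueError("score level must be in [0, 1]")
        if level <= background_score:
            raise ValueError("score level must exceed background_score")
        if count > _BLOCK * _BLOCK:
            raise ValueError("positive count exceeds block capacity")
        block = occupied[r0 : r0 + _BLOCK, c0 : c0 + _BLOCK]
        if block.any():
            raise ValueError("overlapping hotspot blocks")
        block[:] = True
        flat = rng.choice(_BLOCK * _BLOCK, size=count, replace=False)
        rr, cc = np.unravel_index(flat, (_BLOCK, _BLOCK))
        scores[r0 + rr, c0 + cc] = level
    return MetScoreMap(
        scores=scores,
        valid_mask=np.ones((rows, cols), dtype=bool),
        compartment=compartment,
        slide_id=slide_id,
    )


# --------------------------------------------------------------------------
# External interfaces: tiled PNGs + JSON manifest, GeoJSON annotations
# --------------------------------------------------------------------------


def write_slide(slide: np.ndarray, out_dir: str | Path, slide_id: str, tile_px: int) -> Path:
    """Write a slide as tiled PNGs plus a JSON grid manifest."""
    from PIL import Image

    out = Path(out_dir) / slide_id
    out.mkdir(parents=True, exist_ok=True)
    rows = slide.shape[0] // tile_px
    cols = slide.shape[1] // tile_px
    for r in range(rows):
        for c in range(cols):
            tile = slide[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px]
            Image.fromarray(tile).save(out / f"tile_r{r:03d}_c{c:03d}.png")
    manifest = {
        "slide_id": slide_id,
        "tile_px": tile_px,
        "rows": rows,
        "cols": cols,
        "tiles": [
            {"row": r, "col": c, "file": f"tile_r{r:03d}_c{c:03d}.png"}
            for r in range(rows)
            for c in range(cols)
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def write_annotations(annotations: list[AnnotationRegion], path: str | Path) -> Path:
    """Write annotation regions as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(v) for v in (*a.polygon, a.polygon[0])]],
            },
            "properties": {"tissue_class": a.tissue_class},
        }
        for a in annotations
    ]
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
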