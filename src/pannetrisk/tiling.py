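"""Slide tiling, background exclusion, color normalization and augmentation.

Slides are partitioned into non-overlapping square tiles (default 150 px)
after an integer downsampling step (default 4×, area averaging), matching
the tissue-annotation grid.  Tiles with too little saturated (stained)
area are flagged as background and excluded from classification.  Training
tiles are expanded by a fixed catalogue of 46 deterministic augmentations
(orientation plus hue/blur/noise/contrast adjustments) and color-normalized
by channel-statistics matching in a decorrelated (lab) space against a
packaged reference.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from skimage import color as skcolor
from skimage.filters import gaussian

logger = logging.getLogger(__name__)

# Canonical class order; also the tie-break priority for predominant-class
# labeling (earlier wins).
CLASS_ORDER: tuple[str, ...] = ("CANCER", "CANCER_STROMA", "STROMA", "NORMAL", "FAT")

__all__ = [
    "CLASS_ORDER",
    "TileImage",
    "AnnotationRegion",
    "AugmentationCatalogue",
    "TilingResult",
    "tile_slide",
    "ColorReference",
    "default_color_reference",
    "color_normalize",
    "build_augmentation_catalogue",
    "augment_tile",
    "extract_ground_truth_tiles",
]


@dataclass
class TileImage:
    """A square image tile with its grid position on the (downsampled) slide."""

    pixels: np.ndarray  # H×W×3 uint8
    grid_row: int
    grid_col: int
    slide_id: str = ""
    downsample: int = 1
    is_background: bool = False

    @property
    def tile_size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class AnnotationRegion:
    """A ground-truth polygon (level-0 pixel coordinates) with one class."""

    polygon: tuple[tuple[float, float], ...]
    tissue_class: str

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.tissue_class not in CLASS_ORDER:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        object.__setattr__(self, "polygon", tuple(tuple(map(float, v)) for v in self.polygon))
        if not self.shapely.is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


# --------------------------------------------------------------------------
# Tiling
# --------------------------------------------------------------------------


def _downsample_area(slide: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor downsampling by area averaging (trailing rows cropped)."""
    if factor == 1:
        return slide
    h = (slide.shape[0] // factor) * factor
    w = (slide.shape[1] // factor) * factor
    cropped = slide[:h, :w].astype(np.float64)
    pooled = cropped.reshape(h // factor, factor, w // factor, factor, -1).mean(axis=(1, 3))
    return np.clip(np.rint(pooled), 0, 255).astype(np.uint8)


def _saturation_fraction(pixels: np.ndarray, sat_threshold: float) -> float:
    hsv = skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    return float(np.mean(hsv[..., 1] > sat_threshold))


@dataclass
class TilingResult:
    """Foreground tiles plus the full grid manifest (incl. background flags)."""

    tiles: list[TileImage]
    manifest: pd.DataFrame
    grid_shape: tuple[int, int]


def tile_slide(
    slide: np.ndarray,
    tile_size: int = 150,
    overlap_fraction: float = 0.0,
    downsample: int = 4,
    slide_id: str = "",
    saturation_threshold: float = 0.05,
    min_tissue_fraction: float = 0.5,
) -> TilingResult:
    """Partition a slide into square tiles on a regular grid.

    The slide is first downsampled by the integer ``downsample`` factor
    (area averaging), then windows of ``tile_size`` are cut with stride
    ``tile_size * (1 - overlap_fraction)``.  Partial edge windows are
    dropped.  A tile is background when fewer than ``min_tissue_fraction``
    of its pixels exceed ``saturation_threshold`` in unit saturation;
    background tiles are excluded from ``tiles`` but recorded in the
    manifest.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if downsample < 1:
        raise ValueError("downsample must be a positive integer")
    ds = _downsample_area(np.asarray(slide), downsample)
    stride = max(1, int(round(tile_size * (1.0 - overlap_fraction))))
    h, w = ds.shape[:2]
    if h < tile_size or w < tile_size:
        warnings.warn("slide smaller than one tile after downsampling", stacklevel=2)
        return TilingResult(
            tiles=[],
            manifest=pd.DataFrame(
                columns=["slide_id", "grid_row", "grid_col", "y0", "x0", "is_background"]
            ),
            grid_shape=(0, 0),
        )
    row_origins = range(0, h - tile_size + 1, stride)
    col_origins = range(0, w - tile_size + 1, stride)
    tiles: list[TileImage] = []
    rows_out = []
    for gr, y0 in enumerate(row_origins):
        for gc, x0 in enumerate(col_origins):
            window = ds[y0 : y0 + tile_size, x0 : x0 + tile_size]
            bg = _saturation_fraction(window, saturation_threshold) < min_tissue_fraction
            rows_out.append(
                {
                    "slide_id": slide_id,
                    "grid_row": gr,
                    "grid_col": gc,
                    "y0": y0,
                    "x0": x0,
                    "is_background": bg,
                }
            )
            if not bg:
                tiles.append(
                    TileImage(
                        pixels=window.copy(),
                        grid_row=gr,
                        grid_col=gc,
                        slide_id=slide_id,
                        downsample=downsample,
                        is_background=False,
                    )
                )
    return TilingResult(
        tiles=tiles,
        manifest=pd.DataFrame(rows_out),
        grid_shape=(len(list(row_origins)), len(list(col_origins))),
    )


# --------------------------------------------------------------------------
# Color normalization (channel statistics matched in lab space)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorReference:
    """Target per-channel mean/sd in the decorrelated (lab) color space."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]


def _lab_stats(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lab = skcolor.rgb2lab(pixels.astype(np.float64) / 255.0)
    return lab.reshape(-1, 3).mean(axis=0), lab.reshape(-1, 3).std(axis=0)


def _reference_tile(size: int = 64) -> np.ndarray:
    """The packaged reference texture: a deterministic pink-tinted field."""
    rng = np.random.default_rng(20210225)
    base = np.array([205.0, 145.0, 170.0])
    img = np.tile(base, (size, size, 1)) + rng.normal(0, 18.0, size=(size, size, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def default_color_reference() -> ColorReference:
    means, sds = _lab_stats(_reference_tile())
    return ColorReference(means=tuple(means), sds=tuple(sds))


def color_normalize(tile: TileImage, reference: ColorReference | None = None) -> TileImage:
    """Match the tile's lab-space channel statistics to the reference.

    Zero-variance (constant color) tiles are returned unchanged with a
    warning: there is no stain signal to renormalize.
    """
    reference = reference or default_color_reference()
    pixels = tile.pixels
    if float(pixels.std()) == 0.0:
        warnings.warn("zero-variance tile left unnormalized", stacklevel=2)
        return tile
    lab = skcolor.rgb2lab(pixels.astype(np.float64) / 255.0)
    flat = lab.reshape(-1, 3)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    out = (flat - mean) / sd * np.asarray(reference.sds) + np.asarray(reference.means)
    rgb = skcolor.lab2rgb(out.reshape(lab.shape))
    norm = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return TileImage(
        pixels=norm,
        grid_row=tile.grid_row,
        grid_col=tile.grid_col,
        slide_id=tile.slide_id,
        downsample=tile.downsample,
        is_background=tile.is_background,
    )


# --------------------------------------------------------------------------
# Deterministic ×46 augmentation catalogue
# --------------------------------------------------------------------------


def _dihedral(pixels: np.ndarray, k_rot: int, flip: bool) -> np.ndarray:
    out = np.rot90(pixels, k_rot)
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def _hue_shift(pixels: np.ndarray, degrees: float) -> np.ndarray:
    hsv = skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + degrees / 360.0) % 1.0
    return np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def _saturation_scale(pixels: np.ndarray, factor: float) -> np.ndarray:
    hsv = skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * factor, 0.0, 1.0)
    return np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def _contrast_scale(pixels: np.ndarray, factor: float) -> np.ndarray:
    img = pixels.astype(np.float64)
    mean = img.mean(axis=(0, 1), keepdims=True)
    return np.clip(np.rint((img - mean) * factor + mean), 0, 255).astype(np.uint8)


def _blur(pixels: np.ndarray, sigma: float) -> np.ndarray:
    out = gaussian(pixels.astype(np.float64) / 255.0, sigma=sigma, channel_axis=2)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _additive_noise(pixels: np.ndarray, sigma: float, name: str) -> np.ndarray:
    # deterministic at apply time: the noise stream is seeded by the
    # transform name, not by global state
    seed = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    rng = np.random.default_rng(seed)
    noisy = pixels.astype(np.float64) + rng.normal(0.0, sigma, size=pixels.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


@dataclass
class AugmentationCatalogue:
    """Ordered list of named deterministic tile operators."""

    names: list[str]
    _fns: list = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate catalogue entries")

    def __len__(self) -> int:
        return len(self.names)

    def apply(self, name: str, pixels: np.ndarray) -> np.ndarray:
        return self._fns[self.names.index(name)](pixels)


def build_augmentation_catalogue() -> AugmentationCatalogue:
    """The default 46-entry catalogue.

    8 dihedral orientations × {identity, hue+8°, hue−8°, blur σ=0.6,
    noise σ=3} = 40, plus 6 photometric variants of the unrotated tile
    {contrast ×0.9, ×1.1, saturation ×0.9, ×1.1, hue+16°, hue−16°}.
    The first entry is the identity.
    """
    names: list[str] = []
    fns: list = []

    photometric = [
        ("identity", lambda p: p.copy()),
        ("hue+8", lambda p: _hue_shift(p, 8.0)),
        ("hue-8", lambda p: _hue_shift(p, -8.0)),
        ("blur0.6", lambda p: _blur(p, 0.6)),
    ]
    for k_rot in range(4):
        for flip in (False, True):
            orient = f"rot{90 * k_rot}{'_flip' if flip else ''}"
            for pname, pfn in photometric:
                name = "identity" if (k_rot == 0 and not flip and pname == "identity") else (
                    f"{orient}_{pname}" if not (k_rot == 0 and not flip) else pname
                )
                names.append(name)
                fns.append(
                    lambda p, k=k_rot, f=flip, fn=pfn: fn(_dihedral(p, k, f))
                )
            nname = f"{orient}_noise3"
            names.append(nname)
            fns.append(
                lambda p, k=k_rot, f=flip, nm=nname: _additive_noise(_dihedral(p, k, f), 3.0, nm)
            )

    extras = [
        ("contrast0.9", lambda p: _contrast_scale(p, 0.9)),
        ("contrast1.1", lambda p: _contrast_scale(p, 1.1)),
        ("sat0.9", lambda p: _saturation_scale(p, 0.9)),
        ("sat1.1", lambda p: _saturation_scale(p, 1.1)),
        ("hue+16", lambda p: _hue_shift(p, 16.0)),
        ("hue-16", lambda p: _hue_shift(p, -16.0)),
    ]
    for name, fn in extras:
        names.append(name)
        fns.append(fn)

    assert names[0] == "identity" and len(names) == 46
    return AugmentationCatalogue(names=names, _fns=fns)


def augment_tile(tile: TileImage, catalogue: AugmentationCatalogue) -> list[TileImage]:
    """Apply every catalogue entry to one tile, in catalogue order."""
    out = []
    for name, fn in zip(catalogue.names, catalogue._fns):
        out.append(
            TileImage(
                pixels=fn(tile.pixels),
                grid_row=tile.grid_row,
                grid_col=tile.grid_col,
                slide_id=tile.slide_id,
                downsample=tile.downsample,
            )
        )
    return out


# --------------------------------------------------------------------------
# Ground-truth tile extraction (predominant-class labeling)
# --------------------------------------------------------------------------


def extract_ground_truth_tiles(
    slide: np.ndarray,
    annotations: list[AnnotationRegion],
    tile_size: int = 150,
    slide_id: str = "",
) -> list[tuple[TileImage, str]]:
    """Cut the annotated slide into tiles labeled with the predominant class.

    Each grid tile is labeled with the class covering the largest area of
    its window (polygon intersection area); tiles with zero annotated
    coverage are excluded.  Exact 50/50 ties go to the class earlier in
    the canonical order and are logged.
    """
    slide = np.asarray(slide)
    h, w = slide.shape[:2]
    polys = [(a.shapely, a.tissue_class) for a in annotations]
    out: list[tuple[TileImage, str]] = []
    for y0 in range(0, h - tile_size + 1, tile_size):
        for x0 in range(0, w - tile_size + 1, tile_size):
            window = box(x0, y0, x0 + tile_size, y0 + tile_size)
            areas: dict[str, float] = {}
            for poly, cls in polys:
                a = poly.intersection(window).area
                if a > 0:
                    areas[cls] = areas.get(cls, 0.0) + a
            if not areas:
                continue
            best = max(areas.values())
            winners = [c for c, a in areas.items() if abs(a - best) < 1e-9]
            if len(winners) > 1:
                winners.sort(key=CLASS_ORDER.index)
                logger.info(
                    "predominant-class tie at (%d, %d): %s -> %s",
                    y0, x0, winners, winners[0],
                )
            label = winners[0]
            tile = TileImage(
                pixels=slide[y0 : y0 + tile_size, x0 : x0 + tile_size].copy(),
                grid_row=y0 // tile_size,
                grid_col=x0 // tile_size,
                slide_id=slide_id,
            )
            out.append((tile, label))
    return out
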