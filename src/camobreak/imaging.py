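"""Image containers, simulated-dichromat rendering, and measurement regions.

All pixel data are stored as float64 in [0, 1]; 8- and 16-bit files are
linearly rescaled on read.  Images are treated as already linearized
(white-balanced upstream from a gray standard); no gamma handling is applied.

Coordinate convention (used everywhere in this package): 0-based, x rightward
(columns), y downward (rows), with the center of pixel (col=i, row=j) at
coordinates (x=i, y=j).  Polygon containment uses the half-open even-odd
(crossing-number) rule on pixel centers, so an axis-aligned box [0,10)x[0,10)
covers exactly 100 pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "RGBImage",
    "LuminanceImage",
    "TargetPolygon",
    "RegionSet",
    "to_luminance",
    "simulate_dichromat",
    "rasterize_polygon",
    "build_regions",
    "read_image",
    "write_image",
    "write_mask",
    "read_polygons_csv",
    "read_polygons_json",
]


@dataclass(frozen=True)
class RGBImage:
    """A calibrated RGB raster with channel values in [0, 1].

    ``pixels`` has shape (height, width, 3), float64, channels (R, G, B).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (h, w, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.all(np.isfinite(px)):
            raise ValueError("non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LuminanceImage:
    """A single-channel luminance raster L = (R + G) / 2, values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"expected (h, w) array, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite luminance values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("luminance values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TargetPolygon:
    """An ordered, simple (non-self-intersecting) polygon in pixel coordinates.

    ``vertices`` has shape (k, 2) with columns (x, y), k >= 3.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite vertex coordinates")
        sp = _ShapelyPolygon(v)
        # buffer(0) collapses degenerate rings but keeps bowtie lobes, which
        # separates "zero area" from "self-intersecting" diagnoses
        if sp.buffer(0).area == 0.0:
            raise ValueError("degenerate polygon (zero area)")
        if not sp.is_valid:
            raise ValueError("self-intersecting polygon")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return _ShapelyPolygon(self.vertices).area

    def centroid(self) -> tuple[float, float]:
        c = _ShapelyPolygon(self.vertices).centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class RegionSet:
    """The three measurement regions for one photograph.

    target_mask     -- pixels covered by the target polygon
    annulus_mask    -- "doughnut" of background with edge distance in
                       (inner_gap, outer_radius] px from the target
    whole_bg_mask   -- entire background minus target and inner_gap spacer

    Masks are boolean rasters of identical shape; target, annulus and
    whole-background spacer zone are pairwise disjoint, and the annulus is a
    subset of the whole background.
    """

    target_mask: np.ndarray
    annulus_mask: np.ndarray
    whole_bg_mask: np.ndarray
    inner_gap_px: float = 15.0
    outer_radius_px: float = 500.0

    def __post_init__(self) -> None:
        t = np.asarray(self.target_mask, dtype=bool)
        a = np.asarray(self.annulus_mask, dtype=bool)
        w = np.asarray(self.whole_bg_mask, dtype=bool)
        if not (t.shape == a.shape == w.shape):
            raise ValueError("mask shapes differ")
        if not t.any():
            raise ValueError("empty target mask")
        if (t & a).any() or (t & w).any():
            raise ValueError("target overlaps background masks")
        if (a & ~w).any():
            raise ValueError("annulus must be a subset of the whole background")
        object.__setattr__(self, "target_mask", t)
        object.__setattr__(self, "annulus_mask", a)
        object.__setattr__(self, "whole_bg_mask", w)


def to_luminance(img: RGBImage) -> LuminanceImage:
    """Luminance channel L = (R + G) / 2; the blue channel is ignored.

    This is the achromatic channel a longwave+mediumwave observer uses for
    pattern and spatial processing, and it is by construction identical for
    the trichromatic and the simulated-dichromat rendering of a scene.
    """
    px = img.pixels
    return LuminanceImage((px[..., 0] + px[..., 1]) / 2.0)


def simulate_dichromat(img: RGBImage) -> RGBImage:
    """Render the scene as seen by a red-green-blind (dichromatic) observer.

    The red and green channels are replaced by their average Y = (R + G) / 2,
    producing a blue-yellow image; the blue channel is untouched.  Per-pixel
    luminance (R + G) / 2 is preserved exactly, so every luminance-based
    camouflage metric is identical across viewing conditions.
    """
    px = img.pixels
    y = (px[..., 0] + px[..., 1]) / 2.0
    out = np.empty_like(px)
    out[..., 0] = y
    out[..., 1] = y
    out[..., 2] = px[..., 2]
    return RGBImage(out)


def _crossing_number_mask(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    # Vectorized even-odd (crossing-number) test on pixel centers.  An edge
    # contributes a crossing for center (x, y) when the half-open ray
    # x' > x at height y intersects it; the (y1 > y) != (y2 > y) guard gives
    # half-open behaviour at horizontal boundaries.
    xs = np.arange(width, dtype=np.float64)
    ys = np.arange(height, dtype=np.float64)
    X, Y = np.meshgrid(xs, ys)
    inside = np.zeros((height, width), dtype=bool)
    v = vertices
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (y1 > Y) != (y2 > Y)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (X < x_at)
    return inside


def rasterize_polygon(poly: TargetPolygon, width: int, height: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Uses the even-odd fill rule with the half-open crossing-number
    convention, so abutting polygons tile without double-covering pixels.
    """
    if width < 1 or height < 1:
        raise ValueError("canvas must be at least 1x1")
    v = poly.vertices
    if v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5:
        raise ValueError("polygon extends outside the canvas")
    if v[:, 0].max() > width - 0.5 + 1.0 or v[:, 1].max() > height - 0.5 + 1.0:
        # allow the boundary to touch the last pixel cell but not run far off
        raise ValueError("polygon extends outside the canvas")
    return _crossing_number_mask(v, width, height)


def build_regions(
    target: np.ndarray,
    inner_gap_px: float = 15.0,
    outer_radius_px: float = 500.0,
) -> RegionSet:
    """Build the annulus and whole-background masks around a target mask.

    Distances are exact Euclidean distances from each pixel center to the
    nearest target pixel center.  The annulus keeps pixels with distance in
    (inner_gap_px, outer_radius_px]; the whole background keeps everything
    beyond the inner_gap_px spacer.  Both are clipped at the image edges
    without compensation.
    """
    t = np.asarray(target, dtype=bool)
    if t.ndim != 2:
        raise ValueError("target mask must be 2-D")
    if not t.any():
        raise ValueError("empty target mask")
    if inner_gap_px < 0 or outer_radius_px <= inner_gap_px:
        raise ValueError("need 0 <= inner_gap_px < outer_radius_px")
    d = ndimage.distance_transform_edt(~t)
    whole_bg = d > inner_gap_px
    if not whole_bg.any():
        raise ValueError("target plus spacer fills the whole image")
    annulus = whole_bg & (d <= outer_radius_px)
    return RegionSet(
        target_mask=t,
        annulus_mask=annulus,
        whole_bg_mask=whole_bg,
        inner_gap_px=float(inner_gap_px),
        outer_radius_px=float(outer_radius_px),
    )


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path) -> RGBImage:
    """Read an 8- or 16-bit PNG/TIFF as an RGBImage, rescaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype}")
    return RGBImage(np.clip(arr, 0.0, 1.0))


def write_image(img: RGBImage, path: str | Path, bitdepth: int = 8) -> None:
    """Write an RGBImage as PNG or TIFF at the requested bit depth."""
    path = Path(path)
    if bitdepth == 8:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bitdepth == 16:
            raise ValueError("16-bit RGB PNG is not supported; write TIFF instead")
        iio.imwrite(path, arr)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 8-bit PNG (255 = inside)."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_polygons_csv(path: str | Path) -> dict[str, TargetPolygon]:
    """Read polygon annotations from CSV (photo_id, vertex_index, x, y)."""
    df = pd.read_csv(path)
    required = {"photo_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"polygon CSV needs columns {sorted(required)}")
    out: dict[str, TargetPolygon] = {}
    for pid, grp in df.groupby("photo_id", sort=False):
        grp = grp.sort_values("vertex_index")
        out[str(pid)] = TargetPolygon(grp[["x", "y"]].to_numpy(dtype=float))
    return out


def read_polygons_json(path: str | Path) -> dict[str, TargetPolygon]:
    """Read polygon annotations from JSON: {photo_id: [[x, y], ...], ...}."""
    with open(path) as fh:
        data = json.load(fh)
    return {str(k): TargetPolygon(np.asarray(v, dtype=float)) for k, v in data.items()}
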