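"""Calibrated section images, ROI polygon sets, and the analysis mask.

Whole-slide scoring starts from an RGB image of a cytokeratin-stained
section together with its physical calibration (microns per pixel) and a
set of manually drawn region-of-interest polygons: *include* polygons
delineating the tumor and *exclude* polygons covering necrosis, salivary
glands and other tissue that must not be scored.  This module reads both
and rasterizes them into a boolean analysis mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "CalibratedImage",
    "ROIPolygon",
    "ROISet",
    "AnalysisMask",
    "CalibrationError",
    "ImageFormatError",
    "ROIValidationError",
    "read_image",
    "load_roi",
    "build_mask",
    "write_mask_png",
]


class CalibrationError(ValueError):
    """No microns-per-pixel calibration available for an image."""


class ImageFormatError(ValueError):
    """Image is not 8-bit RGB (or otherwise unusable)."""


class ROIValidationError(ValueError):
    """ROI file violates the polygon contract."""


@dataclass(frozen=True)
class CalibratedImage:
    """RGB pixels plus the physical side length of one pixel in microns."""

    pixels: np.ndarray  # H x W x 3, uint8
    microns_per_pixel: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected H x W x 3 RGB pixels, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must be at least 1 x 1")
        if px.min() < 0 or px.max() > 255:
            raise ImageFormatError("channel values must lie in [0, 255]")
        if not self.microns_per_pixel > 0:
            raise CalibrationError("microns_per_pixel must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def pixel_area_um2(self) -> float:
        """Physical area of one pixel in square microns."""
        return float(self.microns_per_pixel) ** 2


@dataclass(frozen=True)
class ROIPolygon:
    name: str
    role: str  # "include" | "exclude"
    vertices: tuple[tuple[float, float], ...]  # (x, y) in pixel coordinates

    def __post_init__(self) -> None:
        if self.role not in ("include", "exclude"):
            raise ROIValidationError(f"unknown ROI role {self.role!r}")
        if len(self.vertices) < 3:
            raise ROIValidationError(
                f"polygon {self.name!r} has {len(self.vertices)} vertices; need >= 3"
            )

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class ROISet:
    """Collection of named include/exclude polygons in pixel coordinates.

    Coordinate convention: origin at the top-left pixel center, x rightward,
    y downward; vertex coordinates refer to pixel centers.
    """

    polygons: tuple[ROIPolygon, ...]

    @property
    def includes(self) -> tuple[ROIPolygon, ...]:
        return tuple(p for p in self.polygons if p.role == "include")

    @property
    def excludes(self) -> tuple[ROIPolygon, ...]:
        return tuple(p for p in self.polygons if p.role == "exclude")


@dataclass(frozen=True)
class AnalysisMask:
    """Boolean mask of pixels to score, with inherited calibration."""

    mask: np.ndarray  # H x W bool
    microns_per_pixel: float

    def area_um2(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.microns_per_pixel**2


def _tiff_microns_per_pixel(path: Path) -> float | None:
    """Microns/pixel from TIFF XResolution + ResolutionUnit tags, if present."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        xres = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        # pixels per unit -> unit length per pixel
        per_pixel = Fraction(den, num)
        unit_val = getattr(unit, "value", None)
        unit_name = getattr(unit_val, "name", str(unit_val)).upper() if unit_val else "NONE"
        if "CENTIMETER" in unit_name or unit_val == 3:
            return float(per_pixel * 10_000)  # cm -> um
        if "INCH" in unit_name or unit_val == 2:
            return float(per_pixel * 25_400)  # inch -> um
        # Unit NONE: treat the stored resolution as um/px directly, a common
        # convention for scientific TIFFs written without a unit.
        return float(per_pixel)


def read_image(path: str | Path, microns_per_pixel: float | None = None) -> CalibratedImage:
    """Read a TIFF or PNG section image with its physical calibration.

    Calibration precedence: an explicit ``microns_per_pixel`` argument
    overrides file metadata; TIFF resolution tags are honored; a file with
    neither raises :class:`CalibrationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        meta_mpp = _tiff_microns_per_pixel(path)
    elif suffix == ".png":
        pixels = iio.imread(path)
        meta_mpp = None
    else:
        raise ImageFormatError(f"unsupported image format {suffix!r} (TIFF or PNG)")

    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ImageFormatError(f"{path.name}: expected an RGB image, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        if pixels.max(initial=0) > 255 or pixels.min(initial=0) < 0:
            raise ImageFormatError(f"{path.name}: channel values outside [0, 255]")
        pixels = pixels.astype(np.uint8)

    mpp = microns_per_pixel if microns_per_pixel is not None else meta_mpp
    if mpp is None:
        raise CalibrationError(
            f"{path.name}: no microns-per-pixel calibration in metadata and none supplied"
        )
    return CalibratedImage(pixels=pixels, microns_per_pixel=float(mpp), source_id=str(path))


def load_roi(path: str | Path) -> ROISet:
    """Load ROI polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon; a ``role`` property of ``include`` or
    ``exclude`` is honored and defaults to ``include`` when absent.
    Coordinates are x/y in pixel units.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ROIValidationError(f"{path.name}: expected a GeoJSON FeatureCollection")
    polygons: list[ROIPolygon] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ROIValidationError(
                f"{path.name}: feature {i} has geometry {geom.get('type')!r}; only Polygon supported"
            )
        props = feat.get("properties") or {}
        role = props.get("role", "include")
        name = props.get("name", f"roi_{i}")
        ring = geom.get("coordinates", [[]])[0]
        # GeoJSON rings repeat the first vertex at the end; drop the closure.
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        polygons.append(ROIPolygon(name=name, role=role, vertices=tuple(map(tuple, ring))))
    return ROISet(polygons=tuple(polygons))


def _rasterize(polygons: Sequence[ROIPolygon], shape: tuple[int, int]) -> np.ndarray:
    """Union of polygons rasterized by the pixel-center inclusion rule.

    A pixel (row r, col c) is inside when its center (x=c, y=r) lies strictly
    inside the polygon union (even-odd filling via shapely); centers exactly
    on a boundary are treated as outside, which makes rasterization
    deterministic.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    if not polygons:
        return out
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    union = shapely.union_all([p.to_shapely() for p in polygons])
    out = shapely.contains_xy(union, xs.ravel(), ys.ravel()).reshape(h, w)
    return out


def build_mask(image: CalibratedImage, rois: ROISet) -> AnalysisMask:
    """Rasterize include minus exclude polygons onto the image grid.

    The mask is true exactly for pixels whose centers fall inside the union
    of include polygons and outside the union of exclude polygons.  An empty
    result is legal (the downstream bud count is then zero) but warned about.
    """
    if not rois.includes:
        raise ROIValidationError("ROISet has no include polygon")
    h, w = image.shape
    inc = _rasterize(rois.includes, (h, w))
    exc = _rasterize(rois.excludes, (h, w))
    mask = inc & ~exc
    if not mask.any():
        warnings.warn("analysis mask is empty; no pixels will be scored", stacklevel=2)
    return AnalysisMask(mask=mask, microns_per_pixel=image.microns_per_pixel)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit black/white PNG for audit."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
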