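"""Contour-based sepal morphometrics.

Turns black-background sepal photographs (or directly supplied contour
polygons) into the four morphological parameters used downstream: area,
length, width, and aspect ratio.

Conventions
-----------
* Images are ingested with the raster convention (origin top-left, y down)
  and converted to the mathematical convention (y up) before alignment.
* Length is the extent along the contour's principal axis and width the
  extent orthogonal to it (not Feret diameters), so aspect_ratio >= 1 for
  any elongated shape measured after :func:`align_contour`.
* Segmentation is automatic global (Otsu) thresholding followed by
  connected-component labeling, adequate for black-background imaging.
* Calibration is mm per pixel; when absent, parameters are in pixel units.
  All downstream statistics (CV^2, relative effect, aspect ratio) are
  unit-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops

from ._errors import InvalidInputError

__all__ = [
    "Contour",
    "ShapeParams",
    "segment_image",
    "mask_to_contour",
    "align_contour",
    "measure_contour",
    "measure_polygon",
    "batch_measure",
]

log = logging.getLogger(__name__)

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def _shoelace_signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(v: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed polygon (shoelace moments)."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise InvalidInputError("degenerate contour: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass(frozen=True)
class Contour:
    """Closed polygonal outline of one sepal.

    Vertices are ordered counter-clockwise with consecutive duplicates
    removed; ``calibration`` is mm per pixel (None = pixel units).
    """

    vertices: np.ndarray
    closed: bool = True
    calibration: float | None = None

    @classmethod
    def from_vertices(cls, vertices: np.ndarray, calibration: float | None = None) -> "Contour":
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidInputError("vertices must be an (n, 2) array")
        # drop consecutive duplicates (incl. a repeated closing vertex)
        keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
        v = v[keep]
        if v.shape[0] < 3:
            raise InvalidInputError("contour needs at least 3 distinct vertices")
        if calibration is not None and calibration <= 0:
            raise InvalidInputError("calibration must be positive")
        if _shoelace_signed_area(v) < 0:
            v = v[::-1]
        return cls(vertices=v, closed=True, calibration=calibration)


@dataclass(frozen=True)
class ShapeParams:
    """The four morphological parameters of one sepal."""

    area: float
    length: float
    width: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if min(self.area, self.length, self.width) <= 0:
            raise InvalidInputError("shape parameters must be positive")
        if self.length < self.width:
            raise InvalidInputError("length must be >= width")


def segment_image(image: np.ndarray, min_object_px: int = 100) -> list[np.ndarray]:
    """Split a grayscale image into one boolean mask per foreground object.

    Global Otsu thresholding then connected-component labeling; components
    below ``min_object_px`` are discarded.  An image with no usable
    component yields an empty list (not an exception).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise InvalidInputError("segment_image expects a single-channel image")
    if img.max() == img.min():
        return []
    thresh = threshold_otsu(img)
    labeled = label(img > thresh)
    masks = []
    for prop in regionprops(labeled):
        if prop.area >= min_object_px:
            masks.append(labeled == prop.label)
    return masks


def mask_to_contour(mask: np.ndarray, calibration: float | None = None) -> Contour:
    """Outer boundary polygon of the largest component of a binary mask.

    Marching squares at the 0.5 level on a zero-padded copy, so the
    boundary runs half a pixel outside the outermost foreground pixel
    centers and the polygon area tracks the pixel count closely.  Output is
    in math convention (y up).
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2 or not m.any():
        raise InvalidInputError("mask must be a non-empty 2-D binary array")
    labeled = label(m)
    if labeled.max() > 1:
        largest = max(regionprops(labeled), key=lambda p: p.area)
        m = labeled == largest.label
    if m.sum() < 4:
        raise InvalidInputError("component too small to form a contour")

    padded = np.pad(m.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise InvalidInputError("no boundary found")
    rc = max(contours, key=len)  # outer boundary is the longest
    h = m.shape[0]
    x = rc[:, 1] - 1.0
    y = (h - 1.0) - (rc[:, 0] - 1.0)
    return Contour.from_vertices(np.column_stack([x, y]), calibration=calibration)


def _arc_weighted_axes(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal axes of the vertex cloud, weighted by local arc length."""
    edges = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
    w = 0.5 * (edges + np.roll(edges, 1))
    w = w / w.sum()
    mean = w @ v
    d = v - mean
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return evals, evecs, mean


def align_contour(contour: Contour) -> Contour:
    """Translate the area centroid to the origin and rotate the principal
    axis onto the vertical (y) axis.

    The principal axis is the largest-variance direction of the vertex
    coordinates weighted by arc length; a near-tie between the two axes is
    broken in favour of the axis with the larger extent.  Vertex order is
    preserved.
    """
    v = contour.vertices
    centroid = _polygon_centroid(v)
    v = v - centroid
    evals, evecs, _ = _arc_weighted_axes(v)
    major, minor = evecs[:, 1], evecs[:, 0]
    if evals[1] - evals[0] <= 1e-9 * max(evals[1], 1e-30):
        ext_major = np.ptp(v @ major)
        ext_minor = np.ptp(v @ minor)
        if ext_minor > ext_major:
            major = minor
    ux, uy = major
    rot = np.array([[uy, -ux], [ux, uy]])  # maps `major` onto (0, 1)
    return replace(contour, vertices=v @ rot.T)


def measure_contour(contour: Contour) -> ShapeParams:
    """Measure an aligned contour.

    Area is the shoelace polygon area, length the extent along the vertical
    (principal) axis, width the extent along the horizontal axis; the
    calibration (mm/px) converts pixel units if present.  If the horizontal
    extent exceeds the vertical one (possible for shapes whose variance
    axis is not their longest extent) the two are swapped so that
    length >= width always holds.
    """
    v = contour.vertices
    cal = contour.calibration if contour.calibration is not None else 1.0
    area = abs(_shoelace_signed_area(v)) * cal * cal
    ly = float(np.ptp(v[:, 1])) * cal
    lx = float(np.ptp(v[:, 0])) * cal
    length, width = (ly, lx) if ly >= lx else (lx, ly)
    if width <= 0:
        raise InvalidInputError("zero width contour")
    return ShapeParams(area=area, length=length, width=width, aspect_ratio=length / width)


def measure_polygon(vertices: np.ndarray, calibration: float | None = None) -> ShapeParams:
    """Convenience: normalize, align and measure a raw vertex array."""
    return measure_contour(align_contour(Contour.from_vertices(vertices, calibration)))


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(float)
        return rgb @ np.array([0.2126, 0.7152, 0.0722])
    raise InvalidInputError(f"unsupported image shape {img.shape}")


def batch_measure(
    image_dir: str | Path,
    calibration: float | None = None,
    labels: str | Path | pd.DataFrame | None = None,
    min_object_px: int = 100,
) -> pd.DataFrame:
    """Measure every sepal in every image of a directory.

    ``labels`` maps filenames to (genotype, batch): a CSV path or DataFrame
    with columns filename, genotype, batch.  Unlabeled images get genotype
    and batch "unknown".  Unreadable files are logged and skipped; the
    result has one row per detected sepal in the measurement-table schema.
    """
    import imageio.v3 as iio

    if isinstance(labels, (str, Path)):
        labels = pd.read_csv(labels)
    label_map: dict[str, tuple[str, str]] = {}
    if labels is not None:
        for rec in labels.itertuples(index=False):
            label_map[str(rec.filename)] = (str(rec.genotype).lower(), str(rec.batch).lower())

    rows = []
    for path in sorted(Path(image_dir).iterdir()):
        if path.suffix.lower() not in _IMAGE_EXTENSIONS:
            continue
        try:
            img = _to_grayscale(np.asarray(iio.imread(path)))
        except Exception as exc:  # unreadable file: log and move on
            log.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        genotype, batch = label_map.get(path.name, ("unknown", "unknown"))
        for i, mask in enumerate(segment_image(img, min_object_px=min_object_px)):
            try:
                shape = measure_contour(align_contour(mask_to_contour(mask, calibration)))
            except InvalidInputError as exc:
                log.warning("skipping object %d in %s: %s", i, path.name, exc)
                continue
            rows.append({
                "genotype": genotype,
                "batch": batch,
                "sepal_id": f"{path.stem}_{i}",
                "length": shape.length,
                "width": shape.width,
                "area": shape.area,
                "aspect_ratio": shape.aspect_ratio,
            })
    columns = ["genotype", "batch", "sepal_id", "length", "width", "area", "aspect_ratio"]
    return pd.DataFrame(rows, columns=columns)
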