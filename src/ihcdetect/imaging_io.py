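"""Image, annotation and count-table I/O plus physical-unit geometry.

Everything downstream works in pixel coordinates with a 0-based,
(x = column, y = row), pixel-center convention.  Physical distances are
carried in micrometres and converted through :class:`ImageMetadata`,
whose ``pixel_size_um`` defaults to the 0.228 µm/px of a 40× slide scan.

File formats are deliberately plain: PNG/TIFF for pixels, CSV for point
annotations, detections and observer count tables, and a small YAML
sidecar (``<image>.meta.yaml``) for the physical metadata.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

#: Scanner resolution (µm per pixel) of a 40× whole-slide scan; the
#: default for all synthetic data in this package.
DEFAULT_PIXEL_SIZE_UM = 0.228


class InvalidMetadataError(ValueError):
    """Raised for physically impossible image metadata (e.g. pixel size ≤ 0)."""


class AnnotationFormatError(ValueError):
    """Raised when an annotation/detection CSV violates the expected schema."""


class CountTableFormatError(ValueError):
    """Raised when an observer count table is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageMetadata:
    """Physical and identifying metadata of a tissue image.

    Parameters
    ----------
    pixel_size_um:
        Physical edge length of one pixel in micrometres.  Must be > 0.
    marker:
        Stain label, e.g. ``"CD3"``.  Free text.
    image_id:
        Identifier used to join images with annotations and counts.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    marker: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0) or not math.isfinite(self.pixel_size_um):
            raise InvalidMetadataError(
                f"pixel_size_um must be a positive finite number, "
                f"got {self.pixel_size_um!r}"
            )


@dataclass
class RGBImage:
    """An 8-bit RGB image (H×W×3, channel order R,G,B) with metadata."""

    pixels: np.ndarray
    metadata: ImageMetadata = field(default_factory=ImageMetadata)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 RGB pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PointAnnotation:
    """A manually annotated point (cell center or negative-region sample)."""

    x: float
    y: float
    label: str = "positive"
    image_id: str = ""


@dataclass(frozen=True)
class Detection:
    """A detected cell center.

    ``score`` is the radial-symmetry response at the detection and
    ``component_size`` the pixel count of the supporting connected
    component of the thresholded response.
    """

    x: float
    y: float
    score: float
    component_size: int
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.score > 0:
            raise ValueError(f"detection score must be > 0, got {self.score}")
        if self.component_size < 1:
            raise ValueError(
                f"component_size must be ≥ 1, got {self.component_size}"
            )


# ---------------------------------------------------------------------------
# Unit conversions and geometry
# ---------------------------------------------------------------------------


def um_to_px(distance_um: float, meta: ImageMetadata) -> float:
    """Convert a physical distance in µm to pixels.  No rounding."""
    if distance_um < 0:
        raise ValueError(f"distance must be ≥ 0, got {distance_um}")
    return distance_um / meta.pixel_size_um


def px_to_um(distance_px: float, meta: ImageMetadata) -> float:
    """Convert a pixel distance to µm.  Inverse of :func:`um_to_px`."""
    if distance_px < 0:
        raise ValueError(f"distance must be ≥ 0, got {distance_px}")
    return distance_px * meta.pixel_size_um


def image_area_mm2(width_px: int, height_px: int, meta: ImageMetadata) -> float:
    """Physical area of a ``width_px × height_px`` image in mm².

    A 2000×2000 px tile at 0.228 µm/px covers 0.207936 mm² ≈ 0.2 mm².
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("image dimensions must be ≥ 1 px")
    return width_px * height_px * meta.pixel_size_um**2 / 1e6


# ---------------------------------------------------------------------------
# Image files
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def write_image(image: RGBImage, path: str | Path) -> None:
    """Write an RGB image as PNG or TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)
    meta = image.metadata
    _sidecar_path(path).write_text(
        yaml.safe_dump(
            {
                "pixel_size_um": float(meta.pixel_size_um),
                "marker": meta.marker,
                "image_id": meta.image_id or path.stem,
            }
        )
    )


def read_image(
    path: str | Path, metadata: ImageMetadata | None = None
) -> RGBImage:
    """Read a PNG/TIFF image; metadata comes from the sidecar unless given."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    if metadata is None:
        side = _sidecar_path(path)
        if side.exists():
            d = yaml.safe_load(side.read_text()) or {}
            metadata = ImageMetadata(
                pixel_size_um=float(d.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
                marker=str(d.get("marker", "")),
                image_id=str(d.get("image_id", path.stem)),
            )
        else:
            metadata = ImageMetadata(image_id=path.stem)
    return RGBImage(px.astype(np.uint8), metadata)


def write_likelihood_map(values: np.ndarray, path: str | Path,
                         metadata: ImageMetadata | None = None) -> None:
    """Write a per-pixel probability map as a single-channel 32-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    if metadata is not None:
        _sidecar_path(path).write_text(
            yaml.safe_dump(
                {
                    "pixel_size_um": float(metadata.pixel_size_um),
                    "marker": metadata.marker,
                    "image_id": metadata.image_id,
                }
            )
        )


def read_likelihood_map(path: str | Path) -> tuple[np.ndarray, ImageMetadata]:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    side = _sidecar_path(path)
    if side.exists():
        d = yaml.safe_load(side.read_text()) or {}
        meta = ImageMetadata(
            pixel_size_um=float(d.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
            marker=str(d.get("marker", "")),
            image_id=str(d.get("image_id", path.stem)),
        )
    else:
        meta = ImageMetadata(image_id=path.stem)
    return values, meta


# ---------------------------------------------------------------------------
# Annotation / detection / count CSVs
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ("image_id", "x", "y", "label")
_DETECTION_COLUMNS = ("image_id", "x", "y", "score", "component_size")


def read_annotations(path: str | Path) -> list[PointAnnotation]:
    """Read point annotations from CSV with header image_id,x,y,label.

    Coordinates are 0-based pixel indices, taken as printed.  A missing
    column raises :class:`AnnotationFormatError`; a non-numeric coordinate
    raises a parse error naming the offending row (header = row 1).
    """
    path = Path(path)
    out: list[PointAnnotation] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _ANNOTATION_COLUMNS if c not in header]
        if missing:
            raise AnnotationFormatError(
                f"{path}: missing column(s) {missing}; header was {header}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                x = float(row["x"])
                y = float(row["y"])
            except (TypeError, ValueError) as exc:
                raise AnnotationFormatError(
                    f"{path}: non-numeric coordinate in row {rownum}: "
                    f"x={row.get('x')!r} y={row.get('y')!r}"
                ) from exc
            out.append(
                PointAnnotation(
                    x=x, y=y, label=row["label"], image_id=row["image_id"]
                )
            )
    return out


def write_annotations(
    annotations: Iterable[PointAnnotation], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow([a.image_id, f"{a.x:.6g}", f"{a.y:.6g}", a.label])


def write_detections(detections: Iterable[Detection], path: str | Path) -> None:
    """Write detections as CSV (6 significant digits for real-valued fields)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DETECTION_COLUMNS)
        for d in detections:
            writer.writerow(
                [
                    d.image_id,
                    f"{d.x:.6g}",
                    f"{d.y:.6g}",
                    f"{d.score:.6g}",
                    d.component_size,
                ]
            )


def read_detections(path: str | Path) -> list[Detection]:
    path = Path(path)
    out: list[Detection] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _DETECTION_COLUMNS if c not in header]
        if missing:
            raise AnnotationFormatError(
                f"{path}: missing column(s) {missing}; header was {header}"
            )
        for rownum, row in enumerate(reader, start=2):
            try:
                out.append(
                    Detection(
                        x=float(row["x"]),
                        y=float(row["y"]),
                        score=float(row["score"]),
                        component_size=int(row["component_size"]),
                        image_id=row["image_id"],
                    )
                )
            except (TypeError, ValueError) as exc:
                raise AnnotationFormatError(
                    f"{path}: bad detection row {rownum}: {row!r}"
                ) from exc
    return out


def read_observer_counts(path: str | Path) -> pd.DataFrame:
    """Read an image × rater count table.

    The CSV must have an ``image_id`` column plus one column per rater
    (human observers and/or the model).  Returns a DataFrame indexed by
    image_id with one numeric column per rater.  Duplicate image ids and
    missing cells are format errors, not silently tolerated.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "image_id" not in df.columns:
        raise CountTableFormatError(f"{path}: missing 'image_id' column")
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise CountTableFormatError(f"{path}: duplicate image_id rows {dupes}")
    df = df.set_index("image_id")
    if df.shape[1] == 0:
        raise CountTableFormatError(f"{path}: no rater columns")
    if df.isna().any().any():
        bad = [
            (img, col)
            for img, row in df.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise CountTableFormatError(f"{path}: missing count cells at {bad}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise CountTableFormatError(
                f"{path}: non-numeric counts in column {col!r}"
            )
        if (df[col] < 0).any():
            raise CountTableFormatError(f"{path}: negative counts in {col!r}")
    return df


def write_observer_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="image_id")


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tile:
    """A rectangular tile of an image with its provenance.

    ``offset`` is the (y, x) of the tile's top-left pixel in the source
    image; ``core`` the slice of the source image this tile is
    responsible for when stitching (its halo-trimmed interior).
    """

    pixels: np.ndarray
    offset: tuple[int, int]
    core: tuple[slice, slice]

    def core_in_tile(self) -> tuple[slice, slice]:
        """The core region expressed in tile-local coordinates."""
        (oy, ox), (ry, rx) = self.offset, self.core
        return (
            slice(ry.start - oy, ry.stop - oy),
            slice(rx.start - ox, rx.stop - ox),
        )


def tile_image(
    pixels: np.ndarray | RGBImage, tile: int, halo: int
) -> list[Tile]:
    """Split an image (2-D or H×W×C array) into overlapping tiles.

    Adjacent tiles overlap by exactly ``2*halo`` pixels and the
    halo-trimmed cores partition the image, so
    ``stitch_tiles(tile_image(I, ...)) == I`` exactly.  A tile larger
    than the image yields a single tile.
    """
    if isinstance(pixels, RGBImage):
        pixels = pixels.pixels
    arr = np.asarray(pixels)
    if halo < 0:
        raise ValueError("halo must be ≥ 0")
    if tile < 2 * halo + 1:
        raise ValueError(f"tile ({tile}) must be ≥ 2*halo+1 ({2 * halo + 1})")
    H, W = arr.shape[:2]
    step = tile - 2 * halo
    tiles: list[Tile] = []
    for cy in range(0, H, step):
        core_y = slice(cy, min(cy + step, H))
        y0, y1 = max(0, cy - halo), min(H, core_y.stop + halo)
        for cx in range(0, W, step):
            core_x = slice(cx, min(cx + step, W))
            x0, x1 = max(0, cx - halo), min(W, core_x.stop + halo)
            tiles.append(
                Tile(
                    pixels=arr[y0:y1, x0:x1].copy(),
                    offset=(y0, x0),
                    core=(core_y, core_x),
                )
            )
    return tiles


def stitch_tiles(
    tiles: Sequence[Tile], shape: tuple[int, ...] | None = None
) -> np.ndarray:
    """Reassemble tiles produced by :func:`tile_image` into one array."""
    if not tiles:
        raise ValueError("no tiles to stitch")
    if shape is None:
        H = max(t.core[0].stop for t in tiles)
        W = max(t.core[1].stop for t in tiles)
        shape = (H, W) + tiles[0].pixels.shape[2:]
    out = np.zeros(shape, dtype=tiles[0].pixels.dtype)
    for t in tiles:
        out[t.core] = t.pixels[t.core_in_tile()]
    return out


__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "ImageMetadata",
    "RGBImage",
    "PointAnnotation",
    "Detection",
    "Tile",
    "InvalidMetadataError",
    "AnnotationFormatError",
    "CountTableFormatError",
    "um_to_px",
    "px_to_um",
    "image_area_mm2",
    "read_image",
    "write_image",
    "read_likelihood_map",
    "write_likelihood_map",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
    "read_observer_counts",
    "write_observer_counts",
    "tile_image",
    "stitch_tiles",
]
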