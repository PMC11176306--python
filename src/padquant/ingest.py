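"""Raster and table ingestion for circular-zone densitometry.

Colorimetric paper devices are read by averaging the R, G and B channels
over the whole circular detection zone inside the hydrophobic barrier.
This module loads scans (TIFF/JPEG/PNG), extracts per-zone channel means,
auto-detects barrier-ring grids, and reads tabular RGB exports (a native
CSV schema or ImageJ "Results"-style tables).

Conventions: coordinates are 0-based with ``x`` = column and ``y`` = row,
origin at the top-left; radii are in pixels. A pixel belongs to a circular
zone when its centre lies within ``radius`` (inclusive) of the zone centre.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import (
    DetectionError,
    ImageFormatError,
    ImageReadError,
    ParseError,
    SchemaError,
    ZoneError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ImageRaster",
    "ZoneSpec",
    "ZoneMeasurement",
    "load_image",
    "save_image",
    "extract_zone_mean",
    "detect_zone_grid",
    "read_rgb_table",
    "read_zone_layout",
    "write_rgb_csv",
    "write_zone_layout",
]


@dataclass
class ImageRaster:
    """An RGB raster on the 0–255 intensity scale.

    ``pixels`` is a float64 array of shape (height, width, 3). Sources with
    other bit depths or colour layouts are normalised on load; the original
    bit depth is kept for provenance.
    """

    pixels: np.ndarray
    source_path: str | None = None
    bit_depth_original: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"raster must have exactly 3 channels, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageFormatError("raster must be at least 1x1")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ImageFormatError("raster intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ZoneSpec:
    """Geometry and labelling of one circular detection zone."""

    zone_id: str
    center_x: float
    center_y: float
    radius: float
    concentration: float | None = None
    unit: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ZoneError(f"zone {self.zone_id!r}: radius must be > 0")


@dataclass
class ZoneMeasurement:
    """Mean channel intensities of one zone; the atomic datum of the pipeline."""

    zone_id: str
    concentration: float | None
    mean_R: float
    mean_G: float
    mean_B: float
    unit: str = ""
    replicate: int = 1
    n_pixels: int | None = None

    @property
    def rgb(self) -> tuple[float, float, float]:
        return (self.mean_R, self.mean_G, self.mean_B)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_SUPPORTED_FORMATS = {"tiff", "tif", "jpeg", "jpg", "png"}


def load_image(path: str | Path, format: str | None = None) -> ImageRaster:
    """Load a TIFF/JPEG/PNG raster as a 3-channel image on the 0–255 scale.

    16-bit sources are rescaled by 255/65535, greyscale images are
    replicated into three identical channels, and an alpha channel is
    discarded. CMYK (or other unsupported colour models) raise
    :class:`ImageFormatError`.
    """
    path = Path(path)
    if format is not None and format.lower() not in _SUPPORTED_FORMATS:
        raise ImageFormatError(f"unsupported format {format!r}")
    try:
        img = Image.open(path)
        img.load()
    except FileNotFoundError as exc:
        raise ImageReadError(f"cannot read image {path}: file not found") from exc
    except OSError as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc

    mode = img.mode
    bit_depth = 8
    if mode in ("CMYK", "YCbCr", "LAB", "HSV"):
        raise ImageFormatError(f"unsupported colour model {mode!r} in {path}")

    if mode in ("I;16", "I;16B", "I;16L", "I"):
        arr = np.asarray(img, dtype=np.float64)
        bit_depth = 16
        arr = arr * (255.0 / 65535.0)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif mode == "L":
        arr = np.asarray(img, dtype=np.float64)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif mode == "LA":
        arr = np.asarray(img, dtype=np.float64)[:, :, 0]
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif mode == "P":
        arr = np.asarray(img.convert("RGB"), dtype=np.float64)
    elif mode == "RGB":
        arr = np.asarray(img, dtype=np.float64)
    elif mode == "RGBA":
        arr = np.asarray(img, dtype=np.float64)[:, :, :3]
    else:
        raise ImageFormatError(f"unsupported image mode {mode!r} in {path}")

    arr = np.clip(arr, 0.0, 255.0)
    return ImageRaster(arr, source_path=str(path), bit_depth_original=bit_depth)


def save_image(raster: ImageRaster, path: str | Path) -> None:
    """Write a raster as 8-bit RGB; the format follows the file extension."""
    path = Path(path)
    arr = np.clip(np.rint(raster.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


# ---------------------------------------------------------------------------
# zone extraction
# ---------------------------------------------------------------------------

def _circle_mask(height: int, width: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[0:height, 0:width]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def extract_zone_mean(raster: ImageRaster, zone: ZoneSpec) -> ZoneMeasurement:
    """Average each channel over all pixels whose centre lies in the zone circle.

    Means are never rounded; the pixel count is reported. A circle so small
    (or so far outside the raster) that it selects no pixels raises
    :class:`ZoneError`.
    """
    mask = _circle_mask(raster.height, raster.width, zone.center_x, zone.center_y, zone.radius)
    n = int(mask.sum())
    if n == 0:
        raise ZoneError(
            f"zone {zone.zone_id!r}: circle at ({zone.center_x}, {zone.center_y}) "
            f"r={zone.radius} selects no pixels"
        )
    means = raster.pixels[mask].mean(axis=0)
    return ZoneMeasurement(
        zone_id=zone.zone_id,
        concentration=zone.concentration,
        unit=zone.unit,
        replicate=zone.replicate,
        mean_R=float(means[0]),
        mean_G=float(means[1]),
        mean_B=float(means[2]),
        n_pixels=n,
    )


def detect_zone_grid(
    raster: ImageRaster,
    rows: int,
    cols: int,
    margin_frac: float = 0.0,
    min_area: int = 50,
) -> list[ZoneSpec]:
    """Locate a ``rows x cols`` grid of dark barrier rings on a light background.

    Rings are found as dark connected components (Otsu threshold); each
    component's centroid estimates the zone centre and the minimum
    centroid-to-component distance estimates the interior radius. Returned
    radii are shrunk by ``margin_frac`` so extraction stays clear of the
    barrier ink. Zones are ordered row-major (top-to-bottom, left-to-right).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    grey = raster.pixels.mean(axis=2)
    if grey.max() - grey.min() < 1e-9:
        raise DetectionError(f"expected {rows * cols} zones, found 0 (uniform image)")
    thr = threshold_otsu(grey)
    dark = grey < thr
    labelled = label(dark)
    regions = [r for r in regionprops(labelled) if r.area >= min_area]
    if len(regions) != rows * cols:
        raise DetectionError(
            f"expected {rows * cols} zones, found {len(regions)} dark components"
        )

    found: list[tuple[float, float, float]] = []
    for region in regions:
        cy, cx = region.centroid
        d = np.hypot(region.coords[:, 0] - cy, region.coords[:, 1] - cx)
        inner_radius = float(d.min())
        found.append((cx, cy, inner_radius))

    # row-major ordering: sort by y, chunk into rows, sort each chunk by x
    found.sort(key=lambda t: t[1])
    zones: list[ZoneSpec] = []
    idx = 1
    for r in range(rows):
        chunk = sorted(found[r * cols : (r + 1) * cols], key=lambda t: t[0])
        for cx, cy, radius in chunk:
            zones.append(
                ZoneSpec(
                    zone_id=f"z{idx:02d}",
                    center_x=cx,
                    center_y=cy,
                    radius=radius * (1.0 - margin_frac),
                )
            )
            idx += 1
    return zones


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_NATIVE_COLUMNS = ["zone_id", "concentration", "replicate", "R", "G", "B"]


def _to_float(value: object, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row}: cannot parse {column}={value!r} as a number"
        ) from exc


def read_rgb_table(path: str | Path, dialect: str = "native") -> list[ZoneMeasurement]:
    """Read per-zone mean RGB values from CSV.

    ``native`` dialect expects columns zone_id, concentration, replicate,
    R, G, B (plus optional unit). ``imagej`` dialect expects a Results-style
    export with a Mean column; rows are matched to zones by the Label
    column, either via "(red)"/"(green)"/"(blue)" suffixes or as
    consecutive R, G, B triples from channel-split stacks. Labels may carry
    concentration and replicate as ``id:conc`` or ``id:conc:rep``.
    """
    path = Path(path)
    if dialect == "native":
        return _read_native(path)
    if dialect == "imagej":
        return _read_imagej(path)
    raise SchemaError(f"unknown RGB table dialect {dialect!r}")


def _read_native(path: Path) -> list[ZoneMeasurement]:
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in _NATIVE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out: list[ZoneMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        out.append(
            ZoneMeasurement(
                zone_id=str(rec["zone_id"]),
                concentration=_to_float(rec["concentration"], i, "concentration"),
                replicate=int(_to_float(rec["replicate"], i, "replicate")),
                mean_R=_to_float(rec["R"], i, "R"),
                mean_G=_to_float(rec["G"], i, "G"),
                mean_B=_to_float(rec["B"], i, "B"),
                unit=str(rec.get("unit", "") or ""),
                n_pixels=int(_to_float(rec["n_pixels"], i, "n_pixels"))
                if "n_pixels" in df.columns and not pd.isna(rec.get("n_pixels"))
                else None,
            )
        )
    return out


_CHANNEL_SUFFIX = re.compile(r"\((red|green|blue)\)\s*$", re.IGNORECASE)


def _parse_imagej_label(base: str, fallback_id: str) -> tuple[str, float | None, int]:
    parts = [p.strip() for p in base.split(":") if p.strip() != ""]
    zone_id = parts[0] if parts else fallback_id
    conc = None
    rep = 1
    if len(parts) >= 2:
        try:
            conc = float(parts[1])
        except ValueError:
            pass
    if len(parts) >= 3:
        try:
            rep = int(float(parts[2]))
        except ValueError:
            pass
    return zone_id, conc, rep


def _read_imagej(path: Path) -> list[ZoneMeasurement]:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "Mean" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'Mean'")
    labels = (
        df["Label"].astype(str).tolist()
        if "Label" in df.columns
        else [f"roi{i + 1}" for i in range(len(df))]
    )
    means = [ _to_float(v, i + 1, "Mean") for i, v in enumerate(df["Mean"].tolist()) ]

    suffixed = any(_CHANNEL_SUFFIX.search(lab) for lab in labels)
    out: list[ZoneMeasurement] = []
    if suffixed:
        groups: dict[str, dict[str, float]] = {}
        order: list[str] = []
        for lab, mean in zip(labels, means):
            m = _CHANNEL_SUFFIX.search(lab)
            if not m:
                raise ParseError(f"label {lab!r} lacks a channel suffix")
            channel = m.group(1).lower()
            base = _CHANNEL_SUFFIX.sub("", lab).strip()
            if base not in groups:
                groups[base] = {}
                order.append(base)
            groups[base][channel] = mean
        for base in order:
            g = groups[base]
            missing = {"red", "green", "blue"} - set(g)
            if missing:
                raise SchemaError(f"zone {base!r}: missing channel rows {sorted(missing)}")
            zone_id, conc, rep = _parse_imagej_label(base, base)
            out.append(
                ZoneMeasurement(zone_id, conc, g["red"], g["green"], g["blue"], replicate=rep)
            )
    else:
        if len(means) % 3 != 0:
            raise SchemaError(
                f"{path}: channel-split stack export needs row count divisible by 3, "
                f"got {len(means)}"
            )
        for k in range(0, len(means), 3):
            base = _CHANNEL_SUFFIX.sub("", labels[k]).strip()
            zone_id, conc, rep = _parse_imagej_label(base, f"roi{k // 3 + 1}")
            out.append(
                ZoneMeasurement(zone_id, conc, means[k], means[k + 1], means[k + 2], replicate=rep)
            )
    return out


def read_zone_layout(path: str | Path) -> list[ZoneSpec]:
    """Read a zone layout CSV: zone_id, center_x, center_y, radius
    plus optional concentration, unit, replicate columns."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("zone_id", "center_x", "center_y", "radius"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    zones: list[ZoneSpec] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        zone_id = str(rec["zone_id"])
        if zone_id in seen:
            raise SchemaError(f"{path}: duplicate zone_id {zone_id!r}")
        seen.add(zone_id)
        conc_raw = rec.get("concentration")
        conc = None if conc_raw is None or pd.isna(conc_raw) else _to_float(conc_raw, i, "concentration")
        rep_raw = rec.get("replicate")
        rep = 1 if rep_raw is None or pd.isna(rep_raw) else int(_to_float(rep_raw, i, "replicate"))
        zones.append(
            ZoneSpec(
                zone_id=zone_id,
                center_x=_to_float(rec["center_x"], i, "center_x"),
                center_y=_to_float(rec["center_y"], i, "center_y"),
                radius=_to_float(rec["radius"], i, "radius"),
                concentration=conc,
                unit=str(rec.get("unit", "") or "") if not pd.isna(rec.get("unit", "")) else "",
                replicate=rep,
            )
        )
    return zones


def write_zone_layout(zones: Sequence[ZoneSpec], path: str | Path) -> None:
    """Write a zone layout CSV in the schema read_zone_layout expects."""
    df = pd.DataFrame(
        {
            "zone_id": [z.zone_id for z in zones],
            "center_x": [z.center_x for z in zones],
            "center_y": [z.center_y for z in zones],
            "radius": [z.radius for z in zones],
            "concentration": [z.concentration for z in zones],
            "unit": [z.unit for z in zones],
            "replicate": [z.replicate for z in zones],
        }
    )
    df.to_csv(path, index=False)


def write_rgb_csv(measurements: Iterable[ZoneMeasurement], path: str | Path) -> None:
    """Write zone measurements in the native CSV dialect."""
    rows = list(measurements)
    df = pd.DataFrame(
        {
            "zone_id": [m.zone_id for m in rows],
            "concentration": [m.concentration for m in rows],
            "replicate": [m.replicate for m in rows],
            "R": [m.mean_R for m in rows],
            "G": [m.mean_G for m in rows],
            "B": [m.mean_B for m in rows],
            "unit": [m.unit for m in rows],
            "n_pixels": [m.n_pixels for m in rows],
        }
    )
    df.to_csv(path, index=False)
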