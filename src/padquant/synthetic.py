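"""Synthetic scans and RGB datasets with known ground truth.

The generator emulates a flatbed scan of a paper device: a grid of
circular detection zones bounded by dark wax-ink barrier rings on a light
paper background. Zone colour follows a linear per-channel response,

    mean_c(conc) = clip(blank_c + slope_c * conc + N(0, replicate_sd), 0, 255),

with independent Gaussian between-replicate noise per channel, and
(when rendering pixels) additional within-zone Gaussian pixel noise.
This is the simplest model consistent with linear calibration practice;
it deliberately omits scanner optics, JPEG artefacts, paper texture and
chromatographic spreading.

Defaults reproduce the bromothymol-blue (BTB) model-dye conditions:
blank ≈ (230.0, 226.1, 226.9), channel slopes (−0.594, −0.386, −0.212)
signal units per mg/L, six concentrations spanning 0–100 mg/L and three
replicate zones per concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import LayoutError, SaturationWarning
from .ingest import ImageRaster, ZoneMeasurement, ZoneSpec

__all__ = [
    "ResponseModel",
    "ScanLayout",
    "BTB_LIKE",
    "ZN_LIKE",
    "DEFAULT_CONCENTRATIONS",
    "generate_rgb_dataset",
    "render_scan",
    "write_manifest",
    "read_manifest",
]

#: calibration levels used by default (concentration units of the model)
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass
class ResponseModel:
    """Linear per-channel concentration response with Gaussian noise."""

    blank_rgb: tuple[float, float, float] = (230.0, 226.1, 226.9)
    channel_slopes: tuple[float, float, float] = (-0.594, -0.386, -0.212)
    replicate_sd: float = 1.5
    pixel_sd: float = 2.0
    unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.replicate_sd < 0 or self.pixel_sd < 0:
            raise LayoutError("noise SDs must be >= 0")

    def true_mean(self, concentration: float) -> np.ndarray:
        """Noise-free channel means before clipping."""
        return np.asarray(self.blank_rgb) + np.asarray(self.channel_slopes) * concentration


#: BTB-like dye response (all three channels darken with concentration)
BTB_LIKE = ResponseModel()

#: Zn(II)-complex-like response: only the green channel responds, over a
#: 0–0.4 mmol/L range (slope in signal units per mmol/L)
ZN_LIKE = ResponseModel(
    blank_rgb=(195.5, 195.6, 189.0),
    channel_slopes=(0.0, -78.65, 0.0),
    replicate_sd=1.5,
    pixel_sd=2.0,
    unit="mmol/L",
)


@dataclass
class ScanLayout:
    """Grid geometry of a rendered scan (pixels)."""

    rows: int = 3
    cols: int = 6
    circle_diameter_px: int = 60
    border_width_px: int = 3
    spacing_px: int = 12
    background_rgb: tuple[float, float, float] = (252.0, 250.0, 248.0)
    border_rgb: tuple[float, float, float] = (30.0, 28.0, 26.0)

    def __post_init__(self) -> None:
        if self.border_width_px < 1:
            raise LayoutError("border_width_px must be >= 1")
        if self.circle_diameter_px < 2:
            raise LayoutError("circle_diameter_px must be >= 2")

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    @property
    def cell_px(self) -> int:
        return self.circle_diameter_px + 2 * self.border_width_px + self.spacing_px


def _zone_means(
    model: ResponseModel,
    concentrations: Sequence[float],
    replicates: int,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, float, int, np.ndarray]], int]:
    """Per-zone channel means in deposition order; returns (zones, n_clipped)."""
    zones = []
    n_clipped = 0
    idx = 1
    for conc in concentrations:
        for rep in range(1, replicates + 1):
            raw = model.true_mean(conc) + rng.normal(0.0, model.replicate_sd, size=3)
            clipped = np.clip(raw, 0.0, 255.0)
            if np.any(raw != clipped):
                n_clipped += 1
            zones.append((f"z{idx:02d}", float(conc), rep, clipped))
            idx += 1
    return zones, n_clipped


def _saturation_check(n_clipped: int, n_total: int) -> None:
    if n_total and n_clipped / n_total > 0.20:
        warnings.warn(
            f"{n_clipped}/{n_total} zone means hit the [0, 255] clip bounds; "
            "the response model saturates the 8-bit scale",
            SaturationWarning,
            stacklevel=3,
        )


def _manifest(model: ResponseModel, concentrations, replicates, seed) -> dict[str, object]:
    return {
        "seed": seed,
        "unit": model.unit,
        "replicates": replicates,
        "concentrations": ",".join(str(c) for c in concentrations),
        "blank_R": model.blank_rgb[0],
        "blank_G": model.blank_rgb[1],
        "blank_B": model.blank_rgb[2],
        "slope_R": model.channel_slopes[0],
        "slope_G": model.channel_slopes[1],
        "slope_B": model.channel_slopes[2],
        "replicate_sd": model.replicate_sd,
        "pixel_sd": model.pixel_sd,
    }


def generate_rgb_dataset(
    model: ResponseModel,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[ZoneMeasurement], dict[str, object]]:
    """Draw zone-mean RGB data from the response model.

    Returns the measurements and a ground-truth manifest (true blanks,
    slopes, noise levels, seed). Reproducible: the same seed yields the
    same dataset.
    """
    if replicates < 1:
        raise LayoutError("replicates must be >= 1")
    if 0.0 not in [float(c) for c in concentrations]:
        raise LayoutError("concentrations must include 0 (the blank)")
    rng = np.random.default_rng(seed)
    zones, n_clipped = _zone_means(model, concentrations, replicates, rng)
    _saturation_check(n_clipped, len(zones))
    measurements = [
        ZoneMeasurement(
            zone_id=zid, concentration=conc, replicate=rep,
            mean_R=float(rgb[0]), mean_G=float(rgb[1]), mean_B=float(rgb[2]),
            unit=model.unit,
        )
        for zid, conc, rep, rgb in zones
    ]
    return measurements, _manifest(model, concentrations, replicates, seed)


def render_scan(
    layout: ScanLayout,
    model: ResponseModel,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ImageRaster, list[ZoneSpec], dict[str, object]]:
    """Render a synthetic scan of the zone grid.

    Zones fill the grid row-major in deposition order. Interior pixels are
    drawn from Normal(zone mean, pixel_sd) clipped to [0, 255]; the barrier
    ring (inner radius = circle radius, width = border_width_px) is drawn
    in the border colour. The returned ZoneSpecs are ground truth: the
    interior circles with their concentration and replicate labels.
    """
    n_zones = len(concentrations) * replicates
    if n_zones > layout.capacity:
        raise LayoutError(
            f"layout holds {layout.capacity} zones but {n_zones} were requested"
        )
    rng = np.random.default_rng(seed)
    zone_data, n_clipped = _zone_means(model, concentrations, replicates, rng)
    _saturation_check(n_clipped, len(zone_data))

    r_in = layout.circle_diameter_px / 2.0
    cell = layout.cell_px
    height = layout.rows * cell + layout.spacing_px
    width = layout.cols * cell + layout.spacing_px
    pixels = np.empty((height, width, 3), dtype=np.float64)
    pixels[:, :] = layout.background_rgb

    yy, xx = np.mgrid[0:height, 0:width]
    specs: list[ZoneSpec] = []
    for k, (zid, conc, rep, mean_rgb) in enumerate(zone_data):
        row, col = divmod(k, layout.cols)
        cx = layout.spacing_px + col * cell + (cell - layout.spacing_px) / 2.0
        cy = layout.spacing_px + row * cell + (cell - layout.spacing_px) / 2.0
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        interior = d2 <= r_in**2
        ring = (d2 > r_in**2) & (d2 <= (r_in + layout.border_width_px) ** 2)
        n_px = int(interior.sum())
        noise = rng.normal(0.0, model.pixel_sd, size=(n_px, 3))
        pixels[interior] = np.clip(mean_rgb[None, :] + noise, 0.0, 255.0)
        pixels[ring] = layout.border_rgb
        specs.append(
            ZoneSpec(
                zone_id=zid, center_x=cx, center_y=cy, radius=r_in,
                concentration=conc, unit=model.unit, replicate=rep,
            )
        )

    manifest = _manifest(model, concentrations, replicates, seed)
    manifest.update(
        rows=layout.rows, cols=layout.cols,
        circle_radius_px=r_in, border_width_px=layout.border_width_px,
    )
    raster = ImageRaster(pixels, source_path=None, bit_depth_original=8)
    return raster, specs, manifest


def write_manifest(manifest: dict[str, object], path: str | Path) -> None:
    """Write a ground-truth manifest as sorted key=value lines."""
    lines = [f"{k}={manifest[k]}" for k in sorted(manifest)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            out[k] = v
    return out
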