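"""Analytical-signal transforms for RGB zone means.

A colorimetric reaction in a paper device darkens (or shifts) the zone
colour; quantitation regresses a scalar *analytical signal* (AS) derived
from the mean R, G, B intensities against analyte concentration. Nineteen
candidate transforms are in common use, here frozen to a fixed numbering
so that reports are comparable across assays:

===  ==============================  =============
id   signal                          needs blank
===  ==============================  =============
1    R                               no
2    G                               no
3    B                               no
4    (R+G+B)/3                       no
5–7  log10(I0/I) for R, G, B         yes
8–10 I0 − I for R, G, B              yes
11   ΔR + ΔG + ΔB                    yes
12   (R+G+B)/R                       no
13   (R+G+B)/G                       no
14   (R+G+B)/B                       no
15   R/G                             no
16   G/B                             no
17   R/B                             no
18   ED = sqrt(ΔR² + ΔG² + ΔB²)      yes
19   −γ·log10(R·G·B / R0·G0·B0)      yes
===  ==============================  =============

where Δc = c0 − c (blank minus reacted zone) and I0 is the blank
intensity. The log base is 10 by analogy with attenuance; it is
configurable. HSV channel conversion is provided for completeness.
"""

from __future__ import annotations

import colorsys
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DivisionGuardError,
    DomainError,
    PairingError,
)
from .ingest import ZoneMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "BlankReference",
    "MethodSpec",
    "SignalValue",
    "HSVTriple",
    "METHODS",
    "METHOD_IDS",
    "get_method",
    "compute_signal",
    "compute_all_signals",
    "multi_zone_ed",
    "rgb_to_hsv",
    "hsv_to_rgb",
]


@dataclass
class BlankReference:
    """Channel means (and replicate SDs) of the zero-concentration zones."""

    R0: float
    G0: float
    B0: float
    n_blank: int = 1
    sd_R0: float = 0.0
    sd_G0: float = 0.0
    sd_B0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R0", "G0", "B0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ConfigurationError(f"blank {name}={v} outside [0, 255]")
        if self.n_blank < 1:
            raise ConfigurationError("n_blank must be >= 1")
        if min(self.sd_R0, self.sd_G0, self.sd_B0) < 0:
            raise ConfigurationError("blank SDs must be >= 0")

    @property
    def rgb(self) -> tuple[float, float, float]:
        return (self.R0, self.G0, self.B0)

    @classmethod
    def from_measurements(cls, zones: Iterable[ZoneMeasurement]) -> "BlankReference":
        """Aggregate all zero-concentration zones into a blank reference."""
        blanks = [z for z in zones if z.concentration == 0]
        if not blanks:
            raise ConfigurationError("no zero-concentration zones to form a blank")
        arr = np.array([[z.mean_R, z.mean_G, z.mean_B] for z in blanks], dtype=float)
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1) if len(blanks) > 1 else np.zeros(3)
        return cls(
            R0=float(means[0]), G0=float(means[1]), B0=float(means[2]),
            n_blank=len(blanks),
            sd_R0=float(sds[0]), sd_G0=float(sds[1]), sd_B0=float(sds[2]),
        )


@dataclass(frozen=True)
class MethodSpec:
    """One enumerated signal transform."""

    method_id: int
    label: str
    column: str
    requires_blank: bool
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.method_id <= 19:
            raise ConfigurationError(f"method_id must be in 1..19, got {self.method_id}")


@dataclass
class SignalValue:
    """One analytical-signal value for one zone."""

    method_id: int
    zone_id: str
    value: float


@dataclass
class HSVTriple:
    """Hue in degrees [0, 360), saturation and value in percent [0, 100]."""

    H: float
    S: float
    V: float


_BLANK_METHODS = frozenset({5, 6, 7, 8, 9, 10, 11, 18, 19})

METHODS: dict[int, MethodSpec] = {
    m.method_id: m
    for m in [
        MethodSpec(1, "R", "m01_R", False),
        MethodSpec(2, "G", "m02_G", False),
        MethodSpec(3, "B", "m03_B", False),
        MethodSpec(4, "(R+G+B)/3", "m04_mean", False),
        MethodSpec(5, "log(R0/R)", "m05_logR", True),
        MethodSpec(6, "log(G0/G)", "m06_logG", True),
        MethodSpec(7, "log(B0/B)", "m07_logB", True),
        MethodSpec(8, "R0-R", "m08_dR", True),
        MethodSpec(9, "G0-G", "m09_dG", True),
        MethodSpec(10, "B0-B", "m10_dB", True),
        MethodSpec(11, "dR+dG+dB", "m11_sumdelta", True),
        MethodSpec(12, "(R+G+B)/R", "m12_sumoverR", False),
        MethodSpec(13, "(R+G+B)/G", "m13_sumoverG", False),
        MethodSpec(14, "(R+G+B)/B", "m14_sumoverB", False),
        MethodSpec(15, "R/G", "m15_RoverG", False),
        MethodSpec(16, "G/B", "m16_GoverB", False),
        MethodSpec(17, "R/B", "m17_RoverB", False),
        MethodSpec(18, "ED", "m18_ed", True),
        MethodSpec(19, "-log(RGB/R0G0B0)", "m19_logprod", True),
    ]
}

METHOD_IDS: tuple[int, ...] = tuple(sorted(METHODS))

assert all(METHODS[i].requires_blank == (i in _BLANK_METHODS) for i in METHODS)


def get_method(method: "int | MethodSpec") -> MethodSpec:
    if isinstance(method, MethodSpec):
        return method
    if method not in METHODS:
        raise ConfigurationError(f"unknown method id {method!r}")
    return METHODS[method]


def _guard_positive(value: float, name: str, clamp: bool) -> float:
    if value > 0:
        return value
    if clamp:
        return 1.0
    raise DomainError(f"{name}={value} is not positive; log method undefined")


def _guard_denominator(value: float, name: str, clamp: bool) -> float:
    if value != 0:
        return value
    if clamp:
        return 1.0
    raise DivisionGuardError(f"denominator channel {name} is zero")


def compute_signal(
    method: int | MethodSpec,
    z: ZoneMeasurement,
    blank: BlankReference | None = None,
    *,
    log_base: float = 10.0,
    clamp: bool = False,
) -> SignalValue:
    """Compute one analytical-signal value for one zone.

    ``clamp=True`` replaces non-positive intensities (log methods) or zero
    denominators (ratio methods) by 1 instead of raising; it is off by
    default because silent clamping biases calibrations.
    """
    m = get_method(method)
    if m.requires_blank and blank is None:
        raise ConfigurationError(f"method {m.method_id} ({m.label}) requires a blank reference")

    R, G, B = z.mean_R, z.mean_G, z.mean_B
    log = lambda v: math.log(v, log_base)  # noqa: E731

    if m.method_id == 1:
        value = R
    elif m.method_id == 2:
        value = G
    elif m.method_id == 3:
        value = B
    elif m.method_id == 4:
        value = (R + G + B) / 3.0
    elif m.method_id in (5, 6, 7):
        i0 = (blank.R0, blank.G0, blank.B0)[m.method_id - 5]
        i = (R, G, B)[m.method_id - 5]
        name = "RGB"[m.method_id - 5]
        value = log(_guard_positive(i0, name + "0", clamp) / _guard_positive(i, name, clamp))
    elif m.method_id in (8, 9, 10):
        i0 = (blank.R0, blank.G0, blank.B0)[m.method_id - 8]
        i = (R, G, B)[m.method_id - 8]
        value = i0 - i
    elif m.method_id == 11:
        value = (blank.R0 - R) + (blank.G0 - G) + (blank.B0 - B)
    elif m.method_id == 12:
        value = (R + G + B) / _guard_denominator(R, "R", clamp)
    elif m.method_id == 13:
        value = (R + G + B) / _guard_denominator(G, "G", clamp)
    elif m.method_id == 14:
        value = (R + G + B) / _guard_denominator(B, "B", clamp)
    elif m.method_id == 15:
        value = R / _guard_denominator(G, "G", clamp)
    elif m.method_id == 16:
        value = G / _guard_denominator(B, "B", clamp)
    elif m.method_id == 17:
        value = R / _guard_denominator(B, "B", clamp)
    elif m.method_id == 18:
        value = math.sqrt((blank.R0 - R) ** 2 + (blank.G0 - G) ** 2 + (blank.B0 - B) ** 2)
    elif m.method_id == 19:
        num = (
            _guard_positive(R, "R", clamp)
            * _guard_positive(G, "G", clamp)
            * _guard_positive(B, "B", clamp)
        )
        den = (
            _guard_positive(blank.R0, "R0", clamp)
            * _guard_positive(blank.G0, "G0", clamp)
            * _guard_positive(blank.B0, "B0", clamp)
        )
        value = -m.gamma * log(num / den)
    else:  # pragma: no cover
        raise ConfigurationError(f"unhandled method id {m.method_id}")

    return SignalValue(method_id=m.method_id, zone_id=z.zone_id, value=float(value))


def compute_all_signals(
    zones: Sequence[ZoneMeasurement],
    blank: BlankReference | None = None,
    methods: Sequence[int | MethodSpec] | None = None,
    *,
    include_hsv: bool = False,
    log_base: float = 10.0,
    gamma: float = 1.0,
    clamp: bool = False,
) -> pd.DataFrame:
    """Build the zone × method signal table.

    One row per zone (zone_id, concentration, replicate, then one column
    per method). Per-zone method failures (e.g. a zero denominator) are
    recorded as NaN with a logged reason rather than aborting the table.
    """
    if not zones:
        raise ConfigurationError("compute_all_signals needs at least one zone")
    specs = [get_method(m) for m in (methods if methods is not None else METHOD_IDS)]
    specs = [replace(s, gamma=gamma) if s.method_id == 19 else s for s in specs]

    records: list[dict[str, object]] = []
    for z in zones:
        rec: dict[str, object] = {
            "zone_id": z.zone_id,
            "concentration": z.concentration,
            "replicate": z.replicate,
        }
        for spec in specs:
            try:
                rec[spec.column] = compute_signal(
                    spec, z, blank, log_base=log_base, clamp=clamp
                ).value
            except (DivisionGuardError, DomainError, ConfigurationError) as exc:
                logger.warning(
                    "zone %s method %d (%s): %s", z.zone_id, spec.method_id, spec.label, exc
                )
                rec[spec.column] = np.nan
        if include_hsv:
            hsv = rgb_to_hsv(z)
            rec["hue_deg"] = hsv.H
            rec["sat_pct"] = hsv.S
            rec["val_pct"] = hsv.V
        records.append(rec)
    return pd.DataFrame.from_records(records)


def multi_zone_ed(
    zones: Sequence[ZoneMeasurement], blanks: Sequence[BlankReference]
) -> SignalValue:
    """Euclidean RGB distance accumulated over several zone/blank pairs.

    The squared per-channel deltas of every pair are summed before the
    square root; with a single pair this reduces to method 18.
    """
    if len(zones) != len(blanks):
        raise PairingError(f"{len(zones)} zones cannot pair with {len(blanks)} blanks")
    if not zones:
        raise PairingError("multi_zone_ed needs at least one zone/blank pair")
    total = 0.0
    for z, b in zip(zones, blanks):
        total += (b.R0 - z.mean_R) ** 2 + (b.G0 - z.mean_G) ** 2 + (b.B0 - z.mean_B) ** 2
    zone_id = zones[0].zone_id if len(zones) == 1 else "+".join(z.zone_id for z in zones)
    return SignalValue(method_id=18, zone_id=zone_id, value=math.sqrt(total))


def rgb_to_hsv(z: ZoneMeasurement | tuple[float, float, float]) -> HSVTriple:
    """Standard hexcone RGB→HSV conversion.

    Hue in degrees [0, 360), saturation and value in percent. Hue is 0 by
    convention on the grey axis (R = G = B, where saturation is 0).
    """
    r, g, b = z.rgb if isinstance(z, ZoneMeasurement) else z
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return HSVTriple(H=(h * 360.0) % 360.0, S=s * 100.0, V=v * 100.0)


def hsv_to_rgb(hsv: HSVTriple) -> tuple[float, float, float]:
    """Inverse hexcone conversion back to 0–255 channel intensities."""
    r, g, b = colorsys.hsv_to_rgb((hsv.H % 360.0) / 360.0, hsv.S / 100.0, hsv.V / 100.0)
    return (r * 255.0, g * 255.0, b * 255.0)
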