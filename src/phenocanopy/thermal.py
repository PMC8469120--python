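"""Thermal raster handling: centikelvin conversion, pseudocolor, zonal stats.

Thermal cameras of the kind used for canopy-temperature screening store each
pixel as a 16-bit raw value in centikelvin (hundredths of a Kelvin), so

    celsius = raw / 100 - 273.15

e.g. raw 29,200 is 18.85 degC and 29,350 is 20.35 degC — the default
rendering range, with plants under drought showing up warm.  This module
renders a discrete blue-to-red pseudocolor for inspection and computes the
mean canopy temperature per pot ROI (zonal statistics with pixel-center
containment), the headless equivalent of a GIS circle-polygon + zonal-stats
workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .layout import ExperimentLayout, PotRoi

__all__ = [
    "ThermalRaster",
    "ZonalStat",
    "ZonalError",
    "PseudocolorSpec",
    "raw_to_celsius",
    "pseudocolor",
    "pseudocolor_rgb",
    "zonal_mean",
    "zonal_table",
    "read_thermal_tif",
    "write_thermal_tif",
]

PLAUSIBLE_RAW = (20000, 40000)  # roughly -73 .. +127 degC


class ZonalError(ValueError):
    """An ROI covers no valid raster pixels."""


@dataclass
class ThermalRaster:
    """Single-band 16-bit raster of raw centikelvin values."""

    pixels: np.ndarray
    nodata: Optional[int] = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("thermal raster must be a single 2-D band")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("thermal raster must hold integer raw values")
        self.pixels = px.astype(np.uint16)
        valid = self.valid_mask()
        if valid.any():
            lo, hi = int(self.pixels[valid].min()), int(self.pixels[valid].max())
            if lo < PLAUSIBLE_RAW[0] or hi > PLAUSIBLE_RAW[1]:
                warnings.warn(
                    f"raw values span [{lo}, {hi}], outside the plausible "
                    f"centikelvin range {PLAUSIBLE_RAW}",
                    stacklevel=2,
                )

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.pixels != self.nodata

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def celsius(self) -> np.ndarray:
        """Float degC image; nodata pixels become NaN."""
        c = self.pixels.astype(float) / 100.0 - 273.15
        if self.nodata is not None:
            c = np.where(self.valid_mask(), c, np.nan)
        return c


@dataclass(frozen=True)
class ZonalStat:
    roi_id: str
    mean_c: float
    min_c: float
    max_c: float
    n_pixels: int


@dataclass(frozen=True)
class PseudocolorSpec:
    """Discrete rendering of raw values into n equal-width bins, blue to red."""

    low_raw: int = 29200
    high_raw: int = 29350
    n_bins: int = 8
    palette: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.low_raw >= self.high_raw:
            raise ValueError("low_raw must be < high_raw")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.palette is None:
            object.__setattr__(self, "palette", _blue_red_palette(self.n_bins))
        else:
            pal = np.asarray(self.palette, dtype=np.uint8)
            if pal.shape != (self.n_bins, 3):
                raise ValueError(f"palette must be ({self.n_bins}, 3)")
            object.__setattr__(self, "palette", pal)


def _blue_red_palette(n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    pal = np.stack([255 * t, np.zeros(n), 255 * (1 - t)], axis=1)
    return np.round(pal).astype(np.uint8)


def raw_to_celsius(raw):
    """Convert raw centikelvin values to degrees Celsius (raw/100 - 273.15)."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("raw thermal values must be positive")
    out = raw / 100.0 - 273.15
    return float(out) if out.ndim == 0 else out


def pseudocolor(raster: ThermalRaster, spec: PseudocolorSpec | None = None) -> np.ndarray:
    """Bin index image in [0, n_bins): half-open equal-width bins over
    [low_raw, high_raw], clamped — below range falls in the first bin, above
    range (including high_raw itself) in the last."""
    if spec is None:
        spec = PseudocolorSpec()
    raw = raster.pixels.astype(float)
    width = (spec.high_raw - spec.low_raw) / spec.n_bins
    idx = np.floor((np.clip(raw, spec.low_raw, spec.high_raw) - spec.low_raw) / width)
    return np.clip(idx, 0, spec.n_bins - 1).astype(np.uint8)


def pseudocolor_rgb(raster: ThermalRaster, spec: PseudocolorSpec | None = None) -> np.ndarray:
    """RGB rendering of the discrete pseudocolor (for writing to PNG)."""
    if spec is None:
        spec = PseudocolorSpec()
    return spec.palette[pseudocolor(raster, spec)]


def zonal_mean(raster: ThermalRaster, roi: PotRoi) -> ZonalStat:
    """Mean/min/max canopy temperature (degC) over one pot ROI.

    Pixels are included when their centers fall inside the geometry; nodata
    pixels are excluded from all statistics.
    """
    h, w = raster.shape
    inside = roi.pixel_mask(h, w) & raster.valid_mask()
    n = int(inside.sum())
    if n == 0:
        raise ZonalError(f"roi {roi.id!r} covers no valid raster pixels")
    c = raw_to_celsius(raster.pixels[inside].astype(float))
    return ZonalStat(
        roi_id=roi.id,
        mean_c=float(np.mean(c)),
        min_c=float(np.min(c)),
        max_c=float(np.max(c)),
        n_pixels=n,
    )


def zonal_table(raster: ThermalRaster, layout: ExperimentLayout) -> pd.DataFrame:
    """Zonal statistics for every pot of a layout, as a tidy table."""
    rows = [zonal_mean(raster, pot).__dict__ for pot in layout.pots]
    return pd.DataFrame(rows, columns=["roi_id", "mean_c", "min_c", "max_c", "n_pixels"])


def read_thermal_tif(path, nodata: Optional[int] = None) -> ThermalRaster:
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return ThermalRaster(pixels=np.asarray(arr), nodata=nodata)


def write_thermal_tif(raster: ThermalRaster, path) -> None:
    import tifffile

    tifffile.imwrite(path, raster.pixels.astype(np.uint16))
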