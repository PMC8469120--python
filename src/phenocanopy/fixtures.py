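"""Synthetic scenes, thermal rasters and growth cohorts with exact ground truth.

Nothing here tries to look photorealistic.  The generators emulate the
*statistical structure* the pipeline relies on — green leaves with a strong
green-minus-red excess over a dark floor, senescent leaves with a distinct
color mode, soil clutter, drought-warmed pots in thermal rasters, logistic
growth with treatment effects and programmed emergence days — while keeping
per-pixel / per-record ground truth, so every downstream module can be
tested to zero tolerance.

Color-margin guarantee
----------------------
Rendered leaf pixels always satisfy ``40 <= G - R <= 50`` (10 units above
the default G - R threshold of 30 and within the despeckle deviation
threshold of 50, so the outlier filter provably never touches them), and the
background/soil use luminance-only noise (the same offset added to all three
channels), so their channel differences are exactly zero.  Under these
margins the segmentation mask equals the rendered plant mask pixel for
pixel, which is what makes zero-error pipeline tests meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .classifier import GREEN, YELLOW
from .layout import ExperimentLayout, PotRoi, grid_layout
from .thermal import ThermalRaster

__all__ = [
    "PlantPlacement",
    "SoilPatch",
    "PlantSceneSpec",
    "SceneTruth",
    "ThermalTruth",
    "CohortTruth",
    "make_plant_image",
    "sample_training_pixels",
    "make_thermal_raster",
    "make_growth_cohort",
    "scene_spec_for_layout",
]

GR_RANGE = (40, 50)  # guaranteed G - R excess of every rendered leaf pixel


@dataclass(frozen=True)
class PlantPlacement:
    """One plant: a rosette of elliptical leaves around a center (row, col)."""

    center: tuple[float, float]
    n_leaves: int = 5
    leaf_len: tuple[float, float] = (8.0, 14.0)
    leaf_width: tuple[float, float] = (3.0, 6.0)
    yellow_fraction: float = 0.0


@dataclass(frozen=True)
class SoilPatch:
    """A soil-colored disc; fails both channel-difference masks by design."""

    center: tuple[float, float]
    radius: float
    color: tuple[int, int, int] = (90, 70, 50)


@dataclass(frozen=True)
class PlantSceneSpec:
    size: tuple[int, int] = (120, 160)
    background: tuple[int, int, int] = (15, 15, 15)
    background_noise_sd: float = 2.0
    plants: tuple[PlantPlacement, ...] = ()
    soil: tuple[SoilPatch, ...] = ()
    green_mu: tuple[int, int, int] = (70, 115, 30)
    green_sd: float = 4.0
    yellow_mu: tuple[int, int, int] = (150, 195, 40)
    yellow_sd: float = 4.0
    seed: int = 0


@dataclass
class SceneTruth:
    """Exact per-pixel ground truth of a rendered scene."""

    mask: np.ndarray
    labels: np.ndarray
    green_count: int
    yellow_count: int

    def per_roi_counts(self, layout: ExperimentLayout) -> dict[str, tuple[int, int]]:
        h, w = self.labels.shape
        out = {}
        for pot in layout.pots:
            inside = pot.pixel_mask(h, w)
            out[pot.id] = (
                int(((self.labels == GREEN) & inside).sum()),
                int(((self.labels == YELLOW) & inside).sum()),
            )
        return out


def _luminance_fill(img: np.ndarray, where, color, sd: float, rng) -> None:
    """Paint ``color`` + per-pixel luminance jitter (same offset per channel)."""
    rr, cc = where
    n = len(rr)
    jitter = np.round(rng.normal(0.0, sd, n)).astype(int) if sd > 0 else np.zeros(n, int)
    lo = -min(color)
    hi = 255 - max(color)
    jitter = np.clip(jitter, lo, hi)
    for ch in range(3):
        img[rr, cc, ch] = (color[ch] + jitter).astype(np.uint8)


def _leaf_colors(n: int, mu, sd: float, rng) -> np.ndarray:
    """Sample n leaf-pixel colors with the margin guarantee (see module doc)."""
    r = np.clip(np.round(rng.normal(mu[0], sd, n)), 0, 205).astype(int)
    d = rng.integers(GR_RANGE[0], GR_RANGE[1] + 1, n)
    g = r + d  # 40 <= G - R <= 50 exactly
    b = np.clip(np.round(rng.normal(mu[2], sd, n)), 0, None).astype(int)
    b = np.minimum(b, g - 5)  # keep B - G well below the (3, 255) band
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def make_plant_image(spec: PlantSceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render a top-view RGB scene and its exact ground truth.

    Deterministic given ``spec`` (the seed fixes every sample).  Leaves
    falling outside the canvas are clipped and the ground truth reflects the
    clipped rendering; overlapping leaves follow paint order, so the final
    per-pixel label always matches the visible color.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((h, w, 3), dtype=np.uint8)
    _luminance_fill(
        img,
        np.nonzero(np.ones((h, w), dtype=bool)),
        spec.background,
        spec.background_noise_sd,
        rng,
    )
    labels = np.zeros((h, w), dtype=np.uint8)

    for patch in spec.soil:
        rr, cc = draw_disk(patch.center, patch.radius, shape=(h, w))
        _luminance_fill(img, (rr, cc), patch.color, spec.background_noise_sd, rng)
        labels[rr, cc] = 0

    for plant in spec.plants:
        cy, cx = plant.center
        for _ in range(plant.n_leaves):
            angle = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(*plant.leaf_len)
            width = rng.uniform(*plant.leaf_width)
            # leaf grows outward from the plant center
            ecy = cy + 0.6 * length * np.sin(angle)
            ecx = cx + 0.6 * length * np.cos(angle)
            rr, cc = draw_ellipse(ecy, ecx, width, length, shape=(h, w), rotation=angle)
            if len(rr) == 0:
                continue
            is_yellow = rng.random() < plant.yellow_fraction
            mu, sd = (
                (spec.yellow_mu, spec.yellow_sd)
                if is_yellow
                else (spec.green_mu, spec.green_sd)
            )
            img[rr, cc] = _leaf_colors(len(rr), mu, sd, rng)
            labels[rr, cc] = YELLOW if is_yellow else GREEN

    mask = labels > 0
    return img, SceneTruth(
        mask=mask,
        labels=labels,
        green_count=int((labels == GREEN).sum()),
        yellow_count=int((labels == YELLOW).sum()),
    )


def sample_training_pixels(
    spec: PlantSceneSpec, n_per_class: int = 500, seed: int = 12345
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled (r, g, b) training pixels from the scene's color model.

    These emulate hand-labelled green/yellow leaf regions for fitting the
    pixel classifier; they use the same constrained sampler as the renderer.
    """
    rng = np.random.default_rng(seed)
    Xg = _leaf_colors(n_per_class, spec.green_mu, spec.green_sd, rng)
    Xy = _leaf_colors(n_per_class, spec.yellow_mu, spec.yellow_sd, rng)
    X = np.concatenate([Xg, Xy]).astype(float)
    y = np.concatenate([np.full(n_per_class, GREEN), np.full(n_per_class, YELLOW)])
    return X, y


def scene_spec_for_layout(
    layout: ExperimentLayout,
    size: tuple[int, int],
    seed: int = 0,
    yellow_fraction: float = 0.25,
    n_leaves: int = 5,
    soil: bool = True,
) -> PlantSceneSpec:
    """Place one plant (and optionally a soil patch) inside every pot ROI."""
    rng = np.random.default_rng(seed)
    plants = []
    patches = []
    for pot in layout.pots:
        x0, y0, x1, y1 = pot.bounding_box()
        cy = (y0 + y1) / 2.0
        cx = (x0 + x1) / 2.0
        plants.append(
            PlantPlacement(
                center=(cy, cx),
                n_leaves=n_leaves,
                yellow_fraction=yellow_fraction,
            )
        )
        if soil:
            patches.append(
                SoilPatch(center=(cy + 0.2 * (y1 - y0), cx - 0.2 * (x1 - x0)), radius=4.0)
            )
    return PlantSceneSpec(
        size=size,
        plants=tuple(plants),
        soil=tuple(patches),
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
    )


# --- thermal ------------------------------------------------------------


@dataclass
class ThermalTruth:
    roi_mean_c: dict[str, float]
    roi_n_pixels: dict[str, int]
    base_raw: int


def make_thermal_raster(
    rois,
    shape: tuple[int, int] = (60, 80),
    base_raw: int = 29275,
    roi_deltas: Optional[dict[str, float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ThermalRaster, ThermalTruth]:
    """Flat raster + per-ROI raw offsets + rounded Gaussian noise.

    Emulates a canopy-temperature frame where drought pots sit a fixed raw
    offset above the background.  Ground truth stores the exact per-ROI mean
    temperature of the *realized* (noisy, rounded) raster.
    """
    rng = np.random.default_rng(seed)
    roi_deltas = roi_deltas or {}
    h, w = shape
    raw = np.full((h, w), float(base_raw))
    for roi in rois:
        delta = roi_deltas.get(roi.id, 0.0)
        if delta:
            raw[roi.pixel_mask(h, w)] += delta
    if noise_sd > 0:
        raw += rng.normal(0.0, noise_sd, (h, w))
    raw = np.clip(np.round(raw), 1, 65535).astype(np.uint16)
    raster = ThermalRaster(pixels=raw)

    mean_c, n_px = {}, {}
    for roi in rois:
        inside = roi.pixel_mask(h, w)
        vals = raw[inside].astype(float) / 100.0 - 273.15
        mean_c[roi.id] = float(vals.mean())
        n_px[roi.id] = int(inside.sum())
    return raster, ThermalTruth(roi_mean_c=mean_c, roi_n_pixels=n_px, base_raw=base_raw)


# --- growth cohort ------------------------------------------------------


@dataclass
class CohortTruth:
    layout: ExperimentLayout
    emergence_day: dict[str, int]          # programmed emergence per unit
    sampled_emergence_day: dict[str, int]  # first sampling day >= programmed
    effect_profile: dict[str, float]
    drought_windows: dict[str, tuple[int, int, float]]
    target_correlation: Optional[float]
    weight_per_pixel: float
    weight_noise_sd: float


def _logistic_area(
    t: np.ndarray, emergence: float, capacity: float, rate: float, half_rise: float
) -> np.ndarray:
    area = capacity / (1.0 + np.exp(-rate * ((t - emergence) - half_rise)))
    return np.where(t >= emergence, area, 0.0)


def make_growth_cohort(
    n_per_treatment: int = 4,
    effect_profile: Optional[dict[str, float]] = None,
    drought_windows: Optional[dict[str, tuple[int, int, float]]] = None,
    emergence_days: Optional[dict[str, list[int]]] = None,
    days: Optional[np.ndarray] = None,
    growth_noise_sd: float = 0.05,
    target_correlation: Optional[float] = 0.96,
    carrying_capacity: float = 60000.0,
    rate: float = 0.25,
    half_rise: float = 20.0,
    weight_per_pixel: float = 1.2e-4,
    dry_ratio: float = 0.12,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a pot experiment's biomass and conventional-weight tables.

    Green-pixel series follow a logistic rise per pot, scaled by a
    per-treatment growth multiplier, depressed by a factor inside an optional
    drought window, zero before the unit's programmed emergence day, and
    jittered by multiplicative lognormal noise (``growth_noise_sd``).

    Defaults mirror a wheat-style four-arm design: control, drought at stem
    elongation (days 38-44, depression 0.6), drought at heading (days 45-51,
    depression 0.5) and extra nitrogen at heading (multiplier 1.15), four
    replicates each, sampled every second day from day 7 to day 57.

    Fresh weight is ``base + a * green_pixels + e`` with the noise variance
    of ``e`` calibrated against the closed-form attenuation
    ``r = 1 / sqrt(1 + var(e) / var(a * signal))`` so that the pooled
    digital-vs-fresh correlation targets ``target_correlation`` (None for
    exact linear weights); dry weight is a fixed fraction of fresh.

    Returns tidy biomass and conventional tables plus the full ground truth
    (layout, emergence schedule, calibration constants).
    """
    rng = np.random.default_rng(seed)
    if effect_profile is None:
        effect_profile = {"control": 1.0, "D_SE": 1.0, "D_H": 1.0, "H_N": 1.15}
    if drought_windows is None:
        drought_windows = {"D_SE": (38, 44, 0.6), "D_H": (45, 51, 0.5)}
        drought_windows = {
            k: v for k, v in drought_windows.items() if k in effect_profile
        }
    if days is None:
        days = np.arange(7, 58, 2)
    days = np.asarray(days, dtype=int)

    treatments = list(effect_profile)
    pots = []
    for t_idx, treatment in enumerate(treatments):
        for rep in range(n_per_treatment):
            pots.append(
                PotRoi(
                    id=f"{treatment}_{rep + 1}",
                    shape="rectangle",
                    coords=(t_idx * 10, rep * 10, t_idx * 10 + 10, rep * 10 + 10),
                    treatment=treatment,
                    replicate=rep + 1,
                )
            )
    layout = ExperimentLayout(name="synthetic-cohort", pots=pots)

    emergence: dict[str, int] = {}
    sampled_emergence: dict[str, int] = {}
    bio_rows = []
    for pot in pots:
        if emergence_days and pot.treatment in emergence_days:
            choices = emergence_days[pot.treatment]
            e_day = int(choices[(pot.replicate - 1) % len(choices)])
        else:
            e_day = int(days[0])
        emergence[pot.id] = e_day
        on_grid = days[days >= e_day]
        sampled_emergence[pot.id] = int(on_grid[0]) if on_grid.size else -1

        mult = effect_profile[pot.treatment]
        area = _logistic_area(days.astype(float), e_day, carrying_capacity * mult, rate, half_rise)
        if pot.treatment in drought_windows:
            start, end, factor = drought_windows[pot.treatment]
            in_window = (days >= start) & (days <= end)
            area = np.where(in_window, area * factor, area)
        if growth_noise_sd > 0:
            area = area * np.exp(rng.normal(0.0, growth_noise_sd, len(days)))
        green = np.round(area).astype(int)
        # senescence: a late-season yellow fraction ramping up after heading
        yellow = np.round(green * np.clip((days - 45) / 60.0, 0.0, 0.25)).astype(int)
        for d, g, y in zip(days, green, yellow):
            bio_rows.append(
                {
                    "pot_id": pot.id,
                    "day": int(d),
                    "green_pixels": int(g),
                    "yellow_pixels": int(y),
                }
            )
    biomass = pd.DataFrame(bio_rows, columns=["pot_id", "day", "green_pixels", "yellow_pixels"])

    green_all = biomass["green_pixels"].to_numpy(float)
    signal = weight_per_pixel * green_all
    if target_correlation is None:
        noise_sd = 0.0
    else:
        r = float(target_correlation)
        noise_sd = float(np.std(signal) * np.sqrt(1.0 / r**2 - 1.0))
    base_weight = max(0.5, 4.0 * noise_sd)
    fresh = base_weight + signal + rng.normal(0.0, noise_sd, len(signal))
    fresh = np.clip(fresh, 0.0, None)
    dry = dry_ratio * fresh
    conventional = pd.DataFrame(
        {
            "pot_id": biomass["pot_id"],
            "day": biomass["day"],
            "fresh_weight_g": fresh,
            "dry_weight_g": dry,
        }
    )
    truth = CohortTruth(
        layout=layout,
        emergence_day=emergence,
        sampled_emergence_day=sampled_emergence,
        effect_profile=dict(effect_profile),
        drought_windows=dict(drought_windows),
        target_correlation=target_correlation,
        weight_per_pixel=weight_per_pixel,
        weight_noise_sd=noise_sd,
    )
    return biomass, conventional, truth
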