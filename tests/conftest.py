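"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results with the dumbest possible
loops so they share no code path with the implementation they check.
"""

import numpy as np
import pytest

from phenocanopy import GaussianPixelClassifier, grid_layout
from phenocanopy import fixtures as fx


def oracle_remove_outliers(img, radius, threshold, polarity):
    """Double-loop reference for the despeckle filter (edge-truncated disc,
    lower median, replacements from the original image)."""
    img = np.asarray(img, dtype=int)
    h, w = img.shape
    out = img.copy()
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy * dy + dx * dx > radius * radius:
                        continue
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w:
                        vals.append(img[ny, nx])
            vals.sort()
            m = vals[(len(vals) - 1) // 2]
            v = img[y, x]
            if polarity == "bright" and v - m > threshold:
                out[y, x] = m
            elif polarity == "dark" and m - v > threshold:
                out[y, x] = m
    return out


def oracle_zonal(raw, roi):
    """Exhaustive pixel-center containment + mean/min/max in Celsius."""
    h, w = raw.shape
    vals = []
    for y in range(h):
        for x in range(w):
            if roi.shape == "rectangle":
                x0, y0, x1, y1 = roi.coords
                inside = (x0 <= x < x1) and (y0 <= y < y1)
            else:
                cx, cy, r = roi.coords
                inside = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
            if inside:
                vals.append(raw[y, x] / 100.0 - 273.15)
    return vals


@pytest.fixture(scope="session")
def scene_layout():
    return grid_layout(2, 2, 60, name="scene")


@pytest.fixture(scope="session")
def scene(scene_layout):
    spec = fx.scene_spec_for_layout(scene_layout, size=(120, 120), seed=7, yellow_fraction=0.3)
    img, truth = fx.make_plant_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def trained_model(scene):
    spec, _, _ = scene
    X, y = fx.sample_training_pixels(spec, n_per_class=400, seed=99)
    return GaussianPixelClassifier().fit(X, y)
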