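"""Color-difference plant segmentation for top-view pot images.

The segmentation exploits the channel imbalance of vegetation against a dark
floor: green leaves have a strong green-minus-red excess, and a second
blue-minus-green difference catches leaves the first mask misses.  The full
pipeline for one pot is

1. zero every pixel outside the pot's region of interest;
2. compute the two saturating channel differences (G - R and B - G);
3. despeckle each difference with an ImageJ-style "Remove Outliers" rank
   filter (circular neighborhood, bright polarity);
4. apply a fixed inclusive band threshold to each difference — (30, 255) for
   G - R and (3, 255) for B - G under constant illumination;
5. fuse the two binary masks with a pixelwise OR.

The mask marks candidate plant pixels (green and yellow leaves and, in some
scenes, soil); a downstream color classifier splits them into classes.

Median convention
-----------------
Neighborhood medians use the *lower median*: sort the in-bounds neighborhood
values ascending and take the element at index ``(n - 1) // 2``.  This is
integer-valued and deterministic, which keeps the filter exactly checkable
against a brute-force oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

from .layout import PotRoi

__all__ = [
    "CHANNELS",
    "SegmentationParams",
    "EmptyRoiError",
    "zero_outside_roi",
    "channel_difference",
    "threshold_mask",
    "remove_outliers",
    "fuse_masks",
    "segment_plant",
]

logger = logging.getLogger(__name__)

CHANNELS = {"red": 0, "green": 1, "blue": 2}


class EmptyRoiError(ValueError):
    """The ROI contains no pixels of the image."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    Defaults are the fixed values used under constant chamber illumination:
    band (30, 255) on green-minus-red, band (3, 255) on blue-minus-green, and
    a bright-polarity outlier filter with radius 10 px and deviation
    threshold 50.
    """

    thr_gr: tuple[int, int] = (30, 255)
    thr_bg: tuple[int, int] = (3, 255)
    outlier_radius: int = 10
    outlier_threshold: int = 50
    outlier_polarity: str = "bright"

    def __post_init__(self):
        for name, (lo, hi) in (("thr_gr", self.thr_gr), ("thr_bg", self.thr_bg)):
            if lo > hi:
                raise ValueError(f"{name}: low {lo} exceeds high {hi}")
        if self.outlier_radius < 1:
            raise ValueError("outlier_radius must be >= 1")
        if self.outlier_polarity not in ("bright", "dark"):
            raise ValueError("outlier_polarity must be 'bright' or 'dark'")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SegmentationParams":
        with open(path) as fh:
            d = json.load(fh)
        if "thr_gr" in d:
            d["thr_gr"] = tuple(d["thr_gr"])
        if "thr_bg" in d:
            d["thr_bg"] = tuple(d["thr_bg"])
        return cls(**d)


def _as_rgb(img) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("RGB image must be 8-bit (values in [0, 255])")
    return img


def zero_outside_roi(img, roi: PotRoi) -> np.ndarray:
    """Blacken every pixel outside the pot ROI, leaving the inside untouched."""
    img = _as_rgb(img)
    h, w = img.shape[:2]
    inside = roi.pixel_mask(h, w)
    if not inside.any():
        raise EmptyRoiError(f"roi {roi.id!r} contains no pixels of a {h}x{w} image")
    out = np.zeros_like(img)
    out[inside] = img[inside]
    return out


def channel_difference(img, minuend: str = "green", subtrahend: str = "red") -> np.ndarray:
    """Saturating per-pixel channel subtraction, ``max(minuend - subtrahend, 0)``.

    Returns an 8-bit grayscale image; negative differences clamp to zero, the
    behavior of an 8-bit image-calculator subtraction.
    """
    img = _as_rgb(img)
    for name in (minuend, subtrahend):
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}; choose from {sorted(CHANNELS)}")
    a = img[..., CHANNELS[minuend]].astype(np.int16)
    b = img[..., CHANNELS[subtrahend]].astype(np.int16)
    return np.clip(a - b, 0, 255).astype(np.uint8)


def threshold_mask(diff, low: int, high: int) -> np.ndarray:
    """Band threshold, inclusive on both ends: true iff ``low <= v <= high``."""
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    diff = np.asarray(diff)
    return (diff >= low) & (diff <= high)


def _disc_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _lower_median_disc(img: np.ndarray, radius: int) -> np.ndarray:
    """Lower median of the in-bounds circular neighborhood of every pixel.

    Interior pixels (full footprint in bounds) go through scipy's C rank
    filter; border pixels are recomputed exactly with edge truncation, which
    scipy's padding modes cannot express.
    """
    h, w = img.shape
    offsets = _disc_offsets(radius)
    n = len(offsets)

    footprint = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
    footprint[offsets[:, 0] + radius, offsets[:, 1] + radius] = True
    med = ndi.rank_filter(img, rank=(n - 1) // 2, footprint=footprint, mode="nearest")

    border = np.zeros((h, w), dtype=bool)
    b = min(radius, h)
    border[:b, :] = True
    border[h - b :, :] = True
    c = min(radius, w)
    border[:, :c] = True
    border[:, w - c :] = True

    ys, xs = np.nonzero(border)
    for y, x in zip(ys, xs):
        ny = y + offsets[:, 0]
        nx = x + offsets[:, 1]
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        vals = np.sort(img[ny[ok], nx[ok]])
        med[y, x] = vals[(len(vals) - 1) // 2]
    return med


def remove_outliers(
    diff,
    radius: int = 10,
    threshold: int = 50,
    polarity: str = "bright",
) -> np.ndarray:
    """ImageJ-style "Remove Outliers" despeckle on a grayscale image.

    A pixel is replaced by the lower median ``m`` of its circular
    neighborhood (Euclidean distance <= radius, center included, truncated at
    image edges) when it deviates from ``m`` by more than ``threshold`` in
    the chosen polarity: ``v - m > threshold`` for bright outliers,
    ``m - v > threshold`` for dark ones.  All medians come from the original
    image, so replacements never cascade.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    diff = np.asarray(diff)
    if diff.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    med = _lower_median_disc(diff.astype(np.int32, copy=False), int(radius))
    v = diff.astype(np.int32, copy=False)
    if polarity == "bright":
        replace = v - med > threshold
    else:
        replace = med - v > threshold
    out = diff.copy()
    out[replace] = med[replace].astype(diff.dtype)
    return out


def fuse_masks(a, b) -> np.ndarray:
    """Pixelwise logical OR of two binary masks of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a | b


def segment_plant(img, roi: PotRoi, params: SegmentationParams | None = None) -> np.ndarray:
    """Full color-difference segmentation of one pot; returns a boolean mask.

    Composition: ROI zeroing, then two parallel branches
    (G - R -> despeckle -> band (30, 255)) and
    (B - G -> despeckle -> band (3, 255)), fused by OR.
    """
    if params is None:
        params = SegmentationParams()
    cropped = zero_outside_roi(img, roi)

    diff_gr = channel_difference(cropped, "green", "red")
    diff_gr = remove_outliers(
        diff_gr, params.outlier_radius, params.outlier_threshold, params.outlier_polarity
    )
    mask_gr = threshold_mask(diff_gr, *params.thr_gr)

    diff_bg = channel_difference(cropped, "blue", "green")
    diff_bg = remove_outliers(
        diff_bg, params.outlier_radius, params.outlier_threshold, params.outlier_polarity
    )
    mask_bg = threshold_mask(diff_bg, *params.thr_bg)

    fused = fuse_masks(mask_gr, mask_bg)
    logger.debug(
        "segment_plant roi=%s: mask_gr=%d px, mask_bg=%d px, fused=%d px",
        roi.id,
        int(mask_gr.sum()),
        int(mask_bg.sum()),
        int(fused.sum()),
    )
    return fused
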