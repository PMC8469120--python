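"""Shared readers/writers: 8-bit images, masks, label images, biomass CSV."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_rgb_image",
    "write_mask_png",
    "read_mask_png",
    "write_label_pngs",
    "read_label_png",
    "BIOMASS_COLUMNS",
    "append_biomass_csv",
    "read_biomass_csv",
    "records_from_frame",
]

BIOMASS_COLUMNS = ["pot_id", "day", "green_pixels", "yellow_pixels", "total_pixels"]

# display gray levels for the 0/1/2 label image: background, green, yellow
LABEL_DISPLAY = np.array([0, 128, 255], dtype=np.uint8)


def read_rgb_image(path) -> np.ndarray:
    """Read a JPG/PNG as an 8-bit H x W x 3 array (RGB channel order)."""
    img = iio.imread(path)
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got dtype {img.dtype}")
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {img.shape}")
    return img


def write_mask_png(mask, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (mask * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    return iio.imread(path) > 0


def write_label_pngs(labels, display_path=None, data_path=None) -> None:
    """Write the label image: a display PNG (0/128/255) and/or a raw 0/1/2 PNG."""
    labels = np.asarray(labels, dtype=np.uint8)
    if display_path is not None:
        iio.imwrite(display_path, LABEL_DISPLAY[labels])
    if data_path is not None:
        iio.imwrite(data_path, labels)


def read_label_png(path) -> np.ndarray:
    """Read a label PNG written by :func:`write_label_pngs` (either variant)."""
    arr = iio.imread(path)
    if arr.max() > 2:  # display encoding
        out = np.zeros(arr.shape, dtype=np.uint8)
        out[arr == 128] = 1
        out[arr == 255] = 2
        return out
    return arr.astype(np.uint8)


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "pot_id": r.pot_id,
            "day": r.day,
            "green_pixels": r.green_pixels,
            "yellow_pixels": r.yellow_pixels,
            "total_pixels": r.total_pixels,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=BIOMASS_COLUMNS)


def append_biomass_csv(records, path) -> None:
    """Append biomass records to a tidy CSV with a fixed column order."""
    path = Path(path)
    df = records_to_frame(records)
    header = not path.exists()
    df.to_csv(path, mode="a", header=header, index=False)


def read_biomass_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pot_id", "day", "green_pixels", "yellow_pixels"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: biomass CSV missing columns {sorted(missing)}")
    return df


def records_from_frame(df: pd.DataFrame):
    """Turn a biomass table back into BiomassRecord objects."""
    from .classifier import BiomassRecord

    return [
        BiomassRecord(
            pot_id=str(row.pot_id),
            day=int(row.day),
            green_pixels=int(row.green_pixels),
            yellow_pixels=int(row.yellow_pixels),
        )
        for row in df.itertuples()
    ]
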