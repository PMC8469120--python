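"""Experiment layout: pot regions of interest and the image manifest.

A layout JSON ties together everything the pipeline needs to know about an
experiment that is not in the pixels themselves: where each pot sits in the
frame, which treatment and replicate it belongs to, and which image files
were taken on which day.  Pots are addressed by a row/column identifier, the
same bookkeeping a phenotyping chamber uses when pots are labelled by
position.

Coordinate conventions (used consistently across segmentation and thermal
zonal statistics):

* pixel coordinates are 0-based; a pixel's *center* sits at integer (x, y);
* rectangles are half-open ``[x0, x1) x [y0, y1)``;
* circles include every pixel whose center lies within Euclidean distance
  ``r`` of ``(cx, cy)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "LayoutError",
    "PotRoi",
    "ImageEntry",
    "ExperimentLayout",
    "load_layout",
    "save_layout",
    "grid_layout",
]


class LayoutError(ValueError):
    """Raised when a layout file or ROI definition is invalid."""


@dataclass(frozen=True)
class PotRoi:
    """A single pot's region of interest plus its experimental metadata.

    ``shape`` is ``"rectangle"`` with ``coords = (x0, y0, x1, y1)`` or
    ``"circle"`` with ``coords = (cx, cy, r)``, both in pixel coordinates.
    """

    id: str
    shape: str
    coords: tuple
    row_label: str = ""
    col_label: str = ""
    treatment: str = ""
    replicate: int = 0

    def __post_init__(self):
        if self.shape not in ("rectangle", "circle"):
            raise LayoutError(
                f"pot {self.id!r}: shape must be 'rectangle' or 'circle', got {self.shape!r}"
            )
        coords = tuple(float(c) for c in self.coords)
        object.__setattr__(self, "coords", coords)
        if self.shape == "rectangle":
            if len(coords) != 4:
                raise LayoutError(f"pot {self.id!r}: rectangle needs (x0, y0, x1, y1)")
            x0, y0, x1, y1 = coords
            if x1 <= x0 or y1 <= y0:
                raise LayoutError(f"pot {self.id!r}: rectangle is empty ({coords})")
        else:
            if len(coords) != 3:
                raise LayoutError(f"pot {self.id!r}: circle needs (cx, cy, r)")
            if coords[2] <= 0:
                raise LayoutError(f"pot {self.id!r}: circle radius must be > 0")

    def pixel_mask(self, height: int, width: int) -> np.ndarray:
        """Boolean (height, width) mask of pixels whose centers fall inside."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.coords
            xs = np.arange(width)
            ys = np.arange(height)
            inside_x = (xs >= x0) & (xs < x1)
            inside_y = (ys >= y0) & (ys < y1)
            return inside_y[:, None] & inside_x[None, :]
        cx, cy, r = self.coords
        ys, xs = np.mgrid[0:height, 0:width]
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2

    def bounding_box(self) -> tuple[float, float, float, float]:
        if self.shape == "rectangle":
            return self.coords
        cx, cy, r = self.coords
        return (cx - r, cy - r, cx + r, cy + r)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coords"] = list(self.coords)
        return d


@dataclass(frozen=True)
class ImageEntry:
    """One manifest row: an image file, the sampling day, and its scope.

    ``pot_id`` of ``None`` means a full-frame image covering every pot in the
    layout; otherwise the image shows a single pot.
    """

    path: str
    day: int
    pot_id: Optional[str] = None


@dataclass
class ExperimentLayout:
    name: str
    species: str = ""
    pots: list[PotRoi] = field(default_factory=list)
    images: list[ImageEntry] = field(default_factory=list)
    schedule: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.id for p in self.pots]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise LayoutError(f"duplicate pot ids: {dupes}")
        self._by_id = {p.id: p for p in self.pots}

    def pot(self, pot_id: str) -> PotRoi:
        try:
            return self._by_id[pot_id]
        except KeyError:
            raise LayoutError(f"unknown pot id {pot_id!r}") from None

    @property
    def pot_ids(self) -> list[str]:
        return [p.id for p in self.pots]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": self.species,
            "pots": [p.to_dict() for p in self.pots],
            "images": [asdict(e) for e in self.images],
            "schedule": self.schedule,
        }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise LayoutError(f"{where}: missing required field {key!r}")
    return d[key]


def load_layout(path) -> ExperimentLayout:
    """Read and validate a layout JSON file."""
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LayoutError(f"{path}: not valid JSON ({exc})") from exc
    return layout_from_dict(data, where=str(path))


def layout_from_dict(data: dict, where: str = "layout") -> ExperimentLayout:
    if not isinstance(data, dict):
        raise LayoutError(f"{where}: top level must be a JSON object")
    name = _require(data, "name", where)
    pots = []
    for i, pd in enumerate(data.get("pots", [])):
        loc = f"{where}.pots[{i}]"
        pots.append(
            PotRoi(
                id=str(_require(pd, "id", loc)),
                shape=_require(pd, "shape", loc),
                coords=tuple(_require(pd, "coords", loc)),
                row_label=str(pd.get("row_label", "")),
                col_label=str(pd.get("col_label", "")),
                treatment=str(pd.get("treatment", "")),
                replicate=int(pd.get("replicate", 0)),
            )
        )
    images = []
    for i, ed in enumerate(data.get("images", [])):
        loc = f"{where}.images[{i}]"
        images.append(
            ImageEntry(
                path=str(_require(ed, "path", loc)),
                day=int(_require(ed, "day", loc)),
                pot_id=ed.get("pot_id"),
            )
        )
    layout = ExperimentLayout(
        name=str(name),
        species=str(data.get("species", "")),
        pots=pots,
        images=images,
        schedule=dict(data.get("schedule", {})),
    )
    for e in layout.images:
        if e.pot_id is not None and e.pot_id not in layout._by_id:
            raise LayoutError(f"{where}: image {e.path!r} references unknown pot {e.pot_id!r}")
    return layout


def save_layout(layout: ExperimentLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def grid_layout(
    n_rows: int,
    n_cols: int,
    cell: int,
    name: str = "grid",
    margin: int = 0,
    treatment_of=None,
    shape: str = "rectangle",
) -> ExperimentLayout:
    """Build a regular row x column grid of pot ROIs (one per tray cell).

    ``treatment_of(row, col)`` may assign treatments; by default all cells are
    untreated.  Useful both in tests and for chambers where pots sit in an
    evenly spaced grid.
    """
    pots = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0 = margin + c * cell
            y0 = margin + r * cell
            treat = treatment_of(r, c) if treatment_of else ""
            if shape == "rectangle":
                coords = (x0, y0, x0 + cell, y0 + cell)
            else:
                half = cell / 2.0
                coords = (x0 + half, y0 + half, half)
            pots.append(
                PotRoi(
                    id=f"r{r + 1}c{c + 1}",
                    shape=shape,
                    coords=coords,
                    row_label=str(r + 1),
                    col_label=str(c + 1),
                    treatment=treat,
                    replicate=r + 1,
                )
            )
    return ExperimentLayout(name=name, pots=pots)
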