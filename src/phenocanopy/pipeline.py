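"""Orchestration: run segment -> classify -> count over an image manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .classifier import GaussianPixelClassifier, classify_pixels, count_labels
from .layout import ExperimentLayout
from .segmentation import SegmentationParams, segment_plant

__all__ = ["PipelineSummary", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineSummary:
    n_images: int = 0
    n_records: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_pipeline(
    layout: ExperimentLayout,
    model: GaussianPixelClassifier,
    params: SegmentationParams | None = None,
    out_dir=None,
    image_root=None,
) -> tuple[pd.DataFrame, PipelineSummary]:
    """Process every manifest image: segment each pot, classify, count.

    Full-frame images (``pot_id`` None) are processed against every pot ROI
    of the layout; single-pot images only against their own ROI.  Per-image
    failures are logged and skipped, and collected in the summary.  Output is
    deterministic: rows follow manifest order then layout pot order, and the
    biomass CSV is rewritten from scratch on every run.
    """
    if params is None:
        params = SegmentationParams()
    image_root = Path(image_root) if image_root else None
    records = []
    summary = PipelineSummary()
    if not layout.images:
        logger.warning("layout %r has an empty image manifest", layout.name)
    for entry in layout.images:
        path = Path(entry.path)
        if image_root and not path.is_absolute():
            path = image_root / path
        summary.n_images += 1
        try:
            img = pio.read_rgb_image(path)
            pots = [layout.pot(entry.pot_id)] if entry.pot_id else layout.pots
            for pot in pots:
                mask = segment_plant(img, pot, params)
                labels = classify_pixels(img, mask, model)
                rec = count_labels(labels, pot_id=pot.id, day=entry.day)
                records.append(rec)
                summary.n_records += 1
                logger.debug(
                    "%s pot=%s day=%d: green=%d yellow=%d",
                    path.name,
                    pot.id,
                    entry.day,
                    rec.green_pixels,
                    rec.yellow_pixels,
                )
        except Exception as exc:  # per-image isolation
            logger.error("failed on %s: %s", path, exc)
            summary.failures.append((str(entry.path), str(exc)))
    table = pio.records_to_frame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "biomass.csv", index=False)
        with open(out_dir / "run_log.txt", "w") as fh:
            fh.write(f"images: {summary.n_images}\nrecords: {summary.n_records}\n")
            for path, msg in summary.failures:
                fh.write(f"FAILED {path}: {msg}\n")
    return table, summary
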