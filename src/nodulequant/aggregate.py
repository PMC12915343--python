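"""Per-image and batch summaries of nodulation traits.

Produces the per-class count/area/brightness summary table, nodule
occupancy percentages (including an externally supplied count of dark,
fluorescence-free nodules, which no fluorescence pipeline can detect), and
a deterministic batch driver over a directory of images.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .core_io import CLASS_ORDER, FluorClass, RunConfig, read_image, summaries_frame
from .quantify import NoduleRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClassSummary:
    """Aggregate nodulation traits for one class in one image.

    When ``n_nodules`` is zero, totals and averages are reported as 0 by
    convention (keeps the output table rectangular; flagged by n = 0).
    """

    image_id: str
    fluor_class: FluorClass
    n_nodules: int = 0
    total_area_px2: int = 0
    avg_area_px2: float = 0.0
    total_area_mm2: float = 0.0
    avg_area_mm2: float = 0.0
    avg_brightness: float = 0.0
    total_brightness: float = 0.0


@dataclasses.dataclass
class OccupancyReport:
    """Percentage of nodules occupied by each reporter class.

    ``n_unlabeled`` counts dark nodules supplied externally (manual counts);
    labelled and unlabelled percentages sum to 100 when any nodule exists.
    A MIXED nodule counts once in the totals, not once per partner class.
    """

    image_id: str
    per_class_pct: dict
    n_total: int
    n_unlabeled: int
    mixed_pct: float

    @property
    def unlabeled_pct(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_unlabeled / self.n_total


def summarize_image(records: list[NoduleRecord],
                    configured_classes: Iterable[FluorClass] = CLASS_ORDER,
                    image_id: Optional[str] = None) -> list[ClassSummary]:
    """One ClassSummary per configured class (zero-rows for absent classes),
    in the deterministic order CYAN, YELLOW, RED, MIXED.

    All records must share an image_id.
    """
    ids = {r.image_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple images: {sorted(ids)}")
    img_id = image_id if image_id is not None else (next(iter(ids)) if ids else "")
    summaries = []
    for fc in CLASS_ORDER:
        if fc not in set(configured_classes):
            continue
        group = [r for r in records if r.fluor_class is fc]
        s = ClassSummary(image_id=img_id, fluor_class=fc, n_nodules=len(group))
        if group:
            s.total_area_px2 = sum(r.area_px2 for r in group)
            s.avg_area_px2 = s.total_area_px2 / len(group)
            s.total_area_mm2 = sum(r.area_mm2 for r in group)
            s.avg_area_mm2 = s.total_area_mm2 / len(group)
            s.total_brightness = sum(r.brightness_0_100 for r in group)
            s.avg_brightness = s.total_brightness / len(group)
        summaries.append(s)
    return summaries


def occupancy(records: list[NoduleRecord], n_unlabeled: int = 0,
              image_id: Optional[str] = None) -> OccupancyReport:
    """Nodule occupancy percentages over labelled + unlabelled nodules."""
    if n_unlabeled < 0:
        raise ValueError("n_unlabeled must be >= 0")
    ids = {r.image_id for r in records}
    img_id = image_id if image_id is not None else (next(iter(ids)) if ids else "")
    n_total = len(records) + n_unlabeled
    per_class = {}
    for fc in CLASS_ORDER:
        count = sum(1 for r in records if r.fluor_class is fc)
        per_class[fc] = 100.0 * count / n_total if n_total else 0.0
    mixed_pct = per_class[FluorClass.MIXED]
    return OccupancyReport(image_id=img_id, per_class_pct=per_class,
                           n_total=n_total, n_unlabeled=n_unlabeled,
                           mixed_pct=mixed_pct)


BATCH_COLUMNS = [
    "image", "class", "n_nodules", "total_area_px2", "avg_area_px2",
    "total_area_mm2", "avg_area_mm2", "avg_brightness", "total_brightness",
    "error",
]


def batch_process(directory, config: RunConfig) -> pd.DataFrame:
    """Process every .png/.tif/.tiff image in a directory through the full
    pipeline and concatenate the per-class summaries into one long table.

    Images are processed in lexicographic filename order.  An image that
    fails to load or process is logged and recorded as a single error row
    rather than aborting the batch.
    """
    from .pipeline import process_image  # deferred: avoids an import cycle

    d = Path(directory)
    if not d.is_dir():
        raise NotADirectoryError(str(d))
    paths = sorted(p for p in d.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    rows = []
    for p in paths:
        try:
            image = read_image(p, pixel_size_mm=config.pixel_size_mm)
            result = process_image(image, config, image_id=p.name)
            logger.info("processed %s: %d nodules", p.name,
                        len(result.records))
            for s in result.summaries:
                rows.append({
                    "image": s.image_id,
                    "class": s.fluor_class.value,
                    "n_nodules": s.n_nodules,
                    "total_area_px2": s.total_area_px2,
                    "avg_area_px2": s.avg_area_px2,
                    "total_area_mm2": s.total_area_mm2,
                    "avg_area_mm2": s.avg_area_mm2,
                    "avg_brightness": s.avg_brightness,
                    "total_brightness": s.total_brightness,
                    "error": "",
                })
        except Exception as e:  # noqa: BLE001 - per-image isolation is the contract
            logger.warning("skipping %s: %s", p.name, e)
            rows.append({c: "" for c in BATCH_COLUMNS} | {
                "image": p.name, "error": str(e)})
    return pd.DataFrame(rows, columns=BATCH_COLUMNS)


def summaries_table(summaries: list[ClassSummary]) -> pd.DataFrame:
    """Convenience wrapper re-exporting the deterministic summary frame."""
    return summaries_frame(summaries)
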