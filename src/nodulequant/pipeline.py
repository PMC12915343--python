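"""Single-image orchestration: detect -> quantify -> root distances -> summarise."""

from __future__ import annotations

import dataclasses
from typing import Optional

from . import aggregate, detect, quantify, rootgraph
from .core_io import Detection, ImageRGB, RunConfig


@dataclasses.dataclass
class PipelineResult:
    image_id: str
    detections: list
    network: rootgraph.RootNetwork
    distances: list
    records: list
    summaries: list


def process_image(image: ImageRGB, config: RunConfig,
                  detections: Optional[list[Detection]] = None,
                  image_id: Optional[str] = None) -> PipelineResult:
    """Run the full quantification pipeline on one image.

    When ``detections`` is given (imported predictions), the confidence
    filter and mixed-nodule merge are applied to them exactly as in the
    classical path; otherwise the classical HSB-gating backend runs.
    The analysis path is seed-free and fully deterministic.
    """
    img_id = image_id if image_id is not None else image.source_path
    if detections is None:
        dets = detect.detect_classical(image, config)
    else:
        dets = detect.apply_common_filters(list(detections), config)
    network = rootgraph.build_network(image, dets, config)
    distances = rootgraph.nodule_root_distances(dets, network, config.pixel_size_mm)
    records = quantify.build_records(image, dets, config, distances, image_id=img_id)
    summaries = aggregate.summarize_image(records, image_id=img_id)
    return PipelineResult(image_id=img_id, detections=dets, network=network,
                          distances=distances, records=records,
                          summaries=summaries)
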