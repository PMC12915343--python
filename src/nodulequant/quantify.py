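"""Photometric and morphometric measurement of detections.

Brightness follows the class-specific channel rules used for the three
reporter classes: the cyan class (sfCFP) is characterised by the
blue-channel mean alone, while the yellow (sfYFP) and red (mScarlet-I)
classes average the red-channel mean with the "yellow channel" mean, where
the yellow pseudo-channel of an RGB image is defined per pixel as
(R + G) / 2.  Raw 8-bit values are normalised linearly to a 0-100 scale.

Brightness is computed over the detection's bounding-box crop of the
original RGB image (not the mask), which mirrors the published measurement
procedure; a mask-based alternative is available behind a config switch.
Projected area, by contrast, is the mask pixel count.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .core_io import Detection, FluorClass, ImageRGB, RunConfig


@dataclasses.dataclass
class NoduleRecord:
    """A fully quantified nodule."""

    nodule_id: int
    image_id: str
    fluor_class: FluorClass
    area_px2: int
    area_mm2: float
    brightness_0_100: float
    centroid: tuple[float, float]
    confidence: float
    dist_to_root_px: Optional[float]
    dist_to_root_mm: Optional[float]
    reachable: bool
    mixed: bool
    partner_classes: frozenset


def crop_bbox_means(image: ImageRGB, bbox: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Arithmetic per-channel means over a (clipped) half-open bbox crop."""
    H, W = image.shape
    r0, c0, r1, c1 = bbox
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(H, r1), min(W, c1)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("empty bbox after clipping to image")
    crop = image.pixels[r0:r1, c0:c1].astype(np.float64)
    means = crop.mean(axis=(0, 1))
    return float(means[0]), float(means[1]), float(means[2])


def mask_means(image: ImageRGB, detection: Detection) -> tuple[float, float, float]:
    """Per-channel means over the detection mask (config-switch alternative)."""
    coords = np.array(sorted(detection.mask))
    vals = image.pixels[coords[:, 0], coords[:, 1]].astype(np.float64)
    m = vals.mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


def yellow_channel_mean(mean_r: float, mean_g: float) -> float:
    """Yellow pseudo-channel of an RGB image: (R + G) / 2."""
    return (mean_r + mean_g) / 2.0


def _raw_brightness(fc: FluorClass, means: tuple[float, float, float]) -> float:
    mean_r, mean_g, mean_b = means
    if fc is FluorClass.CYAN:
        return mean_b
    if fc in (FluorClass.YELLOW, FluorClass.RED):
        return (mean_r + yellow_channel_mean(mean_r, mean_g)) / 2.0
    raise ValueError(f"no direct brightness rule for class {fc}")


def nodule_brightness(image: ImageRGB, detection: Detection,
                      use_mask: bool = False) -> float:
    """Class-specific nodule brightness on the 0-100 scale.

    CYAN uses the blue-channel mean; YELLOW and RED use the mean of the
    red channel and the yellow pseudo-channel.  MIXED nodules take the
    maximum over their partner-class rules.  ``use_mask`` switches the
    photometry region from the bounding box to the segmentation mask.
    """
    means = mask_means(image, detection) if use_mask else crop_bbox_means(image, detection.bbox)
    if detection.fluor_class is FluorClass.MIXED:
        partners = detection.partner_classes or frozenset(
            (FluorClass.CYAN, FluorClass.YELLOW, FluorClass.RED))
        raw = max(_raw_brightness(fc, means) for fc in partners)
    else:
        raw = _raw_brightness(detection.fluor_class, means)
    return 100.0 * raw / 255.0


def area_px2(detection: Detection) -> int:
    """Projected area: pixel count of the segmentation mask."""
    if not detection.mask:
        raise ValueError("empty detection mask")
    return len(detection.mask)


def px2_to_mm2(area: int, pixel_size_mm: float) -> float:
    """Convert a pixel area to mm^2: area * pixel_size_mm^2."""
    if not pixel_size_mm > 0:
        raise ValueError("pixel_size_mm must be positive")
    return area * pixel_size_mm * pixel_size_mm


def centroid(detection: Detection) -> tuple[float, float]:
    """Unweighted mean of the mask pixel coordinates."""
    if not detection.mask:
        raise ValueError("empty detection mask")
    rows = [r for r, _ in detection.mask]
    cols = [c for _, c in detection.mask]
    return float(np.mean(rows)), float(np.mean(cols))


def build_records(image: ImageRGB, detections: list[Detection],
                  config: RunConfig, distances=None,
                  image_id: Optional[str] = None) -> list[NoduleRecord]:
    """Assemble NoduleRecords from detections and (optional) root distances.

    ``distances`` is a list of DistanceResult aligned with ``detections``;
    when omitted, distance fields are marked unreachable.
    """
    img_id = image_id if image_id is not None else image.source_path
    records = []
    for i, det in enumerate(detections):
        a = area_px2(det)
        if distances is not None:
            dr = distances[i]
            reachable = dr.path_exists
            dist_px = dr.dist_px if reachable else None
            dist_mm = dist_px * config.pixel_size_mm if reachable else None
        else:
            reachable, dist_px, dist_mm = False, None, None
        records.append(NoduleRecord(
            nodule_id=det.det_id,
            image_id=img_id,
            fluor_class=det.fluor_class,
            area_px2=a,
            area_mm2=px2_to_mm2(a, config.pixel_size_mm),
            brightness_0_100=nodule_brightness(image, det, use_mask=config.mask_brightness),
            centroid=centroid(det),
            confidence=det.confidence,
            dist_to_root_px=dist_px,
            dist_to_root_mm=dist_mm,
            reachable=reachable,
            mixed=det.fluor_class is FluorClass.MIXED,
            partner_classes=det.partner_classes,
        ))
    return records
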