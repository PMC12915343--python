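"""Classical nodule detection and detection post-processing.

The classical backend mirrors the standard ImageJ colour-threshold recipe
for fluorescent nodule counting: optional linear intensity stretch, HSB
colour gating tailored to each reporter class, 8-connected particle
analysis with a particle-size filter, and a brightness-derived
pseudo-confidence.  Confidence filtering and mixed-nodule merging are
applied uniformly to classical and imported detections.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

from .core_io import (
    Detection,
    FluorClass,
    HSBGate,
    ImageRGB,
    RunConfig,
    detection_from_mask,
)


@dataclasses.dataclass
class HSBPlanes:
    """Hue/saturation/brightness planes of an image, each H x W in [0, 1].

    Achromatic pixels (R = G = B) have hue 0 by convention; black pixels
    have saturation 0.
    """

    hue: np.ndarray
    sat: np.ndarray
    bri: np.ndarray


def adjust_intensity(image: ImageRGB, lo: int, hi: int) -> ImageRGB:
    """Per-channel linear stretch v' = clamp(round(255*(v-lo)/(hi-lo)), 0, 255).

    Rounding is half-away-from-zero.  (lo, hi) = (0, 255) is the identity.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    v = image.pixels.astype(np.float64)
    scaled = 255.0 * (v - lo) / (hi - lo)
    out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return ImageRGB(pixels=out, source_path=image.source_path,
                    pixel_size_mm=image.pixel_size_mm)


def rgb_to_hsb(image: ImageRGB) -> HSBPlanes:
    """Standard hexcone RGB -> HSB conversion.

    bri = max(R,G,B)/255, sat = (max-min)/max (0 when max = 0), hue in
    [0, 1) with red at 0, green at 1/3, blue at 2/3.
    """
    hsv = skcolor.rgb2hsv(image.pixels)
    hue = np.mod(hsv[:, :, 0], 1.0)
    return HSBPlanes(hue=hue, sat=hsv[:, :, 1], bri=hsv[:, :, 2])


def gate_mask(planes: HSBPlanes, gate: HSBGate) -> np.ndarray:
    """Binary mask of pixels passing an HSB gate (hue wraps through 1.0
    when hue_lo > hue_hi)."""
    return np.asarray(gate.passes(planes.hue, planes.sat, planes.bri))


def score_confidence(detection: Detection, planes: HSBPlanes,
                     gate: HSBGate | None = None) -> float:
    """Brightness-proportional pseudo-confidence for classical detections.

    Mean HSB brightness over the detection mask.  The classical pipeline has
    no model confidence; this deterministic score makes the confidence
    filter meaningful for both backends.
    """
    if not detection.mask:
        raise ValueError("empty detection mask")
    vals = [planes.bri[r, c] for r, c in detection.mask]
    return float(np.mean(vals))


def extract_particles(mask: np.ndarray, fluor_class: FluorClass,
                      min_area_px: int, max_area_px: int,
                      planes: HSBPlanes | None = None) -> list[Detection]:
    """8-connected particle analysis of a binary mask with a size filter.

    Components with area outside [min_area_px, max_area_px] are discarded as
    background noise.  Surviving components become classical Detections,
    det_ids assigned in scan order (top-left first).  When ``planes`` is
    given each detection's confidence is its mean brightness; otherwise 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = skmeasure.label(mask, connectivity=2)
    comps = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_area_px or region.area > max_area_px:
            continue
        coords = {(int(r), int(c)) for r, c in region.coords}
        first = min(coords)  # row-major scan order of the top-left pixel
        comps.append((first, coords))
    comps.sort(key=lambda t: t[0])
    detections = []
    for i, (_, coords) in enumerate(comps):
        det = detection_from_mask(i, fluor_class, coords, confidence=1.0,
                                  source="classical")
        if planes is not None:
            det.confidence = score_confidence(det, planes)
        detections.append(det)
    return detections


def filter_confidence(detections: Iterable[Detection], threshold: float) -> list[Detection]:
    """Keep detections with confidence >= threshold (inclusive), order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [d for d in detections if d.confidence >= threshold]


def _mask_overlap_frac(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / min(len(a), len(b))


def merge_mixed(detections: list[Detection], overlap_frac: float) -> list[Detection]:
    """Merge overlapping detections of different classes into MIXED nodules.

    Two non-MIXED detections of different classes merge when their mask
    intersection covers at least ``overlap_frac`` of the smaller mask.
    Merging is transitive (union-find over the overlap graph).  The merged
    detection's mask is the union, its confidence the maximum of the group,
    and ``partner_classes`` records the contributing classes.  Applying the
    operation twice equals applying it once.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError("overlap_frac must lie in (0, 1]")
    n = len(detections)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        di = detections[i]
        if di.fluor_class is FluorClass.MIXED:
            continue
        for j in range(i + 1, n):
            dj = detections[j]
            if dj.fluor_class is FluorClass.MIXED:
                continue
            if di.fluor_class is dj.fluor_class:
                continue
            if _mask_overlap_frac(di.mask, dj.mask) >= overlap_frac:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out: list[Detection] = []
    emitted = set()
    for i in range(n):
        root = find(i)
        if root in emitted:
            continue
        emitted.add(root)
        members = groups[root]
        if len(members) == 1:
            out.append(detections[i])
            continue
        dets = [detections[m] for m in members]
        mask = frozenset().union(*(d.mask for d in dets))
        classes = frozenset(d.fluor_class for d in dets)
        out.append(
            detection_from_mask(
                det_id=min(d.det_id for d in dets),
                fluor_class=FluorClass.MIXED,
                mask=mask,
                confidence=max(d.confidence for d in dets),
                source=dets[0].source,
                partner_classes=classes,
            )
        )
    return out


def detect_classical(image: ImageRGB, config: RunConfig) -> list[Detection]:
    """Full classical detection pipeline for one image.

    Optional intensity stretch -> HSB conversion -> per-class gating ->
    particle analysis with size filter -> confidence filter -> mixed-nodule
    merging.  Detections are re-numbered deterministically (class order,
    then scan order).
    """
    work = image
    if config.intensity_rescale is not None:
        rescale = config.intensity_rescale
        if len(rescale) == 2 and np.isscalar(rescale[0]):
            work = adjust_intensity(work, int(rescale[0]), int(rescale[1]))
        else:
            # one (lo, hi) pair per channel
            chans = []
            for ch, (lo, hi) in enumerate(rescale):
                sub = ImageRGB(np.repeat(work.pixels[:, :, ch:ch + 1], 3, axis=2),
                               work.source_path, work.pixel_size_mm)
                chans.append(adjust_intensity(sub, int(lo), int(hi)).pixels[:, :, 0])
            work = ImageRGB(np.stack(chans, axis=2), work.source_path,
                            work.pixel_size_mm)
    planes = rgb_to_hsb(work)
    detections: list[Detection] = []
    for fc in (FluorClass.CYAN, FluorClass.YELLOW, FluorClass.RED):
        gate = config.gates.get(fc)
        if gate is None:
            continue
        mask = gate_mask(planes, gate)
        detections.extend(
            extract_particles(mask, fc, config.min_area_px, config.max_area_px,
                              planes=planes)
        )
    for i, det in enumerate(detections):
        det.det_id = i
    detections = filter_confidence(detections, config.confidence_threshold)
    detections = merge_mixed(detections, config.mixed_overlap_frac)
    return detections


def apply_common_filters(detections: list[Detection], config: RunConfig) -> list[Detection]:
    """Confidence filter + mixed merge, applied uniformly to imported detections."""
    return merge_mixed(filter_confidence(detections, config.confidence_threshold),
                       config.mixed_overlap_frac)
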