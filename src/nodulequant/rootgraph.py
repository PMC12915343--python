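"""Root extraction and path-based nodule-to-root distances.

The root structure is segmented by Otsu thresholding of the mean-channel
grayscale image followed by morphological closing and opening.  Nodules
are computationally excluded from the binary mask, a proximity filter
removes foreground noise far from the root structure, and the distance
from each nodule to the primary root is the shortest path on the
8-connected grid graph of navigable pixels with octile weights (1 for axis
steps, sqrt(2) for diagonal steps) — replacing straight-line Euclidean
distance, which ignores root topology.

Two structures matter and are kept distinct:

* the *root structure* — the largest 8-connected foreground component after
  nodule exclusion; the proximity filter retains only pixels within
  ``proximity_px`` of it (noise removal);
* the *primary root* — the main axis region, extracted as the largest
  component of a morphological opening wide enough to erase lateral roots
  (``primary_open_radius_px``).  Distances are measured to this region, so
  a nodule sitting on a lateral is credited with the navigable path length
  along that lateral back to the main root.

Detection masks are re-inserted into the navigable set (but never into the
primary) so that path searches can start at the nodule centroid.
"""

from __future__ import annotations

import dataclasses
import heapq
import math
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .core_io import Detection, ImageRGB, RunConfig

SQRT2 = math.sqrt(2.0)

#: 8-neighbourhood offsets with octile step weights.
_NEIGHBORS = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, SQRT2), (-1, 1, SQRT2), (1, -1, SQRT2), (1, 1, SQRT2),
]


@dataclasses.dataclass
class RootNetwork:
    """Navigable pixel network with an identified primary-root region."""

    navigable: np.ndarray  # H x W bool
    primary: np.ndarray    # H x W bool, subset of navigable
    proximity_px: int


@dataclasses.dataclass
class DistanceResult:
    nodule_id: int
    dist_px: Optional[float]
    path_exists: bool
    attach_pixel: Optional[tuple[int, int]]
    dist_mm: Optional[float] = None


def root_mask(image: ImageRGB, morph_radius_px: int) -> np.ndarray:
    """Binary root mask: Otsu threshold on the mean-channel grayscale,
    then morphological closing followed by opening with a disc element.

    A constant image yields an empty mask (propagates as unreachable
    distances downstream).
    """
    gray = image.pixels.astype(np.float64).mean(axis=2)
    gray8 = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    if gray8.min() == gray8.max():
        return np.zeros(gray8.shape, dtype=bool)
    thresh = skfilters.threshold_otsu(gray8)
    mask = gray8 > thresh
    if morph_radius_px > 0:
        selem = skmorph.disk(morph_radius_px)
        mask = skmorph.closing(mask, selem)
        mask = skmorph.opening(mask, selem)
    return mask


def exclude_nodules(mask: np.ndarray, detections: Iterable[Detection]) -> np.ndarray:
    """Set foreground pixels belonging to any detection mask to background."""
    out = np.asarray(mask, dtype=bool).copy()
    H, W = out.shape
    for det in detections:
        for r, c in det.mask:
            if 0 <= r < H and 0 <= c < W:
                out[r, c] = False
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component (ties broken by smallest label, i.e.
    scan order); empty input yields an empty mask."""
    labels = skmeasure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(mask.shape, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def proximity_filter(mask: np.ndarray, proximity_px: int,
                     reference_mask: Optional[np.ndarray] = None) -> RootNetwork:
    """Drop foreground pixels farther than ``proximity_px`` (Euclidean) from
    the root structure; the structure is the largest 8-connected component.

    By default the structure is found in ``mask`` itself.  The pipeline
    passes the pre-exclusion root mask as ``reference_mask`` instead:
    carving nodules out of the root can bisect it, and measuring proximity
    to one fragment would discard the rest of the root as "noise".  The
    returned network's ``primary`` is the structure component; callers that
    need the main-axis region override it via :func:`extract_primary`.
    """
    if proximity_px < 0:
        raise ValueError("proximity_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    ref = mask if reference_mask is None else np.asarray(reference_mask, dtype=bool)
    structure = _largest_component(ref)
    if not structure.any():
        empty = np.zeros(mask.shape, dtype=bool)
        return RootNetwork(navigable=empty, primary=empty, proximity_px=proximity_px)
    dist = ndi.distance_transform_edt(~structure)
    navigable = mask & (dist <= proximity_px)
    return RootNetwork(navigable=navigable, primary=structure & mask,
                       proximity_px=proximity_px)


def extract_primary(mask: np.ndarray, open_radius_px: int) -> np.ndarray:
    """Primary-root axis region: largest component of a morphological
    opening that erases structures thinner than the opening disc.

    With the default radius, lateral roots (narrower than the main root)
    vanish under the opening, leaving the dominant main-root body.  Applied
    to the root mask *before* nodule exclusion so nodules sitting on the
    primary root remain attached to it (and thus score distance zero).
    """
    mask = np.asarray(mask, dtype=bool)
    if open_radius_px > 0:
        opened = skmorph.opening(mask, skmorph.disk(open_radius_px))
    else:
        opened = mask
    return _largest_component(opened)


def build_network(image: ImageRGB, detections: list[Detection],
                  config: RunConfig) -> RootNetwork:
    """Full network construction for one image.

    threshold/morphology -> primary-axis extraction (pre-exclusion) ->
    nodule exclusion -> proximity filter -> detection-mask re-insertion.
    """
    m = root_mask(image, config.morph_radius_px)
    primary = extract_primary(m, config.primary_open_radius_px)
    m_ex = exclude_nodules(m, detections)
    net = proximity_filter(m_ex, config.proximity_px, reference_mask=m)
    navigable = net.navigable.copy()
    H, W = navigable.shape
    for det in detections:
        for r, c in det.mask:
            if 0 <= r < H and 0 <= c < W:
                navigable[r, c] = True
    primary &= navigable
    return RootNetwork(navigable=navigable, primary=primary,
                       proximity_px=config.proximity_px)


def attach_point(detection: Detection, network: RootNetwork) -> Optional[tuple[int, int]]:
    """Navigable pixel nearest (Euclidean) to the detection centroid.

    Ties break by (row, col) order; returns None when the network is empty.
    """
    coords = np.argwhere(network.navigable)
    if coords.size == 0:
        return None
    rows = [r for r, _ in detection.mask]
    cols = [c for _, c in detection.mask]
    cr, cc = float(np.mean(rows)), float(np.mean(cols))
    d2 = (coords[:, 0] - cr) ** 2 + (coords[:, 1] - cc) ** 2
    best = int(np.argmin(d2))  # argwhere is row-major sorted -> lexicographic tie-break
    return int(coords[best, 0]), int(coords[best, 1])


def shortest_path_distance(network: RootNetwork, source: tuple[int, int],
                           nodule_id: int = -1) -> DistanceResult:
    """Octile-weight Dijkstra from ``source`` over the navigable grid graph,
    stopping at the nearest primary pixel.

    Unit weight for axis neighbours, sqrt(2) for diagonal neighbours.
    Raises ``ValueError`` when the source is not navigable; returns an
    unreachable result when no path to the primary exists.
    """
    nav = network.navigable
    prim = network.primary
    H, W = nav.shape
    r0, c0 = source
    if not (0 <= r0 < H and 0 <= c0 < W) or not nav[r0, c0]:
        raise ValueError("source pixel is not navigable")
    if prim[r0, c0]:
        return DistanceResult(nodule_id, 0.0, True, (r0, c0))
    dist = np.full((H, W), np.inf)
    dist[r0, c0] = 0.0
    heap = [(0.0, r0, c0)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        if prim[r, c]:
            return DistanceResult(nodule_id, d, True, (r, c))
        for dr, dc, w in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < H and 0 <= nc < W and nav[nr, nc]:
                nd = d + w
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    return DistanceResult(nodule_id, None, False, None)


def _touches_primary(detection: Detection, primary: np.ndarray) -> bool:
    """True when the mask overlaps or is 8-adjacent to the primary region."""
    H, W = primary.shape
    for r, c in detection.mask:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if 0 <= nr < H and 0 <= nc < W and primary[nr, nc]:
                    return True
    return False


def nodule_root_distances(detections: list[Detection], network: RootNetwork,
                          pixel_size_mm: float = 1.0) -> list[DistanceResult]:
    """Per-detection shortest navigable path distance to the primary root.

    Zero exactly when the nodule mask touches the primary; otherwise the
    network-internal Dijkstra distance from the attach point (no Euclidean
    gap is added).  ``dist_mm = dist_px * pixel_size_mm``.
    """
    results = []
    for det in detections:
        if network.primary.any() and _touches_primary(det, network.primary):
            res = DistanceResult(det.det_id, 0.0, True, min(det.mask))
        else:
            src = attach_point(det, network)
            if src is None:
                res = DistanceResult(det.det_id, None, False, None)
            else:
                res = shortest_path_distance(network, src, nodule_id=det.det_id)
        if res.path_exists:
            res.dist_mm = res.dist_px * pixel_size_mm
        results.append(res)
    return results
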