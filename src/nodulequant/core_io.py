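"""Shared data model, coordinate conventions, and file I/O.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based, row-major, origin at the top-left corner,
  written ``(row, col)``.
* Bounding boxes are half-open: ``(row_min, col_min, row_max, col_max)``
  with the max indices exclusive, so ``width = col_max - col_min``.
* Prediction files use the remote-inference dialect of center-based boxes in
  ``(x=col, y=row)`` order; conversion to pixel boxes rounds
  half-away-from-zero.  The dialect is versioned via the ``schema_version``
  key in the file header.
* Images are 8-bit per channel, channel order R, G, B.  Higher bit depths
  are rejected rather than rescaled so that the 0-100 brightness
  normalisation stays exact.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image


# ---------------------------------------------------------------------------
# Fluorophore classes
# ---------------------------------------------------------------------------

class FluorClass(enum.Enum):
    """Reporter colour identity of a nodule.

    CYAN (sfCFP), YELLOW (sfYFP) and RED (mScarlet-I and variants) are
    detector classes.  MIXED marks a nodule occupied by two differently
    labelled strains; it is only ever produced by merging overlapping
    detections of different classes, never by a detector directly.
    """

    CYAN = "CYAN"
    YELLOW = "YELLOW"
    RED = "RED"
    MIXED = "MIXED"


#: Deterministic reporting order for per-class outputs.
CLASS_ORDER: tuple[FluorClass, ...] = (
    FluorClass.CYAN,
    FluorClass.YELLOW,
    FluorClass.RED,
    FluorClass.MIXED,
)

#: Default mapping from prediction-file class names to FluorClass.  The
#: cyan reporter is labelled both "Blue" and "Cyan" in the wild.
DEFAULT_ALIASES: dict[str, FluorClass] = {
    "cyan": FluorClass.CYAN,
    "blue": FluorClass.CYAN,
    "yellow": FluorClass.YELLOW,
    "red": FluorClass.RED,
}


def resolve_class(name: str, alias_table: Optional[Mapping[str, FluorClass]] = None) -> FluorClass:
    """Map a free-text class name to a :class:`FluorClass` (case-insensitive)."""
    table = {k.lower(): v for k, v in (alias_table or DEFAULT_ALIASES).items()}
    key = str(name).lower()
    if key not in table:
        raise ValueError(f"unknown class name: {name!r}")
    return table[key]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ImageRGB:
    """An H x W raster of 3-channel 8-bit pixels plus acquisition metadata.

    ``pixel_size_mm`` is the physical side length of one pixel in mm; it
    defaults to 1.0 for uncalibrated images, in which case mm^2 outputs equal
    px^2 numerically.
    """

    pixels: np.ndarray
    source_path: str = ""
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("zero-size image")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


_HIGH_DEPTH_MODES = {"I", "I;16", "I;16B", "I;16L", "I;16N", "F"}


def read_image(path, pixel_size_mm: float = 1.0) -> ImageRGB:
    """Read an 8-bit PNG or TIFF as an :class:`ImageRGB`.

    Grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.  Images deeper than 8 bits per channel
    raise ``ValueError`` rather than being silently rescaled.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    with Image.open(p) as img:
        if img.mode in _HIGH_DEPTH_MODES:
            raise ValueError(f"unsupported bit depth (mode {img.mode}); only 8-bit images are supported")
        if img.mode == "P":
            img = img.convert("RGB")
        if img.mode == "LA":
            img = img.convert("L")
        if img.mode == "RGBA":
            img = img.convert("RGB")
        if img.mode == "L":
            arr = np.asarray(img, dtype=np.uint8)
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        elif img.mode == "RGB":
            arr = np.asarray(img, dtype=np.uint8)
        else:
            raise ValueError(f"unsupported image mode: {img.mode}")
    if arr.size == 0:
        raise ValueError("zero-size image")
    return ImageRGB(pixels=arr, source_path=str(p), pixel_size_mm=pixel_size_mm)


def write_image(image: ImageRGB, path) -> None:
    """Write an :class:`ImageRGB` to PNG or TIFF (by file extension)."""
    Image.fromarray(image.pixels, mode="RGB").save(str(path))


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

def bbox_of_mask(mask: Iterable[tuple[int, int]]) -> tuple[int, int, int, int]:
    """Tight half-open bounding box of a set of (row, col) pixels."""
    rows = [r for r, _ in mask]
    cols = [c for _, c in mask]
    if not rows:
        raise ValueError("empty mask")
    return min(rows), min(cols), max(rows) + 1, max(cols) + 1


@dataclasses.dataclass
class Detection:
    """One candidate nodule.

    ``mask`` is the set of (row, col) pixels belonging to the nodule;
    ``bbox`` is always the tight half-open box of the mask.  ``source`` is
    ``"classical"`` for the HSB-gating backend and ``"imported"`` for
    detections read from a prediction file.  ``partner_classes`` is non-empty
    only for MIXED detections produced by :func:`nodulequant.detect.merge_mixed`.
    """

    det_id: int
    fluor_class: FluorClass
    mask: frozenset
    bbox: tuple[int, int, int, int]
    confidence: float
    source: str = "classical"
    partner_classes: frozenset = dataclasses.field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.mask:
            raise ValueError("detection mask must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.source not in ("classical", "imported"):
            raise ValueError(f"unknown detection source: {self.source}")


def detection_from_mask(
    det_id: int,
    fluor_class: FluorClass,
    mask: Iterable[tuple[int, int]],
    confidence: float,
    source: str = "classical",
    partner_classes: Iterable[FluorClass] = (),
) -> Detection:
    """Build a Detection with the bbox derived from the mask."""
    fmask = frozenset((int(r), int(c)) for r, c in mask)
    return Detection(
        det_id=det_id,
        fluor_class=fluor_class,
        mask=fmask,
        bbox=bbox_of_mask(fmask),
        confidence=float(confidence),
        source=source,
        partner_classes=frozenset(partner_classes),
    )


# ---------------------------------------------------------------------------
# HSB gates and run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HSBGate:
    """Hue/saturation/brightness gate for one fluorophore class.

    Hue bounds live in [0, 1); a wrapped interval (``hue_lo > hue_hi``) is
    interpreted as passing through 1.0, which is how the red class straddles
    hue 0.
    """

    fluor_class: FluorClass
    hue_lo: float
    hue_hi: float
    sat_min: float
    bri_min: float

    def __post_init__(self) -> None:
        for v, name in ((self.sat_min, "sat_min"), (self.bri_min, "bri_min")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def hue_passes(self, hue):
        hue = np.asarray(hue)
        if self.hue_lo <= self.hue_hi:
            return (hue >= self.hue_lo) & (hue <= self.hue_hi)
        return (hue >= self.hue_lo) | (hue <= self.hue_hi)

    def passes(self, hue, sat, bri):
        """Vectorised gate predicate over HSB values."""
        return self.hue_passes(hue) & (np.asarray(sat) >= self.sat_min) & (np.asarray(bri) >= self.bri_min)


def default_gates() -> dict[FluorClass, HSBGate]:
    """Default per-class gates (config-overridable).

    Real imagery needs per-image tuning; these defaults bracket the class
    peak colours used by the simulator and typical reporter emission hues.
    """
    return {
        FluorClass.CYAN: HSBGate(FluorClass.CYAN, 0.42, 0.58, 0.3, 0.15),
        FluorClass.YELLOW: HSBGate(FluorClass.YELLOW, 0.10, 0.20, 0.3, 0.15),
        FluorClass.RED: HSBGate(FluorClass.RED, 0.92, 0.06, 0.3, 0.15),
    }


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration shared by the CLI and library entry points."""

    pixel_size_mm: float = 1.0
    gates: dict = dataclasses.field(default_factory=default_gates)
    min_area_px: int = 20
    max_area_px: int = 100_000
    confidence_threshold: float = 0.3
    proximity_px: int = 20
    morph_radius_px: int = 2
    primary_open_radius_px: int = 3
    mixed_overlap_frac: float = 0.5
    intensity_rescale: Optional[tuple] = None
    mask_brightness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_area_px <= self.max_area_px):
            raise ValueError("require 0 < min_area_px <= max_area_px")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    def to_dict(self) -> dict:
        gates = {
            fc.value: {
                "hue_lo": g.hue_lo,
                "hue_hi": g.hue_hi,
                "sat_min": g.sat_min,
                "bri_min": g.bri_min,
            }
            for fc, g in self.gates.items()
        }
        d = dataclasses.asdict(self)
        d["gates"] = gates
        if self.intensity_rescale is not None:
            d["intensity_rescale"] = list(self.intensity_rescale)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "gates" in d and d["gates"] is not None:
            gates = {}
            for name, g in d["gates"].items():
                fc = FluorClass(name)
                gates[fc] = HSBGate(fc, g["hue_lo"], g["hue_hi"], g["sat_min"], g["bri_min"])
            base = default_gates()
            base.update(gates)
            d["gates"] = base
        if d.get("intensity_rescale") is not None:
            d["intensity_rescale"] = tuple(d["intensity_rescale"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; missing keys use defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Prediction files
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round half away from zero (the box-conversion rounding rule)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def rasterize_polygon(points: Sequence[tuple[float, float]], shape: tuple[int, int]) -> set:
    """Rasterize a polygon given as (x, y) vertices to a set of (row, col) pixels.

    A pixel belongs to the polygon when its integer-coordinate center is
    inside under the even-odd rule; centers exactly on an edge count as
    inside.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        return set()
    H, W = shape
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    c0 = max(0, int(math.floor(min(xs))))
    c1 = min(W - 1, int(math.ceil(max(xs))))
    r0 = max(0, int(math.floor(min(ys))))
    r1 = min(H - 1, int(math.ceil(max(ys))))
    if c1 < c0 or r1 < r0:
        return set()
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    px = cols.ravel().astype(float)
    py = rows.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(pts)
    eps = 1e-9
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        dy = y2 - y1
        cond = (y1 > py) != (y2 > py)
        if dy != 0.0:
            xint = x1 + (py - y1) * (x2 - x1) / dy
            inside ^= cond & (px < xint)
        dx = x2 - x1
        seg2 = dx * dx + dy * dy
        cross = dx * (py - y1) - dy * (px - x1)
        dot = (px - x1) * dx + (py - y1) * dy
        if seg2 > 0:
            scale = math.sqrt(seg2)
            on_edge |= (np.abs(cross) <= eps * max(1.0, scale)) & (dot >= -eps) & (dot <= seg2 + eps)
        else:
            on_edge |= (np.abs(px - x1) <= eps) & (np.abs(py - y1) <= eps)
    keep = inside | on_edge
    return {(int(r), int(c)) for r, c, k in zip(py, px, keep) if k}


def _bbox_from_center(x: float, y: float, width: float, height: float,
                      shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Convert a center-based (x, y, width, height) box to a clipped half-open
    (row, col) box using round-half-away-from-zero."""
    H, W = shape
    row_min = round_half_away(y - height / 2.0)
    col_min = round_half_away(x - width / 2.0)
    row_max = row_min + round_half_away(height)
    col_max = col_min + round_half_away(width)
    row_min_c, col_min_c = max(0, row_min), max(0, col_min)
    row_max_c, col_max_c = min(H, row_max), min(W, col_max)
    if row_max_c <= row_min_c or col_max_c <= col_min_c:
        raise ValueError("bbox fully outside image")
    return row_min_c, col_min_c, row_max_c, col_max_c


def _points_of(entry) -> list[tuple[float, float]]:
    pts = entry.get("points") or []
    out = []
    for p in pts:
        if isinstance(p, Mapping):
            out.append((float(p["x"]), float(p["y"])))
        else:
            out.append((float(p[0]), float(p[1])))
    return out


def load_predictions(path, image: ImageRGB,
                     alias_table: Optional[Mapping[str, FluorClass]] = None) -> list[Detection]:
    """Load a prediction JSON file into a list of imported Detections.

    Each prediction carries a class name, a center-based bounding box, a
    confidence, and optionally a segmentation polygon.  When a polygon is
    present the mask is its rasterization (pixel centers, even-odd rule) and
    the bbox is re-derived as the tight box of that mask; otherwise the mask
    is the full rasterized bounding box.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed prediction JSON: {e}") from e
    if isinstance(data, list):
        preds = data
    else:
        preds = data.get("predictions")
        if preds is None:
            raise ValueError("prediction file lacks a 'predictions' list")
    detections: list[Detection] = []
    shape = image.shape
    for i, entry in enumerate(preds):
        name = entry.get("class", entry.get("class_name"))
        if name is None:
            raise ValueError(f"prediction {i} lacks a class name")
        fc = resolve_class(name, alias_table)
        bbox = _bbox_from_center(
            float(entry["x"]), float(entry["y"]),
            float(entry["width"]), float(entry["height"]), shape,
        )
        points = _points_of(entry)
        if points:
            mask = rasterize_polygon(points, shape)
            if not mask:
                # degenerate polygon: fall back to the bounding box
                mask = {(r, c) for r in range(bbox[0], bbox[2]) for c in range(bbox[1], bbox[3])}
        else:
            mask = {(r, c) for r in range(bbox[0], bbox[2]) for c in range(bbox[1], bbox[3])}
        detections.append(
            detection_from_mask(
                det_id=i,
                fluor_class=fc,
                mask=mask,
                confidence=float(entry.get("confidence", 1.0)),
                source="imported",
            )
        )
    return detections


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

NODULE_COLUMNS = [
    "image", "nodule_id", "class", "centroid_row", "centroid_col",
    "area_px2", "area_mm2", "brightness_0_100", "confidence",
    "dist_to_root_px", "dist_to_root_mm", "reachable", "mixed",
    "partner_classes",
]

SUMMARY_COLUMNS = [
    "image", "class", "n_nodules", "total_area_px2", "avg_area_px2",
    "total_area_mm2", "avg_area_mm2", "avg_brightness", "total_brightness",
]


def partner_string(partner_classes: Iterable[FluorClass]) -> str:
    ordered = [fc.value for fc in CLASS_ORDER if fc in set(partner_classes)]
    return "+".join(ordered)


def records_frame(records) -> pd.DataFrame:
    """Per-nodule records as a DataFrame in deterministic row order."""
    rows = []
    for r in records:
        rows.append({
            "image": r.image_id,
            "nodule_id": r.nodule_id,
            "class": r.fluor_class.value,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area_px2": r.area_px2,
            "area_mm2": r.area_mm2,
            "brightness_0_100": r.brightness_0_100,
            "confidence": r.confidence,
            "dist_to_root_px": r.dist_to_root_px if r.reachable else np.nan,
            "dist_to_root_mm": r.dist_to_root_mm if r.reachable else np.nan,
            "reachable": bool(r.reachable),
            "mixed": bool(r.mixed),
            "partner_classes": partner_string(r.partner_classes),
        })
    df = pd.DataFrame(rows, columns=NODULE_COLUMNS)
    return df.sort_values(["image", "nodule_id"], kind="mergesort").reset_index(drop=True)


def summaries_frame(summaries) -> pd.DataFrame:
    """Per-class summaries as a DataFrame in deterministic row order."""
    order = {fc.value: i for i, fc in enumerate(CLASS_ORDER)}
    rows = []
    for s in summaries:
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
        })
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df["_ord"] = df["class"].map(order)
    df = df.sort_values(["image", "_ord"], kind="mergesort").drop(columns="_ord")
    return df.reset_index(drop=True)


def write_results(records, summaries, out_dir) -> tuple[Path, Path]:
    """Write per-nodule and per-class CSV files; returns the two paths.

    Output is deterministic: fixed column order, rows sorted by
    (image, nodule_id), UTF-8, '.' decimal separator, '\\n' line endings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nod_path = out / "nodules.csv"
    sum_path = out / "summaries.csv"
    records_frame(records).to_csv(nod_path, index=False, lineterminator="\n")
    summaries_frame(summaries).to_csv(sum_path, index=False, lineterminator="\n")
    return nod_path, sum_path
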