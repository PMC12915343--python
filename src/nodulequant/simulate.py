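"""Synthetic fluorescence micrograph generator with exact ground truth.

Emulates the gross features of nodulated-root fluorescence imagery: a dark
background, a bright gray primary root descending through the frame with
thinner lateral roots branching off, and nodules of three spectral classes
(cyan, yellow, red) rendered as uniform discs or squares at class peak
colours, optionally with additive Gaussian pixel noise.

Every render is fully determined by the seed and emits per-nodule ground
truth: class, exact pixel mask, projected area, the closed-form brightness
of the nodule's bounding box on the noise-free render, and — for nodules
placed on a lateral — the octile arc length along the lateral from the
nodule center to the rendered primary-root boundary.  Truth files mirror
the prediction-file schema so they can be loaded back through
``core_io.load_predictions`` for round-trip and evaluation tests.

Square nodules exist so brightness checks are exact (a square fills its
bounding box, so the box mean is the peak colour with no background
contamination); discs exercise area and distance realism.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from . import quantify
from .core_io import (
    Detection,
    FluorClass,
    ImageRGB,
    default_gates,
    detection_from_mask,
)
from .detect import rgb_to_hsb

SQRT2 = math.sqrt(2.0)

#: Default class peak colours; chosen to sit centrally in the default gates.
CLASS_COLORS: dict[FluorClass, tuple[int, int, int]] = {
    FluorClass.CYAN: (0, 200, 255),
    FluorClass.YELLOW: (230, 220, 30),
    FluorClass.RED: (220, 40, 40),
}


@dataclasses.dataclass
class Placement:
    """Where a nodule sits: on the primary axis at a fractional position, or
    on lateral ``lateral_index`` at a given octile arc offset (px) from the
    rendered primary-root boundary."""

    kind: str  # "on_primary" | "on_lateral"
    primary_frac: Optional[float] = None
    lateral_index: int = 0
    arc_offset_px: float = 0.0


@dataclasses.dataclass
class NoduleSpec:
    fluor_class: FluorClass
    placement: Placement
    shape: str = "disc"  # "disc" | "square"
    radius_px: int = 6
    side_px: int = 11
    peak_rgb: Optional[tuple[int, int, int]] = None

    def color(self) -> tuple[int, int, int]:
        return self.peak_rgb if self.peak_rgb is not None else CLASS_COLORS[self.fluor_class]


@dataclasses.dataclass
class SimConfig:
    seed: int = 0
    height: int = 512
    width: int = 512
    root_width_px: int = 9        # rendered primary-root width (odd)
    lateral_width_px: int = 5     # rendered lateral width (odd)
    n_laterals: int = 4
    lateral_len_px: int = 170
    nodules: list = dataclasses.field(default_factory=list)
    background_level: int = 10
    noise_sd: float = 0.0
    root_intensity: int = 180
    curvature_sd: float = 0.15    # 0 -> straight vertical primary
    lateral_curvature_sd: float = 0.02
    allow_mixed_overlap: bool = False
    pixel_size_mm: float = 1.0


@dataclasses.dataclass
class TruthNodule:
    truth_id: int
    fluor_class: FluorClass
    mask: frozenset
    area_px2: int
    brightness_0_100: float
    arc_dist_px: float
    centroid: tuple[float, float]


@dataclasses.dataclass
class GroundTruth:
    nodules: list
    root_mask: np.ndarray     # rendered root (primary + laterals), no nodules
    primary_mask: np.ndarray  # rendered primary root only
    primary_path: list        # ordered (row, col) centerline pixels


@dataclasses.dataclass
class RootGeometry:
    primary: list   # ordered (row, col) centerline pixels, top to bottom
    laterals: list  # list of ordered pixel lists, junction outward


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def generate_root(config: SimConfig) -> RootGeometry:
    """Seeded root geometry: a momentum-damped monotone-downward primary
    walk spanning the image plus laterals branching at spaced positions."""
    H, W = config.height, config.width
    margin = max(config.root_width_px, config.lateral_width_px) + 2
    if W <= 2 * margin or H < 8:
        raise ValueError("image too small for the configured root width")
    rng = np.random.default_rng(config.seed)
    col = W / 2.0 + (rng.uniform(-0.05, 0.05) * W if config.curvature_sd > 0 else 0.0)
    heading = 0.0
    primary = []
    for r in range(H):
        primary.append((r, int(round(col))))
        heading = 0.9 * heading + rng.normal(0.0, config.curvature_sd)
        heading = float(np.clip(heading, -0.9, 0.9))
        col = float(np.clip(col + heading, margin, W - 1 - margin))

    laterals = []
    if config.n_laterals > 0:
        fracs = np.linspace(0.18, 0.85, config.n_laterals)
        for i, frac in enumerate(fracs):
            idx = int(frac * (H - 1))
            r0, c0 = primary[idx]
            side = 1 if i % 2 == 0 else -1
            tilt = rng.uniform(0.15, 0.40)  # radians below horizontal
            angle = tilt
            pos_r, pos_c = float(r0), float(c0)
            path = [(r0, c0)]
            for _ in range(config.lateral_len_px):
                pos_r += math.sin(angle)
                pos_c += side * math.cos(angle)
                angle += rng.normal(0.0, config.lateral_curvature_sd)
                angle = float(np.clip(angle, -0.5, 0.9))
                pr, pc = int(round(pos_r)), int(round(pos_c))
                if not (margin <= pr < H - margin and margin <= pc < W - margin):
                    break
                if (pr, pc) != path[-1]:
                    path.append((pr, pc))
            laterals.append(path)
    return RootGeometry(primary=primary, laterals=laterals)


def _paint_path(shape: tuple[int, int], path, radius: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rows = [r for r, _ in path]
    cols = [c for _, c in path]
    mask[rows, cols] = True
    if radius > 0:
        mask = skmorph.dilation(mask, skmorph.disk(radius))
    return mask


def disc_mask(center: tuple[int, int], radius: int,
              shape: Optional[tuple[int, int]]) -> frozenset:
    """Pixels whose integer centers lie within ``radius`` of the center;
    ``shape=None`` skips image-bound clipping."""
    cr, cc = center
    H, W = shape if shape is not None else (None, None)
    pixels = set()
    for r in range(cr - radius, cr + radius + 1):
        for c in range(cc - radius, cc + radius + 1):
            if (r - cr) ** 2 + (c - cc) ** 2 <= radius * radius:
                if shape is None or (0 <= r < H and 0 <= c < W):
                    pixels.add((r, c))
    return frozenset(pixels)


def square_mask(center: tuple[int, int], side: int,
                shape: Optional[tuple[int, int]]) -> frozenset:
    cr, cc = center
    H, W = shape if shape is not None else (None, None)
    r0, c0 = cr - side // 2, cc - side // 2
    return frozenset(
        (r, c)
        for r in range(r0, r0 + side)
        for c in range(c0, c0 + side)
        if shape is None or (0 <= r < H and 0 <= c < W)
    )


def _octile_step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _lateral_arc_table(path, primary_path, junction_radius: float):
    """Cumulative octile arc length along a lateral.

    Arc zero sits where the lateral clears the junction zone — the last
    path pixel within ``junction_radius`` (Euclidean) of the primary
    centerline.  At the scale of the rendered root widths the exact point
    where a lateral "leaves" the primary is ambiguous; half the sum of the
    two widths is the geometric radius at which the two tubes stop
    overlapping.  Returns (start_index, cum) where cum[k] is the arc from
    path[start_index] to path[k].
    """
    centerline = np.asarray(primary_path, dtype=float)
    start = 0
    for k, (r, c) in enumerate(path):
        d2 = np.min((centerline[:, 0] - r) ** 2 + (centerline[:, 1] - c) ** 2)
        if d2 <= junction_radius * junction_radius:
            start = k
        else:
            break
    cum = [0.0] * len(path)
    for k in range(start + 1, len(path)):
        cum[k] = cum[k - 1] + _octile_step(path[k - 1], path[k])
    return start, cum


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _validate_peak(spec: NoduleSpec) -> None:
    """Check the nodule's peak colour passes its class's default HSB gate."""
    fc = spec.fluor_class
    if fc is FluorClass.MIXED:
        raise ValueError("simulator nodules carry concrete classes, not MIXED")
    r, g, b = spec.color()
    img = ImageRGB(np.array([[[r, g, b]]], dtype=np.uint8))
    planes = rgb_to_hsb(img)
    gate = default_gates()[fc]
    if not bool(gate.passes(planes.hue, planes.sat, planes.bri)[0, 0]):
        raise ValueError(
            f"peak colour {spec.color()} fails the default {fc.value} gate")


def render(config: SimConfig) -> tuple[ImageRGB, GroundTruth]:
    """Render a synthetic micrograph and its exact ground truth."""
    H, W = config.height, config.width
    shape = (H, W)
    geom = generate_root(config)
    primary_mask = _paint_path(shape, geom.primary, config.root_width_px // 2)
    root = primary_mask.copy()
    for path in geom.laterals:
        root |= _paint_path(shape, path, config.lateral_width_px // 2)
    junction_radius = (config.root_width_px + config.lateral_width_px) / 2.0
    lateral_tables = [
        _lateral_arc_table(path, geom.primary, junction_radius)
        for path in geom.laterals
    ]

    canvas = np.full((H, W, 3), float(config.background_level))
    canvas[root] = float(config.root_intensity)

    # resolve nodule placements
    placed: list[tuple[NoduleSpec, frozenset, tuple[int, int], float]] = []
    rng = np.random.default_rng(config.seed + 1_000_003)
    for spec in config.nodules:
        _validate_peak(spec)
        pl = spec.placement
        for attempt in range(100):
            if pl.kind == "on_primary":
                frac = pl.primary_frac
                if frac is None:
                    frac = float(rng.uniform(0.08, 0.92))
                idx = int(frac * (len(geom.primary) - 1))
                center = geom.primary[idx]
                arc = 0.0
            elif pl.kind == "on_lateral":
                if pl.lateral_index >= len(geom.laterals):
                    raise ValueError("lateral_index out of range")
                path = geom.laterals[pl.lateral_index]
                start, cum = lateral_tables[pl.lateral_index]
                idx = next((k for k in range(start, len(path))
                            if cum[k] >= pl.arc_offset_px), None)
                if idx is None:
                    raise ValueError(
                        f"lateral {pl.lateral_index} shorter than arc offset "
                        f"{pl.arc_offset_px}")
                center = path[idx]
                arc = cum[idx]
            else:
                raise ValueError(f"unknown placement kind: {pl.kind}")
            if spec.shape == "disc":
                mask = disc_mask(center, spec.radius_px, shape)
                unclipped = disc_mask(center, spec.radius_px, None)
            elif spec.shape == "square":
                mask = square_mask(center, spec.side_px, shape)
                unclipped = square_mask(center, spec.side_px, None)
            else:
                raise ValueError(f"unknown nodule shape: {spec.shape}")
            if len(mask) != len(unclipped):
                # clipped by the image border
                if pl.primary_frac is None and pl.kind == "on_primary":
                    continue
                raise ValueError("nodule placement extends outside the image")
            # separation: keep a 1-px buffer so distinct nodules never touch
            clash = any(
                mask & other or _adjacent(mask, other)
                for _, other, _, _ in placed
            )
            if clash and not config.allow_mixed_overlap:
                if pl.primary_frac is None and pl.kind == "on_primary":
                    continue  # retry a fresh random position
                raise ValueError("overlapping nodules require a mixed scenario")
            placed.append((spec, mask, center, arc))
            break
        else:
            raise ValueError("could not place nodule after bounded retries")

    # draw: later nodules overwrite; co-located pairs split left/right halves
    for i, (spec, mask, center, _) in enumerate(placed):
        color = np.array(spec.color(), dtype=float)
        overlap = set()
        for j in range(i):
            overlap |= set(mask) & set(placed[j][1])
        for r, c in mask:
            if (r, c) in overlap and c < center[1]:
                continue  # leave the earlier partner's colour on the left half
            canvas[r, c] = color

    noiseless = canvas.copy()
    truth_nodules = []
    clean_img = ImageRGB(np.clip(np.floor(noiseless + 0.5), 0, 255).astype(np.uint8),
                         source_path="synthetic", pixel_size_mm=config.pixel_size_mm)
    for i, (spec, mask, center, arc) in enumerate(placed):
        det = detection_from_mask(i, spec.fluor_class, mask, 1.0, "classical")
        brightness = quantify.nodule_brightness(clean_img, det)
        rows = [r for r, _ in mask]
        cols = [c for _, c in mask]
        truth_nodules.append(TruthNodule(
            truth_id=i,
            fluor_class=spec.fluor_class,
            mask=mask,
            area_px2=len(mask),
            brightness_0_100=brightness,
            arc_dist_px=float(arc),
            centroid=(float(np.mean(rows)), float(np.mean(cols))),
        ))

    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
    pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    image = ImageRGB(pixels=pixels, source_path="synthetic",
                     pixel_size_mm=config.pixel_size_mm)
    truth = GroundTruth(nodules=truth_nodules, root_mask=root,
                        primary_mask=primary_mask, primary_path=geom.primary)
    return image, truth


def _adjacent(a, b) -> bool:
    """True when two pixel sets touch under 8-connectivity."""
    small, big = (a, b) if len(a) <= len(b) else (b, a)
    big = set(big)
    for r, c in small:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (r + dr, c + dc) in big:
                    return True
    return False


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def _mask_polygon(mask: frozenset, shape: tuple[int, int]) -> list:
    """Sub-pixel outline of a mask whose even-odd rasterization reproduces
    the mask exactly (contour at the 0.5 level passes between pixel centers)."""
    H, W = shape
    arr = np.zeros((H + 2, W + 2), dtype=float)
    for r, c in mask:
        arr[r + 1, c + 1] = 1.0
    contours = skmeasure.find_contours(arr, 0.5)
    contour = max(contours, key=len)
    return [{"x": float(c - 1), "y": float(r - 1)} for r, c in contour]


def write_truth(truth: GroundTruth, path, shape: Optional[tuple[int, int]] = None) -> None:
    """Serialise ground truth as a prediction-schema JSON file.

    The file loads through ``core_io.load_predictions`` (class, center box,
    confidence 1.0, polygon points) and adds truth-only fields under a
    ``truth`` key.  Serialization is deterministic (sorted keys).
    """
    if shape is None:
        shape = truth.root_mask.shape
    preds = []
    for n in truth.nodules:
        rows = [r for r, _ in n.mask]
        cols = [c for _, c in n.mask]
        r0, c0, r1, c1 = min(rows), min(cols), max(rows) + 1, max(cols) + 1
        w, h = float(c1 - c0), float(r1 - r0)
        preds.append({
            "class": n.fluor_class.value.capitalize(),
            "x": c0 + w / 2.0,
            "y": r0 + h / 2.0,
            "width": w,
            "height": h,
            "confidence": 1.0,
            "points": _mask_polygon(n.mask, shape),
            "truth": {
                "truth_id": n.truth_id,
                "area_px2": n.area_px2,
                "brightness_0_100": n.brightness_0_100,
                "arc_dist_px": n.arc_dist_px,
                "centroid": [n.centroid[0], n.centroid[1]],
            },
        })
    payload = {"schema_version": 1, "predictions": preds}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def truth_to_detections(truth: GroundTruth) -> list[Detection]:
    """Ground-truth nodules as Detections (for evaluation)."""
    return [
        detection_from_mask(n.truth_id, n.fluor_class, n.mask, 1.0, "imported")
        for n in truth.nodules
    ]


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = ("clean", "noisy", "split-root", "mixed")


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Named study conditions.

    clean      5 cyan + 5 yellow + 5 red well-separated disc nodules on the
               primary axis, zero noise.
    noisy      the clean layout plus Gaussian pixel noise (sd 8).
    split-root cyan nodules confined to one side's laterals and yellow to
               the other, emulating a split-root co-inoculation readout.
    mixed      nine single-class nodules plus one co-located cyan+yellow
               pair: a 10% mixed-infection rate.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset: {name!r} (choose from {PRESETS})")
    classes = (FluorClass.CYAN, FluorClass.YELLOW, FluorClass.RED)
    if name in ("clean", "noisy"):
        nodules = [
            NoduleSpec(classes[i % 3],
                       Placement("on_primary", primary_frac=f))
            for i, f in enumerate(np.linspace(0.05, 0.95, 15))
        ]
        return SimConfig(seed=seed, nodules=nodules,
                         noise_sd=8.0 if name == "noisy" else 0.0)
    if name == "split-root":
        # even lateral indices grow to the right, odd to the left
        nodules = []
        for i, arc in enumerate((25.0, 60.0, 95.0)):
            nodules.append(NoduleSpec(
                FluorClass.CYAN,
                Placement("on_lateral", lateral_index=0, arc_offset_px=arc),
                radius_px=4))
            nodules.append(NoduleSpec(
                FluorClass.YELLOW,
                Placement("on_lateral", lateral_index=1, arc_offset_px=arc),
                radius_px=4))
        nodules.append(NoduleSpec(FluorClass.CYAN,
                                  Placement("on_primary", primary_frac=0.08)))
        nodules.append(NoduleSpec(FluorClass.YELLOW,
                                  Placement("on_primary", primary_frac=0.95)))
        return SimConfig(seed=seed, nodules=nodules)
    # mixed
    nodules = [
        NoduleSpec(classes[i % 3], Placement("on_primary", primary_frac=f))
        for i, f in enumerate(np.linspace(0.06, 0.80, 9))
    ]
    nodules.append(NoduleSpec(FluorClass.CYAN,
                              Placement("on_primary", primary_frac=0.93)))
    nodules.append(NoduleSpec(FluorClass.YELLOW,
                              Placement("on_primary", primary_frac=0.93)))
    return SimConfig(seed=seed, nodules=nodules, allow_mixed_overlap=True)
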