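"""Color-gate histomorphometry of resin-embedded, SVG-stained scaffold sections.

Sections stained with Stevenel's blue / van Gieson's picro fuchsin show the
ceramic scaffold as near-black, mineralized bone as orange–purple, and soft
tissue as blue.  Pixels are classified by inclusive box gates in 8-bit HSV
space (hue 0–179, saturation/value 0–255); the scaffold envelope is closed
morphologically with a user-chosen square kernel; and percent bony ingrowth is
reported for named regions of the section: the scaffold interior (split into
superficial and deep halves about the centroid's horizontal centerline), a
circumferential band along the scaffold border, the flanking "sides", and a
central disk.

Default gates::

    scaffold: [0, 0, 0] .. [70, 67, 90]
    bone:     [155, 57, 67] .. [179, 202, 187]

All coordinates are 0-based with origin at the top-left corner, x rightward
and y downward.  Percentages are computed against non-scaffold pixels of each
region, so a region fully occupied by struts has an undefined (NaN) metric
rather than a misleading zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology

# label raster codes
LABEL_OTHER = 0
LABEL_SCAFFOLD = 1
LABEL_BONE = 2

# region raster codes (mutually exclusive, cover the raster)
REGION_EXTERIOR = 0
REGION_SUPERFICIAL = 1
REGION_DEEP = 2
REGION_CIRCUMFERENCE = 3
REGION_SIDES = 4

REGION_NAMES = {
    REGION_EXTERIOR: "exterior",
    REGION_SUPERFICIAL: "superficial",
    REGION_DEEP: "deep",
    REGION_CIRCUMFERENCE: "circumference",
    REGION_SIDES: "sides",
}

HUE_MAX = 179
SV_MAX = 255


class GateOverlapError(ValueError):
    """Two color gates claim a common HSV box — classification is ambiguous."""


class EmptyScaffoldError(ValueError):
    """No scaffold-gated pixel found; the section geometry is undefined."""


@dataclass(frozen=True)
class HSVGate:
    """Inclusive box gate in 8-bit HSV (hue 0–179, sat/val 0–255)."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    label: str

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != (3,) or up.shape != (3,):
            raise ValueError("gate bounds must be (h, s, v) triplets")
        if np.any(lo > up):
            raise ValueError(f"gate {self.label}: lower bound exceeds upper bound")
        if up[0] > HUE_MAX or up[1] > SV_MAX or up[2] > SV_MAX or np.any(lo < 0):
            raise ValueError(f"gate {self.label}: bounds outside 8-bit HSV range")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean membership for an (..., 3) array of 8-bit HSV triplets."""
        hsv = np.asarray(hsv)
        lo = np.asarray(self.lower)
        up = np.asarray(self.upper)
        return np.all((hsv >= lo) & (hsv <= up), axis=-1)

    def overlaps(self, other: "HSVGate") -> bool:
        lo = np.maximum(self.lower, other.lower)
        up = np.minimum(self.upper, other.upper)
        return bool(np.all(lo <= up))


#: Gates used by the original slide-analysis program.
DEFAULT_SCAFFOLD_GATE = HSVGate((0, 0, 0), (70, 67, 90), "scaffold")
DEFAULT_BONE_GATE = HSVGate((155, 57, 67), (179, 202, 187), "bone")
DEFAULT_GATES = (DEFAULT_SCAFFOLD_GATE, DEFAULT_BONE_GATE)


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to the 8-bit HSV convention of the gates.

    Hue is scaled to 0–179 (so 179 sits at the red end of the wheel, which is
    why the bone gate's upper hue is 179), saturation and value to 0–255.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
    out = np.empty_like(hsv)
    out[..., 0] = np.round(hsv[..., 0] * HUE_MAX)
    out[..., 1] = np.round(hsv[..., 1] * SV_MAX)
    out[..., 2] = np.round(hsv[..., 2] * SV_MAX)
    return out.astype(np.uint8)


def hsv8_to_rgb(hsv8: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv8` (up to 8-bit quantization)."""
    hsv8 = np.asarray(hsv8, dtype=np.float64)
    hsv = np.empty_like(hsv8)
    hsv[..., 0] = hsv8[..., 0] / HUE_MAX
    hsv[..., 1] = hsv8[..., 1] / SV_MAX
    hsv[..., 2] = hsv8[..., 2] / SV_MAX
    rgb = skcolor.hsv2rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def gate_pixels(image: np.ndarray, gates=DEFAULT_GATES) -> np.ndarray:
    """Classify each RGB pixel as scaffold, bone, or other by HSV box gates.

    Parameters
    ----------
    image:
        (H, W, 3) uint8 RGB raster.
    gates:
        Iterable of :class:`HSVGate`, exactly one labeled ``scaffold`` and one
        labeled ``bone``.  Gates must not overlap.

    Returns
    -------
    (H, W) uint8 label raster with values LABEL_OTHER / LABEL_SCAFFOLD /
    LABEL_BONE.
    """
    gates = list(gates)
    by_label = {g.label: g for g in gates}
    if set(by_label) != {"scaffold", "bone"} or len(gates) != 2:
        raise ValueError("expected exactly one scaffold gate and one bone gate")
    if by_label["scaffold"].overlaps(by_label["bone"]):
        raise GateOverlapError("scaffold and bone gates overlap")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    hsv = rgb_to_hsv8(image)
    labels = np.full(hsv.shape[:2], LABEL_OTHER, dtype=np.uint8)
    labels[by_label["scaffold"].contains(hsv)] = LABEL_SCAFFOLD
    labels[by_label["bone"].contains(hsv)] = LABEL_BONE
    return labels


@dataclass
class RegionPartition:
    """Geometry of a section: scaffold envelope, landmarks, and region labels."""

    scaffold_mask: np.ndarray
    hull_mask: np.ndarray
    centroid: tuple[float, float]  # (x, y)
    extremes: dict  # left/right/top/bottom -> (x, y)
    centerline_y: float
    regions: np.ndarray  # uint8 raster of REGION_* codes
    center_mask: np.ndarray  # central disk (overlaps interior regions)
    kernel_px: int
    band_px: int

    @property
    def interior_mask(self) -> np.ndarray:
        return (self.regions == REGION_SUPERFICIAL) | (self.regions == REGION_DEEP)


def find_scaffold(labels: np.ndarray, kernel_px: int = 25, band_px: int | None = None) -> RegionPartition:
    """Close the scaffold mask into an envelope and partition the raster.

    The scaffold envelope ("hull") is the morphological closing of the
    scaffold-gated mask with a square kernel of side ``kernel_px`` followed by
    hole filling, so a porous lattice becomes one solid silhouette provided the
    kernel exceeds the pore spacing.  The centroid is the mean coordinate of
    hull pixels; extreme points are the hull pixels of minimal/maximal x and y.

    Regions:

    * circumference — hull pixels within ``band_px`` of the hull boundary
      (default band = ``kernel_px``),
    * superficial / deep — remaining hull pixels above / below the horizontal
      centerline through the centroid (their union is the scaffold interior),
    * sides — exterior pixels within ``band_px`` of the left or right extreme
      point,
    * exterior — everything else.

    A central disk of radius ``0.25 * min(hull width, hull height)`` about the
    centroid is kept as a separate (overlapping) mask for the "center" metric.
    """
    labels = np.asarray(labels)
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be a positive odd integer")
    scaffold = labels == LABEL_SCAFFOLD
    if not scaffold.any():
        raise EmptyScaffoldError("no scaffold-gated pixels in the raster")
    if band_px is None:
        band_px = kernel_px

    footprint = morphology.footprint_rectangle((kernel_px, kernel_px))
    hull = morphology.closing(scaffold, footprint)
    hull = ndimage.binary_fill_holes(hull)

    ys, xs = np.nonzero(hull)
    centroid = (float(xs.mean()), float(ys.mean()))
    extremes = {
        "left": (int(xs[np.argmin(xs)]), int(ys[np.argmin(xs)])),
        "right": (int(xs[np.argmax(xs)]), int(ys[np.argmax(xs)])),
        "top": (int(xs[np.argmin(ys)]), int(ys[np.argmin(ys)])),
        "bottom": (int(xs[np.argmax(ys)]), int(ys[np.argmax(ys)])),
    }
    centerline_y = centroid[1]

    # distance of hull pixels to the nearest non-hull pixel: 1 on the boundary
    dist_in = ndimage.distance_transform_edt(hull)
    circumference = hull & (dist_in <= band_px)
    interior = hull & ~circumference

    yy, xx = np.indices(hull.shape)
    superficial = interior & (yy < centerline_y)
    deep = interior & ~superficial

    exterior = ~hull
    sides = np.zeros_like(hull)
    for key in ("left", "right"):
        ex, ey = extremes[key]
        sides |= (xx - ex) ** 2 + (yy - ey) ** 2 <= band_px**2
    sides &= exterior

    regions = np.full(hull.shape, REGION_EXTERIOR, dtype=np.uint8)
    regions[sides] = REGION_SIDES
    regions[circumference] = REGION_CIRCUMFERENCE
    regions[superficial] = REGION_SUPERFICIAL
    regions[deep] = REGION_DEEP

    hull_w = extremes["right"][0] - extremes["left"][0] + 1
    hull_h = extremes["bottom"][1] - extremes["top"][1] + 1
    radius = 0.25 * min(hull_w, hull_h)
    cx, cy = centroid
    center_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2

    return RegionPartition(
        scaffold_mask=scaffold,
        hull_mask=hull,
        centroid=centroid,
        extremes=extremes,
        centerline_y=centerline_y,
        regions=regions,
        center_mask=center_mask,
        kernel_px=kernel_px,
        band_px=band_px,
    )


@dataclass
class HistoMetrics:
    """Percent bony ingrowth per region, with the denominators used."""

    interior_pct: float
    superficial_pct: float
    deep_pct: float
    circumference_pct: float
    sides_pct: float
    center_pct: float
    denominators: dict = field(default_factory=dict)
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "interior_pct": self.interior_pct,
            "superficial_pct": self.superficial_pct,
            "deep_pct": self.deep_pct,
            "circumference_pct": self.circumference_pct,
            "sides_pct": self.sides_pct,
            "center_pct": self.center_pct,
        }


def _region_pct(labels: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    denom_mask = mask & (labels != LABEL_SCAFFOLD)
    denom = int(denom_mask.sum())
    if denom == 0:
        return float("nan"), 0
    bone = int((denom_mask & (labels == LABEL_BONE)).sum())
    return 100.0 * bone / denom, denom


def measure_ingrowth(labels: np.ndarray, partition: RegionPartition) -> HistoMetrics:
    """Percent bone per region: 100 × bone pixels / non-scaffold region pixels.

    Regions with no non-scaffold pixel are reported as NaN and listed in
    ``undefined`` rather than silently zero.
    """
    labels = np.asarray(labels)
    if labels.shape != partition.regions.shape:
        raise ValueError("label raster and partition have different shapes")
    masks = {
        "interior": partition.interior_mask,
        "superficial": partition.regions == REGION_SUPERFICIAL,
        "deep": partition.regions == REGION_DEEP,
        "circumference": partition.regions == REGION_CIRCUMFERENCE,
        "sides": partition.regions == REGION_SIDES,
        "center": partition.center_mask,
    }
    pct, denoms, undefined = {}, {}, set()
    for name, mask in masks.items():
        p, d = _region_pct(labels, mask)
        pct[name], denoms[name] = p, d
        if d == 0:
            undefined.add(name)
            warnings.warn(f"region '{name}' has no non-scaffold pixels; metric undefined", stacklevel=2)
    return HistoMetrics(
        interior_pct=pct["interior"],
        superficial_pct=pct["superficial"],
        deep_pct=pct["deep"],
        circumference_pct=pct["circumference"],
        sides_pct=pct["sides"],
        center_pct=pct["center"],
        denominators=denoms,
        undefined=undefined,
    )


def analyze_section(
    image: np.ndarray,
    kernel_px: int = 25,
    gates=DEFAULT_GATES,
    band_px: int | None = None,
) -> tuple[np.ndarray, RegionPartition, HistoMetrics]:
    """One-call pipeline: gate pixels, find the scaffold, measure ingrowth."""
    labels = gate_pixels(image, gates)
    partition = find_scaffold(labels, kernel_px=kernel_px, band_px=band_px)
    metrics = measure_ingrowth(labels, partition)
    return labels, partition, metrics


_REGION_TINTS = {
    REGION_SUPERFICIAL: (255, 255, 0),
    REGION_DEEP: (0, 255, 255),
    REGION_CIRCUMFERENCE: (255, 0, 255),
    REGION_SIDES: (0, 255, 0),
}


def render_overlay(
    image: np.ndarray,
    partition: RegionPartition,
    metrics: HistoMetrics | None = None,
    alpha: float = 0.25,
) -> np.ndarray:
    """Annotated copy of the section for visual QC of the computed geometry.

    Region tints are alpha-blended, the hull boundary is drawn in red, the
    centerline as a red row, and the centroid as a red cross.  Deterministic:
    identical inputs yield byte-identical output.
    """
    out = np.asarray(image).astype(np.float64).copy()
    for code, tint in _REGION_TINTS.items():
        mask = partition.regions == code
        out[mask] = (1 - alpha) * out[mask] + alpha * np.asarray(tint, dtype=np.float64)

    boundary = partition.hull_mask & (ndimage.distance_transform_edt(partition.hull_mask) <= 1)
    out[boundary] = (255, 0, 0)

    h, w = partition.regions.shape
    cy = int(round(partition.centerline_y))
    if 0 <= cy < h:
        out[cy, :] = (255, 0, 0)
    cx = int(round(partition.centroid[0]))
    half = 5
    out[max(cy - half, 0) : min(cy + half + 1, h), max(cx, 0) : min(cx + 1, w)] = (255, 0, 0)
    out[max(cy, 0) : min(cy + 1, h), max(cx - half, 0) : min(cx + half + 1, w)] = (255, 0, 0)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
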