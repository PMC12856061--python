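"""Deterministic generators for every input the pipeline consumes.

Each generator emulates one acquisition modality of a scaffold-cranioplasty
study and carries its own ground truth, recomputed from the emitted artifact
(never echoed from the request), so that downstream analysis modules can be
validated by round trip:

* :func:`generate_micrograph` — a stained-section raster: a dark square strut
  lattice (0.9 mm pore spacing in the real scaffold), pores filled with
  bone-colored pixels at requested per-region fractions, soft tissue
  elsewhere.
* :func:`generate_indent_curve` — a load-controlled indentation trace with the
  standard profile (60 μN/s ramp for 5 s, 300 μN hold for 10 s, 2 s unload)
  whose unloading branch is constructed so Oliver–Pharr analysis of the
  noiseless curve returns the requested modulus and hardness exactly.
* :func:`generate_interface` — an annular implant–bone interface with known
  bridged arcs.
* :func:`generate_hu_volume` — a Hounsfield volume with analytic inclusions.
* :func:`generate_cohort` — per-subject group tables with stated effects.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give bit-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridging import InterfaceModel
from .ct_volumetrics import CTVolume
from .histomorphometry import (
    DEFAULT_BONE_GATE,
    DEFAULT_SCAFFOLD_GATE,
    LABEL_BONE,
    gate_pixels,
    hsv8_to_rgb,
)
from .nanoindentation import DEFAULT_INDENTER, UN_PER_NM2_TO_GPA, IndenterSpec, IndentCurve


class InvalidGeometryError(ValueError):
    """Requested lattice geometry cannot be drawn (e.g. pitch <= strut width)."""


# ---------------------------------------------------------------------------
# Micrographs
# ---------------------------------------------------------------------------

@dataclass
class MicrographSpec:
    """Parameters of a synthetic stained-section raster.

    ``strut_pitch`` maps the scaffold's 0.9 mm pore spacing onto pixels; pores
    are the cells between struts.  ``pore_fill`` gives the bone fill fraction
    per generator region: the outermost ring of pore cells (``circumference``)
    and the remaining cells above/below the lattice midline (``superficial`` /
    ``deep``); an ``interior`` key is shorthand that sets both halves.  Colors
    are 8-bit HSV triplets (hue 0-179): defaults sit safely inside the
    scaffold gate, inside the bone gate, and in the blue soft-tissue range
    outside both.  ``noise_sd`` is additive Gaussian noise in HSV units.
    """

    width: int = 600
    height: int = 600
    strut_pitch: int = 45  # ~0.9 mm at 20 px/mm
    strut_width: int = 9
    pore_fill: dict = field(default_factory=lambda: {"interior": 0.4, "circumference": 0.4})
    scaffold_color: tuple[int, int, int] = (20, 30, 40)
    bone_color: tuple[int, int, int] = (165, 130, 130)
    tissue_color: tuple[int, int, int] = (110, 150, 200)
    noise_sd: float = 0.0
    margin: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strut_pitch <= self.strut_width:
            raise InvalidGeometryError("strut_pitch must exceed strut_width")
        fills = dict(self.pore_fill)
        if "interior" in fills:
            inner = fills.pop("interior")
            fills.setdefault("superficial", inner)
            fills.setdefault("deep", inner)
        fills.setdefault("superficial", 0.0)
        fills.setdefault("deep", 0.0)
        fills.setdefault("circumference", 0.0)
        unknown = set(fills) - {"superficial", "deep", "circumference"}
        if unknown:
            raise ValueError(f"unknown pore regions: {sorted(unknown)}")
        for name, frac in fills.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"pore fill fraction for {name} must lie in [0, 1]")
        self.pore_fill = fills
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not DEFAULT_SCAFFOLD_GATE.contains(np.asarray(self.scaffold_color)):
            raise ValueError("scaffold_color must sit inside the scaffold gate")
        if not DEFAULT_BONE_GATE.contains(np.asarray(self.bone_color)):
            raise ValueError("bone_color must sit inside the bone gate")
        tissue = np.asarray(self.tissue_color)
        if DEFAULT_SCAFFOLD_GATE.contains(tissue) or DEFAULT_BONE_GATE.contains(tissue):
            raise ValueError("tissue_color must sit outside both gates")


@dataclass
class MicrographTruth:
    """Ground truth recomputed from the emitted pixels."""

    fractions: dict  # region -> bone-gated fraction of pore pixels
    strut_mask: np.ndarray
    pore_mask: np.ndarray
    pore_region_masks: dict  # region -> boolean raster
    block_bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) inclusive-exclusive

    def as_json_dict(self) -> dict:
        return {
            "fractions": {k: float(v) for k, v in self.fractions.items()},
            "block_bbox": list(self.block_bbox),
            "n_pore_pixels": {k: int(m.sum()) for k, m in self.pore_region_masks.items()},
        }


def _lattice_masks(spec: MicrographSpec):
    """Strut mask, pore mask, and per-cell region assignment of the lattice."""
    n_cells_x = (spec.width - 2 * spec.margin - spec.strut_width) // spec.strut_pitch
    n_cells_y = (spec.height - 2 * spec.margin - spec.strut_width) // spec.strut_pitch
    if n_cells_x < 3 or n_cells_y < 3:
        raise InvalidGeometryError("image too small for a lattice of >= 3x3 pore cells")
    block_w = n_cells_x * spec.strut_pitch + spec.strut_width
    block_h = n_cells_y * spec.strut_pitch + spec.strut_width
    x0 = (spec.width - block_w) // 2
    y0 = (spec.height - block_h) // 2

    strut = np.zeros((spec.height, spec.width), dtype=bool)
    block = np.zeros_like(strut)
    block[y0 : y0 + block_h, x0 : x0 + block_w] = True
    for k in range(n_cells_x + 1):
        xs = x0 + k * spec.strut_pitch
        strut[y0 : y0 + block_h, xs : xs + spec.strut_width] = True
    for k in range(n_cells_y + 1):
        ys = y0 + k * spec.strut_pitch
        strut[ys : ys + spec.strut_width, x0 : x0 + block_w] = True

    pore = block & ~strut
    region_masks = {name: np.zeros_like(strut) for name in ("superficial", "deep", "circumference")}
    mid_y = y0 + block_h / 2.0
    for cy in range(n_cells_y):
        for cx in range(n_cells_x):
            px = x0 + cx * spec.strut_pitch + spec.strut_width
            py = y0 + cy * spec.strut_pitch + spec.strut_width
            cell = np.zeros_like(strut)
            cell[py : py + spec.strut_pitch - spec.strut_width, px : px + spec.strut_pitch - spec.strut_width] = True
            if cx in (0, n_cells_x - 1) or cy in (0, n_cells_y - 1):
                region = "circumference"
            elif py + (spec.strut_pitch - spec.strut_width) / 2.0 < mid_y:
                region = "superficial"
            else:
                region = "deep"
            region_masks[region] |= cell
    return strut, pore, region_masks, (x0, y0, x0 + block_w, y0 + block_h)


def generate_micrograph(spec: MicrographSpec) -> tuple[np.ndarray, MicrographTruth]:
    """Emit an RGB section raster plus ground truth from the emitted pixels.

    Exactly ``round(fraction * n_pore_pixels)`` pore pixels of each region are
    painted bone color (chosen by a seeded permutation), so the emitted
    fraction is within one pixel quantum of the request even before gating.
    Truth fractions are then recomputed by gating the emitted image, so 8-bit
    quantization and any HSV noise are already accounted for.
    """
    rng = np.random.default_rng(spec.seed)
    strut, pore, region_masks, bbox = _lattice_masks(spec)

    hsv = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    hsv[:] = spec.tissue_color
    hsv[strut] = spec.scaffold_color

    for name in ("superficial", "deep", "circumference"):
        mask = region_masks[name] & pore
        idx = np.flatnonzero(mask.ravel())
        n_fill = int(round(spec.pore_fill[name] * idx.size))
        chosen = rng.permutation(idx)[:n_fill]
        flat = hsv.reshape(-1, 3)
        flat[chosen] = spec.bone_color

    if spec.noise_sd > 0:
        hsv += rng.normal(0.0, spec.noise_sd, size=hsv.shape)
    hsv[..., 0] = np.clip(hsv[..., 0], 0, 179)
    hsv[..., 1:] = np.clip(hsv[..., 1:], 0, 255)
    image = hsv8_to_rgb(np.round(hsv).astype(np.uint8))

    labels = gate_pixels(image)
    fractions = {}
    for name, rmask in region_masks.items():
        pore_px = rmask & pore
        n = int(pore_px.sum())
        fractions[name] = float((pore_px & (labels == LABEL_BONE)).sum()) / n if n else float("nan")
    interior = (region_masks["superficial"] | region_masks["deep"]) & pore
    n_int = int(interior.sum())
    fractions["interior"] = float((interior & (labels == LABEL_BONE)).sum()) / n_int if n_int else float("nan")

    truth = MicrographTruth(
        fractions=fractions,
        strut_mask=strut,
        pore_mask=pore,
        pore_region_masks=region_masks,
        block_bbox=bbox,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Indentation curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadProfile:
    """Load-controlled indentation schedule (defaults: the standard profile)."""

    loading_rate: float = 60.0  # μN/s
    load_duration: float = 5.0  # s
    peak_load: float = 300.0  # μN
    hold_duration: float = 10.0  # s
    unload_duration: float = 2.0  # s
    sample_rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        for name in ("loading_rate", "load_duration", "peak_load", "hold_duration", "unload_duration", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(self.loading_rate * self.load_duration, self.peak_load, rel_tol=1e-9):
            raise ValueError("loading_rate x load_duration must equal peak_load")


DEFAULT_PROFILE = LoadProfile()


@dataclass
class MaterialTruth:
    """Ground-truth mechanical properties for simulated indents.

    ``m`` is the unloading power-law exponent.  The residual depth ``hf`` is
    not free: given the profile, indenter and (Er, H, m) it is fixed by the
    requirement that the Oliver–Pharr stiffness at peak depth matches the
    requested modulus; it is filled in by :func:`curve_ground_truth`.
    """

    Er_true: float  # GPa
    H_true: float  # GPa
    m: float = 1.5
    hf: float | None = None

    def __post_init__(self) -> None:
        if self.Er_true <= 0 or self.H_true <= 0:
            raise ValueError("true modulus and hardness must be positive")
        if not 1.0 <= self.m <= 2.0:
            raise ValueError("power-law exponent must lie in [1, 2]")


def curve_ground_truth(
    truth: MaterialTruth,
    profile: LoadProfile = DEFAULT_PROFILE,
    indenter: IndenterSpec = DEFAULT_INDENTER,
) -> dict:
    """Closed-form curve parameters consistent with (Er, H, m).

    Inverting the Oliver–Pharr relations at peak load, with the GPa inputs
    converted to the curve units of μN/nm² (1 μN/nm² = 1000 GPa)::

        A    = Pmax / H
        hc   = sqrt(A / C0)
        S    = Er * 2 * sqrt(A) / sqrt(pi)
        hmax = hc + epsilon * Pmax / S
        hf   = hmax - m * Pmax / S        (tangency: dP/dh at hmax equals S)
        alpha = Pmax / (hmax - hf)**m
    """
    Pmax = profile.peak_load
    A = Pmax / (truth.H_true / UN_PER_NM2_TO_GPA)
    hc = math.sqrt(A / indenter.C0)
    S = (truth.Er_true / UN_PER_NM2_TO_GPA) * 2.0 * math.sqrt(A) / math.sqrt(math.pi)
    hmax = hc + indenter.epsilon * Pmax / S
    hf = hmax - truth.m * Pmax / S
    if hf < 0:
        raise ValueError("inconsistent truth: residual depth would be negative")
    alpha = Pmax / (hmax - hf) ** truth.m
    return {"Pmax": Pmax, "A": A, "hc": hc, "S": S, "hmax": hmax, "hf": hf, "alpha": alpha, "m": truth.m}


def generate_indent_curve(
    truth: MaterialTruth,
    profile: LoadProfile = DEFAULT_PROFILE,
    indenter: IndenterSpec = DEFAULT_INDENTER,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IndentCurve:
    """Simulate one labeled load–displacement trace.

    Loading ramps at the profile rate with quadratic load–depth coupling
    (P ∝ h², the self-similarity law for a pyramidal indenter); the hold sits
    at peak load and depth (no creep model); unloading decreases the load
    linearly in time while the depth follows the inverse of the power law
    P = alpha (h - hf)^m.  Gaussian noise of ``noise_sd`` μN is added to the
    load channel only.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    gt = curve_ground_truth(truth, profile, indenter)
    dt = 1.0 / profile.sample_rate
    t_total = profile.load_duration + profile.hold_duration + profile.unload_duration
    time = np.arange(0.0, t_total + dt / 2.0, dt)

    t1 = profile.load_duration
    t2 = t1 + profile.hold_duration
    load = np.empty_like(time)
    depth = np.empty_like(time)
    Pmax, hmax, hf, alpha, m = gt["Pmax"], gt["hmax"], gt["hf"], gt["alpha"], gt["m"]
    segment = np.empty(time.size, dtype=object)

    loading = time < t1
    hold = (time >= t1) & (time <= t2)
    unloading = time > t2
    load[loading] = profile.loading_rate * time[loading]
    depth[loading] = hmax * np.sqrt(load[loading] / Pmax)
    load[hold] = Pmax
    depth[hold] = hmax
    frac = np.clip(1.0 - (time[unloading] - t2) / profile.unload_duration, 0.0, 1.0)
    load[unloading] = Pmax * frac
    depth[unloading] = hf + (load[unloading] / alpha) ** (1.0 / m)
    segment[loading] = "loading"
    segment[hold] = "hold"
    segment[unloading] = "unloading"

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        load = load + rng.normal(0.0, noise_sd, size=load.shape)

    return IndentCurve(time=time, load=load, depth=depth, segment=segment)


# ---------------------------------------------------------------------------
# Interfaces, volumes, cohorts
# ---------------------------------------------------------------------------

def generate_interface(arc_spec, radius_mm: float = 25.0) -> InterfaceModel:
    """Interface ring with contact = 1 on the given (start°, end°) arcs.

    Arcs must be disjoint and lie within [0°, 360°]; the total bridged
    fraction is the summed arc length over 360°.
    """
    return InterfaceModel(tuple((float(a), float(b)) for a, b in arc_spec), radius_mm=radius_mm)


def sphere_inclusion(center_mm, radius_mm: float, hu: float) -> dict:
    return {"kind": "sphere", "center_mm": tuple(float(c) for c in center_mm), "radius_mm": float(radius_mm), "hu": float(hu)}


def box_inclusion(lo_vox, hi_vox, hu: float) -> dict:
    return {"kind": "box", "lo_vox": tuple(int(v) for v in lo_vox), "hi_vox": tuple(int(v) for v in hi_vox), "hu": float(hu)}


def generate_hu_volume(
    shape,
    spacing,
    inclusions=(),
    background_hu: float = 40.0,
) -> tuple[CTVolume, list[dict]]:
    """Hounsfield volume with rasterized inclusions and analytic truth volumes.

    The background (soft-tissue-like, 40 HU by default) sits below the bone
    threshold.  Spheres are defined in mm and rasterized by voxel-center
    distance; boxes by integer voxel extents.  Each returned truth record
    carries the analytic volume in mm³ and the inclusion's HU.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    vox = np.full(shape, background_hu, dtype=np.float64)
    centers = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    truth = []
    for inc in inclusions:
        if inc["kind"] == "sphere":
            cx, cy, cz = inc["center_mm"]
            r = inc["radius_mm"]
            dx2 = (centers[0] - cx) ** 2
            dy2 = (centers[1] - cy) ** 2
            dz2 = (centers[2] - cz) ** 2
            mask = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :] <= r**2
            analytic = 4.0 / 3.0 * math.pi * r**3
        elif inc["kind"] == "box":
            lo, hi = inc["lo_vox"], inc["hi_vox"]
            mask = np.zeros(shape, dtype=bool)
            mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
            analytic = float(mask.sum()) * float(np.prod(spacing))
        else:
            raise ValueError(f"unknown inclusion kind {inc['kind']!r}")
        vox[mask] = inc["hu"]
        truth.append({"kind": inc["kind"], "hu": inc["hu"], "volume_mm3": analytic, "voxels": int(mask.sum())})
    return CTVolume(vox, spacing), truth


def generate_cohort(groups, seed: int = 0) -> pd.DataFrame:
    """Per-subject table from (label, mean, sd, n) group specifications.

    Values are drawn from normal distributions; the table has columns
    ``subject``, ``group``, ``value`` and is deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n in groups:
        if sd < 0:
            raise ValueError("sd must be non-negative")
        if n < 2:
            raise ValueError("each group needs n >= 2")
        values = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        for i, v in enumerate(values, start=1):
            rows.append({"subject": f"{label}{i}", "group": label, "value": float(v)})
    return pd.DataFrame(rows)
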