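"""Oliver–Pharr analysis of nanoindentation load–displacement curves.

A Berkovich diamond probe is driven into the specimen under load control, held
at peak load, and withdrawn.  The unloading branch is fitted with the power law

    P = alpha * (h - hf)**m

on the upper part of the unloading range; the contact stiffness S = dP/dh at
maximum depth then yields the contact depth, reduced modulus, hardness, and —
through the compliance relation with the indenter constants — the elastic
modulus of the bone itself:

    hc  = hmax - epsilon * Pmax / S
    A   = C0 * hc**2                       (ideal Berkovich: C0 = 24.5)
    Er  = (sqrt(pi) / 2) * S / sqrt(A)
    H   = Pmax / A
    Eb  = (1 - vb**2) * Ei * Er / (Ei - (1 - vi**2) * Er)

Units are fixed internally to μN for load, nm for depth and nm² for area;
stresses therefore come out in μN/nm² = 10¹² Pa, and moduli and hardness are
converted to GPa with the factor 1 μN/nm² = 1000 GPa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

UN_PER_NM2_TO_GPA = 1.0e3  # 1 μN/nm² = 1e-6 N / 1e-18 m² = 1e12 Pa = 1000 GPa


class MalformedCurveError(ValueError):
    """The load trace does not show the ramp/hold/unload structure."""


class FitError(RuntimeError):
    """The unloading power-law fit did not converge."""


class NonphysicalInputError(ValueError):
    """Reduced modulus at or above the indenter compliance limit."""


@dataclass(frozen=True)
class IndenterSpec:
    """Probe constants entering the Oliver–Pharr relations.

    Defaults describe a diamond Berkovich tip: Ei = 1140 GPa, vi = 0.07,
    ideal area constant C0 = 24.5, contact-depth intercept epsilon = 0.75.
    A calibrated area polynomial A(hc) = sum(c_k * hc**(2 - k)) may replace
    the ideal area via ``area_coeffs``.
    """

    Ei: float = 1140.0  # GPa
    vi: float = 0.07
    C0: float = 24.5
    epsilon: float = 0.75
    area_coeffs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.Ei <= 0:
            raise ValueError("indenter modulus must be positive")
        if not 0 <= self.vi < 0.5:
            raise ValueError("indenter Poisson ratio must lie in [0, 0.5)")
        if self.C0 <= 0:
            raise ValueError("area constant C0 must be positive")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


DEFAULT_INDENTER = IndenterSpec()

SEGMENT_LOADING = "loading"
SEGMENT_HOLD = "hold"
SEGMENT_UNLOADING = "unloading"


@dataclass
class IndentCurve:
    """A load–displacement trace: time (s), load (μN), depth (nm)."""

    time: np.ndarray
    load: np.ndarray
    depth: np.ndarray
    segment: np.ndarray | None = None  # per-sample labels, filled by segment_curve

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.time.size
        if self.load.size != n or self.depth.size != n:
            raise ValueError("time, load and depth must have equal length")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.segment is not None:
            self.segment = np.asarray(self.segment)
            if self.segment.size != n:
                raise ValueError("segment labels must match the trace length")

    def to_frame(self) -> pd.DataFrame:
        seg = self.segment if self.segment is not None else np.full(self.time.size, "", dtype=object)
        return pd.DataFrame(
            {"time_s": self.time, "load_uN": self.load, "depth_nm": self.depth, "segment": seg}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndentCurve":
        df = pd.read_csv(path)
        required = {"time_s", "load_uN", "depth_nm"}
        if not required.issubset(df.columns):
            raise ValueError(f"curve CSV {path} missing columns {sorted(required - set(df.columns))}")
        seg = df["segment"].to_numpy() if "segment" in df.columns else None
        if seg is not None and pd.isna(seg).all():
            seg = None
        return cls(
            time=df["time_s"].to_numpy(),
            load=df["load_uN"].to_numpy(),
            depth=df["depth_nm"].to_numpy(),
            segment=seg,
        )


@dataclass
class IndentationResult:
    """Derived Oliver–Pharr quantities for a single indent."""

    S: float  # μN/nm
    hc: float  # nm
    Pmax: float  # μN
    hmax: float  # nm
    A: float  # nm²
    Er: float  # GPa
    H: float  # GPa
    Eb: float  # GPa
    vb: float
    hf: float  # nm, fitted residual depth
    m: float  # fitted power-law exponent


def _plateau_run(flags: np.ndarray, anchor: int) -> tuple[int, int]:
    """Bounds of the contiguous True run containing ``anchor``."""
    start = anchor
    while start > 0 and flags[start - 1]:
        start -= 1
    end = anchor
    while end < flags.size - 1 and flags[end + 1]:
        end += 1
    return start, end


def segment_curve(curve: IndentCurve, rel_tol: float = 0.02, noise_mult: float = 5.0) -> IndentCurve:
    """Label samples as loading / hold / unloading from the load trajectory.

    The hold is detected in two passes: a coarse run of samples within
    ``rel_tol`` of the peak anchors a robust (MAD-based) estimate of the load
    noise; the plateau is then the contiguous run around the maximum whose
    load stays within ``noise_mult`` noise standard deviations of the plateau
    median, so a clean curve is segmented at sample resolution while a noisy
    one keeps its full hold.  Everything before is loading, everything after
    unloading.  A plateau shorter than three samples, or one running into the
    end of the trace (a monotone ramp), raises :class:`MalformedCurveError`.
    """
    if curve.time.size < 50:
        raise MalformedCurveError("need at least 50 samples to segment a curve")
    load = curve.load
    pmax = float(load.max())
    ipeak = int(np.argmax(load))
    coarse = load >= (1.0 - rel_tol) * pmax
    c0, c1 = _plateau_run(coarse, ipeak)
    run = load[c0 : c1 + 1]
    center = float(np.median(run))
    sigma = float(np.median(np.abs(run - center))) / 0.6745
    threshold = center - max(noise_mult * sigma, 1e-6 * pmax)
    near_peak = load >= threshold
    start, end = _plateau_run(near_peak, ipeak)
    if end - start + 1 < 3 or end >= load.size - 1:
        raise MalformedCurveError("no hold plateau found in the load trace")
    labels = np.empty(load.size, dtype=object)
    labels[:start] = SEGMENT_LOADING
    labels[start : end + 1] = SEGMENT_HOLD
    labels[end + 1 :] = SEGMENT_UNLOADING
    return IndentCurve(curve.time, curve.load, curve.depth, segment=labels)


def _unloading_mask(curve: IndentCurve) -> np.ndarray:
    """Unloading samples plus the final hold sample (the peak-depth point),
    which by convention belongs to the unloading branch."""
    mask = curve.segment == SEGMENT_UNLOADING
    idx = np.flatnonzero(mask)
    if idx.size and idx[0] > 0:
        mask = mask.copy()
        mask[idx[0] - 1] = True
    return mask


def fit_unloading(
    curve: IndentCurve, fit_range: tuple[float, float] = (0.95, 0.20)
) -> tuple[float, float, float, float]:
    """Fit P = alpha (h - hf)^m to the upper unloading branch.

    ``fit_range`` gives the load window as fractions of the unloading load
    range (default: from 95% down to 20%).  Returns ``(S, hf, m, alpha)``
    where S = dP/dh evaluated at the maximum unloading depth.
    """
    if curve.segment is None:
        curve = segment_curve(curve)
    mask = _unloading_mask(curve)
    if mask.sum() < 10:
        raise MalformedCurveError("unloading segment has fewer than 10 samples")
    h = curve.depth[mask]
    p = curve.load[mask]
    hi, lo = fit_range
    p0, p1 = float(p.min()), float(p.max())
    window = (p >= p0 + lo * (p1 - p0)) & (p <= p0 + hi * (p1 - p0))
    if window.sum() < 5:
        raise FitError("fewer than 5 samples inside the unloading fit window")
    hw, pw = h[window], p[window]
    hmax = float(h.max())
    hf0 = float(h.min())  # unloading ends near the residual depth

    def model(hh, alpha, hf, m):
        return alpha * np.clip(hh - hf, 1e-12, None) ** m

    alpha0 = p1 / max(hmax - hf0, 1e-9) ** 1.5
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                hw,
                pw,
                p0=(alpha0, hf0 * 0.9, 1.5),
                bounds=([1e-12, -np.inf, 1.0], [np.inf, hw.min() - 1e-9, 3.0]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(f"unloading power-law fit failed: {exc}") from exc
    alpha, hf, m = (float(v) for v in popt)
    S = alpha * m * (hmax - hf) ** (m - 1.0)
    return S, hf, m, alpha


def contact_area(hc: float, spec: IndenterSpec = DEFAULT_INDENTER) -> float:
    """Projected contact area A(hc) in nm² (ideal C0·hc² unless calibrated)."""
    if hc <= 0:
        raise ValueError("contact depth must be positive")
    if spec.area_coeffs is not None:
        # calibrated polynomial: c0*hc^2 + c1*hc + c2*hc^(1/2) + c3*hc^(1/4) + ...
        exps = [2.0] + [2.0 ** (1 - k) for k in range(1, len(spec.area_coeffs))]
        return float(sum(c * hc**e for c, e in zip(spec.area_coeffs, exps)))
    return spec.C0 * hc**2


def reduced_modulus(S: float, A: float) -> float:
    """Reduced elastic modulus Er = (sqrt(pi)/2) * S / sqrt(A), in GPa."""
    if S <= 0 or A <= 0:
        raise ValueError("stiffness and area must be positive")
    return (math.sqrt(math.pi) / 2.0) * S / math.sqrt(A) * UN_PER_NM2_TO_GPA


def hardness(Pmax: float, A: float) -> float:
    """Indentation hardness H = Pmax / A(hc), in GPa."""
    if Pmax <= 0 or A <= 0:
        raise ValueError("peak load and area must be positive")
    return Pmax / A * UN_PER_NM2_TO_GPA


def bone_modulus(Er: float, vb: float = 0.3, spec: IndenterSpec = DEFAULT_INDENTER) -> float:
    """Specimen modulus from the reduced modulus via the compliance relation.

    1/Er = (1 - vb²)/Eb + (1 - vi²)/Ei, solved for Eb.  Er must stay below the
    indenter limit Ei / (1 - vi²), else the specimen compliance would be
    negative.
    """
    if not 0 <= vb < 0.5:
        raise ValueError("bone Poisson ratio must lie in [0, 0.5)")
    limit = spec.Ei / (1.0 - spec.vi**2)
    if Er >= limit:
        raise NonphysicalInputError(f"Er = {Er:.3f} GPa exceeds the indenter limit {limit:.3f} GPa")
    return (1.0 - vb**2) * Er * spec.Ei / (spec.Ei - (1.0 - spec.vi**2) * Er)


def reduced_from_bone(Eb: float, vb: float = 0.3, spec: IndenterSpec = DEFAULT_INDENTER) -> float:
    """Forward compliance relation: Er from a specimen modulus (inverse of
    :func:`bone_modulus`)."""
    return 1.0 / ((1.0 - vb**2) / Eb + (1.0 - spec.vi**2) / spec.Ei)


def analyze_curve(
    curve: IndentCurve,
    spec: IndenterSpec = DEFAULT_INDENTER,
    vb: float = 0.3,
    fit_range: tuple[float, float] = (0.95, 0.20),
) -> IndentationResult:
    """Full per-indent pipeline: segment, fit unloading, evaluate Er/H/Eb."""
    if curve.segment is None:
        curve = segment_curve(curve)
    S, hf, m, _alpha = fit_unloading(curve, fit_range=fit_range)
    Pmax = float(curve.load.max())
    unl = _unloading_mask(curve)
    hmax = float(curve.depth[unl].max())
    hc = hmax - spec.epsilon * Pmax / S
    if hc <= 0:
        raise FitError("non-positive contact depth; unloading fit unreliable")
    A = contact_area(hc, spec)
    Er = reduced_modulus(S, A)
    H = hardness(Pmax, A)
    if H > Er:
        warnings.warn("hardness exceeds reduced modulus — implausible for bone-like material", stacklevel=2)
    Eb = bone_modulus(Er, vb=vb, spec=spec)
    return IndentationResult(S=S, hc=hc, Pmax=Pmax, hmax=hmax, A=A, Er=Er, H=H, Eb=Eb, vb=vb, hf=hf, m=m)


def aggregate_indents(results: list[IndentationResult]) -> dict:
    """Specimen summary over an indent grid: n, mean and SD of Er, Eb, H."""
    if len(results) < 2:
        raise ValueError("aggregation requires at least 2 indents")
    out = {"n": len(results)}
    for name in ("Er", "Eb", "H"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1))
    return out


def analyze_directory(
    curves_dir,
    spec: IndenterSpec = DEFAULT_INDENTER,
    vb: float = 0.3,
) -> pd.DataFrame:
    """Analyze every ``*.csv`` curve in a directory into a tidy results table."""
    rows = []
    for path in sorted(Path(curves_dir).glob("*.csv")):
        res = analyze_curve(IndentCurve.from_csv(path), spec=spec, vb=vb)
        rows.append(
            {
                "specimen": path.stem.rsplit("_", 1)[0],
                "indent_id": path.stem,
                "S_uN_per_nm": res.S,
                "hc_nm": res.hc,
                "A_nm2": res.A,
                "Er_GPa": res.Er,
                "H_GPa": res.H,
                "Eb_GPa": res.Eb,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no curve CSV files found in {curves_dir}")
    return pd.DataFrame(rows)
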