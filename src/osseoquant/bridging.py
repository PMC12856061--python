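"""Clock-face scoring of implant–bone bridging and inter-rater reliability.

The perimeter of a circular cranial implant is modelled as an angular contact
function: a set of disjoint arcs (in degrees) where continuous bone bridges
the implant–skull interface.  Scoring divides the perimeter into equal angular
segments — 12 for the longitudinal "clock face" protocol, 8 for the
high-resolution postmortem protocol — and reports the bridged fraction of each
segment as a percent, plus their unweighted mean as the overall score.
Segment 0 starts at 0° (anterior) and segments proceed clockwise; the anchor
is a convention and can be shifted by rotating the model.

Rater agreement is summarised with the intraclass correlation coefficient
ICC(2,1): two-way random effects, absolute agreement, single rater.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class InterfaceModel:
    """Angular contact function around the implant perimeter.

    ``arcs`` is a sorted tuple of (start, end) pairs in degrees, each within
    [0, 360], disjoint, with start < end; contact is 1 on the arcs and 0
    elsewhere.  ``radius_mm`` is the nominal implant radius (25 mm for the
    5-cm implant) and is metadata only — all scoring is angular.
    """

    arcs: tuple[tuple[float, float], ...]
    radius_mm: float = 25.0

    def __post_init__(self) -> None:
        arcs = tuple(sorted((float(a), float(b)) for a, b in self.arcs))
        for a, b in arcs:
            if not (0.0 <= a < b <= 360.0):
                raise ValueError(f"arc ({a}, {b}) must satisfy 0 <= start < end <= 360")
        for (a0, b0), (a1, b1) in zip(arcs, arcs[1:]):
            if a1 < b0:
                raise ValueError(f"arcs ({a0}, {b0}) and ({a1}, {b1}) overlap")
        object.__setattr__(self, "arcs", arcs)

    @property
    def bridged_fraction(self) -> float:
        return sum(b - a for a, b in self.arcs) / 360.0

    def rotate(self, offset_deg: float) -> "InterfaceModel":
        """Rotate the contact function by ``offset_deg``, splitting arcs that
        cross the 0°/360° seam."""
        pieces = []
        for a, b in self.arcs:
            a, b = (a + offset_deg) % 360.0, a + offset_deg + (b - a)
            if b <= 360.0 or np.isclose(b, 360.0):
                pieces.append((a, min(b, 360.0)))
            else:
                pieces.append((a, 360.0))
                pieces.append((0.0, b - 360.0))
        # merge a piece ending at 360 with one starting at 0 if contiguous
        return InterfaceModel(tuple(pieces), radius_mm=self.radius_mm)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"arcs": list(self.arcs), "radius_mm": self.radius_mm}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "InterfaceModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(tuple(tuple(a) for a in obj["arcs"]), radius_mm=obj.get("radius_mm", 25.0))


@dataclass
class BridgingScore:
    """Per-segment and overall percent bridging for one rater (or the mean)."""

    per_segment: list[float]
    n_segments: int
    overall: float = field(init=False)
    rater_id: str = "auto"

    def __post_init__(self) -> None:
        if len(self.per_segment) != self.n_segments:
            raise ValueError("per_segment length must equal n_segments")
        self.per_segment = [float(v) for v in self.per_segment]
        self.overall = float(np.mean(self.per_segment))


def score_interface(model: InterfaceModel, n_segments: int = 12, rater_id: str = "auto") -> BridgingScore:
    """Score percent bridging per equal angular segment.

    Segment k spans [k·360/n, (k+1)·360/n); its score is the bridged arc
    length inside the segment divided by the segment span, in percent.  The
    overall score is the unweighted mean, which equals the total bridged
    fraction of the perimeter for any n.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    span = 360.0 / n_segments
    per_segment = []
    for k in range(n_segments):
        s0, s1 = k * span, (k + 1) * span
        covered = sum(max(0.0, min(b, s1) - max(a, s0)) for a, b in model.arcs)
        per_segment.append(100.0 * covered / span)
    return BridgingScore(per_segment=per_segment, n_segments=n_segments, rater_id=rater_id)


def average_raters(scores: list[BridgingScore]) -> BridgingScore:
    """Element-wise mean of several raters' segment scores."""
    if not scores:
        raise ValueError("need at least one score")
    n = scores[0].n_segments
    if any(s.n_segments != n for s in scores):
        raise ValueError("all raters must use the same number of segments")
    stacked = np.array([s.per_segment for s in scores], dtype=float)
    return BridgingScore(per_segment=stacked.mean(axis=0).tolist(), n_segments=n, rater_id="mean")


def icc(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects × k raters) matrix with no missing cells.
    From the two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE))

    Returns NaN with a warning when the matrix has no variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n>=2 subjects) x (k>=2 raters) matrix")
    if np.isnan(x).any():
        raise ValueError("ratings matrix contains missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        warnings.warn("ratings matrix has zero total variance; ICC undefined", stacklevel=2)
        return float("nan")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def icc_from_table(df, subject_col: str = "subject", rater_col: str = "rater", value_col: str = "score") -> float:
    """ICC(2,1) from a long-format table of (subject, rater, score) rows."""
    wide = df.pivot(index=subject_col, columns=rater_col, values=value_col)
    if wide.isna().any().any():
        raise ValueError("every subject must be scored by every rater")
    return icc(wide.to_numpy())
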