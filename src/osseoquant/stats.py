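"""Statistical battery for small-cohort group comparisons, plus a driver that
regenerates every derivable number from the study's per-subject tables.

The battery mirrors common practice for n-of-3 animal cohorts: Shapiro–Wilk
normality screening (advisory only — it never switches the test branch
automatically), one-way ANOVA with Tukey HSD post hoc for normal data,
pooled-variance unpaired t-tests with optional Bonferroni correction for
pairwise contrasts, and Mann–Whitney U / Kruskal–Wallis with Dunn's post hoc
for non-normal data.  Omnibus and rank tests delegate to scipy; Dunn's z-tests
are computed here from the pooled mid-ranks with tie correction.

Fixture tables shipped with the package hold the printed per-subject values of
the cranioplasty study (micro-CT bridging and explant volumes; regional
histomorphometry; longitudinal bridging) so that every group mean, ANOVA p and
pairwise t-test in those tables can be recomputed and checked side by side
with the printed numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: tuple | float | None
    p: float
    method: str
    adjusted: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _groups_from_table(table: pd.DataFrame, group_col="group", value_col="value") -> list[np.ndarray]:
    clean = table.dropna(subset=[value_col])
    return [g[value_col].to_numpy(dtype=float) for _, g in clean.groupby(group_col, sort=True)]


def shapiro_wilk(sample) -> TestResult:
    """Shapiro–Wilk normality test for 3 <= n <= 50 observations.

    A constant sample has no distributional shape to assess; it is reported
    as NaN/NaN with a warning rather than an arbitrary decision.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 50:
        raise ValueError("Shapiro–Wilk here supports 3 <= n <= 50")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: Shapiro–Wilk undefined", stacklevel=2)
        return TestResult(float("nan"), None, float("nan"), "shapiro-wilk")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), None, float(res.pvalue), "shapiro-wilk")


def one_way_anova(table: pd.DataFrame, group_col="group", value_col="value") -> TestResult:
    """One-way fixed-effects ANOVA on a long-format (group, value) table.

    Missing values are dropped, so unbalanced designs (a subject unmeasured at
    one timepoint) are handled with unequal n.  Degenerate inputs: equal group
    means with zero within-group variance give F = 0, p = 1; distinct means
    with zero within-group variance give F = inf, p = 0.
    """
    groups = _groups_from_table(table, group_col, value_col)
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("ANOVA needs >= 2 non-empty groups")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    df = (k - 1, n_total - k)
    if df[1] < 1:
        raise ValueError("no within-group degrees of freedom")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    if ssw == 0:
        if ssb == 0:
            return TestResult(0.0, df, 1.0, "one-way ANOVA")
        return TestResult(float("inf"), df, 0.0, "one-way ANOVA")
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), df, float(res.pvalue), "one-way ANOVA")


def tukey_hsd(table: pd.DataFrame, group_col="group", value_col="value") -> dict:
    """Tukey HSD family-wise pairwise comparisons after a one-way ANOVA."""
    clean = table.dropna(subset=[value_col])
    labels = sorted(clean[group_col].unique())
    groups = [clean.loc[clean[group_col] == lab, value_col].to_numpy(dtype=float) for lab in labels]
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    if np.ptp(np.concatenate(groups)) == 0:
        # all values identical: no pair differs
        return {(a, b): TestResult(0.0, None, 1.0, "tukey-hsd") for a, b in combinations(labels, 2)}
    res = sps.tukey_hsd(*groups)
    out = {}
    for i, j in combinations(range(len(labels)), 2):
        out[(labels[i], labels[j])] = TestResult(
            float(res.statistic[i, j]), None, float(res.pvalue[i, j]), "tukey-hsd", adjusted=True
        )
    return out


def pooled_t_test(a, b) -> TestResult:
    """Two-sided unpaired Student's t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, a.size + b.size - 2, 1.0, "pooled t")
        return TestResult(float("inf"), a.size + b.size - 2, 0.0, "pooled t")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "pooled t")


def bonferroni(result: TestResult, k: int) -> TestResult:
    """Bonferroni adjustment: multiply p by the number of comparisons, cap at 1."""
    if k < 1:
        raise ValueError("number of comparisons must be >= 1")
    return TestResult(result.statistic, result.df, min(1.0, result.p * k), result.method + " + bonferroni", adjusted=True)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test (exact when samples are small and tie-free)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(a.size * b.size / 2.0, None, 1.0, "mann-whitney U")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), None, float(res.pvalue), "mann-whitney U")


def kruskal_wallis(table: pd.DataFrame, group_col="group", value_col="value") -> TestResult:
    """Kruskal–Wallis rank test across >= 2 groups, with tie correction."""
    groups = _groups_from_table(table, group_col, value_col)
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("Kruskal–Wallis needs >= 2 non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return TestResult(0.0, len(groups) - 1, 1.0, "kruskal-wallis")
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), len(groups) - 1, float(res.pvalue), "kruskal-wallis")


def dunn_posthoc(table: pd.DataFrame, group_col="group", value_col="value", adjust: str = "bonferroni") -> dict:
    """Dunn's pairwise z-tests on pooled mid-ranks after Kruskal–Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )
    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.  Two-sided
    normal p-values, Bonferroni-adjusted across all pairs by default
    (``adjust="none"`` disables).
    """
    clean = table.dropna(subset=[value_col])
    labels = sorted(clean[group_col].unique())
    values = clean[value_col].to_numpy(dtype=float)
    if len(labels) < 2:
        raise ValueError("Dunn post hoc needs >= 2 groups")
    ranks = sps.rankdata(values)
    n_total = values.size
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    for lab in labels:
        sel = (clean[group_col] == lab).to_numpy()
        mean_ranks[lab] = ranks[sel].mean()
        sizes[lab] = int(sel.sum())
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = {}
    for a, b in combinations(labels, 2):
        if var_base <= 0:  # every value tied
            out[(a, b)] = TestResult(0.0, None, 1.0, "dunn", adjusted=adjust != "none")
            continue
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        elif adjust != "none":
            raise ValueError(f"unknown adjustment {adjust!r}")
        out[(a, b)] = TestResult(float(z), None, float(p), "dunn", adjusted=adjust != "none")
    return out


# ---------------------------------------------------------------------------
# Table reproduction driver
# ---------------------------------------------------------------------------

#: Printed values from the study's tables and narrative, used only for the
#: side-by-side comparison the driver emits.
PRINTED = {
    "microct_bridging_mean_pct": {"BMP": 90, "DIPY": 9, "NS": 10},
    "volume_mean_mm3": {"BMP": 7621, "DIPY": 6466, "NS": 6348},
    "volume_sd_mm3": {"BMP": 145, "DIPY": 693, "NS": 663},
    "histology_interior_mean_pct": {"BMP": 65, "DIPY": 39, "NS": 27},
    "histology_superficial_mean_pct": {"BMP": 48, "DIPY": 11, "NS": 3},
    "histology_deep_mean_pct": {"BMP": 66, "DIPY": 28, "NS": 25},
    "anova_p": {
        "volume": 0.036,
        "microct_bridging": 0.001,  # printed as "< 0.001"
        "histology_interior": 0.226,
        "histology_superficial": 0.114,
        "histology_deep": 0.120,
        "bridging_2mo": 0.073,
        "bridging_4mo": 0.158,
        "bridging_6mo": 0.450,
        "bridging_8mo": 0.414,
        "bridging_10mo": 0.404,
        "bridging_12mo": 0.462,
    },
    "ttest_p": {("BMP", "NS"): 0.02, ("BMP", "DIPY"): 0.03},
}


def fixtures_dir() -> Path:
    """Directory of the packaged per-subject fixture tables."""
    return Path(resources.files("osseoquant") / "data")


def load_fixture(name: str, tables_dir=None) -> pd.DataFrame:
    base = Path(tables_dir) if tables_dir is not None else fixtures_dir()
    path = base / name
    if not path.exists():
        raise FileNotFoundError(f"fixture table not found: {path}")
    return pd.read_csv(path)


def _check(computed: float, printed: float, decimals: int, less_than: bool = False) -> dict:
    if less_than:
        ok = computed < printed
    else:
        ok = round(float(computed), decimals) == round(float(printed), decimals)
    return {"computed": float(computed), "printed": float(printed), "match": bool(ok)}


def reproduce_tables(tables_dir=None) -> dict:
    """Recompute every derivable statistic of the study tables.

    Reads the per-subject fixture CSVs (micro-CT bridging + explant volumes,
    regional histomorphometry, longitudinal bridging), recomputes group means,
    omnibus ANOVA p-values, and the pairwise volume t-tests, and compares each
    against the printed value at its printed rounding.  Cells where the
    printed value cannot be recovered at that rounding are flagged
    (``match: False``) rather than forced; unrounded values are always
    reported.
    """
    bridging = load_fixture("table2_bridging.csv", tables_dir)
    volumes = load_fixture("table2_volumes.csv", tables_dir)
    histo = load_fixture("table3_histology.csv", tables_dir)
    for df, cols in ((bridging, {"subject", "group", "timepoint", "value"}),
                     (volumes, {"subject", "group", "volume_mm3"}),
                     (histo, {"subject", "group", "interior_pct", "superficial_pct", "deep_pct"})):
        if not cols.issubset(df.columns):
            raise ValueError(f"fixture missing columns {sorted(cols - set(df.columns))}")

    report: dict = {"group_means": {}, "anova": {}, "ttests": {}, "sd": {}}

    # --- micro-CT bridging ---
    micro = bridging[bridging["timepoint"] == "microct"]
    means = micro.groupby("group")["value"].mean()
    report["group_means"]["microct_bridging_pct"] = {
        g: _check(means[g], PRINTED["microct_bridging_mean_pct"][g], 0) for g in means.index
    }
    res = one_way_anova(micro)
    report["anova"]["microct_bridging"] = {
        "computed": res.p,
        "printed": "< 0.001",
        "match": res.p < PRINTED["anova_p"]["microct_bridging"],
    }

    # --- explant volumes ---
    vmeans = volumes.groupby("group")["volume_mm3"].mean()
    vsds = volumes.groupby("group")["volume_mm3"].std(ddof=1)
    report["group_means"]["volume_mm3"] = {
        g: _check(vmeans[g], PRINTED["volume_mean_mm3"][g], 0) for g in vmeans.index
    }
    report["sd"]["volume_mm3"] = {
        g: _check(vsds[g], PRINTED["volume_sd_mm3"][g], 0) for g in vsds.index
    }
    vres = one_way_anova(volumes.rename(columns={"volume_mm3": "value"}))
    report["anova"]["volume"] = _check(vres.p, PRINTED["anova_p"]["volume"], 3)
    for a, b in PRINTED["ttest_p"]:
        t = pooled_t_test(
            volumes.loc[volumes["group"] == a, "volume_mm3"],
            volumes.loc[volumes["group"] == b, "volume_mm3"],
        )
        report["ttests"][f"{a}_vs_{b}"] = _check(t.p, PRINTED["ttest_p"][(a, b)], 2)

    # --- longitudinal bridging ANOVA per timepoint ---
    for months in (2, 4, 6, 8, 10, 12):
        sub = bridging[bridging["timepoint"] == str(months)]
        res = one_way_anova(sub)
        report["anova"][f"bridging_{months}mo"] = _check(res.p, PRINTED["anova_p"][f"bridging_{months}mo"], 3)

    # --- regional histomorphometry ---
    for col, key in (("interior_pct", "interior"), ("superficial_pct", "superficial"), ("deep_pct", "deep")):
        hmeans = histo.groupby("group")[col].mean()
        report["group_means"][f"histology_{key}_pct"] = {
            g: _check(hmeans[g], PRINTED[f"histology_{key}_mean_pct"][g], 0) for g in hmeans.index
        }
        res = one_way_anova(histo.rename(columns={col: "value"}))
        report["anova"][f"histology_{key}"] = _check(res.p, PRINTED["anova_p"][f"histology_{key}"], 3)

    return report


def report_to_markdown(report: dict) -> str:
    """Render the reproduction report as a readable markdown table set."""
    lines = ["# Table reproduction report", ""]
    lines += ["## Group means", "", "| quantity | group | computed | printed | match |", "|---|---|---|---|---|"]
    for qty, groups in report["group_means"].items():
        for g, cell in groups.items():
            lines.append(f"| {qty} | {g} | {cell['computed']:.2f} | {cell['printed']:.0f} | {'yes' if cell['match'] else 'NO'} |")
    lines += ["", "## Group SDs", "", "| quantity | group | computed | printed | match |", "|---|---|---|---|---|"]
    for qty, groups in report["sd"].items():
        for g, cell in groups.items():
            lines.append(f"| {qty} | {g} | {cell['computed']:.1f} | {cell['printed']:.0f} | {'yes' if cell['match'] else 'NO'} |")
    lines += ["", "## Omnibus ANOVA p-values", "", "| comparison | computed | printed | match |", "|---|---|---|---|"]
    for qty, cell in report["anova"].items():
        lines.append(f"| {qty} | {cell['computed']:.4f} | {cell['printed']} | {'yes' if cell['match'] else 'NO'} |")
    lines += ["", "## Pairwise volume t-tests", "", "| pair | computed | printed | match |", "|---|---|---|---|"]
    for qty, cell in report["ttests"].items():
        lines.append(f"| {qty} | {cell['computed']:.4f} | {cell['printed']} | {'yes' if cell['match'] else 'NO'} |")
    lines.append("")
    return "\n".join(lines)
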