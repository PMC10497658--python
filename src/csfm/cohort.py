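"""Cohort-level statistics: group comparisons, ILI-displacement regression,
displacement-cutoff subsets, and symptom contrasts.

The cohort is a tidy table with one row per subject:

    id, group ('CMI' | 'control'), ili_dyn_cm5,
    disp_cerebellum_um, disp_brainstem_um,
    imbalance, vertigo, swallowing, nausea_vomiting, hoarseness (0/1, optional),
    mpq, diq (optional scores)

Tests follow common clinical-biomechanics practice: Welch's unequal-variance
t-test for group contrasts, Pearson correlation with OLS regression (slope,
intercept, 95% CIs) for the ILI-displacement relationship, Shapiro-Wilk for
normality.  All p-values are two-sided and uncorrected by default; an
optional Bonferroni correction is available for the symptom table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CohortError",
    "WelchResult",
    "RegressionResult",
    "welch_t_test",
    "pearson_regression",
    "shapiro_wilk",
    "cutoff_subset_analysis",
    "symptom_comparison",
    "group_summary",
    "analyze_cohort",
    "MEASURES",
    "SYMPTOMS",
]

MEASURES = ("ili_dyn_cm5", "disp_cerebellum_um", "disp_brainstem_um")
SYMPTOMS = ("imbalance", "vertigo", "swallowing", "nausea_vomiting", "hoarseness")


class CohortError(ValueError):
    """Raised for invalid cohort tables or degenerate statistical inputs."""


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    pvalue: float
    df: float


@dataclass(frozen=True)
class RegressionResult:
    r: float
    pvalue: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int


def welch_t_test(group_a, group_b) -> WelchResult:
    """Unpaired t-test with unequal variances (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CohortError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variation
        if a.mean() == b.mean():
            return WelchResult(statistic=0.0, pvalue=1.0, df=float(a.size + b.size - 2))
        return WelchResult(statistic=np.inf, pvalue=0.0, df=float(a.size + b.size - 2))
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(statistic=float(res.statistic), pvalue=float(res.pvalue), df=float(res.df))


def pearson_regression(x, y) -> RegressionResult:
    """Pearson r (two-sided t-distribution p) plus OLS line with 95% CIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CohortError("need matched x and y with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CohortError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CohortError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        r=float(r),
        pvalue=float(p),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        n=int(x.size),
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise CohortError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise CohortError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def cutoff_subset_analysis(
    records: pd.DataFrame,
    cutoffs=(150.0, 200.0, 250.0),
    measure: str = "disp_cerebellum_um",
) -> pd.DataFrame:
    """ILI-displacement regression on CMI subsets above displacement cutoffs.

    For each cutoff c, CMI subjects with ``measure`` strictly above c are
    selected and Pearson regression of displacement on ILI is run; rows with
    fewer than 3 subjects carry NaN r and p.  ``n_ties`` counts subjects
    sitting exactly at the cutoff (excluded by the strict rule).
    """
    cmi = records[records["group"] == "CMI"]
    if cmi.empty:
        raise CohortError("no CMI subjects in the table")
    rows = []
    for c in cutoffs:
        sub = cmi[cmi[measure] > c]
        ties = int((cmi[measure] == c).sum())
        if len(sub) < 3:
            rows.append({"cutoff_um": c, "n": len(sub), "r": np.nan, "p": np.nan, "n_ties": ties})
            continue
        reg = pearson_regression(sub["ili_dyn_cm5"], sub[measure])
        rows.append(
            {"cutoff_um": c, "n": reg.n, "r": reg.r, "p": reg.pvalue, "n_ties": ties}
        )
    return pd.DataFrame(rows)


def symptom_comparison(
    records: pd.DataFrame,
    symptom: str,
    correction: str | None = None,
) -> pd.DataFrame:
    """Welch tests of each biomechanical measure between CMI subjects with
    and without a symptom.

    ``correction="bonferroni"`` multiplies p by the number of measures.
    """
    if symptom not in records.columns:
        raise CohortError(f"symptom column {symptom!r} missing")
    cmi = records[(records["group"] == "CMI") & records[symptom].notna()]
    pos = cmi[cmi[symptom].astype(float) > 0]
    neg = cmi[cmi[symptom].astype(float) == 0]
    if pos.empty or neg.empty:
        raise CohortError(f"symptom {symptom!r}: one arm is empty")
    if len(pos) < 4 or len(neg) < 4:
        import warnings

        warnings.warn(f"symptom {symptom!r}: fewer than 4 subjects in an arm", stacklevel=2)
    rows = []
    for m in MEASURES:
        res = welch_t_test(pos[m], neg[m])
        p = res.pvalue
        if correction == "bonferroni":
            p = min(1.0, p * len(MEASURES))
        rows.append(
            {
                "symptom": symptom,
                "measure": m,
                "n_with": len(pos),
                "n_without": len(neg),
                "mean_with": float(pos[m].mean()),
                "mean_without": float(neg[m].mean()),
                "t": res.statistic,
                "df": res.df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean/SD of each measure, Welch contrast and normality p."""
    rows = []
    groups = dict(tuple(records.groupby("group")))
    for m in MEASURES:
        row: dict = {"measure": m}
        for g, df in groups.items():
            row[f"mean_{g}"] = float(df[m].mean())
            row[f"sd_{g}"] = float(df[m].std(ddof=1))
            try:
                row[f"shapiro_p_{g}"] = shapiro_wilk(df[m])[1]
            except CohortError:
                row[f"shapiro_p_{g}"] = np.nan
        if {"CMI", "control"} <= groups.keys():
            res = welch_t_test(groups["CMI"][m], groups["control"][m])
            row["welch_t"] = res.statistic
            row["welch_p"] = res.pvalue
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    records: pd.DataFrame,
    cutoffs=(150.0, 200.0, 250.0),
) -> dict[str, pd.DataFrame]:
    """Full statistical bundle: group summary, per-group ILI-displacement
    correlations, cutoff table, and symptom table (when flags are present)."""
    out: dict[str, pd.DataFrame] = {"group_summary": group_summary(records)}

    corr_rows = []
    for g, df in records.groupby("group"):
        for m in ("disp_cerebellum_um", "disp_brainstem_um"):
            try:
                reg = pearson_regression(df["ili_dyn_cm5"], df[m])
                corr_rows.append(
                    {
                        "group": g,
                        "measure": m,
                        "n": reg.n,
                        "r": reg.r,
                        "p": reg.pvalue,
                        "slope": reg.slope,
                        "intercept": reg.intercept,
                        "slope_ci_lo": reg.slope_ci[0],
                        "slope_ci_hi": reg.slope_ci[1],
                    }
                )
            except CohortError:
                corr_rows.append(
                    {"group": g, "measure": m, "n": len(df), "r": np.nan, "p": np.nan}
                )
    out["correlations"] = pd.DataFrame(corr_rows)
    out["cutoff_table"] = cutoff_subset_analysis(records, cutoffs=cutoffs)

    present = [s for s in SYMPTOMS if s in records.columns and records[s].notna().any()]
    if present:
        tables = []
        for s in present:
            try:
                tables.append(symptom_comparison(records, s))
            except CohortError:
                continue
        if tables:
            out["symptom_table"] = pd.concat(tables, ignore_index=True)
    return out
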