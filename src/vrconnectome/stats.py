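"""Group statistics over cohort-level connectome metrics.

The comparison of network metrics between the no-aphasia (NA) and
glioma-induced-aphasia (GIA) groups uses ANCOVA with tumor size as the
covariate: a least-squares fit of

    metric = intercept + beta_g * 1[group = GIA] + beta_c * tumor_size

reporting the group coefficient's t statistic (n - 3 residual df) and its
two-sided p, plus the equivalent one-df F.  Demographics use the independent
t-test and the chi-square test; region-count comparisons use Mann-Whitney U;
metric-vs-aphasia-level associations use Spearman (default, the level is
ordinal) or Pearson correlation over the pooled cohort.  Benjamini-Hochberg
FDR is applied within each output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .connectome import MATRIX_KINDS

__all__ = [
    "StatResult",
    "ancova_group_test",
    "independent_t",
    "chi_square",
    "mann_whitney",
    "correlate_with_aphasia",
    "fdr_adjust",
    "build_tables",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class StatResult:
    """One statistical comparison (statistic, p, optional FDR-adjusted p)."""

    comparison: str
    stat_name: str  # "T", "F", "K", "U" or "R"
    statistic: float
    p: float
    p_adjusted: float | None = None
    group_means: dict[str, float] = field(default_factory=dict)
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.comparison}: non-finite statistic")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.comparison}: p outside [0, 1]")


def ancova_group_test(
    values,
    groups,
    covariate,
    group_order: tuple[str, str] = ("NA", "GIA"),
    comparison: str = "ancova",
) -> StatResult:
    """ANCOVA group comparison with one covariate.

    Fits ``value ~ 1 + group + covariate`` by OLS and reports the group
    indicator's t (two-sided, n - 3 df).  The indicator is 1 for the second
    entry of ``group_order``, so a negative group mean difference
    (means[second] < means[first]) yields a negative coefficient.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    cov = np.asarray(covariate, dtype=float)
    if y.shape != g.shape or y.shape != cov.shape:
        raise ValueError("values, groups and covariate must have equal length")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite")
    for name in group_order:
        if (g == name).sum() < 3:
            raise ValueError(f"need >= 3 subjects in group {name!r}")
    indicator = (g == group_order[1]).astype(float)
    design = np.column_stack([np.ones_like(y), indicator, cov])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "rank-deficient ANCOVA design: the covariate is collinear with the "
            "intercept/group columns (e.g. constant within groups)"
        )
    fit = sm.OLS(y, design).fit()
    tval = float(fit.tvalues[1])
    pval = float(fit.pvalues[1])
    means = {name: float(y[g == name].mean()) for name in group_order}
    return StatResult(
        comparison=comparison,
        stat_name="T",
        statistic=tval,
        p=pval,
        group_means=means,
        extra={
            "F": tval**2,
            "df_resid": float(fit.df_resid),
            "group_coef": float(fit.params[1]),
            "covariate_coef": float(fit.params[2]),
        },
    )


def independent_t(a, b, comparison: str = "t") -> StatResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return StatResult(comparison, "T", 0.0, 1.0,
                              group_means={"a": float(a.mean()), "b": float(b.mean())})
        raise ValueError("zero within-group variance with unequal means")
    t, p = sps.ttest_ind(a, b)
    return StatResult(comparison, "T", float(t), float(p),
                      group_means={"a": float(a.mean()), "b": float(b.mean())})


def chi_square(table, correction: bool = False, comparison: str = "chi2") -> StatResult:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction by default)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency table must be 2-D and non-negative")
    k, p, dof, _ = sps.chi2_contingency(table, correction=correction)
    return StatResult(comparison, "K", float(k), float(p), extra={"dof": float(dof)})


def mann_whitney(a, b, comparison: str = "mwu") -> StatResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult(comparison, "U", float(u), float(p),
                      group_means={"a": float(a.mean()), "b": float(b.mean())})


def correlate_with_aphasia(
    values, levels, method: str = "spearman", comparison: str = "correlation"
) -> StatResult:
    """Correlation of a metric with the ordinal aphasia level (pooled cohort)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(levels, dtype=float)
    if len(y) != len(x) or len(y) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        r, p = sps.spearmanr(y, x)
    elif method == "pearson":
        r, p = sps.pearsonr(y, x)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return StatResult(comparison, "R", float(r), float(p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Output tables

_METRICS = ("ad", "eg", "el")
_BLOCKS = ("25", "50", "diff")


def _metric_column(block: str, metric: str) -> str:
    return f"{metric}_diff" if block == "diff" else metric


def build_tables(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    correlation_method: str = "spearman",
    group_order: tuple[str, str] = ("NA", "GIA"),
    thresholds: tuple[float, float] = (25.0, 50.0),
) -> dict[str, pd.DataFrame]:
    """Cohort-level comparison tables.

    ``metrics`` is tidy per-subject output: columns subject_id, kind,
    threshold (the two VR percentages or "diff"), ad, eg, el (and for the
    diff rows ad_diff, eg_diff, el_diff).  ``cohort`` carries subject_id,
    group, tumor_size_cm3, aphasia_level.

    Returns ``{"group_comparison": ..., "aphasia_correlation": ...}``:
    matrix-kind x metric x {25, 50, DIFF} rows with group means, ANCOVA t,
    raw and BH-adjusted p (one FDR family per table) and an alpha = 0.05
    significance flag.
    """
    missing = set(cohort["subject_id"]) - set(metrics["subject_id"])
    if missing:
        raise ValueError(f"metrics missing for subjects {sorted(missing)}")
    merged = metrics.merge(
        cohort[["subject_id", "group", "tumor_size_cm3", "aphasia_level"]],
        on="subject_id", how="inner", validate="many_to_one",
    )
    lo, hi = (str(int(t)) for t in thresholds)
    block_of = {lo: "25", hi: "50", "diff": "diff"}

    comp_rows, corr_rows = [], []
    for kind in MATRIX_KINDS:
        for block_label, block in block_of.items():
            sub = merged[(merged["kind"] == kind)
                         & (merged["threshold"].astype(str) == block_label)]
            if sub.empty:
                raise ValueError(f"no metric rows for kind={kind}, block={block_label}")
            for metric in _METRICS:
                col = _metric_column(block, metric)
                vals = sub[col].to_numpy(dtype=float)
                grp = sub["group"].to_numpy()
                if np.ptp(vals) == 0:
                    # constant outcome: no detectable group difference
                    means = {name: float(vals[grp == name].mean()) for name in group_order}
                    t_val, f_val, p_val = 0.0, 0.0, 1.0
                else:
                    res = ancova_group_test(
                        vals, grp, sub["tumor_size_cm3"].to_numpy(),
                        group_order=group_order,
                        comparison=f"{kind}:{metric}:{block}",
                    )
                    means = res.group_means
                    t_val, f_val, p_val = res.statistic, res.extra["F"], res.p
                comp_rows.append({
                    "kind": kind, "metric": metric, "block": block.upper(),
                    f"mean_{group_order[0]}": means[group_order[0]],
                    f"mean_{group_order[1]}": means[group_order[1]],
                    "t_value": t_val, "f_value": f_val,
                    "p_value": p_val,
                })
                if np.ptp(vals) == 0:
                    r_val, p_val = np.nan, np.nan
                else:
                    corr = correlate_with_aphasia(
                        vals, sub["aphasia_level"].to_numpy(),
                        method=correlation_method,
                        comparison=f"{kind}:{metric}:{block}",
                    )
                    r_val, p_val = corr.statistic, corr.p
                corr_rows.append({
                    "kind": kind, "metric": metric, "block": block.upper(),
                    "r_value": r_val, "p_value": p_val,
                })

    comp = pd.DataFrame(comp_rows)
    comp["p_fdr"] = fdr_adjust(comp["p_value"].to_numpy())
    comp["significant"] = comp["p_value"] < ALPHA

    corr = pd.DataFrame(corr_rows)
    valid = corr["p_value"].notna()
    adjusted = np.full(len(corr), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = fdr_adjust(corr.loc[valid, "p_value"].to_numpy())
    corr["p_fdr"] = adjusted
    corr["significant"] = corr["p_value"] < ALPHA

    return {"group_comparison": comp, "aphasia_correlation": corr}
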