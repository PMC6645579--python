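"""Genotype group analysis over the eight attention measures.

The statistical stage mirrors a standard candidate-gene analysis: a
stepwise regression of each measure on numeric allele-dose codes for the
two genotypes (step 1) and their interaction (step 2); a mixed-design ANOVA
for the Genotype x Task-half interaction on per-half d' (with the other
genotype as a covariate); pooled-variance post-hoc t-tests with Bonferroni
correction; and a linear trend contrast over allele dose.

With a two-level within-subject factor, the Genotype x Half interaction F
of the mixed ANOVA equals the between-group (ANCOVA) F on the per-subject
half differences, which is how it is computed here (on statsmodels OLS).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .core import TrialRecord

__all__ = [
    "stepwise_genotype_regression",
    "rm_anova_genotype_by_half",
    "pairwise_t_tests",
    "bonferroni",
    "bonferroni_display",
    "linear_trend_contrast",
    "per_duration_report_stats",
]

#: The eight dependent attention measures of the group stage.
MEASURES = ("d_change", "rt_sd", "fa_rate", "vstm_K", "t0", "C", "alpha", "w_index")


def _check_measure(table: pd.DataFrame, measure: str) -> None:
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    if not np.all(np.isfinite(table[measure].to_numpy(dtype=float))):
        raise ValueError(f"measure {measure!r} contains non-finite values")


def stepwise_genotype_regression(
    table: pd.DataFrame,
    measure: str,
    comt_col: str = "comt_dose",
    dbh_col: str = "dbh_dose",
) -> pd.DataFrame:
    """Two-step OLS of a measure on genotype dose codes.

    Step 1 regresses the measure on the numeric COMT and DBH allele doses;
    step 2 adds their product (the interaction).  Returns one row per
    (step, factor) with coefficient, standard error and p-value, mirroring
    the layout of a genotype-association coefficient table.
    """
    _check_measure(table, measure)
    for col in (comt_col, dbh_col):
        if table[col].nunique() < 2:
            raise ValueError(f"degenerate design: {col} has a single level")
    y = table[measure].astype(float)
    x1 = sm.add_constant(table[[comt_col, dbh_col]].astype(float))
    fit1 = sm.OLS(y, x1).fit()
    x2 = x1.copy()
    x2["interaction"] = table[comt_col].astype(float) * table[dbh_col].astype(float)
    if np.linalg.matrix_rank(x2.to_numpy()) < x2.shape[1]:
        raise ValueError("degenerate design: collinear genotype codes")
    fit2 = sm.OLS(y, x2).fit()
    rows = []
    for step, fit, factors in (
        (1, fit1, [comt_col, dbh_col]),
        (2, fit2, [comt_col, dbh_col, "interaction"]),
    ):
        for f in factors:
            rows.append(
                dict(
                    step=step,
                    measure=measure,
                    factor={comt_col: "COMT", dbh_col: "DBH"}.get(f, "COMT x DBH"),
                    coef=float(fit.params[f]),
                    se=float(fit.bse[f]),
                    p=float(fit.pvalues[f]),
                )
            )
    return pd.DataFrame(rows)


def rm_anova_genotype_by_half(
    d_half1: Sequence[float],
    d_half2: Sequence[float],
    genotype: Sequence[str],
    covariate: Optional[Sequence[float]] = None,
) -> dict[str, float]:
    """Mixed-design ANOVA: the Genotype x Half interaction on per-half d'.

    ``d_half1``/``d_half2`` are each participant's first- and second-half
    sensitivities, ``genotype`` the between-subject factor, ``covariate`` an
    optional between-subject regressor (e.g. the other genotype's dose,
    ANCOVA-style).  Returns the interaction F, its dfs, p, and partial
    eta^2 = SS_effect / (SS_effect + SS_error).
    """
    d1 = np.asarray(d_half1, dtype=float)
    d2 = np.asarray(d_half2, dtype=float)
    geno = pd.Series(list(genotype), name="genotype")
    if len(d1) != len(d2) or len(d1) != len(geno):
        raise ValueError("half vectors and genotype labels must align")
    sizes = geno.value_counts()
    if (sizes < 2).any():
        raise ValueError("every genotype group needs at least 2 participants")
    df = pd.DataFrame({"diff": d2 - d1, "genotype": geno.to_numpy()})
    if np.allclose(df["diff"].var(ddof=0), 0.0):
        # no half-difference variation at all: interaction exactly absent
        k = geno.nunique()
        return {
            "F": 0.0,
            "df1": float(k - 1),
            "df2": float(len(df) - k - (0 if covariate is None else 1)),
            "p": 1.0,
            "partial_eta_sq": 0.0,
        }
    formula = "diff ~ C(genotype)"
    if covariate is not None:
        df["covariate"] = np.asarray(covariate, dtype=float)
        formula += " + covariate"
    fit = smf.ols(formula, data=df).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    ss_eff = float(an.loc["C(genotype)", "sum_sq"])
    ss_err = float(an.loc["Residual", "sum_sq"])
    f_val = float(an.loc["C(genotype)", "F"])
    df1 = float(an.loc["C(genotype)", "df"])
    df2 = float(an.loc["Residual", "df"])
    p = float(an.loc["C(genotype)", "PR(>F)"])
    return {
        "F": f_val,
        "df1": df1,
        "df2": df2,
        "p": p,
        "partial_eta_sq": ss_eff / (ss_eff + ss_err),
    }


def pairwise_t_tests(
    table: pd.DataFrame,
    measure: str,
    grouping: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests for every pair of groups, with 95% CIs.

    Pooled-variance by default (df = n1 + n2 - 2); set ``equal_var=False``
    for Welch.  A pair with zero variance in both groups has an undefined t
    and is returned as NaN.
    """
    _check_measure(table, measure)
    groups = sorted(table[grouping].unique())
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            a = table.loc[table[grouping] == g1, measure].to_numpy(dtype=float)
            b = table.loc[table[grouping] == g2, measure].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                raise ValueError("each group needs n >= 2")
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                t, p, df, lo, hi = (0.0, 1.0, len(a) + len(b) - 2, 0.0, 0.0)
            elif a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                t, p, df, lo, hi = (np.nan, np.nan, np.nan, np.nan, np.nan)
            else:
                res = sps.ttest_ind(a, b, equal_var=equal_var)
                t, p = float(res.statistic), float(res.pvalue)
                df = float(res.df)
                ci = res.confidence_interval(0.95)
                lo, hi = float(ci.low), float(ci.high)
            rows.append(
                dict(group1=g1, group2=g2, t=t, df=df, p=p, ci_low=lo, ci_high=hi)
            )
    return pd.DataFrame(rows)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bonferroni_display(alpha: float, m: int) -> float:
    """Corrected alpha rounded to 3 decimals for display (0.05/3 -> 0.017)."""
    return round(bonferroni(alpha, m), 3)


def linear_trend_contrast(
    table: pd.DataFrame, measure: str, dose_col: str
) -> dict[str, float]:
    """Linear contrast (-1, 0, +1) over three ordered dose-group means.

    F = (sum c_i m_i)^2 / (MSE * sum c_i^2 / n_i) against the pooled
    within-group error; location-invariant by construction.
    """
    _check_measure(table, measure)
    doses = sorted(table[dose_col].unique())
    if len(doses) != 3:
        raise ValueError(f"linear trend needs exactly 3 dose levels, got {doses}")
    weights = (-1.0, 0.0, 1.0)
    means, ns, ss_within = [], [], 0.0
    for d in doses:
        vals = table.loc[table[dose_col] == d, measure].to_numpy(dtype=float)
        means.append(vals.mean())
        ns.append(len(vals))
        ss_within += float(np.sum((vals - vals.mean()) ** 2))
    df_err = sum(ns) - 3
    mse = ss_within / df_err
    contrast = float(np.dot(weights, means))
    denom = mse * sum(c * c / n for c, n in zip(weights, ns))
    f_val = contrast**2 / denom
    p = float(sps.f.sf(f_val, 1, df_err))
    return {"F": f_val, "df1": 1.0, "df2": float(df_err), "p": p, "contrast": contrast}


def per_duration_report_stats(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Mean errors and mean reported letters per exposure duration.

    Errors on a trial are reported letters that are not among the displayed
    target letters (intrusions and guesses); the second column is the total
    number of reported letters regardless of correctness.
    """
    rows = []
    for t in trials:
        targets = set(t.target_letters)
        errors = sum(1 for ch in t.reported if ch not in targets)
        rows.append(
            dict(
                exposure_ms=t.display.exposure_ms,
                errors=errors,
                reported=len(t.reported),
            )
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("exposure_ms", as_index=False)
        .agg(mean_errors=("errors", "mean"), mean_reported=("reported", "mean"))
        .sort_values("exposure_ms", ignore_index=True)
    )
    return out
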