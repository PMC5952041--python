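"""Rater reliability and group statistics for tract metric tables.

Implements the validation statistics used to qualify a dissection
protocol: two-way intraclass correlation with its F-based 95% confidence
interval, ANCOVA gender comparison with estimated marginal means (EMMs)
adjusted for age and intracranial volume, and partial correlation of each
metric with age controlling gender and eTIV.

The ICC variant is two-way random effects, absolute agreement, single
measures (ICC(2,1) in Shrout-Fleiss terms): with n subjects, k raters and
the two-way ANOVA mean squares MSR (rows/subjects), MSC (columns/raters)
and MSE (residual),

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

Agreement (not consistency) is the standard choice when raters are meant
to be interchangeable; the consistency variant ICC(3,1) is available by
flag.  Reliability uses the raw two-rater table; rater measures are
averaged before any group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

METRIC_COLUMNS = (
    "length_mm", "volume_mm3", "fa", "md", "ad", "rd", "cl", "cp", "cs",
)
COVARIATE_COLUMNS = ("age", "gender", "etiv")


@dataclass(frozen=True)
class ReliabilityResult:
    metric: str
    icc: float
    ci95: tuple[float, float]
    variant: str
    degenerate: bool = False


@dataclass(frozen=True)
class GroupStatsResult:
    metric: str
    emm: dict  # gender level -> (emm, se, ci_lo, ci_hi); plus "total"
    gender_p: float
    gender_t: float
    partial_r_age: float
    partial_p_age: float
    df_resid: int


def validate_rater_table(table: pd.DataFrame, metrics=None) -> list[str]:
    """Check the subjects x raters x metrics invariants; return metric names."""
    for col in ("subject", "rater"):
        if col not in table.columns:
            raise ValueError(f"rater table needs a {col!r} column")
    counts = table.groupby("subject")["rater"].nunique()
    per_row = table.groupby(["subject", "rater"]).size()
    if (per_row != 1).any():
        raise ValueError("each subject must have exactly one row per rater")
    if counts.nunique() != 1:
        raise ValueError("all subjects must be rated by the same raters")
    for cov in COVARIATE_COLUMNS:
        if cov in table.columns:
            if (table.groupby("subject")[cov].nunique() != 1).any():
                raise ValueError(f"covariate {cov!r} differs across a subject's rows")
    metrics = [m for m in (metrics or METRIC_COLUMNS) if m in table.columns]
    if table[list(metrics)].isna().any().any():
        raise ValueError("metric values must not be missing")
    return metrics


def _anova_mean_squares(wide: np.ndarray):
    """Two-way (subject x rater) mean squares for one metric."""
    n, k = wide.shape
    grand = wide.mean()
    row_m = wide.mean(axis=1)
    col_m = wide.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((wide - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc_two_way(
    table: pd.DataFrame,
    metric: str,
    variant: str = "agreement",
    alpha: float = 0.05,
) -> ReliabilityResult:
    """Two-way random ICC with F-based confidence interval.

    ``variant="agreement"`` gives absolute-agreement single-measure
    ICC(2,1); ``variant="consistency"`` gives ICC(3,1).  Confidence bounds
    follow the standard F approximations (McGraw & Wong).  A table with
    (near-)zero between-subject variance is reported as degenerate rather
    than raised.
    """
    validate_rater_table(table, metrics=[metric])
    wide = (
        table.pivot(index="subject", columns="rater", values=metric)
        .to_numpy(dtype=float)
    )
    n, k, msr, msc, mse = _anova_mean_squares(wide)
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    degenerate = msr <= mse * (1 + 1e-12) and np.isclose(msr, mse)
    if variant == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / st.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * st.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif variant == "agreement":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df for the F bounds on ICC(2,1)
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and mse > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_star = st.f.ppf(1 - alpha / 2, n - 1, v)
            lo = (
                n * (msr - f_star * mse)
                / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            f_star2 = st.f.ppf(1 - alpha / 2, v, n - 1)
            hi = (
                n * (f_star2 * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
            )
        else:
            lo, hi = icc, icc
    else:
        raise ValueError("variant must be 'agreement' or 'consistency'")
    icc = float(icc)
    lo = float(min(lo, icc))
    hi = float(max(hi, icc))
    return ReliabilityResult(
        metric=metric, icc=icc, ci95=(lo, hi), variant=variant,
        degenerate=bool(degenerate),
    )


def average_raters(table: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Per-subject table with rater measures averaged, covariates carried."""
    metrics = validate_rater_table(table, metrics)
    keep = {m: "mean" for m in metrics}
    keep.update({c: "first" for c in COVARIATE_COLUMNS if c in table.columns})
    return table.groupby("subject", as_index=False).agg(keep)


def _design(table: pd.DataFrame, metric: str):
    y = table[metric].to_numpy(dtype=float)
    g = table["gender"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(table)),
            g,
            table["age"].to_numpy(dtype=float),
            table["etiv"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j, name in enumerate(["intercept", "gender", "age", "etiv"]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                raise ValueError(f"rank-deficient design: column {name!r} is collinear")
        raise ValueError("rank-deficient design")
    return y, X, g


def ancova_gender(table: pd.DataFrame, metric: str, alpha: float = 0.05):
    """ANCOVA of one (rater-averaged) metric on gender + age + eTIV.

    Returns a :class:`GroupStatsResult` with the gender partial test and
    estimated marginal means: each gender EMM evaluates the fitted model at
    the sample covariate means, the grand EMM is the unweighted average of
    the two gender EMMs, and CIs use t with n - 4 residual df.
    """
    levels = np.unique(table["gender"])
    if len(levels) != 2:
        raise ValueError("both gender levels must be present")
    y, X, g = _design(table, metric)
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError("more model parameters than subjects")
    model = sm.OLS(y, X).fit()
    df_resid = int(model.df_resid)  # n - 4
    gender_t = float(model.tvalues[1])
    gender_p = float(model.pvalues[1])
    age_m = table["age"].mean()
    etiv_m = table["etiv"].mean()
    tcrit = st.t.ppf(1 - alpha / 2, df_resid)
    emm = {}
    rows = {lvl: np.array([1.0, float(lvl), age_m, etiv_m]) for lvl in levels}
    rows["total"] = np.mean(list(rows.values()), axis=0)
    for name, x in rows.items():
        est = float(x @ model.params)
        se = float(np.sqrt(x @ model.cov_params() @ x))
        emm[name] = (est, se, est - tcrit * se, est + tcrit * se)
    r, p = partial_correlation(table, metric, target="age",
                               controls=("gender", "etiv"))
    return GroupStatsResult(
        metric=metric, emm=emm, gender_p=gender_p, gender_t=gender_t,
        partial_r_age=r, partial_p_age=p, df_resid=df_resid,
    )


def partial_correlation(
    table: pd.DataFrame,
    metric: str,
    target: str = "age",
    controls: tuple[str, ...] = ("gender", "etiv"),
) -> tuple[float, float]:
    """Partial Pearson correlation of metric with target given controls.

    Both variables are residualized on the controls (with intercept); the
    two-sided p-value uses t = r sqrt((n - 2 - k)/(1 - r^2)) with k the
    number of controls.  With no controls this is the plain Pearson r.
    """
    y = table[metric].to_numpy(dtype=float)
    x = table[target].to_numpy(dtype=float)
    n = len(y)
    k = len(controls)
    if n <= k + 3:
        raise ValueError("too few subjects for the requested controls")
    Z = np.column_stack(
        [np.ones(n)] + [table[c].to_numpy(dtype=float) for c in controls]
    )
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    ry = y - Z @ beta_y
    rx = x - Z @ beta_x
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y)))
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x)))
    if sy <= tol_y or sx <= tol_x:
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.clip((ry @ rx) / (sy * sx), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r**2))
    p = float(2 * st.t.sf(abs(t), dof))
    return r, p


def reliability_report(
    table: pd.DataFrame, metrics=None, variant: str = "agreement"
) -> pd.DataFrame:
    """ICC + CI for every metric column present, as a tidy frame."""
    metrics = validate_rater_table(table, metrics)
    rows = []
    for m in metrics:
        r = icc_two_way(table, m, variant=variant)
        rows.append(
            {"metric": m, "icc": r.icc, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
             "variant": r.variant, "degenerate": r.degenerate}
        )
    return pd.DataFrame(rows)


def group_report(table: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """ANCOVA gender EMMs and age partial correlations for each metric."""
    metrics = [m for m in (metrics or METRIC_COLUMNS) if m in table.columns]
    rows = []
    for m in metrics:
        g = ancova_gender(table, m)
        row = {"metric": m, "gender_p": g.gender_p,
               "partial_r_age": g.partial_r_age, "partial_p_age": g.partial_p_age}
        for lvl, (est, se, lo, hi) in g.emm.items():
            tag = f"emm_{lvl}"
            row.update({tag: est, f"{tag}_se": se, f"{tag}_lo": lo, f"{tag}_hi": hi})
        rows.append(row)
    return pd.DataFrame(rows)
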