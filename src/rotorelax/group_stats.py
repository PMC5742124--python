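"""Per-ROI group comparisons with group-specific variances.

Each MRI outcome is compared between each patient group and controls with a
linear model that does not assume a common residual variance across groups:
without covariates this is the Welch two-sample problem with Satterthwaite
degrees of freedom; with covariates (age, and mean FD for the functional
metrics) a two-step feasible GLS is used — OLS first, per-group residual
variances next, then a weighted refit whose Wald contrast is referred to a
Satterthwaite-type t distribution.

Familywise error over the two contrasts (PD vs control, iRBD vs control)
is controlled per (ROI, metric) with Holm's step-down adjustment; the
multiplicity over the MRI outcomes is handled per (ROI, contrast) with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "holm_adjust",
    "bh_fdr",
    "between_subject_cv",
    "control_cv_table",
    "summarize_cohort",
    "anova_oneway",
    "analyze_cohort",
    "CONTRASTS",
]

CONTRASTS = (("PD", "control"), ("iRBD", "control"))

#: Metrics for which mean FD enters as a nuisance covariate.
FUNCTIONAL_METRICS = ("network_strength", "ReHo")


@dataclass
class ComparisonResult:
    roi_name: str
    metric_name: str
    contrast: str            # e.g. "PD-control"
    estimate: float
    se: float
    df: float
    p_raw: float
    p_holm: float = np.nan
    p_fdr: float = np.nan
    age_adjusted: bool = False


def _welch(a: np.ndarray, b: np.ndarray):
    """Welch comparison of mean(a) - mean(b): estimate, SE, Satterthwaite
    df and two-sided p."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    est = a.mean() - b.mean()
    se2 = va / na + vb / nb
    se = np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * stats.t.sf(abs(t), df)
    return float(est), float(se), float(df), float(p)


def compare_groups(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
    contrasts=CONTRASTS,
    roi_name: str = "",
    metric_name: str = "",
    force_equal_variances: bool = False,
) -> list[ComparisonResult]:
    """Group contrasts with group-specific variances.

    Without covariates each contrast is a Welch two-sample comparison.
    With covariates the full sample is fitted by two-step feasible GLS
    (OLS -> per-group residual variances -> WLS) and each contrast is the
    Wald test on the corresponding group coefficient, with a
    Satterthwaite-type df built from the two groups' variance-over-n
    contributions (falling back to a normal approximation when either
    group has fewer than 3 subjects).  ``force_equal_variances`` pools the
    variance, reducing the no-covariate case to the classical t-test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        if len(covariates) != len(values):
            raise ValueError("covariates must match values in length")
        if covariates.isna().any().any():
            raise ValueError("covariates must be complete (no missing values)")
    for g1, g2 in contrasts:
        for g in (g1, g2):
            if (groups == g).sum() < 2:
                raise ValueError(
                    f"insufficient group sizes: group {g!r} has "
                    f"{(groups == g).sum()} subjects (< 2)"
                )
    adjusted = covariates is not None and len(covariates.columns) > 0
    results = []
    if not adjusted:
        for g1, g2 in contrasts:
            a, b = values[groups == g1], values[groups == g2]
            if force_equal_variances:
                t, p = stats.ttest_ind(a, b, equal_var=True)
                sp2 = (
                    (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
                ) / (len(a) + len(b) - 2)
                se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
                est, df = a.mean() - b.mean(), len(a) + len(b) - 2
                results.append(ComparisonResult(
                    roi_name, metric_name, f"{g1}-{g2}",
                    float(est), float(se), float(df), float(p)))
                continue
            est, se, df, p = _welch(a, b)
            results.append(ComparisonResult(
                roi_name, metric_name, f"{g1}-{g2}", est, se, df, p))
        return results

    # two-step FGLS on the pooled sample
    levels = [g for g in ("control", "iRBD", "PD") if g in set(groups)]
    levels += [g for g in np.unique(groups) if g not in levels]
    dummies = {g: (groups == g).astype(float) for g in levels[1:]}
    x_cols = [np.ones(len(values))]
    col_names = ["intercept"]
    for g, d in dummies.items():
        x_cols.append(d)
        col_names.append(f"group[{g}]")
    for c in covariates.columns:
        x_cols.append(covariates[c].to_numpy(dtype=float))
        col_names.append(str(c))
    x = np.column_stack(x_cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix in covariate-adjusted model")
    n, p_par = x.shape
    beta_ols = np.linalg.lstsq(x, values, rcond=None)[0]
    resid = values - x @ beta_ols
    sig2 = {}
    for g in levels:
        sel = groups == g
        n_g = int(sel.sum())
        # spread the model's p parameters over groups in proportion to size
        ddof_g = max(n_g - p_par * n_g / n, 1.0)
        sig2[g] = float((resid[sel] ** 2).sum() / ddof_g)
    w = np.array([1.0 / sig2[g] for g in groups])
    xw = x * w[:, None]
    xtwx_inv = np.linalg.inv(x.T @ xw)
    beta = xtwx_inv @ (xw.T @ values)
    cov = xtwx_inv  # weights are inverse variances, so this is the GLS cov

    q_cov = len(covariates.columns)
    for g1, g2 in contrasts:
        c = np.zeros(p_par)
        if g1 != levels[0]:
            c[col_names.index(f"group[{g1}]")] = 1.0
        if g2 != levels[0]:
            c[col_names.index(f"group[{g2}]")] = -1.0
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        n1, n2 = int((groups == g1).sum()), int((groups == g2).sum())
        if min(n1 - 1 - q_cov, n2 - 1 - q_cov) < 1 or min(n1, n2) < 3:
            df = np.inf  # normal approximation for very small groups
        else:
            u1, u2 = sig2[g1] / n1, sig2[g2] / n2
            df = (u1 + u2) ** 2 / (
                u1**2 / (n1 - 1 - q_cov) + u2**2 / (n2 - 1 - q_cov)
            )
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(df) else 2 * stats.norm.sf(abs(t))
        results.append(ComparisonResult(
            roi_name, metric_name, f"{g1}-{g2}",
            est, se, float(df), float(p), age_adjusted=True))
    return results


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values (order-preserving, capped at 1)."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def between_subject_cv(values) -> float:
    """Percent coefficient of variation: 100 * sample SD / sample mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def control_cv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Between-subject CV among controls, per metric.

    The CV is computed within each (ROI, metric) cell over control subjects
    and then summarized per metric as the mean across ROIs.
    """
    ctrl = table[table["group"] == "control"]
    rows = []
    for metric, sub in ctrl.groupby("metric_name"):
        per_roi = sub.groupby("roi_name")["value"].apply(
            lambda v: between_subject_cv(v) if len(v) >= 2 else np.nan
        )
        rows.append({"metric_name": metric, "cv_percent": float(per_roi.mean())})
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD per (group, roi, metric), long format.

    Cells with a single subject report the SD as missing.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    g = table.groupby(["group", "roi_name", "metric_name"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n="count").reset_index()
    return out


def anova_oneway(values, groups) -> tuple[float, float]:
    """Standard one-way ANOVA F-test across groups (e.g. on residual DOF)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def analyze_cohort(
    table: pd.DataFrame,
    adjustments=(False, True),
    contrasts=CONTRASTS,
) -> pd.DataFrame:
    """Run every (ROI, metric) contrast, with and without age adjustment.

    Holm is applied over the contrasts within each (ROI, metric,
    adjustment); BH-FDR over the metrics within each (ROI, contrast,
    adjustment).  Functional metrics additionally carry mean FD as a
    covariate whenever covariates are in play.
    """
    required = {"subject_id", "group", "roi_name", "metric_name", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    results: list[ComparisonResult] = []
    for adjust in adjustments:
        for (roi, metric), sub in table.groupby(["roi_name", "metric_name"]):
            sub = sub.dropna(subset=["value"])
            cov = None
            if adjust:
                cols = {"age": sub["age"].to_numpy(dtype=float)}
                if metric in FUNCTIONAL_METRICS and "FD" in sub.columns:
                    cols["FD"] = sub["FD"].to_numpy(dtype=float)
                cov = pd.DataFrame(cols)
            results.extend(
                compare_groups(
                    sub["value"].to_numpy(), sub["group"].to_numpy(),
                    covariates=cov, contrasts=contrasts,
                    roi_name=roi, metric_name=metric,
                )
            )
    df = pd.DataFrame([vars(r) for r in results])
    # Holm over the contrasts within (roi, metric, adjustment)
    for _, idx in df.groupby(["roi_name", "metric_name", "age_adjusted"]).groups.items():
        df.loc[idx, "p_holm"] = holm_adjust(df.loc[idx, "p_raw"].to_numpy())
    # BH-FDR over the metrics within (roi, contrast, adjustment)
    for _, idx in df.groupby(["roi_name", "contrast", "age_adjusted"]).groups.items():
        df.loc[idx, "p_fdr"] = bh_fdr(df.loc[idx, "p_holm"].to_numpy())
    return df
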