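"""Normative and determinants statistics for pRNFL grayscale cohorts.

Implements the statistical layer of a normative-database study on a
merged cohort table (covariates + per-eye measurements):

* age-decade summary tables (mean +/- SD per parameter, plus Total row);
* within-eye pairwise sector comparisons, Bonferroni-corrected over all
  15 sector pairs (paired t-tests: each eye contributes all six sector
  values, so contrasts are paired by design);
* a univariable screen (one simple linear regression per covariate,
  reporting the standardized coefficient, which in simple regression
  equals the Pearson correlation) feeding a carry-forward rule
  (p < alpha enters the multivariable model);
* a multivariable ordinary-least-squares fit with optional forced
  covariates (axial length is forced by default in the pipeline, on the
  clinical ground that eye size shifts the peripapillary anatomy even
  when its univariable signal is weak);
* a two-observer agreement ICC.

OLS fits go through statsmodels; the surrounding screening/carry-forward
logic and the ICC decomposition are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import NotEstimableError
from .sectors import SECTOR_ORDER

#: Default age-group bin edges (years); the last bin is open-ended.
DEFAULT_AGE_EDGES = (18, 30, 40, 50, 60, 70)

#: Covariates of the determinant analysis, in reporting order.
COVARIATE_ORDER = (
    "age", "sex", "se", "bcva", "al", "iop", "vf_md",
    "thick_mean", "rpe_gray", "imageq",
)

#: The 7+7 normative parameters summarised per age group.
PARAMETER_COLUMNS = (
    "gray_mean", *[f"gray_{s}" for s in SECTOR_ORDER],
    "thick_mean", *[f"thick_{s}" for s in SECTOR_ORDER],
)


@dataclass
class CovariateResult:
    """One covariate's row of a regression table."""

    name: str
    included: bool
    slope: float | None = None  # outcome units per covariate unit
    std_coef: float | None = None
    p_value: float | None = None
    std_error: float | None = None
    ci95: tuple[float, float] | None = None
    note: str = ""


@dataclass
class RegressionResult:
    """A univariable screen or multivariable fit."""

    outcome: str
    n: int
    covariates: dict[str, CovariateResult]
    intercept: float | None = None
    model: object | None = None  # statsmodels result for the curious

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.covariates.items():
            rows.append(
                {
                    "covariate": name,
                    "beta": r.slope if r.included else np.nan,
                    "std_coef": r.std_coef if r.included else np.nan,
                    "p_value": r.p_value if r.included else np.nan,
                    "se": r.std_error if r.included else np.nan,
                    "included": r.included,
                    "note": r.note,
                }
            )
        return pd.DataFrame(rows)

    def carry_forward(self, alpha: float = 0.05) -> list[str]:
        """Covariates significant at ``alpha`` (univariable screen rule)."""
        return [
            name
            for name, r in self.covariates.items()
            if r.included and r.p_value is not None and r.p_value < alpha
        ]


def _analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded records; analyses are complete-case."""
    df = cohort
    if "excluded" in df.columns:
        df = df[df["excluded"].isna() | (df["excluded"] == "")]
    return df.reset_index(drop=True)


def age_group_summary(
    cohort: pd.DataFrame,
    edges: tuple[float, ...] = DEFAULT_AGE_EDGES,
    parameters: tuple[str, ...] = PARAMETER_COLUMNS,
) -> pd.DataFrame:
    """Mean +/- SD of every parameter per age group, plus a Total row.

    ``edges`` are left edges; the last group is open-ended (>= last
    edge).  Empty bins appear with n = 0 and NaN moments.  SDs are
    sample SDs (n - 1).
    """
    df = _analysis_frame(cohort)
    bins = list(edges) + [np.inf]
    labels = [
        f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f">={int(lo)}"
        for lo, hi in zip(bins[:-1], bins[1:])
    ]
    grp = pd.cut(df["age"], bins=bins, labels=labels, right=False)

    out_rows = []
    for label in labels + ["Total"]:
        sub = df if label == "Total" else df[grp == label]
        row: dict[str, object] = {"age_group": label, "n": len(sub)}
        for par in parameters:
            if len(sub) == 0:
                row[f"{par}_mean"], row[f"{par}_sd"] = np.nan, np.nan
            else:
                row[f"{par}_mean"] = float(sub[par].mean())
                row[f"{par}_sd"] = float(sub[par].std(ddof=1)) if len(sub) > 1 else np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def compare_sectors(
    cohort: pd.DataFrame,
    prefix: str = "gray",
    highlight: str = "N",
) -> pd.DataFrame:
    """All 15 pairwise within-eye sector comparisons, Bonferroni-adjusted.

    Paired t-tests on the per-eye sector differences; adjusted
    p = min(1, raw p * 15).  Pairs with zero within-eye variance are
    reported as degenerate (NaN p).  The ``highlight`` column marks the
    contrasts involving the nasal sector, the normative pattern of
    interest.
    """
    df = _analysis_frame(cohort)
    if len(df) < 2:
        raise NotEstimableError("sector comparison needs at least 2 subjects")
    pairs = [
        (a, b)
        for i, a in enumerate(SECTOR_ORDER)
        for b in SECTOR_ORDER[i + 1:]
    ]
    n_family = len(pairs)
    rows = []
    for a, b in pairs:
        xa = df[f"{prefix}_{a}"].to_numpy(dtype=float)
        xb = df[f"{prefix}_{b}"].to_numpy(dtype=float)
        diff = xa - xb
        mean_diff = float(diff.mean())
        if np.allclose(diff.std(ddof=1), 0.0):
            raw_p = np.nan
            tstat = np.nan
            degenerate = True
        else:
            tstat, raw_p = sps.ttest_rel(xa, xb)
            degenerate = False
        adj_p = min(1.0, float(raw_p) * n_family) if np.isfinite(raw_p) else np.nan
        rows.append(
            {
                "sector_a": a,
                "sector_b": b,
                "mean_diff": mean_diff,
                "t": float(tstat) if np.isfinite(tstat) else np.nan,
                "p_raw": float(raw_p) if np.isfinite(raw_p) else np.nan,
                "p_bonferroni": adj_p,
                "degenerate": degenerate,
                "involves_highlight": highlight in (a, b),
            }
        )
    return pd.DataFrame(rows)


def nasal_lowest_significant(
    comparison: pd.DataFrame, alpha: float = 0.001, nasal: str = "N"
) -> bool:
    """True when the nasal sector is below every other sector with
    Bonferroni-adjusted significance (the headline normative pattern)."""
    sub = comparison[comparison["involves_highlight"]]
    ok = True
    for _, row in sub.iterrows():
        signed = row["mean_diff"] if row["sector_b"] == nasal else -row["mean_diff"]
        # signed > 0 means "other minus nasal > 0", i.e. nasal lower
        ok &= bool(signed > 0 and np.isfinite(row["p_bonferroni"]) and row["p_bonferroni"] < alpha)
    return ok


def univariable_screen(
    cohort: pd.DataFrame,
    outcome: str = "gray_mean",
    covariates: tuple[str, ...] = COVARIATE_ORDER,
) -> RegressionResult:
    """One simple linear regression per covariate.

    Reports the unstandardized slope, the standardized coefficient
    (slope * SD(x) / SD(y), equal to the Pearson correlation here) and
    the two-sided p-value.  A constant covariate is flagged
    not-estimable without disturbing the others.  ``carry_forward``
    on the result applies the p < alpha inclusion rule (default 0.05).
    """
    df = _analysis_frame(cohort)
    y = df[outcome].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise NotEstimableError(f"outcome {outcome!r} has zero variance")
    results: dict[str, CovariateResult] = {}
    for name in covariates:
        if name == outcome:
            continue
        x = df[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            results[name] = CovariateResult(
                name=name, included=False, note="constant covariate"
            )
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        slope = float(fit.params[1])
        std_coef = slope * float(np.std(x, ddof=1) / np.std(y, ddof=1))
        results[name] = CovariateResult(
            name=name,
            included=True,
            slope=slope,
            std_coef=std_coef,
            p_value=float(fit.pvalues[1]),
            std_error=float(fit.bse[1]),
        )
    return RegressionResult(
        outcome=outcome, n=len(df), covariates=results, model=None
    )


def multivariable_fit(
    cohort: pd.DataFrame,
    outcome: str = "gray_mean",
    carry_forward: tuple[str, ...] | list[str] = (),
    forced: tuple[str, ...] | list[str] = ("al",),
    report: tuple[str, ...] = COVARIATE_ORDER,
) -> RegressionResult:
    """OLS of the outcome on carry-forward plus forced covariates.

    Slopes are unstandardized (outcome units per covariate unit).
    Covariates in ``report`` but not entered appear with included=False
    (the table's "-" rows).  Exact collinearity raises with the names of
    the offending columns.
    """
    df = _analysis_frame(cohort)
    entered = list(dict.fromkeys(list(carry_forward) + list(forced)))
    if not entered:
        raise NotEstimableError("no covariates entered the multivariable model")
    X = df[entered].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the dependent columns via QR on standardized columns
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1.0, X.std(0))
        _, R = np.linalg.qr(Z)
        bad = [entered[j] for j in range(len(entered)) if abs(R[j, j]) < 1e-8]
        raise NotEstimableError(
            f"design matrix is rank deficient; collinear covariates: {bad or entered}"
        )
    fit = sm.OLS(y, Xc).fit()
    ci = np.asarray(fit.conf_int(alpha=0.05))

    sy = float(np.std(y, ddof=1))
    results: dict[str, CovariateResult] = {}
    for name in report:
        if name == outcome:
            continue
        if name not in entered:
            results[name] = CovariateResult(name=name, included=False, note="-")
            continue
        j = entered.index(name) + 1  # constant first
        sx = float(df[name].std(ddof=1))
        results[name] = CovariateResult(
            name=name,
            included=True,
            slope=float(fit.params[j]),
            std_coef=float(fit.params[j]) * sx / sy,
            p_value=float(fit.pvalues[j]),
            std_error=float(fit.bse[j]),
            ci95=(float(ci[j, 0]), float(ci[j, 1])),
        )
    # entered covariates outside the reporting list still get rows
    for name in entered:
        if name not in results:
            j = entered.index(name) + 1
            results[name] = CovariateResult(
                name=name, included=True, slope=float(fit.params[j]),
                p_value=float(fit.pvalues[j]), std_error=float(fit.bse[j]),
                ci95=(float(ci[j, 0]), float(ci[j, 1])),
            )
    return RegressionResult(
        outcome=outcome,
        n=len(df),
        covariates=results,
        intercept=float(fit.params[0]),
        model=fit,
    )


def icc_two_observers(values_obs1, values_obs2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, for two observers rating the same subjects.

    From the two-way ANOVA decomposition with n subjects and k = 2
    observers::

        ICC(2,1) = (MSR - MSE) /
                   (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the subject (row), observer (column) and
    residual mean squares.  Raises when n < 3 or the total variance is
    zero (agreement undefined).
    """
    x1 = np.asarray(values_obs1, dtype=float)
    x2 = np.asarray(values_obs2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("observer vectors must be 1-D and equal length")
    n = x1.size
    k = 2
    if n < 3:
        raise NotEstimableError("ICC needs at least 3 paired observations")
    data = np.stack([x1, x2], axis=1)
    grand = data.mean()
    if np.allclose(data.var(), 0.0):
        raise NotEstimableError("zero total variance: agreement undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc)
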