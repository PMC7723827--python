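"""Validation statistics: the analysis pipeline applied to cohort tables.

The predictive-validity question — do the lostness measures predict
knowledge-test performance once experience covariates are controlled? —
is answered with a fixed sequence: descriptives, zero-order Pearson
correlations, a simultaneous-entry (ENTER) multiple linear regression on
z-scored variables with collinearity (VIF) and Shapiro–Wilk normality
checks, a paired t comparison of the two lostness measures, and a
one-sided outlier screen (above mean + 2 SD) on local lostness.

p-values are two-sided throughout and unadjusted by default (a Holm
option exists for users who want family-wise control).  Missing data:
pairwise-complete for correlations, listwise for regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS, add_constant
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    PairingError,
    SingularityError,
)

__all__ = [
    "CorrelationMatrix",
    "RegressionResult",
    "ComparisonResult",
    "CohortReport",
    "describe",
    "correlation_matrix",
    "standardized_regression",
    "normality_check",
    "paired_comparison",
    "exclude_outliers",
    "cohort_report",
    "COHORT_VARIABLES",
    "PREDICTORS",
]

#: canonical analysis variables of a cohort table
COHORT_VARIABLES = [
    "global_lostness",
    "local_lostness",
    "knowledge_overall",
    "knowledge_spatial",
    "presence",
    "engagement",
    "cognitive_interest",
]

#: the ENTER-method predictor set
PREDICTORS = [
    "global_lostness",
    "local_lostness",
    "presence",
    "cognitive_interest",
    "engagement",
]


def _numeric(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    sub = table[list(variables)]
    bad = [v for v in variables if not pd.api.types.is_numeric_dtype(sub[v])]
    if bad:
        raise TypeError(f"non-numeric columns: {bad}")
    return sub.astype(float)


def describe(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Sample mean and SD (n−1 denominator) per variable."""
    sub = _numeric(table, variables)
    if len(sub) < 2:
        raise InsufficientDataError("describe needs at least 2 rows")
    return pd.DataFrame(
        {"mean": sub.mean(), "sd": sub.std(ddof=1), "n": sub.notna().sum()}
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    #: pairs whose correlation is undefined (a zero-variance member)
    undefined: tuple[tuple[str, str], ...]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.r.loc[pair[0], pair[1]])


def correlation_matrix(
    table: pd.DataFrame, variables: Sequence[str], holm: bool = False
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Zero-variance variables yield NaN entries and are listed in
    ``undefined`` rather than raising.  ``holm`` applies a Holm
    adjustment across the off-diagonal p-values.
    """
    sub = _numeric(table, variables)
    if sub.dropna().shape[0] < 3:
        raise InsufficientDataError("correlations need at least 3 complete rows")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    undefined = []
    raw_ps = []
    idx_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or x.std() == 0 or y.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((variables[i], variables[j]))
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            raw_ps.append(res.pvalue)
            idx_pairs.append((i, j))
    if holm and raw_ps:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raw_ps, method="holm")[1]
        for (i, j), q in zip(idx_pairs, adj):
            p[i, j] = p[j, i] = q
    names = tuple(variables)
    return CorrelationMatrix(
        variables=names,
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names),
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class RegressionResult:
    """ENTER-method OLS on z-scored variables."""

    criterion: str
    predictors: tuple[str, ...]
    beta: dict[str, float]
    p_value: dict[str, float]
    vif: dict[str, float]
    multiple_r: float
    r_squared: float
    f_statistic: float
    f_p_value: float
    df_model: int
    df_resid: int
    n: int


def standardized_regression(
    table: pd.DataFrame, criterion: str, predictors: Sequence[str]
) -> RegressionResult:
    """All predictors entered simultaneously; betas are standardized.

    Listwise deletion; exact collinearity raises
    :class:`SingularityError` naming the dependent columns.
    """
    cols = [criterion, *predictors]
    sub = _numeric(table, cols).dropna()
    n, k = len(sub), len(predictors)
    if n <= k + 1:
        raise InsufficientDataError(
            f"regression with {k} predictors needs more than {k + 1} rows, got {n}"
        )
    sds = sub.std(ddof=1)
    constant = [c for c in cols if sds[c] == 0]
    if constant:
        raise SingularityError(
            f"zero-variance columns: {constant}", columns=tuple(constant)
        )
    z = (sub - sub.mean()) / sds
    x = z[list(predictors)].to_numpy()
    if np.linalg.matrix_rank(x) < k:
        dependent = []
        for j, name in enumerate(predictors):
            others = np.delete(x, j, axis=1)
            resid = x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]
            if float(resid @ resid) < 1e-10 * n:
                dependent.append(name)
        raise SingularityError(
            f"exactly collinear predictors: {dependent}", columns=tuple(dependent)
        )
    design = add_constant(x, has_constant="add")
    fit = OLS(z[criterion].to_numpy(), design).fit()
    vif = {
        name: float(variance_inflation_factor(design, j + 1))
        for j, name in enumerate(predictors)
    }
    return RegressionResult(
        criterion=criterion,
        predictors=tuple(predictors),
        beta={name: float(fit.params[j + 1]) for j, name in enumerate(predictors)},
        p_value={name: float(fit.pvalues[j + 1]) for j, name in enumerate(predictors)},
        vif=vif,
        multiple_r=float(np.sqrt(fit.rsquared)),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=n,
    )


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and two-sided p.  Advisory: the downstream
    regression is routinely run even when normality is rejected."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk needs 3..5000 values, got {len(x)}"
        )
    if x.std() == 0:
        raise DegenerateDataError("Shapiro-Wilk is undefined for a constant vector")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ComparisonResult:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    #: zero-variance differences: t is ±inf (or 0), flagged, not an error
    degenerate: bool = False


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Paired t-test of per-player differences, df = n − 1, two-sided."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise InsufficientDataError("paired comparison needs at least 2 pairs")
    diff = x - y
    mean = float(diff.mean())
    if diff.std(ddof=1) == 0:
        t = 0.0 if mean == 0 else float(np.sign(mean)) * float("inf")
        p = 1.0 if mean == 0 else 0.0
        return ComparisonResult(mean, t, n - 1, p, degenerate=True)
    res = sps.ttest_rel(x, y)
    return ComparisonResult(
        mean_difference=mean,
        t_statistic=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
    )


def exclude_outliers(
    values: Sequence[float], k: float = 2.0, symmetric: bool = False
) -> np.ndarray:
    """Inclusion mask; ``False`` marks values strictly above mean + k·SD.

    One-sided above by default — the screen used on local lostness, where
    only an extremely *high* (disoriented) score marks a participant who
    never engaged with the content.  Mean and SD come from the full
    sample.  ``symmetric=True`` also excludes below mean − k·SD.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("outlier rule needs at least 3 values")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outliers excluded", stacklevel=2)
        return np.ones(len(x), dtype=bool)
    keep = x <= mean + k * sd
    if symmetric:
        keep &= x >= mean - k * sd
    return keep


# ---------------------------------------------------------------------
# full cohort report


@dataclass(frozen=True)
class CohortReport:
    n_input: int
    n_analyzed: int
    excluded_players: tuple[str, ...]
    descriptives: pd.DataFrame
    correlations: CorrelationMatrix
    regressions: dict[str, RegressionResult]
    measure_comparison: ComparisonResult
    normality: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_analyzed": self.n_analyzed,
            "excluded_players": list(self.excluded_players),
            "descriptives": {
                v: {"mean": float(row["mean"]), "sd": float(row["sd"])}
                for v, row in self.descriptives.iterrows()
            },
            "correlations": {
                "r": self.correlations.r.round(10).to_dict(),
                "p": self.correlations.p.round(10).to_dict(),
                "undefined_pairs": [list(p) for p in self.correlations.undefined],
            },
            "regressions": {
                crit: {
                    "beta": res.beta,
                    "p_value": res.p_value,
                    "vif": res.vif,
                    "multiple_r": res.multiple_r,
                    "f_statistic": res.f_statistic,
                    "f_p_value": res.f_p_value,
                    "df": [res.df_model, res.df_resid],
                    "n": res.n,
                }
                for crit, res in self.regressions.items()
            },
            "measure_comparison": {
                "mean_difference": self.measure_comparison.mean_difference,
                "t": self.measure_comparison.t_statistic,
                "df": self.measure_comparison.df,
                "p": self.measure_comparison.p_value,
            },
            "normality": {
                v: {"W": w, "p": p} for v, (w, p) in self.normality.items()
            },
        }

    def to_text(self) -> str:
        lines = [
            f"Cohort: {self.n_input} players, {self.n_analyzed} analyzed"
            + (
                f" (excluded: {', '.join(self.excluded_players)})"
                if self.excluded_players
                else ""
            ),
            "",
            "Means and standard deviations",
            self.descriptives[["mean", "sd"]].round(3).to_string(),
            "",
            "Zero-order correlations (Pearson r)",
            self.correlations.r.round(3).to_string(),
            "",
        ]
        for crit, res in self.regressions.items():
            lines += [
                f"Standardized regression on {crit} "
                f"(multiple R = {res.multiple_r:.3f}, "
                f"F({res.df_model}, {res.df_resid}) = {res.f_statistic:.3f}, "
                f"p = {res.f_p_value:.3f})",
            ]
            for name in res.predictors:
                lines.append(
                    f"  {name:<18} beta = {res.beta[name]:+.3f}  "
                    f"p = {res.p_value[name]:.3f}  VIF = {res.vif[name]:.2f}"
                )
            lines.append("")
        mc = self.measure_comparison
        lines.append(
            f"Global vs local lostness: mean difference = "
            f"{mc.mean_difference:+.3f}, t({mc.df}) = {mc.t_statistic:.3f}, "
            f"p = {mc.p_value:.4f}"
        )
        return "\n".join(lines)


def cohort_report(
    table: pd.DataFrame,
    criteria: Sequence[str] = ("knowledge_overall", "knowledge_spatial"),
    predictors: Sequence[str] = tuple(PREDICTORS),
    apply_outlier_rule: bool = True,
    holm: bool = False,
) -> CohortReport:
    """Run the full pipeline on a cohort table.

    The one-sided outlier screen on local lostness is applied first (as
    the study design prescribes); excluded players are reported.
    """
    required = set(predictors) | set(criteria)
    missing = sorted(required - set(table.columns))
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    working = table.copy()
    if "complete" in working.columns:
        working = working[working["complete"].astype(bool)]
    working = working.dropna(subset=sorted(required))
    if len(working) < 3:
        raise InsufficientDataError(
            f"cohort has {len(working)} analyzable rows; need at least 3"
        )
    excluded: tuple[str, ...] = ()
    if apply_outlier_rule:
        keep = exclude_outliers(working["local_lostness"].to_numpy())
        if "player" in working.columns:
            excluded = tuple(working.loc[~keep, "player"].astype(str))
        else:
            excluded = tuple(str(i) for i in working.index[~keep])
        working = working[keep]

    variables = [v for v in COHORT_VARIABLES if v in working.columns]
    desc = describe(working, variables)
    corr = correlation_matrix(working, variables, holm=holm)
    regressions = {
        crit: standardized_regression(working, crit, predictors) for crit in criteria
    }
    comparison = paired_comparison(
        working["global_lostness"], working["local_lostness"]
    )
    normality = {}
    for v in variables:
        try:
            normality[v] = normality_check(working[v])
        except (DegenerateDataError, InsufficientDataError):
            normality[v] = (float("nan"), float("nan"))
    return CohortReport(
        n_input=len(table),
        n_analyzed=len(working),
        excluded_players=excluded,
        descriptives=desc,
        correlations=corr,
        regressions=regressions,
        measure_comparison=comparison,
        normality=normality,
    )
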