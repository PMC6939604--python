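"""Inferential stage: group comparison, correlations and regressions.

Implements the analysis plan applied to the cohort table: a MANCOVA
(Pillai's trace, unique/Type-III sums of squares) comparing the seven
task-performance and diffusion measures between groups with age as a
covariate; age-partialed correlations between parent-rated inattention
and each measure, pooled and per group; Fisher r-to-z comparisons of
the per-group correlations; a hierarchical regression with group and
age forced into Model 1 and the candidate task measures entered
stepwise (p-to-enter .05, p-to-remove .10); and a forced-entry
regression adding group-by-measure interaction terms in a final step.

Partial correlations use the residual method: Pearson correlation of
the residuals of x and y after least-squares projection onto the
controls (plus intercept), with the t test on n - 2 - k degrees of
freedom.  Listwise deletion is applied once per operation over the
variables that operation uses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "AnalysisError",
    "PartialCorrelationResult",
    "FisherComparison",
    "MancovaResult",
    "RegressionModel",
    "partial_correlation",
    "fisher_compare",
    "mancova_pillai",
    "hierarchical_stepwise_regression",
    "interaction_regression",
    "age_adjusted_means",
    "P_ENTER_DEFAULT",
    "P_REMOVE_DEFAULT",
]

P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10


class AnalysisError(ValueError):
    """Degenerate analysis input (zero variance, collinearity, ...)."""


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    n: int
    k: int  # number of control covariates
    p: float


@dataclass(frozen=True)
class FisherComparison:
    z: float
    p: float


@dataclass(frozen=True)
class MancovaResult:
    """Pillai's trace tests, one row per model effect."""

    table: pd.DataFrame  # effect, pillai, F, df1, df2, p
    n: int

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


@dataclass
class RegressionModel:
    """One step of a hierarchical regression.

    ``beta`` holds standardized coefficients (b * sd_x / sd_y on the
    analysis sample); ``delta_*`` fields describe the increment over
    the previous step and are None for the first step.
    """

    label: str
    predictors: list[str]
    beta: dict[str, float]
    coef_p: dict[str, float]
    r2: float
    f: float
    df1: int
    df2: int
    p: float
    delta_r2: float | None = None
    delta_f: float | None = None
    delta_df: tuple[int, int] | None = None
    delta_p: float | None = None
    n: int = 0


# ---------------------------------------------------------------------------
# Partial correlation and Fisher comparison
# ---------------------------------------------------------------------------

def partial_correlation(
    x, y, controls=None
) -> PartialCorrelationResult:
    """Correlation of x and y with the controls partialed out.

    With no controls this reduces to the plain Pearson correlation
    (projection onto the intercept only).  The two-sided p-value comes
    from t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z.reshape(-1, 1)
        elif Z.ndim == 2 and Z.shape[0] != x.size and Z.shape[1] == x.size:
            Z = Z.T  # accept a (k, n) stack of control vectors
    if x.size != y.size or Z.shape[0] != x.size:
        raise AnalysisError("x, y and controls must have equal length")
    n, k = x.size, Z.shape[1]
    if n < k + 4:
        raise AnalysisError(f"need at least k + 4 = {k + 4} rows, got {n}")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(Z).any():
        raise AnalysisError("missing values: apply listwise deletion upstream")

    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0.0 or sy == 0.0:
        raise AnalysisError("zero residual variance: partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrelationResult(r=r, n=n, k=k, p=float(p))


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> FisherComparison:
    """Fisher r-to-z test of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.  Antisymmetric in the two groups.
    """
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise AnalysisError("|r| = 1 has an infinite z-transform")
    if n1 <= 3 or n2 <= 3:
        raise AnalysisError("group sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return FisherComparison(z=z, p=float(2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# MANCOVA (Pillai's trace)
# ---------------------------------------------------------------------------

def mancova_pillai(
    data: pd.DataFrame,
    outcomes: list[str],
    group: str = "group",
    covariate: str = "age_years",
) -> MancovaResult:
    """Multivariate group comparison with a covariate, Pillai's trace.

    Fits the multivariate linear model Y ~ 1 + group + covariate and,
    for each single-df effect, forms the hypothesis cross-product
    matrix H from the corresponding coefficient row (each effect
    adjusted for the other: unique/Type-III sums of squares) and the
    error matrix E from the residuals.  Pillai's V = tr(H (H + E)^-1);
    with df_h = 1 the F approximation is exact with df1 = p outcomes
    and df2 = N - rank(X) - p + 1.
    """
    cols = [group, covariate] + list(outcomes)
    work = data[cols].dropna()
    n = len(work)
    p = len(outcomes)
    if n < p + 3:
        raise AnalysisError(f"need at least p + rank(X) = {p + 3} complete rows")

    levels = sorted(work[group].unique())
    if len(levels) != 2:
        raise AnalysisError(f"group must have 2 levels, found {levels}")
    g = (work[group] == levels[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), g, work[covariate].to_numpy(dtype=float)])
    Y = work[list(outcomes)].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise AnalysisError("design matrix is rank-deficient")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_e = n - rank

    rows = []
    for effect_name, idx in (("group", 1), (covariate, 2)):
        L = np.zeros((1, X.shape[1]))
        L[0, idx] = 1.0
        LB = L @ B
        M = np.linalg.inv(L @ XtX_inv @ L.T)
        H = LB.T @ M @ LB
        try:
            V = float(np.trace(H @ np.linalg.inv(H + E)))
        except np.linalg.LinAlgError as exc:
            raise AnalysisError("singular error matrix") from exc
        # Pillai F approximation, general s = min(df_h, p) form.
        df_h = 1
        s_ = min(df_h, p)
        m = (abs(p - df_h) - 1) / 2.0
        n_ = (df_e - p - 1) / 2.0
        df1 = int(s_ * (2 * m + s_ + 1))
        df2 = int(s_ * (2 * n_ + s_ + 1))
        F = (df2 / df1) * V / (s_ - V)
        rows.append(
            {
                "effect": effect_name,
                "pillai": V,
                "F": float(F),
                "df1": df1,
                "df2": df2,
                "p": float(sps.f.sf(F, df1, df2)),
            }
        )
    return MancovaResult(table=pd.DataFrame(rows), n=n)


def age_adjusted_means(
    data: pd.DataFrame,
    outcomes: list[str],
    group: str = "group",
    covariate: str = "age_years",
) -> pd.DataFrame:
    """Covariate-adjusted marginal means and SEs per group and outcome.

    For each outcome an ANCOVA (outcome ~ group + covariate) is fitted
    and each group's mean is predicted at the pooled covariate mean.
    """
    rows = []
    for outcome in outcomes:
        work = data[[group, covariate, outcome]].dropna()
        levels = sorted(work[group].unique())
        g = (work[group] == levels[1]).astype(float)
        X = sm.add_constant(
            pd.DataFrame({"g": g, covariate: work[covariate].astype(float)})
        )
        fit = sm.OLS(work[outcome].astype(float), X).fit()
        age_bar = work[covariate].mean()
        for lvl, gval in zip(levels, (0.0, 1.0)):
            pred = fit.get_prediction(
                pd.DataFrame({"const": [1.0], "g": [gval], covariate: [age_bar]})
            )
            rows.append(
                {
                    "measure": outcome,
                    "group": lvl,
                    "adjusted_mean": float(pred.predicted_mean[0]),
                    "se": float(pred.se_mean[0]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def _check_collinearity(X: pd.DataFrame) -> None:
    mat = sm.add_constant(X.astype(float)).to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # Name the offending columns: those whose removal restores rank.
        offending = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(
                sm.add_constant(X.drop(columns=[c]).astype(float)).to_numpy()
            )
            == rank
        ]
        raise AnalysisError(f"collinear design; offending columns: {offending}")


def _fit_step(
    work: pd.DataFrame,
    y: str,
    predictors: list[str],
    label: str,
    prev: RegressionModel | None,
) -> RegressionModel:
    X = work[predictors]
    _check_collinearity(X)
    fit = sm.OLS(work[y].astype(float), sm.add_constant(X.astype(float))).fit()
    sd_y = work[y].std(ddof=1)
    beta = {
        c: float(fit.params[c] * work[c].std(ddof=1) / sd_y) for c in predictors
    }
    coef_p = {c: float(fit.pvalues[c]) for c in predictors}
    model = RegressionModel(
        label=label,
        predictors=list(predictors),
        beta=beta,
        coef_p=coef_p,
        r2=float(fit.rsquared),
        f=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p=float(fit.f_pvalue),
        n=len(work),
    )
    if prev is not None:
        q = len(predictors) - len(prev.predictors)
        dr2 = model.r2 - prev.r2
        denom = (1.0 - model.r2) / model.df2
        delta_f = (dr2 / q) / denom if denom > 0 else math.inf
        model.delta_r2 = dr2
        model.delta_f = float(delta_f)
        model.delta_df = (q, model.df2)
        model.delta_p = float(sps.f.sf(delta_f, q, model.df2))
    return model


def _listwise(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    work = data[cols].dropna().copy()
    if work.empty:
        raise AnalysisError("no complete rows after listwise deletion")
    return work


def _encode_group(work: pd.DataFrame, group: str) -> pd.DataFrame:
    """Code the group factor 0/1 (term = 0, VP = 1) in place."""
    if work[group].dtype == object:
        levels = sorted(work[group].unique())
        if set(levels) == {"VP", "term"}:
            mapping = {"term": 0.0, "VP": 1.0}
        else:
            mapping = {lvl: float(i) for i, lvl in enumerate(levels)}
        work[group] = work[group].map(mapping)
    return work


def hierarchical_stepwise_regression(
    data: pd.DataFrame,
    y: str = "swan_inattention",
    forced: list[str] = ("group", "age_years"),
    candidates: list[str] = ("hit_rate_pct", "sdrt_ms", "v"),
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
) -> list[RegressionModel]:
    """Hierarchical regression: forced block, then stepwise candidates.

    Model 1 contains the forced predictors only.  Candidates then enter
    one at a time: at each iteration the not-yet-entered candidate with
    the smallest partial-F p-value enters if that p <= p_enter, after
    which any entered candidate whose p-value has risen to >= p_remove
    is removed.  Each change of the entered set is reported as a new
    model step with standardized betas, R^2, the increment over the
    previous step, and the overall F.
    """
    forced = list(forced)
    candidates = list(candidates)
    work = _listwise(data, [y] + forced + candidates)
    work = _encode_group(work, forced[0]) if "group" in forced else work

    models = [_fit_step(work, y, forced, "Model 1", None)]
    entered: list[str] = []
    step = 2
    while True:
        changed = False
        # Forward: best candidate by partial-F p-value.
        best_c, best_p = None, None
        for c in candidates:
            if c in entered:
                continue
            trial_fit = sm.OLS(
                work[y].astype(float),
                sm.add_constant(work[forced + entered + [c]].astype(float)),
            ).fit()
            pv = float(trial_fit.pvalues[c])
            if best_p is None or pv < best_p:
                best_c, best_p = c, pv
        if best_c is not None and best_p <= p_enter:
            entered.append(best_c)
            changed = True
            models.append(
                _fit_step(work, y, forced + entered, f"Model {step}", models[-1])
            )
            step += 1
        # Backward: drop any entered candidate that lost significance.
        while entered:
            fit = sm.OLS(
                work[y].astype(float),
                sm.add_constant(work[forced + entered].astype(float)),
            ).fit()
            worst = max(entered, key=lambda c: float(fit.pvalues[c]))
            if float(fit.pvalues[worst]) >= p_remove:
                entered.remove(worst)
                changed = True
                models.append(
                    _fit_step(work, y, forced + entered, f"Model {step}", models[-1])
                )
                step += 1
            else:
                break
        if not changed:
            break
    return models


def interaction_regression(
    data: pd.DataFrame,
    y: str = "swan_inattention",
    measures: list[str] = ("hit_rate_pct", "sdrt_ms", "v"),
    group: str = "group",
    covariate: str = "age_years",
) -> list[RegressionModel]:
    """Forced-entry regression with group-by-measure interactions.

    Three nested steps: {group, covariate}; + measures (mean-centered
    on the analysis sample); + group x centered-measure products.  The
    interaction step's delta-R^2 F test asks whether the
    measure-inattention slopes differ between groups.
    """
    measures = list(measures)
    work = _listwise(data, [y, group, covariate] + measures)
    work = _encode_group(work, group)
    inter_cols = []
    for mcol in measures:
        centered = work[mcol] - work[mcol].mean()
        work[mcol] = centered
        icol = f"{group}_x_{mcol}"
        work[icol] = work[group] * centered
        inter_cols.append(icol)

    step1 = _fit_step(work, y, [group, covariate], "Step 1", None)
    step2 = _fit_step(work, y, [group, covariate] + measures, "Step 2", step1)
    step3 = _fit_step(
        work, y, [group, covariate] + measures + inter_cols, "Step 3", step2
    )
    return [step1, step2, step3]
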