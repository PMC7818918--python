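"""Group comparisons and the nonadherence risk-factor screen.

The statistical battery mirrors a claims-study analysis plan: two-sample
t-tests for mean PDC (Welch by default since the cohort SDs differ;
switchable to pooled), Pearson chi-square on 2x2 adherent/nonadherent
tables without continuity correction, Bonferroni multiplicity control
(m = 9 planned tests, threshold 0.05/9 = 0.00556), then a univariate
logistic screen for nonadherence (PDC < 80%) keeping candidates with
P < 0.1, followed by stepwise (forward entry / backward elimination)
multivariate logistic regression reporting odds ratios with Wald 95% CIs.

Missingness is handled complete-case per variable in the univariate stage
and complete-case across the candidate set in the stepwise stage.
Categorical covariates enter as dummy variables against their most
frequent level, with a likelihood-ratio p-value per variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_M_TESTS = 9
SCREEN_P = 0.1
STEP_ENTRY_P = 0.05
STEP_STAY_P = 0.05


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class LogisticFit:
    variable: str
    odds_ratio: float
    wald_ci_low: float
    wald_ci_high: float
    p_value: float
    stage: str  # univariate | multivariate
    n: int = 0


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, m: int = DEFAULT_M_TESTS) -> float:
    """Per-test significance threshold alpha / m (0.05 / 9 = 0.00556)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_groups(
    values_a,
    values_b,
    kind: str,
    *,
    name: str = "",
    alpha: float = DEFAULT_ALPHA,
    m: int = DEFAULT_M_TESTS,
    equal_var: bool = False,
) -> TestResult:
    """Two-group comparison: ``mean`` -> t-test, ``proportion`` -> chi-square.

    For ``proportion`` the inputs are arrays of 0/1 indicators.  The
    significance flag applies the Bonferroni-adjusted threshold alpha/m.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if kind == "mean":
        if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
            if a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                raise ValueError("zero-variance groups with different means: t-test undefined")
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    elif kind == "proportion":
        table = np.array(
            [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
        )
        degenerate = np.array_equal(table[0] / a.size, table[1] / b.size)
        if degenerate or (table.sum(axis=0) == 0).any():
            # identical proportions, or an empty margin: no discordance to test
            stat, p = 0.0, 1.0
        else:
            stat, p = chi2_2x2(table)
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    threshold = bonferroni_threshold(alpha, m)
    return TestResult(name or kind, float(stat), float(p), bool(p < threshold))


def _design(df: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Model matrix: numeric columns as-is, categoricals as dummies vs mode."""
    pieces = []
    for var in variables:
        col = df[var]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            pieces.append(col.astype(float).rename(var))
        else:
            col = col.astype("object")
            reference = col.mode().iloc[0]
            levels = [lv for lv in pd.unique(col.dropna()) if lv != reference]
            for lv in sorted(map(str, levels)):
                pieces.append(
                    (col.astype(str) == lv).astype(float).rename(f"{var}[{lv}]")
                )
    out = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=df.index)
    return sm.add_constant(out, has_constant="add")


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Logit fit; returns None on separation / non-convergence."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        log.warning("logistic fit failed: %s", exc)
        return None
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
        log.warning("logistic fit did not converge cleanly; excluding")
        return None
    return res


def _variable_p(res, var_cols: list[str]) -> float:
    """Wald p for a single column, likelihood-ratio p for a dummy block."""
    if len(var_cols) == 1:
        return float(res.pvalues[var_cols[0]])
    lr = 2.0 * (res.llf - res.llnull)
    return float(stats.chi2.sf(lr, len(var_cols)))


def univariate_screen(
    covariates: pd.DataFrame,
    nonadherent: pd.Series,
    *,
    screen_p: float = SCREEN_P,
) -> tuple[list[LogisticFit], list[str]]:
    """One single-covariate logistic fit per variable, complete-case each.

    Returns the fits plus the list of candidate variables with P < 0.1 for
    the stepwise stage.  Constant and separation-prone variables are
    excluded with a warning.
    """
    if nonadherent.nunique() < 2:
        raise ValueError("outcome must contain both adherent and nonadherent patients")
    fits: list[LogisticFit] = []
    candidates: list[str] = []
    for var in covariates.columns:
        sub = pd.concat([covariates[var], nonadherent.rename("_y")], axis=1).dropna()
        if sub.empty or sub[var].nunique() < 2 or sub["_y"].nunique() < 2:
            log.warning("variable %s is constant or empty after complete-case; excluded", var)
            continue
        X = _design(sub, [var])
        res = _fit_logit(sub["_y"].astype(float).to_numpy(), X)
        if res is None:
            continue
        var_cols = [c for c in X.columns if c != "const"]
        p = _variable_p(res, var_cols)
        if len(var_cols) == 1:
            coef = float(res.params[var_cols[0]])
            lo, hi = res.conf_int().loc[var_cols[0]]
            or_, ci = float(np.exp(coef)), (float(np.exp(lo)), float(np.exp(hi)))
        else:
            or_, ci = float("nan"), (float("nan"), float("nan"))
        fits.append(LogisticFit(var, or_, ci[0], ci[1], p, "univariate", len(sub)))
        if p < screen_p:
            candidates.append(var)
    return fits, candidates


def stepwise_multivariate(
    covariates: pd.DataFrame,
    nonadherent: pd.Series,
    candidates: list[str],
    *,
    entry_p: float = STEP_ENTRY_P,
    stay_p: float = STEP_STAY_P,
) -> list[LogisticFit]:
    """Forward-entry / backward-elimination logistic selection.

    Entry and removal are judged by likelihood-ratio p-values at the 0.05 /
    0.05 defaults.  The final model's odds ratios with Wald 95% CIs are
    reported per retained term; an empty final model returns [].
    """
    if not candidates:
        raise ValueError("at least one candidate variable required")
    data = pd.concat([covariates[candidates], nonadherent.rename("_y")], axis=1).dropna()
    y = data["_y"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome constant after complete-case restriction")

    def loglik(variables: list[str]) -> tuple[float, int] | None:
        X = _design(data, variables)
        res = _fit_logit(y, X)
        return (res.llf, X.shape[1]) if res is not None else None

    included: list[str] = []
    base = loglik([])
    while True:
        changed = False
        # forward step
        best_var, best_p = None, entry_p
        cur = loglik(included)
        for var in candidates:
            if var in included:
                continue
            trial = loglik(included + [var])
            if trial is None or cur is None:
                continue
            df_diff = trial[1] - cur[1]
            p_add = float(stats.chi2.sf(2.0 * (trial[0] - cur[0]), max(df_diff, 1)))
            if p_add < best_p:
                best_var, best_p = var, p_add
        if best_var is not None:
            included.append(best_var)
            changed = True
        # backward step
        if included:
            full = loglik(included)
            worst_var, worst_p = None, stay_p
            for var in included:
                reduced = loglik([v for v in included if v != var])
                if full is None or reduced is None:
                    continue
                df_diff = full[1] - reduced[1]
                p_drop = float(stats.chi2.sf(2.0 * (full[0] - reduced[0]), max(df_diff, 1)))
                if p_drop > worst_p:
                    worst_var, worst_p = var, p_drop
            if worst_var is not None:
                included.remove(worst_var)
                changed = True
                if worst_var == best_var:
                    break  # add/remove cycle: stop
        if not changed:
            break

    if not included:
        log.warning("no variable entered the stepwise model")
        return []
    X = _design(data, included)
    res = _fit_logit(y, X)
    if res is None:
        return []
    out: list[LogisticFit] = []
    conf = res.conf_int()
    for col in X.columns:
        if col == "const":
            continue
        coef = float(res.params[col])
        lo, hi = conf.loc[col]
        out.append(
            LogisticFit(
                col,
                float(np.exp(coef)),
                float(np.exp(lo)),
                float(np.exp(hi)),
                float(res.pvalues[col]),
                "multivariate",
                len(data),
            )
        )
    return out


def risk_factor_table(
    univariate: list[LogisticFit], multivariate: list[LogisticFit]
) -> pd.DataFrame:
    """Table-5-shaped summary: variable, univariate p, multivariate p, OR (CI)."""
    multi = {f.variable.split("[")[0]: f for f in multivariate}
    rows = []
    for f in univariate:
        m = multi.get(f.variable)
        rows.append(
            {
                "variable": f.variable,
                "univariate_p": f.p_value,
                "multivariate_p": m.p_value if m else np.nan,
                "odds_ratio": m.odds_ratio if m else np.nan,
                "ci_low": m.wald_ci_low if m else np.nan,
                "ci_high": m.wald_ci_high if m else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
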