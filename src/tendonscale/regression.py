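"""Statistical pipeline for the multiscale variable table.

Implements the ledger of procedures applied to per-specimen data: the
2.2*IQR outlier fence, a bivariate Pearson screen of candidate predictors,
backward stepwise multiple linear regression with a collinearity tolerance
gate (a predictor is excluded when 1 - R_k^2 < 0.01 against the other
predictors), and the Durbin-Watson statistic on the final residuals (values
below 1.08 flag serial correlation / collinearity problems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class StepwiseResult:
    retained: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    f_pvalue: float
    durbin_watson: float
    dw_flag: bool                       # True when DW < 1.08
    removal_trace: pd.DataFrame         # step, action, term, p_value
    gated_out: list[str]                # terms removed by the tolerance gate
    base_terms: dict[str, str]          # design column -> source variable


def detect_outliers(column, fence: float = 2.2) -> np.ndarray:
    """Boolean mask of values beyond ``fence`` * IQR outside [Q1, Q3].

    A zero-IQR (constant) column flags nothing — the rule is vacuous there.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 observations for quartile fences")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return (x > q3 + fence * iqr) | (x < q1 - fence * iqr)


def _design(table: pd.DataFrame, outcome: str,
            candidates: list[str] | None = None
            ) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Numeric design matrix with treatment-coded categoricals.

    Reference levels are the first-listed (uninjured / quasi-static in the
    standard schema).  Returns (X, y, column -> source variable map).
    """
    if candidates is None:
        candidates = [c for c in table.columns if c != outcome]
    y = table[outcome].astype(float)
    cols = {}
    source = {}
    for c in candidates:
        s = table[c]
        if pd.api.types.is_numeric_dtype(s):
            cols[c] = s.astype(float)
            source[c] = c
        else:
            levels = pd.unique(s)
            for lv in levels[1:]:
                name = f"{c}[{lv}]"
                cols[name] = (s == lv).astype(float)
                source[name] = c
    X = pd.DataFrame(cols, index=table.index)
    return X, y, source


def pearson_screen(table: pd.DataFrame, outcome: str,
                   candidates: list[str] | None = None) -> pd.DataFrame:
    """Pearson r and two-sided p for every candidate against the outcome.

    Categorical candidates are screened through their binary indicator
    columns.  Zero-variance columns are excluded with a warning.
    """
    from scipy import stats
    X, y, source = _design(table, outcome, candidates)
    rows = []
    for c in X.columns:
        x = X[c].to_numpy()
        if np.std(x) == 0:
            warnings.warn(f"column {c!r} has zero variance; excluded from screen")
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"term": c, "variable": source[c], "r": r, "p": p})
    return pd.DataFrame(rows).set_index("term")


def durbin_watson(residuals) -> float:
    """DW = sum (e_i - e_{i-1})^2 / sum e_i^2 on ordered residuals; range [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need >= 3 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ZeroDivisionError("all residuals are zero; DW undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def tolerance_gate(X: pd.DataFrame, tolerance_min: float = 0.01
                   ) -> tuple[list[str], list[str]]:
    """Iteratively drop columns whose tolerance 1 - R_k^2 falls below the gate.

    R_k^2 is the coefficient of determination of column k regressed on the
    remaining columns; near-duplicate columns (tolerance ~ 0) are removed one
    at a time until every survivor passes.
    """
    keep = list(X.columns)
    gated = []
    while len(keep) > 1:
        worst, worst_tol = None, np.inf
        Xk = X[keep].to_numpy()
        for i, c in enumerate(keep):
            others = np.delete(Xk, i, axis=1)
            A = np.column_stack([np.ones(len(Xk)), others])
            beta, *_ = np.linalg.lstsq(A, Xk[:, i], rcond=None)
            resid = Xk[:, i] - A @ beta
            tss = np.sum((Xk[:, i] - Xk[:, i].mean()) ** 2)
            tol = float(resid @ resid / tss) if tss > 0 else 0.0
            if tol < worst_tol:
                worst, worst_tol = c, tol
        if worst_tol >= tolerance_min:
            break
        keep.remove(worst)
        gated.append(worst)
    return keep, gated


def backward_stepwise(table: pd.DataFrame, outcome: str,
                      candidates: list[str] | None = None,
                      p_enter: float = 0.05, p_remove: float = 0.10,
                      tolerance_min: float = 0.01,
                      allow_reentry: bool = True,
                      screen_alpha: float | None = None) -> StepwiseResult:
    """Backward stepwise OLS with tolerance gating and optional re-entry.

    Starts from all candidates passing the collinearity tolerance gate (and,
    when ``screen_alpha`` is given, a bivariate Pearson pre-screen at that
    level).  Each step removes the predictor with the largest partial-F
    p-value above ``p_remove``; previously removed predictors may re-enter
    when their add-one p-value falls below ``p_enter``.  The Durbin-Watson
    statistic of the final residuals is reported, flagged below 1.08.
    """
    X, y, source = _design(table, outcome, candidates)
    n = len(y)
    if n <= X.shape[1] + 2:
        raise ValueError("need n > number of candidate terms + 2")
    zero_var = [c for c in X.columns if X[c].std() == 0]
    X = X.drop(columns=zero_var)

    if screen_alpha is not None:
        scr = pearson_screen(table, outcome, candidates)
        passed = set(scr.index[scr["p"] < screen_alpha])
        X = X[[c for c in X.columns if c in passed]]

    keep, gated = tolerance_gate(X, tolerance_min)
    X = X[keep]
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()])) \
            < X.shape[1] + 1:
        raise np.linalg.LinAlgError(
            f"singular design even after tolerance gate: columns {list(X.columns)}")

    current = list(X.columns)
    removed: list[str] = []
    trace = []
    step = 0

    def fit(cols):
        A = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, A).fit()

    while True:
        step += 1
        changed = False
        if current:
            model = fit(current)
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                current.remove(worst)
                removed.append(worst)
                trace.append({"step": step, "action": "remove", "term": worst,
                              "p_value": float(pvals[worst])})
                changed = True
        if allow_reentry and removed:
            best, best_p = None, np.inf
            for c in removed:
                m = fit(current + [c])
                p = float(m.pvalues[c])
                if p < best_p:
                    best, best_p = c, p
            if best is not None and best_p < p_enter:
                removed.remove(best)
                current.append(best)
                trace.append({"step": step, "action": "enter", "term": best,
                              "p_value": best_p})
                changed = True
        if not changed:
            break

    model = fit(current) if current else fit([])
    resid = model.resid.to_numpy()
    dw = durbin_watson(resid)
    coefs = model.params
    retained_vars = sorted({source[c] for c in current})
    return StepwiseResult(
        retained=retained_vars,
        coefficients=coefs,
        std_errors=model.bse,
        p_values=model.pvalues,
        r_squared=float(model.rsquared),
        f_pvalue=float(model.f_pvalue) if current else np.nan,
        durbin_watson=dw,
        dw_flag=bool(dw < 1.08),
        removal_trace=pd.DataFrame(trace,
                                   columns=["step", "action", "term", "p_value"]),
        gated_out=[source[c] for c in gated],
        base_terms=source)
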