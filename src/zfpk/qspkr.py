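"""Quantitative structure–pharmacokinetic relationship (QSPkR) analysis.

Relates per-compound PK quantities (Q, RE over a window, ke, t1/2) to
molecular descriptors.  The workflow is the classical small-n QSPR one:

1. screen the descriptor table for collinearity and keep only groups of
   mutually low-correlated descriptors;
2. fit candidate multiple linear regressions, in particular the
   centered-quadratic lipophilicity model

       y = b0 + b1·LogD + b2·(LogD − mean(LogD))²

   which captures the parabolic dependence of uptake on LogD (centering
   the square at the sample mean decorrelates it from the linear term;
   predictions are invariant to the centering constant);
3. optionally search candidate terms by bidirectional stepwise AIC and
   report a model only when its overall F-test clears significance.

With only seven compounds, candidate models are capped at three
estimated coefficients so at least three residual degrees of freedom
remain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionModel",
    "covariance_screen",
    "fit_centered_quadratic",
    "fit_linear_model",
    "stepwise_select",
    "regression_stats",
    "models_to_frame",
]

DESCRIPTOR_COLUMNS = ("LogD", "MW", "TPSA", "MR", "HBA", "HBD", "rotor")

#: maximum estimated coefficients (incl. intercept) for n = 7 panels
MAX_MODEL_PARAMS = 3


@dataclass(frozen=True)
class RegressionModel:
    """A fitted linear model with its summary statistics.

    ``terms`` are the non-intercept regressor names; a name like
    ``"(LogD-c)^2"`` denotes the square of LogD centered at ``center``.
    ``p_value`` is the overall F-test against the intercept-only model
    (NaN for the intercept-only model itself).
    """

    response: str
    terms: tuple[str, ...]
    center: float
    coefficients: dict[str, float]      # includes "intercept"
    r2: float
    r2_adj: float
    rmse: float
    p_value: float
    n: int
    aic: float = float("nan")

    def predict(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _design_matrix(x, self.terms, self.center)
        beta = np.array([self.coefficients["intercept"]]
                        + [self.coefficients[t] for t in self.terms])
        return X @ beta


def _design_matrix(x, terms: tuple[str, ...], center: float) -> np.ndarray:
    """Build [1, terms...] columns; squared terms derive from their base column."""
    if isinstance(x, pd.DataFrame):
        get = lambda name: x[name].to_numpy(dtype=float)
        n = len(x)
    else:
        arr = np.asarray(x, dtype=float)
        get = lambda name: arr
        n = arr.size
    cols = [np.ones(n)]
    for term in terms:
        if term.endswith("^2") and term.startswith("("):
            base = term[1:term.index("-c)^2")] if "-c)^2" in term else term[1:-3]
            cols.append((get(base) - center) ** 2)
        else:
            cols.append(get(term))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(beta, SSE, SST) by least squares; raises on rank deficiency."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    return beta, sse, sst


def regression_stats(sse: float, sst: float, n: int, p: int) -> tuple[float, float, float, float, float]:
    """(r2, r2_adj, rmse, F, p_value) for a model with p non-intercept terms.

    r2_adj = 1 − (1 − r2)(n − 1)/(n − p − 1); rmse = sqrt(SSE/(n − p − 1));
    F = (SSR/p)/(SSE/(n − p − 1)) with the p-value from F(p, n − p − 1).
    """
    if sst == 0:
        raise ZeroDivisionError("response has zero variance; R^2 undefined")
    dof = n - p - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    rmse = np.sqrt(sse / dof)
    if p == 0:
        return r2, r2_adj, rmse, np.nan, np.nan
    ssr = sst - sse
    if sse == 0:
        return r2, r2_adj, rmse, np.inf, 0.0
    f = (ssr / p) / (sse / dof)
    p_value = float(stats.f.sf(f, p, dof))
    return r2, r2_adj, rmse, float(f), p_value


def _gaussian_aic(sse: float, n: int, k: int) -> float:
    """AIC with the concentrated Gaussian log-likelihood: n·log(SSE/n) + 2k.

    k counts estimated mean-model coefficients (intercept + terms).
    """
    sse = max(sse, 1e-300)
    return n * np.log(sse / n) + 2 * k


def covariance_screen(
    table: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[list[str]], pd.DataFrame]:
    """Partition descriptors into groups with pairwise |Pearson r| <= threshold.

    Constant columns are excluded with a warning.  Returns the groups (a
    greedy first-fit partition in column order) and the full correlation
    matrix of the non-constant descriptors.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 compounds to screen correlations")
    usable = []
    for col in table.columns:
        if np.isclose(table[col].std(ddof=1), 0.0):
            warnings.warn(f"descriptor {col!r} is constant; excluded from screen",
                          UserWarning, stacklevel=2)
        else:
            usable.append(col)
    corr = table[usable].corr(method="pearson")
    groups: list[list[str]] = []
    for col in usable:
        for group in groups:
            if all(abs(corr.loc[col, other]) <= threshold for other in group):
                group.append(col)
                break
        else:
            groups.append([col])
    return groups, corr


def fit_linear_model(
    table: pd.DataFrame,
    y: np.ndarray,
    terms: tuple[str, ...],
    response_name: str = "y",
    center: float | None = None,
) -> RegressionModel:
    """OLS of y on an intercept plus the named terms.

    Squared terms (names ending ``^2``) are centered at ``center``; when
    ``center`` is None it defaults to the sample mean of LogD (recomputed
    from the data, never hard-coded).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if center is None:
        center = float(table["LogD"].mean()) if "LogD" in table else 0.0
    X = _design_matrix(table, terms, center)
    if n < X.shape[1] + 1:
        raise ValueError(f"n = {n} too small for {X.shape[1]} coefficients")
    beta, sse, sst = _ols(X, y)
    p = len(terms)
    r2, r2_adj, rmse, _, p_value = regression_stats(sse, sst, n, p)
    coef = {"intercept": float(beta[0])}
    coef.update({t: float(b) for t, b in zip(terms, beta[1:])})
    return RegressionModel(
        response=response_name, terms=tuple(terms), center=center,
        coefficients=coef, r2=r2, r2_adj=r2_adj, rmse=float(rmse),
        p_value=p_value, n=n, aic=_gaussian_aic(sse, n, p + 1),
    )


def fit_centered_quadratic(
    x: np.ndarray, y: np.ndarray, response_name: str = "y"
) -> RegressionModel:
    """The lipophilicity model: y ~ 1 + LogD + (LogD − mean)²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4 for a 3-parameter model")
    if np.isclose(x.std(ddof=1), 0.0):
        raise np.linalg.LinAlgError("all LogD values equal; design is singular")
    table = pd.DataFrame({"LogD": x})
    return fit_linear_model(table, y, ("LogD", "(LogD-c)^2"), response_name)


def stepwise_select(
    table: pd.DataFrame,
    y: np.ndarray,
    response_name: str = "y",
    candidates: tuple[str, ...] | None = None,
    include_squares: tuple[str, ...] = ("LogD",),
    alpha: float = 0.05,
    max_params: int = MAX_MODEL_PARAMS,
) -> RegressionModel | None:
    """Bidirectional stepwise search minimizing AIC from the intercept-only model.

    Candidate terms are the table columns (plus centered squares of the
    ``include_squares`` columns); models are capped at ``max_params``
    estimated coefficients.  The winning model is reported only when its
    overall F-test p-value is below ``alpha``; otherwise None (no
    significant model), which is also returned when nothing beats the
    intercept-only AIC.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if candidates is None:
        candidates = tuple(table.columns)
    terms = list(candidates) + [f"({c}-c)^2" for c in include_squares if c in candidates]
    if n <= len(terms):
        warnings.warn(
            f"{response_name}: n = {n} <= {len(terms)} candidate terms; "
            "search restricted to small models", UserWarning, stacklevel=2)
    max_terms = min(max_params - 1, n - 2)
    center = float(table["LogD"].mean()) if "LogD" in table else 0.0

    def score(selected: tuple[str, ...]) -> float:
        X = _design_matrix(table, selected, center)
        try:
            _, sse, _ = _ols(X, y)
        except np.linalg.LinAlgError:
            return np.inf
        return _gaussian_aic(sse, n, len(selected) + 1)

    current: tuple[str, ...] = ()
    current_aic = score(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, tuple[str, ...]]] = []
        if len(current) < max_terms:
            for t in terms:
                if t not in current:
                    cand = current + (t,)
                    moves.append((score(cand), cand))
        for t in current:
            cand = tuple(u for u in current if u != t)
            moves.append((score(cand), cand))
        if moves:
            best_aic, best = min(moves, key=lambda m: m[0])
            if best_aic < current_aic - 1e-12:
                current, current_aic = best, best_aic
                improved = True

    if not current:
        return None
    model = fit_linear_model(table, y, current, response_name, center=center)
    if not (model.p_value < alpha):
        return None
    return model


def models_to_frame(models: "dict[str, RegressionModel | None]") -> pd.DataFrame:
    """Tidy report, one row per response (significant models only)."""
    rows = []
    for response, m in models.items():
        if m is None:
            rows.append({"response": response, "model": "none significant",
                         "r2_adj": np.nan, "rmse": np.nan, "p_value": np.nan})
            continue
        formula = " + ".join(
            [f"{m.coefficients['intercept']:.4g}"]
            + [f"{m.coefficients[t]:.4g}*{t}" for t in m.terms]
        )
        rows.append({"response": response, "model": formula, "r2_adj": m.r2_adj,
                     "rmse": m.rmse, "p_value": m.p_value})
    return pd.DataFrame(rows)
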