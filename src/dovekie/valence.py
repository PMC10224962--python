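"""Contextual-valence attribution and its effect on call acoustics.

Valence of the production context is assigned from fitness reasoning:
contexts that promote fitness (interactions with the social partner) are
assumed to elicit positive states, contexts that threaten fitness
(predator presence, human handling) negative ones.  Only calls of clear
positive or negative valence enter inference; *likely negative* and
*unknown* calls are carried through descriptive outputs but excluded.

Two inferential stages:

* a MANOVA of the first five PC scores on valence with call type as a
  control fixed factor (Pillai's trace).  Call type is nested within
  valence here (clucking is the only positive type; terror and handling
  the negative ones), so the two factors are partially aliased; sums of
  squares are sequential (Type I) with valence entered first.
* per-parameter ordinary least squares of each selected acoustic
  parameter on valence, negative as the reference level, so the intercept
  is the negative-valence mean and the effect the positive-minus-negative
  difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as slinalg
from scipy import stats as sstats
import statsmodels.api as sm

__all__ = [
    "VALENCE_BY_TYPE",
    "VALENCE_MODEL_PARAMETERS",
    "ValenceModelResult",
    "ManovaResult",
    "assign_valence",
    "add_valence",
    "valence_subset",
    "manova_on_pcs",
    "fit_valence_models",
    "valence_report",
]

#: Assigned contextual valence per call type.
VALENCE_BY_TYPE: dict[str, str] = {
    "clucking": "positive",
    "terror": "negative",
    "handling": "negative",
    "low_trill": "likely_negative",
    "short": "likely_negative",
    "short_trill": "likely_negative",
    "single": "unknown",
    "classic": "unknown",
}

VALENCE_LEVELS = ("positive", "negative", "likely_negative", "unknown")

#: Parameters entered into the per-parameter linear models (selected for
#: contributing > 6% to the first five PCA dimensions in the original
#: analysis).
VALENCE_MODEL_PARAMETERS = (
    "f0_max", "f0_mean", "f0_range", "q50", "f0_abs_slope", "f0_var",
    "f0_end", "duration",
)


def assign_valence(call_type: str, context: str | None = None) -> str:
    """Deterministic call-type -> valence mapping.

    ``context`` is accepted for interface symmetry (the mapping is defined
    at the level of call types, whose definitions subsume their most
    common production context).
    """
    try:
        return VALENCE_BY_TYPE[call_type]
    except KeyError:
        raise ValueError(
            f"unknown call_type {call_type!r}; expected one of "
            f"{sorted(VALENCE_BY_TYPE)}") from None


def add_valence(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``valence`` column derived from ``call_type``."""
    out = table.copy()
    out["valence"] = [assign_valence(ct) for ct in out["call_type"]]
    return out


def valence_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Rows of clear positive or negative valence (the inferential set).

    With the full 8-type, 30-calls-per-type design this keeps 90 calls:
    30 clucking (positive) + 30 terror + 30 handling (negative).
    """
    if "valence" not in table.columns:
        table = add_valence(table)
    sub = table[table["valence"].isin(["positive", "negative"])].copy()
    if len(sub) == 0:
        raise ValueError("no calls of positive or negative valence")
    if sub["valence"].nunique() < 2:
        import warnings
        warnings.warn("only one valence level present; contrasts undefined",
                      stacklevel=2)
    return sub.reset_index(drop=True)


@dataclass
class ManovaResult:
    """Pillai's trace test of one model term."""

    term: str
    pillai: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float

    def summary(self) -> dict[str, float]:
        return {"term": self.term, "pillai": self.pillai, "F": self.f_value,
                "df_num": self.df_num, "df_den": self.df_den,
                "p": self.p_value}


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _resid_sscp(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual SSCP of the multivariate least-squares fit and rank(X)."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R, int(rank)


def _pillai_f(H: np.ndarray, E: np.ndarray, df_h: int, df_e: int
              ) -> tuple[float, float, float, float, float]:
    """Pillai's trace and its standard F approximation."""
    p = H.shape[0]
    # generalized symmetric eigenproblem H v = theta (H+E) v; H+E is PD
    theta = slinalg.eigh(H, H + E, eigvals_only=True)
    V = float(np.clip(theta, 0.0, 1.0).sum())
    s = min(p, df_h)
    m = (abs(p - df_h) - 1) / 2.0
    n = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    if df2 <= 0 or V >= s:
        raise ValueError("degenerate MANOVA: insufficient error df")
    F = (df2 / df1) * V / (s - V)
    pval = float(sstats.f.sf(F, df1, df2))
    return V, F, df1, df2, pval


def manova_on_pcs(pcs: pd.DataFrame | np.ndarray, valence: pd.Series | np.ndarray,
                  call_type: pd.Series | np.ndarray) -> ManovaResult:
    """Sequential MANOVA of PC scores on valence, controlling call type.

    The model is ``PCs ~ valence + call_type`` with Type-I (sequential)
    sums of squares and valence entered first: the valence hypothesis SSCP
    is the reduction in residual SSCP from adding valence to the intercept
    model, and the error SSCP comes from the full model.  This is the only
    well-defined ordering here because each call type carries exactly one
    valence (the factors are partially aliased).  Returns Pillai's trace
    with its F approximation for the valence term.
    """
    Y = np.asarray(pcs, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    val = np.asarray(valence)
    ct = np.asarray(call_type)
    if len(np.unique(val)) < 2:
        raise ValueError("need at least 2 valence levels")
    n = Y.shape[0]
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("degenerate MANOVA: responses have no variance")
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, _dummies(val)])
    X2 = np.hstack([X1, _dummies(ct)])
    E0, r0 = _resid_sscp(Y, ones)
    E1, r1 = _resid_sscp(Y, X1)
    E2, r2 = _resid_sscp(Y, X2)
    H = E0 - E1
    df_h = r1 - r0
    df_e = n - r2
    V, F, df1, df2, pval = _pillai_f(H, E2, df_h, df_e)
    return ManovaResult(term="valence", pillai=V, f_value=F,
                        df_num=df1, df_den=df2, p_value=pval)


@dataclass
class ValenceModelResult:
    """One parameter's linear model on valence (negative = reference)."""

    parameter: str
    intercept_estimate: float
    intercept_ci: tuple[float, float]
    intercept_p: float
    effect_estimate: float
    effect_ci: tuple[float, float]
    effect_p: float
    r2: float
    r2_adj: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.intercept_ci[0] > self.intercept_ci[1]:
            raise ValueError("intercept CI bounds out of order")
        if self.effect_ci[0] > self.effect_ci[1]:
            raise ValueError("effect CI bounds out of order")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 out of [0, 1]")


def fit_valence_models(table: pd.DataFrame,
                       parameters: tuple[str, ...] | list[str] | None = None
                       ) -> list[ValenceModelResult]:
    """Per-parameter OLS of raw acoustic values on valence.

    ``parameter ~ valence`` with negative valence as the reference level,
    so the intercept estimates the negative-valence mean and the effect
    the positive-minus-negative difference (for a single binary factor
    these equal the group sample means exactly).  95% CIs are Wald
    t-intervals.  Parameters absent from the table are skipped.
    """
    if "valence" not in table.columns:
        table = add_valence(table)
    sub = table[table["valence"].isin(["positive", "negative"])]
    levels = set(sub["valence"].unique())
    if levels != {"positive", "negative"}:
        raise ValueError(f"need both valence levels, got {sorted(levels)}")
    if parameters is None:
        parameters = [p for p in VALENCE_MODEL_PARAMETERS if p in sub.columns]
    results = []
    x = (sub["valence"] == "positive").to_numpy(dtype=float)
    X = sm.add_constant(x)
    for param in parameters:
        if param not in sub.columns:
            continue
        fit = sm.OLS(sub[param].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int(alpha=0.05)
        results.append(ValenceModelResult(
            parameter=param,
            intercept_estimate=float(fit.params[0]),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            intercept_p=float(fit.pvalues[0]),
            effect_estimate=float(fit.params[1]),
            effect_ci=(float(ci[1, 0]), float(ci[1, 1])),
            effect_p=float(fit.pvalues[1]),
            r2=float(fit.rsquared),
            r2_adj=float(fit.rsquared_adj),
            n_obs=int(fit.nobs)))
    if not results:
        raise ValueError("no requested parameters present in the table")
    return results


def valence_report(results: list[ValenceModelResult]) -> pd.DataFrame:
    """Arrange model results as a table of estimates, CIs, p, and R²."""
    rows = []
    for r in results:
        rows.append({
            "parameter": r.parameter,
            "negative_intercept": r.intercept_estimate,
            "intercept_ci_low": r.intercept_ci[0],
            "intercept_ci_high": r.intercept_ci[1],
            "intercept_p": r.intercept_p,
            "positive_effect": r.effect_estimate,
            "effect_ci_low": r.effect_ci[0],
            "effect_ci_high": r.effect_ci[1],
            "effect_p": r.effect_p,
            "r2": r.r2,
            "r2_adj": r.r2_adj,
            "n_obs": r.n_obs,
        })
    return pd.DataFrame(rows)
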