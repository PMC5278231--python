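"""Quartile association, trend, ROC/AUC, and inflammation-marker models.

Logistic regression of MetS on OBS quartile indicators (Q1 reference) with
age, sex, area and BMI adjustment; a linear-trend test entering the quartile
as an ordinal score; rank-based AUC of the fitted model; and ordinary least
squares of inflammation markers (log CRP, WBC) on the same design.  Wald
intervals and p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .obs import QUARTILE_LABELS

DEFAULT_COVARIATES = ["age", "sex", "area", "bmi"]


@dataclass
class QuartileLogisticResult:
    rows: pd.DataFrame            # quartile, n_cases, n_controls, or, ci, p
    p_trend: float
    auc: float
    scheme: str


def _quartile_design(quartile: pd.Series,
                     covariates: pd.DataFrame | None) -> pd.DataFrame:
    dummies = pd.get_dummies(quartile, prefix="", prefix_sep="")
    dummies = dummies.reindex(columns=QUARTILE_LABELS, fill_value=0)
    X = dummies[QUARTILE_LABELS[1:]].astype(float)   # Q1 is the reference
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_quartile_logistic(status: pd.Series, quartile: pd.Series,
                          covariates: pd.DataFrame | None = None, *,
                          scheme: str = "equal") -> QuartileLogisticResult:
    """Logistic model of case status on OBS quartiles (Q1 reference).

    Returns one row per quartile with case/control counts, odds ratio,
    Wald 95% CI and p (Q1 carries OR = 1 with no interval), plus the ordinal
    trend p and the AUC of the fitted probabilities.
    """
    y = status.astype(float)
    counts = pd.crosstab(quartile, y)
    counts = counts.reindex(index=QUARTILE_LABELS, fill_value=0)
    if (counts.min(axis=1) == 0).any():
        bad = counts.index[counts.min(axis=1) == 0].tolist()
        raise ValueError(f"quartiles without both cases and controls: {bad}")

    X = _quartile_design(quartile, covariates)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:
        raise RuntimeError(f"quartile logistic model failed ({scheme}): "
                           f"{exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError(f"quartile logistic model did not converge "
                           f"({scheme})")

    ci = fit.conf_int()
    rows = [{"quartile": "Q1",
             "n_cases": int(counts.loc["Q1", 1.0]),
             "n_controls": int(counts.loc["Q1", 0.0]),
             "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
             "p": np.nan, "scheme": scheme}]
    for q in QUARTILE_LABELS[1:]:
        rows.append({
            "quartile": q,
            "n_cases": int(counts.loc[q, 1.0]),
            "n_controls": int(counts.loc[q, 0.0]),
            "odds_ratio": float(np.exp(fit.params[q])),
            "ci_low": float(np.exp(ci.loc[q, 0])),
            "ci_high": float(np.exp(ci.loc[q, 1])),
            "p": float(fit.pvalues[q]),
            "scheme": scheme,
        })
    table = pd.DataFrame(rows)
    p_trend = trend_test(status, quartile, covariates)
    auc = compute_auc(pd.Series(fit.predict(X), index=y.index), status)
    return QuartileLogisticResult(table, p_trend, auc, scheme)


def trend_test(status: pd.Series, quartile: pd.Series,
               covariates: pd.DataFrame | None = None) -> float:
    """Linear-trend Wald p: quartile entered as a single ordinal 1-4 score."""
    score = quartile.map({q: i + 1 for i, q in enumerate(QUARTILE_LABELS)})
    X = pd.DataFrame({"trend": score.astype(float)})
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.Logit(status.astype(float), X).fit(disp=0, maxiter=100)
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("trend model did not converge")
    return float(fit.pvalues["trend"])


def compute_auc(predicted: pd.Series, status: pd.Series) -> float:
    """Rank-based (Mann-Whitney) AUC of a score against a binary status."""
    y = np.asarray(status, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: outcome has a single class")
    return float(roc_auc_score(y, np.asarray(predicted, dtype=float)))


def fit_marker_linear(marker: pd.Series, quartile: pd.Series,
                      covariates: pd.DataFrame | None = None, *,
                      log_transform: bool = False, offset: float = 0.0,
                      name: str | None = None) -> pd.DataFrame:
    """OLS of an inflammation marker on quartile indicators plus covariates.

    ``log_transform`` applies ``log(marker + offset)`` first (CRP is right
    skewed; WBC is modelled on its raw scale).  Returns one row per quartile
    with the coefficient relative to Q1 (which is 0 by construction), a Wald
    95% CI and p, plus a ``p_trend`` column repeated on every row.
    """
    vals = marker.astype(float)
    if log_transform:
        shifted = vals + offset
        if (shifted <= 0).any():
            raise ValueError("non-positive marker under log transform; "
                             "pass a positive offset")
        vals = np.log(shifted)
    X = _quartile_design(quartile, covariates)
    fit = sm.OLS(vals, X).fit()
    ci = fit.conf_int()

    trend = quartile.map({q: i + 1 for i, q in enumerate(QUARTILE_LABELS)})
    Xt = pd.DataFrame({"trend": trend.astype(float)})
    if covariates is not None:
        Xt = pd.concat([Xt, covariates.astype(float)], axis=1)
    p_trend = float(sm.OLS(vals, sm.add_constant(Xt, has_constant="add"))
                    .fit().pvalues["trend"])

    rows = [{"marker": name or marker.name, "quartile": "Q1",
             "coef": 0.0, "ci_low": np.nan, "ci_high": np.nan,
             "p": np.nan, "p_trend": p_trend}]
    for q in QUARTILE_LABELS[1:]:
        rows.append({"marker": name or marker.name, "quartile": q,
                     "coef": float(fit.params[q]),
                     "ci_low": float(ci.loc[q, 0]),
                     "ci_high": float(ci.loc[q, 1]),
                     "p": float(fit.pvalues[q]),
                     "p_trend": p_trend})
    return pd.DataFrame(rows)


def crude_odds_ratio(n_cases_exposed: int, n_controls_exposed: int,
                     n_cases_ref: int, n_controls_ref: int) -> float:
    """Closed-form 2x2 cross-product odds ratio (no covariates)."""
    return (n_cases_exposed * n_controls_ref) / (n_controls_exposed
                                                 * n_cases_ref)
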