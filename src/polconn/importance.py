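"""Variable importance via L1-penalized logistic regression.

The LASSO's selection property shrinks uninformative predictor
coefficients to exactly zero; the absolute value of a surviving
coefficient (on the standardized-predictor scale) is that predictor's
importance. The penalty strength is chosen by cross-validated binomial
deviance over a geometric penalty path. Selected variables are then refit
in an unpenalized logistic regression for interpretable coefficients, Wald
standard errors and two-sided p-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV


def lasso_importance(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_penalties: int = 50,
    one_se_rule: bool = False,
) -> pd.DataFrame:
    """Rank predictors by |L1-penalized coefficient| at the CV-chosen penalty.

    Features are standardized to unit variance inside the call, so the
    importance ranking is invariant to affine rescaling of the raw
    predictors. Predictors whose coefficient is exactly zero at the chosen
    penalty are dropped. With ``one_se_rule`` the sparsest penalty within
    one standard error of the best CV deviance is used instead of the
    minimizer.

    Returns a frame with columns variable, importance, sorted descending.
    """
    X = features.to_numpy(float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = features.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance feature: {bad!r}")
    Xs = (X - X.mean(axis=0)) / sd

    Cs = np.geomspace(1e-3, 1e2, n_penalties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        cv = LogisticRegressionCV(
            Cs=Cs,
            cv=n_folds,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=2000,
            refit=False,
        )
        cv.fit(Xs, y)
        scores = cv.scores_[1]  # folds x penalties, higher is better
        mean_score = scores.mean(axis=0)
        best = int(np.argmax(mean_score))
        if one_se_rule:
            se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
            ok = mean_score >= mean_score[best] - se[best]
            best = int(np.flatnonzero(ok)[0])  # smallest C (strongest penalty)
        final = LogisticRegressionCV(
            Cs=[Cs[best]],
            cv=n_folds,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=2000,
        )
        final.fit(Xs, y)
    coefs = pd.Series(final.coef_[0], index=features.columns)
    table = (
        pd.DataFrame({"variable": features.columns, "importance": coefs.abs().values})
        .loc[lambda d: d["importance"] > 0]
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    if table.empty:
        warnings.warn("all penalized coefficients are zero; empty importance table")
    return table


def refit_selected(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    selected: list[str],
) -> pd.DataFrame:
    """Unpenalized logistic refit of the selected variables.

    Returns a frame with columns variable, coefficient, se, p_value (Wald,
    two-sided, uncorrected). Perfect separation is flagged by statsmodels
    and re-raised with context.
    """
    if len(selected) == 0:
        raise ValueError("no variables selected; refusing intercept-only refit")
    X = sm.add_constant(features[list(selected)].to_numpy(float))
    y = np.asarray(labels, dtype=int)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as err:  # statsmodels raises on perfect separation
        raise RuntimeError(f"logistic refit failed (separation?): {err}") from err
    return pd.DataFrame(
        {
            "variable": selected,
            "coefficient": fit.params[1:],
            "se": fit.bse[1:],
            "p_value": fit.pvalues[1:],
        }
    ).reset_index(drop=True)


def importance_table(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full importance report: LASSO ranking plus unpenalized refit columns."""
    ranked = lasso_importance(features, labels, n_folds=n_folds, seed=seed)
    if ranked.empty:
        return ranked.assign(coefficient=[], se=[], p_value=[])
    try:
        refit = refit_selected(features, labels, list(ranked["variable"]))
    except (RuntimeError, np.linalg.LinAlgError) as err:
        warnings.warn(f"unpenalized refit failed ({err}); reporting LASSO "
                      "importances without coefficients")
        return ranked.assign(coefficient=np.nan, se=np.nan, p_value=np.nan)
    return ranked.merge(refit, on="variable")
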