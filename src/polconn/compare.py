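"""Monte Carlo cross-validated comparison of logistic ideology classifiers.

Ideology is dichotomized (Likert 1-3 liberal, 4-6 conservative) and
candidate predictor sets — out-of-fold task scores, survey covariates,
combinations, and a parent-conservatism benchmark — are compared by
repeated random train/test splits with a randomly drawn test fraction.
Within each Monte Carlo sample every model sees the identical split, so
comparisons are paired. Models are summarized by mean AUC, its SD and a
percentile 95% CI, and classified against the benchmark by CI disjointness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .containers import SURVEY_COVARIATES, IdeologyScoreMatrix

#: Survey predictors used in the full survey-based model.
SURVEY_MODEL_PREDICTORS: tuple[str, ...] = (
    "age",
    "education",
    "income",
    "origin_city_conservatism",
    "current_city_conservatism",
    "parent_income",
    "mother_conservatism",
    "father_conservatism",
)

#: Variant including sex.
SURVEY_MODEL_PREDICTORS_WITH_SEX: tuple[str, ...] = ("male",) + SURVEY_MODEL_PREDICTORS

PARENT_CONSERVATISM_PREDICTORS: tuple[str, ...] = (
    "mother_conservatism",
    "father_conservatism",
)


def dichotomize(cohort: pd.DataFrame) -> pd.Series:
    """Binary labels: 1 = conservative (Likert 4-6), 0 = liberal (1-3)."""
    y = cohort["conservatism"].to_numpy()
    if ((y < 1) | (y > 6)).any():
        raise ValueError("ideology must be in 1..6")
    return pd.Series(
        (y >= 4).astype(int), index=cohort["subject_id"].to_numpy(), name="conservative"
    )


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor set over the assembled feature table."""

    name: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.predictors) == 0:
            raise ValueError("predictor set must be non-empty")


def assemble_features(
    scores: IdeologyScoreMatrix | None,
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Join task-score columns with survey covariates, indexed by subject."""
    surv = cohort.set_index("subject_id")[list(SURVEY_COVARIATES)]
    if scores is None:
        return surv
    feats = scores.scores.join(surv, how="inner")
    if len(feats) != len(scores.scores):
        raise ValueError("cohort does not cover all scored subjects")
    return feats


def default_model_specs(task_ids: list[str]) -> list[ModelSpec]:
    """The standard comparison set: per-task FC models, all-task FC model,
    survey model, parent-conservatism benchmark, and the combined model."""
    specs = [ModelSpec(f"fc_{t}", (t,)) for t in task_ids]
    specs += [
        ModelSpec("fc_all_tasks", tuple(task_ids)),
        ModelSpec("survey", SURVEY_MODEL_PREDICTORS),
        ModelSpec("parent_conservatism", PARENT_CONSERVATISM_PREDICTORS),
        ModelSpec("fc_plus_survey", tuple(task_ids) + SURVEY_MODEL_PREDICTORS),
    ]
    return specs


@dataclass
class FittedLogistic:
    """Maximum-likelihood logistic fit (regularized fallback on separation)."""

    coef: np.ndarray
    intercept: float
    predictors: tuple[str, ...]
    separation_flagged: bool = False

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.predictors)].to_numpy(float)
        eta = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def fit_logistic(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    predictors: tuple[str, ...],
) -> FittedLogistic:
    """Fit an (unpenalized) logistic regression on the named predictors.

    Complete or quasi-complete separation makes the ML estimate diverge; it
    is detected via non-convergence or exploding coefficients, flagged, and
    the fit falls back to a lightly ridge-regularized solution.
    """
    X = features[list(predictors)].to_numpy(float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LogisticRegression(C=np.inf, max_iter=500, tol=1e-8)
        model.fit(X, y)
    # ML estimates diverge under separation: flag implausibly large
    # standardized slopes or a solver that hit its iteration cap
    scale = X.std(axis=0)
    flagged = (
        bool(np.abs(model.coef_[0] * np.where(scale > 0, scale, 1.0)).max() > 30)
        or model.n_iter_[0] >= 500
    )
    if flagged:
        model = LogisticRegression(C=1.0, max_iter=1000)
        model.fit(X, y)
    return FittedLogistic(
        coef=model.coef_[0],
        intercept=float(model.intercept_[0]),
        predictors=predictors,
        separation_flagged=flagged,
    )


@dataclass
class ComparisonResult:
    """Per-model Monte Carlo AUC/accuracy vectors with summary statistics."""

    auc: pd.DataFrame  # samples x models
    accuracy: pd.DataFrame  # samples x models
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for name in self.auc.columns:
            a = self.auc[name].to_numpy()
            lo, hi = np.percentile(a, [2.5, 97.5])
            rows.append(
                {
                    "model": name,
                    "mean_auc": a.mean(),
                    "sd_auc": a.std(ddof=1),
                    "ci_low": lo,
                    "ci_high": hi,
                    "mean_accuracy": self.accuracy[name].mean(),
                }
            )
        self.summary = pd.DataFrame(rows).set_index("model")


def monte_carlo_cv(
    models: list[ModelSpec],
    features: pd.DataFrame,
    labels: pd.Series,
    n_samples: int = 1000,
    test_fraction_range: tuple[float, float] = (0.05, 0.50),
    seed: int = 0,
    max_resample: int = 100,
) -> ComparisonResult:
    """Monte Carlo cross-validation shared across models.

    Per sample: draw the test fraction uniformly from
    ``test_fraction_range``, draw a random test set of that size, fit every
    model on the remaining subjects and evaluate test AUC and accuracy
    (probability threshold 0.5). Splits whose test or training set lacks a
    class are redrawn (up to ``max_resample`` times, then an error).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = test_fraction_range
    if not (0 < lo <= hi < 1):
        raise ValueError("test_fraction_range must satisfy 0 < lo <= hi < 1")
    for spec in models:
        missing = [p for p in spec.predictors if p not in features.columns]
        if missing:
            raise ValueError(f"model {spec.name!r} has unknown predictors {missing}")
    y = labels.loc[features.index].to_numpy(int)
    n = len(features)
    rng = np.random.default_rng(seed)

    auc = np.empty((n_samples, len(models)))
    acc = np.empty((n_samples, len(models)))
    warned = False
    for s in range(n_samples):
        for attempt in range(max_resample + 1):
            frac = rng.uniform(lo, hi)
            n_test = max(1, int(round(frac * n)))
            n_test = min(n_test, n - 2)
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if np.unique(y[test_idx]).size == 2 and np.unique(y[train_idx]).size == 2:
                break
            if not warned:
                warnings.warn("redrew a Monte Carlo split with a single class")
                warned = True
        else:
            raise RuntimeError(
                f"could not draw a two-class split in {max_resample} attempts"
            )
        train_feats = features.iloc[train_idx]
        test_feats = features.iloc[test_idx]
        for j, spec in enumerate(models):
            fit = fit_logistic(train_feats, y[train_idx], spec.predictors)
            p = fit.predict_proba(test_feats)
            auc[s, j] = roc_auc_score(y[test_idx], p)
            acc[s, j] = np.mean((p >= 0.5).astype(int) == y[test_idx])

    names = [m.name for m in models]
    return ComparisonResult(
        auc=pd.DataFrame(auc, columns=names),
        accuracy=pd.DataFrame(acc, columns=names),
    )


def compare_to_benchmark(
    result: ComparisonResult, benchmark_name: str = "parent_conservatism"
) -> pd.Series:
    """Classify each model against the benchmark by 95%-CI disjointness.

    'above' if a model's CI lies entirely above the benchmark's, 'below' if
    entirely below, otherwise 'indistinguishable'.
    """
    if benchmark_name not in result.summary.index:
        raise ValueError(f"benchmark {benchmark_name!r} not among compared models")
    b = result.summary.loc[benchmark_name]
    out = {}
    for name, row in result.summary.iterrows():
        if row["ci_low"] > b["ci_high"]:
            out[name] = "above"
        elif row["ci_high"] < b["ci_low"]:
            out[name] = "below"
        else:
            out[name] = "indistinguishable"
    return pd.Series(out, name="vs_benchmark")
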