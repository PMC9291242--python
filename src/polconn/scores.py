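"""Analytics on out-of-fold ideology scores.

Covers: Pearson correlation of each task's scores with true ideology
(overall, and stratified into moderate vs extreme responders), with
Bonferroni correction across tasks; pairwise task-score correlations; and
PCA of the subjects x tasks score matrix to determine the effective
dimension of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IdeologyScoreMatrix

SUBGROUPS = ("overall", "moderate", "extreme")


def stratify_ideology(cohort: pd.DataFrame) -> pd.Series:
    """Label each subject 'extreme' (ideology 1 or 6) or 'moderate' (2-5)."""
    y = cohort["conservatism"].to_numpy()
    if ((y < 1) | (y > 6)).any():
        raise ValueError("ideology must be in 1..6")
    labels = np.where(np.isin(y, (1, 6)), "extreme", "moderate")
    return pd.Series(labels, index=cohort["subject_id"].to_numpy(), name="subgroup")


def _subgroup_mask(cohort: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup not in SUBGROUPS:
        raise ValueError(f"subgroup must be one of {SUBGROUPS}")
    labels = stratify_ideology(cohort)
    if subgroup == "overall":
        return pd.Series(True, index=labels.index)
    return labels == subgroup


def pearson_pvalue_chi2(r: float, n: int) -> float:
    """Chi-squared (1 df) significance of a Pearson correlation.

    Score-test style approximation: n * r^2 ~ chi2(1) under the null.
    Nonstandard; kept as an optional variant of the exact t test.
    """
    return float(stats.chi2.sf(n * r**2, df=1))


def correlate_scores(
    scores: IdeologyScoreMatrix,
    cohort: pd.DataFrame,
    subgroup: str = "overall",
    m_tests: int = 9,
    p_method: str = "t",
) -> pd.DataFrame:
    """Per-task Pearson correlation of scores with true ideology.

    Correlations are computed over the subjects in ``subgroup``; two-sided
    p-values come from the exact t test for Pearson r (``p_method='t'``) or
    from the chi-squared variant (``p_method='chi2'``). The Bonferroni
    column multiplies the raw p by ``m_tests`` and caps at 1.

    Returns a frame with columns task_id, subgroup, n, r, p_raw,
    p_bonferroni.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if p_method not in ("t", "chi2"):
        raise ValueError("p_method must be 't' or 'chi2'")
    mask = _subgroup_mask(cohort, subgroup)
    subjects = [s for s in scores.subject_ids if mask.get(s, False)]
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects in subgroup {subgroup!r}")
    y = cohort.set_index("subject_id").loc[subjects, "conservatism"].to_numpy(float)
    if y.std() == 0:
        raise ValueError("ideology has zero variance in subgroup")
    rows = []
    for task in scores.task_ids:
        x = scores.scores.loc[subjects, task].to_numpy(float)
        if x.std() == 0:
            raise ValueError(f"scores for task {task!r} have zero variance")
        if p_method == "t":
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            p = pearson_pvalue_chi2(r, len(subjects))
        rows.append(
            {
                "task_id": task,
                "subgroup": subgroup,
                "n": len(subjects),
                "r": r,
                "p_raw": p,
                "p_bonferroni": min(1.0, m_tests * p),
            }
        )
    return pd.DataFrame(rows)


def pairwise_score_correlations(
    scores: IdeologyScoreMatrix,
    cohort: pd.DataFrame | None = None,
    subgroup: str = "overall",
) -> pd.DataFrame:
    """Tasks x tasks Pearson correlation matrix of the score columns."""
    if cohort is None:
        subjects = scores.subject_ids
    else:
        mask = _subgroup_mask(cohort, subgroup)
        subjects = [s for s in scores.subject_ids if mask.get(s, False)]
    X = scores.scores.loc[subjects].to_numpy(float)
    if X.std(axis=0).min() == 0:
        raise ValueError("zero-variance score column in subgroup")
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=scores.task_ids, columns=scores.task_ids)


@dataclass
class PCAResult:
    """PCA of the score matrix on the correlation scale.

    ``variance_fraction`` is the percent of total variance per component;
    ``contributions`` gives each task's percent contribution to each
    component, 100 * loading^2 / sum of squared loadings; both sum to 100.
    """

    variance_fraction: np.ndarray  # (n_components,) percent
    contributions: pd.DataFrame  # tasks x components, percent
    component_scores: pd.DataFrame  # subjects x components


def pca_scores(scores: IdeologyScoreMatrix, standardize: bool = True) -> PCAResult:
    """PCA of the subjects x tasks score matrix.

    Columns are centered and (by default) scaled to unit variance, so the
    decomposition is of the task-score correlation matrix and every task
    enters on an equal footing.
    """
    X = scores.scores.to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than tasks for PCA")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = scores.task_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance score column: {bad!r}")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (n - 1)
    variance_fraction = 100.0 * eigvals / eigvals.sum()
    loadings = Vt.T  # unit-norm columns
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    comps = [f"PC{i + 1}" for i in range(p)]
    return PCAResult(
        variance_fraction=variance_fraction,
        contributions=pd.DataFrame(
            contributions, index=scores.task_ids, columns=comps
        ),
        component_scores=pd.DataFrame(
            U * S, index=scores.scores.index, columns=comps
        ),
    )
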