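"""Core data containers shared across the pipeline.

The pipeline moves through four in-memory representations:

* a cohort table (:class:`pandas.DataFrame`) of survey covariates plus the
  6-point liberal-conservative self-placement (1 = Very liberal ... 6 = Very
  conservative);
* :class:`RoiTimeSeries`, ROI-averaged BOLD signal for one subject and task;
* :class:`FCMatrix`, the symmetric functional-connectivity correlation
  matrix derived from one time series;
* :class:`IdeologyScoreMatrix`, out-of-fold continuous ideology predictions,
  one column per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Survey covariates and their integer Likert ranges. ``male`` is binary and
#: ``age`` is in years; every other variable is an ordered Likert response.
LIKERT_RANGES: dict[str, tuple[int, int]] = {
    "male": (0, 1),
    "age": (18, 40),
    "education": (1, 5),
    "father_education": (1, 5),
    "mother_education": (1, 5),
    "father_conservatism": (1, 6),
    "mother_conservatism": (1, 6),
    "income": (1, 6),
    "parent_income": (1, 6),
    "religiosity": (1, 6),
    "origin_city_conservatism": (1, 6),
    "current_city_conservatism": (1, 6),
    "conservatism": (1, 6),
}

COHORT_COLUMNS: tuple[str, ...] = ("subject_id",) + tuple(LIKERT_RANGES)

#: Covariate columns usable as predictors (everything except the outcome).
SURVEY_COVARIATES: tuple[str, ...] = tuple(
    c for c in LIKERT_RANGES if c != "conservatism"
)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its schema."""


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table: columns, integer ranges, unique subjects.

    Returns the validated frame (unchanged) so callers can chain.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"cohort missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortValidationError(f"duplicate subject_id: {dup!r}")
    for col, (lo, hi) in LIKERT_RANGES.items():
        vals = cohort[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise CohortValidationError(f"missing value in {col!r} at row {row}")
        arr = vals.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise CohortValidationError(f"non-integer value in {col!r}")
        bad = (arr < lo) | (arr > hi)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"{col!r} out of range [{lo}, {hi}] at row {row}: {arr[bad][0]}"
            )
    return cohort


@dataclass
class RoiTimeSeries:
    """ROI-averaged BOLD time series for one subject and task.

    ``data`` is a T x R array in arbitrary BOLD units; columns listed in
    ``missing_rois`` (1-based original atlas indices) contain only NaN.
    """

    subject_id: str
    task_id: str
    data: np.ndarray
    missing_rois: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be T x R with T >= 2")
        self.missing_rois = frozenset(int(r) for r in self.missing_rois)
        for roi in self.missing_rois:
            if not (1 <= roi <= self.data.shape[1]):
                raise ValueError(f"missing ROI index {roi} outside 1..R")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Functional connectivity matrix for one subject and task.

    ``values`` is symmetric with an exactly-zero diagonal and off-diagonal
    Pearson correlations in [-1, 1]. ``roi_labels`` carries the 1-based
    original atlas indices of the retained ROIs, so excluded ROIs remain
    traceable after the matrix shrinks.
    """

    subject_id: str
    task_id: str
    values: np.ndarray
    roi_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        E = self.values
        if E.ndim != 2 or E.shape[0] != E.shape[1]:
            raise ValueError("FC matrix must be square")
        if len(self.roi_labels) != E.shape[0]:
            raise ValueError("roi_labels length must match matrix dimension")
        if not np.allclose(E, E.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.diag(E) != 0.0):
            raise ValueError("FC diagonal must be exactly zero")
        off = E[~np.eye(E.shape[0], dtype=bool)]
        if off.size and (np.nanmax(np.abs(off)) > 1.0 + 1e-12):
            raise ValueError("off-diagonal FC entries must lie in [-1, 1]")
        self.roi_labels = tuple(int(r) for r in self.roi_labels)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class IdeologyScoreMatrix:
    """Out-of-fold continuous ideology predictions, subjects x tasks.

    Each entry is the network's prediction for a subject produced while the
    subject sat in the held-out fold, so a score never leaks its own label.
    ``fold_assignment`` maps subject_id to fold index (None for scores not
    produced by cross-validation, e.g. synthetic matrices).
    """

    scores: pd.DataFrame  # index: subject_id, columns: task_id
    fold_assignment: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("score matrix contains non-finite entries")
        if self.fold_assignment is not None:
            missing = set(self.scores.index) - set(self.fold_assignment)
            if missing:
                raise ValueError(f"subjects without fold assignment: {missing}")

    @property
    def task_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores.index)
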