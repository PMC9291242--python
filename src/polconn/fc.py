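"""Functional connectivity construction from ROI time series.

Task-evoked BOLD activation is regressed out by ordinary least squares
before connectivity is computed, so that the FC matrix captures intrinsic
co-fluctuation rather than shared stimulus response. Connectivity is the
raw Pearson correlation between retained ROI columns (no Fisher-z
transform), stored as a full symmetric matrix with zeros on the diagonal.
ROIs that are entirely missing or have zero variance are excluded; with a
269-ROI parcellation and one all-missing ROI this yields a 268 x 268
matrix. ROI indices are 1-based throughout and the retained original
indices travel with each matrix in ``roi_labels``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FCMatrix, RoiTimeSeries


def regress_out_task(ts: RoiTimeSeries, design: np.ndarray) -> RoiTimeSeries:
    """Replace each non-missing ROI column by its OLS residual on the design.

    The design matrix (T x K) is augmented with an intercept; it must have
    full column rank after augmentation. Residual columns are orthogonal to
    every design column. Missing-ROI columns pass through unchanged.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"design has {design.shape[0]} rows, time series has "
            f"{ts.n_timepoints} timepoints"
        )
    X = np.column_stack([np.ones(ts.n_timepoints), design])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix (with intercept) is rank deficient")

    data = ts.data.copy()
    keep = np.ones(ts.n_rois, dtype=bool)
    for roi in ts.missing_rois:
        keep[roi - 1] = False
    Y = data[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    data[:, keep] = Y - X @ beta
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        task_id=ts.task_id,
        data=data,
        missing_rois=ts.missing_rois,
    )


def compute_fc(ts: RoiTimeSeries) -> FCMatrix:
    """Pearson-correlation FC matrix over retained ROIs.

    ROIs flagged missing or with zero sample variance are dropped and their
    original 1-based indices omitted from ``roi_labels``. The diagonal is
    set exactly to zero.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    keep = np.ones(ts.n_rois, dtype=bool)
    for roi in ts.missing_rois:
        keep[roi - 1] = False
    # Degenerate (constant) columns make Pearson undefined; drop them too.
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(ts.data, axis=0)
    keep &= sd > 0
    keep &= np.isfinite(ts.data).all(axis=0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 retained ROIs; cannot build FC matrix")
    labels = tuple(int(i) for i in np.flatnonzero(keep) + 1)
    E = np.corrcoef(ts.data[:, keep], rowvar=False)
    E = np.clip(E, -1.0, 1.0)
    E = (E + E.T) / 2.0
    np.fill_diagonal(E, 0.0)
    return FCMatrix(
        subject_id=ts.subject_id, task_id=ts.task_id, values=E, roi_labels=labels
    )


def restrict_to_labels(fc: FCMatrix, labels: tuple[int, ...]) -> FCMatrix:
    """Restrict an FC matrix to a subset of its retained ROI labels."""
    pos = {lab: i for i, lab in enumerate(fc.roi_labels)}
    try:
        idx = np.array([pos[lab] for lab in labels])
    except KeyError as err:
        raise ValueError(f"ROI label {err.args[0]} not retained in matrix") from None
    return FCMatrix(
        subject_id=fc.subject_id,
        task_id=fc.task_id,
        values=fc.values[np.ix_(idx, idx)],
        roi_labels=tuple(labels),
    )


def assemble_dataset(
    series: list[RoiTimeSeries],
    designs: dict[str, np.ndarray] | None = None,
) -> tuple[dict[tuple[str, str], FCMatrix], pd.DataFrame]:
    """Build one FC matrix per subject-task with dataset-wide ROI harmonization.

    Every subject must have every task. If ``designs`` maps a task to a
    design matrix, task regression is applied to that task's series first.
    All output matrices are restricted to the intersection of retained ROIs
    across the dataset, so dimensions agree for model input. Returns the
    matrix dict keyed by (subject_id, task_id) and an exclusion manifest
    listing each dropped ROI and the reason.
    """
    subjects = sorted({ts.subject_id for ts in series})
    tasks = sorted({ts.task_id for ts in series})
    seen = {(ts.subject_id, ts.task_id) for ts in series}
    for s in subjects:
        for t in tasks:
            if (s, t) not in seen:
                raise ValueError(f"subject {s!r} is missing task {t!r}")

    matrices: dict[tuple[str, str], FCMatrix] = {}
    n_rois_orig = series[0].n_rois
    for ts in series:
        if ts.n_rois != n_rois_orig:
            raise ValueError(
                f"inconsistent ROI count: {ts.n_rois} vs {n_rois_orig} "
                f"for {ts.subject_id!r}/{ts.task_id!r}"
            )
        if designs is not None and ts.task_id in designs:
            ts = regress_out_task(ts, designs[ts.task_id])
        matrices[(ts.subject_id, ts.task_id)] = compute_fc(ts)

    shared = set(matrices[(subjects[0], tasks[0])].roi_labels)
    for fc in matrices.values():
        shared &= set(fc.roi_labels)
    shared_labels = tuple(sorted(shared))
    if len(shared_labels) < 2:
        raise ValueError("fewer than 2 ROIs shared across the dataset")

    excluded = sorted(set(range(1, n_rois_orig + 1)) - shared)
    manifest = pd.DataFrame(
        {
            "roi": excluded,
            "reason": [
                "missing_or_degenerate_in_some_series" for _ in excluded
            ],
        }
    )
    out = {
        key: restrict_to_labels(fc, shared_labels) for key, fc in matrices.items()
    }
    return out, manifest
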