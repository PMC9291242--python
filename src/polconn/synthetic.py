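"""Synthetic cohorts, BOLD time series, and score matrices with planted truth.

The generator emulates the statistical structure of a 174-subject cohort
scanned under nine fMRI conditions (eight tasks plus resting state) and
parcellated into 269 ROIs, one of which (the 252nd) is entirely missing.
Survey covariates are tied to the 6-point ideology outcome through a
latent-Gaussian copula so that each covariate hits a configurable target
correlation; edge-level brain signal is planted by making the latent
correlation of chosen ROI pairs a linear function of standardized ideology.
Everything is seeded, so every downstream stage has a reproducible
ground-truth test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    LIKERT_RANGES,
    IdeologyScoreMatrix,
    RoiTimeSeries,
    validate_cohort,
)

# Study-scale defaults: 6-point ideology histogram of the emulated cohort
# (1 = Very liberal ... 6 = Very conservative).
DEFAULT_IDEOLOGY_COUNTS: tuple[int, ...] = (24, 52, 49, 36, 9, 4)

#: Default covariate -> ideology correlation targets, matching the survey
#: summary of the emulated cohort.
DEFAULT_COVARIATE_TARGETS: dict[str, float] = {
    "male": 0.180,
    "age": -0.133,
    "education": -0.137,
    "father_education": 0.113,
    "mother_education": 0.081,
    "father_conservatism": 0.349,
    "mother_conservatism": 0.417,
    "income": -0.051,
    "parent_income": 0.194,
    "religiosity": 0.279,
    "origin_city_conservatism": 0.054,
    "current_city_conservatism": -0.007,
}

# Marginal Likert response counts for each covariate in the emulated cohort;
# used as discretization probabilities for the copula.
_DEFAULT_MARGINALS: dict[str, tuple[int, ...]] = {
    "male": (113, 61),  # P(male) = 0.351
    "education": (4, 131, 12, 8, 19),
    "father_education": (32, 20, 60, 8, 54),
    "mother_education": (29, 25, 76, 13, 31),
    "father_conservatism": (5, 28, 33, 41, 37, 30),
    "mother_conservatism": (9, 37, 46, 35, 31, 16),
    "income": (164, 9, 1, 0, 0, 0),
    "parent_income": (20, 22, 35, 29, 39, 29),
    "religiosity": (44, 40, 24, 29, 26, 11),
    "origin_city_conservatism": (1, 17, 44, 57, 40, 15),
    "current_city_conservatism": (16, 64, 64, 23, 6, 1),
}

_AGE_MEAN, _AGE_SD, _AGE_RANGE = 21.43, 3.83, (18, 40)

DEFAULT_TASKS: tuple[str, ...] = (
    "affect",
    "empathy",
    "encoding",
    "retrieval",
    "gonogo",
    "reward",
    "working_memory",
    "tom",
    "resting",
)


@dataclass(frozen=True)
class SignalEdge:
    """One planted edge-ideology association.

    The latent correlation of ROI pair (roi_i, roi_j) in ``task_id`` is
    ``base_correlation + effect_size * z`` where z is the subject's
    standardized ideology. Indices are 1-based and roi_i < roi_j.
    """

    task_id: str
    roi_i: int
    roi_j: int
    effect_size: float
    base_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_i == self.roi_j:
            raise ValueError("signal edge endpoints must differ")
        if self.roi_i > self.roi_j:
            raise ValueError("signal edge must have roi_i < roi_j")


@dataclass
class PlantedTruth:
    """Ground truth injected into synthetic BOLD data."""

    signal_edges: list[SignalEdge] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        rois_per_task: dict[str, set[int]] = {}
        for e in self.signal_edges:
            key = (e.task_id, e.roi_i, e.roi_j)
            if key in seen:
                raise ValueError(f"duplicate signal edge {key}")
            seen.add(key)
            used = rois_per_task.setdefault(e.task_id, set())
            if e.roi_i in used or e.roi_j in used:
                raise ValueError(
                    "signal edges within a task must not share ROIs "
                    f"(task {e.task_id!r}, edge {(e.roi_i, e.roi_j)})"
                )
            used.update((e.roi_i, e.roi_j))

    def edges_for_task(self, task_id: str) -> list[SignalEdge]:
        return [e for e in self.signal_edges if e.task_id == task_id]


def _thresholds(probs: np.ndarray) -> np.ndarray:
    """Interior standard-normal thresholds for given category probabilities."""
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def _attenuation(probs: np.ndarray, values: np.ndarray) -> float:
    """corr(discretized Z, Z) for a standard normal cut at given probabilities.

    Discretizing attenuates correlation; this factor lets the copula
    compensate so realized Likert-Likert correlations hit their targets.
    """
    t = np.concatenate([[-np.inf], _thresholds(probs), [np.inf]])
    phi = stats.norm.pdf(np.where(np.isfinite(t), t, 0.0))
    phi[~np.isfinite(t)] = 0.0
    cov = float(np.sum(values * (phi[:-1] - phi[1:])))  # E[v(Z) * Z]
    mean = float(np.sum(values * probs))
    var = float(np.sum(values**2 * probs) - mean**2)
    if var <= 0:
        return 1.0
    return cov / np.sqrt(var)


def _latent_ideology(
    ideology: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Latent standard-normal value consistent with each ideology category."""
    probs = counts / counts.sum()
    t = np.concatenate([[-np.inf], _thresholds(probs), [np.inf]])
    lo = t[ideology - 1]
    hi = t[ideology]
    u = rng.uniform(size=ideology.size)
    return stats.norm.ppf(
        stats.norm.cdf(lo) + u * (stats.norm.cdf(hi) - stats.norm.cdf(lo))
    )


def generate_cohort(
    n: int = 174,
    ideology_counts: tuple[int, ...] = DEFAULT_IDEOLOGY_COUNTS,
    covariate_targets: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort with an exact ideology histogram and copula covariates.

    Ideology categories are assigned deterministically to match
    ``ideology_counts`` and then shuffled by ``seed``. Each covariate is tied
    to ideology through a latent bivariate Gaussian with a correlation chosen
    (attenuation-corrected) so that the discretized Likert variable hits the
    target correlation; covariates are conditionally independent given
    ideology.

    Parameters
    ----------
    n : cohort size; must equal ``sum(ideology_counts)``.
    ideology_counts : 6-vector of category counts for conservatism 1..6.
    covariate_targets : map covariate -> target Pearson correlation with
        ideology, each in (-1, 1). Defaults to the study-scale targets.
    seed : RNG seed; same seed gives a bit-identical cohort.
    """
    counts = np.asarray(ideology_counts, dtype=int)
    if counts.size != 6 or (counts < 0).any():
        raise ValueError("ideology_counts must be six non-negative counts")
    if counts.sum() != n:
        raise ValueError(f"ideology_counts sum to {counts.sum()}, expected n={n}")
    targets = dict(DEFAULT_COVARIATE_TARGETS)
    if covariate_targets is not None:
        unknown = set(covariate_targets) - set(DEFAULT_COVARIATE_TARGETS)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        targets.update(covariate_targets)
    for name, r in targets.items():
        if not (-1.0 < r < 1.0):
            raise ValueError(f"target correlation for {name!r} outside (-1, 1): {r}")

    rng = np.random.default_rng(seed)
    ideology = np.repeat(np.arange(1, 7), counts)
    rng.shuffle(ideology)
    z_ideo = _latent_ideology(ideology, counts, rng)

    probs_ideo = counts / counts.sum()
    a_ideo = _attenuation(probs_ideo, np.arange(1, 7, dtype=float))

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i + 1:04d}" for i in range(n)]),
        "conservatism": ideology,
    }
    for name, target in targets.items():
        eps = rng.standard_normal(n)
        if name == "age":
            rho = np.clip(target / a_ideo, -0.999, 0.999)
            latent = rho * z_ideo + np.sqrt(1 - rho**2) * eps
            age = np.round(_AGE_MEAN + _AGE_SD * latent)
            data[name] = np.clip(age, *_AGE_RANGE).astype(int)
            continue
        marg = np.asarray(_DEFAULT_MARGINALS[name], dtype=float)
        marg_probs = marg / marg.sum()
        lo, hi = LIKERT_RANGES[name]
        values = np.arange(lo, hi + 1, dtype=float)
        a_cov = _attenuation(marg_probs, values)
        rho = np.clip(target / (a_ideo * a_cov), -0.999, 0.999)
        latent = rho * z_ideo + np.sqrt(1 - rho**2) * eps
        t = _thresholds(marg_probs)
        data[name] = (lo + np.searchsorted(t, latent)).astype(int)

    cohort = pd.DataFrame(data)[
        ["subject_id"] + list(LIKERT_RANGES)
    ].reset_index(drop=True)
    return validate_cohort(cohort)


def standardized_ideology(cohort: pd.DataFrame) -> np.ndarray:
    """Ideology centered and scaled to unit variance (population SD)."""
    y = cohort["conservatism"].to_numpy(dtype=float)
    sd = y.std()
    if sd == 0:
        raise ValueError("ideology has zero variance")
    return (y - y.mean()) / sd


def generate_bold_timeseries(
    cohort: pd.DataFrame,
    truth: PlantedTruth,
    n_rois: int = 269,
    n_timepoints: int = 150,
    missing_roi: int | None = 252,
    task_design: np.ndarray | None = None,
    task_ids: tuple[str, ...] = DEFAULT_TASKS,
    task_amplitude: float = 1.0,
) -> list[RoiTimeSeries]:
    """Generate per-subject, per-task ROI time series with planted edge signal.

    For each signal edge the two ROI columns share a latent factor whose
    loading makes their correlation ``base + effect_size * z`` in the
    subject's standardized ideology z. If ``task_design`` (T x K) is given, a
    shared task-evoked component ``design @ B`` with seeded coefficients B is
    added to every ROI of every series; the underlying noise stream is
    unaffected, so regenerating without the design yields the ground-truth
    noise-only series. If ``missing_roi`` is set (1-based), that column is
    entirely NaN and flagged.
    """
    if n_timepoints < 30:
        raise ValueError("n_timepoints must be >= 30")
    for e in truth.signal_edges:
        if e.task_id not in task_ids:
            raise ValueError(f"signal edge references unknown task {e.task_id!r}")
        if e.roi_j > n_rois:
            raise ValueError("signal edge ROI index exceeds n_rois")
    if task_design is not None:
        task_design = np.asarray(task_design, dtype=float)
        if task_design.shape[0] != n_timepoints:
            raise ValueError("task_design must have n_timepoints rows")

    # standardized ideology is only needed to scale planted signal; a null
    # truth must work even on a constant-ideology subset
    z = (
        standardized_ideology(cohort)
        if truth.signal_edges
        else np.zeros(len(cohort))
    )
    # Independent child streams: one for task coefficients, one per
    # subject-task, so adding/removing the design leaves noise unchanged.
    ss = np.random.SeedSequence(truth.seed)
    coef_ss, noise_ss = ss.spawn(2)
    coef_rng = np.random.default_rng(coef_ss)
    B = None
    if task_design is not None:
        B = task_amplitude * coef_rng.standard_normal(
            (task_design.shape[1], n_rois)
        )
    subject_streams = noise_ss.spawn(len(cohort) * len(task_ids))

    out: list[RoiTimeSeries] = []
    for k, subject in enumerate(cohort["subject_id"]):
        for t_idx, task in enumerate(task_ids):
            rng = np.random.default_rng(subject_streams[k * len(task_ids) + t_idx])
            X = rng.standard_normal((n_timepoints, n_rois))
            for e in truth.edges_for_task(task):
                rho = e.base_correlation + e.effect_size * z[k]
                if not (-1.0 < rho < 1.0):
                    raise ValueError(
                        f"planted correlation {rho:.3f} outside (-1, 1) for "
                        f"edge {(e.roi_i, e.roi_j)} at ideology z={z[k]:.2f}"
                    )
                f = rng.standard_normal(n_timepoints)
                a = np.sqrt(abs(rho))
                s = np.sign(rho) if rho != 0 else 1.0
                i, j = e.roi_i - 1, e.roi_j - 1
                X[:, i] = np.sqrt(1 - a**2) * X[:, i] + a * f
                X[:, j] = np.sqrt(1 - a**2) * X[:, j] + s * a * f
            X *= truth.noise_sd
            if B is not None:
                X = X + task_design @ B
            missing: frozenset[int] = frozenset()
            if missing_roi is not None:
                X[:, missing_roi - 1] = np.nan
                missing = frozenset({missing_roi})
            out.append(
                RoiTimeSeries(
                    subject_id=str(subject),
                    task_id=task,
                    data=X,
                    missing_rois=missing,
                )
            )
    return out


def generate_score_matrix(
    cohort: pd.DataFrame,
    task_signal: dict[str, float] | None = None,
    seed: int = 0,
    task_ids: tuple[str, ...] = DEFAULT_TASKS,
) -> IdeologyScoreMatrix:
    """Generate a subjects x tasks score matrix with known per-task signal.

    Column t is ``rho_t * z + sqrt(1 - rho_t^2) * e`` rescaled to ideology
    units (same mean and SD as the cohort's conservatism), where z is
    standardized ideology, rho_t = ``task_signal[t]`` (default 0), and the
    Gaussian noise e is orthogonalized against z in-sample so that the
    realized score-ideology correlation equals rho_t exactly. This lets the
    score-analysis and model-comparison stages be tested with exactly known
    score-ideology correlations, without network training.
    """
    signal = {t: 0.0 for t in task_ids}
    if task_signal is not None:
        unknown = set(task_signal) - set(task_ids)
        if unknown:
            raise ValueError(f"unknown tasks in task_signal: {sorted(unknown)}")
        signal.update(task_signal)
    for t, rho in signal.items():
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"task_signal[{t!r}] outside (-1, 1): {rho}")

    rng = np.random.default_rng(seed)
    z = standardized_ideology(cohort)
    y = cohort["conservatism"].to_numpy(dtype=float)
    cols = {}
    for t in task_ids:
        rho = signal[t]
        e = rng.standard_normal(len(cohort))
        e = e - e.mean() - (e @ z) / (z @ z) * z  # in-sample orthogonal to z
        e /= e.std()
        col = rho * z + np.sqrt(1 - rho**2) * e
        cols[t] = y.mean() + y.std() * col
    frame = pd.DataFrame(cols, index=pd.Index(cohort["subject_id"], name="subject_id"))
    return IdeologyScoreMatrix(scores=frame)
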