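"""Readers, writers, run configuration, and the end-to-end pipeline driver.

All tabular artifacts are tab-delimited text with a header row; FC
matrices are additionally stored in a checksummed compressed archive for
speed. Every run writes a manifest (seeds, config hash, package version)
sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FCMatrix, IdeologyScoreMatrix, RoiTimeSeries, validate_cohort
from .synthetic import DEFAULT_IDEOLOGY_COUNTS, DEFAULT_TASKS, PlantedTruth, SignalEdge

log = logging.getLogger("polconn")


# ---------------------------------------------------------------- cohort I/O

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-delimited cohort table."""
    cohort = pd.read_csv(path, sep="\t")
    validate_cohort(cohort)
    log.info("read cohort of %d subjects from %s", len(cohort), path)
    return cohort


# ----------------------------------------------------------- time series I/O

def write_timeseries(series: list[RoiTimeSeries], directory: str | Path) -> None:
    """One delimited matrix per subject-task, named ``<subject>_<task>.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ts in series:
        np.savetxt(
            directory / f"{ts.subject_id}_{ts.task_id}.tsv", ts.data, delimiter="\t"
        )


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    """Read one ``<subject>_<task>.tsv`` matrix; NaN columns become missing."""
    path = Path(path)
    subject_id, _, task_id = path.stem.partition("_")
    data = np.loadtxt(path, delimiter="\t")
    missing = frozenset(
        int(j) + 1 for j in range(data.shape[1]) if np.isnan(data[:, j]).all()
    )
    return RoiTimeSeries(
        subject_id=subject_id, task_id=task_id, data=data, missing_rois=missing
    )


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    doc = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "signal_edges": [asdict(e) for e in truth.signal_edges],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth(path: str | Path) -> PlantedTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return PlantedTruth(
        signal_edges=[SignalEdge(**e) for e in doc.get("signal_edges", [])],
        noise_sd=float(doc.get("noise_sd", 1.0)),
        seed=int(doc.get("seed", 0)),
    )


# ------------------------------------------------------------- FC archive

class ArchiveCorruptError(RuntimeError):
    """Raised when an FC archive fails its checksum."""


def _dataset_checksum(payload: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(payload):
        h.update(key.encode())
        h.update(np.ascontiguousarray(payload[key]).tobytes())
    return h.hexdigest()


def write_fc_archive(
    matrices: dict[tuple[str, str], FCMatrix], path: str | Path
) -> None:
    """Compressed archive keyed by ``subject|task`` with a global checksum."""
    payload: dict[str, np.ndarray] = {}
    for (subj, task), fc in matrices.items():
        payload[f"values::{subj}|{task}"] = fc.values
        payload[f"labels::{subj}|{task}"] = np.asarray(fc.roi_labels, dtype=int)
    checksum = _dataset_checksum(payload)
    np.savez_compressed(path, __checksum__=np.array(checksum), **payload)


def read_fc_archive(path: str | Path) -> dict[tuple[str, str], FCMatrix]:
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as err:
        raise ArchiveCorruptError(f"cannot read FC archive {path}: {err}") from err
    stored = str(data.pop("__checksum__"))
    if _dataset_checksum(data) != stored:
        raise ArchiveCorruptError(f"FC archive {path} failed its checksum")
    out: dict[tuple[str, str], FCMatrix] = {}
    for key, values in data.items():
        kind, _, rest = key.partition("::")
        if kind != "values":
            continue
        subj, _, task = rest.partition("|")
        labels = tuple(int(x) for x in data[f"labels::{rest}"])
        out[(subj, task)] = FCMatrix(
            subject_id=subj, task_id=task, values=values, roi_labels=labels
        )
    return out


def write_score_matrix(matrix: IdeologyScoreMatrix, path: str | Path) -> None:
    """Scores as subjects x tasks TSV with a fold column when available."""
    frame = matrix.scores.copy()
    if matrix.fold_assignment is not None:
        frame["fold"] = [matrix.fold_assignment[s] for s in frame.index]
    frame.to_csv(path, sep="\t")


def read_score_matrix(path: str | Path) -> IdeologyScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    folds = None
    if "fold" in frame.columns:
        folds = {str(s): int(f) for s, f in frame["fold"].items()}
        frame = frame.drop(columns="fold")
    frame.index = frame.index.astype(str)
    return IdeologyScoreMatrix(scores=frame, fold_assignment=folds)


# ------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run.

    ``atlas`` is a path to a grouping TSV, the string "default" for the
    packaged 269-ROI table, "auto" for a deterministic balanced grouping
    into ``n_regions``, or None (saliency then unavailable).
    """

    output_dir: str = "polconn_run"
    seed: int = 0
    # simulate
    n_subjects: int = 174
    ideology_counts: tuple[int, ...] = DEFAULT_IDEOLOGY_COUNTS
    n_rois: int = 269
    n_timepoints: int = 150
    missing_roi: int | None = 252
    tasks: tuple[str, ...] = DEFAULT_TASKS
    signal_edges: list[dict] = field(default_factory=list)
    noise_sd: float = 1.0
    # train (defaults mirror the full random-search space)
    k_folds: int = 10
    n_search_draws: int = 10
    n_epochs: tuple[int, ...] = (50, 100, 200)
    n_e2n_filters: tuple[int, ...] = (16, 32, 64)
    n_n2g_units: tuple[int, ...] = (16, 32, 64)
    learning_rate_range: tuple[float, float] = (1e-4, 1e-2)
    batch_size: tuple[int, ...] = (8, 16)
    stratify_folds: bool = False
    # compare
    mc_samples: int = 200
    test_fraction_range: tuple[float, float] = (0.05, 0.50)
    # saliency
    atlas: str | None = "auto"
    n_regions: int = 78
    flag_z: float = 1.645
    # stage selection
    stages: tuple[str, ...] = (
        "simulate", "fc", "train", "score-analysis", "compare", "importance",
        "saliency",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        return cfg.validated()

    def validated(self) -> "RunConfig":
        if "saliency" in self.stages and self.atlas is None:
            raise ValueError("saliency stage requested but no atlas configured")
        if self.atlas not in (None, "auto", "default") and not Path(self.atlas).exists():
            raise ValueError(f"atlas file not found: {self.atlas}")
        if sum(self.ideology_counts) != self.n_subjects:
            raise ValueError("ideology_counts must sum to n_subjects")
        return self

    def config_hash(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def demo(cls, output_dir: str = "polconn_demo", seed: int = 0) -> "RunConfig":
        """Desk-scale preset: 60 subjects, 40 ROIs, 3 tasks, small search."""
        return cls(
            output_dir=output_dir,
            seed=seed,
            n_subjects=60,
            ideology_counts=(9, 18, 17, 12, 3, 1),
            n_rois=40,
            n_timepoints=120,
            missing_roi=None,
            tasks=("affect", "empathy", "reward"),
            k_folds=5,
            n_search_draws=1,
            n_epochs=(60,),
            n_e2n_filters=(4,),
            n_n2g_units=(8,),
            learning_rate_range=(1e-2, 1e-2),
            mc_samples=100,
            n_regions=10,
        )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages end-to-end and write all artifacts.

    Stages: simulate -> fc -> train -> score-analysis -> compare ->
    importance -> saliency. Any failure is re-raised with the stage name.
    Returns the output directory.
    """
    from . import compare as cmp_mod
    from . import importance as imp_mod
    from . import scores as scores_mod
    from .fc import assemble_dataset
    from .network import SearchSpace, cross_validated_scores
    from .saliency import AtlasMap, task_saliency
    from .synthetic import generate_bold_timeseries, generate_cohort

    config = config.validated()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
    }
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name not in config.stages:
                return fn
            t0 = time.time()
            log.info("stage %s: starting", name)
            try:
                fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            log.info("stage %s: done (%.1fs)", name, time.time() - t0)
            return fn

        return deco

    truth = PlantedTruth(
        signal_edges=[SignalEdge(**e) for e in config.signal_edges],
        noise_sd=config.noise_sd,
        seed=config.seed,
    )

    @stage("simulate")
    def _simulate():
        cohort = generate_cohort(
            n=config.n_subjects,
            ideology_counts=config.ideology_counts,
            seed=config.seed,
        )
        series = generate_bold_timeseries(
            cohort,
            truth,
            n_rois=config.n_rois,
            n_timepoints=config.n_timepoints,
            missing_roi=config.missing_roi,
            task_ids=config.tasks,
        )
        write_cohort(cohort, out / "cohort.tsv")
        write_truth(truth, out / "truth.yaml")
        state["cohort"], state["series"] = cohort, series

    @stage("fc")
    def _fc():
        if "series" not in state:
            raise RuntimeError("fc stage requires the simulate stage in this run")
        matrices, roi_manifest = assemble_dataset(state["series"])
        write_fc_archive(matrices, out / "fc_matrices.npz")
        roi_manifest.to_csv(out / "roi_exclusions.tsv", sep="\t", index=False)
        state["matrices"] = matrices

    @stage("train")
    def _train():
        space = SearchSpace(
            n_e2n_filters=config.n_e2n_filters,
            n_n2g_units=config.n_n2g_units,
            learning_rate_range=config.learning_rate_range,
            n_epochs=config.n_epochs,
            batch_size=config.batch_size,
            n_draws=config.n_search_draws,
        )
        cv = cross_validated_scores(
            state["matrices"],
            state["cohort"],
            k=config.k_folds,
            space=space,
            seed=config.seed,
            stratify=config.stratify_folds,
        )
        write_score_matrix(cv.score_matrix, out / "ideology_scores.tsv")
        losses = pd.DataFrame(
            [
                {"task": t, "fold": f, "epoch": i, "loss": v}
                for (t, f), m in cv.models.items()
                for i, v in enumerate(m.loss_history)
            ]
        )
        losses.to_csv(out / "training_log.tsv", sep="\t", index=False)
        state["cv"] = cv

    @stage("score-analysis")
    def _score_analysis():
        sm = state["cv"].score_matrix
        reports = []
        for subgroup in scores_mod.SUBGROUPS:
            try:
                reports.append(
                    scores_mod.correlate_scores(
                        sm, state["cohort"], subgroup, m_tests=len(config.tasks)
                    )
                )
            except ValueError as err:
                log.warning("skipping subgroup %s: %s", subgroup, err)
        pd.concat(reports).to_csv(out / "score_correlations.tsv", sep="\t",
                                  index=False)
        pca = scores_mod.pca_scores(sm)
        pca.contributions.to_csv(out / "pca_contributions.tsv", sep="\t")
        pd.DataFrame(
            {"component": pca.contributions.columns,
             "variance_pct": pca.variance_fraction}
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)

    @stage("compare")
    def _compare():
        feats = cmp_mod.assemble_features(state["cv"].score_matrix, state["cohort"])
        labels = cmp_mod.dichotomize(state["cohort"])
        specs = cmp_mod.default_model_specs(list(config.tasks))
        result = cmp_mod.monte_carlo_cv(
            specs, feats, labels,
            n_samples=config.mc_samples,
            test_fraction_range=config.test_fraction_range,
            seed=config.seed,
        )
        cls = cmp_mod.compare_to_benchmark(result)
        table = result.summary.join(cls)
        table.to_csv(out / "model_comparison.tsv", sep="\t")
        state["comparison"] = result

    @stage("importance")
    def _importance():
        feats = cmp_mod.assemble_features(state["cv"].score_matrix, state["cohort"])
        feats = feats.loc[:, feats.std() > 0]  # small cohorts: constant covariates
        labels = cmp_mod.dichotomize(state["cohort"])
        table = imp_mod.importance_table(
            feats, labels.loc[feats.index], seed=config.seed
        )
        table.to_csv(out / "variable_importance.tsv", sep="\t", index=False)

    @stage("saliency")
    def _saliency():
        if config.atlas == "default":
            atlas = AtlasMap.default()
        elif config.atlas == "auto":
            excluded = (config.missing_roi,) if config.missing_roi else ()
            atlas = AtlasMap.synthetic(config.n_rois, config.n_regions, excluded)
        else:
            atlas = AtlasMap.from_tsv(config.atlas)
        tops = []
        for task in config.tasks:
            res = task_saliency(
                state["cv"], state["matrices"], task, atlas, flag_z=config.flag_z
            )
            res.region_importance.assign(task=task).to_csv(
                out / f"region_importance_{task}.tsv", sep="\t", index=False
            )
            np.savetxt(out / f"edge_gradients_{task}.tsv", res.gradients,
                       delimiter="\t")
            tops.append(
                {
                    "task": task,
                    "liberal_edge": str(res.top_edges.liberal),
                    "conservative_edge": str(res.top_edges.conservative),
                }
            )
        pd.DataFrame(tops).to_csv(out / "top_edges.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
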