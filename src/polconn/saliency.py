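"""Gradient-based saliency: which edges and regions drive the prediction.

For each subject the gradient of the predicted ideology score with respect
to every input edge is computed through the subject's own out-of-fold
model (evaluation mode, dropout off), then averaged over the dataset to
give a per-task edge-importance map G_t. Summing absolute values over the
rows yields a weighted degree centrality per ROI; ROI centralities are
averaged within anatomical regions (a 269-ROI parcellation grouped into 78
regions) and regions whose importance is statistically above the
across-region average are flagged. The most positive and most negative
mean gradients identify the edge pairs that push predictions toward
conservatism and liberalism respectively.

Sign convention: ideology is coded 1 = Very liberal ... 6 = Very
conservative, so a positive mean gradient marks an edge whose strength
pushes the prediction toward conservatism, and a negative one toward
liberalism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .containers import FCMatrix
from .network import CVResult, FittedModel, input_gradient


@dataclass
class AtlasMap:
    """ROI -> (region, hemisphere) grouping with an exclusion list.

    ``table`` has columns roi, region, hemisphere; excluded ROIs appear in
    ``excluded`` and carry no mapping. ROI indices are 1-based.
    """

    table: pd.DataFrame
    excluded: frozenset[int]

    def __post_init__(self) -> None:
        if self.table["roi"].duplicated().any():
            raise ValueError("atlas maps an ROI more than once")
        overlap = set(self.table["roi"]) & set(self.excluded)
        if overlap:
            raise ValueError(f"excluded ROIs must be unmapped: {sorted(overlap)}")

    @property
    def n_regions(self) -> int:
        return self.table.groupby(["region", "hemisphere"]).ngroups

    def region_of(self, roi: int) -> tuple[str, str]:
        row = self.table.loc[self.table["roi"] == roi]
        if row.empty:
            raise KeyError(f"ROI {roi} is not mapped by the atlas")
        return str(row["region"].iloc[0]), str(row["hemisphere"].iloc[0])

    @classmethod
    def from_tsv(cls, path) -> "AtlasMap":
        """Load a tab-delimited atlas (columns roi, region, hemisphere;
        hemisphere '-' marks an excluded ROI)."""
        raw = pd.read_csv(path, sep="\t")
        for col in ("roi", "region", "hemisphere"):
            if col not in raw.columns:
                raise ValueError(f"atlas file missing column {col!r}")
        excl = raw.loc[raw["hemisphere"] == "-", "roi"].astype(int)
        table = raw.loc[raw["hemisphere"] != "-"].reset_index(drop=True)
        table["roi"] = table["roi"].astype(int)
        return cls(table=table, excluded=frozenset(int(r) for r in excl))

    @classmethod
    def default(cls) -> "AtlasMap":
        """The packaged synthetic 269-ROI -> 78-region grouping.

        A deterministic stand-in grouping table (not a real anatomical
        atlas): 268 retained ROIs distributed over 39 region labels per
        hemisphere, with ROI 252 excluded.
        """
        with resources.as_file(
            resources.files("polconn.data") / "atlas_synthetic.tsv"
        ) as path:
            return cls.from_tsv(path)

    @classmethod
    def synthetic(
        cls, n_rois: int, n_regions: int, excluded: tuple[int, ...] = ()
    ) -> "AtlasMap":
        """Deterministic grouping of ``n_rois`` ROIs into ``n_regions``
        regions (balanced contiguous blocks), for tests at arbitrary scale."""
        retained = [r for r in range(1, n_rois + 1) if r not in excluded]
        if n_regions > len(retained):
            raise ValueError("more regions than retained ROIs")
        rows = []
        for i, roi in enumerate(retained):
            g = i * n_regions // len(retained)
            rows.append(
                {
                    "roi": roi,
                    "region": f"REG{g // 2 + 1:02d}",
                    "hemisphere": "L" if g % 2 == 0 else "R",
                }
            )
        return cls(table=pd.DataFrame(rows), excluded=frozenset(excluded))


def edge_gradients(
    cv_result: CVResult,
    dataset: dict[tuple[str, str], FCMatrix],
    task_id: str,
    mode: str = "out_of_fold",
) -> np.ndarray:
    """Dataset-mean gradient of the score w.r.t. each input edge, one task.

    Each subject's gradient is taken through the model that scored that
    subject out-of-fold (``mode='out_of_fold'``) or through the average of
    the gradients from all fold models (``mode='pooled'``). The diagonal
    (structurally zero self-edges) is zeroed.
    """
    if mode not in ("out_of_fold", "pooled"):
        raise ValueError("mode must be 'out_of_fold' or 'pooled'")
    subjects = cv_result.score_matrix.subject_ids
    fold_models = {
        f: m for (t, f), m in cv_result.models.items() if t == task_id
    }
    if not fold_models:
        raise KeyError(f"no fitted models for task {task_id!r}")
    total: np.ndarray | None = None
    for subj in subjects:
        fc = dataset[(subj, task_id)]
        if mode == "out_of_fold":
            models: list[FittedModel] = [cv_result.model_for(subj, task_id)]
        else:
            models = list(fold_models.values())
        g = np.mean(
            [input_gradient(fc, m.params, m.config, m.stats) for m in models],
            axis=0,
        )
        total = g if total is None else total + g
    assert total is not None
    G = total / len(subjects)
    np.fill_diagonal(G, 0.0)
    return G


def node_centrality(G: np.ndarray) -> np.ndarray:
    """Weighted degree centrality: centrality[i] = sum_j |G[i, j]|."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("gradient map must be square")
    return np.abs(G).sum(axis=1)


def aggregate_to_regions(
    centrality: np.ndarray,
    roi_labels: tuple[int, ...],
    atlas: AtlasMap,
    flag_z: float = 1.645,
) -> pd.DataFrame:
    """Average ROI centralities within atlas regions and flag the high ones.

    A region is flagged when its mean centrality exceeds the across-region
    mean by more than ``flag_z`` across-region standard deviations
    (one-sided; the default corresponds to a 95% normal quantile).

    Returns a frame with columns region, hemisphere, importance, flagged,
    sorted by importance descending.
    """
    centrality = np.asarray(centrality, dtype=float)
    if centrality.size != len(roi_labels):
        raise ValueError("centrality length must match roi_labels")
    mapped = dict(
        zip(atlas.table["roi"], zip(atlas.table["region"], atlas.table["hemisphere"]))
    )
    rows = []
    for roi, c in zip(roi_labels, centrality):
        if roi not in mapped:
            raise ValueError(f"retained ROI {roi} is not mapped by the atlas")
        region, hemi = mapped[roi]
        rows.append({"region": region, "hemisphere": hemi, "centrality": c})
    per_roi = pd.DataFrame(rows)
    agg = (
        per_roi.groupby(["region", "hemisphere"], as_index=False)["centrality"]
        .mean()
        .rename(columns={"centrality": "importance"})
    )
    mu = agg["importance"].mean()
    sd = agg["importance"].std(ddof=1)
    agg["flagged"] = agg["importance"] > mu + flag_z * (sd if np.isfinite(sd) else 0.0)
    if sd == 0 or not np.isfinite(sd):
        agg["flagged"] = False
    return agg.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )


@dataclass
class TopEdges:
    """Most liberal- and conservative-predictive edges (1-based ROI labels).

    Either side is None when no gradient of the corresponding sign exists;
    a warning is emitted in that case.
    """

    liberal: tuple[int, int] | None
    conservative: tuple[int, int] | None


def top_signed_edges(
    G: np.ndarray, roi_labels: tuple[int, ...] | None = None
) -> TopEdges:
    """Extreme entries of the symmetrized mean-gradient map.

    The conservative pair maximizes the symmetrized gradient over i < j
    (most positive); the liberal pair minimizes it (most negative). Ties
    break to the lowest (i, j) in lexicographic order. Raises on an
    all-zero map.
    """
    G = np.asarray(G, dtype=float)
    R = G.shape[0]
    if G.shape != (R, R):
        raise ValueError("gradient map must be square")
    S = (G + G.T) / 2.0
    iu, ju = np.triu_indices(R, k=1)  # lexicographic (i, j) order
    vals = S[iu, ju]
    if not np.any(vals != 0):
        raise ValueError("gradient map is all zero; no edges to rank")
    labels = roi_labels if roi_labels is not None else tuple(range(1, R + 1))

    def _pair(flat_idx: int) -> tuple[int, int]:
        return (labels[iu[flat_idx]], labels[ju[flat_idx]])

    conservative = liberal = None
    if vals.max() > 0:
        conservative = _pair(int(np.argmax(vals)))
    else:
        warnings.warn("no positive gradients; conservative edge undefined")
    if vals.min() < 0:
        liberal = _pair(int(np.argmin(vals)))
    else:
        warnings.warn("no negative gradients; liberal edge undefined")
    return TopEdges(liberal=liberal, conservative=conservative)


@dataclass
class SaliencyResult:
    """Full saliency summary for one task."""

    task_id: str
    gradients: np.ndarray  # (R, R) dataset-mean edge gradients
    roi_labels: tuple[int, ...]
    centrality: np.ndarray  # (R,)
    region_importance: pd.DataFrame
    top_edges: TopEdges


def task_saliency(
    cv_result: CVResult,
    dataset: dict[tuple[str, str], FCMatrix],
    task_id: str,
    atlas: AtlasMap,
    flag_z: float = 1.645,
) -> SaliencyResult:
    """Gradients, centralities, region aggregates and top edges for a task."""
    some_fc = next(fc for (s, t), fc in dataset.items() if t == task_id)
    G = edge_gradients(cv_result, dataset, task_id)
    cent = node_centrality(G)
    regions = aggregate_to_regions(cent, some_fc.roi_labels, atlas, flag_z=flag_z)
    return SaliencyResult(
        task_id=task_id,
        gradients=G,
        roi_labels=some_fc.roi_labels,
        centrality=cent,
        region_importance=regions,
        top_edges=top_signed_edges(G, some_fc.roi_labels),
    )
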