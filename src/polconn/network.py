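"""Connectome regression network with edge-to-node and node-to-graph layers.

The model maps an R x R functional-connectivity matrix to a single
continuous ideology score. Architecture::

    input normalization -> E2N -> very-leaky ReLU -> N2G -> very-leaky ReLU
    -> dropout(0.5, training only) -> linear unit -> scalar

The edge-to-node (E2N) layer applies cross-shaped filters: node i's feature
f sums a row filter over E[i, :] and a column filter over E[:, i]. The
node-to-graph (N2G) layer collapses the R x F node-feature map to G scalars
through full weighted summation. The very leaky ReLU is f(x) = x for
x >= 0 and x/3 otherwise. Training minimizes the Euclidean (mean squared)
loss on the raw 1-6 ideology targets treated as continuous.

Forward and backward passes are written out explicitly in numpy; the
backward pass extends to the input edges themselves, giving exact analytic
gradients d(score)/d(E_ij) for the saliency stage.

Hyperparameters left open by the architecture (filter counts, learning
rate, epochs, batch size) are tuned per cross-validation fold by random
search minimizing the final training loss. Out-of-fold scoring partitions
subjects into k folds once, reused across tasks; a subject's score always
comes from the model trained without its fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FCMatrix, IdeologyScoreMatrix

_EPS = 1e-5  # variance floor in input normalization


def vleaky_relu(x: np.ndarray | float) -> np.ndarray | float:
    """Very leaky ReLU: x for x >= 0, x/3 for x < 0 (elementwise)."""
    return np.where(np.asarray(x) >= 0, x, np.asarray(x) / 3.0)


def _vleaky_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, 1.0 / 3.0)


def e2n_forward(
    E: np.ndarray,
    row_weights: np.ndarray,
    col_weights: np.ndarray,
    bias: np.ndarray,
) -> np.ndarray:
    """Edge-to-node layer, pre-activation.

    output[i, f] = sum_j row_weights[f, j] * E[i, j]
                 + sum_j col_weights[f, j] * E[j, i] + bias[f]
    """
    E = np.asarray(E, dtype=float)
    row_weights = np.asarray(row_weights, dtype=float)
    col_weights = np.asarray(col_weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    R = E.shape[0]
    if E.shape != (R, R):
        raise ValueError("E must be square")
    F = row_weights.shape[0]
    if row_weights.shape != (F, R) or col_weights.shape != (F, R):
        raise ValueError("filter weights must be F x R")
    if bias.shape != (F,):
        raise ValueError("bias must have length F")
    return E @ row_weights.T + E.T @ col_weights.T + bias


def n2g_forward(H: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Node-to-graph layer, pre-activation.

    output[m] = sum_i sum_f weights[m, i, f] * H[i, f] + bias[m]
    """
    H = np.asarray(H, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be R x F")
    G = weights.shape[0]
    if weights.shape != (G,) + H.shape:
        raise ValueError("weights must be G x R x F")
    if bias.shape != (G,):
        raise ValueError("bias must have length G")
    return np.tensordot(weights, H, axes=([1, 2], [0, 1])) + bias


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one network instance.

    ``dropout_rate`` and ``leak_slope`` are architectural constants (0.5 and
    1/3) and validated as such. ``normalization`` selects how edge inputs
    are standardized: "batch" uses minibatch statistics during training and
    training-set statistics at evaluation; "dataset" uses fixed training-set
    statistics everywhere; "none" disables normalization.
    """

    n_e2n_filters: int = 16
    n_n2g_units: int = 32
    learning_rate: float = 1e-3
    n_epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    dropout_rate: float = 0.5
    leak_slope: float = 1.0 / 3.0
    tie_e2n_weights: bool = False
    normalization: str = "batch"

    def __post_init__(self) -> None:
        if self.dropout_rate != 0.5:
            raise ValueError("dropout_rate is fixed at 0.5")
        if not math.isclose(self.leak_slope, 1.0 / 3.0):
            raise ValueError("leak_slope is fixed at 1/3")
        for name in ("n_e2n_filters", "n_n2g_units", "n_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.normalization not in ("batch", "dataset", "none"):
            raise ValueError("normalization must be 'batch', 'dataset' or 'none'")


@dataclass
class NetworkParams:
    """Learnable parameters; shapes follow the layer definitions."""

    row_weights: np.ndarray  # (F, R)
    col_weights: np.ndarray  # (F, R)
    e2n_bias: np.ndarray  # (F,)
    n2g_weights: np.ndarray  # (G, R, F)
    n2g_bias: np.ndarray  # (G,)
    out_weights: np.ndarray  # (G,)
    out_bias: np.ndarray  # (1,)

    @classmethod
    def init(cls, n_rois: int, config: NetworkConfig, rng: np.random.Generator
             ) -> "NetworkParams":
        F, G, R = config.n_e2n_filters, config.n_n2g_units, n_rois
        # He-style scaling: fan-in of E2N is 2R edges per node, of N2G is R*F.
        rw = rng.standard_normal((F, R)) * np.sqrt(2.0 / (2 * R))
        cw = (
            rw.copy()
            if config.tie_e2n_weights
            else rng.standard_normal((F, R)) * np.sqrt(2.0 / (2 * R))
        )
        w2 = rng.standard_normal((G, R, F)) * np.sqrt(2.0 / (R * F))
        w3 = rng.standard_normal(G) * np.sqrt(2.0 / G)
        return cls(rw, cw, np.zeros(F), w2, np.zeros(G), w3, np.zeros(1))

    def flat(self) -> list[np.ndarray]:
        return [
            self.row_weights,
            self.col_weights,
            self.e2n_bias,
            self.n2g_weights,
            self.n2g_bias,
            self.out_weights,
            self.out_bias,
        ]


@dataclass
class NormStats:
    """Per-edge normalization statistics (training-set mean and variance)."""

    mean: np.ndarray  # (R, R)
    var: np.ndarray  # (R, R)

    @classmethod
    def from_batch(cls, E: np.ndarray) -> "NormStats":
        return cls(mean=E.mean(axis=0), var=E.var(axis=0))

    @classmethod
    def identity(cls, n_rois: int) -> "NormStats":
        return cls(mean=np.zeros((n_rois, n_rois)), var=np.ones((n_rois, n_rois)) - _EPS)


def _normalize(E: np.ndarray, stats: NormStats) -> tuple[np.ndarray, np.ndarray]:
    scale = 1.0 / np.sqrt(stats.var + _EPS)
    return (E - stats.mean) * scale, scale


def _forward(
    E: np.ndarray,
    params: NetworkParams,
    stats: NormStats,
    training_mode: bool,
    dropout_rng: np.random.Generator | None,
) -> dict[str, np.ndarray]:
    """Batched forward pass; E is (B, R, R). Returns the full cache."""
    Z, scale = _normalize(E, stats)
    H = (
        np.einsum("bij,fj->bif", Z, params.row_weights)
        + np.einsum("bji,fj->bif", Z, params.col_weights)
        + params.e2n_bias
    )
    A1 = vleaky_relu(H)
    g = np.einsum("bif,mif->bm", A1, params.n2g_weights) + params.n2g_bias
    A2 = vleaky_relu(g)
    if training_mode:
        if dropout_rng is None:
            raise ValueError("training-mode forward requires a dropout RNG")
        mask = (dropout_rng.uniform(size=A2.shape) >= 0.5) / 0.5  # inverted dropout
        A2d = A2 * mask
    else:
        mask = np.ones_like(A2)
        A2d = A2
    y = A2d @ params.out_weights + params.out_bias[0]
    return {
        "Z": Z, "scale": scale, "H": H, "A1": A1, "g": g, "A2": A2,
        "mask": mask, "A2d": A2d, "y": y,
    }


def _backward(
    cache: dict[str, np.ndarray],
    params: NetworkParams,
    dy: np.ndarray,
    want_input_grad: bool = False,
) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Gradients of sum(dy * y) w.r.t. parameters and (optionally) inputs."""
    A2d, mask, g, A1, H, Z = (
        cache["A2d"], cache["mask"], cache["g"], cache["A1"], cache["H"], cache["Z"],
    )
    d_w3 = A2d.T @ dy
    d_b3 = dy.sum()
    dA2 = np.outer(dy, params.out_weights) * mask
    dg = dA2 * _vleaky_grad(g)
    d_W2 = np.einsum("bm,bif->mif", dg, A1)
    d_b2 = dg.sum(axis=0)
    dA1 = np.einsum("bm,mif->bif", dg, params.n2g_weights)
    dH = dA1 * _vleaky_grad(H)
    d_rw = np.einsum("bif,bij->fj", dH, Z)
    d_cw = np.einsum("bif,bji->fj", dH, Z)
    d_b1 = dH.sum(axis=(0, 1))
    grads = [d_rw, d_cw, d_b1, d_W2, d_b2, d_w3, np.atleast_1d(d_b3)]
    dE = None
    if want_input_grad:
        dZ = np.einsum("bif,fj->bij", dH, params.row_weights) + np.einsum(
            "bif,fj->bji", dH, params.col_weights
        )
        dE = dZ * cache["scale"]  # normalization Jacobian folded in
    return grads, dE


def model_forward(
    E: FCMatrix | np.ndarray,
    params: NetworkParams,
    config: NetworkConfig,
    stats: NormStats,
    training_mode: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> float:
    """Score a single FC matrix. Evaluation mode is deterministic."""
    values = E.values if isinstance(E, FCMatrix) else np.asarray(E, dtype=float)
    if values.shape != stats.mean.shape:
        raise ValueError(
            f"FC matrix shape {values.shape} does not match model "
            f"dimension {stats.mean.shape}"
        )
    cache = _forward(values[None], params, stats, training_mode, dropout_rng)
    return float(cache["y"][0])


def input_gradient(
    E: FCMatrix | np.ndarray,
    params: NetworkParams,
    config: NetworkConfig,
    stats: NormStats,
) -> np.ndarray:
    """Exact gradient of the evaluation-mode score w.r.t. each input edge."""
    values = E.values if isinstance(E, FCMatrix) else np.asarray(E, dtype=float)
    cache = _forward(values[None], params, stats, training_mode=False,
                     dropout_rng=None)
    _, dE = _backward(cache, params, np.ones(1), want_input_grad=True)
    assert dE is not None
    return dE[0]


@dataclass(frozen=True)
class SearchSpace:
    """Random-search space over training hyperparameters.

    Filter/unit counts, epochs and batch sizes are uniform over the listed
    choices; the learning rate is log-uniform over ``learning_rate_range``.
    """

    n_e2n_filters: tuple[int, ...] = (16, 32, 64)
    n_n2g_units: tuple[int, ...] = (16, 32, 64)
    learning_rate_range: tuple[float, float] = (1e-4, 1e-2)
    n_epochs: tuple[int, ...] = (50, 100, 200)
    batch_size: tuple[int, ...] = (8, 16)
    n_draws: int = 10

    def __post_init__(self) -> None:
        for name in ("n_e2n_filters", "n_n2g_units", "n_epochs", "batch_size"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty choice set for {name}")
        lo, hi = self.learning_rate_range
        if not (0 < lo <= hi):
            raise ValueError("learning_rate_range must satisfy 0 < lo <= hi")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


#: Small single-draw space for quick experiments and null-calibration runs.
REDUCED_SEARCH_SPACE = SearchSpace(
    n_e2n_filters=(4,),
    n_n2g_units=(8,),
    learning_rate_range=(1e-2, 1e-2),
    n_epochs=(60,),
    batch_size=(16,),
    n_draws=1,
)

#: Desk-scale single-draw space with enough capacity and epochs for reliable
#: planted-signal recovery on networks of a few dozen ROIs.
DESK_SEARCH_SPACE = SearchSpace(
    n_e2n_filters=(8,),
    n_n2g_units=(16,),
    learning_rate_range=(1e-2, 1e-2),
    n_epochs=(100,),
    batch_size=(16,),
    n_draws=1,
)


def sample_hyperparameters(space: SearchSpace, seed: int) -> list[NetworkConfig]:
    """Draw ``space.n_draws`` configurations uniformly; reproducible by seed."""
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(space.n_draws):
        lo, hi = space.learning_rate_range
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        configs.append(
            NetworkConfig(
                n_e2n_filters=int(rng.choice(space.n_e2n_filters)),
                n_n2g_units=int(rng.choice(space.n_n2g_units)),
                learning_rate=lr,
                n_epochs=int(rng.choice(space.n_epochs)),
                batch_size=int(rng.choice(space.batch_size)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class FittedModel:
    """A trained network: parameters, its config, normalization statistics,
    and the per-epoch training-loss trace."""

    params: NetworkParams
    config: NetworkConfig
    stats: NormStats
    loss_history: np.ndarray

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1])

    def predict(self, matrices: list[FCMatrix] | np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode scores for a batch of matrices."""
        E = _stack(matrices)
        cache = _forward(E, self.params, self.stats, training_mode=False,
                         dropout_rng=None)
        return cache["y"]


def _stack(matrices: list[FCMatrix] | np.ndarray) -> np.ndarray:
    if isinstance(matrices, np.ndarray):
        return matrices
    return np.stack([m.values for m in matrices])


def _train_one(
    E: np.ndarray, targets: np.ndarray, config: NetworkConfig
) -> FittedModel:
    """Train a single configuration with Adam on mean-squared loss."""
    n, R = E.shape[0], E.shape[1]
    rng = np.random.default_rng(config.seed)
    params = NetworkParams.init(R, config, rng)
    train_stats = NormStats.from_batch(E)
    if config.normalization == "none":
        train_stats = NormStats.identity(R)

    theta = params.flat()
    m = [np.zeros_like(p) for p in theta]
    v = [np.zeros_like(p) for p in theta]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    batch = min(config.batch_size, n)
    losses = []
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Eb, tb = E[idx], targets[idx]
            if config.normalization == "batch" and len(idx) > 1:
                stats = NormStats.from_batch(Eb)
            else:
                stats = train_stats
            cache = _forward(Eb, params, stats, training_mode=True, dropout_rng=rng)
            resid = cache["y"] - tb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"lr={config.learning_rate:g}, config={config}"
                )
            epoch_loss += loss * len(idx)
            dy = 2.0 * resid / len(idx)
            grads, _ = _backward(cache, params, dy)
            if config.tie_e2n_weights:
                shared = grads[0] + grads[1]
                grads[0] = grads[1] = shared
            step += 1
            for p, g_, m_, v_ in zip(theta, grads, m, v):
                m_ *= beta1
                m_ += (1 - beta1) * g_
                v_ *= beta2
                v_ += (1 - beta2) * g_**2
                mhat = m_ / (1 - beta1**step)
                vhat = v_ / (1 - beta2**step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        losses.append(epoch_loss / n)
    # Evaluation uses training-set statistics (fixed, deterministic).
    return FittedModel(params, config, train_stats, np.array(losses))


def fit_fold(
    train_matrices: list[FCMatrix] | np.ndarray,
    targets: np.ndarray,
    space: SearchSpace = REDUCED_SEARCH_SPACE,
    seed: int = 0,
) -> FittedModel:
    """Random-search tuning on one training fold.

    Trains one network per sampled configuration and returns the fitted
    model with the lowest final training loss. Targets are the raw 1-6
    ideology values treated as continuous.
    """
    E = _stack(train_matrices)
    targets = np.asarray(targets, dtype=float)
    if E.shape[0] != targets.size:
        raise ValueError("number of matrices and targets differ")
    if E.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    best: FittedModel | None = None
    for config in sample_hyperparameters(space, seed):
        fitted = _train_one(E, targets, config)
        if best is None or fitted.final_loss < best.final_loss:
            best = fitted
    assert best is not None
    return best


def make_folds(
    subject_ids: list[str],
    k: int,
    seed: int,
    ideology: np.ndarray | None = None,
) -> dict[str, int]:
    """Seeded partition of subjects into k folds.

    Unstratified by default; if ``ideology`` is given, subjects are sorted
    by ideology and dealt round-robin (after a seeded within-tie shuffle),
    balancing the outcome across folds.
    """
    n = len(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if ideology is not None:
        order = order[np.argsort(np.asarray(ideology)[order], kind="stable")]
    assignment: dict[str, int] = {}
    for pos, idx in enumerate(order):
        assignment[subject_ids[idx]] = pos % k
    return assignment


@dataclass
class CVResult:
    """Out-of-fold scores plus the per-(task, fold) fitted models."""

    score_matrix: IdeologyScoreMatrix
    models: dict[tuple[str, int], FittedModel]

    @property
    def fold_assignment(self) -> dict[str, int]:
        assert self.score_matrix.fold_assignment is not None
        return self.score_matrix.fold_assignment

    def model_for(self, subject_id: str, task_id: str) -> FittedModel:
        """The model that scored this subject (trained without its fold)."""
        return self.models[(task_id, self.fold_assignment[subject_id])]


def cross_validated_scores(
    dataset: dict[tuple[str, str], FCMatrix],
    cohort: pd.DataFrame,
    k: int = 10,
    space: SearchSpace = REDUCED_SEARCH_SPACE,
    seed: int = 0,
    stratify: bool = False,
) -> CVResult:
    """Out-of-fold ideology scores for every subject and task.

    Subjects are partitioned into ``k`` folds once (seeded) and the same
    partition is reused for every task. For each task and fold, a network
    is tuned and trained on the out-of-fold subjects only and then scores
    the held-out subjects, so no score ever uses a model that saw its
    subject. ``k = n`` gives leave-one-out.
    """
    subjects = list(cohort["subject_id"].astype(str))
    tasks = sorted({t for (_, t) in dataset})
    for s in subjects:
        for t in tasks:
            if (s, t) not in dataset:
                raise ValueError(f"dataset missing matrix for subject {s!r}, task {t!r}")
    y = cohort.set_index("subject_id")["conservatism"].astype(float)
    folds = make_folds(
        subjects, k, seed,
        ideology=y.loc[subjects].to_numpy() if stratify else None,
    )

    scores = pd.DataFrame(
        np.nan, index=pd.Index(subjects, name="subject_id"), columns=tasks
    )
    models: dict[tuple[str, int], FittedModel] = {}
    search_rng = np.random.default_rng(seed)
    for task in tasks:
        for fold in range(k):
            test_subjects = [s for s in subjects if folds[s] == fold]
            train_subjects = [s for s in subjects if folds[s] != fold]
            train_mats = [dataset[(s, task)] for s in train_subjects]
            fold_seed = int(search_rng.integers(0, 2**31 - 1))
            fitted = fit_fold(
                train_mats, y.loc[train_subjects].to_numpy(), space, fold_seed
            )
            models[(task, fold)] = fitted
            test_mats = [dataset[(s, task)] for s in test_subjects]
            scores.loc[test_subjects, task] = fitted.predict(test_mats)

    matrix = IdeologyScoreMatrix(scores=scores, fold_assignment=folds)
    return CVResult(score_matrix=matrix, models=models)
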