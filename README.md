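# polconn

Connectome-based prediction of political ideology from functional
connectivity (FC), for researchers in network neuroscience and political
neuroscience who want a tested, reusable, fully seeded pipeline from
ROI-averaged BOLD time series to region-level saliency maps.

The scientific question the pipeline addresses: given per-subject,
per-task FC matrices **E** (entries `E_ij` = Pearson correlation between
the BOLD series of brain regions i and j, after task-evoked activation is
regressed out), how well does brain connectivity predict a subject's
6-point liberal-conservative self-placement `y_k`, which tasks carry that
signal, does FC add to classical survey predictors such as parental
conservatism, and which edges and regions drive the prediction?

## The model

A connectome convolutional regression network maps each R x R matrix to a
continuous ideology score:

    normalize -> E2N -> f -> N2G -> f -> dropout(0.5) -> linear -> y_hat

The edge-to-node (E2N) layer applies cross-shaped filters,
`H_if = sum_j ( rw_fj E_ij + cw_fj E_ji ) + b_f`; the node-to-graph (N2G)
layer collapses node features by full weighted summation; the activation
is the very leaky ReLU `f(x) = x` for `x >= 0`, `x/3` otherwise; training
minimizes the Euclidean (squared-error) loss on the raw 1-6 labels, with
hyperparameters tuned per fold by random search. Scores are strictly
out-of-fold: subject k's score `y_{t,k}` for task t comes from a model
that never saw subject k.

Downstream, the 174 x 9 score matrix feeds Pearson correlation analyses
(overall / moderate / extreme responders, Bonferroni-corrected), PCA of
the score matrix, Monte Carlo cross-validated AUC comparison of logistic
models against a parent-conservatism benchmark, L1-penalized (LASSO)
variable importance with an unpenalized refit, and gradient saliency: the
dataset-mean `d y_{t,k} / d E_ij`, summarized as weighted degree
centrality and aggregated to 78 anatomical regions.

The forward *and* backward passes are written explicitly in numpy, so the
saliency gradients are exact (they are checked against central finite
differences in the test suite). A seeded synthetic-data generator emulates
the cohort structure the pipeline targets — exact ideology histogram,
copula-linked survey covariates, planted edge-ideology signal — so every
stage is testable against known ground truth. See `docs/methods.md` for
the full model description and design choices.

## Worked example

A desk-scale end-to-end run — 174 synthetic subjects, 40 ROIs, two tasks,
with a two-edge signal planted in the `empathy` task (positive effect on
edge (3, 7), negative on (12, 20)):

```python
import numpy as np
from polconn import (
    PlantedTruth, SignalEdge, generate_cohort, generate_bold_timeseries,
    assemble_dataset, cross_validated_scores, top_signed_edges,
)
from polconn.network import DESK_SEARCH_SPACE
from polconn.saliency import edge_gradients

cohort = generate_cohort(seed=0)          # 174 subjects, histogram 24/52/49/36/9/4
truth = PlantedTruth(signal_edges=[
    SignalEdge("empathy", 3, 7, effect_size=0.18, base_correlation=0.35),
    SignalEdge("empathy", 12, 20, effect_size=-0.18, base_correlation=-0.35),
], seed=0)
series = generate_bold_timeseries(cohort, truth, n_rois=40, n_timepoints=150,
                                  missing_roi=None, task_ids=("affect", "empathy"))
matrices, _ = assemble_dataset(series)
cv = cross_validated_scores(matrices, cohort, k=5, space=DESK_SEARCH_SPACE, seed=100)

y = cohort["conservatism"].to_numpy(float)
for task in ("affect", "empathy"):
    r = np.corrcoef(cv.score_matrix.scores[task], y)[0, 1]
    print(f"{task:8s} score-ideology r = {r:+.3f}")
G = edge_gradients(cv, matrices, "empathy")
top = top_signed_edges(G, matrices[(cohort['subject_id'][0], 'empathy')].roi_labels)
print("conservatism edge:", top.conservative, " liberalism edge:", top.liberal)
```

prints

```
affect   score-ideology r = -0.037
empathy  score-ideology r = +0.556
conservatism edge: (3, 7)  liberalism edge: (12, 20)
```

The null task stays near zero, the planted task's out-of-fold scores
correlate with true ideology at r = 0.556, and the signed saliency map
recovers both planted edges exactly.

The same run is available from the shell:

```sh
polconn run-all --demo --seed 0 --out demo_run
```

which writes the cohort, FC archive, out-of-fold score matrix, correlation
and PCA tables, the model-comparison table (mirroring the AUC bar chart of
a typical study report), the LASSO importance table, and per-task region
importance and top-edge tables, plus a manifest with seeds and the config
hash.

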