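# Methods

`polconn` implements a connectome-based prediction pipeline for a
6-point liberal-conservative self-placement ("ideology", coded
1 = Very liberal ... 6 = Very conservative), from ROI-averaged BOLD time
series to region-level saliency maps. This note records the model, its
assumptions, the tunable parameters that matter, and the design choices
made where the design was genuinely open.

## Functional connectivity

For each subject and task condition, task-evoked activation is removed by
ordinary least squares: each ROI's time series is replaced by its residual
on `[intercept | design]`, where the design matrix encodes the task
regressors and is accepted as given (no HRF convolution is imposed).
Connectivity is the raw Pearson correlation between retained ROI columns —
no Fisher-z transform — stored as a full symmetric matrix with an exactly
zero diagonal and off-diagonal entries in [-1, 1].

A ROI is excluded when its column is entirely missing *or* has zero sample
variance; the second rule is ours (Pearson is undefined there), the first
mirrors the emulated study design, in which the 252nd of 269 ROIs is
all-missing, leaving a 268 x 268 matrix. ROI indices are 1-based
everywhere and the retained original indices travel with each matrix.
At dataset level, all matrices are restricted to the intersection of
retained ROIs so model input dimensions agree; exclusions are manifested.

## The regression network

The predictor is a small convolutional network tailored to connectivity
matrices:

    normalize -> E2N -> f -> N2G -> f -> dropout(0.5) -> linear -> score

* **E2N (edge-to-node)**: node i's feature f is a cross-shaped filter,
  `sum_j rw[f,j] E[i,j] + cw[f,j] E[j,i] + b[f]`. Because E is symmetric
  the row and column filters are redundant in expectation; both are kept to
  match the architecture, with `tie_e2n_weights` to share them.
* **N2G (node-to-graph)**: full weighted summation of the R x F node
  feature map into G graph-level scalars.
* **Activation** f is the very leaky ReLU, `f(x) = x` for `x >= 0`, `x/3`
  otherwise.
* **Dropout** (rate 0.5, architectural constant) follows the N2G
  activation and is active only in training mode; evaluation is
  deterministic.
* **Normalization**: vectorized edge inputs are standardized per edge. In
  the default "batch" mode, minibatch statistics are used during training
  (treated as constants in the backward pass) and training-set statistics
  at evaluation; a "dataset" mode uses fixed training-set statistics
  throughout, and "none" disables it.
* **Loss**: mean squared (Euclidean) error on the raw 1-6 Likert values
  treated as continuous. Classification happens downstream by logistic
  regression on the scores, never in the network.

Depth is exactly one E2N and one N2G layer plus a single linear output
unit; no edge-to-edge layer. The forward and backward passes are written
explicitly in numpy. The backward pass extends to the input edges, so the
saliency stage uses exact analytic gradients (verified against central
finite differences at 1e-4 relative tolerance in the test suite), with the
normalization Jacobian folded in; gradients are taken with respect to the
raw input edges.

Training uses Adam on shuffled minibatches. Hyperparameters the
architecture leaves open — filter counts, learning rate, epochs, batch
size — live in a random-search space; per cross-validation fold, one
network per sampled configuration is trained and the configuration with
the lowest final training loss wins. The documented full space is filters
in {16, 32, 64}, units in {16, 32, 64}, learning rate log-uniform in
[1e-4, 1e-2], epochs in {50, 100, 200}, batch size in {8, 16}. Two frozen
single-draw presets serve desk-scale work: `REDUCED_SEARCH_SPACE`
(4 filters, 8 units, lr 1e-2, 60 epochs) for null-calibration runs, and
`DESK_SEARCH_SPACE` (8 filters, 16 units, lr 1e-2, 100 epochs), sized so
that planted-signal recovery is reliable on networks of a few dozen ROIs.

### Out-of-fold scoring

Subjects are partitioned into k folds (default 10) once, seeded, and the
same partition is reused across all tasks. A subject's score for a task is
always produced by the model trained without that subject's fold, so no
score leaks its own label; tuning also sees training folds only. Fold
assignment is an unstratified seeded partition by default (stratification
by ideology is available). `k = n` gives leave-one-out.

## Score analytics

Per task, the Pearson correlation of out-of-fold scores with true ideology
is reported for the full sample and stratified subgroups: *extreme*
responders (categories 1 and 6) and *moderate* responders (2-5).
Significance uses the exact t-distribution test for Pearson r; a
chi-squared variant (`n r^2 ~ chi2(1)`) is available behind a flag because
its intent in the source protocol is unclear, but it is not the default.
Bonferroni correction multiplies the raw p by the number of simultaneous
tests (default 9, one per task) and caps at 1.

PCA of the subjects x tasks score matrix is computed on the correlation
scale (columns centered and scaled to unit variance) so that tasks
contribute on an equal footing; raw-covariance PCA is a switch. The
contribution of task j to component m is `100 * loading_jm^2 / sum_j
loading_jm^2`; variance fractions and per-component contributions each sum
to 100%.

## Model comparison

Ideology is dichotomized: categories 1-3 are liberal, 4-6 conservative.
Candidate logistic models (per-task scores, all task scores, survey
covariates, parent conservatism, combinations) are compared by Monte Carlo
cross-validation: each sample draws a test fraction uniformly from
[0.05, 0.50], draws a test set of that size, fits every model on the rest
(identical splits across models, so comparisons are paired), and records
test AUC and accuracy (0.5 probability threshold). The default is 1,000
samples. Splits whose train or test part lacks a class are redrawn, with a
cap of 100 retries. Models are summarized by mean AUC, SD and a percentile
95% CI, and classified against the parent-conservatism benchmark as
above / below / indistinguishable by CI disjointness — the source protocol
does not define its test, so this rule is ours and is stated in output.

A property worth knowing when interpreting null runs: conditional on one
dataset realization, repeated-split Monte Carlo AUC concentrates around a
dataset-specific value that can sit away from 0.5, because train and test
subsets share whatever spurious feature-label association that realization
happens to contain. The estimator is unbiased only across dataset
replicates, so chance-level checks here aggregate (median) over replicate
synthetic datasets.

## Variable importance

All task scores and survey covariates enter an L1-penalized logistic
regression; features are standardized to unit variance inside the call so
the absolute penalized coefficient is a comparable importance (this also
makes the ranking invariant to affine rescaling of raw features). The
penalty is chosen by cross-validated binomial deviance over a geometric
path of 50 strengths (1e-3 to 1e2 on the inverse-regularization scale);
the one-standard-error rule is optional. Variables surviving selection are
refit unpenalized for coefficients, Wald standard errors and two-sided
p-values, reported without multiplicity correction.

## Saliency

For each task, each subject's FC matrix is pushed through the model that
scored that subject out-of-fold (evaluation mode, dropout off), and the
exact gradient of the score with respect to every input edge is averaged
over subjects into a map G_t; the structurally-zero diagonal is zeroed.
A pooled variant averages over all fold models instead.

* **Centrality**: weighted degree, `centrality(i) = sum_j |G_t(i, j)|`.
* **Region aggregation**: ROI centralities are averaged within atlas
  regions; a region is flagged when its value exceeds the across-region
  mean by more than 1.645 across-region SDs (a one-sided 95% normal rule;
  configurable, and ours — the source protocol does not define its test).
* **Top signed edges**: after symmetrizing `(G + G^T)/2` (the two
  orientations of a symmetric input are not separately identifiable), the
  most positive entry over i < j is the top conservatism-predictive edge
  and the most negative the top liberalism-predictive edge. Sign
  convention: ideology is coded with conservatism high, so positive
  gradients push predictions toward conservatism. Ties break to the lowest
  (i, j) lexicographically; an all-zero map is an error, and a side with
  no gradient of its sign is returned as undefined with a warning.

The packaged 269-ROI -> 78-region grouping table
(`data/atlas_synthetic.tsv`) is a deterministic synthetic stand-in — 268
retained ROIs distributed over 39 anatomically-styled region labels per
hemisphere, ROI 252 excluded — because the exact atlas grouping of the
emulated study is not published. Users substitute their own table via
`AtlasMap.from_tsv`.

## Synthetic data generator

The generator emulates the statistical structure of the study the
pipeline targets: 174 subjects, ideology histogram (24, 52, 49, 36, 9, 4),
nine task conditions, 269 ROIs with the 252nd all-missing, and survey
covariates with the published covariate-ideology correlations (e.g.
mother's conservatism 0.417, father's 0.349, religiosity 0.279).

* **Cohort**: ideology categories are assigned exactly to the requested
  counts, then shuffled by seed. Each covariate is tied to ideology
  through a latent bivariate Gaussian copula and discretized to its Likert
  range using the study's marginal response frequencies; the latent
  correlation is attenuation-corrected for discretization on both sides,
  so realized Likert-Likert correlations hit their targets (within ±0.05
  at n = 5,000). Covariates are conditionally independent given ideology —
  only covariate-outcome correlations are published — with inter-covariate
  structure deliberately not modeled.
* **BOLD series**: independent standard normal columns per ROI; each
  planted signal edge makes its two ROI columns share a latent factor
  whose loading sets their correlation to `base + effect * z` in the
  subject's standardized ideology z (error if outside (-1, 1)). Planted
  edges within a task must not share ROIs. An optional design-spanned
  task-evoked component with seeded coefficients can be added without
  disturbing the noise stream, so the regression stage can be tested
  against the noise-only ground truth. Missingness is encoded as NaN, not
  zero.
* **Score matrices**: for testing the analytics stages without training,
  columns with exactly known score-ideology correlations are generated by
  orthogonalizing Gaussian noise against ideology in-sample.

What the generator does **not** emulate: temporal autocorrelation of BOLD,
hemodynamic response shape, spatial correlation among neighboring ROIs,
scanner/session effects, and inter-covariate dependence. Passing tests
therefore demonstrate that the pipeline recovers structure it is pointed
at and stays calibrated under a clean null — not that the real
neuroimaging effect sizes are reproduced.

## Numerical choices and degenerate inputs

Normalization uses a 1e-5 variance floor (constant edges, including the
zero diagonal, normalize to 0). Training aborts with diagnostics on a
non-finite loss. Logistic fits detect separation via implausible
standardized slopes or solver saturation and fall back to a lightly
ridge-regularized fit, flagged. Monte Carlo splits with a single-class
side are redrawn. The FC archive carries a SHA-256 checksum; truncation is
detected on read. All randomness flows from explicit integer seeds;
repeated runs on the same platform produce byte-identical score tables.

## Problem sizes used in the shipped checks

The test suite and the acceptance script exercise the pipeline at desk
scale, chosen as the smallest sizes at which each statistical claim is
comfortably testable: 174 synthetic subjects, 40 ROIs and 150 timepoints
for training runs (10 folds; 5 folds in the per-seed saliency
replicates), 200 Monte Carlo comparison samples, and 5-10 replicate seeds
for rate-style claims; structural-count checks use the full 269-ROI
geometry. Study-scale runs (269 ROIs, full random search) use the same
code paths through `RunConfig` defaults.
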