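"""Tests of the connectome network: layer forwards against brute-force
oracles, activation formula, input gradients against finite differences,
random-search tuning, training sanity and out-of-fold bookkeeping."""

import numpy as np
import pytest

from polconn.network import (
    REDUCED_SEARCH_SPACE,
    NetworkConfig,
    NetworkParams,
    NormStats,
    SearchSpace,
    cross_validated_scores,
    e2n_forward,
    fit_fold,
    input_gradient,
    make_folds,
    model_forward,
    n2g_forward,
    sample_hyperparameters,
    vleaky_relu,
)


def _brute_e2n(E, rw, cw, b):
    R, F = E.shape[0], rw.shape[0]
    out = np.zeros((R, F))
    for i in range(R):
        for f in range(F):
            acc = b[f]
            for j in range(R):
                acc += rw[f, j] * E[i, j] + cw[f, j] * E[j, i]
            out[i, f] = acc
    return out


def _brute_n2g(H, W, b):
    G = W.shape[0]
    out = np.zeros(G)
    for m in range(G):
        acc = b[m]
        for i in range(H.shape[0]):
            for f in range(H.shape[1]):
                acc += W[m, i, f] * H[i, f]
        out[m] = acc
    return out


class TestVleakyRelu:
    @pytest.mark.parametrize("x,expected", [(3.0, 3.0), (-3.0, -1.0), (0.0, 0.0)])
    def test_scalar_values(self, x, expected):
        assert vleaky_relu(x) == expected

    def test_elementwise(self):
        np.testing.assert_allclose(
            vleaky_relu(np.array([-6.0, -1.5, 0.0, 2.0])),
            [-2.0, -0.5, 0.0, 2.0],
        )


class TestLayerOracles:
    def test_e2n_hand_computation(self):
        E = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = e2n_forward(E, np.array([[0.0, 1.0]]), np.zeros((1, 2)), np.zeros(1))
        np.testing.assert_allclose(out[:, 0], [1.0, 0.0])

    def test_e2n_zero_weights_broadcast_bias(self, rng):
        E = rng.standard_normal((4, 4))
        out = e2n_forward(E, np.zeros((3, 4)), np.zeros((3, 4)), np.array([1., 2., 3.]))
        np.testing.assert_allclose(out, np.tile([1.0, 2.0, 3.0], (4, 1)))

    def test_n2g_all_ones_sums_entries(self, rng):
        H = rng.standard_normal((5, 3))
        out = n2g_forward(H, np.ones((2, 5, 3)), np.zeros(2))
        np.testing.assert_allclose(out, [H.sum(), H.sum()])

    def test_n2g_zero_input_gives_bias(self):
        out = n2g_forward(np.zeros((4, 2)), np.ones((3, 4, 2)), np.array([5., 6., 7.]))
        np.testing.assert_allclose(out, [5.0, 6.0, 7.0])

    def test_random_instances_match_brute_force(self):
        # 50 random instances of each layer against triple-loop evaluation
        rng = np.random.default_rng(123)
        for _ in range(50):
            R, F, G = rng.integers(2, 8), rng.integers(1, 5), rng.integers(1, 4)
            E = rng.standard_normal((R, R))
            rw, cw = rng.standard_normal((2, F, R))
            b1 = rng.standard_normal(F)
            H = e2n_forward(E, rw, cw, b1)
            np.testing.assert_allclose(H, _brute_e2n(E, rw, cw, b1),
                                       rtol=1e-10, atol=1e-10)
            W2 = rng.standard_normal((G, R, F))
            b2 = rng.standard_normal(G)
            np.testing.assert_allclose(
                n2g_forward(H, W2, b2), _brute_n2g(H, W2, b2),
                rtol=1e-10, atol=1e-10,
            )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            e2n_forward(rng.standard_normal((3, 3)),
                        rng.standard_normal((2, 4)),
                        rng.standard_normal((2, 4)), np.zeros(2))
        with pytest.raises(ValueError):
            n2g_forward(rng.standard_normal((3, 2)),
                        rng.standard_normal((2, 3, 3)), np.zeros(2))


def _random_model(rng, R=10, F=3, G=4):
    cfg = NetworkConfig(n_e2n_filters=F, n_n2g_units=G)
    params = NetworkParams.init(R, cfg, rng)
    stats = NormStats.from_batch(rng.standard_normal((20, R, R)))
    return cfg, params, stats


def _sym(rng, R):
    E = rng.standard_normal((R, R))
    E = (E + E.T) / 2
    np.fill_diagonal(E, 0.0)
    return E


class TestModelForward:
    def test_zero_params_return_bias(self, rng):
        cfg, params, stats = _random_model(rng)
        for arr in params.flat():
            arr[...] = 0.0
        params.out_bias[0] = 2.5
        assert model_forward(_sym(rng, 10), params, cfg, stats) == pytest.approx(2.5)

    def test_linear_functional_composition(self, rng):
        # one filter / one unit wired to realize score = sum_j c_j Z[0, j]
        R = 6
        cfg = NetworkConfig(n_e2n_filters=1, n_n2g_units=1)
        c = rng.uniform(0.5, 1.5, size=R)  # positive weights keep activations
        params = NetworkParams(                      # in the identity branch
            row_weights=c[None, :],
            col_weights=np.zeros((1, R)),
            e2n_bias=np.array([10.0]),  # bias keeps E2N output positive
            n2g_weights=np.zeros((1, R, 1)),
            n2g_bias=np.zeros(1),
            out_weights=np.ones(1),
            out_bias=np.zeros(1),
        )
        params.n2g_weights[0, 0, 0] = 1.0
        stats = NormStats.identity(R)
        E = np.abs(_sym(rng, R))  # non-negative entries
        expected = float(c @ E[0]) + 10.0
        assert model_forward(E, params, cfg, stats) == pytest.approx(expected)

    def test_evaluation_mode_deterministic(self, rng):
        cfg, params, stats = _random_model(rng)
        E = _sym(rng, 10)
        assert model_forward(E, params, cfg, stats) == model_forward(
            E, params, cfg, stats
        )

    def test_dimension_mismatch_rejected(self, rng):
        cfg, params, stats = _random_model(rng, R=10)
        with pytest.raises(ValueError, match="dimension"):
            model_forward(_sym(rng, 8), params, cfg, stats)

    def test_input_gradient_matches_finite_differences(self):
        # central differences on random 10-ROI models
        rng = np.random.default_rng(7)
        for trial in range(3):
            cfg, params, stats = _random_model(rng)
            E = _sym(rng, 10)
            g = input_gradient(E, params, cfg, stats)
            h = 1e-5
            fd = np.zeros_like(E)
            for i in range(10):
                for j in range(10):
                    Ep, Em = E.copy(), E.copy()
                    Ep[i, j] += h
                    Em[i, j] -= h
                    fd[i, j] = (
                        model_forward(Ep, params, cfg, stats)
                        - model_forward(Em, params, cfg, stats)
                    ) / (2 * h)
            denom = np.abs(fd).max()
            assert np.abs(g - fd).max() / denom < 1e-4


class TestConfigValidation:
    def test_architectural_constants_fixed(self):
        with pytest.raises(ValueError, match="dropout"):
            NetworkConfig(dropout_rate=0.3)
        with pytest.raises(ValueError, match="leak"):
            NetworkConfig(leak_slope=0.5)


class TestSampleHyperparameters:
    def test_singleton_space_returns_that_config(self):
        space = SearchSpace(
            n_e2n_filters=(8,), n_n2g_units=(4,),
            learning_rate_range=(1e-3, 1e-3), n_epochs=(10,),
            batch_size=(4,), n_draws=1,
        )
        (cfg,) = sample_hyperparameters(space, seed=0)
        assert (cfg.n_e2n_filters, cfg.n_n2g_units) == (8, 4)
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert (cfg.n_epochs, cfg.batch_size) == (10, 4)

    def test_same_seed_identical_draws(self):
        space = SearchSpace(n_draws=5)
        assert sample_hyperparameters(space, 3) == sample_hyperparameters(space, 3)

    def test_two_choice_frequencies_balanced(self):
        space = SearchSpace(n_epochs=(10, 20), n_draws=1000)
        draws = sample_hyperparameters(space, seed=1)
        frac = np.mean([c.n_epochs == 10 for c in draws])
        assert 0.45 <= frac <= 0.55

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SearchSpace(n_e2n_filters=())


def _planted_batch(rng, n=200, R=8, slope=1.2):
    """FC-like symmetric matrices where edge (0,1) carries a linear signal."""
    y = rng.uniform(1, 6, size=n)
    E = rng.standard_normal((n, R, R)) * 0.1
    E = (E + E.transpose(0, 2, 1)) / 2
    signal = (y - 3.5) / 2.5 * slope
    E[:, 0, 1] = E[:, 1, 0] = signal
    for b in range(n):
        np.fill_diagonal(E[b], 0.0)
    return E, y


class TestFitFold:
    def test_constant_targets_learned(self, rng):
        # dropout keeps injecting noise, so the collapse to a constant needs
        # a longer epoch budget than the signal-recovery settings
        E, _ = _planted_batch(rng, n=40)
        space = SearchSpace(n_e2n_filters=(4,), n_n2g_units=(8,),
                            learning_rate_range=(1e-2, 1e-2), n_epochs=(600,),
                            batch_size=(16,), n_draws=1)
        model = fit_fold(E, np.full(40, 4.0), space, seed=0)
        assert np.abs(model.predict(E) - 4.0).max() < 0.1

    def test_planted_signal_beats_intercept_baseline(self, rng):
        E, y = _planted_batch(rng)
        model = fit_fold(E, y, REDUCED_SEARCH_SPACE, seed=0)
        assert model.final_loss < y.var()

    def test_seed_reproducibility(self, rng):
        E, y = _planted_batch(rng, n=30)
        space = SearchSpace(n_draws=3, n_epochs=(5,), n_e2n_filters=(2, 4),
                            n_n2g_units=(4,), batch_size=(8,))
        a = fit_fold(E, y, space, seed=9)
        b = fit_fold(E, y, space, seed=9)
        assert a.config == b.config
        np.testing.assert_array_equal(a.loss_history, b.loss_history)

    def test_too_few_subjects_rejected(self, rng):
        E, y = _planted_batch(rng, n=1)
        with pytest.raises(ValueError, match="2 training subjects"):
            fit_fold(E[:1], y[:1], REDUCED_SEARCH_SPACE, seed=0)


class TestFolds:
    def test_partition_covers_all_subjects(self):
        subs = [f"S{i}" for i in range(23)]
        folds = make_folds(subs, k=5, seed=0)
        assert set(folds) == set(subs)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(["a", "b"], k=3, seed=0)

    def test_stratified_balances_outcome(self):
        ideology = np.repeat([1, 2, 3, 4, 5, 6], 10)
        subs = [f"S{i}" for i in range(60)]
        folds = make_folds(subs, k=5, seed=1, ideology=ideology)
        means = [
            np.mean([ideology[i] for i, s in enumerate(subs) if folds[s] == f])
            for f in range(5)
        ]
        assert max(means) - min(means) < 0.8


class TestCrossValidatedScores:
    def test_leave_one_out_contract(self, small_cohort, small_fc_dataset):
        tiny = small_cohort.head(6).reset_index(drop=True)
        dataset = {
            (s, t): fc
            for (s, t), fc in small_fc_dataset.items()
            if s in set(tiny["subject_id"])
        }
        space = SearchSpace(n_e2n_filters=(2,), n_n2g_units=(2,),
                            learning_rate_range=(1e-2, 1e-2), n_epochs=(3,),
                            batch_size=(4,), n_draws=1)
        cv = cross_validated_scores(dataset, tiny, k=6, space=space, seed=0)
        folds = cv.fold_assignment
        assert sorted(folds.values()) == list(range(6))
        assert np.isfinite(cv.score_matrix.scores.to_numpy()).all()

    def test_scores_never_use_own_fold_model(self, small_cohort, small_fc_dataset):
        space = SearchSpace(n_e2n_filters=(2,), n_n2g_units=(2,),
                            learning_rate_range=(1e-2, 1e-2), n_epochs=(5,),
                            batch_size=(8,), n_draws=1)
        cv = cross_validated_scores(
            small_fc_dataset, small_cohort, k=3, space=space, seed=1
        )
        # recompute each subject's score with its out-of-fold model: must match
        for subj in small_cohort["subject_id"].head(5):
            model = cv.model_for(subj, "affect")
            expected = model.predict([small_fc_dataset[(subj, "affect")]])[0]
            assert cv.score_matrix.scores.loc[subj, "affect"] == pytest.approx(
                expected
            )

    def test_missing_matrix_rejected(self, small_cohort, small_fc_dataset):
        broken = dict(small_fc_dataset)
        key = (small_cohort["subject_id"].iloc[0], "affect")
        del broken[key]
        with pytest.raises(ValueError, match="missing matrix"):
            cross_validated_scores(broken, small_cohort, k=3,
                                   space=REDUCED_SEARCH_SPACE, seed=0)
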