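"""Bias-space geometry: drift correction, augmentation, speed axis."""

import autograd.numpy as anp
import numpy as np
import pytest
from scipy.stats import spearmanr

import clfads as cl
from clfads.biasspace import solve_speed_shift_fn


class TestDriftCorrection:
    def test_equal_means_is_identity(self, rng):
        b = rng.normal(0, 1, (6, 3))
        b[3:] = b[:3]  # early and late sets identical
        out = cl.correct_bias_drift(b, [0, 1, 2], [3, 4, 5])
        assert np.allclose(out, b)

    def test_arithmetic_example(self):
        # early mean (1,1), late mean (3,2): early bias (1,0) -> (3,1)
        b = np.array([[1.0, 0.0], [1.0, 2.0], [3.0, 2.0]])
        out = cl.correct_bias_drift(b, [0, 1], [2])
        assert np.allclose(out[0], [3.0, 1.0])
        assert np.allclose(out[2], b[2])  # late untouched

    def test_corrected_early_mean_equals_late_mean(self, rng):
        b = rng.normal(0, 2, (20, 4))
        early, late = np.arange(8), np.arange(12, 20)
        out = cl.correct_bias_drift(b, early, late)
        assert np.allclose(out[early].mean(0), b[late].mean(0), atol=1e-12)

    def test_idempotent(self, rng):
        b = rng.normal(0, 1, (10, 3))
        early, late = np.arange(4), np.arange(6, 10)
        once = cl.correct_bias_drift(b, early, late)
        twice = cl.correct_bias_drift(once, early, late)
        assert np.allclose(once, twice, atol=1e-12)

    def test_same_algebra_for_initial_conditions(self, rng):
        g0 = rng.normal(0, 1, (10, 6))
        early, late = np.arange(3), np.arange(7, 10)
        out = cl.correct_initial_conditions(g0, early, late)
        assert np.allclose(out[early].mean(0), g0[late].mean(0), atol=1e-12)
        assert np.allclose(out[late], g0[late])

    def test_invalid_id_sets_rejected(self, rng):
        b = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError):
            cl.correct_bias_drift(b, [], [1])
        with pytest.raises(ValueError):
            cl.correct_bias_drift(b, [0, 1], [1, 2])


class TestAugmentTrials:
    def test_empty_early_set_equals_plain_inference(self, tiny_model,
                                                    tiny_dataset):
        train, _, _ = tiny_dataset
        late = np.arange(4, 8)
        # an empty early set is expressed by augmenting nothing: compare
        # the late part of the corpus against direct inference
        aug = cl.augment_trials(tiny_model, train, [0], late)
        _, roll = cl.infer(train.subset(late), tiny_model)
        late_rows = ~aug.is_corrected
        assert np.allclose(aug.rates[late_rows], roll.rates, rtol=1e-6)

    def test_zero_drift_leaves_rates_bitwise_unchanged(self, tiny_model,
                                                       tiny_dataset):
        train, _, _ = tiny_dataset
        post = tiny_model.encode(train)
        # construct early/late sets with exactly equal posterior means by
        # duplicating trials: trial 0 plays both roles via two copies
        doubled = train.subset([0, 0, 1, 1])
        aug = cl.augment_trials(tiny_model, doubled, [0], [1])
        # rows 0 (corrected early copy) and 1 (late copy) are the same trial
        # with zero measured drift, rolled out in the same batch
        assert bool(aug.is_corrected[0]) and not bool(aug.is_corrected[1])
        assert np.array_equal(aug.rates[0], aug.rates[1])

    def test_empty_late_set_is_an_error(self, tiny_model, tiny_dataset):
        with pytest.raises(ValueError, match="late"):
            cl.augment_trials(tiny_model, tiny_dataset[0], [0, 1], [])


class TestSolveSpeedShift:
    def test_alpha_one_returns_zero_shift(self, tiny_model, tiny_dataset):
        train, _, _ = tiny_dataset
        post, roll = cl.infer(train, tiny_model.astype(np.float64))
        db, j = cl.solve_speed_shift(tiny_model, roll.g[:4], post.b_mean[:4],
                                     alpha=1.0)
        assert np.linalg.norm(db) < 1e-6
        assert j < 1e-10

    def test_linear_generator_matches_normal_equations(self, rng):
        # g' = W g + U b + c: the objective is an exact least squares in db
        G_, d_ = 5, 3
        W = rng.normal(0, 0.3, (G_, G_))
        U = rng.normal(0, 1.0, (d_, G_))
        c = rng.normal(0, 1.0, G_)

        def F(Gm, Bm):
            return anp.dot(Gm, W) + anp.dot(Bm, U) + c

        M = 40
        states = rng.normal(0, 1, (M, G_))
        biases = rng.normal(0, 1, (M, d_))
        alpha = 1.2
        D = (alpha - 1) * (np.asarray(F(states, biases)) - states)
        db_closed = np.linalg.solve(M * (U @ U.T), U @ D.sum(axis=0))
        db, _ = solve_speed_shift_fn(F, states, biases, alpha, d_)
        assert np.max(np.abs(db - db_closed)) < 1e-5

    def test_objective_never_worse_than_zero_shift(self, tiny_model,
                                                   tiny_dataset, rng):
        train, _, _ = tiny_dataset
        post, roll = cl.infer(train, tiny_model.astype(np.float64))
        for alpha in (0.7, 1.3):
            db, j = cl.solve_speed_shift(tiny_model, roll.g[:4],
                                         post.b_mean[:4], alpha)
            # evaluate the objective at db = 0 independently
            F = lambda B: tiny_model.step(roll.g[:4].reshape(-1, 12),
                                          b=np.repeat(post.b_mean[:4],
                                                      train.n_bins, 0) + B)
            G = roll.g[:4].reshape(-1, 12)
            F0 = F(np.zeros(3))
            target = G + alpha * (F0 - G)
            j0 = float(np.sum((F0 - target) ** 2))
            assert j <= j0 + 1e-12

    def test_speedup_shift_increases_update_norm(self, tiny_model,
                                                 tiny_dataset):
        train, _, _ = tiny_dataset
        m64 = tiny_model.astype(np.float64)
        post, roll = cl.infer(train, m64)
        G = roll.g.reshape(-1, 12)
        Bm = np.repeat(post.b_mean, train.n_bins, axis=0)
        db, _ = cl.solve_speed_shift(tiny_model, roll.g, post.b_mean, 1.2)
        step0 = np.asarray(m64.step(G, b=Bm)) - G
        step1 = np.asarray(m64.step(G, b=Bm + db)) - G
        assert np.mean(np.linalg.norm(step1, axis=1)) \
            > np.mean(np.linalg.norm(step0, axis=1))


class TestSpeedAxis:
    def test_rank_one_shifts_recover_direction(self):
        v = np.array([1.0, 2.0, -1.0])
        v /= np.linalg.norm(v)
        shifts = {a: (a - 1) * v for a in (0.7, 0.8, 0.9, 1.1, 1.2, 1.3)}
        ax = cl.speed_axis(shifts)
        assert np.allclose(ax, v, atol=1e-12)

    def test_mixed_sign_columns_sign_fixed_by_largest_alpha(self):
        v = np.array([0.0, 1.0])
        shifts = {0.7: 0.5 * v, 1.3: -0.4 * v}
        ax = cl.speed_axis(shifts)
        # shift at alpha=1.3 must project positively
        assert (-0.4 * v) @ ax > 0

    def test_column_permutation_invariant(self, rng):
        d = 4
        M = rng.normal(0, 1, (d, 6))
        alphas = [0.7, 0.8, 0.9, 1.1, 1.2, 1.3]
        ax = cl.speed_axis(M, alphas)
        perm = rng.permutation(6)
        ax_p = cl.speed_axis(M[:, perm], [alphas[i] for i in perm])
        assert np.allclose(ax, ax_p, atol=1e-10)


class TestSortBySpeed:
    def test_increasing_multiples_give_identity_order(self):
        v = np.array([0.6, -0.8])
        biases = np.outer([0.1, 0.5, 1.0, 2.0], v)
        order = cl.sort_by_speed(biases, v)
        assert np.array_equal(order, [0, 1, 2, 3])

    def test_axis_flip_reverses_order(self, rng):
        biases = rng.normal(0, 1, (7, 3))
        ax = rng.normal(0, 1, 3)
        a = cl.sort_by_speed(biases, ax)
        b = cl.sort_by_speed(biases, -ax)
        assert np.array_equal(a, b[::-1])


class TestDriftAxis:
    def test_linear_trend_recovered_in_low_noise_limit(self, rng):
        v = np.array([0.5, -1.0, 2.0])
        v /= np.linalg.norm(v)
        idx = np.arange(300)
        b = np.outer(idx, v) * 0.01 + rng.normal(0, 1e-4, (300, 3))
        ax = cl.drift_axis(cl.BiasEmbedding.from_biases(b, idx))
        assert min(np.abs(ax - v).max(), np.abs(ax + v).max()) < 1e-2

    def test_no_trend_no_spurious_correlation(self, rng):
        idx = np.arange(400)
        b = rng.normal(0, 1, (400, 3))
        emb = cl.BiasEmbedding.from_biases(b, idx)
        ax = cl.drift_axis(emb)
        rho = spearmanr(idx, b @ ax).statistic
        # permutation null: the observed correlation should be unremarkable
        null = []
        for s in range(200):
            perm = np.random.default_rng(s).permutation(400)
            null.append(abs(spearmanr(idx, (b @ ax)[perm]).statistic))
        assert abs(rho) < np.quantile(null, 0.99) + 0.15

    def test_translation_invariant(self, rng):
        idx = np.arange(50)
        b = rng.normal(0, 1, (50, 4)) + np.outer(idx, rng.normal(0, 1, 4)) * 0.05
        a1 = cl.drift_axis(cl.BiasEmbedding.from_biases(b, idx))
        a2 = cl.drift_axis(cl.BiasEmbedding.from_biases(b + 100.0, idx))
        assert np.allclose(a1, a2, atol=1e-10)
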