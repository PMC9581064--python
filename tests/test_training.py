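import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from consdeepsignaling import (CONSDEEP_SCHEDULE, DNN_SCHEDULE, LRSchedule,
                               ModelConfig, PathwayMembership,
                               build_gene_feature_mask, build_gene_pathway_mask,
                               init_model, kfold_split, lr_at_epoch, pearson,
                               train, cross_validate, permutation_null)


def tiny_model(seed=0, n=2, s=1, K=1):
    gf = build_gene_feature_mask(K, n)
    membership = PathwayMembership({"P": {f"g{j+1}" for j in range(n)}}, ["P"])
    gp = build_gene_pathway_mask(membership, [f"g{j+1}" for j in range(n)])
    return init_model(ModelConfig(K=K, n=n, s=s, head_sizes=(4,), seed=seed), gf, gp)


class TestLRSchedule:
    # the two staged schedules: same five rates, different epoch bands
    @pytest.mark.parametrize("schedule,epoch,rate", [
        (CONSDEEP_SCHEDULE, 1, 1e-3), (CONSDEEP_SCHEDULE, 30, 1e-3),
        (CONSDEEP_SCHEDULE, 31, 1e-4), (CONSDEEP_SCHEDULE, 45, 5e-5),
        (CONSDEEP_SCHEDULE, 51, 1e-5), (CONSDEEP_SCHEDULE, 100, 1e-6),
        (DNN_SCHEDULE, 15, 1e-3), (DNN_SCHEDULE, 20, 1e-4),
        (DNN_SCHEDULE, 31, 5e-5), (DNN_SCHEDULE, 70, 1e-5),
        (DNN_SCHEDULE, 71, 1e-6),
    ])
    def test_staged_rates(self, schedule, epoch, rate):
        assert lr_at_epoch(schedule, epoch) == rate

    def test_out_of_range_epoch(self):
        with pytest.raises(ValueError):
            lr_at_epoch(CONSDEEP_SCHEDULE, 0)
        with pytest.raises(ValueError):
            lr_at_epoch(CONSDEEP_SCHEDULE, 101)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):  # gap between stages
            LRSchedule(((1, 10, 1e-3), (12, 20, 1e-4)))
        with pytest.raises(ValueError):  # increasing rate
            LRSchedule(((1, 10, 1e-4), (11, 20, 1e-3)))
        with pytest.raises(ValueError):  # empty stage
            LRSchedule(((1, 0, 1e-3),))


class TestKFold:
    def test_printed_fold_sizes_largest_last(self):
        split = kfold_split(16761, 5, seed=0)
        sizes = [len(split.test_indices(f)) for f in range(5)]
        assert sizes == [3352, 3352, 3352, 3352, 3353]
        # complementary train sizes
        assert [len(split.train_indices(f)) for f in range(5)] == \
            [13409, 13409, 13409, 13409, 13408]

    def test_exact_division(self):
        split = kfold_split(10, 5, seed=1)
        assert [len(split.test_indices(f)) for f in range(5)] == [2] * 5

    def test_same_seed_identical(self):
        a, b = kfold_split(100, 5, seed=3), kfold_split(100, 5, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    @given(n=st.integers(5, 200), k=st.integers(2, 5), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_folds_partition_samples(self, n, k, seed):
        if n < k:
            return
        split = kfold_split(n, k, seed)
        sizes = [len(split.test_indices(f)) for f in range(k)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == n
        all_test = np.concatenate([split.test_indices(f) for f in range(k)])
        assert len(np.unique(all_test)) == n


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        y = np.array([0.1, 0.4, 0.2, 0.9])
        assert pearson(y, y) == pytest.approx(1.0)
        assert pearson(y, -y + 7) == pytest.approx(-1.0)

    def test_closed_form_hand_value(self):
        # cov = 4.7, sd_y^2 = 5.0, sd_h^2 = 4.5 -> r = 4.7 / sqrt(22.5)
        r = pearson(np.array([1, 2, 3, 4.0]), np.array([1.1, 1.9, 3.2, 3.8]))
        assert r == pytest.approx(0.9908470001860922, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y, h = rng.normal(size=30), rng.normal(size=30)
            assert pearson(y, h) == pytest.approx(stats.pearsonr(y, h).statistic)

    def test_constant_input_is_error_not_zero(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))

    @given(scale=st.floats(0.01, 100), shift=st.floats(-10, 10),
           seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_positive_affine_maps(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        y, h = rng.normal(size=20), rng.normal(size=20)
        assert pearson(y * scale + shift, h) == pytest.approx(pearson(y, h))


class TestTrain:
    def test_single_sample_interpolation(self):
        # one sample, tiny model, enough constant-rate epochs: MSE -> 0
        model = tiny_model(seed=0)
        X = np.array([[1.0, 2.0]])
        y = np.array([0.7])
        history = train(model, X, y, LRSchedule(((1, 1500, 1e-2),)),
                        epochs=1500, batch_size=1, seed=0)
        assert history[-1] < 1e-6

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        model = tiny_model(seed=1)
        before = [p.value.copy() for p in model.params()]
        schedule = LRSchedule(((1, 10, 1e-300),))  # effectively zero
        rng = np.random.default_rng(0)
        train(model, rng.normal(size=(16, 2)), rng.random(16), schedule,
              epochs=10, batch_size=8, seed=0)
        for p, b in zip(model.params(), before):
            np.testing.assert_allclose(p.value, b, atol=1e-250)

    def test_training_is_reproducible_bitwise(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(40, 2)), rng.random(40)
        runs = []
        for _ in range(2):
            model = tiny_model(seed=5)
            h = train(model, X, y, CONSDEEP_SCHEDULE, epochs=5, batch_size=8, seed=3)
            runs.append((h, [p.value.copy() for p in model.params()]))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_epoch_beyond_schedule_rejected(self):
        with pytest.raises(ValueError):
            train(tiny_model(), np.ones((4, 2)), np.ones(4), CONSDEEP_SCHEDULE,
                  epochs=101)


class TestCrossValidate:
    def test_reports_and_predictions_consistent(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = np.clip(0.5 + 0.3 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(0, .01, 60), 0, 1)
        report, preds = cross_validate(
            X, y, lambda s: tiny_model(seed=s), CONSDEEP_SCHEDULE,
            provenance=[("d", f"c{i}") for i in range(60)],
            k=3, epochs=30, batch_size=16, seed=0)
        assert len(report.folds) == 3
        assert len(preds) == 60  # every sample appears in exactly one test fold
        assert set(preds["fold"]) == {0, 1, 2}
        for f in range(3):
            fold_preds = preds[preds["fold"] == f]
            assert np.mean((fold_preds.auc_true - fold_preds.auc_pred) ** 2) == \
                pytest.approx(report.test_mse[f])


class FixedModel:
    """Deterministic stub: predicts a fixed linear readout of X (no training)."""

    def __init__(self, w):
        self.w = w

    def predict(self, X):
        return X @ self.w


class TestPermutationNull:
    def _run(self, y_strength, n_perm=5, add_one=False, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3))
        y = y_strength * X[:, 0] + rng.normal(size=40)

        # model_builder returning an untrainable fixed readout makes the
        # null distribution cheap and fully predictable
        class Stub(FixedModel):
            pass

        def builder(s):
            return Stub(np.array([1.0, 0, 0]))

        # monkey-patch train to a no-op via epochs=1 on a zero-rate schedule
        schedule = LRSchedule(((1, 1, 1e-300),))
        import consdeepsignaling.training as tr
        orig = tr.train
        tr.train = lambda model, X, y, *a, **k: [0.0]
        try:
            null = permutation_null(X, y, builder, schedule, n_perm=n_perm,
                                    k=2, epochs=1, seed=seed,
                                    add_one_correction=add_one)
        finally:
            tr.train = orig
        return null

    def test_strong_signal_gives_zero_p(self):
        null = self._run(y_strength=50.0)
        assert null.p_values == [0.0, 0.0]
        assert all(f == 0.0 for f in null.fdr)

    def test_anti_signal_gives_p_one(self):
        # observed r ~ -1 sits below every null draw -> p = 1 on both folds
        null = self._run(y_strength=-50.0)
        assert null.p_values == [1.0, 1.0]

    def test_add_one_correction_bounds_p_away_from_zero(self):
        null = self._run(y_strength=50.0, n_perm=4, add_one=True)
        assert null.p_values == [pytest.approx(1 / 5)] * 2

    def test_observed_equal_to_null_counts_as_extreme(self):
        # ECDF convention: p = #{null >= observed} / n_perm, so a null value
        # tied with the observed statistic contributes
        from consdeepsignaling.training import _ecdf_p
        assert _ecdf_p(0.5, [0.5, 0.3], add_one=False) == 0.5
        assert _ecdf_p(0.5, [0.4, 0.3], add_one=False) == 0.0
        assert _ecdf_p(0.5, [0.6], add_one=False) == 1.0
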