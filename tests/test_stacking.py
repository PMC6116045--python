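import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from conftest import SMALL_GRIDS
from dbpstack import stacking
from dbpstack.stacking import (
    BaseModelSpec,
    MetaFeatureMatrix,
    fit_base,
    fit_meta,
    fit_stacked,
    majority_vote,
    oof_meta_features,
    predict,
    specs_for_family,
)


def separable_toy(rng, n=30):
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(scale=0.3, size=(n, 2)) + y[:, None] * 3.0
    return x, y


class _StubVoter:
    """Duck-typed voter with a fixed positive-class probability per sample."""

    def __init__(self, block, probas):
        self.spec = BaseModelSpec("gaussian_nb", block)
        self._probas = np.asarray(probas, dtype=float)

    def positive_proba(self, x):
        return self._probas


class TestFitBase:
    def test_separable_toy_reaches_training_accuracy_one(self):
        rng = np.random.default_rng(0)
        x, y = separable_toy(rng)
        fb = fit_base(
            BaseModelSpec("svm_rbf", "d188", SMALL_GRIDS["svm_rbf"]), x, y, seed=0
        )
        pred = (fb.positive_proba(x) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    def test_same_seed_selects_same_hyperparameters(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        spec = BaseModelSpec(
            "svm_rbf", "d188", {"C": [0.1, 1.0, 10.0], "gamma": [0.01, 1.0]}
        )
        a = fit_base(spec, x, y, seed=5)
        b = fit_base(spec, x, y, seed=5)
        assert a.chosen_params == b.chosen_params

    def test_single_point_grid_is_used_directly(self):
        rng = np.random.default_rng(2)
        x, y = separable_toy(rng)
        fb = fit_base(
            BaseModelSpec("svm_rbf", "d188", {"C": [7.0], "gamma": [0.5]}),
            x, y, seed=0,
        )
        assert fb.chosen_params == {"C": 7.0, "gamma": 0.5}

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_base(
                BaseModelSpec("svm_rbf", "d188", SMALL_GRIDS["svm_rbf"]),
                x, np.ones(10, dtype=int), seed=0,
            )


class TestOofMetaFeatures:
    def test_shape_and_range(self, svm_specs, planted_matrices):
        matrices, y, _ = planted_matrices
        mf = oof_meta_features(svm_specs, matrices, y, k=4, seed=0)
        assert mf.values.shape == (len(y), 4)
        assert np.all(np.isfinite(mf.values))
        assert np.all((mf.values >= 0) & (mf.values <= 1))

    def test_oracle_block_separates_classes_perfectly(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 20)
        blocks = {
            "oracle": y[:, None] + rng.normal(scale=0.01, size=(40, 1)),
            "noise": rng.normal(size=(40, 5)),
        }
        specs = [
            BaseModelSpec("svm_rbf", "oracle", SMALL_GRIDS["svm_rbf"]),
            BaseModelSpec("svm_rbf", "noise", SMALL_GRIDS["svm_rbf"]),
        ]
        mf = oof_meta_features(specs, blocks, y, k=5, seed=0)
        assert roc_auc_score(y, mf.values[:, 0]) == 1.0

    def test_leave_one_out_when_k_equals_m(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 6)
        blocks = {"b": y[:, None] + rng.normal(scale=0.1, size=(12, 1))}
        specs = [BaseModelSpec("gaussian_nb", "b")]
        mf = oof_meta_features(specs, blocks, y, k=12, seed=0)
        assert np.all(np.isfinite(mf.values))


class TestFitMeta:
    def test_label_copy_meta_feature_reproduces_labels(self):
        y = np.repeat([0, 1], 15)
        mf = MetaFeatureMatrix(y[:, None].astype(float), y)
        theta = fit_meta(mf)
        assert theta[1] > 0
        pred = (1 / (1 + np.exp(-(theta[0] + mf.values @ theta[1:]))) >= 0.5)
        assert np.array_equal(pred.astype(int), y)

    def test_uninformative_meta_feature_stays_near_chance(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=200)
        mf = MetaFeatureMatrix(rng.uniform(size=(200, 1)), y)
        theta = fit_meta(mf)
        fresh = rng.uniform(size=(200, 1))
        pred = (1 / (1 + np.exp(-(theta[0] + fresh @ theta[1:]))) >= 0.5).astype(int)
        acc = (pred == rng.integers(0, 2, size=200)).mean()
        assert 0.43 <= acc <= 0.57  # binomial 95% band at n=200

    def test_duplicated_column_predictions_match_single_column(self):
        # overlapping class-conditional distributions keep the MLE finite
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 25)
        f = np.clip(rng.normal(0.35 + 0.3 * y, 0.15), 0, 1)[:, None]
        theta_single = fit_meta(MetaFeatureMatrix(f, y))
        theta_double = fit_meta(MetaFeatureMatrix(np.hstack([f, f]), y))
        p1 = 1 / (1 + np.exp(-(theta_single[0] + f @ theta_single[1:])))
        p2 = 1 / (
            1 + np.exp(-(theta_double[0] + np.hstack([f, f]) @ theta_double[1:]))
        )
        np.testing.assert_allclose(p1, p2, atol=1e-4)


class TestStackedModel:
    @pytest.mark.parametrize(
        "family,expected", [("svm", 4), ("svm,rf", 8), ("svm,rf,nb", 12)]
    )
    def test_meta_feature_count_per_family(self, family, expected):
        assert len(specs_for_family(family)) == expected

    def test_heterogeneous_family_trains_and_predicts(self, planted_matrices):
        matrices, y, _ = planted_matrices
        # truncate the blocks so the 12-model stack stays quick
        small = {name: x[:, :20] for name, x in matrices.items()}
        specs = specs_for_family("svm,rf,nb", grids=SMALL_GRIDS)
        model = fit_stacked(small, y, specs, k=4, seed=0)
        assert model.n_meta_features == 12
        proba, labels = predict(model, small)
        assert proba.shape == labels.shape == y.shape
        assert np.all((proba >= 0) & (proba <= 1))

    def test_stacked_training_accuracy_at_least_best_base(
        self, svm_specs, planted_matrices
    ):
        matrices, y, _ = planted_matrices
        model = fit_stacked(matrices, y, svm_specs, k=4, seed=0)
        _, labels = predict(model, matrices)
        stacked_acc = (labels == y).mean()
        base_accs = [
            ((fb.positive_proba(matrices[fb.spec.feature_block]) >= 0.5) == y).mean()
            for fb in model.base_models
        ]
        assert stacked_acc >= max(base_accs)

    def test_probability_tie_goes_positive(self, svm_specs, planted_matrices):
        matrices, y, _ = planted_matrices
        model = fit_stacked(matrices, y, svm_specs, k=4, seed=0)
        model.theta = np.zeros_like(model.theta)  # forces probability 0.5
        proba, labels = predict(model, matrices)
        assert np.all(proba == 0.5) and np.all(labels == 1)

    def test_sample_permutation_equivariance(self, svm_specs, planted_matrices):
        matrices, y, _ = planted_matrices
        model = fit_stacked(matrices, y, svm_specs, k=4, seed=0)
        perm = np.random.default_rng(8).permutation(len(y))
        proba, _ = predict(model, matrices)
        proba_perm, _ = predict(model, {k: v[perm] for k, v in matrices.items()})
        np.testing.assert_allclose(proba_perm, proba[perm])

    def test_same_seed_is_bit_reproducible(self, svm_specs, planted_matrices):
        matrices, y, _ = planted_matrices
        a = fit_stacked(matrices, y, svm_specs, k=4, seed=3)
        b = fit_stacked(matrices, y, svm_specs, k=4, seed=3)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(
            predict(a, matrices)[0], predict(b, matrices)[0]
        )

    def test_save_load_round_trip(self, svm_specs, planted_matrices, tmp_path):
        matrices, y, _ = planted_matrices
        model = fit_stacked(matrices, y, svm_specs, k=4, seed=0)
        stacking.save_model(model, tmp_path / "model")
        loaded = stacking.load_model(tmp_path / "model")
        np.testing.assert_array_equal(loaded.theta, model.theta)
        np.testing.assert_allclose(
            predict(loaded, matrices)[0], predict(model, matrices)[0]
        )


class TestMajorityVote:
    def test_unanimous_voters(self):
        blocks = {"b": np.zeros((3, 1))}
        voters = [_StubVoter("b", [0.9, 0.1, 0.8]) for _ in range(3)]
        assert np.array_equal(majority_vote(voters, blocks), [1, 0, 1])

    def test_tie_broken_by_mean_probability(self):
        blocks = {"b": np.zeros((1, 1))}
        voters = [
            _StubVoter("b", [0.9]),
            _StubVoter("b", [0.9]),
            _StubVoter("b", [0.3]),
            _StubVoter("b", [0.3]),
        ]
        assert majority_vote(voters, blocks)[0] == 1  # mean 0.6 -> positive
        low = [
            _StubVoter("b", [0.6]),
            _StubVoter("b", [0.6]),
            _StubVoter("b", [0.1]),
            _StubVoter("b", [0.1]),
        ]
        assert majority_vote(low, blocks)[0] == 0  # mean 0.35 -> negative

    def test_vote_accuracy_between_worst_and_best_voter(
        self, svm_specs, planted_matrices
    ):
        matrices, y, _ = planted_matrices
        voters = [
            fit_base(spec, matrices[spec.feature_block], y, seed=0)
            for spec in svm_specs
        ]
        vote_acc = (majority_vote(voters, matrices) == y).mean()
        accs = [
            ((fb.positive_proba(matrices[fb.spec.feature_block]) >= 0.5) == y).mean()
            for fb in voters
        ]
        slack = 2 * np.sqrt(0.25 / len(y))  # binomial noise allowance
        assert min(accs) - slack <= vote_acc <= max(accs) + slack
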