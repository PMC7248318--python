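import numpy as np
import pytest

import husdosboost as hb
from husdosboost.boost import (
    BoostConfig,
    DegenerateFitError,
    EnsembleModel,
    beta_from_error,
    update_boosting_weights,
    variable_importance,
    weighted_error,
)
from husdosboost.synthdata import SynthConfig, generate_eism
from husdosboost.tree import TreeConfig, fit_weighted_tree


class TestRoundArithmetic:
    def test_weighted_error_counts_misclassified_mass(self):
        w = np.full(4, 0.25)
        y = np.array([0, 0, 1, 1])
        assert weighted_error(y, y, w) == 0.0
        assert weighted_error(1 - y, y, w) == 1.0
        assert weighted_error(np.array([0, 0, 1, 0]), y, w) == pytest.approx(0.25)

    def test_weighted_error_rejects_misaligned_inputs(self):
        with pytest.raises(ValueError):
            weighted_error(np.zeros(3), np.zeros(4), np.full(4, 0.25))

    @pytest.mark.parametrize(
        "eps,expected",
        [(0.25, 1 / 3), (1e-10, pytest.approx(1e-10)), (0.499999, pytest.approx(1.0, rel=1e-4))],
    )
    def test_beta_from_error(self, eps, expected):
        assert beta_from_error(eps) == expected

    def test_beta_rejects_out_of_range(self):
        for eps in (0.0, 0.5, 0.7):
            with pytest.raises(ValueError):
                beta_from_error(eps)

    def test_boosting_weight_update_arithmetic(self):
        D = np.array([0.5, 0.5])
        new, z = update_boosting_weights(
            D, np.array([0, 0]), np.array([0, 1]), beta=1 / 3
        )
        np.testing.assert_allclose(new, [0.25, 0.75])
        assert z == pytest.approx(0.5 / 3 + 0.5)

    def test_all_correct_update_is_identity(self):
        D = np.array([0.2, 0.3, 0.5])
        y = np.array([0, 1, 1])
        new, _ = update_boosting_weights(D, y, y, beta=0.4)
        np.testing.assert_allclose(new, D)

    def test_beta_one_update_is_identity(self):
        D = np.array([0.2, 0.8])
        new, _ = update_boosting_weights(D, np.array([0, 1]), np.array([1, 1]), 1.0)
        np.testing.assert_allclose(new, D)


def constant_tree(prediction):
    """Depth-0 tree predicting one class, for hand-built ensembles."""
    y = np.full(4, prediction)
    return fit_weighted_tree(np.zeros((4, 1)), y, feature_names=["v1"])


def two_member_ensemble(alphas, schema):
    return EnsembleModel(
        trees=[constant_tree(1), constant_tree(0)],
        alphas=np.asarray(alphas, float),
        schema=schema,
        config=BoostConfig(),
        records=[],
        feature_names=("v1",),
    )


class TestEnsembleVote:
    @pytest.fixture
    def schema(self, dataset_factory):
        return dataset_factory(np.zeros((2, 1)), [0, 1], names=["v1"]).schema

    def test_single_member_follows_its_tree(self, dataset_factory):
        ds = dataset_factory([[0.0], [1.0], [2.0], [3.0]], [0, 0, 1, 1], names=["v1"])
        model = hb.fit(ds, BoostConfig.variant("adaboost", n_rounds=1, seed=0))
        assert model.n_rounds_fitted == 1
        np.testing.assert_array_equal(
            model.predict(ds.features), model.trees[0].predict(ds.features)
        )

    def test_disagreement_follows_larger_vote(self, schema):
        model = two_member_ensemble([0.7, 0.3], schema)
        X = np.zeros((1, 1))
        assert model.predict(X)[0] == 1  # the 0.7 member votes minority
        assert model.score(X)[0] == pytest.approx(0.4)

    def test_unanimous_scores_hit_the_extremes(self, schema):
        X = np.zeros((3, 1))
        all_min = EnsembleModel(
            [constant_tree(1)], np.array([1.0]), schema, BoostConfig(), [], ("v1",)
        )
        all_maj = EnsembleModel(
            [constant_tree(0)], np.array([1.0]), schema, BoostConfig(), [], ("v1",)
        )
        assert (all_min.score(X) == 1.0).all()
        assert (all_maj.score(X) == -1.0).all()

    def test_exact_tie_goes_to_majority(self, schema):
        model = two_member_ensemble([0.5, 0.5], schema)
        X = np.zeros((1, 1))
        assert model.score(X)[0] == pytest.approx(0.0)
        assert model.predict(X)[0] == 0


class TestFitEngine:
    def test_t1_trains_on_balanced_round_sample(self):
        ds, _ = generate_eism(SynthConfig(n_min=10, n_maj=100, seed=5))
        model = hb.fit(ds, BoostConfig(n_rounds=1, seed=1))
        rec = model.records[0]
        assert len(rec.sampled_majority) == 20  # n_u = n_min + n_o
        assert rec.n_artificial == 10  # n_o = n_min
        assert model.n_rounds_fitted == 1

    def test_variant_round_sample_provenance(self):
        ds, _ = generate_eism(SynthConfig(n_min=10, n_maj=100, seed=5))
        part = hb.partition_classes(ds)
        for name, n_u, n_o in [
            ("husdos", 20, 10),
            ("husboost", 10, 0),
            ("rusboost", 10, 0),
        ]:
            model = hb.fit(ds, BoostConfig.variant(name, n_rounds=2, seed=1))
            rec = model.records[0]
            assert len(rec.sampled_majority) == n_u, name
            assert rec.n_artificial == n_o, name
            assert set(rec.sampled_majority) <= set(part.majority_idx), name
        full = hb.fit(ds, BoostConfig.variant("adaboost", n_rounds=2, seed=1))
        np.testing.assert_array_equal(
            full.records[0].sampled_majority, part.majority_idx
        )

    def test_round_one_hus_equals_rus_in_distribution(self):
        # with uniform initial sampling weights the first HUS draw is uniform
        ds, _ = generate_eism(SynthConfig(n_min=10, n_maj=50, seed=5))
        h = hb.fit(ds, BoostConfig.variant("husboost", n_rounds=1, seed=9))
        r = hb.fit(ds, BoostConfig.variant("rusboost", n_rounds=1, seed=9))
        assert len(h.records[0].sampled_majority) == len(r.records[0].sampled_majority)

    def test_identical_seed_gives_bit_identical_model(self):
        ds, _ = generate_eism(SynthConfig(seed=11))
        a = hb.fit(ds, BoostConfig(seed=4, n_rounds=12))
        b = hb.fit(ds, BoostConfig(seed=4, n_rounds=12))
        assert a.to_json() == b.to_json()

    def test_zero_error_round_is_clamped_not_dropped(self, dataset_factory):
        ds = dataset_factory(
            [[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]],
            [0, 0, 0, 1, 1, 1],
            names=["v1"],
        )
        model = hb.fit(ds, BoostConfig.variant("adaboost", n_rounds=3, seed=0))
        assert model.records[0].epsilon == 0.0
        assert model.records[0].epsilon_clamped == pytest.approx(1e-10)
        assert np.isfinite(model.alphas).all() and (model.alphas > 0).all()

    def test_all_votes_positive_and_weights_conserved(self):
        ds, _ = generate_eism(SynthConfig(n_min=10, n_maj=200, seed=2))
        model = hb.fit(ds, BoostConfig(n_rounds=25, seed=2))
        assert (model.alphas > 0).all()
        for rec in model.records:
            assert 0.0 <= rec.epsilon < 0.5
            assert 0.0 < rec.beta < 1.0

    def test_degenerate_data_raises_with_diagnostics(self, dataset_factory):
        # constant variable with exactly balanced classes: every tree is a
        # tied depth-0 leaf predicting the majority class, so eps = 0.5 on
        # every attempt and no weak classifier can ever be retained
        ds = dataset_factory(np.zeros((4, 1)), [1, 1, 0, 0], names=["v1"])
        with pytest.raises(DegenerateFitError, match="degenerate"):
            hb.fit(ds, BoostConfig.variant("adaboost", n_rounds=5, seed=0))

    def test_separable_eism_reaches_perfect_training_gmean(self):
        ds, _ = generate_eism(
            SynthConfig(n_min=20, n_maj=500, n_informative=1, n_noise=0,
                        delta=6.0, seed=3)
        )
        model = hb.fit(ds, BoostConfig(n_rounds=30, seed=3))
        counts = hb.confusion_counts(model.predict(ds.features), ds.labels)
        assert hb.g_mean(counts.sensitivity, counts.specificity) == 1.0


class TestImportance:
    def test_single_variable_ensemble_concentrates_importance(self, dataset_factory):
        ds = dataset_factory(
            np.column_stack([np.linspace(-1, 1, 8), np.zeros(8)]),
            [0, 0, 0, 0, 1, 1, 1, 1],
            names=["signal", "flat"],
        )
        model = hb.fit(ds, BoostConfig.variant("adaboost", n_rounds=3, seed=0))
        report = variable_importance(model)
        assert report.importances["signal"] == pytest.approx(1.0)
        assert report.importances["flat"] == 0.0

    def test_stump_free_ensemble_is_rejected(self, dataset_factory):
        schema = dataset_factory(np.zeros((2, 1)), [0, 1], names=["v1"]).schema
        model = EnsembleModel(
            [constant_tree(0)], np.array([1.0]), schema, BoostConfig(), [], ("v1",)
        )
        with pytest.raises(ValueError, match="no splits"):
            variable_importance(model)

    def test_hand_computed_two_tree_weighted_sum(self):
        # two stumps on different variables with known gains g1, g2 and
        # votes a1, a2: VI = (a1 g1, a2 g2) / (a1 g1 + a2 g2)
        X1 = np.array([[-1.0, 0.0], [-0.5, 0.0], [0.5, 0.0], [1.0, 0.0]])
        X2 = X1[:, ::-1]
        y = np.array([0, 0, 1, 1])
        t1 = fit_weighted_tree(X1, y, feature_names=["a", "b"])
        t2 = fit_weighted_tree(X2, y, feature_names=["a", "b"])
        g1 = t1.variable_gains()["a"]
        g2 = t2.variable_gains()["b"]
        schema = hb.FeatureSchema(
            (hb.Variable("a", "continuous"), hb.Variable("b", "continuous")),
            label="y", minority_value="minority",
        )
        model = EnsembleModel(
            [t1, t2], np.array([0.7, 0.3]), schema, BoostConfig(), [], ("a", "b")
        )
        report = variable_importance(model)
        z = 0.7 * g1 + 0.3 * g2
        assert report.importances["a"] == pytest.approx(0.7 * g1 / z)
        assert report.importances["b"] == pytest.approx(0.3 * g2 / z)
        assert sum(report.importances.values()) == pytest.approx(1.0)


class TestConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            BoostConfig(n_rounds=0)
        with pytest.raises(ValueError):
            BoostConfig(epsilon_min=0.5)
        with pytest.raises(ValueError):
            BoostConfig(under_sampling="bootstrap")
        with pytest.raises(ValueError):
            BoostConfig.variant("smote")

    def test_size_resolution_balances_round_sample(self):
        part = hb.ClassPartition(np.arange(20), np.arange(20, 1020))
        assert BoostConfig().resolve_sizes(part) == (40, 20)
        assert BoostConfig.variant("rusboost").resolve_sizes(part) == (20, 0)
        assert BoostConfig.variant("adaboost").resolve_sizes(part) == (1000, 0)
        assert BoostConfig(n_u_factor=3.0, n_o_factor=2.0).resolve_sizes(part) == (60, 40)

    def test_oversized_draw_rejected(self):
        part = hb.ClassPartition(np.arange(20), np.arange(20, 30))
        with pytest.raises(ValueError):
            BoostConfig(n_u=11).resolve_sizes(part)
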