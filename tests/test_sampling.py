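import json
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from husdosboost.datamodel import FeatureSchema, Variable
from husdosboost.sampling import (
    DistributionModel,
    GaussianDistribution,
    SamplingState,
    dos_generate,
    fit_minority_distributions,
    hus_sample,
    init_sampling_weights,
    rus_sample,
    update_sampling_weights,
    variance_floor,
)
from husdosboost.datamodel import ClassPartition


class TestSamplingWeights:
    def test_initial_weights_are_uniform(self):
        state = init_sampling_weights(4)
        np.testing.assert_allclose(state.weights, [0.25] * 4)
        assert state.round == 1

    def test_single_majority_example(self):
        np.testing.assert_allclose(init_sampling_weights(1).weights, [1.0])

    def test_empty_majority_rejected(self):
        with pytest.raises(ValueError):
            init_sampling_weights(0)

    def test_update_arithmetic(self):
        # multipliers beta / (1/beta) / 1, then renormalize:
        # (1/3,1/3,1/3) -> unnormalized (1/9, 1, 1/3) -> (1/13, 9/13, 3/13)
        state = SamplingState(np.full(3, 1 / 3))
        new = update_sampling_weights(
            state, np.array([0, 1]), np.array([True, False]), beta=1 / 3
        )
        np.testing.assert_allclose(new.weights, [1 / 13, 9 / 13, 3 / 13])
        assert new.round == 2

    def test_beta_one_is_identity(self):
        state = SamplingState(np.array([0.5, 0.3, 0.2]))
        new = update_sampling_weights(
            state, np.array([0, 2]), np.array([True, False]), beta=1.0
        )
        np.testing.assert_allclose(new.weights, state.weights)

    def test_uniform_multiplier_cancels(self):
        state = SamplingState(np.array([0.5, 0.3, 0.2]))
        new = update_sampling_weights(
            state, np.arange(3), np.ones(3, bool), beta=0.1
        )
        np.testing.assert_allclose(new.weights, state.weights)

    def test_misclassified_gains_relative_to_correct(self):
        # before normalization the mis/correct ratio is multiplied by 1/beta^2
        beta = 0.25
        state = SamplingState(np.array([0.5, 0.5]))
        new = update_sampling_weights(
            state, np.array([0, 1]), np.array([True, False]), beta=beta
        )
        before = state.weights[1] / state.weights[0]
        after = new.weights[1] / new.weights[0]
        assert after == pytest.approx(before / beta ** 2)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_update_sequences_conserve_mass(self, data):
        n = data.draw(st.integers(2, 8))
        state = init_sampling_weights(n)
        for _ in range(data.draw(st.integers(1, 5))):
            k = data.draw(st.integers(1, n))
            sampled = np.array(
                data.draw(
                    st.lists(
                        st.integers(0, n - 1), min_size=k, max_size=k, unique=True
                    )
                )
            )
            correct = np.array(data.draw(st.lists(st.booleans(), min_size=k, max_size=k)))
            beta = data.draw(st.floats(1e-6, 1.0, exclude_min=True))
            state = update_sampling_weights(state, sampled, correct, beta)
            assert state.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert (state.weights >= 0).all()


class TestDrawing:
    def test_degenerate_weight_always_picked(self, rng):
        state = SamplingState(np.array([1.0, 0.0, 0.0]))
        for _ in range(10):
            assert list(hus_sample(state, 1, rng)) == [0]

    def test_full_draw_returns_every_index(self, rng):
        state = init_sampling_weights(5)
        np.testing.assert_array_equal(hus_sample(state, 5, rng), np.arange(5))

    def test_oversized_draw_rejected(self, rng):
        with pytest.raises(ValueError):
            hus_sample(init_sampling_weights(3), 4, rng)

    def test_weighted_pick_frequency_matches_weights(self, rng):
        # first-draw inclusion frequency of index 0 should track its weight
        state = SamplingState(np.array([0.5, 0.25, 0.25]))
        n_draws = 10 ** 5
        hits = sum(hus_sample(state, 1, rng)[0] == 0 for _ in range(n_draws))
        se = np.sqrt(0.5 * 0.5 / n_draws)
        assert abs(hits / n_draws - 0.5) < 3 * se

    def test_rus_uniform_and_reproducible(self):
        part = ClassPartition(np.array([8, 9]), np.arange(8))
        full = rus_sample(part, 8, np.random.default_rng(0))
        np.testing.assert_array_equal(full, np.arange(8))
        a = rus_sample(part, 3, np.random.default_rng(42))
        b = rus_sample(part, 3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_rus_single_draw_frequencies(self, rng):
        part = ClassPartition(np.array([4, 5]), np.arange(4))
        n_draws = 4 * 10 ** 4
        counts = np.zeros(4)
        for _ in range(n_draws):
            counts[rus_sample(part, 1, rng)[0]] += 1
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert np.all(np.abs(counts / n_draws - 0.25) < 4 * se)


def gender_minority_frame():
    """24 minority rows: 15 male, 9 female, plus a continuous column."""
    male = np.array([1.0] * 15 + [0.0] * 9)
    height = np.linspace(1.5, 1.9, 24)
    return pd.DataFrame({"height": height, "gender": male})


GENDER_SCHEMA = FeatureSchema(
    variables=(
        Variable("height", "continuous"),
        Variable("gender", "binary", ("female", "male")),
    ),
    label="status",
    minority_value="case",
)


class TestDistributionFit:
    def test_gender_proportions(self):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        gender = model.distributions[1]
        assert gender.proportions["male"] == pytest.approx(15 / 24)
        assert gender.proportions["female"] == pytest.approx(9 / 24)
        assert model.n_a == 24

    def test_continuous_mean_and_variance(self):
        frame = pd.DataFrame({"height": [1.0, 2.0, 3.0], "gender": [1.0, 0.0, 1.0]})
        model = fit_minority_distributions(frame, GENDER_SCHEMA)
        height = model.distributions[0]
        assert height.mean == pytest.approx(2.0)
        assert height.variance == pytest.approx(1.0)  # unbiased

    def test_constant_variable_hits_variance_floor(self, caplog):
        frame = pd.DataFrame({"height": [1.7] * 4, "gender": [1.0, 0.0, 1.0, 0.0]})
        with caplog.at_level(logging.WARNING):
            model = fit_minority_distributions(frame, GENDER_SCHEMA)
        assert model.distributions[0].variance == pytest.approx(variance_floor(1.7))
        assert any("floored" in r.message for r in caplog.records)

    def test_single_minority_example_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_minority_distributions(gender_minority_frame().iloc[:1], GENDER_SCHEMA)

    def test_json_round_trip(self):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        restored = DistributionModel.from_json(model.to_json(), GENDER_SCHEMA)
        assert restored.n_a == model.n_a
        assert restored.distributions[1].proportions == pytest.approx(
            model.distributions[1].proportions
        )


class TestDosGenerate:
    def test_single_attribute_category_is_constant(self, rng):
        frame = pd.DataFrame({"height": [1.6, 1.7], "gender": [1.0, 1.0]})
        model = fit_minority_distributions(frame, GENDER_SCHEMA)
        out = dos_generate(model, 50, rng)
        assert (out.features["gender"] == 1.0).all()

    def test_empty_generation(self, rng):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        assert dos_generate(model, 0, rng).n == 0

    def test_labels_are_minority_and_schema_conforms(self, rng):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        out = dos_generate(model, 100, rng)
        assert (out.labels == 1).all()
        assert list(out.features.columns) == GENDER_SCHEMA.encoded_names
        assert set(np.unique(out.features["gender"])) <= {0.0, 1.0}

    def test_gaussian_marginal_matches_fit(self, rng):
        model = DistributionModel(
            (
                GaussianDistribution("height", 5.0, 4.0),
                fit_minority_distributions(
                    gender_minority_frame(), GENDER_SCHEMA
                ).distributions[1],
            ),
            24,
            GENDER_SCHEMA,
        )
        out = dos_generate(model, 10 ** 4, rng)
        x = out.features["height"]
        assert abs(x.mean() - 5.0) < 3 * 2.0 / 100  # 3 SE at n=1e4, sd=2
        assert x.var(ddof=1) == pytest.approx(4.0, rel=0.1)

    def test_binomial_marginal_matches_fit(self, rng):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        out = dos_generate(model, 10 ** 4, rng)
        p = 15 / 24
        se = np.sqrt(p * (1 - p) / 10 ** 4)
        assert abs(out.features["gender"].mean() - p) < 3 * se

    def test_generated_variables_are_uncorrelated(self, rng):
        schema = FeatureSchema(
            (Variable("a", "continuous"), Variable("b", "continuous")),
            label="y",
            minority_value="m",
        )
        frame = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        model = fit_minority_distributions(frame, schema)
        out = dos_generate(model, 10 ** 4, rng)
        r = np.corrcoef(out.features["a"], out.features["b"])[0, 1]
        assert abs(r) < 0.05

    def test_clipping_respects_observed_range(self, rng):
        frame = pd.DataFrame({"height": [1.0, 1.2, 1.4], "gender": [1.0, 0.0, 1.0]})
        model = fit_minority_distributions(frame, GENDER_SCHEMA)
        out = dos_generate(model, 1000, rng, clip_to_range=True)
        assert out.features["height"].between(1.0, 1.4).all()

    def test_categorical_chi_square_goodness_of_fit(self, rng):
        model = fit_minority_distributions(gender_minority_frame(), GENDER_SCHEMA)
        out = dos_generate(model, 10 ** 4, rng)
        males = int(out.features["gender"].sum())
        expected = np.array([15 / 24, 9 / 24]) * 10 ** 4
        _, p = stats.chisquare([males, 10 ** 4 - males], expected)
        assert p > 0.01
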