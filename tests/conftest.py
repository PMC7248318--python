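import numpy as np
import pandas as pd
import pytest

from husdosboost.datamodel import FeatureSchema, LabeledDataset, Variable


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def continuous_schema():
    """Two continuous variables, labels 'case'/'control'."""
    return FeatureSchema(
        variables=(Variable("x1", "continuous"), Variable("x2", "continuous")),
        label="status",
        minority_value="case",
        majority_value="control",
    )


@pytest.fixture
def mixed_schema():
    """Continuous + binary + 3-level categorical."""
    return FeatureSchema(
        variables=(
            Variable("height", "continuous"),
            Variable("gender", "binary", ("female", "male")),
            Variable("smoker", "categorical", ("never", "former", "current")),
        ),
        label="status",
        minority_value="case",
        majority_value="control",
    )


def make_dataset(X, y, names=None):
    """Build a LabeledDataset from a plain numeric matrix and 0/1 labels."""
    X = np.asarray(X, dtype=float)
    names = names or [f"v{j + 1}" for j in range(X.shape[1])]
    schema = FeatureSchema(
        variables=tuple(Variable(n, "continuous") for n in names),
        label="class",
        minority_value="minority",
    )
    return LabeledDataset(
        pd.DataFrame(X, columns=names), np.asarray(y, dtype=np.int8), schema
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
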