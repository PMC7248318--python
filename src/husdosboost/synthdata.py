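"""Seeded generators of extremely imbalanced, small-minority (EISM) tables.

No public dataset at the 16-in-7,000 scale ships with the package, so the
generator produces tables with the same shape: a handful of minority rows
against thousands of majority rows, mixed continuous and binary variables,
a known informative subset, and a tunable class separation.

Continuous informative variables are class-shifted unit-variance Gaussians —
the minority mean sits ``delta`` within-class standard deviations above the
majority mean — noise variables are N(0, 1) in both classes, and binary
variables carry per-class success probabilities. Variables are
class-conditionally independent, which matches the independence assumption
of the distribution-based over-sampler and makes the implied Bayes-optimal
rule a simple log-likelihood-ratio threshold that tests can evaluate.

Defaults (20 minority / 2,000 majority, two informative variables at
delta = 1.5 among eight noise variables) give a moderately separable 1%
problem: hard enough that method differences are visible, not so hard that
every method sits at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    FeatureSchema,
    LabeledDataset,
    MAJORITY,
    MINORITY,
    Variable,
    partition_classes,
)


@dataclass(frozen=True)
class BinaryVariableSpec:
    """A 0/1 variable with per-class success probabilities."""

    name: str
    p_min: float
    p_maj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min <= 1.0 and 0.0 <= self.p_maj <= 1.0):
            raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Shape and separation of a generated EISM table."""

    n_min: int = 20
    n_maj: int = 2000
    n_informative: int = 2
    delta: float = 1.5  # minority mean shift, in within-class SD units
    n_noise: int = 8
    binary_vars: tuple[BinaryVariableSpec, ...] = ()
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.n_maj < 1:
            raise ValueError("n_maj must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("variable counts must be >= 0")
        if self.n_informative + self.n_noise + len(self.binary_vars) < 1:
            raise ValueError("at least one variable is required")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: the informative set and the Bayes rule.

    ``params`` maps each variable name to its class-conditional parameters:
    ``{"kind": "gaussian", "mean_min", "mean_maj", "sd_min", "sd_maj"}`` or
    ``{"kind": "binary", "p_min", "p_maj"}``.
    """

    informative: tuple[str, ...]
    params: dict[str, dict]
    description: str

    def log_likelihood_ratio(self, features: pd.DataFrame) -> np.ndarray:
        """Per-example log p(x | minority) - log p(x | majority)."""
        llr = np.zeros(len(features))
        for name, p in self.params.items():
            x = features[name].to_numpy(dtype=float)
            if p["kind"] == "gaussian":
                sd_min, sd_maj = p["sd_min"], p["sd_maj"]
                llr += (
                    -0.5 * ((x - p["mean_min"]) / sd_min) ** 2
                    - np.log(sd_min)
                    + 0.5 * ((x - p["mean_maj"]) / sd_maj) ** 2
                    + np.log(sd_maj)
                )
            else:
                pm, pM = p["p_min"], p["p_maj"]
                eps = 1e-12
                llr += x * (np.log(pm + eps) - np.log(pM + eps)) + (1 - x) * (
                    np.log(1 - pm + eps) - np.log(1 - pM + eps)
                )
        return llr

    def bayes_predict(self, features: pd.DataFrame) -> np.ndarray:
        """Equal-prior Bayes rule: minority iff the LLR is positive.

        Equal priors make this the balanced rule, the natural reference for
        G-mean rather than raw accuracy.
        """
        return (self.log_likelihood_ratio(features) > 0).astype(np.int8)


def _assemble(
    blocks: dict[str, np.ndarray],
    labels: np.ndarray,
    variables: Sequence[Variable],
    rng: np.random.Generator,
) -> LabeledDataset:
    schema = FeatureSchema(
        tuple(variables), label="class", minority_value="minority"
    )
    order = rng.permutation(len(labels))
    features = pd.DataFrame(
        {name: col[order] for name, col in blocks.items()},
        columns=schema.encoded_names,
        dtype=float,
    )
    return LabeledDataset(features, labels[order], schema)


def generate_eism(config: SynthConfig) -> tuple[LabeledDataset, GroundTruth]:
    """Generate one EISM table with exact class counts and known truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_min + config.n_maj
    labels = np.concatenate(
        [
            np.full(config.n_min, MINORITY, dtype=np.int8),
            np.full(config.n_maj, MAJORITY, dtype=np.int8),
        ]
    )
    is_min = labels == MINORITY

    blocks: dict[str, np.ndarray] = {}
    variables: list[Variable] = []
    params: dict[str, dict] = {}
    informative: list[str] = []

    for j in range(config.n_informative):
        name = f"inf_{j + 1}"
        x = rng.normal(0.0, 1.0, size=n)
        x[is_min] += config.delta
        blocks[name] = x
        variables.append(Variable(name, "continuous"))
        params[name] = {
            "kind": "gaussian",
            "mean_min": config.delta, "mean_maj": 0.0,
            "sd_min": 1.0, "sd_maj": 1.0,
        }
        if config.delta > 0:
            informative.append(name)
    for j in range(config.n_noise):
        name = f"noise_{j + 1}"
        blocks[name] = rng.normal(0.0, 1.0, size=n)
        variables.append(Variable(name, "continuous"))
        params[name] = {
            "kind": "gaussian",
            "mean_min": 0.0, "mean_maj": 0.0, "sd_min": 1.0, "sd_maj": 1.0,
        }
    for spec in config.binary_vars:
        x = np.where(
            is_min,
            rng.random(n) < spec.p_min,
            rng.random(n) < spec.p_maj,
        ).astype(float)
        blocks[spec.name] = x
        variables.append(Variable(spec.name, "binary", ("no", "yes")))
        params[spec.name] = {
            "kind": "binary", "p_min": spec.p_min, "p_maj": spec.p_maj,
        }
        if spec.p_min != spec.p_maj:
            informative.append(spec.name)

    truth = GroundTruth(
        informative=tuple(informative),
        params=params,
        description=(
            f"minority iff sum of class-conditional log-likelihood ratios > 0; "
            f"informative continuous variables are shifted by "
            f"delta={config.delta} within-class SDs"
        ),
    )
    return _assemble(blocks, labels, variables, rng), truth


def reduce_minority(
    dataset: LabeledDataset, n_keep: int, rng: np.random.Generator
) -> LabeledDataset:
    """Randomly drop minority rows until ``n_keep`` remain; majority untouched."""
    partition = partition_classes(dataset)
    if not 2 <= n_keep <= partition.n_min:
        raise ValueError(
            f"n_keep={n_keep} outside [2, n_min={partition.n_min}]"
        )
    keep_min = np.sort(
        rng.choice(partition.minority_idx, size=n_keep, replace=False)
    )
    keep = np.sort(np.concatenate([keep_min, partition.majority_idx]))
    return dataset.subset(keep)


def generate_hr_like(
    seed: Optional[int] = None,
    n_min: int = 16,
    n_maj: int = 7379,
) -> tuple[LabeledDataset, GroundTruth]:
    """A 41-variable health-record-like preset at ~0.2% prevalence.

    One informative age-like variable (majority 56.6 +/- 11.6 years,
    minority 68.8 +/- 10.8), a gender variable with mildly different
    per-class male shares (10/16 vs 3890/7379), four uninformative yes/no
    lifestyle-habit variables, and 35 continuous noise variables.
    """
    rng = np.random.default_rng(seed)
    n = n_min + n_maj
    labels = np.concatenate(
        [np.full(n_min, MINORITY, np.int8), np.full(n_maj, MAJORITY, np.int8)]
    )
    is_min = labels == MINORITY

    blocks: dict[str, np.ndarray] = {}
    variables: list[Variable] = []
    params: dict[str, dict] = {}

    age = np.where(
        is_min, rng.normal(68.8, 10.8, n), rng.normal(56.6, 11.6, n)
    )
    blocks["age"] = age
    variables.append(Variable("age", "continuous"))
    params["age"] = {
        "kind": "gaussian",
        "mean_min": 68.8, "mean_maj": 56.6, "sd_min": 10.8, "sd_maj": 11.6,
    }

    p_min_male, p_maj_male = 10 / 16, 3890 / 7379
    gender = np.where(
        is_min, rng.random(n) < p_min_male, rng.random(n) < p_maj_male
    ).astype(float)
    blocks["gender"] = gender
    variables.append(Variable("gender", "binary", ("female", "male")))
    params["gender"] = {"kind": "binary", "p_min": p_min_male, "p_maj": p_maj_male}

    for j in range(4):
        name = f"habit_{j + 1}"
        blocks[name] = (rng.random(n) < 0.3).astype(float)
        variables.append(Variable(name, "binary", ("no", "yes")))
        params[name] = {"kind": "binary", "p_min": 0.3, "p_maj": 0.3}

    for j in range(35):
        name = f"lab_{j + 1}"
        blocks[name] = rng.normal(0.0, 1.0, n)
        variables.append(Variable(name, "continuous"))
        params[name] = {
            "kind": "gaussian",
            "mean_min": 0.0, "mean_maj": 0.0, "sd_min": 1.0, "sd_maj": 1.0,
        }

    truth = GroundTruth(
        informative=("age", "gender"),
        params=params,
        description=(
            "minority iff the summed log-likelihood ratio over age and gender "
            "is positive; age carries nearly all the signal "
            "(about a one-SD mean shift)"
        ),
    )
    return _assemble(blocks, labels, variables, rng), truth
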