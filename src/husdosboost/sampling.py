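"""Majority under-sampling and minority over-sampling primitives.

Two unrelated kinds of resampling live here:

* **Heuristic under-sampling (HUS)** keeps a separate vector of *sampling
  weights* over the majority examples. After each boosting round, sampled
  majority examples that the round's weak classifier got right are
  down-weighted by the round's beta, sampled-and-misclassified ones are
  up-weighted by 1/beta, and unsampled ones are untouched; the vector is then
  renormalized. Hard majority examples therefore tend to re-enter later
  training sets. Random under-sampling (RUS) is the uniform baseline.

* **Distribution-based over-sampling (DOS)** fits a per-variable model to the
  minority class — category proportions p_k = N_k / N_a for discrete
  variables, a Gaussian N(mu, sigma^2) for continuous ones — and draws
  artificial minority examples variable-by-variable, independently. It never
  interpolates between real examples, so it remains usable when the minority
  class has only a handful of members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    ClassPartition,
    FeatureSchema,
    LabeledDataset,
    MINORITY,
)

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SamplingState:
    """Sampling weights over the majority examples for one boosting round."""

    weights: np.ndarray
    round: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any():
            raise ValueError("sampling weights must be nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("sampling weights must sum to 1")

    @property
    def n_maj(self) -> int:
        return len(self.weights)


def init_sampling_weights(n_maj: int) -> SamplingState:
    """Uniform sampling weights 1/N_maj at round 1."""
    if n_maj < 1:
        raise ValueError("need at least one majority example")
    return SamplingState(np.full(n_maj, 1.0 / n_maj), round=1)


def hus_sample(
    state: SamplingState, n_u: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_u`` distinct majority positions by sampling weight.

    Weighted sampling *without* replacement (sequential draws with weight
    removal): a duplicated majority row would add no information to the weak
    learner. Positions are indices into ``state.weights``; callers map them to
    dataset rows. If fewer than ``n_u`` weights are nonzero, all nonzero
    positions are taken and the remainder filled uniformly from the rest.
    """
    n_maj = state.n_maj
    if not 1 <= n_u <= n_maj:
        raise ValueError(f"n_u={n_u} outside [1, n_maj={n_maj}]")
    p = state.weights / state.weights.sum()
    nonzero = np.flatnonzero(p > 0)
    if len(nonzero) >= n_u:
        picked = rng.choice(n_maj, size=n_u, replace=False, p=p)
    else:
        zero = np.setdiff1d(np.arange(n_maj), nonzero)
        fill = rng.choice(zero, size=n_u - len(nonzero), replace=False)
        picked = np.concatenate([nonzero, fill])
    return np.sort(picked)


def rus_sample(
    partition: ClassPartition, n_u: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of ``n_u`` distinct majority *dataset* indices."""
    if not 1 <= n_u <= partition.n_maj:
        raise ValueError(f"n_u={n_u} outside [1, n_maj={partition.n_maj}]")
    return np.sort(rng.choice(partition.majority_idx, size=n_u, replace=False))


def update_sampling_weights(
    state: SamplingState,
    sampled: np.ndarray,
    correct: np.ndarray,
    beta: float,
) -> SamplingState:
    """Post-round sampling-weight update.

    Sampled-and-correct positions are multiplied by ``beta``, sampled-and-
    misclassified ones by ``1/beta``, unsampled ones by 1; the vector is then
    renormalized. With beta < 1 this raises the selection probability of the
    majority examples the round's classifier got wrong.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    sampled = np.asarray(sampled, dtype=int)
    correct = np.asarray(correct, dtype=bool)
    if len(sampled) != len(correct):
        raise ValueError("sampled and correct must align")
    w = state.weights.copy()
    w[sampled[correct]] *= beta
    w[sampled[~correct]] /= beta
    return SamplingState(w / w.sum(), round=state.round + 1)


# ---------------------------------------------------------------------------
# Distribution-based over-sampling


@dataclass(frozen=True)
class CategoricalDistribution:
    """Category proportions p_k = N_k / N_a for one discrete variable."""

    variable: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()))
        if (vals < 0).any() or abs(vals.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"{self.variable}: proportions must be nonnegative and sum to 1"
            )


@dataclass(frozen=True)
class GaussianDistribution:
    """Fitted N(mu, sigma^2) for one continuous variable.

    ``observed_min``/``observed_max`` record the minority range for the
    optional clipping mode; draws are unclipped by default.
    """

    variable: str
    mean: float
    variance: float
    observed_min: float = float("-inf")
    observed_max: float = float("inf")

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError(f"{self.variable}: variance must be positive")


@dataclass(frozen=True)
class KernelDensityDistribution:
    """Gaussian-KDE alternative for continuous variables (config switch)."""

    variable: str
    values: np.ndarray
    bandwidth: float
    observed_min: float = float("-inf")
    observed_max: float = float("inf")


AnyDistribution = Union[
    CategoricalDistribution, GaussianDistribution, KernelDensityDistribution
]


def variance_floor(mean: float) -> float:
    """Smallest admissible variance, scaled so constant variables survive."""
    return 1e-12 * (1.0 + mean * mean)


@dataclass(frozen=True)
class DistributionModel:
    """Per-variable minority distributions, aligned with a schema."""

    distributions: tuple[AnyDistribution, ...]
    n_a: int
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if len(self.distributions) != len(self.schema.variables):
            raise ValueError("need exactly one distribution per schema variable")

    def to_json(self, path: str | Path | None = None) -> str:
        entries = []
        for d in self.distributions:
            if isinstance(d, CategoricalDistribution):
                entries.append(
                    {"variable": d.variable, "kind": "categorical",
                     "proportions": d.proportions}
                )
            elif isinstance(d, GaussianDistribution):
                entries.append(
                    {"variable": d.variable, "kind": "gaussian", "mean": d.mean,
                     "variance": d.variance, "observed_min": d.observed_min,
                     "observed_max": d.observed_max}
                )
            else:
                entries.append(
                    {"variable": d.variable, "kind": "kde",
                     "values": list(map(float, d.values)),
                     "bandwidth": d.bandwidth,
                     "observed_min": d.observed_min,
                     "observed_max": d.observed_max}
                )
        text = json.dumps({"n_a": self.n_a, "distributions": entries}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str, schema: FeatureSchema) -> "DistributionModel":
        d = json.loads(text)
        dists: list[AnyDistribution] = []
        for e in d["distributions"]:
            if e["kind"] == "categorical":
                dists.append(CategoricalDistribution(e["variable"], e["proportions"]))
            elif e["kind"] == "gaussian":
                dists.append(
                    GaussianDistribution(
                        e["variable"], e["mean"], e["variance"],
                        e["observed_min"], e["observed_max"],
                    )
                )
            else:
                dists.append(
                    KernelDensityDistribution(
                        e["variable"], np.asarray(e["values"], float),
                        e["bandwidth"], e["observed_min"], e["observed_max"],
                    )
                )
        return cls(tuple(dists), d["n_a"], schema)


def fit_minority_distributions(
    minority_features: pd.DataFrame,
    schema: FeatureSchema,
    *,
    continuous_model: str = "gaussian",
) -> DistributionModel:
    """Fit per-variable minority distributions from encoded minority rows.

    Continuous variables get a Gaussian (sample mean, unbiased variance;
    floored when the variable is constant). Binary and categorical variables
    get category proportions computed from their indicator columns.
    ``continuous_model="kde"`` swaps the Gaussian for a Gaussian KDE
    (Scott-factor bandwidth).
    """
    n_a = len(minority_features)
    if n_a < 2:
        raise ValueError(f"need >= 2 minority examples to fit distributions, got {n_a}")
    if continuous_model not in ("gaussian", "kde"):
        raise ValueError(f"unknown continuous_model {continuous_model!r}")

    dists: list[AnyDistribution] = []
    for var in schema.variables:
        if var.vtype == "continuous":
            x = minority_features[var.name].to_numpy(dtype=float)
            mu = float(x.mean())
            lo, hi = float(x.min()), float(x.max())
            if continuous_model == "kde":
                bw = float(n_a ** (-1.0 / 5.0) * max(x.std(ddof=1), 1e-12))
                dists.append(KernelDensityDistribution(var.name, x.copy(), bw, lo, hi))
                continue
            s2 = float(x.var(ddof=1))
            floor = variance_floor(mu)
            if s2 < floor:
                logger.warning(
                    "variable %r is (near-)constant in the minority class; "
                    "variance floored at %.3g", var.name, floor,
                )
                s2 = floor
            dists.append(GaussianDistribution(var.name, mu, s2, lo, hi))
        else:
            if var.vtype == "binary":
                p1 = float(minority_features[var.name].mean())
                props = {var.categories[0]: 1.0 - p1, var.categories[1]: p1}
            else:
                cols = [f"{var.name}={c}" for c in var.categories]
                counts = minority_features[cols].to_numpy().sum(axis=0)
                props = {
                    c: float(k) / n_a for c, k in zip(var.categories, counts)
                }
            dists.append(CategoricalDistribution(var.name, props))
    return DistributionModel(tuple(dists), n_a, schema)


def dos_generate(
    model: DistributionModel,
    n_o: int,
    rng: np.random.Generator,
    *,
    clip_to_range: bool = False,
) -> LabeledDataset:
    """Draw ``n_o`` artificial minority examples, one variable at a time.

    Each variable is sampled independently from its fitted distribution; any
    correlation between generated variables arises only by chance. Labels are
    all minority. ``clip_to_range`` clips continuous draws to the observed
    minority range (off by default).
    """
    if n_o < 0:
        raise ValueError("n_o must be nonnegative")
    schema = model.schema
    cols: dict[str, np.ndarray] = {}
    for dist in model.distributions:
        var = schema.variable(dist.variable)
        if isinstance(dist, CategoricalDistribution):
            cats = list(var.categories)
            p = np.array([dist.proportions[c] for c in cats])
            picks = rng.choice(len(cats), size=n_o, p=p / p.sum())
            if var.vtype == "binary":
                cols[var.name] = (picks == 1).astype(float)
            else:
                for j, c in enumerate(cats):
                    cols[f"{var.name}={c}"] = (picks == j).astype(float)
        else:
            if isinstance(dist, GaussianDistribution):
                x = rng.normal(dist.mean, np.sqrt(dist.variance), size=n_o)
            else:
                base = rng.choice(dist.values, size=n_o, replace=True)
                x = base + rng.normal(0.0, dist.bandwidth, size=n_o)
            if clip_to_range:
                x = np.clip(x, dist.observed_min, dist.observed_max)
            cols[var.name] = x
    features = pd.DataFrame(cols, columns=schema.encoded_names, dtype=float)
    return LabeledDataset(features, np.full(n_o, MINORITY, dtype=np.int8), schema)
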