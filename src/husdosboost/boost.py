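"""AdaBoost.M1 engine with pluggable per-round resampling.

One engine implements four named variants through its sampling switches:

========== ================ =============
variant     under_sampling   over_sampling
========== ================ =============
adaboost    none             none
rusboost    rus              none
husboost    hus              none
husdos      hus              dos
========== ================ =============

Every round t draws a majority sample (all of it when under-sampling is off),
appends the full original minority plus n_o artificial minority examples
drawn by DOS, fits a weighted tree on that round set, and then evaluates the
tree on the *full* dataset: the weighted error

    eps_t = sum over misclassified of D_{t,n}

drives both beta_t = eps_t / (1 - eps_t) and the two weight updates — the
boosting weights D (correct examples multiplied by beta_t, renormalized) and,
for HUS, the majority sampling weights (sampled-and-correct x beta_t,
sampled-and-wrong x 1/beta_t, renormalized). The fitted ensemble classifies
by the weighted vote with votes alpha_t = log(1 / beta_t).

Artificial minority examples live only inside their round: they enter the
tree's objective with weight equal to the mean boosting weight of the real
minority examples, and the boosting-weight update runs over original
examples only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ClassPartition,
    FeatureSchema,
    LabeledDataset,
    MAJORITY,
    MINORITY,
    partition_classes,
)
from .sampling import (
    DistributionModel,
    SamplingState,
    dos_generate,
    fit_minority_distributions,
    hus_sample,
    init_sampling_weights,
    rus_sample,
    update_sampling_weights,
)
from .tree import TreeConfig, TreeModel, fit_weighted_tree

logger = logging.getLogger(__name__)

UNDER_SAMPLING = ("hus", "rus", "none")
OVER_SAMPLING = ("dos", "none")
_VARIANTS = {
    "husdos": ("hus", "dos"),
    "husboost": ("hus", "none"),
    "hus": ("hus", "none"),
    "rusboost": ("rus", "none"),
    "rus": ("rus", "none"),
    "adaboost": ("none", "none"),
}


@dataclass(frozen=True)
class BoostConfig:
    """Engine configuration.

    ``n_u`` / ``n_o`` are the per-round majority sample size and artificial
    minority count. Left as None they are derived from the training data's
    minority count: n_o = n_min when over-sampling is on (else 0) and
    n_u = n_min + n_o, a balanced round sample. ``n_u_factor`` / ``n_o_factor``
    instead set them as multiples of the minority count, which is what the
    sampling-size sweep protocols vary.
    """

    n_rounds: int = 100
    n_u: Optional[int] = None
    n_o: Optional[int] = None
    n_u_factor: Optional[float] = None
    n_o_factor: Optional[float] = None
    under_sampling: str = "hus"
    over_sampling: str = "dos"
    epsilon_min: float = 1e-10
    artificial_weight: str = "mean_minority"  # or "mean_all"
    tree: TreeConfig = field(default_factory=TreeConfig)
    max_degenerate_retries: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0.0 < self.epsilon_min < 0.5:
            raise ValueError("epsilon_min must lie in (0, 0.5)")
        if self.under_sampling not in UNDER_SAMPLING:
            raise ValueError(f"under_sampling must be one of {UNDER_SAMPLING}")
        if self.over_sampling not in OVER_SAMPLING:
            raise ValueError(f"over_sampling must be one of {OVER_SAMPLING}")
        if self.artificial_weight not in ("mean_minority", "mean_all"):
            raise ValueError("artificial_weight must be 'mean_minority' or 'mean_all'")

    @classmethod
    def variant(cls, name: str, **overrides) -> "BoostConfig":
        """Named preset: husdos | husboost | rusboost | adaboost."""
        try:
            under, over = _VARIANTS[name]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}"
            ) from None
        return cls(under_sampling=under, over_sampling=over, **overrides)

    def resolve_sizes(self, partition: ClassPartition) -> tuple[int, int]:
        """Concrete (n_u, n_o) for a given training partition."""
        n_min, n_maj = partition.n_min, partition.n_maj
        if self.over_sampling == "none":
            n_o = 0
        elif self.n_o is not None:
            n_o = self.n_o
        elif self.n_o_factor is not None:
            n_o = int(round(self.n_o_factor * n_min))
        else:
            n_o = n_min
        if self.under_sampling == "none":
            n_u = n_maj
        elif self.n_u is not None:
            n_u = self.n_u
        elif self.n_u_factor is not None:
            n_u = min(n_maj, int(round(self.n_u_factor * n_min)))
        else:
            n_u = min(n_maj, n_min + n_o)
        if not 1 <= n_u <= n_maj:
            raise ValueError(f"n_u={n_u} outside [1, n_maj={n_maj}]")
        if n_o < 0:
            raise ValueError("n_o must be >= 0")
        return n_u, n_o

    def to_dict(self) -> dict:
        return {
            "n_rounds": self.n_rounds,
            "n_u": self.n_u,
            "n_o": self.n_o,
            "n_u_factor": self.n_u_factor,
            "n_o_factor": self.n_o_factor,
            "under_sampling": self.under_sampling,
            "over_sampling": self.over_sampling,
            "epsilon_min": self.epsilon_min,
            "artificial_weight": self.artificial_weight,
            "tree": {"max_depth": self.tree.max_depth,
                     "min_leaf_weight": self.tree.min_leaf_weight},
            "max_degenerate_retries": self.max_degenerate_retries,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class RoundRecord:
    """Log entry for one retained boosting round."""

    t: int
    epsilon: float  # raw weighted error on the full dataset
    epsilon_clamped: float
    beta: float
    alpha: float
    z_boost: float  # normalization constant of the D update
    z_sampling: Optional[float]  # of the SW update (HUS only)
    sampled_majority: np.ndarray  # dataset indices
    n_artificial: int
    retries: int  # discarded degenerate attempts before this round stuck


@dataclass
class BoostState:
    """Mutable per-fit state: boosting weights, sampling weights, history."""

    boosting_weights: np.ndarray  # D over all N examples, sums to 1
    sampling_state: Optional[SamplingState]
    records: list[RoundRecord] = field(default_factory=list)


class DegenerateFitError(RuntimeError):
    """Raised when no non-degenerate weak classifier can be fitted."""


def weighted_error(
    predictions: np.ndarray, labels: np.ndarray, boosting_weights: np.ndarray
) -> float:
    """eps_t: total boosting weight of the misclassified examples."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    w = np.asarray(boosting_weights, dtype=float)
    if not (len(predictions) == len(labels) == len(w)):
        raise ValueError("predictions, labels and weights must align")
    return float(w[predictions != labels].sum())


def beta_from_error(epsilon: float) -> float:
    """beta_t = eps_t / (1 - eps_t); callers clamp eps into [eps_min, 0.5)."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon={epsilon} must lie in (0, 0.5)")
    return epsilon / (1.0 - epsilon)


def update_boosting_weights(
    weights: np.ndarray,
    predictions: np.ndarray,
    labels: np.ndarray,
    beta: float,
) -> tuple[np.ndarray, float]:
    """Multiply correct examples by beta, renormalize; returns (D, Z_t)."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    w = np.asarray(weights, dtype=float).copy()
    correct = np.asarray(predictions) == np.asarray(labels)
    w[correct] *= beta
    z = float(w.sum())
    return w / z, z


@dataclass
class EnsembleModel:
    """Fitted weighted-vote ensemble of weak trees."""

    trees: list[TreeModel]
    alphas: np.ndarray
    schema: FeatureSchema
    config: BoostConfig
    records: list[RoundRecord]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.trees) != len(self.alphas):
            raise ValueError("one vote per tree required")
        if not np.all(np.isfinite(self.alphas)) or (self.alphas <= 0).any():
            raise ValueError("votes must be finite and positive")

    @property
    def n_rounds_fitted(self) -> int:
        return len(self.trees)

    def _matrix(self, examples) -> np.ndarray:
        if isinstance(examples, LabeledDataset):
            examples = examples.features
        return examples

    def score(self, examples) -> np.ndarray:
        """Normalized vote margin in [-1, 1]; positive favors the minority."""
        X = self._matrix(examples)
        total = self.alphas.sum()
        margin = np.zeros(len(X))
        for tree, alpha in zip(self.trees, self.alphas):
            h = tree.predict(X)
            margin += alpha * np.where(h == MINORITY, 1.0, -1.0)
        return margin / total

    def predict(self, examples) -> np.ndarray:
        """Weighted-vote class; an exact tie goes to the majority class."""
        return (self.score(examples) > 0).astype(np.int8)

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "schema": self.schema.to_dict(),
            "feature_names": list(self.feature_names),
            "alphas": list(map(float, self.alphas)),
            "trees": [json.loads(t.to_json()) for t in self.trees],
            "rounds": [
                {
                    "t": r.t,
                    "epsilon": r.epsilon,
                    "beta": r.beta,
                    "alpha": r.alpha,
                    "n_sampled_majority": int(len(r.sampled_majority)),
                    "n_artificial": r.n_artificial,
                    "retries": r.retries,
                }
                for r in self.records
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class ImportanceReport:
    """Normalized per-variable importance VI_p, summing to 1."""

    importances: dict[str, float]
    z_vi: float

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: -kv[1])

    def to_text(self) -> str:
        lines = [f"{'variable':<24}  VI"]
        for name, vi in self.ranked():
            lines.append(f"{name:<24}  {vi:.4f}")
        return "\n".join(lines)


def fit(
    dataset: LabeledDataset,
    config: BoostConfig | None = None,
    rng: np.random.Generator | None = None,
) -> EnsembleModel:
    """Fit a boosted ensemble on a labeled dataset.

    ``rng`` overrides ``config.seed`` when given (the cross-validation
    harness threads spawned generators through here). Identical data, config
    and seed give a bit-identical model.
    """
    config = config or BoostConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    partition = partition_classes(dataset)
    n_u, n_o = config.resolve_sizes(partition)
    X = dataset.X
    y = np.asarray(dataset.labels)
    n = len(y)
    min_idx = partition.minority_idx
    maj_idx = partition.majority_idx

    dist_model: DistributionModel | None = None
    if config.over_sampling == "dos":
        dist_model = fit_minority_distributions(
            dataset.features.iloc[min_idx], dataset.schema
        )

    state = BoostState(
        boosting_weights=np.full(n, 1.0 / n),
        sampling_state=(
            init_sampling_weights(partition.n_maj)
            if config.under_sampling == "hus"
            else None
        ),
    )

    trees: list[TreeModel] = []
    alphas: list[float] = []
    consecutive_failures = 0
    weights_reset = False

    t = 1
    while t <= config.n_rounds:
        # -- assemble the round's training set
        if config.under_sampling == "hus":
            positions = hus_sample(state.sampling_state, n_u, rng)
            sampled_maj = maj_idx[positions]
        elif config.under_sampling == "rus":
            positions = None
            sampled_maj = rus_sample(partition, n_u, rng)
        else:
            positions = None
            sampled_maj = maj_idx

        parts_X = [X[sampled_maj], X[min_idx]]
        parts_y = [y[sampled_maj], y[min_idx]]
        D = state.boosting_weights
        parts_w = [D[sampled_maj], D[min_idx]]
        if n_o > 0:
            artificial = dos_generate(dist_model, n_o, rng)
            parts_X.append(artificial.X)
            parts_y.append(artificial.labels)
            base = D.mean() if config.artificial_weight == "mean_all" else D[min_idx].mean()
            parts_w.append(np.full(n_o, base))
        train_X = np.concatenate(parts_X)
        train_y = np.concatenate(parts_y)
        train_w = np.concatenate(parts_w)

        tree = fit_weighted_tree(
            train_X, train_y, train_w, config.tree,
            feature_names=dataset.schema.encoded_names,
        )
        h = tree.predict(X)
        eps = weighted_error(h, y, D)

        if eps >= 0.5:
            # degenerate round: discard and redraw; after repeated failures
            # reset both weight vectors once, then give up
            consecutive_failures += 1
            logger.debug("round %d attempt degenerate (eps=%.3f)", t, eps)
            if consecutive_failures >= config.max_degenerate_retries:
                if not weights_reset:
                    logger.warning(
                        "resetting boosting and sampling weights after %d "
                        "degenerate attempts at round %d",
                        consecutive_failures, t,
                    )
                    state.boosting_weights = np.full(n, 1.0 / n)
                    if state.sampling_state is not None:
                        state.sampling_state = init_sampling_weights(partition.n_maj)
                    weights_reset = True
                    consecutive_failures = 0
                elif trees:
                    logger.warning("stopping early at round %d: degenerate", t)
                    break
                else:
                    raise DegenerateFitError(
                        f"no non-degenerate weak classifier found in "
                        f"{config.max_degenerate_retries} attempts per phase "
                        f"(last eps={eps:.3f}, n_u={n_u}, n_o={n_o})"
                    )
            continue

        retries = consecutive_failures
        consecutive_failures = 0
        weights_reset = False

        eps_eff = max(eps, config.epsilon_min)
        beta = beta_from_error(eps_eff)
        alpha = math.log(1.0 / beta)

        new_D, z_boost = update_boosting_weights(D, h, y, beta)
        state.boosting_weights = new_D

        z_sampling = None
        if config.under_sampling == "hus":
            correct = h[sampled_maj] == y[sampled_maj]
            prev = state.sampling_state
            state.sampling_state = update_sampling_weights(
                prev, positions, correct, beta
            )
            multipliers = np.ones(prev.n_maj)
            multipliers[positions[correct]] = beta
            multipliers[positions[~correct]] = 1.0 / beta
            z_sampling = float(np.sum(prev.weights * multipliers))

        state.records.append(
            RoundRecord(
                t=t,
                epsilon=eps,
                epsilon_clamped=eps_eff,
                beta=beta,
                alpha=alpha,
                z_boost=z_boost,
                z_sampling=z_sampling,
                sampled_majority=sampled_maj,
                n_artificial=n_o,
                retries=retries,
            )
        )
        trees.append(tree)
        alphas.append(alpha)
        t += 1

    return EnsembleModel(
        trees=trees,
        alphas=np.asarray(alphas),
        schema=dataset.schema,
        config=config,
        records=state.records,
        feature_names=tuple(dataset.schema.encoded_names),
    )


def ensemble_predict(model: EnsembleModel, examples) -> np.ndarray:
    """Weighted-vote labels (1 = minority); exact ties go to the majority."""
    return model.predict(examples)


def ensemble_score(model: EnsembleModel, examples) -> np.ndarray:
    """Vote margin in [-1, 1]; sign agrees with prediction off ties."""
    return model.score(examples)


def variable_importance(model: EnsembleModel) -> ImportanceReport:
    """Vote-weighted variable importance of the ensemble.

    VI_p is the sum over rounds of alpha_t times the round tree's impurity
    decrease attributed to variable p, normalized so the importances sum
    to 1. Raises if no tree in the ensemble ever split.
    """
    totals = dict.fromkeys(model.feature_names, 0.0)
    for tree, alpha in zip(model.trees, model.alphas):
        for name, gain in tree.variable_gains().items():
            totals[name] += alpha * gain
    z = sum(totals.values())
    if z <= 0:
        raise ValueError("no splits in the ensemble; importance undefined")
    return ImportanceReport(
        {name: val / z for name, val in totals.items()}, z_vi=z
    )
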