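"""Evaluation protocols: repeated stratified CV and sampling-size sweeps.

The core protocol is repeated k-fold cross-validation (default 10 folds,
10 repeats), stratified by class. Stratification is the default because with
16-30 minority examples an unstratified fold is often minority-free, leaving
sensitivity undefined; it can be switched off, in which case a minority-free
test fold aborts with guidance. Per-round sampling sizes are always resolved
from the *training fold's* minority count, never from the full dataset.

On top of repeated CV sit three experiment designs: a sweep over the
artificial-minority count N_o (under-sample size held at the minority
count), a sweep over the majority-sample size N_u (N_o held at the minority
count), and a minority-reduction curve comparing variants as minority rows
are randomly discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import boost
from .boost import BoostConfig, EnsembleModel
from .datamodel import LabeledDataset, MINORITY, partition_classes
from .metrics import MetricsReport, evaluate
from .synthdata import reduce_minority

METRIC_NAMES = ("sensitivity", "specificity", "g_mean", "auc", "auprc")


@dataclass(frozen=True)
class CVProtocol:
    """Repeated k-fold protocol parameters."""

    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    report: MetricsReport


@dataclass
class EvalReport:
    """Per-fold metric reports plus their mean +/- SD aggregation."""

    folds: list[FoldResult]
    config: BoostConfig
    protocol: CVProtocol

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": f.repeat, "fold": f.fold, **f.report.to_dict()}
            for f in self.folds
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Metric -> (mean, SD) over all fold-level values."""
        frame = self.to_frame()
        return {
            m: (float(frame[m].mean()), float(frame[m].std(ddof=0)))
            for m in METRIC_NAMES
        }

    def format_summary(self) -> str:
        lines = []
        for metric, (mean, sd) in self.summary().items():
            lines.append(f"{metric:<12} {mean:.2f}±{sd:.2f}")
        return "\n".join(lines)


def _fold_indices(
    labels: np.ndarray, protocol: CVProtocol, random_state: int
):
    cls = StratifiedKFold if protocol.stratified else KFold
    splitter = cls(
        n_splits=protocol.n_folds, shuffle=True, random_state=random_state
    )
    return splitter.split(np.zeros(len(labels)), labels)


def repeated_cv(
    dataset: LabeledDataset,
    boost_config: BoostConfig,
    protocol: CVProtocol,
) -> EvalReport:
    """Run the repeated stratified CV protocol and aggregate fold metrics."""
    partition = partition_classes(dataset)
    if protocol.stratified and partition.n_min < protocol.n_folds:
        raise ValueError(
            f"stratified {protocol.n_folds}-fold CV needs at least "
            f"{protocol.n_folds} minority examples (have {partition.n_min})"
        )
    ss = np.random.SeedSequence(protocol.seed)
    labels = np.asarray(dataset.labels)
    folds: list[FoldResult] = []
    for repeat in range(protocol.n_repeats):
        split_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        assignment = list(_fold_indices(labels, protocol, split_seed))
        for fold, (_, test_idx) in enumerate(assignment):
            if np.sum(labels[test_idx] == MINORITY) == 0:
                raise ValueError(
                    f"repeat {repeat}, fold {fold}: test fold has no minority "
                    "examples; enable stratification (CVProtocol.stratified=True)"
                )
        for fold, (train_idx, test_idx) in enumerate(assignment):
            train = dataset.subset(train_idx)
            test = dataset.subset(test_idx)
            rng = np.random.default_rng(ss.spawn(1)[0])
            model = boost.fit(train, boost_config, rng=rng)
            report = evaluate(
                test.labels, model.predict(test.features), model.score(test.features)
            )
            folds.append(FoldResult(repeat, fold, report))
    return EvalReport(folds, boost_config, protocol)


@dataclass(frozen=True)
class SweepRow:
    multiplier: float
    n_per_round: int  # resolved examples per round at the full-data scale
    report: EvalReport


@dataclass
class SweepReport:
    parameter: str  # "n_o" or "n_u"
    rows: list[SweepRow]

    def to_frame(self) -> pd.DataFrame:
        out = []
        for row in self.rows:
            summary = row.report.summary()
            entry = {"multiplier": row.multiplier, self.parameter: row.n_per_round}
            for metric, (mean, sd) in summary.items():
                entry[f"{metric}_mean"] = mean
                entry[f"{metric}_sd"] = sd
            out.append(entry)
        return pd.DataFrame(out)


def sweep_oversampling(
    dataset: LabeledDataset,
    n_o_multipliers: Sequence[float],
    boost_config: BoostConfig,
    protocol: CVProtocol,
    *,
    max_round_minority: Optional[int] = None,
) -> SweepReport:
    """Repeated CV per N_o = multiplier x minority count; N_u = minority count.

    ``max_round_minority`` caps the per-round minority set size
    |original + artificial|; multipliers exceeding it are skipped with a
    warning.
    """
    n_min = partition_classes(dataset).n_min
    rows: list[SweepRow] = []
    for m in n_o_multipliers:
        n_o = int(round(m * n_min))
        if max_round_minority is not None and n_min + n_o > max_round_minority:
            warnings.warn(
                f"skipping N_o multiplier {m}: round minority set "
                f"{n_min + n_o} exceeds cap {max_round_minority}"
            )
            continue
        cfg = replace(
            boost_config, n_o=None, n_u=None, n_o_factor=float(m), n_u_factor=1.0
        )
        rows.append(SweepRow(float(m), n_o, repeated_cv(dataset, cfg, protocol)))
    return SweepReport("n_o", rows)


def sweep_undersampling(
    dataset: LabeledDataset,
    n_u_multipliers: Sequence[float],
    boost_config: BoostConfig,
    protocol: CVProtocol,
) -> SweepReport:
    """Repeated CV per N_u = multiplier x minority count; N_o = minority count.

    Multipliers that would require more majority examples than exist are
    skipped with a warning.
    """
    partition = partition_classes(dataset)
    n_min = partition.n_min
    rows: list[SweepRow] = []
    for m in n_u_multipliers:
        n_u = int(round(m * n_min))
        if n_u > partition.n_maj:
            warnings.warn(
                f"skipping N_u multiplier {m}: {n_u} exceeds the "
                f"{partition.n_maj} available majority examples"
            )
            continue
        cfg = replace(
            boost_config, n_u=None, n_o=None, n_u_factor=float(m), n_o_factor=1.0
        )
        rows.append(SweepRow(float(m), n_u, repeated_cv(dataset, cfg, protocol)))
    return SweepReport("n_u", rows)


@dataclass(frozen=True)
class CurveCell:
    variant: str
    n_keep: int
    report: EvalReport


@dataclass
class CurveReport:
    """G-mean (and friends) per (variant, retained-minority-count) cell."""

    cells: list[CurveCell]

    def to_frame(self) -> pd.DataFrame:
        out = []
        for cell in self.cells:
            summary = cell.report.summary()
            entry = {"variant": cell.variant, "n_keep": cell.n_keep}
            for metric, (mean, sd) in summary.items():
                entry[f"{metric}_mean"] = mean
                entry[f"{metric}_sd"] = sd
            out.append(entry)
        return pd.DataFrame(out)

    def crossover(self, a: str = "husdos", b: str = "rusboost") -> pd.DataFrame:
        """Per-n_keep G-mean difference a - b, for crossover diagnostics."""
        frame = self.to_frame()
        fa = frame[frame.variant == a].set_index("n_keep")["g_mean_mean"]
        fb = frame[frame.variant == b].set_index("n_keep")["g_mean_mean"]
        return pd.DataFrame({a: fa, b: fb, "difference": fa - fb}).reset_index()


def minority_reduction_curve(
    dataset: LabeledDataset,
    keep_grid: Sequence[int],
    variants: Sequence[str],
    protocol: CVProtocol,
    boost_config: BoostConfig | None = None,
) -> CurveReport:
    """Evaluate variants as the minority class is randomly thinned.

    For each count in ``keep_grid`` the minority class is subsampled once
    (same reduced dataset for every variant) and each variant is scored with
    the repeated-CV protocol.
    """
    base = boost_config or BoostConfig()
    n_min = partition_classes(dataset).n_min
    bad = [k for k in keep_grid if not 2 <= k <= n_min]
    if bad:
        raise ValueError(f"keep_grid entries outside [2, {n_min}]: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence(protocol.seed).spawn(1)[0])
    cells: list[CurveCell] = []
    for n_keep in keep_grid:
        reduced = (
            dataset if n_keep == n_min else reduce_minority(dataset, n_keep, rng)
        )
        for variant in variants:
            under, over = boost._VARIANTS[variant]
            cfg = replace(base, under_sampling=under, over_sampling=over)
            cells.append(
                CurveCell(variant, n_keep, repeated_cv(reduced, cfg, protocol))
            )
    return CurveReport(cells)
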