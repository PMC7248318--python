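"""Domain types and tabular I/O for labeled mixed-type datasets.

The central convention of the package is fixed here: the *minority* class is
the positive class (label 1) everywhere, so that sensitivity always measures
minority detection. Categorical variables with more than two levels are
expanded to one-hot binary columns at load time; downstream code (the tree
learner, the over-sampler) only ever sees numeric columns, with the logical
variable structure retained in the schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VTYPES = ("continuous", "binary", "categorical")

MAJORITY, MINORITY = 0, 1  # internal integer labels; minority = positive


@dataclass(frozen=True)
class Variable:
    """One logical input variable: a name, a type, and its categories.

    ``categories`` is empty for continuous variables, has exactly two entries
    for binary variables and two or more for categorical ones.
    """

    name: str
    vtype: str
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(
                f"variable {self.name!r}: unknown type {self.vtype!r}; "
                f"expected one of {VTYPES}"
            )
        if self.vtype == "continuous":
            if self.categories:
                raise ValueError(
                    f"variable {self.name!r}: continuous variables take no categories"
                )
            return
        if not self.categories:
            raise ValueError(f"variable {self.name!r}: categories must be non-empty")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"variable {self.name!r}: categories must be unique")
        if self.vtype == "binary" and len(self.categories) != 2:
            raise ValueError(
                f"variable {self.name!r}: binary variables need exactly 2 categories"
            )
        if self.vtype == "categorical" and len(self.categories) < 2:
            raise ValueError(
                f"variable {self.name!r}: categorical variables need >= 2 categories"
            )


@dataclass(frozen=True)
class EncodedColumn:
    """One numeric column of the encoded feature matrix.

    ``category`` is the level this column indicates: for a binary variable the
    second declared category (value 1 means that level), for a one-hot column
    its level, and None for continuous columns.
    """

    name: str
    source: str  # logical variable name
    kind: str  # "continuous" | "binary"
    category: str | None = None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered variable declarations plus the label column contract."""

    variables: tuple[Variable, ...]
    label: str
    minority_value: str
    majority_value: str = "majority"

    def __post_init__(self) -> None:
        if self.minority_value == self.majority_value:
            raise ValueError("minority and majority label values must differ")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.label in names:
            raise ValueError("label column must not appear among the variables")

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def encoded_columns(self) -> tuple[EncodedColumn, ...]:
        cols: list[EncodedColumn] = []
        for v in self.variables:
            if v.vtype == "continuous":
                cols.append(EncodedColumn(v.name, v.name, "continuous"))
            elif v.vtype == "binary":
                # value 1 <=> second declared category
                cols.append(EncodedColumn(v.name, v.name, "binary", v.categories[1]))
            else:
                for cat in v.categories:
                    cols.append(
                        EncodedColumn(f"{v.name}={cat}", v.name, "binary", cat)
                    )
        return tuple(cols)

    @property
    def encoded_names(self) -> list[str]:
        return [c.name for c in self.encoded_columns]

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "type": v.vtype, "categories": list(v.categories)}
                for v in self.variables
            ],
            "label": {
                "name": self.label,
                "minority_value": self.minority_value,
                "majority_value": self.majority_value,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        variables = tuple(
            Variable(e["name"], e["type"], tuple(e.get("categories") or ()))
            for e in d["variables"]
        )
        return cls(
            variables,
            d["label"]["name"],
            str(d["label"]["minority_value"]),
            str(d["label"].get("majority_value", "majority")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSchema":
        """Read a YAML or JSON sidecar schema."""
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class LabeledDataset:
    """Encoded feature matrix plus binary labels (1 = minority).

    ``features`` holds one column per :attr:`FeatureSchema.encoded_columns`,
    all numeric; ``labels`` is an int array in {0, 1}.
    """

    features: pd.DataFrame
    labels: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        expected = self.schema.encoded_names
        if list(self.features.columns) != expected:
            raise ValueError(
                "feature columns do not match the schema's encoded layout"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            self.features.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            self.schema,
        )


@dataclass(frozen=True)
class ClassPartition:
    """Index split of a dataset into minority and majority examples."""

    minority_idx: np.ndarray
    majority_idx: np.ndarray

    @property
    def n_min(self) -> int:
        return len(self.minority_idx)

    @property
    def n_maj(self) -> int:
        return len(self.majority_idx)


def partition_classes(dataset: LabeledDataset) -> ClassPartition:
    """Split a dataset's indices by class.

    Raises if the minority class has fewer than two examples, because the
    over-sampler needs at least two points to fit a variance.
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    minority_idx = np.flatnonzero(dataset.labels == MINORITY)
    majority_idx = np.flatnonzero(dataset.labels == MAJORITY)
    if len(minority_idx) < 2:
        raise ValueError(
            f"minority class too small to model (n_min={len(minority_idx)}; need >= 2)"
        )
    return ClassPartition(minority_idx, majority_idx)


def imbalance_ratio(partition: ClassPartition) -> float:
    """Minority share of the dataset as a percentage: 100 * n_min / N."""
    if partition.n_min <= 0 or partition.n_maj < 0:
        raise ValueError("counts must be positive")
    return 100.0 * partition.n_min / (partition.n_min + partition.n_maj)


# ---------------------------------------------------------------------------
# I/O


def _delimiter_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def encode_frame(raw: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Encode a raw (string-valued) frame into the numeric column layout."""
    out: dict[str, np.ndarray] = {}
    for col in schema.encoded_columns:
        var = schema.variable(col.source)
        raw_col = raw[col.source]
        if col.kind == "continuous":
            out[col.name] = pd.to_numeric(raw_col).to_numpy(dtype=float)
        else:
            values = raw_col.astype(str).to_numpy()
            known = np.isin(values, list(var.categories))
            if not known.all():
                bad = values[~known][0]
                row = int(np.flatnonzero(~known)[0])
                raise ValueError(
                    f"unknown category {bad!r} in column {var.name!r} (row {row})"
                )
            out[col.name] = (values == col.category).astype(float)
    return pd.DataFrame(out, columns=schema.encoded_names)


def decode_frame(encoded: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Invert :func:`encode_frame` back to original (string-valued) columns."""
    out: dict[str, object] = {}
    for var in schema.variables:
        if var.vtype == "continuous":
            out[var.name] = encoded[var.name].to_numpy()
        elif var.vtype == "binary":
            vals = encoded[var.name].to_numpy()
            out[var.name] = np.where(vals >= 0.5, var.categories[1], var.categories[0])
        else:
            cols = [f"{var.name}={c}" for c in var.categories]
            hot = encoded[cols].to_numpy()
            picks = hot.argmax(axis=1)
            out[var.name] = np.asarray(var.categories)[picks]
    return pd.DataFrame(out, columns=[v.name for v in schema.variables])


def load_dataset(
    path: str | Path,
    schema: FeatureSchema,
    *,
    drop_missing: bool = False,
) -> LabeledDataset:
    """Load a delimited text file (CSV, or TSV by extension) against a schema.

    Missing cells are an error naming the offending row and column, unless
    ``drop_missing`` is set, in which case incomplete rows are removed and the
    count is logged. Label values must be one of the two declared classes.
    """
    raw = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    needed = [v.name for v in schema.variables] + [schema.label]
    missing_cols = [c for c in needed if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"file {path} lacks columns {missing_cols}")
    raw = raw[needed]

    na_mask = raw.isna()
    if na_mask.to_numpy().any():
        if drop_missing:
            n_before = len(raw)
            raw = raw.dropna().reset_index(drop=True)
            logger.info(
                "dropped %d rows with missing values from %s",
                n_before - len(raw),
                path,
            )
        else:
            rows, cols = np.nonzero(na_mask.to_numpy())
            raise ValueError(
                f"missing value at row {rows[0]}, column {raw.columns[cols[0]]!r} "
                f"(pass drop_missing=True to drop incomplete rows)"
            )

    label_raw = raw[schema.label].astype(str).to_numpy()
    uniques = set(np.unique(label_raw))
    extra = uniques - {schema.minority_value, schema.majority_value}
    if extra:
        raise ValueError(
            f"label column {schema.label!r} has values outside the declared "
            f"classes: {sorted(extra)}"
        )
    labels = (label_raw == schema.minority_value).astype(np.int8)
    features = encode_frame(raw, schema)
    return LabeledDataset(features, labels, schema)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset back to delimited text in the original column layout.

    Round-trips with :func:`load_dataset` on values and schema.
    """
    schema = dataset.schema
    frame = decode_frame(dataset.features, schema)
    frame[schema.label] = np.where(
        dataset.labels == MINORITY, schema.minority_value, schema.majority_value
    )
    frame.to_csv(path, sep=_delimiter_for(path), index=False)
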