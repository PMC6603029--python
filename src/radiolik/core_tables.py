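"""Data model and CSV I/O for radiomic feature tables.

A cohort is represented as a :class:`FeatureTable`: a samples x features
numeric matrix with unique sample ids, optional binary malignancy labels
(0 = benign, 1 = malignant), and per-feature class metadata.  Feature
classes follow the PyRadiomics convention of encoding the class in the
column-name prefix (``shape_Volume``, ``glcm_SumEntropy``, ...); the six
texture classes plus shape give seven classes in total, and the
shape/texture dichotomy used for signature construction derives directly
from the class (shape iff class is ``shape``).

CSV is the single canonical exchange format.  Values are serialized at
full ``repr`` precision so that a write/read round-trip is bit-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CLASSES",
    "FeatureMeta",
    "FeatureTable",
    "infer_feature_class",
    "read_feature_table",
    "write_feature_table",
]

#: The seven radiomic feature classes (shape + six gray-level texture
#: families: first-order statistics, co-occurrence, dependence,
#: size-zone, run-length and tone-difference matrices).
FEATURE_CLASSES = (
    "shape",
    "firstorder",
    "glcm",
    "gldm",
    "glszm",
    "glrlm",
    "ngtdm",
)

FeatureClass = Literal[
    "shape", "firstorder", "glcm", "gldm", "glszm", "glrlm", "ngtdm"
]


def infer_feature_class(name: str) -> str:
    """Infer a feature's class from its column-name prefix.

    The prefix is the (case-insensitive) substring before the first
    underscore, e.g. ``"glszm_LargeAreaLowGrayLevelEmphasis"`` -> ``"glszm"``.
    Unknown prefixes fall back to ``"firstorder"`` (a texture class) with
    a warning, so that tables with unconventional names still load.
    """
    prefix = name.split("_", 1)[0].lower()
    if prefix in FEATURE_CLASSES:
        return prefix
    warnings.warn(
        f"feature {name!r}: unknown class prefix {prefix!r}; "
        "defaulting to 'firstorder'",
        stacklevel=2,
    )
    return "firstorder"


@dataclass(frozen=True)
class FeatureMeta:
    """Name and class metadata for one radiomic feature."""

    name: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature class {self.feature_class!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )

    @property
    def kind(self) -> str:
        """``"shape"`` or ``"texture"`` — shape iff the class is shape."""
        return "shape" if self.feature_class == "shape" else "texture"

    @classmethod
    def from_name(cls, name: str) -> "FeatureMeta":
        return cls(name=name, feature_class=infer_feature_class(name))


@dataclass
class FeatureTable:
    """Samples x features radiomic data with optional binary labels.

    Parameters
    ----------
    sample_ids
        Unique per-row identifiers.
    values
        Numeric matrix of shape ``(n_samples, n_features)``; all entries
        must be finite.
    features
        One :class:`FeatureMeta` per column.
    labels
        Optional 0/1 vector (0 = benign, 1 = malignant), one per sample.
    """

    sample_ids: list[str]
    values: np.ndarray
    features: list[FeatureMeta]
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.features) != p:
            raise ValueError(
                f"{len(self.features)} feature metas for {p} matrix columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        names = [m.name for m in self.features]
        if len(set(names)) != p:
            raise ValueError("duplicate feature names")
        if self.values.size and not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {names[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal number of samples")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.features]

    def column(self, name: str) -> np.ndarray:
        """Return one feature column by name."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df


def read_feature_table(
    path: str | Path, label_column: str | None = None
) -> FeatureTable:
    """Read a feature table from CSV.

    The first column holds sample ids; ``label_column``, when given,
    names the 0/1 label column and every remaining column is a feature.
    Rows with non-numeric feature cells are rejected with an error that
    names the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 1:
        raise ValueError(f"{path}: empty CSV")
    id_col = df.columns[0]
    sample_ids = df[id_col].astype(str).tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids")

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(
                f"{path}: label column {label_column!r} not found "
                f"(columns: {list(df.columns)})"
            )
        raw = df[label_column]
        lab = pd.to_numeric(raw, errors="coerce")
        if lab.isna().any() or not lab.isin([0, 1]).all():
            bad = raw[~lab.isin([0, 1])].iloc[0]
            raise ValueError(
                f"{path}: label column {label_column!r} contains "
                f"non-binary value {bad!r}"
            )
        labels = lab.to_numpy(dtype=int)

    feat_cols = [c for c in df.columns[1:] if c != label_column]
    numeric = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    if feat_cols and numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = sample_ids[int(numeric[col].isna().idxmax())]
        raise ValueError(
            f"{path}: unparsable numeric cell at row {row!r}, column {col!r}"
        )
    values = numeric.to_numpy(dtype=float).reshape(len(sample_ids), len(feat_cols))
    features = [FeatureMeta.from_name(c) for c in feat_cols]
    return FeatureTable(
        sample_ids=sample_ids, values=values, features=features, labels=labels
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table to CSV, readable back by :func:`read_feature_table`.

    Values are written with ``repr`` so the round-trip is lossless.
    """
    path = Path(path)
    header = ["sample_id"]
    if table.labels is not None:
        header.append("label")
    header.extend(table.feature_names)
    lines = [",".join(header)]
    for i, sid in enumerate(table.sample_ids):
        row = [sid]
        if table.labels is not None:
            row.append(str(int(table.labels[i])))
        row.extend(repr(float(v)) for v in table.values[i])
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def subset_features(table: FeatureTable, names: Sequence[str]) -> FeatureTable:
    """Return a new table restricted to the named feature columns."""
    idx = [table.feature_names.index(n) for n in names]
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        values=table.values[:, idx],
        features=[table.features[j] for j in idx],
        labels=None if table.labels is None else table.labels.copy(),
    )
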