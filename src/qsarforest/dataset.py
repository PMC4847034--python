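"""Descriptor tables, activity labels and the preprocessing they undergo.

A QSAR data set is a dense table of real-valued molecular descriptors
(e.g. the ~777 descriptors Mold2 computes from a 2D structure) with one
row per chemical, optionally paired with a binary activity label
(1 = binder, 0 = non-binder).  Before model fitting, descriptors that are
constant across the training chemicals are removed and the survivors are
min-max scaled to [0, 1].  Scaling parameters fitted on a training set are
frozen and re-applied to later chemicals; values of new chemicals falling
outside the training range are mapped linearly (no clipping), which is
harmless for threshold-based tree models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScalingState",
    "DescriptorMatrix",
    "ActivityLabels",
    "Dataset",
    "ScalingParams",
    "load_dataset",
    "write_dataset",
    "remove_constant_descriptors",
    "fit_minmax_scaling",
    "apply_minmax_scaling",
    "save_scaling_params",
    "load_scaling_params",
]


class ScalingState(str, Enum):
    RAW = "raw"
    SCALED = "scaled"


#: per-descriptor (min, max) pairs, keyed by descriptor name
ScalingParams = dict


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for n in names:
        if n in seen:
            dups.append(n)
        seen[n] = seen.get(n, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class DescriptorMatrix:
    """Chemicals x descriptors table with explicit scaling state."""

    chemical_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    scaling_state: ScalingState = ScalingState.RAW
    scaling_params: ScalingParams | None = None

    def __post_init__(self) -> None:
        self.chemical_ids = [str(c) for c in self.chemical_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if n != len(self.chemical_ids):
            raise ValueError(
                f"{len(self.chemical_ids)} chemical ids but {n} rows of values"
            )
        if d != len(self.descriptor_names):
            raise ValueError(
                f"{len(self.descriptor_names)} descriptor names but {d} columns"
            )
        _check_unique(self.chemical_ids, "chemical ids")
        _check_unique(self.descriptor_names, "descriptor names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "missing or non-finite descriptor value at chemical "
                f"{self.chemical_ids[bad[0]]!r}, descriptor "
                f"{self.descriptor_names[bad[1]]!r}"
            )
        if self.scaling_state is ScalingState.SCALED:
            if self.scaling_params is None:
                raise ValueError("scaled matrix must record its scaling parameters")
            for name, (lo, hi) in self.scaling_params.items():
                if not lo < hi:
                    raise ValueError(
                        f"scaling parameters for {name!r} violate min < max"
                    )

    @property
    def n_chemicals(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"descriptor {name!r} not present") from None
        return self.values[:, j]

    def column_index(self, name: str) -> int:
        try:
            return self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"descriptor {name!r} not present") from None

    def take_rows(self, idx: Sequence[int]) -> "DescriptorMatrix":
        idx = np.asarray(idx, dtype=int)
        return DescriptorMatrix(
            [self.chemical_ids[i] for i in idx],
            list(self.descriptor_names),
            self.values[idx],
            self.scaling_state,
            self.scaling_params,
        )

    def take_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        cols = [self.column_index(n) for n in names]
        params = None
        if self.scaling_params is not None:
            params = {n: self.scaling_params[n] for n in names if n in self.scaling_params}
        return DescriptorMatrix(
            list(self.chemical_ids),
            [self.descriptor_names[j] for j in cols],
            self.values[:, cols],
            self.scaling_state,
            params,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.chemical_ids, columns=self.descriptor_names
        )


@dataclass
class ActivityLabels:
    """Binary binder (1) / non-binder (0) annotation per chemical."""

    chemical_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.chemical_ids = [str(c) for c in self.chemical_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.chemical_ids):
            raise ValueError("labels must align one-to-one with chemical ids")
        _check_unique(self.chemical_ids, "chemical ids")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0 or 1, found {sorted(bad)}")

    @property
    def n_binders(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonbinders(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class Dataset:
    """A descriptor matrix optionally paired with activity labels."""

    descriptors: DescriptorMatrix
    labels: ActivityLabels | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            if self.labels.chemical_ids != self.descriptors.chemical_ids:
                raise ValueError(
                    "labels and descriptors must list identical chemical ids "
                    "in identical order"
                )

    @property
    def n_chemicals(self) -> int:
        return self.descriptors.n_chemicals

    def take_rows(self, idx: Sequence[int]) -> "Dataset":
        labels = None
        if self.labels is not None:
            idx_arr = np.asarray(idx, dtype=int)
            labels = ActivityLabels(
                [self.labels.chemical_ids[i] for i in idx_arr],
                self.labels.labels[idx_arr],
            )
        return Dataset(self.descriptors.take_rows(idx), labels)

    def with_labels(self, labels: np.ndarray) -> "Dataset":
        return Dataset(
            self.descriptors,
            ActivityLabels(list(self.descriptors.chemical_ids), labels),
        )


def load_dataset(
    path: str | Path,
    label_column: str | None = None,
    id_column: str | None = None,
    sep: str | None = None,
) -> Dataset:
    """Read a CSV/TSV descriptor table into a :class:`Dataset`.

    The first column (or ``id_column``) holds chemical identifiers; every
    remaining numeric column is a descriptor, except ``label_column`` which,
    when given, must contain 0/1 activity calls.  Missing values are
    rejected — the descriptor software emits complete tables and silent
    imputation would be an unstated modelling step.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={0: str} if id_column is None else None,
        float_precision="round_trip",
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus descriptor columns")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise ValueError(f"{path}: id column {id_column!r} not found")
    ids = df[id_column].astype(str).tolist()
    dup = df[id_column][df[id_column].duplicated()].astype(str).unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate chemical ids: {dup}")

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found")
        raw = df[label_column]
        numeric = pd.to_numeric(raw, errors="coerce")
        if numeric.isna().any() or not set(numeric.unique()) <= {0, 1}:
            bad = raw[~numeric.isin([0, 1])].unique().tolist()
            raise ValueError(
                f"{path}: label column {label_column!r} must contain only 0/1, "
                f"found {bad}"
            )
        labels = ActivityLabels(ids, numeric.to_numpy())

    desc_cols = [c for c in df.columns if c not in (id_column, label_column)]
    values = np.empty((len(df), len(desc_cols)), dtype=float)
    for j, c in enumerate(desc_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            i = int(col.index[col.isna()][0])
            raise ValueError(
                f"{path}: non-numeric or missing descriptor value at row "
                f"{i} (chemical {ids[i]!r}), column {c!r}"
            )
        values[:, j] = col.to_numpy(dtype=float)

    matrix = DescriptorMatrix(ids, desc_cols, values)
    return Dataset(matrix, labels)


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    label_column: str = "activity",
    id_column: str = "chemical_id",
    sep: str | None = None,
) -> None:
    """Write a dataset back to CSV/TSV in the dialect ``load_dataset`` reads.

    Floats are written with ``repr`` precision so a round trip reproduces
    values bit for bit.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = dataset.descriptors.to_frame().reset_index(names=id_column)
    if dataset.labels is not None:
        df.insert(1, label_column, dataset.labels.labels)
    # %.17g round-trips any IEEE double exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def remove_constant_descriptors(
    d: DescriptorMatrix,
) -> tuple[DescriptorMatrix, list[str]]:
    """Drop descriptors whose value is identical across all chemicals.

    Returns the reduced matrix (surviving column order preserved) and the
    names of the removed descriptors.
    """
    if d.n_chemicals < 1:
        raise ValueError("matrix must contain at least one chemical")
    constant = np.all(d.values == d.values[0:1, :], axis=0)
    removed = [n for n, c in zip(d.descriptor_names, constant) if c]
    keep = [n for n, c in zip(d.descriptor_names, constant) if not c]
    if not keep:
        raise ValueError("no variable descriptors remain")
    return d.take_columns(keep), removed


def fit_minmax_scaling(d: DescriptorMatrix) -> ScalingParams:
    """Per-descriptor (min, max) over the chemicals of ``d``.

    Constant descriptors must have been removed first; a constant column has
    min == max and cannot be scaled.
    """
    lo = d.values.min(axis=0)
    hi = d.values.max(axis=0)
    flat = np.nonzero(~(lo < hi))[0]
    if flat.size:
        raise ValueError(
            f"constant descriptor {d.descriptor_names[flat[0]]!r} cannot be "
            "min-max scaled; remove constant descriptors first"
        )
    return {n: (float(l), float(h)) for n, l, h in zip(d.descriptor_names, lo, hi)}


def apply_minmax_scaling(
    d: DescriptorMatrix, params: ScalingParams
) -> DescriptorMatrix:
    """Map each value v to (v - min) / (max - min) with frozen parameters.

    Chemicals outside the fitted range map outside [0, 1]; they are not
    clipped.
    """
    missing = [n for n in d.descriptor_names if n not in params]
    if missing:
        raise ValueError(f"no scaling parameters for descriptors: {missing[:5]}")
    lo = np.array([params[n][0] for n in d.descriptor_names])
    hi = np.array([params[n][1] for n in d.descriptor_names])
    scaled = (d.values - lo) / (hi - lo)
    return DescriptorMatrix(
        list(d.chemical_ids),
        list(d.descriptor_names),
        scaled,
        ScalingState.SCALED,
        {n: params[n] for n in d.descriptor_names},
    )


def save_scaling_params(params: ScalingParams, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({n: [lo, hi] for n, (lo, hi) in params.items()}, indent=1)
    )


def load_scaling_params(path: str | Path) -> ScalingParams:
    raw = json.loads(Path(path).read_text())
    return {n: (float(lo), float(hi)) for n, (lo, hi) in raw.items()}
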