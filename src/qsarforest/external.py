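"""The published rat-AFP external validation records.

The original model was trained on 125 assayed chemicals and then
challenged with 22 literature-curated chemicals whose experimental AFP
binding calls and model predictions were published alongside the model.
Those 22 records ship with the package so the external-validation
performance can be recomputed from first principles (count the confusion
table, apply the five metrics) without the undistributed descriptor
matrix.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import ConfusionCounts, MetricReport, compute_metrics, confusion

__all__ = [
    "load_external_validation_records",
    "external_validation_confusion",
    "external_validation_metrics",
]


def load_external_validation_records() -> pd.DataFrame:
    """The 22 external-set chemicals with experimental and predicted calls.

    Columns: chemical_name, experiment (1 = assayed binder), prediction
    (1 = predicted binder).
    """
    ref = resources.files("qsarforest.data") / "afp_external_validation.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def external_validation_confusion() -> ConfusionCounts:
    df = load_external_validation_records()
    return confusion(df["experiment"].to_numpy(), df["prediction"].to_numpy())


def external_validation_metrics() -> MetricReport:
    """The five external-validation metrics recomputed from the records."""
    return compute_metrics(external_validation_confusion())
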