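"""Model validation: repeated k-fold CV, permutation nulls, confidence
stratification and informative-descriptor identification.

The canonical protocol for the consensus model is 1000 iterations of
5-fold cross-validation.  In each iteration the chemicals are randomly
divided into five (near-)equal portions; each portion is predicted once
by a forest trained on the other four, the five fold-level metric reports
are averaged into one per-iteration report, and the run-level summary is
the mean +- standard deviation over iterations.

The permutation (y-scrambling) test repeats the same CV after randomly
shuffling the activity labels while leaving the descriptors untouched,
giving the chance-performance null against which the real CV results are
compared.

Because every fitted forest records which descriptors its trees used,
the same machinery yields descriptor importance: a descriptor used by
more real-CV models than the top-5% frequency of the permutation
background is deemed informative at the 5% level.

Preprocessing (constant-descriptor removal and min-max scaling) is refit
on each training split by default so no information leaks from the held
out fold; a ``global`` mode preprocesses once on the full data instead,
reproducing the original single-pass order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    Dataset,
    apply_minmax_scaling,
    fit_minmax_scaling,
    remove_constant_descriptors,
)
from .forest import DecisionForest, ForestFitConfig, fit_forest, forest_predict_proba
from .metrics import METRIC_NAMES, MetricReport, compute_metrics, confusion

__all__ = [
    "CVConfig",
    "ValidationRun",
    "ConfidenceProfile",
    "ImportanceTable",
    "make_folds",
    "cross_validate",
    "permutation_test",
    "empirical_p_value",
    "confidence_profile",
    "identify_informative_descriptors",
]

N_CONFIDENCE_BINS = 20


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters.

    ``preprocess`` is ``"per-split"`` (leakage-free refit of cleanup and
    scaling on each training split, the default) or ``"global"``
    (preprocess once on the full data before splitting).
    """

    n_folds: int = 5
    n_repeats: int = 1000
    seed: int = 0
    stratified: bool = False
    preprocess: str = "per-split"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        if self.preprocess not in ("per-split", "global"):
            raise ValueError("preprocess must be 'per-split' or 'global'")


@dataclass
class ValidationRun:
    """Everything a repeated-CV run produced.

    fold_metrics: one row per (repeat, fold) with the five metrics.
    repeat_metrics: fold metrics averaged within each repeat.
    predictions: pooled per-chemical predictions (each chemical exactly
        once per repeat) with p, call, confidence and the actual label.
    model_usage: the used-descriptor set of every fitted forest.
    """

    fold_metrics: pd.DataFrame
    repeat_metrics: pd.DataFrame
    predictions: pd.DataFrame
    model_usage: list

    def summary(self) -> pd.DataFrame:
        """Mean +- standard deviation of each metric over repeats."""
        rows = []
        for m in METRIC_NAMES:
            vals = self.repeat_metrics[m].to_numpy(dtype=float)
            rows.append(
                {
                    "metric": m,
                    "mean": float(np.nanmean(vals)),
                    "std": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ConfidenceProfile:
    """Pooled predictions stratified into 20 even confidence bins."""

    table: pd.DataFrame  # bin, lo, hi, n_predictions, n_correct, n_incorrect, accuracy


@dataclass
class ImportanceTable:
    """Per-descriptor model-usage frequencies with the permutation cutoff."""

    table: pd.DataFrame  # descriptor, cv_models, perm_models, informative
    threshold_frequency: int
    alpha: float

    @property
    def informative_descriptors(self) -> list[str]:
        t = self.table
        return t.loc[t["informative"], "descriptor"].tolist()


def make_folds(
    n_chemicals: int,
    n_folds: int,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
    stratified: bool = False,
) -> list[np.ndarray]:
    """Random partition into ``n_folds`` index sets of size within 1.

    With ``stratified=True`` each class is dealt round-robin so fold class
    balances match the data's.
    """
    if n_chemicals < n_folds:
        raise ValueError(
            f"cannot split {n_chemicals} chemicals into {n_folds} folds"
        )
    if stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        start = 0
        for cls in (1, 0):
            idx = np.nonzero(labels == cls)[0]
            idx = rng.permutation(idx)
            for k, i in enumerate(idx):
                folds[(start + k) % n_folds].append(int(i))
            start += len(idx)
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n_chemicals)
    base, extra = divmod(n_chemicals, n_folds)
    out = []
    pos = 0
    for k in range(n_folds):
        size = base + (1 if k < extra else 0)
        out.append(np.sort(perm[pos : pos + size]))
        pos += size
    return out


def _preprocess_split(train: Dataset, test: Dataset) -> tuple[Dataset, Dataset]:
    reduced, _ = remove_constant_descriptors(train.descriptors)
    params = fit_minmax_scaling(reduced)
    train_scaled = Dataset(apply_minmax_scaling(reduced, params), train.labels)
    test_reduced = test.descriptors.take_columns(reduced.descriptor_names)
    test_scaled = Dataset(apply_minmax_scaling(test_reduced, params), test.labels)
    return train_scaled, test_scaled


def _global_preprocess(data: Dataset) -> Dataset:
    reduced, _ = remove_constant_descriptors(data.descriptors)
    params = fit_minmax_scaling(reduced)
    return Dataset(apply_minmax_scaling(reduced, params), data.labels)


def _average_fold_reports(reports: Sequence[MetricReport]) -> dict:
    out = {}
    for m in METRIC_NAMES:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        out[m] = float(np.mean(vals)) if vals else np.nan
    return out


def cross_validate(
    data: Dataset,
    forest_config: ForestFitConfig = ForestFitConfig(),
    cv_config: CVConfig = CVConfig(),
) -> ValidationRun:
    """Repeated k-fold cross-validation of the consensus forest.

    Within each repeat every chemical is predicted exactly once, by the
    forest whose training folds excluded it.  Deterministic for a fixed
    ``cv_config.seed``.
    """
    if data.labels is None:
        raise ValueError("cross_validate requires labeled data")
    rng = np.random.default_rng(np.random.SeedSequence(cv_config.seed))
    labels = data.labels.labels
    working = _global_preprocess(data) if cv_config.preprocess == "global" else data

    fold_rows, repeat_rows, pred_rows = [], [], []
    usage: list[frozenset] = []
    for r in range(cv_config.n_repeats):
        folds = make_folds(
            data.n_chemicals, cv_config.n_folds, rng, labels, cv_config.stratified
        )
        reports = []
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(data.n_chemicals), test_idx)
            train_ds = working.take_rows(train_idx)
            test_ds = working.take_rows(test_idx)
            if cv_config.preprocess == "per-split":
                try:
                    train_ds, test_ds = _preprocess_split(train_ds, test_ds)
                except ValueError as e:
                    raise ValueError(f"repeat {r}, fold {k}: {e}") from e
            try:
                forest = fit_forest(train_ds, forest_config)
            except ValueError as e:
                raise ValueError(f"repeat {r}, fold {k}: {e}") from e
            usage.append(forest.used_descriptors)
            p = forest_predict_proba(forest, test_ds.descriptors)
            calls = (p >= 0.5).astype(int)
            actual = test_ds.labels.labels
            report = compute_metrics(confusion(actual, calls))
            reports.append(report)
            fold_rows.append({"repeat": r, "fold": k, **report.as_dict()})
            for cid, pi, ci, ai in zip(test_ds.descriptors.chemical_ids, p, calls, actual):
                pred_rows.append(
                    {
                        "chemical_id": cid,
                        "repeat": r,
                        "fold": k,
                        "p": float(pi),
                        "call": int(ci),
                        "confidence": abs(float(pi) - 0.5) / 0.5,
                        "actual": int(ai),
                    }
                )
        repeat_rows.append({"repeat": r, **_average_fold_reports(reports)})

    return ValidationRun(
        pd.DataFrame(fold_rows),
        pd.DataFrame(repeat_rows),
        pd.DataFrame(pred_rows),
        usage,
    )


def permutation_test(
    data: Dataset,
    forest_config: ForestFitConfig = ForestFitConfig(),
    cv_config: CVConfig = CVConfig(n_repeats=1),
    n_permutations: int = 1000,
) -> tuple[pd.DataFrame, list]:
    """Label-permutation (y-scrambling) null for the CV protocol.

    Each permutation shuffles the activity labels (class counts are
    preserved), runs one full k-fold CV on the scrambled data, and records
    the fold-averaged metrics.  Returns the per-permutation metric table
    and the used-descriptor set of every fitted model.
    """
    if data.labels is None:
        raise ValueError("permutation_test requires labeled data")
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    ss = np.random.SeedSequence(cv_config.seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = shuffle_rng.integers(0, 2**31 - 1, size=n_permutations)

    rows = []
    usage: list = []
    for i in range(n_permutations):
        shuffled = shuffle_rng.permutation(data.labels.labels)
        perm_data = data.with_labels(shuffled)
        run = cross_validate(
            perm_data,
            forest_config,
            CVConfig(
                n_folds=cv_config.n_folds,
                n_repeats=1,
                seed=int(child_seeds[i]),
                stratified=cv_config.stratified,
                preprocess=cv_config.preprocess,
            ),
        )
        rec = run.repeat_metrics.iloc[0].to_dict()
        rec["permutation"] = i
        del rec["repeat"]
        rows.append(rec)
        usage.extend(run.model_usage)
    return pd.DataFrame(rows), usage


def empirical_p_value(null_values: Sequence[float], observed: float) -> float:
    """(1 + #{null >= observed}) / (1 + n): add-one rule avoids p = 0."""
    null_arr = np.asarray(null_values, dtype=float)
    return (1.0 + int(np.sum(null_arr >= observed))) / (1.0 + len(null_arr))


def confidence_profile(run: ValidationRun) -> ConfidenceProfile:
    """Pooled predictions placed into 20 even confidence bins.

    Bins are [i/20, (i+1)/20) with the last bin closed at 1.0.  Per-bin
    accuracy is correct/total, absent (NaN) for empty bins.
    """
    conf = run.predictions["confidence"].to_numpy(dtype=float)
    correct = (
        run.predictions["call"].to_numpy() == run.predictions["actual"].to_numpy()
    )
    bins = np.minimum((conf * N_CONFIDENCE_BINS).astype(int), N_CONFIDENCE_BINS - 1)
    rows = []
    for b in range(N_CONFIDENCE_BINS):
        mask = bins == b
        n = int(mask.sum())
        n_ok = int(correct[mask].sum())
        rows.append(
            {
                "bin": b + 1,
                "confidence_lo": b / N_CONFIDENCE_BINS,
                "confidence_hi": (b + 1) / N_CONFIDENCE_BINS,
                "n_predictions": n,
                "n_correct": n_ok,
                "n_incorrect": n - n_ok,
                "accuracy": (n_ok / n) if n else np.nan,
            }
        )
    return ConfidenceProfile(pd.DataFrame(rows))


def _usage_frequencies(usage: Iterable[frozenset], universe: list[str]) -> np.ndarray:
    index = {n: j for j, n in enumerate(universe)}
    freq = np.zeros(len(universe), dtype=int)
    for model in usage:
        for name in model:
            freq[index[name]] += 1
    return freq


def identify_informative_descriptors(
    cv_usage: Sequence[frozenset],
    perm_usage: Sequence[frozenset],
    alpha: float = 0.05,
    descriptor_names: Sequence[str] | None = None,
) -> ImportanceTable:
    """Descriptors used by more CV models than the permutation background.

    A descriptor counts once per model it appears in.  The cutoff is the
    smallest frequency f such that at most ``alpha`` of the permutation
    frequencies strictly exceed f; a descriptor is informative when its
    CV frequency strictly exceeds the cutoff.
    """
    if not cv_usage or not perm_usage:
        raise ValueError("both usage collections must be non-empty")
    seen = set()
    for model in list(cv_usage) + list(perm_usage):
        seen |= set(model)
    if descriptor_names is None:
        universe = sorted(seen)
    else:
        universe = list(descriptor_names)
        stray = seen - set(universe)
        if stray:
            raise ValueError(
                f"usage names descriptors outside the stated universe: "
                f"{sorted(stray)[:5]}"
            )
    cv_freq = _usage_frequencies(cv_usage, universe)
    perm_freq = _usage_frequencies(perm_usage, universe)

    d = len(universe)
    m = int(np.floor(alpha * d))  # how many may strictly exceed the cutoff
    threshold = int(np.sort(perm_freq)[d - m - 1])

    table = pd.DataFrame(
        {
            "descriptor": universe,
            "cv_models": cv_freq,
            "perm_models": perm_freq,
            "informative": cv_freq > threshold,
        }
    )
    return ImportanceTable(table, threshold, alpha)
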