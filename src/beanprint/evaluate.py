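"""Balanced split construction, confusion-matrix metrics, and aggregation.

The resampling design mirrors a three-way protocol used for spectral
classification with replicated scans:

1. **Test set** — whole samples are drawn at random per class and *all* of
   their replicate spectra go to the test set, so a bean bag never straddles
   the test boundary. Test sets are intentionally unbalanced.
2. **Training / cross-validation** — from the remaining spectra, the same
   number of spectra per class (the minimum available across classes) is
   drawn and split 80/20 (nearest integer on the training share), giving
   balanced per-class training and cross-validation counts.
3. The whole construction is repeated for several "interactions"
   (independent balanced databases, three by default) and metrics are
   reported as mean ± sample standard deviation across interactions.

Sensitivity and specificity follow the one-vs-rest multi-class convention:
for class c, TP is the diagonal entry, FN the off-diagonal row sum, FP the
off-diagonal column sum, and TN everything else; Se = TP/(TP+FN)·100 and
Sp = TN/(TN+FP)·100. For a two-class task with a designated positive class
these reduce to the familiar binary definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LabelScheme, SpectralDataset


class SplitError(ValueError):
    """Requested balanced design is infeasible for the given class counts."""


@dataclass
class SplitPlan:
    """Train/cv/test spectrum indices for one interaction."""

    interaction_id: int
    test_samples: list[str]
    train_idx: np.ndarray
    cv_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.cv_idx), set(self.test_idx)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise SplitError("train/cv/test index sets overlap")

    def counts(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.cv_idx), len(self.test_idx)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_balanced_splits(
    ds: SpectralDataset,
    scheme: LabelScheme,
    test_sample_counts: dict[str, int],
    n_interactions: int = 3,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> list[SplitPlan]:
    """Build ``n_interactions`` balanced train/cv/test plans.

    ``test_sample_counts`` gives, per class, how many whole samples (with all
    replicates) go to the test set. Indices refer to rows of ``ds`` restricted
    to samples covered by ``scheme`` — callers typically pass the dataset
    already subset with :func:`beanprint.dataset.subset_by_labels`.
    """
    labels = ds.meta["sample_id"].map(dict(scheme.mapping))
    if labels.isna().any():
        raise SplitError(
            "dataset contains samples outside the scheme; subset it first"
        )
    y = labels.to_numpy(dtype=object)
    sample_of = ds.meta["sample_id"].to_numpy(dtype=object)

    samples_by_class: dict[str, np.ndarray] = {}
    for c in scheme.classes:
        samples = pd.unique(sample_of[y == c])
        if len(samples) == 0:
            raise SplitError(f"class {c!r} has no samples")
        n_test = int(test_sample_counts.get(c, 0))
        if len(samples) - n_test < 2:
            raise SplitError(
                f"class {c!r} has {len(samples)} samples; cannot hold out "
                f"{n_test} for test and keep >= 2 for modelling"
            )
        samples_by_class[c] = samples

    root = np.random.SeedSequence(seed)
    plans: list[SplitPlan] = []
    for i, child in enumerate(root.spawn(n_interactions), start=1):
        rng = np.random.default_rng(child)
        test_samples: list[str] = []
        test_idx: list[int] = []
        remaining: dict[str, np.ndarray] = {}
        for c in scheme.classes:
            samples = samples_by_class[c]
            chosen = rng.choice(samples, size=int(test_sample_counts.get(c, 0)), replace=False)
            test_samples.extend(chosen.tolist())
            in_test = np.isin(sample_of, chosen)
            test_idx.extend(np.flatnonzero((y == c) & in_test).tolist())
            remaining[c] = np.flatnonzero((y == c) & ~in_test)
        n_balanced = min(len(v) for v in remaining.values())
        limiting = min(remaining, key=lambda c: len(remaining[c]))
        n_train = _round_half_up(train_fraction * n_balanced)
        n_cv = n_balanced - n_train
        if n_train < 1 or n_cv < 1:
            raise SplitError(
                f"class {limiting!r} leaves only {n_balanced} spectra outside "
                "test; cannot form both training and cross-validation sets"
            )
        train_idx: list[int] = []
        cv_idx: list[int] = []
        for c in scheme.classes:
            drawn = rng.permutation(remaining[c])[:n_balanced]
            train_idx.extend(drawn[:n_train].tolist())
            cv_idx.extend(drawn[n_train:].tolist())
        plans.append(
            SplitPlan(
                interaction_id=i,
                test_samples=sorted(test_samples),
                train_idx=np.sort(np.array(train_idx, dtype=int)),
                cv_idx=np.sort(np.array(cv_idx, dtype=int)),
                test_idx=np.sort(np.array(test_idx, dtype=int)),
                seed=seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# confusion-matrix metrics


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            bad = t if t not in index else p
            raise ValueError(f"label {bad!r} outside declared classes {classes}")
        cm[index[t], index[p]] += 1
    return cm


@dataclass
class ClassReport:
    """Confusion matrix plus accuracy/sensitivity/specificity percentages.

    ``sensitivity_pct``/``specificity_pct`` are per class (NaN for a class
    with no true spectra); ``macro_*`` average the finite entries. For binary
    tasks with a designated positive class, ``summary_*`` quote the positive
    class; otherwise they equal the macro means.
    """

    classes: list[str]
    confusion: np.ndarray
    accuracy_pct: float
    sensitivity_pct: np.ndarray
    specificity_pct: np.ndarray
    positive_class: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def macro_sensitivity_pct(self) -> float:
        return float(np.nanmean(self.sensitivity_pct))

    @property
    def macro_specificity_pct(self) -> float:
        return float(np.nanmean(self.specificity_pct))

    @property
    def summary_sensitivity_pct(self) -> float:
        if self.positive_class is not None:
            return float(self.sensitivity_pct[self.classes.index(self.positive_class)])
        return self.macro_sensitivity_pct

    @property
    def summary_specificity_pct(self) -> float:
        if self.positive_class is not None:
            return float(self.specificity_pct[self.classes.index(self.positive_class)])
        return self.macro_specificity_pct

    def correctly_classified(self) -> np.ndarray:
        return np.diag(self.confusion)

    def class_totals(self) -> np.ndarray:
        return self.confusion.sum(axis=1)


def sensitivity_specificity(
    confusion: np.ndarray,
    classes,
    positive_class: str | None = None,
) -> ClassReport:
    """Per-class Se/Sp and overall accuracy from a confusion matrix.

    One-vs-rest counts per class c: TP = confusion[c, c]; FN = off-diagonal
    row sum; FP = off-diagonal column sum; TN = total - TP - FN - FP.
    A class with an empty row has undefined sensitivity (NaN, warned,
    excluded from macro means).
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    classes = list(classes)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(tp + fn > 0, tp / (tp + fn) * 100.0, np.nan)
        sp = np.where(tn + fp > 0, tn / (tn + fp) * 100.0, np.nan)
    if np.any(np.isnan(se)):
        empty = [c for c, s in zip(classes, se) if np.isnan(s)]
        warnings.warn(
            f"class(es) {empty} have no true spectra; sensitivity undefined "
            "and excluded from macro means",
            stacklevel=2,
        )
    accuracy = float(np.trace(cm)) / total * 100.0 if total else float("nan")
    return ClassReport(
        classes=classes,
        confusion=cm.astype(int),
        accuracy_pct=accuracy,
        sensitivity_pct=se,
        specificity_pct=sp,
        positive_class=positive_class,
    )


def evaluate_predictions(
    y_true, y_pred, classes, positive_class: str | None = None
) -> ClassReport:
    """Confusion matrix + metrics in one call."""
    cm = confusion_matrix(y_true, y_pred, classes)
    return sensitivity_specificity(cm, classes, positive_class)


# ---------------------------------------------------------------------------
# aggregation across interactions


def aggregate_interactions(reports: list[ClassReport]) -> pd.DataFrame:
    """Mean ± sample sd of the summary metrics across interactions.

    Returns a tidy frame with columns ``metric, mean, sd, display`` where
    ``display`` renders one decimal, e.g. ``"98.5 ± 0.1"``.
    """
    if len(reports) < 2:
        raise ValueError("aggregation needs at least 2 interaction reports")
    ref = reports[0].classes
    for r in reports[1:]:
        if r.classes != ref:
            raise ValueError("reports have mismatched class sets")
    rows = []
    metrics = {
        "accuracy_pct": [r.accuracy_pct for r in reports],
        "sensitivity_pct": [r.summary_sensitivity_pct for r in reports],
        "specificity_pct": [r.summary_specificity_pct for r in reports],
    }
    for c in ref:
        i = ref.index(c)
        metrics[f"correct_{c}"] = [float(r.confusion[i, i]) for r in reports]
    for name, vals in metrics.items():
        vals = np.asarray(vals, dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "metric": name,
                "mean": mean,
                "sd": sd,
                "display": f"{mean:.1f} ± {sd:.1f}",
            }
        )
    return pd.DataFrame(rows)
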