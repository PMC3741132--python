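"""Validation protocols and accuracy bookkeeping.

Reports carry per-class accuracies (control %, AD %), their arithmetic mean,
the weighted (overall) mean, and the raw misclassification count, matching
the published report tables.  Protocols accept a zero-argument
``learner_factory`` returning a fresh estimator with ``fit(X, y)`` /
``predict(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort_model import GROUP_AD, GROUP_CONTROL

__all__ = [
    "ProtocolReport",
    "DivergenceReport",
    "kfold_protocol",
    "random_split_protocol",
    "two_subset_protocol",
    "distribution_equivalence",
]


@dataclass
class ProtocolReport:
    """Accuracy summary of one learner under one validation protocol."""

    learner: str
    control_pct: float
    alzheimer_pct: float
    a_mean: float
    w_mean: float
    error_count: int
    n_evaluated: int
    metadata: dict = field(default_factory=dict)
    status: str = "ok"

    @classmethod
    def from_predictions(
        cls,
        learner: str,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        metadata: dict | None = None,
    ) -> "ProtocolReport":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if len(y_true) != len(y_pred):
            raise ValueError("prediction/truth length mismatch")
        correct = y_true == y_pred

        def class_pct(group: str) -> float:
            mask = y_true == group
            if not mask.any():
                return float("nan")
            return 100.0 * float(correct[mask].mean())

        control = class_pct(GROUP_CONTROL)
        alzheimer = class_pct(GROUP_AD)
        errors = int((~correct).sum())
        return cls(
            learner=learner,
            control_pct=control,
            alzheimer_pct=alzheimer,
            a_mean=(control + alzheimer) / 2.0,
            w_mean=100.0 * (1.0 - errors / len(y_true)),
            error_count=errors,
            n_evaluated=len(y_true),
            metadata=metadata or {},
        )

    @classmethod
    def failed(cls, learner: str, reason: str) -> "ProtocolReport":
        return cls(
            learner=learner,
            control_pct=float("nan"), alzheimer_pct=float("nan"),
            a_mean=float("nan"), w_mean=float("nan"),
            error_count=-1, n_evaluated=0,
            metadata={"reason": reason}, status="failed",
        )

    def as_row(self) -> dict:
        return {
            "Learner": self.learner,
            "Control": round(self.control_pct, 2),
            "Alzheimer": round(self.alzheimer_pct, 2),
            "A_Mean": round(self.a_mean, 2),
            "W_Mean": round(self.w_mean, 2),
            "Error": self.error_count,
            "Status": self.status,
        }


def _as_array(x) -> np.ndarray:
    # DesignMatrix or raw array
    return np.asarray(getattr(x, "values", x), dtype=float)


def kfold_protocol(
    data,
    labels: np.ndarray,
    learner_factory: Callable[[], object],
    k: int = 10,
    seed: int = 0,
    learner_name: str = "learner",
) -> ProtocolReport:
    """Stratified K-fold cross validation; each record held out exactly once."""
    x = _as_array(data)
    y = np.asarray(labels, dtype=object)
    if k < 2:
        raise ValueError(f"K must be >= 2, got {k}")
    if k > len(y):
        raise ValueError(f"K={k} exceeds the number of records ({len(y)})")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"cannot stratify: a class has fewer than K={k} records")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    predictions = np.empty(len(y), dtype=object)
    tested = np.zeros(len(y), dtype=int)
    fold_errors = []
    for train_idx, test_idx in splitter.split(x, y):
        model = learner_factory()
        model.fit(x[train_idx], y[train_idx])
        pred = np.asarray(model.predict(x[test_idx]), dtype=object)
        predictions[test_idx] = pred
        tested[test_idx] += 1
        fold_errors.append(int((pred != y[test_idx]).sum()))
    assert np.all(tested == 1), "K-fold coverage violated"
    return ProtocolReport.from_predictions(
        learner_name, y, predictions,
        metadata={"protocol": "kfold", "K": k, "seed": seed, "fold_errors": fold_errors},
    )


def random_split_protocol(
    data,
    labels: np.ndarray,
    learner_factory: Callable[[], object],
    train_fraction: float = 0.5,
    seed: int = 0,
    learner_name: str = "learner",
) -> ProtocolReport:
    """Stratified train/test random split; report covers the test half only."""
    x = _as_array(data)
    y = np.asarray(labels, dtype=object)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=train_fraction, random_state=seed, stratify=y
    )
    if len(set(y[idx_train])) < 2 or len(set(y[idx_test])) < 2:
        raise ValueError("degenerate split: a half is missing a class")
    model = learner_factory()
    model.fit(x[idx_train], y[idx_train])
    pred = model.predict(x[idx_test])
    return ProtocolReport.from_predictions(
        learner_name, y[idx_test], pred,
        metadata={
            "protocol": "random_split",
            "train_fraction": train_fraction,
            "seed": seed,
            "n_train": len(idx_train),
            "n_test": len(idx_test),
        },
    )


def two_subset_protocol(
    data,
    labels: np.ndarray,
    learner_factory: Callable[[], object],
    subset_assignment: np.ndarray,
    learner_name: str = "learner",
) -> ProtocolReport:
    """Train on A / test on B and vice versa; errors summed over both phases.

    Each record is predicted exactly once (while in the held-out subset), so
    per-class accuracies pool over both testing phases.
    """
    x = _as_array(data)
    y = np.asarray(labels, dtype=object)
    assignment = np.asarray(subset_assignment, dtype=bool)
    if len(assignment) != len(y):
        raise ValueError("assignment length mismatch")
    if assignment.all() or (~assignment).all():
        raise ValueError("both subsets must be non-empty")
    predictions = np.empty(len(y), dtype=object)
    phase_errors = []
    for train_mask in (assignment, ~assignment):
        test_mask = ~train_mask
        model = learner_factory()
        model.fit(x[train_mask], y[train_mask])
        pred = np.asarray(model.predict(x[test_mask]), dtype=object)
        predictions[test_mask] = pred
        phase_errors.append(int((pred != y[test_mask]).sum()))
    return ProtocolReport.from_predictions(
        learner_name, y, predictions,
        metadata={
            "protocol": "two_subset",
            "n_a": int(assignment.sum()),
            "n_b": int((~assignment).sum()),
            "phase_errors": phase_errors,
        },
    )


@dataclass
class DivergenceReport:
    per_variable: pd.DataFrame
    max_divergence: float


def distribution_equivalence(
    data,
    partition: np.ndarray,
    column_names: list[str] | None = None,
) -> DivergenceReport:
    """Per-variable absolute mean (or frequency) difference between subsets."""
    x = _as_array(data)
    if column_names is None:
        column_names = list(getattr(data, "column_names", [f"var_{j}" for j in range(x.shape[1])]))
    partition = np.asarray(partition, dtype=bool)
    if len(partition) != x.shape[0]:
        raise ValueError("partition length mismatch")
    if partition.all() or (~partition).all():
        raise ValueError("both parts must be non-empty")
    mean_a = x[partition].mean(axis=0)
    mean_b = x[~partition].mean(axis=0)
    diff = np.abs(mean_a - mean_b)
    df = pd.DataFrame({
        "variable": column_names,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "abs_diff": diff,
    })
    return DivergenceReport(per_variable=df, max_divergence=float(diff.max()))
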