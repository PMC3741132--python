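"""Native KNN classifier and the pluggable battery of external learners.

The nearest-neighbour classifier here is the fitness engine of the
evolutionary selector and is written from scratch with fully specified tie
rules: equidistant neighbours resolve to the lower record index, tied class
votes to the earlier class label (control before AD).  External learners
(the WEKA-style battery) enter through thin scikit-learn adapters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort_model import GROUPS, DesignMatrix
from .validation import ProtocolReport

__all__ = [
    "ClassifierSpec",
    "PredictionResult",
    "KNNClassifier",
    "knn_fit_predict",
    "build_classifier",
    "available_adapters",
    "run_battery",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One battery entry: a nickname plus constructor parameters."""

    nickname: str
    params: tuple = ()
    source: str = "adapter"  # "native" | "adapter"

    @classmethod
    def make(cls, nickname: str, source: str = "adapter", **params) -> "ClassifierSpec":
        return cls(nickname=nickname, params=tuple(sorted(params.items())), source=source)

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


@dataclass
class PredictionResult:
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=object)
        self.y_pred = np.asarray(self.y_pred, dtype=object)
        if len(self.y_true) != len(self.y_pred):
            raise ValueError("length mismatch")

    @property
    def errors(self) -> int:
        return int((self.y_true != self.y_pred).sum())


class KNNClassifier:
    """Euclidean K-nearest-neighbour majority vote with deterministic ties.

    Distance ties resolve to the lower training-record index; vote ties to
    the earlier entry of ``class_order``.
    """

    def __init__(self, k: int = 1, class_order: Sequence[str] = GROUPS):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k
        self.class_order = tuple(class_order)
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=object)
        if x.ndim != 2 or len(x) == 0:
            raise ValueError("training data must be a non-empty 2-D array")
        if len(x) != len(y):
            raise ValueError("X/y length mismatch")
        if self.k > len(x):
            raise ValueError(f"k={self.k} exceeds training size {len(x)}")
        self._x = x
        self._y = y
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("classifier is not fitted")
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self._x.shape[1]:
            raise ValueError(
                f"column mismatch: test has {x.shape[1]} columns, train has {self._x.shape[1]}"
            )
        # squared distances suffice for ordering
        d2 = (
            np.sum(x**2, axis=1)[:, None]
            + np.sum(self._x**2, axis=1)[None, :]
            - 2.0 * x @ self._x.T
        )
        out = np.empty(len(x), dtype=object)
        rank = {label: i for i, label in enumerate(self.class_order)}
        for i in range(len(x)):
            # stable sort: equal distances keep ascending index order
            order = np.argsort(d2[i], kind="stable")[: self.k]
            votes: dict[str, int] = {}
            for j in order:
                votes[self._y[j]] = votes.get(self._y[j], 0) + 1
            out[i] = min(votes, key=lambda c: (-votes[c], rank.get(c, len(rank))))
        return out


def knn_fit_predict(train, train_labels, test, k: int = 1) -> PredictionResult:
    """Fit-and-predict convenience wrapper around :class:`KNNClassifier`.

    Accepts raw arrays or :class:`DesignMatrix` inputs; when both are design
    matrices their column sets must agree exactly.
    """
    if isinstance(train, DesignMatrix) and isinstance(test, DesignMatrix):
        if train.column_names != test.column_names:
            raise ValueError("train/test design matrices have different columns")
    x_train = np.asarray(getattr(train, "values", train), dtype=float)
    x_test = np.asarray(getattr(test, "values", test), dtype=float)
    model = KNNClassifier(k=k).fit(x_train, np.asarray(train_labels, dtype=object))
    pred = model.predict(x_test)
    true = getattr(test, "class_labels", None)
    if true is None:
        true = np.full(len(x_test), "", dtype=object)
    return PredictionResult(y_true=true, y_pred=pred)


def _adapter_registry() -> dict[str, Callable[[dict, int], object]]:
    return {
        "KNN": lambda p, s: KNNClassifier(**p),
        "IBk": lambda p, s: KNNClassifier(**p),  # same default as the WEKA IBk (k=1)
        "J48": lambda p, s: DecisionTreeClassifier(random_state=s, **p),
        "Logistic": lambda p, s: LogisticRegression(max_iter=2000, **p),
        "NaiveBayes": lambda p, s: GaussianNB(**p),
        "RandomForest": lambda p, s: RandomForestClassifier(random_state=s, **p),
        "MLP": lambda p, s: MLPClassifier(random_state=s, max_iter=800, **p),
        "AdaBoost": lambda p, s: AdaBoostClassifier(random_state=s, **p),
        "Bagging": lambda p, s: BaggingClassifier(random_state=s, **p),
        "SMO": lambda p, s: SVC(kernel="linear", random_state=s, **p),
        "LogitBoost": lambda p, s: GradientBoostingClassifier(random_state=s, **p),
    }


def available_adapters() -> list[str]:
    return sorted(_adapter_registry())


def build_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the learner behind a spec (seeded where stochastic)."""
    registry = _adapter_registry()
    if spec.nickname not in registry:
        raise KeyError(f"no adapter registered for {spec.nickname!r}")
    return registry[spec.nickname](spec.params_dict, seed)


def run_battery(
    specs: Sequence[ClassifierSpec],
    protocol: Callable[[Callable[[], object], str], ProtocolReport],
    seed: int = 0,
) -> list[ProtocolReport]:
    """Run every learner through a protocol; sort by descending weighted mean.

    ``protocol`` is called as ``protocol(learner_factory, nickname)``.  An
    adapter that is unavailable or crashes is recorded as a failed row and
    the run continues.
    """
    nicknames = [s.nickname for s in specs]
    if len(set(nicknames)) != len(nicknames):
        raise ValueError(f"duplicate nicknames in battery: {nicknames}")
    reports: list[ProtocolReport] = []
    for spec in specs:
        try:
            factory = lambda spec=spec: build_classifier(spec, seed=seed)
            factory()  # fail fast on construction errors
            reports.append(protocol(factory, spec.nickname))
        except Exception as exc:  # noqa: BLE001 - battery must keep going
            warnings.warn(f"learner {spec.nickname!r} failed: {exc}", stacklevel=2)
            reports.append(ProtocolReport.failed(spec.nickname, str(exc)))
    ok = [r for r in reports if r.status == "ok"]
    failed = [r for r in reports if r.status != "ok"]
    ok.sort(key=lambda r: (-r.w_mean, r.learner))
    return ok + failed
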