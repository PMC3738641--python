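"""Gaussian naive Bayes with leave-one-out cross-validation, confusion
matrices, and wrapper feature-subset selection.

Every sample is predicted by a classifier trained on all other samples
(leave-one-out, also called jackknife, cross-validation). The classifier
is naive Bayes with one Gaussian per feature and class, empirical class
priors, and a per-feature variance floor of 1e-9 * (training range)^2 to
guard against degenerate within-class variances; features enter on their
natural scales (percent for relative densities, cells/mm^2 for absolute
densities and TIC), since naive Bayes is scale-equivariant per feature.

The wrapper selector searches feature subsets by deterministic best-first
forward search scored by LOOCV accuracy: starting from the empty subset
(priors-only classifier), the best unexpanded subset is repeatedly
expanded by adding one feature, and the search stops after five
consecutive expansions that fail to improve the best accuracy found. Ties
prefer the smaller subset, then canonical feature order.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import GROUPS, MARKERS, logger

_VAR_FLOOR_FACTOR = 1e-9
_STALL_LIMIT = 5


# --------------------------------------------------------------------------
# Confusion matrices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-vs-predicted counts; rows = true class, columns = predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), non-negative integers

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_sums(self) -> dict[str, int]:
        return {l: int(s) for l, s in zip(self.labels, self.counts.sum(axis=1))}

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(tuple(d["labels"]), np.asarray(d["counts"], dtype=int))


@dataclass(frozen=True)
class Accuracy:
    correct: int
    total: int
    percent: int  # rounded to the nearest integer percent

    @property
    def fraction(self) -> float:
        return self.correct / self.total


def accuracy_from_confusion(cm: ConfusionMatrix) -> Accuracy:
    """Correct count and percentage (nearest integer) from a confusion
    matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    correct = cm.trace
    return Accuracy(correct, cm.total, int(round(100.0 * correct / cm.total)))


def compare_confusions(a: ConfusionMatrix, b: ConfusionMatrix) -> dict:
    """Per-class and total diagonal differences (a minus b)."""
    if a.labels != b.labels:
        raise ValueError("confusion matrices have different label orders")
    da = np.diag(a.counts)
    db = np.diag(b.counts)
    return {
        "per_class": {l: int(x - y) for l, x, y in zip(a.labels, da, db)},
        "total": int(da.sum() - db.sum()),
    }


# --------------------------------------------------------------------------
# Gaussian naive Bayes + LOOCV
# --------------------------------------------------------------------------


def _nb_predict(
    X_train: np.ndarray, y_train: np.ndarray, x: np.ndarray, labels: Sequence[str]
) -> str:
    """Predict one sample with Gaussian naive Bayes fitted on the training
    data. Per-feature variance floor: 1e-9 * (training range)^2."""
    span = X_train.max(axis=0) - X_train.min(axis=0)
    floor = _VAR_FLOOR_FACTOR * span**2 + 1e-12
    best_label, best_lp = None, -np.inf
    for label in labels:
        sel = y_train == label
        n = int(sel.sum())
        if n == 0:
            continue
        mu = X_train[sel].mean(axis=0)
        var = np.maximum(X_train[sel].var(axis=0), floor)
        lp = np.log(n / len(y_train))
        if X_train.shape[1]:
            lp += -0.5 * np.sum(np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
        if lp > best_lp:  # ties keep the first (canonical) label
            best_label, best_lp = label, lp
    assert best_label is not None
    return best_label


def nb_loocv(
    X: np.ndarray, y: Sequence[str], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Leave-one-out naive-Bayes confusion matrix.

    ``X`` is (n_samples, n_features); ``X`` may have zero columns, in which
    case classification is by training-fold priors alone. Each class needs
    at least two samples (one cannot be left out of a singleton class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if labels is None:
        labels = [g for g in GROUPS if g in set(y)]
        labels += sorted(set(y) - set(labels))
    labels = tuple(labels)
    counts_by_label = {l: int((y == l).sum()) for l in labels}
    small = [l for l, n in counts_by_label.items() if n < 2]
    if small or len(labels) < 2:
        raise ValueError(
            f"LOOCV requires >= 2 classes with >= 2 samples each; offending: {small}"
        )
    idx = {l: i for i, l in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    n = X.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = _nb_predict(X[mask], y[mask], X[i], labels)
        cm[idx[y[i]], idx[pred]] += 1
    return ConfusionMatrix(labels, cm)


def loocv_accuracy(X: np.ndarray, y: Sequence[str]) -> float:
    """LOOCV accuracy fraction (convenience wrapper for the wrapper
    search)."""
    cm = nb_loocv(X, y)
    return cm.trace / cm.total


# --------------------------------------------------------------------------
# Wrapper feature selection
# --------------------------------------------------------------------------


@dataclass
class WrapperResult:
    pool: tuple[str, ...]
    selected: tuple[str, ...]
    accuracy: float  # LOOCV accuracy fraction of the selected subset
    trace: list[dict] = field(default_factory=list)  # search log


def wrapper_select(
    X: np.ndarray,
    y: Sequence[str],
    feature_names: Sequence[str],
    stall_limit: int = _STALL_LIMIT,
) -> WrapperResult:
    """Best-first forward subset search scored by naive-Bayes LOOCV accuracy.

    Deterministic: subsets are keyed by canonical feature indices; among
    equal scores the smaller subset wins, then earlier canonical order.
    The search stops after ``stall_limit`` consecutive expansions that do
    not improve the best score, or when no unexpanded node remains.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = tuple(feature_names)
    if len(names) == 0:
        raise ValueError("feature pool must be non-empty")
    if X.shape[1] != len(names):
        raise ValueError("feature count mismatch")

    score_cache: dict[tuple[int, ...], float] = {}

    def score(subset: tuple[int, ...]) -> float:
        if subset not in score_cache:
            score_cache[subset] = loocv_accuracy(X[:, list(subset)], y)
        return score_cache[subset]

    def better(a: tuple[float, tuple[int, ...]], b: tuple[float, tuple[int, ...]]) -> bool:
        """(score, subset) a beats b: higher score, then smaller, then
        canonical order."""
        if a[0] != b[0]:
            return a[0] > b[0]
        if len(a[1]) != len(b[1]):
            return len(a[1]) < len(b[1])
        return a[1] < b[1]

    root: tuple[int, ...] = ()
    open_nodes: dict[tuple[int, ...], float] = {root: score(root)}
    expanded: set[tuple[int, ...]] = set()
    best = (open_nodes[root], root)
    trace = [{"subset": [], "accuracy": best[0], "event": "root"}]
    stall = 0

    while open_nodes and stall < stall_limit:
        node = None
        node_entry = (-np.inf, ())
        for s, sc in open_nodes.items():
            if node is None or better((sc, s), node_entry):
                node, node_entry = s, (sc, s)
        del open_nodes[node]
        expanded.add(node)
        improved = False
        for j in range(len(names)):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in expanded or child in open_nodes:
                continue
            sc = score(child)
            open_nodes[child] = sc
            trace.append(
                {"subset": [names[i] for i in child], "accuracy": sc,
                 "event": "scored"}
            )
            if better((sc, child), best):
                best = (sc, child)
                improved = True
        stall = 0 if improved else stall + 1

    sel = tuple(names[i] for i in best[1])
    return WrapperResult(pool=names, selected=sel, accuracy=best[0], trace=trace)


# --------------------------------------------------------------------------
# Feature sets from profiles + published fixtures
# --------------------------------------------------------------------------

FEATURE_SETS = ("absolute", "relative", "absolute+tic", "relative+tic")


def build_feature_matrix(
    profiles: pd.DataFrame, feature_set: str
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(X, y, feature names) for one of the standard feature sets.

    Relative feature sets use TIC > 0 samples only (with a warning from
    the composition stage); absolute sets use every sample.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    base, _, with_tic = feature_set.partition("+")
    use = profiles[profiles["valid"]] if base == "relative" else profiles
    if base == "absolute":
        cols = [m.lower() for m in MARKERS]
        names = list(MARKERS)
    else:
        cols = [f"rel_{m.lower()}" for m in MARKERS]
        names = [f"{m}_rel" for m in MARKERS]
    if with_tic:
        cols.append("tic")
        names.append("TIC")
    X = use[cols].to_numpy(dtype=float)
    y = use["group"].to_numpy()
    return X, y, tuple(names)


def load_table5_fixture(panel: str) -> ConfusionMatrix:
    """Published LOOCV confusion matrices (panels "A", "B", "C")."""
    ref = importlib.resources.files("synoclass.data").joinpath(
        "table5_confusions.json"
    )
    data = json.loads(ref.read_text())
    if panel not in data["panels"]:
        raise KeyError(f"panel must be one of {sorted(data['panels'])}")
    return ConfusionMatrix(
        tuple(data["labels"]), np.asarray(data["panels"][panel], dtype=int)
    )
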