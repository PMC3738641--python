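"""Multicategory ROC: hypervolume under the ROC manifold (HUM).

For M diagnosis classes ordered by severity, the HUM of a marker is the
probability that one sample drawn from each class is ranked in the correct
severity order:

    HUM = P(X_1 < X_2 < ... < X_M),   X_m ~ class m

estimated by the U-statistic over all cross-class tuples (exhaustive when
the tuple count is manageable, Monte Carlo otherwise). For M = 2 this is
exactly the two-group AUC. A completely uninformative marker has HUM equal
to the chance level 1/M! (0.0014 for six classes).

Ties: a tuple whose values are non-decreasing but contain ties is credited
1 / (number of distinct strict orderings consistent with the ties), i.e.
1 / prod(len(run)!) over the tie runs. This convention makes an
all-constant marker score exactly 1/M!.

Combining a marker with TIC requires reducing the bivariate feature to a
single severity score per sample. The default reduction fits leave-one-out
diagonal-Gaussian class-conditionals, forms the posterior over the M
classes, and scores each sample by the posterior-expected severity rank
sum(rank_m * posterior_m); HUM of the scores is then computed as usual.
This reduction preserves the 1/M! null. Alternative reduction rules can be
plugged in via the ``reducer`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import GROUPS, MARKERS, SEVERITY_RANK, logger
from .composition import REL_COLUMNS

#: Default ceiling on the exhaustive tuple count.
DEFAULT_MAX_TUPLES = 10_000_000
#: Monte Carlo tuples drawn when the exhaustive count exceeds the ceiling.
DEFAULT_MC_TUPLES = 500_000


@dataclass(frozen=True)
class HumResult:
    """HUM of one feature (or feature pair) over M ordered classes."""

    features: tuple[str, ...]
    class_order: tuple[str, ...]
    hum: float
    null_hum: float
    estimator: str  # "exhaustive" | "monte_carlo"
    tuples: int
    seed: int | None = None


def hum_null(n_classes: int) -> float:
    """Chance-level HUM for M ordered classes: 1/M!."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 1.0 / math.factorial(n_classes)


def _tuple_credits(columns: list[np.ndarray]) -> np.ndarray:
    """Vectorised tie-run credits for tuples given as parallel columns.

    ``columns[i]`` holds the class-i value of each tuple (arrays broadcast
    against each other). Credit is 0 unless the tuple is non-decreasing in
    class order, else 1/prod(tie-run length factorial), accumulated
    incrementally: extending a tie run to length k divides by k.
    """
    credit = None
    runlen = None
    for a, b in zip(columns[:-1], columns[1:]):
        ge = b >= a
        eq = b == a
        if credit is None:
            credit = ge.astype(float)
            runlen = np.where(eq, 2, 1)
            credit = np.where(eq, credit / 2.0, credit)
        else:
            credit = credit * ge
            runlen = np.where(eq, runlen + 1, 1)
            credit = np.where(eq, credit / runlen, credit)
    assert credit is not None
    return credit


def hum_single(
    values_by_class: Mapping[str, Sequence[float]],
    class_order: Sequence[str] | None = None,
    max_tuples: int = DEFAULT_MAX_TUPLES,
    seed: int | None = None,
    mc_tuples: int = DEFAULT_MC_TUPLES,
    feature: str = "marker",
) -> HumResult:
    """HUM of a scalar feature over the ordered classes.

    ``class_order`` lists the classes from least to most severe; by default
    the canonical severity order of the classes present is used. Exhaustive
    over all cross-class tuples when their count is at most ``max_tuples``,
    otherwise Monte Carlo with ``mc_tuples`` seeded draws.
    """
    if class_order is None:
        class_order = [g for g in GROUPS if g in values_by_class]
        extra = [c for c in values_by_class if c not in GROUPS]
        class_order += sorted(extra)
    class_order = tuple(class_order)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    arrays = []
    for c in class_order:
        a = np.asarray(values_by_class[c], dtype=float)
        if a.size == 0:
            raise ValueError(f"class {c!r} is empty")
        arrays.append(a)
    m = len(arrays)
    count = int(np.prod([a.size for a in arrays], dtype=np.int64))
    null = hum_null(m)

    if count <= max_tuples:
        shaped = [
            a.reshape((1,) * i + (-1,) + (1,) * (m - 1 - i))
            for i, a in enumerate(arrays)
        ]
        credits = _tuple_credits(shaped)
        hum = float(credits.sum() / count)
        return HumResult((feature,), class_order, hum, null, "exhaustive", count)

    if seed is None:
        raise ValueError("seed required for the Monte Carlo estimator")
    rng = np.random.default_rng(int(seed) % 2**31)
    cols = [a[rng.integers(0, a.size, mc_tuples)] for a in arrays]
    credits = _tuple_credits(cols)
    hum = float(credits.mean())
    return HumResult((feature,), class_order, hum, null, "monte_carlo",
                     mc_tuples, int(seed) % 2**31)


# --------------------------------------------------------------------------
# Marker + TIC combination
# --------------------------------------------------------------------------

_VAR_FLOOR_FACTOR = 1e-9


def posterior_severity_scores(
    X: np.ndarray, labels: np.ndarray, class_order: Sequence[str]
) -> np.ndarray:
    """Leave-one-out posterior-expected severity rank of each sample.

    Diagonal-Gaussian class-conditionals with empirical priors are fitted
    on all samples except the one being scored; the score is
    sum(rank_m * P(class m | x)). Degenerate training variances are floored
    at 1e-9 * range^2 (with a small absolute floor) and a warning issued.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, d = X.shape
    ranks = {c: i + 1 for i, c in enumerate(class_order)}
    scores = np.empty(n)
    warned = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], labels[mask]
        rng_span = Xt.max(axis=0) - Xt.min(axis=0)
        floor = _VAR_FLOOR_FACTOR * rng_span**2 + 1e-12
        logpost = []
        classes_here = []
        for c in class_order:
            sel = yt == c
            nc = int(sel.sum())
            if nc == 0:
                continue
            mu = Xt[sel].mean(axis=0)
            var = Xt[sel].var(axis=0)
            low = var < floor
            if low.any() and nc > 1 and not warned:
                logger.warning("degenerate class variance floored in posterior scoring")
                warned = True
            var = np.maximum(var, floor)
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (X[i] - mu) ** 2 / var)
            logpost.append(np.log(nc / len(yt)) + ll)
            classes_here.append(c)
        lp = np.array(logpost)
        lp -= lp.max()
        post = np.exp(lp)
        post /= post.sum()
        scores[i] = sum(ranks[c] * p for c, p in zip(classes_here, post))
    return scores


def hum_combined(
    marker_by_class: Mapping[str, Sequence[float]],
    tic_by_class: Mapping[str, Sequence[float]],
    class_order: Sequence[str] | None = None,
    max_tuples: int = DEFAULT_MAX_TUPLES,
    seed: int | None = None,
    mc_tuples: int = DEFAULT_MC_TUPLES,
    feature: str = "marker",
    reducer: Callable[[np.ndarray, np.ndarray, Sequence[str]], np.ndarray]
    | None = None,
) -> HumResult:
    """HUM of a (marker, TIC) feature pair via score reduction.

    The two per-class value maps must be parallel (same classes, same
    per-class sample counts). ``reducer`` maps (X, labels, class_order) to
    one score per sample; the default is
    :func:`posterior_severity_scores`. The null stays 1/M!.
    """
    if class_order is None:
        class_order = [g for g in GROUPS if g in marker_by_class]
        class_order += sorted(c for c in marker_by_class if c not in GROUPS)
    class_order = tuple(class_order)
    if set(marker_by_class) != set(tic_by_class):
        raise ValueError("marker and TIC maps must cover the same classes")
    X_rows, y_rows = [], []
    for c in class_order:
        mv = np.asarray(marker_by_class[c], dtype=float)
        tv = np.asarray(tic_by_class[c], dtype=float)
        if mv.size != tv.size:
            raise ValueError(f"class {c!r}: marker and TIC sample counts differ")
        if mv.size == 0:
            raise ValueError(f"class {c!r} is empty")
        X_rows.append(np.column_stack([mv, tv]))
        y_rows.extend([c] * mv.size)
    X = np.vstack(X_rows)
    y = np.array(y_rows)
    reduce_fn = reducer or posterior_severity_scores
    scores = reduce_fn(X, y, class_order)
    by_class = {c: scores[y == c] for c in class_order}
    res = hum_single(
        by_class, class_order, max_tuples=max_tuples, seed=seed,
        mc_tuples=mc_tuples, feature=feature,
    )
    return HumResult((feature, "TIC"), res.class_order, res.hum, res.null_hum,
                     res.estimator, res.tuples, res.seed)


# --------------------------------------------------------------------------
# Ranking and cohort driver
# --------------------------------------------------------------------------


def rank_features(results: Sequence[HumResult]) -> pd.DataFrame:
    """Descending-HUM ranking; ties broken by feature name; chance-level
    null row appended last."""
    if not results:
        raise ValueError("no results to rank")
    rows = sorted(
        results, key=lambda r: (-r.hum, "/".join(r.features))
    )
    table = [
        {
            "rank": i + 1,
            "feature": "/".join(r.features),
            "hum": r.hum,
            "estimator": r.estimator,
            "tuples": r.tuples,
        }
        for i, r in enumerate(rows)
    ]
    table.append(
        {
            "rank": len(rows) + 1,
            "feature": "null hypothesis",
            "hum": rows[0].null_hum,
            "estimator": "analytic",
            "tuples": 0,
        }
    )
    return pd.DataFrame(table)


def run_hum(
    profiles: pd.DataFrame,
    features: str = "singles",
    seed: int = 0,
    max_tuples: int = DEFAULT_MAX_TUPLES,
) -> list[HumResult]:
    """HUM of cohort features over the severity-ordered classes present.

    ``features``: "singles" (TIC, 5 absolute, 5 relative markers),
    "tic-pairs" (each of the 10 marker features combined with TIC) or
    "both". Relative features use TIC > 0 samples only.
    """
    present = [g for g in GROUPS if (profiles["group"] == g).any()]
    valid = profiles[profiles["valid"]]

    def by_class(frame: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
        return {
            g: frame.loc[frame["group"] == g, col].to_numpy(dtype=float)
            for g in present
        }

    feature_cols = [("TIC", "tic", profiles)]
    feature_cols += [(m, m.lower(), profiles) for m in MARKERS]
    feature_cols += [(f"{m}_rel", f"rel_{m.lower()}", valid) for m in MARKERS]

    results: list[HumResult] = []
    if features in ("singles", "both"):
        for name, col, frame in feature_cols:
            results.append(
                hum_single(by_class(frame, col), present,
                           max_tuples=max_tuples, seed=seed, feature=name)
            )
    if features in ("tic-pairs", "both"):
        for name, col, frame in feature_cols:
            if name == "TIC":
                continue
            results.append(
                hum_combined(
                    by_class(frame, col), by_class(frame, "tic"), present,
                    max_tuples=max_tuples, seed=seed, feature=name,
                )
            )
    if not results:
        raise ValueError("features must be 'singles', 'tic-pairs' or 'both'")
    return results
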