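"""Robust group summaries: trimmed means, the size-dependent
mean-of-trimmed-means rule, ratio-of-ratios contrasts and the gestalt table.

Because the densities are heavy-tailed, group location is summarised not by
a single mean or median but by the *mean of trimmed means*: the trimmed
mean is computed at several trim factors and the results averaged. The trim
factors depend on group size n:

* n < 12  : trim factors 10%, 20%, 30%
* n >= 12 : trim factors 0% (complete sample), 10%, 20%

A trim factor of t% discards floor(t/100 * n) values from *each* side
before averaging (the usual per-side convention).

The ratio-of-ratios contrast for one marker and one ordered group pair
(more inflamed / less inflamed) is

    (abs_1 / abs_2) / (rel_1 / rel_2)

where abs_g and rel_g are the robust group means of the absolute and
relative densities. A value near 1 means the absolute and relative methods
see the same between-group contrast; large values flag comparisons where
overall infiltration, not composition, carries the difference.

The *gestalt* of a group is its robust-mean relative composition (the pie
sections, renormalised to sum to 100) together with its robust-mean TIC
(the pie height, i.e. overall degree of inflammation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    GROUPS,
    MARKERS,
    MARKER_COLUMNS,
    SEVERITY_RANK,
    logger,
    ordered_pairs,
)
from .composition import REL_COLUMNS


@dataclass(frozen=True)
class TrimScheme:
    """Trim factors (percent per side) selected by group size."""

    small_factors: tuple[float, ...] = (10.0, 20.0, 30.0)
    large_factors: tuple[float, ...] = (0.0, 10.0, 20.0)
    threshold: int = 12  # n below this uses small_factors

    def __post_init__(self) -> None:
        for f in self.small_factors + self.large_factors:
            if not 0.0 <= f < 50.0:
                raise ValueError("trim factors must lie in [0, 50)")

    def factors(self, n: int) -> tuple[float, ...]:
        return self.small_factors if n < self.threshold else self.large_factors


DEFAULT_TRIM_SCHEME = TrimScheme()


def trimmed_mean(values, trim: float) -> float:
    """Mean after discarding floor(trim/100 * n) values from each side."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("trimmed_mean requires a non-empty 1-d array")
    if not 0.0 <= trim < 50.0:
        raise ValueError("trim must lie in [0, 50) percent per side")
    k = math.floor(trim / 100.0 * arr.size)
    if 2 * k >= arr.size:
        raise ValueError(
            f"trim {trim}% discards all {arr.size} values"
        )
    return float(stats.trim_mean(arr, trim / 100.0))


def robust_group_mean(values, scheme: TrimScheme = DEFAULT_TRIM_SCHEME) -> float:
    """Mean of the trimmed means at the size-selected trim factors."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 4:
        raise ValueError(
            f"robust_group_mean requires n >= 4 (largest trim factor), got n={n}"
        )
    return float(np.mean([trimmed_mean(arr, f) for f in scheme.factors(n)]))


def _group_center(values, scheme: TrimScheme, context: str) -> float:
    """Robust mean, falling back to the plain mean for tiny groups (n < 4)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan")
    if arr.size < 4:
        logger.warning(
            "%s: group of size %d too small for trimmed means; using plain mean",
            context, arr.size,
        )
        return float(arr.mean())
    return robust_group_mean(arr, scheme)


# --------------------------------------------------------------------------
# Group summaries
# --------------------------------------------------------------------------


def group_summaries(
    profiles: pd.DataFrame, scheme: TrimScheme = DEFAULT_TRIM_SCHEME
) -> pd.DataFrame:
    """Per-group robust means of absolute and relative densities and TIC.

    Relative summaries use only TIC > 0 samples. One row per group present
    in ``profiles``, ordered by severity.
    """
    rows = []
    for g in [g for g in GROUPS if (profiles["group"] == g).any()]:
        sub = profiles[profiles["group"] == g]
        sub_valid = sub[sub["valid"]]
        row: dict[str, object] = {"group": g, "n": len(sub)}
        for m, col, rcol in zip(MARKERS, MARKER_COLUMNS, REL_COLUMNS):
            row[f"abs_{col}"] = _group_center(sub[col], scheme, f"{g}/{m} absolute")
            row[f"rel_{col}"] = _group_center(
                sub_valid[rcol], scheme, f"{g}/{m} relative"
            )
        row["tic"] = _group_center(sub["tic"], scheme, f"{g}/TIC")
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Ratio of ratios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RatioOfRatios:
    """One marker x ordered-group-pair ratio-of-ratios contrast."""

    marker: str
    numerator_group: str  # the more inflamed group
    denominator_group: str
    absolute_ratio: float
    relative_ratio: float
    ratio_of_ratios: float
    defined: bool


def ratio_of_ratios(
    profiles: pd.DataFrame,
    marker: str,
    pair: tuple[str, str],
    scheme: TrimScheme = DEFAULT_TRIM_SCHEME,
) -> RatioOfRatios:
    """Ratio-of-ratios for one marker and one ordered group pair.

    ``pair`` is (numerator, denominator); the numerator must be the more
    inflamed (higher severity rank) group. Zero denominators yield a
    flagged undefined result rather than an exception.
    """
    hi, lo = pair
    if SEVERITY_RANK[hi] <= SEVERITY_RANK[lo]:
        raise ValueError(
            f"numerator group {hi!r} must be more inflamed than {lo!r}"
        )
    if marker not in MARKERS:
        raise KeyError(f"unknown marker {marker!r}")
    col = marker.lower()
    rcol = f"rel_{col}"

    def centers(g: str) -> tuple[float, float]:
        sub = profiles[profiles["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} absent from profiles")
        a = _group_center(sub[col], scheme, f"{g}/{marker} absolute")
        r = _group_center(sub[sub["valid"]][rcol], scheme, f"{g}/{marker} relative")
        return a, r

    a_hi, r_hi = centers(hi)
    a_lo, r_lo = centers(lo)
    if a_lo == 0 or r_lo == 0 or not np.isfinite([a_hi, r_hi, a_lo, r_lo]).all():
        logger.warning(
            "ratio_of_ratios undefined for %s %s:%s (zero or undefined denominator)",
            marker, hi, lo,
        )
        return RatioOfRatios(marker, hi, lo, np.nan, np.nan, np.nan, defined=False)
    abs_ratio = a_hi / a_lo
    rel_ratio = r_hi / r_lo
    if rel_ratio == 0:
        return RatioOfRatios(marker, hi, lo, abs_ratio, 0.0, np.nan, defined=False)
    return RatioOfRatios(
        marker, hi, lo, abs_ratio, rel_ratio, abs_ratio / rel_ratio, defined=True
    )


def all_ratio_of_ratios(
    profiles: pd.DataFrame, scheme: TrimScheme = DEFAULT_TRIM_SCHEME
) -> pd.DataFrame:
    """The full marker x ordered-pair ratio-of-ratios table (75 rows for a
    complete six-group cohort)."""
    present = [g for g in GROUPS if (profiles["group"] == g).any()]
    rows = []
    for hi, lo in ordered_pairs(present):
        for m in MARKERS:
            r = ratio_of_ratios(profiles, m, (hi, lo), scheme)
            rows.append(
                {
                    "pair": f"{hi}:{lo}",
                    "marker": m,
                    "absolute_ratio": r.absolute_ratio,
                    "relative_ratio": r.relative_ratio,
                    "ratio_of_ratios": r.ratio_of_ratios,
                    "defined": r.defined,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gestalt summary
# --------------------------------------------------------------------------


def gestalt_summary(
    profiles: pd.DataFrame, scheme: TrimScheme = DEFAULT_TRIM_SCHEME
) -> dict:
    """Per-group composition (pie sections) and inflammation height.

    Sections are the robust-mean relative densities renormalised to sum to
    100 (robust means of percentages need not sum exactly to 100; the
    renormalisation is recorded in the output metadata). Height is the
    robust-mean TIC.
    """
    summary = group_summaries(profiles, scheme)
    out: dict = {
        "meta": {
            "sections": "robust-mean relative densities, renormalised to 100",
            "height": "robust-mean TIC (cells/mm^2)",
        },
        "groups": {},
    }
    for row in summary.itertuples(index=False):
        secs = np.array([getattr(row, f"rel_{c}") for c in MARKER_COLUMNS])
        total = secs.sum()
        if total > 0:
            secs = 100.0 * secs / total
        out["groups"][row.group] = {
            "n": int(row.n),
            "sections_pct": {m: float(s) for m, s in zip(MARKERS, secs)},
            "height_tic": float(row.tic),
        }
    return out
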