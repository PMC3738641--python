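"""Two-step nonparametric group testing.

For each marker (and separately for the absolute and relative methods), a
Kruskal-Wallis test across all groups acts as a gate; only when it rejects
(p < alpha) are the 15 ordered group pairs tested with two-sided
Mann-Whitney U tests. The Mann-Whitney p-values of one method's family
(up to 5 markers x 15 pairs = 75 tests) are then adjusted with the
Benjamini-Hochberg false-discovery-rate procedure.

The exact Mann-Whitney null distribution is used when the smaller group has
n <= 8 and there are no ties; otherwise the tie-corrected normal
approximation (with continuity correction) is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import GROUPS, MARKERS, SEVERITY_RANK, logger, ordered_pairs
from .composition import REL_COLUMNS

#: Default gate level for the Kruskal-Wallis step.
DEFAULT_ALPHA = 0.05

#: Largest min(n1, n2) for which the exact Mann-Whitney p is used (no ties).
EXACT_MAX_N = 8


@dataclass(frozen=True)
class PairwiseTestResult:
    """One marker x group-pair Mann-Whitney comparison."""

    marker: str
    method: str  # "absolute" | "relative"
    pair: tuple[str, str]  # (more inflamed, less inflamed)
    u_statistic: float
    p_raw: float
    p_fdr: float | None = None
    significant: bool | None = None


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical data (zero rank variance) returns (0, 1) by convention.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (of ``x`` over ``y``) and p-value.

    U counts pairs where x beats y, ties counted half. Exact p when the
    smaller sample has n <= 8 and there are no cross-sample ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if np.all(np.concatenate([x, y]) == x[0]):
        # degenerate: all values identical
        return x.size * y.size / 2.0, 1.0
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pairwise_mann_whitney(
    values_by_group: Mapping[str, Sequence[float]],
    gate_p: float,
    alpha: float = DEFAULT_ALPHA,
    marker: str = "",
    method: str = "",
) -> list[PairwiseTestResult]:
    """Mann-Whitney tests of all ordered group pairs, gated on ``gate_p``.

    ``gate_p`` is the Kruskal-Wallis p-value already obtained for this
    marker/method family; if gate_p >= alpha the family is not tested and
    an empty list is returned. Absent groups are skipped with a warning.
    FDR adjustment is NOT applied here; the caller adjusts within its
    declared family (see :func:`run_rank_tests`).
    """
    if gate_p >= alpha:
        logger.info(
            "Kruskal-Wallis gate not passed (p=%.3g >= %g); pairwise tests skipped",
            gate_p, alpha,
        )
        return []
    present = [g for g in GROUPS if g in values_by_group and len(values_by_group[g]) > 0]
    results = []
    for hi, lo in ordered_pairs(present):
        u, p = mann_whitney_u(values_by_group[hi], values_by_group[lo])
        results.append(
            PairwiseTestResult(marker=marker, method=method, pair=(hi, lo),
                               u_statistic=u, p_raw=p)
        )
    skipped = set(values_by_group) - set(present)
    if skipped:
        logger.warning("groups absent or empty, pairs skipped: %s", sorted(skipped))
    return results


def run_rank_tests(
    profiles: pd.DataFrame,
    method: str,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Full two-step testing of one method's family across all markers.

    Returns one row per Mann-Whitney test actually run, with the marker's
    Kruskal-Wallis gate (H, p), the U statistic, raw p, BH-adjusted p
    (within this method's family) and significance flags at alpha on both
    the raw and adjusted scale.
    """
    if method not in ("absolute", "relative"):
        raise ValueError("method must be 'absolute' or 'relative'")
    use = profiles if method == "absolute" else profiles[profiles["valid"]]
    cols = {m: (m.lower() if method == "absolute" else f"rel_{m.lower()}")
            for m in MARKERS}

    rows = []
    for m in MARKERS:
        vbg = {
            g: use.loc[use["group"] == g, cols[m]].to_numpy(dtype=float)
            for g in GROUPS
            if (use["group"] == g).any()
        }
        h, kw_p = kruskal_wallis(vbg)
        tests = pairwise_mann_whitney(vbg, gate_p=kw_p, alpha=alpha,
                                      marker=m, method=method)
        for t in tests:
            rows.append(
                {
                    "marker": m,
                    "method": method,
                    "pair": f"{t.pair[0]}:{t.pair[1]}",
                    "kw_h": h,
                    "kw_p": kw_p,
                    "u_statistic": t.u_statistic,
                    "p_raw": t.p_raw,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = bh_adjust(df["p_raw"].to_numpy())
        df["significant_raw"] = df["p_raw"] < alpha
        df["significant_fdr"] = df["p_fdr"] < alpha
    return df


def significance_counts(tests: pd.DataFrame) -> dict:
    """Counts of significant pairwise tests on both the raw-p and FDR scale
    (the literature is ambiguous about which tally it reports; both are
    returned)."""
    if len(tests) == 0:
        return {"n_tests": 0, "n_significant_raw": 0, "n_significant_fdr": 0}
    return {
        "n_tests": int(len(tests)),
        "n_significant_raw": int(tests["significant_raw"].sum()),
        "n_significant_fdr": int(tests["significant_fdr"].sum()),
    }
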