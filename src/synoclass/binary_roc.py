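"""Binary two-group ROC analysis per marker.

The AUC is computed with the Mann-Whitney estimator: the fraction of
(positive, negative) sample pairs in which the positive sample has the
higher value, ties counted one half. The positive class of every pair is
the more inflamed group (higher severity rank).

"Corrected" AUCs map raw values below 0.5 to 1 - AUC and set a reversal
flag: with the relative method the higher expression is sometimes found in
the *less* inflamed group, and the reversal flag records that the positive
state flipped.

Inference uses the DeLong variance estimator (Wald 95% CI and two-sided p
against AUC = 0.5). When the DeLong variance degenerates (AUC of exactly 0
or 1), the CI falls back to a seeded stratified bootstrap percentile
interval and the p-value to the exact Mann-Whitney p. P-values are
BH-FDR-adjusted within each method's family, and a comparison is called
significant when the 95% CI excludes 0.5 AND the adjusted p is below 0.05.

The absolute-vs-relative difference analysis computes, per marker and
pair, corrected AUC(absolute) - corrected AUC(relative); differences
strictly above 0.17 are outliers (discrepant scenarios) and the reference
agreement band is [-0.07, 0.17].
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GROUPS, MARKERS, logger, ordered_pairs
from .rank_tests import bh_adjust, mann_whitney_u

#: Corrected-AUC difference above which an (abs, rel) pair is an outlier.
OUTLIER_THRESHOLD = 0.17
#: Lower edge of the abs-vs-rel agreement band.
AGREEMENT_LOWER = -0.07

DEFAULT_N_BOOT = 2000


# --------------------------------------------------------------------------
# AUC estimation and correction
# --------------------------------------------------------------------------


def auc(positive, negative) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos = neg)."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def correct_auc(raw: float) -> tuple[float, bool]:
    """(corrected AUC, reversed flag): raw < 0.5 maps to (1 - raw, True)."""
    if not 0.0 <= raw <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {raw}")
    return (1.0 - raw, True) if raw < 0.5 else (float(raw), False)


# --------------------------------------------------------------------------
# DeLong inference
# --------------------------------------------------------------------------


def delong_variance(positive, negative) -> float:
    """DeLong variance of the Mann-Whitney AUC via structural components."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance requires >= 2 samples per group")
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorised over all pairs
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive structural components
    v01 = psi.mean(axis=0)  # per-negative structural components
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return float(s10 / m + s01 / n)


@dataclass(frozen=True)
class AucInference:
    auc: float
    ci: tuple[float, float]
    p: float
    method: str  # "delong" | "bootstrap"


def auc_inference(
    positive, negative, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> AucInference:
    """95% CI and two-sided p against AUC = 0.5.

    DeLong Wald interval when the variance is positive; otherwise a
    stratified bootstrap percentile CI (seeded, ``n_boot`` resamples) with
    the exact Mann-Whitney p.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("auc_inference requires >= 2 samples per group")
    a = auc(pos, neg)
    var = delong_variance(pos, neg)
    if var > 0:
        se = np.sqrt(var)
        z = stats.norm.ppf(0.975)
        lo, hi = max(0.0, a - z * se), min(1.0, a + z * se)
        p = 2.0 * stats.norm.sf(abs(a - 0.5) / se)
        return AucInference(a, (float(lo), float(hi)), float(min(p, 1.0)), "delong")
    # Degenerate variance (perfect separation): bootstrap CI, exact MWU p.
    if seed is None:
        raise ValueError("seed required for bootstrap fallback")
    rng = np.random.default_rng(int(seed) % 2**31)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = auc(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    _, p = mann_whitney_u(pos, neg)
    return AucInference(a, (float(lo), float(hi)), float(p), "bootstrap")


# --------------------------------------------------------------------------
# Cohort-level ROC tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """One marker x method x group-pair ROC comparison."""

    marker: str  # marker symbol or "TIC"
    method: str  # "absolute" | "relative" | "tic"
    pair: tuple[str, str]  # (positive = more inflamed, negative)
    raw_auc: float
    corrected_auc: float
    reversed: bool
    ci: tuple[float, float]
    p_raw: float
    p_fdr: float | None = None
    significant: bool | None = None


def _method_features(method: str) -> list[tuple[str, str]]:
    """(feature label, profiles column) pairs for one method family."""
    if method == "absolute":
        return [(m, m.lower()) for m in MARKERS]
    if method == "relative":
        return [(m, f"rel_{m.lower()}") for m in MARKERS]
    if method == "tic":
        return [("TIC", "tic")]
    raise ValueError("method must be 'absolute', 'relative' or 'tic'")


def run_binary_roc(
    profiles: pd.DataFrame,
    method: str,
    seed: int = 0,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All marker x ordered-pair ROC comparisons of one method family.

    For the relative method, TIC = 0 samples are excluded. FDR adjustment
    and the significance rule (CI excludes 0.5 and adjusted p < alpha) are
    applied within this family.
    """
    use = profiles[profiles["valid"]] if method == "relative" else profiles
    present = [g for g in GROUPS if (use["group"] == g).any()]
    skipped = [g for g in GROUPS if (profiles["group"] == g).any() and g not in present]
    if skipped:
        logger.warning("groups with no usable samples skipped in ROC: %s", skipped)

    rows = []
    for feat, col in _method_features(method):
        for k, (hi, lo) in enumerate(ordered_pairs(present)):
            pos = use.loc[use["group"] == hi, col].to_numpy(dtype=float)
            neg = use.loc[use["group"] == lo, col].to_numpy(dtype=float)
            # deterministic per-comparison seed for the bootstrap fallback
            sub_seed = (int(seed) * 1009 + hash((feat, hi, lo)) % 100003) % 2**31
            inf = auc_inference(pos, neg, n_boot=n_boot, seed=sub_seed)
            corr, rev = correct_auc(inf.auc)
            rows.append(
                {
                    "marker": feat,
                    "method": method,
                    "pair": f"{hi}:{lo}",
                    "raw_auc": inf.auc,
                    "corrected_auc": corr,
                    "reversed": rev,
                    "ci_lo": inf.ci[0],
                    "ci_hi": inf.ci[1],
                    "ci_method": inf.method,
                    "p_raw": inf.p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_adjust(df["p_raw"].to_numpy())
    ci_excludes = (df["ci_lo"] > 0.5) | (df["ci_hi"] < 0.5)
    df["significant"] = ci_excludes & (df["p_fdr"] < alpha)
    return df


def median_corrected_auc(results: pd.DataFrame, scope: str = "all") -> float:
    """Median corrected AUC over one marker's comparisons or over all.

    ``scope`` is a marker symbol (or "TIC") or "all". Medians over an even
    count use the midpoint convention.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    sub = results if scope == "all" else results[results["marker"] == scope]
    if len(sub) == 0:
        raise ValueError(f"no results in scope {scope!r}")
    return float(np.median(sub["corrected_auc"].to_numpy(dtype=float)))


def table3_summary(roc_abs: pd.DataFrame, roc_rel: pd.DataFrame,
                   roc_tic: pd.DataFrame | None = None) -> pd.DataFrame:
    """Median (range) corrected-AUC summary per marker and method, plus the
    all-marker medians and their difference."""
    rows = []
    for m in MARKERS:
        for label, df in (("absolute", roc_abs), ("relative", roc_rel)):
            sub = df[df["marker"] == m]["corrected_auc"]
            rows.append(
                {"scope": m, "method": label,
                 "median": float(np.median(sub)),
                 "min": float(sub.min()), "max": float(sub.max())}
            )
    med_abs = median_corrected_auc(roc_abs, "all")
    med_rel = median_corrected_auc(roc_rel, "all")
    rows.append({"scope": "all", "method": "absolute", "median": med_abs,
                 "min": float(roc_abs["corrected_auc"].min()),
                 "max": float(roc_abs["corrected_auc"].max())})
    rows.append({"scope": "all", "method": "relative", "median": med_rel,
                 "min": float(roc_rel["corrected_auc"].min()),
                 "max": float(roc_rel["corrected_auc"].max())})
    if roc_tic is not None and len(roc_tic):
        sub = roc_tic["corrected_auc"]
        rows.append({"scope": "TIC", "method": "absolute",
                     "median": float(np.median(sub)),
                     "min": float(sub.min()), "max": float(sub.max())})
    rows.append({"scope": "difference(all)", "method": "absolute-relative",
                 "median": med_abs - med_rel, "min": np.nan, "max": np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Absolute vs relative difference / outlier analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AucDifferenceRecord:
    marker: str
    pair: str
    difference: float  # corrected AUC(absolute) - corrected AUC(relative)
    outlier: bool  # difference strictly above the 0.17 threshold


def auc_difference_analysis(
    abs_results: pd.DataFrame, rel_results: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-(marker, pair) corrected-AUC differences and outlier flags.

    Requires the two tables to cover identical (marker, pair) keys. Returns
    the difference table and a summary with outlier counts per marker, the
    count inside the agreement band [-0.07, 0.17], and (when raw AUCs are
    present in both tables) the same counts on the uncorrected basis.
    """
    a = abs_results.set_index(["marker", "pair"])
    r = rel_results.set_index(["marker", "pair"])
    if set(a.index) != set(r.index):
        raise ValueError("absolute and relative tables cover different (marker, pair) keys")
    r = r.reindex(a.index)
    diff = a["corrected_auc"] - r["corrected_auc"]
    out = pd.DataFrame(
        {
            "marker": [k[0] for k in a.index],
            "pair": [k[1] for k in a.index],
            "difference": diff.to_numpy(dtype=float),
        }
    )
    eps = 1e-9  # float-safe strict comparison at the printed precision
    out["outlier"] = out["difference"] > OUTLIER_THRESHOLD + eps
    out["in_band"] = (out["difference"] >= AGREEMENT_LOWER - eps) & (
        out["difference"] <= OUTLIER_THRESHOLD + eps
    )
    summary = {
        "basis": "corrected",
        "n": int(len(out)),
        "n_outliers": int(out["outlier"].sum()),
        "n_in_band": int(out["in_band"].sum()),
        "outliers_per_marker": {
            m: int(out.loc[out["marker"] == m, "outlier"].sum())
            for m in sorted(out["marker"].unique())
        },
    }
    if "raw_auc" in a.columns and "raw_auc" in r.columns and \
            a["raw_auc"].notna().all() and r["raw_auc"].notna().all():
        rdiff = (a["raw_auc"] - r["raw_auc"]).to_numpy(dtype=float)
        out["difference_raw_basis"] = rdiff
        summary["raw_basis"] = {
            "n_outliers": int((rdiff > OUTLIER_THRESHOLD + eps).sum()),
            "n_in_band": int(
                ((rdiff >= AGREEMENT_LOWER - eps)
                 & (rdiff <= OUTLIER_THRESHOLD + eps)).sum()
            ),
        }
    return out, summary


def reversal_cluster(rel_results: pd.DataFrame) -> pd.DataFrame:
    """Relative-method comparisons where the positive state reversed and the
    comparison is significant (the discrepant cluster of the scatter
    analysis)."""
    return rel_results[
        rel_results["reversed"] & rel_results["significant"].fillna(False)
    ].reset_index(drop=True)


# --------------------------------------------------------------------------
# Printed corrected-AUC fixture
# --------------------------------------------------------------------------


def load_table2_fixture() -> pd.DataFrame:
    """The published corrected-AUC grid: 15 ordered pairs x (5 markers x
    {absolute, relative} + TIC), with significance flags as printed."""
    ref = importlib.resources.files("synoclass.data").joinpath(
        "table2_corrected_aucs.csv"
    )
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False)
    df["corrected_auc"] = df["corrected_auc"].astype(float)
    df["significant"] = df["sig"].isin(["*", "**"])
    return df
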