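"""Pipeline orchestration: cohort -> profiles -> summaries, tests, ROC,
HUM and classification, collected into one structured, reproducible
report.

Given a cohort (read from CSV or simulated) and a seed, ``run_pipeline``
executes every stage in method order and returns a JSON-serialisable
report whose provenance block records the seed, the simulation-config
hash and the package version. Two runs with identical inputs produce
byte-identical serialised reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Cohort, logger, write_table
from .synthetic_cohort import SimulationConfig, default_config, generate_cohort
from .composition import profile_cohort
from .aggregation import all_ratio_of_ratios, gestalt_summary, group_summaries
from .rank_tests import run_rank_tests, significance_counts
from .binary_roc import (
    auc_difference_analysis,
    load_table2_fixture,
    median_corrected_auc,
    reversal_cluster,
    run_binary_roc,
    table3_summary,
)
from .multicategory_roc import rank_features, run_hum
from .bayes_classify import (
    FEATURE_SETS,
    accuracy_from_confusion,
    build_feature_matrix,
    nb_loocv,
    wrapper_select,
)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _df_records(df: pd.DataFrame) -> list[dict]:
    """JSON-safe records with deterministic float text."""
    return json.loads(df.to_json(orient="records", double_precision=12))


def _config_hash(config: SimulationConfig | None) -> str | None:
    if config is None:
        return None
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    cohort: Cohort | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
    n_boot: int = 2000,
    with_classifier: bool = True,
    with_wrapper: bool = True,
) -> dict:
    """Run every analysis stage and collect a structured report.

    Either pass a ``cohort`` or a ``sim_config`` to simulate one (defaults
    to the documented default configuration when both are None).
    """
    t0 = time.time()
    if cohort is None:
        sim_config = sim_config or default_config()
        cohort = generate_cohort(sim_config, seed=seed)
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn, *a, **k):
            t = time.time()
            try:
                out = fn(*a, **k)
            except Exception as exc:  # annotate the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.time() - t, 3)
            logger.info("stage %s done in %.2fs", name, timings[name])
            return out
        return wrap

    profiles = stage("transform")(profile_cohort, cohort)
    gestalt = stage("gestalt")(gestalt_summary, profiles)
    ratios = stage("ratios")(all_ratio_of_ratios, profiles)
    tests_abs = stage("ranktests_abs")(run_rank_tests, profiles, "absolute")
    tests_rel = stage("ranktests_rel")(run_rank_tests, profiles, "relative")
    roc_abs = stage("roc_abs")(run_binary_roc, profiles, "absolute", seed, n_boot)
    roc_rel = stage("roc_rel")(run_binary_roc, profiles, "relative", seed, n_boot)
    roc_tic = stage("roc_tic")(run_binary_roc, profiles, "tic", seed, n_boot)
    diffs, diff_summary = stage("roc_diff")(auc_difference_analysis, roc_abs, roc_rel)
    hum_results = stage("hum")(run_hum, profiles, "both", seed)
    hum_singles = [r for r in hum_results if len(r.features) == 1]
    hum_pairs = [r for r in hum_results if len(r.features) == 2]

    report: dict = {
        "provenance": {
            "package": "synoclass",
            "version": __version__,
            "seed": int(seed),
            "n_boot": int(n_boot),
            "config_hash": _config_hash(sim_config),
            "n_samples": len(cohort),
            "group_sizes": cohort.group_sizes,
        },
        "gestalt": gestalt,
        "ratio_of_ratios": _df_records(ratios),
        "rank_tests": {
            "absolute": _df_records(tests_abs),
            "relative": _df_records(tests_rel),
            "counts": {
                "absolute": significance_counts(tests_abs),
                "relative": significance_counts(tests_rel),
            },
        },
        "roc": {
            "absolute": _df_records(roc_abs),
            "relative": _df_records(roc_rel),
            "tic": _df_records(roc_tic),
            "medians": _df_records(table3_summary(roc_abs, roc_rel, roc_tic)),
            "differences": _df_records(diffs),
            "difference_summary": diff_summary,
            "reversal_cluster": _df_records(reversal_cluster(roc_rel)),
        },
        "hum": {
            "singles": _df_records(rank_features(hum_singles)),
            "tic_pairs": _df_records(rank_features(hum_pairs)) if hum_pairs else [],
        },
    }

    if with_classifier:
        clf: dict = {}
        for fs in FEATURE_SETS:
            X, y, names = build_feature_matrix(profiles, fs)
            cm = stage(f"classify_{fs}")(nb_loocv, X, y)
            acc = accuracy_from_confusion(cm)
            entry = {
                "confusion": cm.to_dict(),
                "accuracy": {"correct": acc.correct, "total": acc.total,
                             "percent": acc.percent},
            }
            if with_wrapper:
                wr = stage(f"wrapper_{fs}")(wrapper_select, X, y, names)
                entry["wrapper"] = {
                    "selected": list(wr.selected),
                    "accuracy": wr.accuracy,
                }
            clf[fs] = entry
        report["classifier"] = clf

    report["provenance"]["timings_s"] = timings
    report["provenance"]["total_s"] = round(time.time() - t0, 3)
    return report


def fixture_report() -> dict:
    """Summary report computed from the published corrected-AUC grid
    (no raw data needed): per-marker and overall medians."""
    fx = load_table2_fixture()
    roc_abs = fx[fx["method"] == "absolute"]
    roc_rel = fx[fx["method"] == "relative"]
    roc_tic = fx[fx["method"] == "tic"]
    return {
        "source": "published corrected-AUC grid",
        "medians": _df_records(table3_summary(roc_abs, roc_rel, roc_tic)),
        "median_all_absolute": median_corrected_auc(roc_abs, "all"),
        "median_all_relative": median_corrected_auc(roc_rel, "all"),
    }


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Deterministic serialisation (sorted keys); optionally written to
    ``path``."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    text = json.dumps(report, indent=2, sort_keys=True, default=default) + "\n"
    # timings vary run to run; reproducibility applies to the content hash
    # of everything else, so strip them from the serialised form.
    stripped = json.loads(text)
    stripped.get("provenance", {}).pop("timings_s", None)
    stripped.get("provenance", {}).pop("total_s", None)
    text = json.dumps(stripped, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
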