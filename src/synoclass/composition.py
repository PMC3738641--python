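"""Per-sample composition transform: absolute densities -> TIC and
relative densities.

TIC (total inflammatory cells) is the sum of the five marker densities of
one sample, in cells/mm^2, and serves as the overall inflammation measure.
The *relative* density of a marker is its percentage of TIC; the five
relative densities of a valid sample sum to 100.

A sample with TIC = 0 (no cell of any of the five types) has undefined
relative densities. Such samples are flagged ``valid = False`` and are
excluded from relative-method analyses (with a warning) but retained for
absolute-method analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Cohort, MARKERS, MARKER_COLUMNS, SampleRecord, logger

#: Relative-density column names in the profiles table.
REL_COLUMNS: tuple[str, ...] = tuple(f"rel_{c}" for c in MARKER_COLUMNS)


@dataclass(frozen=True)
class CompositionProfile:
    """TIC and relative composition of one sample."""

    sample_id: str
    tic: float
    relative: tuple[float, ...]  # percent of TIC, canonical marker order
    valid: bool

    def rel(self, marker: str) -> float:
        if not self.valid:
            raise ValueError(
                f"sample {self.sample_id!r} has TIC = 0; relative densities undefined"
            )
        return float(self.relative[MARKERS.index(marker)])


def compute_tic(sample: SampleRecord | np.ndarray) -> float:
    """Total inflammatory cells: sum of the five marker densities."""
    dens = sample.densities if isinstance(sample, SampleRecord) else sample
    arr = np.asarray(dens, dtype=float)
    if arr.shape != (len(MARKERS),):
        raise ValueError(f"expected {len(MARKERS)} densities, got shape {arr.shape}")
    return float(arr.sum())


def compute_relative(sample: SampleRecord) -> CompositionProfile:
    """Relative densities (percent of TIC); flagged invalid when TIC = 0."""
    tic = compute_tic(sample)
    if tic == 0.0:
        return CompositionProfile(
            sample_id=sample.sample_id,
            tic=0.0,
            relative=(float("nan"),) * len(MARKERS),
            valid=False,
        )
    rel = tuple(100.0 * float(d) / tic for d in sample.densities)
    return CompositionProfile(
        sample_id=sample.sample_id, tic=tic, relative=rel, valid=True
    )


def profile_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort-level profiles table.

    Returns the cohort frame extended with ``tic``, the five ``rel_*``
    percentage columns and a ``valid`` flag. This table is the common
    input to every downstream analysis stage.
    """
    df = cohort.frame.copy()
    dens = df[list(MARKER_COLUMNS)].to_numpy(dtype=float)
    tic = dens.sum(axis=1)
    df["tic"] = tic
    valid = tic > 0
    rel = np.full_like(dens, np.nan)
    rel[valid] = 100.0 * dens[valid] / tic[valid, None]
    for j, col in enumerate(REL_COLUMNS):
        df[col] = rel[:, j]
    df["valid"] = valid
    n_invalid = int((~valid).sum())
    if n_invalid:
        ids = df.loc[~valid, "sample_id"].tolist()
        logger.warning(
            "%d sample(s) with TIC = 0 excluded from relative-method analyses: %s",
            n_invalid, ids,
        )
    return df
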