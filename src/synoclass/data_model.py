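"""Domain types and CSV I/O for synovial-infiltrate cohorts.

A cohort is a table of biopsies, each scored for the absolute density
(positively staining cells per mm^2 of subintima) of five inflammatory-cell
markers:

========  ==========================
marker    cell type
========  ==========================
CD15      neutrophilic granulocytes
CD68      macrophages
CD3       T cells
CD20      B cells
CD38      plasma cells
========  ==========================

Each sample carries one of six diagnosis labels, ordered here by presumed
severity of synovial inflammation (least to most inflamed):

    N (normal synovium) < Orth.A (noninflammatory orthopedic arthropathy)
    < OA (osteoarthritis) < EA (early undifferentiated arthritis)
    < RA (rheumatoid arthritis) < SeA (chronic septic arthritis)

This severity ordering fixes the positive class in every two-group
comparison downstream (the more inflamed group is the positive / numerator
group) and the class order of the multicategory ROC analysis.

Densities are real-valued, not integer: per-sample values are averages over
at least ten microscopic fields.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("synoclass")

# --------------------------------------------------------------------------
# Canonical marker panel and diagnosis groups
# --------------------------------------------------------------------------

#: Canonical marker order used everywhere in the package.
MARKERS: tuple[str, ...] = ("CD15", "CD68", "CD3", "CD20", "CD38")

#: Lower-case CSV column names for the marker densities.
MARKER_COLUMNS: tuple[str, ...] = tuple(m.lower() for m in MARKERS)

#: Diagnosis groups in increasing order of presumed inflammation severity.
GROUPS: tuple[str, ...] = ("N", "Orth.A", "OA", "EA", "RA", "SeA")

#: severity_rank: N=1 (least inflamed) ... SeA=6 (most inflamed).
SEVERITY_RANK: dict[str, int] = {g: i + 1 for i, g in enumerate(GROUPS)}

#: Alias map applied to group labels before validation (case-sensitive).
DEFAULT_GROUP_ALIASES: dict[str, str] = {
    "Normal": "N",
    "Orth. A": "Orth.A",
    "OrthA": "Orth.A",
    "Orth A": "Orth.A",
}

#: Canonical cohort CSV columns.
COHORT_COLUMNS: tuple[str, ...] = ("sample_id", "group") + MARKER_COLUMNS


@dataclass(frozen=True)
class MarkerPanel:
    """The fixed five-marker immunostaining panel, in canonical order."""

    markers: tuple[str, ...] = MARKERS

    def __post_init__(self) -> None:
        if tuple(self.markers) != MARKERS:
            raise ValueError(
                f"marker panel must be exactly {MARKERS} in this order, "
                f"got {tuple(self.markers)}"
            )

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class DiagnosisGroup:
    """A diagnosis label with its severity rank (1 = least inflamed)."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in SEVERITY_RANK:
            raise ValueError(
                f"unknown diagnosis group {self.label!r}; expected one of {GROUPS}"
            )

    @property
    def severity_rank(self) -> int:
        return SEVERITY_RANK[self.label]

    def __lt__(self, other: "DiagnosisGroup") -> bool:
        return self.severity_rank < other.severity_rank


def ordered_pairs(groups: Sequence[str] = GROUPS) -> list[tuple[str, str]]:
    """All (more-inflamed, less-inflamed) group pairs.

    Returned in the conventional report order: pairs with the most inflamed
    numerator first, then its comparators in decreasing severity, e.g.
    (SeA, RA), (SeA, EA), ..., (Orth.A, N). For the six canonical groups
    this yields the 15 paired comparisons.
    """
    by_sev = sorted(set(groups), key=lambda g: SEVERITY_RANK[g], reverse=True)
    return [(hi, lo) for i, hi in enumerate(by_sev) for lo in by_sev[i + 1 :]]


# --------------------------------------------------------------------------
# Sample and cohort containers
# --------------------------------------------------------------------------


class CohortSchemaError(ValueError):
    """A cohort CSV is missing required columns."""


class CohortValidationError(ValueError):
    """A cohort row violates the sample invariants."""


@dataclass(frozen=True)
class SampleRecord:
    """One biopsy: five absolute marker densities plus a diagnosis label."""

    sample_id: str
    group: str
    densities: tuple[float, float, float, float, float]  # canonical marker order

    def __post_init__(self) -> None:
        if self.group not in SEVERITY_RANK:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}"
            )
        if len(self.densities) != len(MARKERS):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: expected {len(MARKERS)} densities"
            )
        arr = np.asarray(self.densities, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: non-finite density"
            )
        if np.any(arr < 0):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: negative density"
            )

    def density(self, marker: str) -> float:
        return float(self.densities[MARKERS.index(marker)])


@dataclass
class Cohort:
    """A validated cohort table (one row per sample, canonical columns)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.frame = _validate_cohort_frame(self.frame)

    @classmethod
    def from_records(cls, records: Iterable[SampleRecord]) -> "Cohort":
        rows = [
            {"sample_id": r.sample_id, "group": r.group,
             **dict(zip(MARKER_COLUMNS, r.densities))}
            for r in records
        ]
        if not rows:
            raise CohortValidationError("cohort must contain at least one sample")
        return cls(pd.DataFrame(rows))

    def records(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=str(row.sample_id),
                group=str(row.group),
                densities=tuple(float(getattr(row, c)) for c in MARKER_COLUMNS),
            )
            for row in self.frame.itertuples(index=False)
        ]

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.frame["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS if counts.get(g, 0) > 0}

    def values(self, marker: str, group: str | None = None) -> np.ndarray:
        """Absolute densities of ``marker``, optionally for one group."""
        col = marker.lower()
        if col not in MARKER_COLUMNS:
            raise KeyError(f"unknown marker {marker!r}")
        df = self.frame if group is None else self.frame[self.frame["group"] == group]
        return df[col].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )


def _validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        raise CohortValidationError("cohort must contain at least one sample")
    df = df.loc[:, list(COHORT_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["group"] = df["group"].astype(str).map(
        lambda g: DEFAULT_GROUP_ALIASES.get(g, g)
    )
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        rows = df.index[df["group"].isin(bad_groups)].tolist()
        raise CohortValidationError(
            f"unknown group labels {bad_groups} in rows {rows}"
        )
    for col in MARKER_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)].tolist()
        if bad:
            raise CohortValidationError(
                f"non-numeric or non-finite density in column {col!r}, rows {bad}"
            )
        neg = df.index[vals < 0].tolist()
        if neg:
            raise CohortValidationError(
                f"negative density in column {col!r}, rows {neg}"
            )
        df[col] = vals.astype(float)
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header and one row per sample.
    schema
        Optional map from canonical column names (``sample_id``, ``group``,
        ``cd15`` ... ``cd38``) to the column names actually present in the
        file. Unmapped canonical names are looked up verbatim.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {actual: canon for canon, actual in schema.items()}
        df = df.rename(columns=rename)
    return Cohort(df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    write_table(cohort.frame, path)


def write_table(results, path: str | Path) -> None:
    """Write a result table to CSV (DataFrame) or JSON (mapping).

    Numeric values are written with 12 significant digits so that
    read-after-write round-trips are lossless at that precision. Empty
    tables are rejected.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        if len(results) == 0:
            raise ValueError("refusing to write an empty table")
        results.to_csv(path, index=False, float_format="%.12g")
    elif isinstance(results, Mapping):
        if len(results) == 0:
            raise ValueError("refusing to write an empty mapping")
        path.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    elif hasattr(results, "to_dict"):
        write_table(results.to_dict(), path)
    else:
        raise TypeError(f"cannot serialise object of type {type(results).__name__}")


def read_table(path: str | Path):
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path)
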