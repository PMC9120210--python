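"""Systematic-review inclusion/exclusion filters with an auditable log.

Candidate data sets are screened in a fixed order — offspring age first
(ratios of older offspring confound the sex ratio at birth with sex-specific
juvenile mortality), then minimum sample size, then duplicates, accessibility
and ambiguous ratio type.  Every input row receives exactly one decision, so
the log partitions the candidate table and category counts depend on the
documented order of application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .core_stats import SexRatioCount
from .meta_analysis import StudyRecord

__all__ = [
    "Decision",
    "CandidateDataset",
    "ExclusionLog",
    "apply_filters",
    "merge_duplicates",
]

#: Age cut-off in days (six weeks); older tagged offspring may already
#: reflect sex-specific mortality rather than the sex ratio at birth.
DEFAULT_MAX_AGE_DAYS = 42
#: Minimum offspring per data set for a meaningful sex-ratio estimate.
DEFAULT_MIN_N = 50


class Decision(str, Enum):
    KEPT = "kept"
    EXCLUDED_AGE = "excluded_age"
    EXCLUDED_SMALL_N = "excluded_small_n"
    EXCLUDED_DUPLICATE = "excluded_duplicate"
    EXCLUDED_INACCESSIBLE = "excluded_inaccessible"
    EXCLUDED_AMBIGUOUS_TYPE = "excluded_ambiguous_type"


@dataclass(frozen=True)
class CandidateDataset:
    """A candidate data set prior to screening.

    ``max_offspring_age_days=None`` means the oldest offspring age is not
    reported; ``duplicate_of`` points at a more holistic collection that
    supersedes this row; ``merge_key`` marks rows to be combined (rows
    sharing a key are pooled by :func:`merge_duplicates`).
    """

    id: str
    counts: SexRatioCount
    reference_id: str = ""
    country: str = ""
    location: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    living_condition: str = ""
    ratio_type: str = ""
    max_offspring_age_days: Optional[int] = None
    duplicate_of: Optional[str] = None
    accessible: bool = True
    ratio_type_known: bool = True
    merge_key: Optional[str] = None

    def to_study_record(self) -> StudyRecord:
        return StudyRecord(
            id=self.id,
            reference_id=self.reference_id,
            counts=self.counts,
            country=self.country,
            location=self.location,
            latitude=self.latitude,
            longitude=self.longitude,
            living_condition=self.living_condition,
            ratio_type=self.ratio_type,
            max_offspring_age_days=self.max_offspring_age_days,
        )


@dataclass
class ExclusionLog:
    """Per-row screening decisions, in order of the input table."""

    entries: list[tuple[str, Decision, str]] = field(default_factory=list)
    filter_order: tuple[str, ...] = (
        "age",
        "small_n",
        "duplicate",
        "inaccessible",
        "ambiguous_type",
    )

    def record(self, dataset_id: str, decision: Decision, note: str = "") -> None:
        self.entries.append((dataset_id, decision, note))

    def count(self, decision: Decision) -> int:
        return sum(1 for _, d, _ in self.entries if d == decision)

    @property
    def n_kept(self) -> int:
        return self.count(Decision.KEPT)

    @property
    def n_excluded(self) -> int:
        return len(self.entries) - self.n_kept

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, d.value, n) for i, d, n in self.entries],
            columns=["id", "decision", "note"],
        )


def _decide(
    row: CandidateDataset, max_age_days: int, min_n: int, strict: bool
) -> tuple[Decision, str]:
    # Order matters and is recorded in the log: age, then sample size, then
    # duplicate/accessibility/ambiguity.
    if row.max_offspring_age_days is not None and row.max_offspring_age_days > max_age_days:
        return (
            Decision.EXCLUDED_AGE,
            f"max offspring age {row.max_offspring_age_days} d > {max_age_days} d",
        )
    if row.counts.n_total < min_n:
        return (
            Decision.EXCLUDED_SMALL_N,
            f"sample size {row.counts.n_total} < {min_n}",
        )
    if row.duplicate_of is not None:
        return (
            Decision.EXCLUDED_DUPLICATE,
            f"superseded by more holistic collection {row.duplicate_of}",
        )
    if not row.accessible:
        return Decision.EXCLUDED_INACCESSIBLE, "reference not accessible"
    if not row.ratio_type_known or row.max_offspring_age_days is None:
        if strict:
            what = "ratio type" if not row.ratio_type_known else "offspring age"
            return Decision.EXCLUDED_AMBIGUOUS_TYPE, f"{what} not reported"
        warnings.warn(
            f"dataset {row.id}: incomplete reporting kept in lenient mode",
            stacklevel=3,
        )
    return Decision.KEPT, ""


def apply_filters(
    table: Sequence[CandidateDataset],
    max_age_days: int = DEFAULT_MAX_AGE_DAYS,
    min_n: int = DEFAULT_MIN_N,
    strict: bool = True,
) -> tuple[list[CandidateDataset], ExclusionLog]:
    """Screen candidate data sets; return the kept rows and the full log.

    Boundaries are inclusive on the kept side: an oldest-offspring age of
    exactly ``max_age_days`` and a sample size of exactly ``min_n`` are kept
    (the exclusion rules are "older than" and "fewer than").  In strict mode
    rows with unreported age or ratio type are excluded as ambiguous; lenient
    mode keeps them with a warning.
    """
    if len(table) == 0:
        raise ValueError("candidate table is empty")
    log = ExclusionLog()
    kept: list[CandidateDataset] = []
    for row in table:
        decision, note = _decide(row, max_age_days, min_n, strict)
        log.record(row.id, decision, note)
        if decision is Decision.KEPT:
            kept.append(row)
    return kept, log


def merge_duplicates(table: Sequence[CandidateDataset]) -> list[CandidateDataset]:
    """Pool rows that share a ``merge_key`` (same location, split across references).

    Counts are summed; the merged id joins constituent ids with '+', and the
    reference ids likewise.  Rows without a merge key pass through unchanged,
    in input order.  Mixing prenatal and secondary ratios within one merge
    group is an error.
    """
    merged: list[CandidateDataset] = []
    seen: dict[str, int] = {}
    groups: dict[str, list[CandidateDataset]] = {}
    order: list[tuple[str, CandidateDataset]] = []
    for row in table:
        if row.merge_key is None:
            order.append(("pass", row))
        else:
            if row.merge_key not in groups:
                order.append(("group", row))
            groups.setdefault(row.merge_key, []).append(row)
    for kind, row in order:
        if kind == "pass":
            merged.append(row)
            continue
        members = groups[row.merge_key]
        if len(members) == 1:
            merged.append(members[0])
            continue
        types = {m.ratio_type for m in members}
        if len(types) > 1:
            raise ValueError(
                f"merge group {row.merge_key!r} mixes ratio types {sorted(types)}"
            )
        counts = SexRatioCount(
            n_female=sum(m.counts.n_female for m in members),
            n_male=sum(m.counts.n_male for m in members),
        )
        ages = [m.max_offspring_age_days for m in members if m.max_offspring_age_days is not None]
        merged.append(
            replace(
                members[0],
                id="+".join(m.id for m in members),
                reference_id="+".join(dict.fromkeys(m.reference_id for m in members)),
                counts=counts,
                max_offspring_age_days=max(ages) if ages else None,
                merge_key=None,
            )
        )
    return merged
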