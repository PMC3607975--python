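"""Deterministic match-code linkage of the two registry populations.

The match code is the five-component key shared by both registries —
hospital code, admission date, discharge date, age in years, and sex —
compared with exact equality and no tolerance (an ad-hoc deterministic
linkage).  Before joining, each registry is checked for within-registry
duplicates: every member of a key-sharing group is excluded, because the
registries are anonymous and no row can be declared authoritative.  After
deduplication keys are unique per side, so the join is one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Tuple, Union

from ._rounding import percent
from .filters import FilterStage, StageName
from .records import PirRecord, RegistryRecord, RegistryTable, Sex, TrRecord, derive_age

__all__ = [
    "MatchKey",
    "NonLinkable",
    "LinkedRecord",
    "LinkResult",
    "FunnelReport",
    "build_match_key",
    "find_duplicates",
    "link",
    "compute_funnel",
]


@dataclass(frozen=True)
class MatchKey:
    """The deterministic five-component linkage key; equality is exact."""

    hospital_code: str
    admission_date: date
    discharge_date: date
    age_years: int
    sex: Sex

    def sort_tuple(self) -> tuple:
        return (
            self.hospital_code,
            self.admission_date.toordinal(),
            self.discharge_date.toordinal(),
            self.age_years,
            self.sex.value,
        )


@dataclass(frozen=True)
class NonLinkable:
    """Signal that a record cannot produce a complete match key."""

    record_id: str
    missing: tuple  # names of the missing/unusable key components


@dataclass
class LinkedRecord:
    """A merged PIR+TR pair; both source records are kept in full."""

    match_key: MatchKey
    pir: PirRecord
    tr: TrRecord


@dataclass
class LinkResult:
    linked: List[LinkedRecord]
    unmatched_pir: List[RegistryRecord]
    unmatched_tr: List[RegistryRecord]
    duplicate_groups_pir: List[List[str]]
    duplicate_groups_tr: List[List[str]]
    non_linkable_pir: List[NonLinkable]
    non_linkable_tr: List[NonLinkable]

    @property
    def duplicates_removed_pir(self) -> int:
        return sum(len(g) for g in self.duplicate_groups_pir)

    @property
    def duplicates_removed_tr(self) -> int:
        return sum(len(g) for g in self.duplicate_groups_tr)

    @property
    def duplicates_removed(self) -> int:
        return self.duplicates_removed_pir + self.duplicates_removed_tr


def build_match_key(record: RegistryRecord) -> Union[MatchKey, NonLinkable]:
    """Build the match key, or report which components are missing.

    Age is resolved through :func:`derive_age` when only a birthdate was
    recorded; unknown sex makes the record non-linkable (not an error).
    The key ignores all clinical payload by construction.
    """
    missing = []
    if record.hospital_code is None:
        missing.append("hospital_code")
    if record.admission_date is None:
        missing.append("admission_date")
    if record.discharge_date is None:
        missing.append("discharge_date")
    age = derive_age(record)
    if age is None:
        missing.append("age_years")
    if record.sex is Sex.UNKNOWN:
        missing.append("sex")
    if missing:
        return NonLinkable(record.record_id, tuple(missing))
    return MatchKey(
        hospital_code=record.hospital_code,
        admission_date=record.admission_date,
        discharge_date=record.discharge_date,
        age_years=age,
        sex=record.sex,
    )


def _key_index(table: RegistryTable):
    """(key -> [records], non-linkable signals) for one registry table."""
    by_key: Dict[MatchKey, List[RegistryRecord]] = {}
    non_linkable: List[NonLinkable] = []
    for rec in table.records:
        key = build_match_key(rec)
        if isinstance(key, NonLinkable):
            non_linkable.append(key)
        else:
            by_key.setdefault(key, []).append(rec)
    return by_key, non_linkable


def find_duplicates(table: RegistryTable) -> List[List[str]]:
    """Groups of record_ids sharing one match key within a registry."""
    by_key, _ = _key_index(table)
    groups = [
        [rec.record_id for rec in recs] for recs in by_key.values() if len(recs) >= 2
    ]
    groups.sort(key=lambda g: g[0])
    return groups


def link(pir: RegistryTable, tr: RegistryTable) -> LinkResult:
    """One-to-one deterministic join after within-registry deduplication.

    Deterministic and independent of input row order: the linked list is
    sorted by match key.
    """
    pir_index, nl_pir = _key_index(pir)
    tr_index, nl_tr = _key_index(tr)

    dup_pir = [
        [r.record_id for r in recs] for recs in pir_index.values() if len(recs) >= 2
    ]
    dup_tr = [[r.record_id for r in recs] for recs in tr_index.values() if len(recs) >= 2]
    dup_pir.sort(key=lambda g: g[0])
    dup_tr.sort(key=lambda g: g[0])

    pir_unique = {k: recs[0] for k, recs in pir_index.items() if len(recs) == 1}
    tr_unique = {k: recs[0] for k, recs in tr_index.items() if len(recs) == 1}

    shared = sorted(set(pir_unique) & set(tr_unique), key=MatchKey.sort_tuple)
    linked = [LinkedRecord(k, pir_unique[k], tr_unique[k]) for k in shared]
    shared_set = set(shared)
    unmatched_pir = [r for k, r in pir_unique.items() if k not in shared_set]
    unmatched_tr = [r for k, r in tr_unique.items() if k not in shared_set]
    unmatched_pir.sort(key=lambda r: r.record_id)
    unmatched_tr.sort(key=lambda r: r.record_id)

    return LinkResult(
        linked=linked,
        unmatched_pir=unmatched_pir,
        unmatched_tr=unmatched_tr,
        duplicate_groups_pir=dup_pir,
        duplicate_groups_tr=dup_tr,
        non_linkable_pir=nl_pir,
        non_linkable_tr=nl_tr,
    )


@dataclass
class FunnelReport:
    """Stage-by-stage record counts and the final linkage rates."""

    stages: List[FilterStage]
    duplicates_removed: int
    non_linkable_pir: int
    non_linkable_tr: int
    linked_count: int
    linkage_rate_pir: float  # percent, one decimal, half-up
    linkage_rate_tr: float

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name.value, "pir": s.pir_count, "tr": s.tr_count}
                for s in self.stages
            ],
            "duplicates_removed": self.duplicates_removed,
            "non_linkable": {"PIR": self.non_linkable_pir, "TR": self.non_linkable_tr},
            "linked_count": self.linked_count,
            "linkage_rate_pir": self.linkage_rate_pir,
            "linkage_rate_tr": self.linkage_rate_tr,
        }


def compute_funnel(
    stages: List[FilterStage],
    duplicates_removed: int,
    linked_count: int,
    non_linkable_pir: int = 0,
    non_linkable_tr: int = 0,
) -> FunnelReport:
    """Assemble the funnel; rates are 100·linked/eligible-after-cascade.

    The eligible denominators are the counts at the last cascade stage
    (year overlap), before deduplication — linkage rates describe how much
    of the eligible population the match code recovered.
    """
    if not stages:
        raise ValueError("funnel needs at least one stage")
    eligible = next(
        (s for s in stages if s.name is StageName.OVERLAPPING_YEARS), stages[-1]
    )
    eligible_pir = eligible.pir_count
    eligible_tr = eligible.tr_count
    if linked_count > 0 and (eligible_pir == 0 or eligible_tr == 0):
        raise ValueError("linked records with an empty eligible population")
    rate_pir = percent(linked_count, eligible_pir, 1) if eligible_pir else 0.0
    rate_tr = percent(linked_count, eligible_tr, 1) if eligible_tr else 0.0
    return FunnelReport(
        stages=list(stages),
        duplicates_removed=duplicates_removed,
        non_linkable_pir=non_linkable_pir,
        non_linkable_tr=non_linkable_tr,
        linked_count=linked_count,
        linkage_rate_pir=rate_pir,
        linkage_rate_tr=rate_tr,
    )
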