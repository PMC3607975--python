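"""Eligibility cascade reducing both registries to the linkable populations.

The cascade mirrors how two national registries with different inclusion
criteria are narrowed to the populations that could plausibly contain the
same patients: (1) keep only hospitals contributing to both registries,
(2) keep only trauma-registry cases carrying a pelvic fracture AIS code
(856xxx.x in AIS-1998), (3) keep only records from hospital-years in which
both registries actually received data.

All filters are pure: outputs are subsets of inputs, order is preserved,
and applying a filter twice equals applying it once.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

from .records import AIS_CODE_RE, Registry, RegistryTable, TrRecord

__all__ = [
    "StageName",
    "FilterStage",
    "AisFormatError",
    "RegistryKindError",
    "is_pelvic_ais",
    "filter_pelvic",
    "restrict_common_hospitals",
    "restrict_overlapping_years",
]

#: AIS-1998 pre-dot prefix denoting pelvic ring and acetabular fractures.
PELVIC_AIS_PREFIX = "856"


class StageName(str, Enum):
    INITIAL = "initial"
    COMMON_HOSPITALS = "common_hospitals"
    PELVIC_AIS = "pelvic_ais"
    OVERLAPPING_YEARS = "overlapping_years"
    LINKABLE_KEY = "linkable_key"


@dataclass(frozen=True)
class FilterStage:
    """Record counts per registry at one stage of the funnel."""

    name: StageName
    pir_count: int
    tr_count: int

    def __post_init__(self) -> None:
        if self.pir_count < 0 or self.tr_count < 0:
            raise ValueError("stage counts must be non-negative")


class AisFormatError(ValueError):
    """An AIS code does not match the 'dddddd.d' format."""


class RegistryKindError(TypeError):
    """A table of the wrong registry dialect was passed to a filter."""


def is_pelvic_ais(code: str) -> bool:
    """True iff ``code`` denotes a pelvic ring or acetabular fracture."""
    if not AIS_CODE_RE.match(code):
        raise AisFormatError(f"malformed AIS code: {code!r}")
    return code.startswith(PELVIC_AIS_PREFIX)


def filter_pelvic(tr: RegistryTable) -> RegistryTable:
    """Retain TR records carrying at least one pelvic AIS code."""
    if tr.registry_id is not Registry.TR:
        raise RegistryKindError("filter_pelvic expects a TR table")
    kept = []
    for rec in tr.records:
        codes = rec.ais_codes if isinstance(rec, TrRecord) else []
        if any(is_pelvic_ais(code) for code in codes):
            kept.append(rec)
    return tr.subset(kept)


def restrict_common_hospitals(
    pir: RegistryTable, tr: RegistryTable
) -> Tuple[RegistryTable, RegistryTable, set]:
    """Restrict both tables to hospitals contributing to both registries.

    Records with a missing hospital code cannot establish membership and are
    excluded.  Returns the restricted tables and the shared hospital-code set.
    """
    pir_hospitals = {r.hospital_code for r in pir.records if r.hospital_code is not None}
    tr_hospitals = {r.hospital_code for r in tr.records if r.hospital_code is not None}
    shared = pir_hospitals & tr_hospitals
    pir_out = pir.subset([r for r in pir.records if r.hospital_code in shared])
    tr_out = tr.subset([r for r in tr.records if r.hospital_code in shared])
    return pir_out, tr_out, shared


def _contribution_cell(rec):
    if rec.hospital_code is None or rec.admission_date is None:
        return None
    return (rec.hospital_code, rec.admission_date.year)


def restrict_overlapping_years(
    pir: RegistryTable, tr: RegistryTable
) -> Tuple[RegistryTable, RegistryTable]:
    """Keep records whose (hospital, admission-year) cell has data on both sides.

    The contribution year is the admission year; a cell overlaps when each
    registry holds at least one record in it.  Records missing hospital code
    or admission date cannot be placed in a cell and are excluded.
    """
    pir_cells = {c for c in (_contribution_cell(r) for r in pir.records) if c is not None}
    tr_cells = {c for c in (_contribution_cell(r) for r in tr.records) if c is not None}
    overlap = pir_cells & tr_cells
    pir_out = pir.subset([r for r in pir.records if _contribution_cell(r) in overlap])
    tr_out = tr.subset([r for r in tr.records if _contribution_cell(r) in overlap])
    return pir_out, tr_out
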