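"""Domain types for anonymous trauma-registry records.

Two registry dialects are modelled: a pelvic-injury register (PIR dialect,
carrying the Tile/OTA fracture class and a complex-pelvic-injury flag) and a
multiple-trauma register (TR dialect, carrying AIS-1998 injury codes).  Both
share the anonymous master data that the deterministic match code is built
from: hospital code, admission and discharge dates, age (or birthdate) and
sex, plus the clinical payload used in the concordance analysis (ISS, initial
haemoglobin, initial systolic blood pressure, vital status).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "Registry",
    "Sex",
    "VitalStatus",
    "TileClass",
    "RegistryRecord",
    "PirRecord",
    "TrRecord",
    "RegistryTable",
    "AIS_CODE_RE",
    "validate_record",
    "derive_age",
]

#: AIS-1998 numeric injury identifier: six digits, a dot, one severity digit.
AIS_CODE_RE = re.compile(r"^\d{6}\.\d$")


class Registry(str, Enum):
    PIR = "PIR"
    TR = "TR"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class VitalStatus(str, Enum):
    ALIVE = "alive"
    DEAD = "dead"
    MISSING = "missing"


class TileClass(str, Enum):
    """Tile/OTA pelvic ring fracture classification.

    A: stable; B: rotationally unstable; C: rotationally and translationally
    unstable; isolated acetabular and/or sacrum fractures are kept as their
    own category, as registries report them alongside the ring classes.
    """

    A = "A"
    B = "B"
    C = "C"
    ACETABULUM_SACRUM_ISOLATED = "acetabulum_sacrum_isolated"
    MISSING = "missing"


@dataclass
class RegistryRecord:
    """One anonymous patient row from either registry."""

    registry_id: Registry
    record_id: str
    hospital_code: Optional[str]
    admission_date: Optional[date]
    discharge_date: Optional[date]
    age_years: Optional[int] = None
    birthdate: Optional[date] = None
    sex: Sex = Sex.UNKNOWN
    vital_status: VitalStatus = VitalStatus.MISSING
    iss: Optional[int] = None
    initial_hb: Optional[float] = None
    initial_sbp: Optional[float] = None
    #: registry-specific fields carried opaquely (e.g. GCS, PRBC, SAPS II);
    #: never computed on, but preserved through I/O and merging.
    payload: dict = field(default_factory=dict)


@dataclass
class PirRecord(RegistryRecord):
    tile_class: TileClass = TileClass.MISSING
    complex_pelvic_injury: Optional[bool] = None

    def __post_init__(self) -> None:
        self.registry_id = Registry.PIR


@dataclass
class TrRecord(RegistryRecord):
    ais_codes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.registry_id = Registry.TR


def validate_record(rec: RegistryRecord) -> list:
    """Return the list of invariant violations for ``rec`` (empty if valid)."""
    problems: list = []
    if rec.admission_date is not None and rec.discharge_date is not None:
        if rec.discharge_date < rec.admission_date:
            problems.append("date order: discharge_date before admission_date")
    if rec.age_years is not None and rec.age_years < 0:
        problems.append("age_years negative")
    if rec.iss is not None and not (1 <= rec.iss <= 75):
        problems.append("iss outside [1, 75]")
    if rec.initial_hb is not None and rec.initial_hb < 0:
        problems.append("initial_hb negative")
    if rec.initial_sbp is not None and rec.initial_sbp < 0:
        problems.append("initial_sbp negative")
    if rec.birthdate is not None and rec.admission_date is not None:
        if rec.birthdate > rec.admission_date:
            problems.append("birthdate after admission_date")
    if isinstance(rec, TrRecord):
        for code in rec.ais_codes:
            if not AIS_CODE_RE.match(code):
                problems.append(f"malformed AIS code: {code!r}")
    return problems


@dataclass
class RegistryTable:
    """An ordered collection of records from a single registry."""

    registry_id: Registry
    records: list
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.registry_id != self.registry_id:
                raise ValueError(
                    f"record {rec.record_id} has registry {rec.registry_id}, "
                    f"table is {self.registry_id}"
                )
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[RegistryRecord]:
        return iter(self.records)

    def subset(self, records: list) -> "RegistryTable":
        """A new table over ``records`` (must be drawn from this table)."""
        return RegistryTable(self.registry_id, list(records), self.source_path)


def derive_age(rec: RegistryRecord, reference: Optional[date] = None) -> Optional[int]:
    """Age in completed years at ``reference`` (default: admission date).

    If the registry stored an age it is returned unchanged; otherwise the age
    is derived from the birthdate as the floor of completed calendar years.
    Returns None when neither age nor birthdate is recorded.
    """
    if rec.age_years is not None:
        return rec.age_years
    if rec.birthdate is None:
        return None
    if reference is None:
        reference = rec.admission_date
    if reference is None:
        return None
    if rec.birthdate > reference:
        raise ValueError(
            f"record {rec.record_id}: birthdate {rec.birthdate} after reference {reference}"
        )
    years = reference.year - rec.birthdate.year
    if (reference.month, reference.day) < (rec.birthdate.month, rec.birthdate.day):
        years -= 1
    return years
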