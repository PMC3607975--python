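"""Delimited-text readers and writers for both registry dialects.

Registry extracts arrive as CSV exports whose column names differ per site;
a :class:`SchemaConfig` maps the logical fields onto the export's columns,
fixes the date dialect (ISO ``YYYY-MM-DD`` or German ``DD.MM.YYYY``), the
sex coding, and the delimiter used inside the AIS-code list cell.

Reading is total: every input row is either accepted into the returned
table or reported in the row-indexed reject diagnostics, never dropped
silently.  Missing numeric values are empty cells — never sentinel numbers —
so that completion rates can distinguish missing from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .records import (
    PirRecord,
    Registry,
    RegistryRecord,
    RegistryTable,
    Sex,
    TileClass,
    TrRecord,
    VitalStatus,
    validate_record,
)

__all__ = [
    "SchemaConfig",
    "SchemaError",
    "RowReject",
    "ReadResult",
    "read_registry_csv",
    "write_registry_csv",
]


class SchemaError(ValueError):
    """The file's header does not satisfy the schema configuration."""


#: logical fields every extract must provide.
REQUIRED_FIELDS = ("record_id", "hospital_code", "admission_date", "discharge_date", "sex")

#: optional logical fields shared by both dialects.
OPTIONAL_FIELDS = (
    "age_years",
    "birthdate",
    "vital_status",
    "iss",
    "initial_hb",
    "initial_sbp",
)

PIR_FIELDS = ("tile_class", "complex_pelvic_injury")
TR_FIELDS = ("ais_codes",)

DEFAULT_SEX_MAP = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "männlich": Sex.MALE,
    "maennlich": Sex.MALE,
    "f": Sex.FEMALE,
    "w": Sex.FEMALE,
    "female": Sex.FEMALE,
    "weiblich": Sex.FEMALE,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}

_VITAL_MAP = {
    "alive": VitalStatus.ALIVE,
    "dead": VitalStatus.DEAD,
    "deceased": VitalStatus.DEAD,
    "": VitalStatus.MISSING,
    "missing": VitalStatus.MISSING,
}

_TILE_MAP = {
    "a": TileClass.A,
    "b": TileClass.B,
    "c": TileClass.C,
    "acetabulum_sacrum_isolated": TileClass.ACETABULUM_SACRUM_ISOLATED,
    "": TileClass.MISSING,
    "missing": TileClass.MISSING,
}

_BOOL_MAP = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


@dataclass
class SchemaConfig:
    """Column-name mapping and value dialects for one registry export."""

    #: logical field -> column name in the file; identity by default.
    columns: dict = dc_field(default_factory=dict)
    #: "iso" (YYYY-MM-DD) or "dmy" (DD.MM.YYYY, German registry exports).
    date_format: str = "iso"
    #: delimiter between AIS codes inside the list cell.
    list_delimiter: str = ";"
    #: raw cell value (lower-cased) -> canonical sex.
    sex_map: dict = dc_field(default_factory=lambda: dict(DEFAULT_SEX_MAP))
    #: carry unmapped columns into the record payload.
    payload_passthrough: bool = True

    def column(self, logical: str) -> str:
        return self.columns.get(logical, logical)

    @classmethod
    def from_yaml(cls, path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sex_map = dict(DEFAULT_SEX_MAP)
        for key, value in (raw.get("sex_map") or {}).items():
            sex_map[str(key).lower()] = Sex(value)
        return cls(
            columns=dict(raw.get("columns") or {}),
            date_format=raw.get("date_format", "iso"),
            list_delimiter=raw.get("list_delimiter", ";"),
            sex_map=sex_map,
            payload_passthrough=bool(raw.get("payload_passthrough", True)),
        )


@dataclass
class RowReject:
    row_index: int  # 0-based data-row index (header excluded)
    record_id: Optional[str]
    reason: str


@dataclass
class ReadResult:
    table: RegistryTable
    rejects: list

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def _parse_date(cell: str, fmt: str) -> Optional[date]:
    cell = cell.strip()
    if not cell:
        return None
    pattern = "%Y-%m-%d" if fmt == "iso" else "%d.%m.%Y"
    return datetime.strptime(cell, pattern).date()


def _parse_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def _parse_int(cell: str) -> Optional[int]:
    cell = cell.strip()
    return int(cell) if cell else None


def read_registry_csv(
    path,
    registry_id: Registry,
    schema_config: Optional[SchemaConfig] = None,
) -> ReadResult:
    """Read and validate one registry extract.

    Rows violating type or domain invariants are collected as
    :class:`RowReject` diagnostics; accepted + rejected always equals the
    number of data rows in the file.
    """
    schema = schema_config or SchemaConfig()
    registry_id = Registry(registry_id)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)

    logical_fields = REQUIRED_FIELDS + OPTIONAL_FIELDS + (
        PIR_FIELDS if registry_id is Registry.PIR else TR_FIELDS
    )
    for logical in REQUIRED_FIELDS:
        if schema.column(logical) not in frame.columns:
            raise SchemaError(
                f"missing required column {schema.column(logical)!r} (field {logical!r})"
            )
    mapped = {schema.column(f) for f in logical_fields if schema.column(f) in frame.columns}
    payload_columns = [c for c in frame.columns if c not in mapped]

    records: list = []
    rejects: list = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        cells = dict(zip(frame.columns, row))

        def cell(logical: str) -> str:
            name = schema.column(logical)
            return cells.get(name, "")

        record_id = cell("record_id").strip() or None
        try:
            if record_id is None:
                raise ValueError("empty record_id")
            common = dict(
                registry_id=registry_id,
                record_id=record_id,
                hospital_code=cell("hospital_code").strip() or None,
                admission_date=_parse_date(cell("admission_date"), schema.date_format),
                discharge_date=_parse_date(cell("discharge_date"), schema.date_format),
                age_years=_parse_int(cell("age_years")),
                birthdate=_parse_date(cell("birthdate"), schema.date_format),
                sex=schema.sex_map[cell("sex").strip().lower()],
                vital_status=_VITAL_MAP[cell("vital_status").strip().lower()],
                iss=_parse_int(cell("iss")),
                initial_hb=_parse_float(cell("initial_hb")),
                initial_sbp=_parse_float(cell("initial_sbp")),
            )
            if schema.payload_passthrough:
                common["payload"] = {
                    c: cells[c] for c in payload_columns if cells[c].strip() != ""
                }
            if registry_id is Registry.PIR:
                rec: RegistryRecord = PirRecord(
                    **common,
                    tile_class=_TILE_MAP[cell("tile_class").strip().lower()],
                    complex_pelvic_injury=_BOOL_MAP.get(
                        cell("complex_pelvic_injury").strip().lower()
                    ),
                )
            else:
                raw_codes = cell("ais_codes").strip()
                codes = (
                    [c.strip() for c in raw_codes.split(schema.list_delimiter) if c.strip()]
                    if raw_codes
                    else []
                )
                rec = TrRecord(**common, ais_codes=codes)
        except KeyError as exc:
            rejects.append(RowReject(idx, record_id, f"unrecognised coded value: {exc}"))
            continue
        except ValueError as exc:
            rejects.append(RowReject(idx, record_id, str(exc)))
            continue

        problems = validate_record(rec)
        if problems:
            rejects.append(RowReject(idx, record_id, "; ".join(problems)))
        else:
            records.append(rec)

    table = RegistryTable(registry_id, records, source_path=str(path))
    return ReadResult(table=table, rejects=rejects)


def _fmt_date(value: Optional[date]) -> str:
    return value.isoformat() if value is not None else ""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_registry_csv(table: RegistryTable, path) -> None:
    """Write ``table`` in the canonical dialect (ISO dates, ';' code lists).

    Round-trip law: reading the written file with the default schema
    reproduces the table field-for-field, including missing values.
    """
    base_cols = list(REQUIRED_FIELDS + OPTIONAL_FIELDS)
    extra_cols = list(PIR_FIELDS if table.registry_id is Registry.PIR else TR_FIELDS)
    payload_cols = sorted({key for rec in table.records for key in rec.payload})
    payload_cols = [c for c in payload_cols if c not in set(base_cols + extra_cols)]

    rows = []
    for rec in table.records:
        row = {
            "record_id": rec.record_id,
            "hospital_code": _fmt(rec.hospital_code),
            "admission_date": _fmt_date(rec.admission_date),
            "discharge_date": _fmt_date(rec.discharge_date),
            "age_years": _fmt(rec.age_years),
            "birthdate": _fmt_date(rec.birthdate),
            "sex": rec.sex.value if rec.sex is not Sex.UNKNOWN else "",
            "vital_status": (
                rec.vital_status.value if rec.vital_status is not VitalStatus.MISSING else ""
            ),
            "iss": _fmt(rec.iss),
            "initial_hb": _fmt(rec.initial_hb),
            "initial_sbp": _fmt(rec.initial_sbp),
        }
        if isinstance(rec, PirRecord):
            row["tile_class"] = (
                rec.tile_class.value if rec.tile_class is not TileClass.MISSING else ""
            )
            row["complex_pelvic_injury"] = _fmt(rec.complex_pelvic_injury)
        elif isinstance(rec, TrRecord):
            row["ais_codes"] = ";".join(rec.ais_codes)
        for col in payload_cols:
            row[col] = _fmt(rec.payload.get(col))
        rows.append(row)

    frame = pd.DataFrame(rows, columns=base_cols + extra_cols + payload_cols)
    frame.to_csv(path, index=False)
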