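"""Deterministic twin-registry instance reproducing the published funnel.

The real registries behind the worked example are confidential, so this
module emits a synthetic instance constructed top-down from the published
stage counts: 4,323 pelvic-registry and 34,134 trauma-registry records, of
which 3,329 / 1,974 lie in the 19 hospitals contributing to both registries
(the trauma-registry arm restricted to 856xxx.x pelvic AIS codes),
2,671 / 947 fall in overlapping hospital-years, and — after exclusion of 10
planted within-registry duplicate rows — exactly 420 cross-registry pairs
share a match code, spread over 15 hospitals.  The linked cohort's clinical
fields reproduce the published cohort description (42 deaths, 77 complex
pelvic injuries, Tile mix 83/124/153/60, blood-pressure/haemoglobin
completion 73 of 420 on the pelvic side and 375/400 of 420 on the trauma
side).

Counts are allocated to hospital×year cells first and records emitted
second; within a cell each record's admission day is unique per registry
side and the per-side day ranges are disjoint, so match keys collide exactly
where planted and nowhere else.  All randomness (clinical values, attribute
permutations) comes from one fixed-seed generator, making the fixture
byte-reproducible.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import (
    PirRecord,
    Registry,
    RegistryTable,
    Sex,
    TileClass,
    TrRecord,
    VitalStatus,
)
from .synthetic import GroundTruth, _OTHER_AIS, _PELVIC_AIS, _TILE_ORDER

__all__ = ["FIXTURE_SEED", "paper_funnel_fixture"]

FIXTURE_SEED = 20130305

_SHARED_HOSPITALS = [f"H{i + 1:03d}" for i in range(19)]
_LINK_HOSPITALS = _SHARED_HOSPITALS[:15]
_PIR_ONLY_HOSPITALS = [f"P{i + 1:02d}" for i in range(12)]
_TR_ONLY_HOSPITALS = [f"H{i + 1:03d}" for i in range(19, 242)]
_OVERLAP_YEARS = (2004, 2005, 2006, 2007)

# per-cell admission-day offsets: linked pairs 0.., pelvic-registry rows
# 1000.., trauma-registry rows 2000.., extra blocks 2500.. — modulo 360 these
# land in disjoint day ranges as long as no cell holds more than ~60 rows.
_C_LINKED = 0
_C_PIR = 1000
_C_PIR_DUP = 1100
_C_TR = 2000
_C_TR_DUP = 2150
_C_TR_NONPELVIC = 2500


def _adm(year: int, c: int) -> date:
    return date(year, 1, 1) + timedelta(days=c % 360)


def _dis(admission: date, c: int) -> date:
    return admission + timedelta(days=3 + (c % 30))


def _sex(c: int) -> Sex:
    return Sex.MALE if c % 2 == 0 else Sex.FEMALE


def _spread(total: int, n_cells: int) -> List[int]:
    base, rem = divmod(total, n_cells)
    return [base + (1 if i < rem else 0) for i in range(n_cells)]


class _Builder:
    def __init__(self) -> None:
        self.rng = np.random.default_rng(FIXTURE_SEED)
        self.pir: List[PirRecord] = []
        self.tr: List[TrRecord] = []
        self.entries: Dict[int, Tuple[Optional[str], Optional[str]]] = {}
        self.duplicates: List[Tuple[str, str, int]] = []
        self.record_to_truth: Dict[Tuple[str, str], int] = {}
        self._truth_i = 0

    def _truth(self, pir_id: Optional[str], tr_id: Optional[str]) -> int:
        i = self._truth_i
        self._truth_i += 1
        self.entries[i] = (pir_id, tr_id)
        if pir_id is not None:
            self.record_to_truth[("PIR", pir_id)] = i
        if tr_id is not None:
            self.record_to_truth[("TR", tr_id)] = i
        return i

    def _clinical(self):
        rng = self.rng
        age = int(np.clip(round(rng.normal(41.6, 19.5)), 16, 95))
        iss = int(np.clip(round(rng.normal(27.0, 13.0)), 1, 75))
        hb = round(max(0.1, rng.normal(8.6, 2.9)), 1)
        bp = float(max(30, round(rng.normal(99.0, 19.0))))
        return age, iss, hb, bp

    def add_pir(
        self,
        hospital: str,
        year: int,
        c: int,
        *,
        age: Optional[int] = None,
        iss: Optional[int] = None,
        hb: Optional[float] = None,
        bp: Optional[float] = None,
        dead: Optional[bool] = None,
        tile: Optional[TileClass] = None,
        is_complex: Optional[bool] = None,
        record_id: Optional[str] = None,
        register_truth: bool = True,
    ) -> PirRecord:
        rng = self.rng
        d_age, d_iss, d_hb, d_bp = self._clinical()
        if age is None:
            age = d_age
        if iss is None:
            iss = d_iss
        if dead is None:
            dead = bool(rng.random() < 0.10)
        if tile is None:
            tile = _TILE_ORDER[int(rng.choice(4, p=(0.198, 0.295, 0.364, 0.143)))]
        if is_complex is None:
            is_complex = bool(rng.random() < 0.183)
        admission = _adm(year, c)
        rec = PirRecord(
            registry_id=Registry.PIR,
            record_id=record_id or f"P{len(self.pir):06d}",
            hospital_code=hospital,
            admission_date=admission,
            discharge_date=_dis(admission, c),
            age_years=age,
            sex=_sex(c),
            vital_status=VitalStatus.DEAD if dead else VitalStatus.ALIVE,
            iss=iss,
            initial_hb=hb,
            initial_sbp=bp,
            payload={"prbc": str(int(rng.integers(0, 12)))},
            tile_class=tile,
            complex_pelvic_injury=is_complex,
        )
        self.pir.append(rec)
        if register_truth:
            self._truth(rec.record_id, None)
        return rec

    def add_tr(
        self,
        hospital: str,
        year: int,
        c: int,
        *,
        pelvic: bool = True,
        age: Optional[int] = None,
        iss: Optional[int] = None,
        hb: Optional[float] = None,
        bp: Optional[float] = None,
        dead: Optional[bool] = None,
        mechanism: Optional[str] = None,
        record_id: Optional[str] = None,
        register_truth: bool = True,
    ) -> TrRecord:
        rng = self.rng
        d_age, d_iss, _, _ = self._clinical()
        if age is None:
            age = d_age
        if iss is None:
            iss = d_iss
        if dead is None:
            dead = bool(rng.random() < 0.10)
        if pelvic:
            codes = [str(rng.choice(_PELVIC_AIS)), str(rng.choice(_OTHER_AIS))]
        else:
            codes = [str(rng.choice(_OTHER_AIS))]
        admission = _adm(year, c)
        rec = TrRecord(
            registry_id=Registry.TR,
            record_id=record_id or f"T{len(self.tr):06d}",
            hospital_code=hospital,
            admission_date=admission,
            discharge_date=_dis(admission, c),
            age_years=age,
            sex=_sex(c),
            vital_status=VitalStatus.DEAD if dead else VitalStatus.ALIVE,
            iss=iss,
            initial_hb=hb,
            initial_sbp=bp,
            payload={"mechanism": mechanism or "blunt"},
            ais_codes=codes,
        )
        self.tr.append(rec)
        if register_truth:
            self._truth(None, rec.record_id)
        return rec


def paper_funnel_fixture() -> Tuple[RegistryTable, RegistryTable, GroundTruth]:
    """The fixed-seed twin-registry instance behind the worked example."""
    b = _Builder()
    rng = b.rng

    # ------------------------------------------------------- linked cohort
    # 420 pairs over 15 hospitals x 4 overlap years, 7 per cell; attributes
    # are assigned through a fixed permutation so clinical structure does not
    # correlate with hospital or year.
    perm = rng.permutation(420)
    tr_bp_missing = set(rng.choice(np.arange(73, 420), size=45, replace=False).tolist())
    tr_hb_missing = set(rng.choice(np.arange(73, 420), size=20, replace=False).tolist())
    penetrating = set(rng.choice(np.arange(73, 420), size=4, replace=False).tolist())
    tile_by_rank = (
        [TileClass.A] * 83
        + [TileClass.B] * 124
        + [TileClass.C] * 153
        + [TileClass.ACETABULUM_SACRUM_ISOLATED] * 60
    )

    j = 0
    for hospital in _LINK_HOSPITALS:
        for year in _OVERLAP_YEARS:
            for c in range(_C_LINKED, _C_LINKED + 7):
                rank = int(perm[j])
                age, iss, hb, bp = b._clinical()
                dead = rank < 42
                is_complex = rank < 77
                pir_complete = rank < 73
                iss_tr = int(np.clip(iss + round(rng.normal(0.0, 9.166)), 1, 75))
                hb_tr = round(max(0.1, hb + rng.normal(1.0, 1.5)), 1)
                bp_tr = float(max(30, round(bp + rng.normal(9.0, 20.0))))
                pir_rec = b.add_pir(
                    hospital,
                    year,
                    c,
                    age=age,
                    iss=iss,
                    hb=hb if pir_complete else None,
                    bp=bp if pir_complete else None,
                    dead=dead,
                    tile=tile_by_rank[rank],
                    is_complex=is_complex,
                    register_truth=False,
                )
                tr_rec = b.add_tr(
                    hospital,
                    year,
                    c,
                    age=age,
                    iss=iss_tr,
                    hb=None if rank in tr_hb_missing else hb_tr,
                    bp=None if rank in tr_bp_missing else bp_tr,
                    dead=dead,
                    mechanism="penetrating" if rank in penetrating else "blunt",
                    register_truth=False,
                )
                b._truth(pir_rec.record_id, tr_rec.record_id)
                j += 1

    overlap_cells = [(h, y) for h in _SHARED_HOSPITALS for y in _OVERLAP_YEARS]

    # ------------------------------------- planted within-registry duplicates
    # 3 pelvic-registry pairs + 2 trauma-registry pairs = 10 rows excluded.
    for hospital in ("H016", "H017", "H018"):
        first = b.add_pir(hospital, 2004, _C_PIR_DUP, register_truth=False)
        dup = b.add_pir(
            hospital,
            2004,
            _C_PIR_DUP,
            age=first.age_years,
            register_truth=False,
            record_id=f"P{len(b.pir):06d}",
        )
        i = b._truth(first.record_id, None)
        b.duplicates.append(("PIR", dup.record_id, i))
        b.record_to_truth[("PIR", dup.record_id)] = i
    for hospital in ("H016", "H017"):
        first = b.add_tr(hospital, 2005, _C_TR_DUP, register_truth=False)
        dup = b.add_tr(
            hospital,
            2005,
            _C_TR_DUP,
            age=first.age_years,
            register_truth=False,
            record_id=f"T{len(b.tr):06d}",
        )
        i = b._truth(None, first.record_id)
        b.duplicates.append(("TR", dup.record_id, i))
        b.record_to_truth[("TR", dup.record_id)] = i

    # ------------------------------------------ unmatched records, overlap cells
    for (hospital, year), count in zip(overlap_cells, _spread(2245, len(overlap_cells))):
        for k in range(count):
            present = rng.random() < 0.17
            age, iss, hb, bp = b._clinical()
            b.add_pir(
                hospital,
                year,
                _C_PIR + k,
                age=age,
                iss=iss,
                hb=hb if present else None,
                bp=bp if present else None,
            )
    for (hospital, year), count in zip(overlap_cells, _spread(523, len(overlap_cells))):
        for k in range(count):
            b.add_tr(hospital, year, _C_TR + k)

    # ------------------- pelvic-registry records in non-overlapping years (2008)
    for hospital, count in zip(_SHARED_HOSPITALS, _spread(658, len(_SHARED_HOSPITALS))):
        for k in range(count):
            b.add_pir(hospital, 2008, _C_PIR + k)

    # --------------------- trauma-registry pelvic records, TR-only years (2009)
    for hospital, count in zip(_SHARED_HOSPITALS, _spread(1027, len(_SHARED_HOSPITALS))):
        for k in range(count):
            b.add_tr(hospital, 2009, _C_TR + k)

    # -------------------- non-pelvic trauma cases in the shared hospitals
    for hospital in _SHARED_HOSPITALS:
        for k in range(10):
            b.add_tr(hospital, 2009, _C_TR_NONPELVIC + k, pelvic=False)

    # ------------------------------------------ pelvic-registry-only hospitals
    for hospital, count in zip(
        _PIR_ONLY_HOSPITALS, _spread(994, len(_PIR_ONLY_HOSPITALS))
    ):
        per_year = _spread(count, 6)
        for year, n_year in zip(range(2004, 2010), per_year):
            for k in range(n_year):
                b.add_pir(hospital, year, _C_PIR + k)

    # ------------------------------------------- trauma-registry-only hospitals
    filler = 0
    for hospital, count in zip(
        _TR_ONLY_HOSPITALS, _spread(31970, len(_TR_ONLY_HOSPITALS))
    ):
        per_year = _spread(count, 6)
        for year, n_year in zip(range(2004, 2010), per_year):
            for k in range(n_year):
                # most multiple-trauma cases carry no pelvic fracture code
                b.add_tr(hospital, year, _C_TR + k, pelvic=(filler % 7 == 0))
                filler += 1

    truth = GroundTruth(b.entries, b.duplicates, b.record_to_truth)
    return (
        RegistryTable(Registry.PIR, b.pir),
        RegistryTable(Registry.TR, b.tr),
        truth,
    )
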