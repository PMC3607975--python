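from datetime import date

import pytest

from traumalink import (
    PirRecord,
    Registry,
    RegistryTable,
    Sex,
    TileClass,
    TrRecord,
    VitalStatus,
    paper_funnel_fixture,
    run_pipeline,
)


def _d(iso: str) -> date:
    return date.fromisoformat(iso)


def make_pir(
    record_id="P1",
    hospital="H01",
    adm="2005-03-02",
    dis="2005-03-20",
    age=41,
    birthdate=None,
    sex=Sex.MALE,
    vital=VitalStatus.ALIVE,
    iss=27,
    hb=8.6,
    sbp=99.0,
    tile=TileClass.C,
    complex_injury=False,
    payload=None,
) -> PirRecord:
    return PirRecord(
        registry_id=Registry.PIR,
        record_id=record_id,
        hospital_code=hospital,
        admission_date=_d(adm) if adm else None,
        discharge_date=_d(dis) if dis else None,
        age_years=age,
        birthdate=_d(birthdate) if birthdate else None,
        sex=sex,
        vital_status=vital,
        iss=iss,
        initial_hb=hb,
        initial_sbp=sbp,
        payload=payload or {},
        tile_class=tile,
        complex_pelvic_injury=complex_injury,
    )


def make_tr(
    record_id="T1",
    hospital="H01",
    adm="2005-03-02",
    dis="2005-03-20",
    age=41,
    sex=Sex.MALE,
    vital=VitalStatus.ALIVE,
    iss=27,
    hb=9.6,
    sbp=108.0,
    ais=("856100.2",),
    payload=None,
) -> TrRecord:
    return TrRecord(
        registry_id=Registry.TR,
        record_id=record_id,
        hospital_code=hospital,
        admission_date=_d(adm) if adm else None,
        discharge_date=_d(dis) if dis else None,
        age_years=age,
        sex=sex,
        vital_status=vital,
        iss=iss,
        initial_hb=hb,
        initial_sbp=sbp,
        payload=payload or {},
        ais_codes=list(ais),
    )


def pir_table(records) -> RegistryTable:
    return RegistryTable(Registry.PIR, list(records))


def tr_table(records) -> RegistryTable:
    return RegistryTable(Registry.TR, list(records))


@pytest.fixture(scope="session")
def funnel_instance():
    """The fixed-seed worked-example registries (generated once per session)."""
    return paper_funnel_fixture()


@pytest.fixture(scope="session")
def funnel_report(funnel_instance):
    pir, tr, truth = funnel_instance
    return run_pipeline(pir, tr, truth=truth)
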