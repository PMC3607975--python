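"""Seeded generator of twin trauma registries with known ground truth.

Each simulated patient is drawn once with latent clinical values (age, sex,
ISS, initial haemoglobin and blood pressure, vital status, Tile class,
complex-injury flag) and then documented — or not — in each registry.  The
pelvic registry stores the latent values; the trauma registry stores them
with configurable entry discrepancies (integer-rounded Gaussian on ISS,
location-shifted Gaussians on haemoglobin and blood pressure), emulating
independent double data entry.  Key-field errors (a date shifted by ±k days
or age by ±1, at most one component per affected record), per-variable
missingness, within-registry duplication and per-hospital-per-year
contribution gaps make every pipeline stage non-trivial.

The generator is fully deterministic given its seed, and every emitted
record is registered in the returned :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
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
    derive_age,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TruthEvaluation",
    "generate",
    "evaluate_against_truth",
]

_PELVIC_AIS = ("856100.2", "856151.3", "856161.4", "856171.5", "856201.2")
_OTHER_AIS = ("450200.2", "854020.2", "140629.4", "441410.3", "816011.2")
_TILE_ORDER = (
    TileClass.A,
    TileClass.B,
    TileClass.C,
    TileClass.ACETABULUM_SACRUM_ISOLATED,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated pair of registries.

    Defaults emulate a six-year observation window of a national pelvic
    registry and a national multiple-trauma registry sharing a pool of
    hospitals: pelvic-registry enrolment is the rule (surgical focus) while
    trauma-registry enrolment requires ICU-level care and is therefore much
    rarer, producing the asymmetric linkage rates such registries report.
    """

    n_hospitals: int = 19
    years: Tuple[int, int] = (2004, 2009)
    n_true_patients: int = 3000
    p_in_pir: float = 0.80
    p_in_tr: float = 0.35
    #: probability a hospital contributed to a registry in a given year
    p_hospital_year_active_pir: float = 0.90
    p_hospital_year_active_tr: float = 0.90
    #: probability a TR-documented patient carries an 856-prefix AIS code
    p_pelvic_ais_given_tr: float = 0.95
    #: per-(variable, registry) probability of a missing entry
    missingness: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("initial_hb", "PIR"): 0.83,
            ("initial_sbp", "PIR"): 0.83,
            ("initial_hb", "TR"): 0.05,
            ("initial_sbp", "TR"): 0.11,
        }
    )
    #: probability that exactly one key component of the TR copy is perturbed
    key_error_rate: float = 0.05
    key_date_jitter_days: int = 1
    duplicate_rate: float = 0.003
    #: entry-discrepancy models, TR value = PIR value + Δ
    iss_delta_sd: float = 9.166
    hb_delta_mean: float = 1.0
    hb_delta_sd: float = 1.5
    bp_delta_mean: float = 9.0
    bp_delta_sd: float = 20.0
    mortality: float = 0.10
    fracture_mix: Tuple[float, float, float, float] = (0.198, 0.295, 0.364, 0.143)
    complex_rate: float = 0.183
    p_blunt: float = 0.99
    p_male: float = 0.60
    #: fraction of pelvic-registry rows storing a birthdate instead of an age
    p_pir_birthdate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_in_pir,
            self.p_in_tr,
            self.p_hospital_year_active_pir,
            self.p_hospital_year_active_tr,
            self.p_pelvic_ais_given_tr,
            self.key_error_rate,
            self.duplicate_rate,
            self.mortality,
            self.complex_rate,
            self.p_blunt,
            self.p_male,
            self.p_pir_birthdate,
            *self.missingness.values(),
            *self.fracture_mix,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.fracture_mix) - 1.0) > 1e-9:
            raise ValueError("fracture_mix must sum to 1")
        if self.n_hospitals < 1 or self.n_true_patients < 0:
            raise ValueError("need at least one hospital and a non-negative cohort")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if self.key_date_jitter_days < 1:
            raise ValueError("date jitter must be at least one day")


@dataclass
class GroundTruth:
    """Planted identity of every emitted record.

    ``entries`` maps the true patient index to the primary record id in each
    registry (None where undocumented); ``duplicates`` lists planted extra
    copies as (registry, record_id, true_index); ``record_to_truth`` resolves
    any emitted record id back to its true patient.
    """

    entries: Dict[int, Tuple[Optional[str], Optional[str]]]
    duplicates: List[Tuple[str, str, int]]
    record_to_truth: Dict[Tuple[str, str], int]

    def co_documented(self) -> List[Tuple[str, str]]:
        return [
            (p, t) for p, t in self.entries.values() if p is not None and t is not None
        ]


@dataclass
class TruthEvaluation:
    sensitivity: float
    ppv: float
    missed: List[Tuple[str, str]]
    false: List[Tuple[str, str]]
    n_true_pairs: int
    n_links: int


def _rand_date(rng: np.random.Generator, year: int) -> date:
    start = date(year, 1, 1)
    span = (date(year + 1, 1, 1) - start).days
    return start + timedelta(days=int(rng.integers(0, span)))


def _perturb_key(rec: TrRecord, rng: np.random.Generator, jitter: int) -> None:
    component = rng.integers(0, 3)
    delta = int(rng.integers(1, jitter + 1)) * (1 if rng.random() < 0.5 else -1)
    if component == 0:
        rec.admission_date = rec.admission_date + timedelta(days=delta)
        if rec.discharge_date < rec.admission_date:
            rec.discharge_date = rec.admission_date
    elif component == 1:
        shifted = rec.discharge_date + timedelta(days=delta)
        if shifted < rec.admission_date:
            shifted = rec.discharge_date + timedelta(days=abs(delta))
        rec.discharge_date = shifted
    else:
        rec.age_years = rec.age_years + 1 if rec.age_years <= 0 or rng.random() < 0.5 else rec.age_years - 1


def _birthdate_for_age(
    admission: date, age: int, rng: np.random.Generator
) -> Optional[date]:
    """A birthdate whose completed years at admission equal ``age`` exactly."""
    try:
        anchor = admission.replace(year=admission.year - age)
    except ValueError:  # Feb 29 anniversary
        anchor = admission.replace(year=admission.year - age, day=28)
    candidate = anchor - timedelta(days=int(rng.integers(0, 330)))
    probe = PirRecord(
        registry_id=Registry.PIR,
        record_id="probe",
        hospital_code=None,
        admission_date=admission,
        discharge_date=None,
        birthdate=candidate,
    )
    return candidate if derive_age(probe, admission) == age else None


def generate(
    config: SyntheticConfig,
) -> Tuple[RegistryTable, RegistryTable, GroundTruth]:
    """Emit the twin registries plus ground truth for ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = list(range(config.years[0], config.years[1] + 1))
    hospitals = [f"H{i + 1:03d}" for i in range(config.n_hospitals)]

    active_pir = {
        (h, y): bool(rng.random() < config.p_hospital_year_active_pir)
        for h in hospitals
        for y in years
    }
    active_tr = {
        (h, y): bool(rng.random() < config.p_hospital_year_active_tr)
        for h in hospitals
        for y in years
    }

    pir_records: List[PirRecord] = []
    tr_records: List[TrRecord] = []
    entries: Dict[int, Tuple[Optional[str], Optional[str]]] = {}
    duplicates: List[Tuple[str, str, int]] = []
    record_to_truth: Dict[Tuple[str, str], int] = {}

    def miss(variable: str, registry: str) -> bool:
        p = config.missingness.get((variable, registry), 0.0)
        return bool(rng.random() < p) if p else False

    for i in range(config.n_true_patients):
        hospital = hospitals[int(rng.integers(0, len(hospitals)))]
        year = years[int(rng.integers(0, len(years)))]
        admission = _rand_date(rng, year)
        discharge = admission + timedelta(days=1 + int(rng.poisson(12)))
        age = int(np.clip(round(rng.normal(41.6, 19.5)), 16, 100))
        sex = Sex.MALE if rng.random() < config.p_male else Sex.FEMALE
        dead = rng.random() < config.mortality
        vital = VitalStatus.DEAD if dead else VitalStatus.ALIVE
        iss = int(np.clip(round(rng.normal(27.0, 13.0)), 1, 75))
        hb = round(max(0.1, rng.normal(9.0, 2.9)), 1)
        bp = float(max(10, round(rng.normal(99.0, 19.0))))
        tile = _TILE_ORDER[int(rng.choice(4, p=config.fracture_mix))]
        is_complex = bool(rng.random() < config.complex_rate)
        mechanism = "blunt" if rng.random() < config.p_blunt else "penetrating"

        in_pir = rng.random() < config.p_in_pir and active_pir[(hospital, year)]
        in_tr = rng.random() < config.p_in_tr and active_tr[(hospital, year)]

        pir_id = tr_id = None
        if in_pir:
            pir_id = f"P{len(pir_records):06d}"
            rec = PirRecord(
                registry_id=Registry.PIR,
                record_id=pir_id,
                hospital_code=hospital,
                admission_date=admission,
                discharge_date=discharge,
                age_years=age,
                sex=sex,
                vital_status=vital,
                iss=iss,
                initial_hb=None if miss("initial_hb", "PIR") else hb,
                initial_sbp=None if miss("initial_sbp", "PIR") else bp,
                payload={"prbc": str(int(rng.integers(0, 12)))},
                tile_class=tile,
                complex_pelvic_injury=is_complex,
            )
            if rng.random() < config.p_pir_birthdate:
                birthdate = _birthdate_for_age(admission, age, rng)
                if birthdate is not None:
                    rec.birthdate = birthdate
                    rec.age_years = None
            pir_records.append(rec)
            record_to_truth[("PIR", pir_id)] = i
            if rng.random() < config.duplicate_rate:
                dup_id = f"P{len(pir_records):06d}"
                pir_records.append(replace(rec, record_id=dup_id))
                duplicates.append(("PIR", dup_id, i))
                record_to_truth[("PIR", dup_id)] = i

        if in_tr:
            tr_id = f"T{len(tr_records):06d}"
            if rng.random() < config.p_pelvic_ais_given_tr:
                codes = [str(rng.choice(_PELVIC_AIS))]
                codes += list(rng.choice(_OTHER_AIS, size=int(rng.integers(0, 3)), replace=False))
            else:
                codes = list(rng.choice(_OTHER_AIS, size=int(rng.integers(1, 4)), replace=False))
            rec_tr = TrRecord(
                registry_id=Registry.TR,
                record_id=tr_id,
                hospital_code=hospital,
                admission_date=admission,
                discharge_date=discharge,
                age_years=age,
                sex=sex,
                vital_status=vital,
                iss=int(np.clip(iss + round(rng.normal(0.0, config.iss_delta_sd)), 1, 75)),
                initial_hb=(
                    None
                    if miss("initial_hb", "TR")
                    else round(max(0.1, hb + rng.normal(config.hb_delta_mean, config.hb_delta_sd)), 1)
                ),
                initial_sbp=(
                    None
                    if miss("initial_sbp", "TR")
                    else float(max(10, round(bp + rng.normal(config.bp_delta_mean, config.bp_delta_sd))))
                ),
                payload={"mechanism": mechanism, "gcs": str(int(rng.integers(3, 16)))},
                ais_codes=codes,
            )
            if rng.random() < config.key_error_rate:
                _perturb_key(rec_tr, rng, config.key_date_jitter_days)
            tr_records.append(rec_tr)
            record_to_truth[("TR", tr_id)] = i
            if rng.random() < config.duplicate_rate:
                dup_id = f"T{len(tr_records):06d}"
                tr_records.append(replace(rec_tr, record_id=dup_id))
                duplicates.append(("TR", dup_id, i))
                record_to_truth[("TR", dup_id)] = i

        entries[i] = (pir_id, tr_id)

    truth = GroundTruth(entries, duplicates, record_to_truth)
    return (
        RegistryTable(Registry.PIR, pir_records),
        RegistryTable(Registry.TR, tr_records),
        truth,
    )


def evaluate_against_truth(links, truth: GroundTruth) -> TruthEvaluation:
    """Sensitivity and positive predictive value of a link set.

    Sensitivity is the share of truly co-documented pairs recovered; PPV the
    share of reported links that are true.  With no links reported PPV is
    vacuously 1 (no false positives were produced).
    """
    for lr in links:
        for registry, rid in (("PIR", lr.pir.record_id), ("TR", lr.tr.record_id)):
            if (registry, rid) not in truth.record_to_truth:
                raise ValueError(f"record {rid!r} ({registry}) unknown to ground truth")
    true_pairs = set(truth.co_documented())
    found = {(lr.pir.record_id, lr.tr.record_id) for lr in links}
    hits = found & true_pairs
    missed = sorted(true_pairs - found)
    false = sorted(found - true_pairs)
    sensitivity = len(hits) / len(true_pairs) if true_pairs else 1.0
    ppv = len(hits) / len(found) if found else 1.0
    return TruthEvaluation(
        sensitivity=sensitivity,
        ppv=ppv,
        missed=missed,
        false=false,
        n_true_pairs=len(true_pairs),
        n_links=len(found),
    )
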