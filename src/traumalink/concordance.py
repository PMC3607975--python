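"""Concordance evaluation of twofold-documented clinical variables.

For every variable recorded in both registries the linked cohort yields a
pair of entries per patient.  Agreement is reported at two levels: exact
match (identical after registry precision — whole points for ISS and mmHg,
one decimal for g/dl) and match within a clinically motivated tolerance band
(±9 ISS points, ±1 g/dl haemoglobin, ±10 mmHg systolic blood pressure;
vital status exact only).  Tolerance boundaries are inclusive.  Only pairs
complete on both sides enter the analysis — no imputation.  Continuous
variables are compared with the paired Wilcoxon signed-rank test,
categorical ones with Pearson's chi-square on the 2×2 registry-by-outcome
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._rounding import percent, round_half_up
from .records import RegistryRecord, TileClass, VitalStatus
from .stats import TestResult, chi_square_2x2, wilcoxon_signed_rank

__all__ = [
    "ToleranceSpec",
    "DEFAULT_TOLERANCES",
    "ConcordanceResult",
    "CohortSummary",
    "InsufficientPairsError",
    "completion_rate",
    "within_tolerance",
    "concordance",
    "summarize_cohort",
]

#: guard against float-representation artefacts at the tolerance boundary
_EPS = 1e-9

#: decimals of the registry entry precision per continuous variable
_PRECISION = {"iss": 0, "initial_hb": 1, "initial_sbp": 0}

CONTINUOUS_VARIABLES = ("iss", "initial_hb", "initial_sbp")
CATEGORICAL_VARIABLES = ("vital_status",)


class InsufficientPairsError(ValueError):
    """Fewer than two complete pairs — concordance is undefined."""


@dataclass(frozen=True)
class ToleranceSpec:
    variable: str
    tolerance: float

    def __post_init__(self) -> None:
        known = CONTINUOUS_VARIABLES + CATEGORICAL_VARIABLES
        if self.variable not in known:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.variable in CATEGORICAL_VARIABLES and self.tolerance != 0:
            raise ValueError("categorical variables admit exact match only")


DEFAULT_TOLERANCES = (
    ToleranceSpec("iss", 9.0),
    ToleranceSpec("initial_hb", 1.0),
    ToleranceSpec("initial_sbp", 10.0),
    ToleranceSpec("vital_status", 0.0),
)


@dataclass
class ConcordanceResult:
    variable: str
    n_pairs_complete: int
    mean_sd_pir: Optional[Tuple[float, float]]
    mean_sd_tr: Optional[Tuple[float, float]]
    exact_match_pct: float
    tolerance_match_pct: float
    test: TestResult
    tolerance: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_pairs_complete": self.n_pairs_complete,
            "mean_sd_pir": list(self.mean_sd_pir) if self.mean_sd_pir else None,
            "mean_sd_tr": list(self.mean_sd_tr) if self.mean_sd_tr else None,
            "exact_match_pct": self.exact_match_pct,
            "tolerance_match_pct": self.tolerance_match_pct,
            "test_name": self.test.name,
            "p_value": self.test.p_value,
            "tolerance": self.tolerance,
        }


def _get_field(rec: RegistryRecord, variable: str):
    value = getattr(rec, variable)
    if variable == "vital_status" and value is VitalStatus.MISSING:
        return None
    return value


def completion_rate(records: Sequence[RegistryRecord], variable: str):
    """(complete_count, total, percent) for one variable.

    A value is complete when it is present; missing is absence, never zero.
    Percent is rounded half-up to the nearest integer.  Raises on an empty
    collection, where the rate is undefined.
    """
    records = list(records)
    if not records:
        raise InsufficientPairsError("completion rate undefined on empty collection")
    if variable not in CONTINUOUS_VARIABLES + CATEGORICAL_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    complete = sum(1 for r in records if _get_field(r, variable) is not None)
    return complete, len(records), percent(complete, len(records), 0)


def within_tolerance(a: float, b: float, tol: float) -> bool:
    """|a - b| <= tol, with the boundary inclusive."""
    return abs(a - b) <= tol + _EPS


def _exact_equal(a, b, variable: str) -> bool:
    nd = _PRECISION[variable]
    return round_half_up(a, nd) == round_half_up(b, nd)


def concordance(linked: Sequence, spec: ToleranceSpec) -> ConcordanceResult:
    """Evaluate one variable's concordance over the linked cohort.

    Restricted to pairs complete on both sides.  Percentages are half-up
    integers (the granularity at which registries report agreement).
    """
    linked = list(linked)
    if not linked:
        raise InsufficientPairsError("no linked records")

    pairs = []
    for lr in linked:
        a = _get_field(lr.pir, spec.variable)
        b = _get_field(lr.tr, spec.variable)
        if a is not None and b is not None:
            pairs.append((a, b))
    if len(pairs) < 2:
        raise InsufficientPairsError(
            f"{spec.variable}: {len(pairs)} complete pair(s), need at least 2"
        )
    n = len(pairs)

    if spec.variable in CATEGORICAL_VARIABLES:
        exact = sum(1 for a, b in pairs if a == b)
        dead_pir = sum(1 for a, _ in pairs if a is VitalStatus.DEAD)
        dead_tr = sum(1 for _, b in pairs if b is VitalStatus.DEAD)
        test = chi_square_2x2(
            [[dead_pir, n - dead_pir], [dead_tr, n - dead_tr]]
        )
        exact_pct = percent(exact, n, 0)
        return ConcordanceResult(
            variable=spec.variable,
            n_pairs_complete=n,
            mean_sd_pir=None,
            mean_sd_tr=None,
            exact_match_pct=exact_pct,
            tolerance_match_pct=exact_pct,
            test=test,
            tolerance=0.0,
        )

    a = np.array([float(p[0]) for p in pairs])
    b = np.array([float(p[1]) for p in pairs])
    exact_mask = np.array([_exact_equal(x, y, spec.variable) for x, y in pairs])
    # exact match implies tolerance match even when rounding crosses the band
    tol_mask = np.abs(a - b) <= spec.tolerance + _EPS
    tol_mask |= exact_mask
    test = wilcoxon_signed_rank(a, b)
    return ConcordanceResult(
        variable=spec.variable,
        n_pairs_complete=n,
        mean_sd_pir=(float(a.mean()), float(a.std(ddof=1))),
        mean_sd_tr=(float(b.mean()), float(b.std(ddof=1))),
        exact_match_pct=percent(int(exact_mask.sum()), n, 0),
        tolerance_match_pct=percent(int(tol_mask.sum()), n, 0),
        test=test,
        tolerance=spec.tolerance,
    )


@dataclass
class CohortSummary:
    """Results-style description of the linked cohort."""

    n: int
    mean_sd_age: Optional[Tuple[float, float]]
    mean_sd_iss: Optional[Tuple[float, float]]
    mortality_pct: Optional[float]
    tile_distribution_pct: dict
    complex_pelvic_pct: Optional[float]
    blunt_pct: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_sd_age": list(self.mean_sd_age) if self.mean_sd_age else None,
            "mean_sd_iss": list(self.mean_sd_iss) if self.mean_sd_iss else None,
            "mortality_pct": self.mortality_pct,
            "tile_distribution_pct": dict(self.tile_distribution_pct),
            "complex_pelvic_pct": self.complex_pelvic_pct,
            "blunt_pct": self.blunt_pct,
        }


def summarize_cohort(linked: Sequence) -> CohortSummary:
    """Cohort description of the linked records.

    The Tile class, complex-injury flag and authoritative vital status come
    from the pelvic-registry side (its surgeons classify the fracture); the
    injury mechanism, when present, from the trauma-registry payload.
    Percentages are half-up to one decimal.
    """
    linked = list(linked)
    if not linked:
        raise InsufficientPairsError("no linked records")
    n = len(linked)

    ages = [lr.match_key.age_years for lr in linked]
    iss = [lr.pir.iss for lr in linked if lr.pir.iss is not None]

    vital = [lr.pir.vital_status for lr in linked if lr.pir.vital_status is not VitalStatus.MISSING]
    mortality = (
        percent(sum(1 for v in vital if v is VitalStatus.DEAD), len(vital), 1)
        if vital
        else None
    )

    tile_classes = [t for t in TileClass if t is not TileClass.MISSING]
    tile_counts = {t: 0 for t in tile_classes}
    for lr in linked:
        if lr.pir.tile_class in tile_counts:
            tile_counts[lr.pir.tile_class] += 1
    tile_pct = {t.value: percent(c, n, 1) for t, c in tile_counts.items()}

    cpx = [lr.pir.complex_pelvic_injury for lr in linked if lr.pir.complex_pelvic_injury is not None]
    complex_pct = percent(sum(1 for c in cpx if c), len(cpx), 1) if cpx else None

    mech = [lr.tr.payload.get("mechanism") for lr in linked]
    mech = [m for m in mech if m]
    blunt_pct = (
        percent(sum(1 for m in mech if m == "blunt"), len(mech), 1) if mech else None
    )

    def mean_sd(values):
        if len(values) < 2:
            return None
        arr = np.asarray(values, dtype=float)
        return (float(arr.mean()), float(arr.std(ddof=1)))

    return CohortSummary(
        n=n,
        mean_sd_age=mean_sd(ages),
        mean_sd_iss=mean_sd(iss),
        mortality_pct=mortality,
        tile_distribution_pct=tile_pct,
        complex_pelvic_pct=complex_pct,
        blunt_pct=blunt_pct,
    )
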