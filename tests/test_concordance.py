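"""Completion rates, tolerance-band agreement, cohort summary."""

import numpy as np
import pytest

from traumalink import (
    LinkedRecord,
    Sex,
    TileClass,
    ToleranceSpec,
    VitalStatus,
    build_match_key,
    completion_rate,
    concordance,
    summarize_cohort,
    within_tolerance,
)
from traumalink.concordance import InsufficientPairsError

from conftest import make_pir, make_tr


def linked_pair(i=0, **overrides):
    pir_kw = {k[4:]: v for k, v in overrides.items() if k.startswith("pir_")}
    tr_kw = {k[3:]: v for k, v in overrides.items() if k.startswith("tr_")}
    adm = f"2005-{(i % 12) + 1:02d}-{(i % 27) + 1:02d}"
    dis = f"2006-01-{(i % 27) + 1:02d}"
    pir = make_pir(f"P{i}", adm=adm, dis=dis, **pir_kw)
    tr = make_tr(f"T{i}", adm=adm, dis=dis, **tr_kw)
    return LinkedRecord(build_match_key(pir), pir, tr)


class TestCompletionRate:
    @pytest.mark.parametrize(
        "complete, total, expected",
        [(73, 420, 17), (375, 420, 89), (400, 420, 95), (420, 420, 100)],
    )
    def test_half_up_integer_percent(self, complete, total, expected):
        records = [
            make_pir(f"P{i}", hb=8.6 if i < complete else None) for i in range(total)
        ]
        assert completion_rate(records, "initial_hb") == (complete, total, expected)

    def test_empty_collection_undefined(self):
        with pytest.raises(InsufficientPairsError):
            completion_rate([], "iss")

    def test_completion_plus_missing_conserves_total(self):
        records = [make_pir(f"P{i}", sbp=None if i % 3 else 99.0) for i in range(50)]
        complete, total, _ = completion_rate(records, "initial_sbp")
        missing = sum(1 for r in records if r.initial_sbp is None)
        assert complete + missing == total == 50


class TestWithinTolerance:
    @pytest.mark.parametrize(
        "a, b, tol, expected",
        [
            (27, 36, 9, True),  # inclusive boundary
            (27, 37, 9, False),
            (8.6, 9.6, 1.0, True),  # float-safe inclusive boundary
            (99, 109, 10, True),
            (99, 109.5, 10, False),
        ],
    )
    def test_inclusive_band(self, a, b, tol, expected):
        assert within_tolerance(a, b, tol) is expected
        assert within_tolerance(b, a, tol) is expected  # symmetric


class TestConcordance:
    def test_identical_pairs_full_agreement_p_one(self):
        linked = [
            linked_pair(i, pir_vital=VitalStatus.DEAD if i < 3 else VitalStatus.ALIVE,
                        tr_vital=VitalStatus.DEAD if i < 3 else VitalStatus.ALIVE)
            for i in range(30)
        ]
        res = concordance(linked, ToleranceSpec("vital_status", 0.0))
        assert res.exact_match_pct == 100.0
        assert res.tolerance_match_pct == 100.0
        assert res.test.p_value == pytest.approx(1.0)

    def test_identical_continuous_pairs_p_one_by_convention(self):
        linked = [linked_pair(i, pir_iss=20 + i, tr_iss=20 + i) for i in range(10)]
        res = concordance(linked, ToleranceSpec("iss", 9.0))
        assert res.exact_match_pct == 100.0 and res.test.p_value == 1.0

    def test_restricted_to_pairwise_complete_cases(self):
        linked = [
            linked_pair(i, pir_hb=8.0 if i < 4 else None, tr_hb=9.0 if i % 2 == 0 else None)
            for i in range(10)
        ]
        res = concordance(linked, ToleranceSpec("initial_hb", 1.0))
        assert res.n_pairs_complete == 2  # i in {0, 2}

    def test_exact_never_exceeds_tolerance_pct(self):
        rng = np.random.default_rng(17)
        linked = [
            linked_pair(
                i,
                pir_iss=int(rng.integers(1, 75)),
                tr_iss=int(rng.integers(1, 75)),
            )
            for i in range(200)
        ]
        res = concordance(linked, ToleranceSpec("iss", 9.0))
        assert 0 <= res.exact_match_pct <= res.tolerance_match_pct <= 100

    def test_exact_match_uses_registry_precision(self):
        # 8.64 and 8.6 are the same entry at 0.1 g/dl registry precision
        linked = [
            linked_pair(0, pir_hb=8.64, tr_hb=8.6),
            linked_pair(1, pir_hb=10.0, tr_hb=12.0),
        ]
        res = concordance(linked, ToleranceSpec("initial_hb", 1.0))
        assert res.exact_match_pct == 50.0

    def test_insufficient_pairs_signal(self):
        linked = [linked_pair(0, pir_hb=None)]
        with pytest.raises(InsufficientPairsError):
            concordance(linked, ToleranceSpec("initial_hb", 1.0))

    def test_tolerance_recovery_matches_analytic_probability(self):
        """Within-±9 ISS agreement converges to P(|Δ| ≤ 9.5) of the Gaussian."""
        rng = np.random.default_rng(20130305)
        n = 10_000
        base = np.clip(np.round(rng.normal(27, 13, size=n)), 1, 75).astype(int)
        delta = np.round(rng.normal(0, 9.166, size=n)).astype(int)
        linked = [
            linked_pair(i % 400, pir_iss=int(b), tr_iss=int(np.clip(b + d, 1, 75)))
            for i, (b, d) in enumerate(zip(base, delta))
        ]
        res = concordance(linked, ToleranceSpec("iss", 9.0))
        from scipy.stats import norm

        p_analytic = 100 * (2 * norm.cdf(9.5 / 9.166) - 1)  # ≈ 70
        se = 100 * np.sqrt(0.7 * 0.3 / n)
        # clipping at the ISS bounds only ever pulls pairs into the band
        assert res.tolerance_match_pct >= p_analytic - 3 * se
        assert res.tolerance_match_pct <= p_analytic + 3 * se + 2.0


class TestCohortSummary:
    def test_single_record_type_c_is_all(self):
        linked = [linked_pair(0, pir_tile=TileClass.C)]
        summary = summarize_cohort(linked)
        assert summary.n == 1
        assert summary.tile_distribution_pct["C"] == 100.0
        assert summary.tile_distribution_pct["A"] == 0.0

    def test_mortality_from_pir_side_vital_status(self):
        linked = [
            linked_pair(
                i,
                pir_vital=VitalStatus.DEAD if i < 1 else VitalStatus.ALIVE,
                tr_vital=VitalStatus.ALIVE,
            )
            for i in range(10)
        ]
        assert summarize_cohort(linked).mortality_pct == 10.0

    def test_blunt_share_from_tr_payload(self):
        linked = [
            linked_pair(i, tr_payload={"mechanism": "blunt" if i else "penetrating"})
            for i in range(4)
        ]
        assert summarize_cohort(linked).blunt_pct == 75.0
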