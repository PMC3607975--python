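"""Match-key construction, deduplication, one-to-one join, funnel arithmetic."""

from datetime import date

import numpy as np
import pytest

from traumalink import (
    FilterStage,
    MatchKey,
    NonLinkable,
    Sex,
    StageName,
    build_match_key,
    compute_funnel,
    find_duplicates,
    link,
)

from conftest import make_pir, make_tr, pir_table, tr_table


class TestBuildMatchKey:
    def test_identity_construction(self):
        key = build_match_key(make_pir())
        assert key == MatchKey("H01", date(2005, 3, 2), date(2005, 3, 20), 41, Sex.MALE)

    def test_missing_discharge_date_signals_non_linkable(self):
        key = build_match_key(make_pir(dis=None))
        assert isinstance(key, NonLinkable)
        assert key.missing == ("discharge_date",)

    def test_unknown_sex_signals_non_linkable(self):
        key = build_match_key(make_pir(sex=Sex.UNKNOWN))
        assert isinstance(key, NonLinkable)
        assert "sex" in key.missing

    def test_key_ignores_clinical_payload(self):
        a = build_match_key(make_pir(iss=9))
        b = build_match_key(make_pir(iss=50, hb=None, payload={"prbc": "8"}))
        assert a == b

    def test_age_resolved_from_birthdate(self):
        stored = build_match_key(make_pir(age=34))
        derived = build_match_key(make_pir(age=None, birthdate="1970-06-15"))
        assert stored == derived


def _random_tables(rng, n_pir, n_tr):
    """Small key space so that duplicates and cross-matches actually occur."""

    def fields(i, prefix):
        return dict(
            record_id=f"{prefix}{i}",
            hospital=f"H{rng.integers(0, 3)}",
            adm=f"2005-01-0{rng.integers(1, 5)}",
            dis=f"2005-02-0{rng.integers(1, 5)}",
            age=int(rng.integers(30, 34)),
            sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        )

    pir = [make_pir(**fields(i, "P")) for i in range(n_pir)]
    tr = [make_tr(**fields(i, "T")) for i in range(n_tr)]
    # sprinkle some non-linkable records
    for rec in pir[: n_pir // 10]:
        rec.discharge_date = None
    return pir_table(pir), tr_table(tr)


def _brute_force_links(pir, tr):
    """O(n·m) nested-loop key-equality join after exclude-all dedup."""

    def usable_keys(table):
        keys = {}
        for rec in table.records:
            k = build_match_key(rec)
            if not isinstance(k, NonLinkable):
                keys.setdefault(k, []).append(rec.record_id)
        return {k: ids[0] for k, ids in keys.items() if len(ids) == 1}

    pk, tk = usable_keys(pir), usable_keys(tr)
    return {(pk[k], tk[k]) for k in set(pk) & set(tk)}


class TestFindDuplicates:
    def test_distinct_keys_no_groups(self):
        table = pir_table([make_pir(f"P{i}", age=30 + i) for i in range(5)])
        assert find_duplicates(table) == []

    def test_three_records_one_key_one_group(self):
        table = pir_table([make_pir(f"P{i}") for i in range(3)])
        groups = find_duplicates(table)
        assert groups == [["P0", "P1", "P2"]]

    def test_agrees_with_pairwise_comparison(self):
        rng = np.random.default_rng(5)
        pir, _ = _random_tables(rng, 50, 0)
        groups = {frozenset(g) for g in find_duplicates(pir)}
        # O(n²) oracle
        expected = {}
        for a in pir.records:
            ka = build_match_key(a)
            if isinstance(ka, NonLinkable):
                continue
            for b in pir.records:
                if a.record_id >= b.record_id:
                    continue
                if ka == build_match_key(b):
                    expected.setdefault(ka, set()).update({a.record_id, b.record_id})
        assert groups == {frozenset(v) for v in expected.values()}


class TestLink:
    def test_disjoint_keys_no_links(self):
        pir = pir_table([make_pir("P1", age=30)])
        tr = tr_table([make_tr("T1", age=31)])
        res = link(pir, tr)
        assert res.linked == []
        assert [r.record_id for r in res.unmatched_pir] == ["P1"]
        assert [r.record_id for r in res.unmatched_tr] == ["T1"]

    def test_matches_brute_force_join_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pir, tr = _random_tables(rng, int(rng.integers(0, 80)), int(rng.integers(0, 80)))
            res = link(pir, tr)
            got = {(lr.pir.record_id, lr.tr.record_id) for lr in res.linked}
            assert got == _brute_force_links(pir, tr)

    def test_one_to_one_no_record_in_two_links(self):
        rng = np.random.default_rng(3)
        pir, tr = _random_tables(rng, 60, 60)
        res = link(pir, tr)
        pir_ids = [lr.pir.record_id for lr in res.linked]
        tr_ids = [lr.tr.record_id for lr in res.linked]
        assert len(pir_ids) == len(set(pir_ids))
        assert len(tr_ids) == len(set(tr_ids))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pir, tr = _random_tables(rng, 40, 40)
        res1 = link(pir, tr)
        shuffled_pir = pir.subset([pir.records[i] for i in rng.permutation(len(pir))])
        shuffled_tr = tr.subset([tr.records[i] for i in rng.permutation(len(tr))])
        res2 = link(shuffled_pir, shuffled_tr)
        assert [(l.pir.record_id, l.tr.record_id) for l in res1.linked] == [
            (l.pir.record_id, l.tr.record_id) for l in res2.linked
        ]
        assert res1.duplicates_removed == res2.duplicates_removed

    def test_conservation_partition_per_registry(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pir, tr = _random_tables(rng, int(rng.integers(1, 70)), int(rng.integers(1, 70)))
            res = link(pir, tr)
            assert (
                len(res.linked)
                + len(res.unmatched_pir)
                + res.duplicates_removed_pir
                + len(res.non_linkable_pir)
                == len(pir)
            )
            assert (
                len(res.linked)
                + len(res.unmatched_tr)
                + res.duplicates_removed_tr
                + len(res.non_linkable_tr)
                == len(tr)
            )


class TestComputeFunnel:
    def _stages(self, pir_eligible, tr_eligible):
        return [
            FilterStage(StageName.INITIAL, 4323, 34134),
            FilterStage(StageName.OVERLAPPING_YEARS, pir_eligible, tr_eligible),
        ]

    def test_published_rates_from_eligible_counts(self):
        funnel = compute_funnel(self._stages(2671, 947), 10, 420)
        assert funnel.linkage_rate_pir == 15.7
        assert funnel.linkage_rate_tr == 44.4

    def test_zero_links_zero_rates(self):
        funnel = compute_funnel(self._stages(100, 100), 0, 0)
        assert funnel.linkage_rate_pir == 0.0 and funnel.linkage_rate_tr == 0.0

    def test_links_without_eligible_population_raises(self):
        with pytest.raises(ValueError):
            compute_funnel(self._stages(0, 0), 0, 5)

    def test_rounding_is_half_up(self):
        funnel = compute_funnel(self._stages(400, 800), 0, 1)  # 0.25% / 0.125%
        assert funnel.linkage_rate_pir == 0.3
        assert funnel.linkage_rate_tr == 0.1
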