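"""Temporal-rule unit and property tests, including boundary-exact checks of
the 90-day gap, 7/30-day readmission and 14-day post-discharge rules, and
day-grid brute-force agreement on random patient histories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bruteforce as bf
from quadim import episodes as ep

DDD = {"A": 10.0, "B": 5.0, "C": 20.0}


def _episodes(rows, gap_days=90):
    df = pd.DataFrame(rows, columns=["patient_id", "day", "atc_code", "total_amount"])
    ddd = pd.DataFrame({"atc_code": list(DDD), "ddd": list(DDD.values())})
    return ep.build_supply_episodes(df, ddd, gap_days)


class TestSupplyEpisodes:
    def test_duration_is_amount_over_ddd(self):
        (e,) = _episodes([("p", 0, "A", 2800.0)])
        assert (e.start_day, e.end_day, e.duration) == (0, 280, 280)

    def test_duration_rounds_up_to_whole_days(self):
        (e,) = _episodes([("p", 0, "A", 15.0)])
        assert e.duration == 2

    @pytest.mark.parametrize("gap,expected_episodes", [(89, 1), (90, 2), (91, 2)])
    def test_gap_rule_boundary(self, gap, expected_episodes):
        # supply of days 0..99, next dispensing at 100 + gap
        eps = _episodes([("p", 0, "A", 1000.0), ("p", 100 + gap, "A", 100.0)])
        assert len(eps) == expected_episodes

    def test_stockpiling_appends_overlapping_supply(self):
        # second fill arrives on day 10 while 30 days of supply still run
        (e,) = _episodes([("p", 0, "A", 300.0), ("p", 10, "A", 300.0)])
        assert (e.start_day, e.end_day, e.n_dispensings) == (0, 60, 2)

    def test_order_invariant_under_shuffling(self):
        rows = [("p", d, "A", 150.0) for d in (200, 0, 40, 310, 120)]
        a = _episodes(rows)
        b = _episodes(rows[::-1])
        assert a == b

    def test_missing_atc_raises_with_code(self):
        with pytest.raises(KeyError, match="ZZZ"):
            _episodes([("p", 0, "ZZZ", 10.0)])

    def test_merging_consecutive_fills_never_shortens_coverage(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(2, 6)
            days = np.sort(rng.integers(0, 300, n))
            amounts = rng.integers(5, 40, n) * 10.0
            merged_days = sum(e.duration for e in _episodes(
                [("p", int(d), "A", float(a)) for d, a in zip(days, amounts)]))
            single = sum(e.duration for e in _episodes([("p", int(days[0]), "A", float(amounts.sum()))]))
            assert merged_days >= single  # gaps can only stretch coverage


intervals_st = st.lists(
    st.tuples(st.integers(0, 700), st.integers(1, 200)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=0, max_size=12)


class TestIntervalPrimitives:
    @given(intervals_st)
    @settings(max_examples=200, derandomize=True)
    def test_merge_yields_sorted_disjoint_union(self, ivs):
        merged = ep.merge_intervals(ivs)
        for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
            assert b1 < a2  # strictly disjoint and sorted
        assert (bf.covered_array(merged) == bf.covered_array(ivs)).all()

    @given(intervals_st, st.integers(0, 400), st.integers(1, 500))
    @settings(max_examples=200, derandomize=True)
    def test_uncovered_runs_partition_the_window(self, ivs, lo, length):
        window = (lo, lo + length)
        runs = ep.uncovered_runs(ivs, window)
        arr = bf.covered_array(ivs, horizon=window[1] + 1)
        uncovered = np.zeros_like(arr)
        for a, b in runs:
            assert window[0] <= a < b <= window[1]
            uncovered[a:b] = True
        for d in range(*window):
            assert uncovered[d] == (not arr[d])


class TestPersistence:
    def test_single_year_long_episode_is_persistent(self):
        assert ep.is_persistent_drug([(0, 365)], (0, 365))

    def test_split_by_120_day_gap_is_not(self):
        assert not ep.is_persistent_drug([(0, 100), (220, 365)], (0, 365))

    def test_final_gap_over_90_days_counts_as_interruption(self):
        assert not ep.is_persistent_drug([(0, 270)], (0, 365))
        assert ep.is_persistent_drug([(0, 276)], (0, 365))

    @pytest.mark.parametrize("days,expected", [
        ((0, 80, 160, 240, 320), True),
        ((0, 100), False),
        ((0, 90, 180, 270, 360), True),  # exactly every 90 days satisfies the rule
        ((0, 91), False),
    ])
    def test_community_contact_spacing(self, days, expected):
        cov = [(d, d + 1) for d in days]
        assert ep.is_persistent_community(cov, 0) is expected

    def test_inpatient_days_count_as_community_coverage(self):
        cov = [(0, 1), (60, 300), (350, 351)]  # contact, CRF stay, contact
        assert ep.is_persistent_community(cov, 0)


class TestPolytherapy:
    def test_two_drugs_overlapping_days_10_to_50(self):
        assert ep.polytherapy_days({"A": [(10, 50)], "B": [(0, 50)]}, (0, 365)) == 40

    def test_single_drug_is_zero(self):
        assert ep.polytherapy_days({"A": [(0, 365)]}, (0, 365)) == 0

    def test_clipped_to_follow_up(self):
        assert ep.polytherapy_days({"A": [(300, 500)], "B": [(300, 500)]}, (0, 365)) == 65


class TestEventSequencing:
    @pytest.mark.parametrize("readm_day,k,expected", [
        (57, 7, True),    # day 7 after discharge: inclusive
        (58, 7, False),
        (58, 30, True),
        (50, 7, False),   # same-day transfer is not a readmission
    ])
    def test_readmission_boundaries(self, readm_day, k, expected):
        flags = ep.readmission_within([10, readm_day], [50, readm_day + 5], k)
        assert bool(flags[0]) is expected

    @pytest.mark.parametrize("contact_day,expected", [(64, True), (65, False), (50, False), (51, True)])
    def test_post_discharge_day14_boundary(self, contact_day, expected):
        flags = ep.contact_within_after_discharge([contact_day], [50], 14)
        assert bool(flags[0]) is expected


class TestDayGridOracle:
    """Agreement with an independent day-grid brute force on random histories."""

    N_HISTORIES = 1000

    def test_drug_rules_match_brute_force(self):
        rng = np.random.default_rng(20150101)
        ddd_df = pd.DataFrame({"atc_code": list(DDD), "ddd": list(DDD.values())})
        for _ in range(self.N_HISTORIES):
            atcs = rng.choice(list(DDD), size=rng.integers(1, 3), replace=False)
            rows, segs_by_atc, arrays = [], {}, []
            for atc in atcs:
                n = int(rng.integers(1, 7))
                days = rng.integers(0, 500, n)
                amounts = rng.integers(1, 30, n) * DDD[atc]
                rows += [("p", int(d), atc, float(a)) for d, a in zip(days, amounts)]
                segs_by_atc[atc] = ep.supply_segments(days, amounts, DDD[atc])
                arrays.append(bf.supply_days(days, amounts, DDD[atc]))
            fu = (0, 365)
            all_segs = [s for segs in segs_by_atc.values() for s in segs]
            union = np.zeros(bf.HORIZON, dtype=bool)
            for a in arrays:
                union |= a
            assert ep.is_persistent_drug(all_segs, fu) == bf.persistent_drug(union, *fu)
            assert ep.polytherapy_days(segs_by_atc, fu) == bf.polytherapy_days(arrays, *fu)
            # segment construction itself matches the day-by-day replay
            for atc, segs in segs_by_atc.items():
                assert (bf.covered_array(segs) == arrays[atcs.tolist().index(atc)]).all()

    def test_community_persistence_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(self.N_HISTORIES):
            n_contacts = int(rng.integers(1, 25))
            days = rng.integers(0, 365, n_contacts)
            cov = [(int(d), int(d) + 1) for d in days]
            for _ in range(rng.integers(0, 3)):
                a = int(rng.integers(0, 400))
                cov.append((a, a + int(rng.integers(1, 200))))
            start = int(days.min())
            assert ep.is_persistent_community(cov, start) == \
                bf.persistent_community(bf.covered_array(cov), start)

    def test_admission_sequencing_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(self.N_HISTORIES):
            n = int(rng.integers(1, 6))
            adm = np.sort(rng.integers(0, 600, n))
            los = rng.integers(0, 60, n)
            dis = adm + los
            for k in (7, 30):
                assert ep.readmission_within(adm, dis, k).tolist() == \
                    bf.readmission_within(adm.tolist(), dis.tolist(), k)
            contacts = rng.integers(0, 700, rng.integers(0, 15))
            assert ep.contact_within_after_discharge(contacts, dis, 14).tolist() == \
                bf.contact_within(contacts.tolist(), dis.tolist(), 14)
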