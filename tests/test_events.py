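"""Event-processing chain: site merging, deployment selection, independence
filtering, occasion construction, count histories, trap rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camuse.events import (
    DetectionArray,
    build_count_histories,
    build_occasions,
    compute_trap_rates,
    filter_independent_events,
    merge_sites,
    select_deployments,
)

from conftest import make_deployments


def _events(offsets_min, species="bear", site="s1", dep="d1",
            t0="2015-06-01 08:00:00"):
    t0 = pd.Timestamp(t0)
    return pd.DataFrame(
        [(site, dep, t0 + pd.Timedelta(minutes=float(m)), species)
         for m in offsets_min],
        columns=["site_id", "deployment_id", "timestamp", "species"],
    )


class TestMergeSites:
    def _deps(self, coords):
        return make_deployments(
            [(f"d{i}", f"s{i}", e, n, "2015-06-01", "2015-07-01")
             for i, (e, n) in enumerate(coords)]
        )

    def test_under_threshold_merges(self):
        out = merge_sites(self._deps([(0, 0), (10, 0)]))
        assert out["site_id"].nunique() == 1

    def test_over_threshold_stays_distinct(self):
        out = merge_sites(self._deps([(0, 0), (20, 0)]))
        assert out["site_id"].nunique() == 2

    def test_transitive_chain_collapses(self):
        # A-B 10 m, B-C 10 m, A-C 20 m: all one site via the closure
        out = merge_sites(self._deps([(0, 0), (10, 0), (20, 0)]))
        assert out["site_id"].nunique() == 1

    def test_canonical_id_is_earliest_deployments(self):
        deps = make_deployments(
            [("d2", "sB", 0, 0, "2016-06-01", "2016-07-01"),
             ("d1", "sA", 5, 0, "2015-06-01", "2015-07-01")]
        )
        out = merge_sites(deps)
        assert set(out["site_id"]) == {"sA"}

    def test_permutation_invariant(self):
        coords = [(0, 0), (10, 0), (200, 0), (205, 0)]
        deps = self._deps(coords)
        shuffled = deps.iloc[[3, 1, 0, 2]].reset_index(drop=True)
        a = merge_sites(deps).sort_values("deployment_id")
        b = merge_sites(shuffled).sort_values("deployment_id")
        assert list(a["site_id"]) == list(b["site_id"])

    def test_missing_coordinates_raise(self):
        deps = self._deps([(0, 0), (10, 0)])
        deps.loc[0, "easting"] = np.nan
        with pytest.raises(ValueError, match="easting/northing"):
            merge_sites(deps)


class TestSelectDeployments:
    def _deps(self, year_dur):
        rows = []
        for i, (year, dur) in enumerate(year_dur):
            start = pd.Timestamp(year=year, month=6, day=1)
            rows.append((f"d{i}", "s1", 0, 0, start, start + pd.Timedelta(days=dur)))
        return make_deployments(rows)

    def test_cap_keeps_four_longest_across_years(self):
        deps = self._deps([(2010, 10), (2011, 50), (2012, 30), (2013, 70), (2014, 20)])
        out = select_deployments(deps)
        durations = sorted((out["end"] - out["start"]).dt.days)
        assert durations == [20, 30, 50, 70]

    def test_one_per_year_keeps_longest(self):
        deps = self._deps([(2012, 40), (2012, 90)])
        out = select_deployments(deps)
        assert len(out) == 1
        assert (out["end"] - out["start"]).dt.days.iloc[0] == 90

    def test_under_cap_all_kept_with_chronological_replicates(self):
        deps = self._deps([(2012, 30), (2010, 10), (2011, 20)])
        out = select_deployments(deps).sort_values("replicate")
        assert list(out["replicate"]) == [1, 2, 3]
        assert list(out["start"].dt.year) == [2010, 2011, 2012]

    def test_empty_input(self):
        out = select_deployments(self._deps([]).iloc[:0])
        assert out.empty


class TestIndependenceFilter:
    GAPS = {"bear": 10.0, "lynx": 1.0, "wolf": 30.0}

    def test_gap_rule_hand_enumeration(self):
        out = filter_independent_events(_events([0, 5, 12, 30]), self.GAPS)
        minutes = ((out["timestamp"] - out["timestamp"].iloc[0])
                   .dt.total_seconds() / 60).tolist()
        assert minutes == [0, 12, 30]

    def test_zero_gap_is_identity(self):
        ev = _events([0, 0.1, 0.2, 5])
        out = filter_independent_events(ev, {"bear": 0.0})
        assert len(out) == len(ev)

    def test_single_event_retained(self):
        out = filter_independent_events(_events([7]), self.GAPS)
        assert len(out) == 1

    def test_passthrough_species_unfiltered(self):
        ev = _events([0, 0.5, 1.0], species="human")
        out = filter_independent_events(ev, self.GAPS)
        assert len(out) == 3

    def test_unconfigured_focal_species_raises(self):
        with pytest.raises(ValueError, match="no independence gap"):
            filter_independent_events(_events([0], species="badger"), self.GAPS)

    def test_idempotent(self):
        ev = _events(np.linspace(0, 120, 25))
        once = filter_independent_events(ev, self.GAPS)
        twice = filter_independent_events(once.reset_index(drop=True), self.GAPS)
        assert len(once) == len(twice)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 500), min_size=1, max_size=30),
           st.floats(0, 60))
    def test_monotone_in_gap(self, offsets, gap):
        ev = _events(sorted(offsets))
        small = filter_independent_events(ev, {"bear": gap})
        large = filter_independent_events(ev, {"bear": gap + 10.0})
        assert len(large) <= len(small) <= len(ev)


class TestOccasions:
    DEP = {"start": "2015-06-01", "end": None}

    def _windows(self, days, length=7):
        dep = pd.Series({"start": pd.Timestamp("2015-06-01"),
                         "end": pd.Timestamp("2015-06-01") + pd.Timedelta(days=days)})
        return build_occasions(dep, length)

    def test_exact_multiple(self):
        wins = self._windows(21)
        assert len(wins) == 3
        assert [w[2] for w in wins] == [7.0, 7.0, 7.0]

    def test_trailing_partial_kept_with_effort(self):
        assert [w[2] for w in self._windows(20)] == [7.0, 7.0, 6.0]

    def test_one_day_deployment(self):
        assert [w[2] for w in self._windows(1)] == [1.0]

    def test_windows_are_half_open_and_contiguous(self):
        wins = self._windows(20)
        for (s0, e0, _), (s1, _, _) in zip(wins, wins[1:]):
            assert e0 == s1


class TestCountHistories:
    def _selected(self, durations, site="s1", year0=2012):
        rows = []
        for i, dur in enumerate(durations):
            start = pd.Timestamp(year=year0 + i, month=6, day=1)
            rows.append((f"d{i}", site, 0, 0, start, start + pd.Timedelta(days=dur)))
        deps = make_deployments(rows)
        return select_deployments(deps)

    def test_counts_and_binary(self):
        deps = self._selected([7])
        # all inside the single 7-day window
        ev = _events([10, 2000, 5000], dep="d0", t0="2012-06-01")
        arr = build_count_histories(ev, deps, ["bear"])
        assert arr.counts[0, 0, 0] == 3
        arr_b = build_count_histories(ev, deps, ["bear"], binary=True)
        assert arr_b.counts[0, 0, 0] == 1

    def test_zero_counts_distinct_from_missing(self):
        deps = self._selected([14])
        arr = build_count_histories(_events([]).iloc[:0], deps, ["bear"])
        assert arr.mask[0].sum() == 2
        assert arr.counts.sum() == 0

    def test_occasions_concatenated_with_replicate_tags(self):
        deps = self._selected([14, 21])  # 2 + 3 occasions
        arr = build_count_histories(_events([]).iloc[:0], deps, ["bear"])
        assert arr.n_occasions == 5
        assert list(arr.replicate[0]) == [1, 1, 2, 2, 2]

    def test_event_outside_windows_raises(self):
        deps = self._selected([7])
        # day 10 of a 7-day deployment
        ev = _events([60 * 24 * 10], dep="d0", t0="2012-06-01")
        with pytest.raises(ValueError, match="outside every occasion window"):
            build_count_histories(ev, deps, ["bear"])

    def test_sum_conservation(self):
        rng = np.random.default_rng(0)
        deps = self._selected([21, 14])
        offs = np.sort(rng.uniform(0, 21 * 24 * 60, size=40))
        ev = pd.concat([
            _events(offs, dep="d0", t0="2012-06-01"),
            _events(np.sort(rng.uniform(0, 14 * 24 * 60, 15)), dep="d1",
                    t0="2013-06-01"),
        ])
        arr = build_count_histories(ev, deps, ["bear"])
        assert arr.counts.sum() == 55

    def test_binarize_matches_binary_flag(self):
        rng = np.random.default_rng(1)
        deps = self._selected([21])
        ev = _events(np.sort(rng.uniform(0, 21 * 24 * 60, 30)), dep="d0",
                     t0="2012-06-01")
        a = build_count_histories(ev, deps, ["bear"]).binarize()
        b = build_count_histories(ev, deps, ["bear"], binary=True)
        assert np.array_equal(a.counts, b.counts)


class TestTrapRates:
    def test_simple_daily_rate(self):
        deps = make_deployments(
            [("d1", "s1", 0, 0, "2015-06-01", "2015-06-08")]
        )
        ev = _events(np.linspace(0, 7 * 24 * 60 - 1, 14), species="human")
        rates = compute_trap_rates(ev, deps)
        assert rates.loc["s1", "human_rate"] == pytest.approx(2.0)
        assert rates.loc["s1", "vehicle_rate"] == 0.0

    def test_duration_weighted_site_mean(self):
        deps = make_deployments(
            [("d1", "s1", 0, 0, "2013-06-01", "2013-06-11"),   # 10 d
             ("d2", "s1", 0, 0, "2014-06-01", "2014-07-01")]   # 30 d
        )
        ev = pd.concat([
            _events(np.linspace(0, 10 * 24 * 60 - 1, 10), species="human",
                    dep="d1", t0="2013-06-01"),                 # rate 1.0
            _events(np.linspace(0, 30 * 24 * 60 - 1, 90), species="human",
                    dep="d2", t0="2014-06-01"),                 # rate 3.0
        ])
        rates = compute_trap_rates(ev, deps)
        assert rates.loc["s1", "human_rate"] == pytest.approx(2.5)

    def test_zero_duration_raises(self):
        deps = make_deployments([("d1", "s1", 0, 0, "2015-06-01", "2015-06-01")])
        with pytest.raises(ValueError, match="zero-duration"):
            compute_trap_rates(_events([]).iloc[:0], deps)


class TestDetectionArray:
    def test_mask_invariant_enforced(self):
        with pytest.raises(ValueError, match="outside the surveyed mask"):
            DetectionArray(
                counts=np.ones((1, 2, 1), dtype=int),
                mask=np.array([[True, False]]),
                replicate=np.array([[1, 0]]),
                effort=np.array([[7.0, 0.0]]),
            )

    def test_long_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        mask = np.array([[True, True, False], [True, False, False]])
        counts = rng.integers(0, 4, size=(2, 3, 2)) * mask[:, :, None]
        arr = DetectionArray(
            counts=counts, mask=mask,
            replicate=np.where(mask, 1, 0), effort=np.where(mask, 7.0, 0.0),
            site_ids=["sA", "sB"], species=["bear", "wolf"],
        )
        arr.write(tmp_path / "h.csv")
        back = DetectionArray.read(tmp_path / "h.csv")
        assert np.array_equal(arr.counts, back.counts)
        assert np.array_equal(arr.mask, back.mask)
        assert np.array_equal(arr.replicate, back.replicate)
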