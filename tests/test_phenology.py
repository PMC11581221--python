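import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzasim import (
    accumulate_gdd,
    build_schedule,
    heading_schedule,
    jointing_leaf_age,
    leaf_emergence_schedule,
    root_node_count,
    seedling_root_events,
    synchrony_events,
    synth_cultivar,
)


@pytest.mark.parametrize("LN,m,expected", [(17, 6, 14), (15, 5, 13)])
def test_jointing_leaf_age_from_leaf_and_internode_counts(LN, m, expected):
    assert jointing_leaf_age(LN, m).value == expected


@given(LN=st.integers(8, 25), m=st.integers(3, 20))
@settings(max_examples=100, deadline=None)
def test_jointing_reciprocal_form_identity(LN, m):
    if m >= LN:
        with pytest.raises(ValueError):
            jointing_leaf_age(LN, m)
    else:
        age = jointing_leaf_age(LN, m).value
        # the (m-2)-th leaf counted from the top is the same leaf
        assert LN - (m - 2) + 1 == age


def test_jointing_rejects_small_m():
    with pytest.raises(ValueError):
        jointing_leaf_age(17, 2)


def test_leaf_emergence_constant_phyllochron(cultivar, gdd_series):
    sched = leaf_emergence_schedule(cultivar, gdd_series)
    ranks = sorted(sched.emergence)
    assert ranks == list(range(1, cultivar.LN + 1))
    times = [sched.emergence[n] for n in ranks]
    assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
    assert sched.emergence[3] == pytest.approx(3 * cultivar.phyllochron)
    assert not sched.truncated


def test_truncated_season_flags_and_schedules_partial(cultivar):
    short = accumulate_gdd([20.0] * 10, cultivar.base_temp)
    sched = leaf_emergence_schedule(cultivar, short)
    assert sched.truncated
    assert max(sched.emergence, default=0) < cultivar.LN


class TestSynchronyRules:
    """Per-leaf event rules keyed to main-stem leaf emergence."""

    def test_leaf7_starts_tiller_at_node4(self, cultivar):
        events = synchrony_events(7, cultivar)
        tillers = [e for e in events if e.organ == "tiller" and e.order == 1]
        assert [e.rank for e in tillers] == [4]

    def test_leaf8_starts_root_segment5(self, cultivar):
        events = synchrony_events(8, cultivar)
        roots = [e for e in events if e.organ == "root_segment"]
        assert [e.rank for e in roots] == [5]

    def test_early_leaf_suppresses_subunit_events(self, cultivar):
        events = synchrony_events(3, cultivar)
        assert not any(e.organ in ("tiller", "root_segment", "root_branch") for e in events)

    def test_out_of_range_rank_rejected(self, cultivar):
        with pytest.raises(ValueError):
            synchrony_events(0, cultivar)
        with pytest.raises(ValueError):
            synchrony_events(cultivar.LN + 1, cultivar)

    @given(n=st.integers(1, 30), seed=st.integers(0, 1000))
    @settings(max_examples=200, deadline=None)
    def test_rule_offsets_hold_for_random_cultivars(self, n, seed):
        params = synth_cultivar(seed)
        if n > params.LN:
            return
        events = synchrony_events(n, params)
        by = {}
        for e in events:
            by.setdefault((e.organ, e.order), []).append(e.rank)
        assert by.get(("sheath", 0)) == [n]
        if n + 1 <= params.LN:
            assert by.get(("leaf", 0)) == [n + 1]
        assert by.get(("tiller", 1)) == ([n - 3] if n - 3 >= 1 else None)
        assert by.get(("tiller", 2)) == ([n - 4] if n - 4 >= 1 else None)
        assert by.get(("root_segment", 0)) == ([n - 3] if n - 3 >= 1 else None)
        assert by.get(("root_branch", 1)) == ([n - 4] if n - 4 >= 1 else None)
        assert by.get(("root_branch", 2)) == ([n - 5] if n - 5 >= 1 else None)
        # no event ever indexes a rank below 1
        assert all(r >= 1 for ranks in by.values() for r in ranks)


def test_seedling_root_sequence():
    events = seedling_root_events()
    assert [e[0] for e in events] == [1, 2, 3]  # ordered by leaf stage
    assert events[1] == (2, "coleoptile_root_count", 5)
    assert "coleoptile" in events[0][1] and "incomplete" in events[2][1]


def test_heading_window_and_internode_fix():
    series = accumulate_gdd([20.0] * 100, 10.0)
    start_gdd = series.gdd_at_day(70)
    h = heading_schedule(start_gdd, series)
    assert h.end_day == pytest.approx(75.0)  # heading spans ~5 days
    assert h.internode_fix_day == pytest.approx(78.0)  # default mid of 7-9
    h9 = heading_schedule(start_gdd, series, fix_days=9.0)
    assert h9.internode_fix_day == pytest.approx(79.0)


@pytest.mark.parametrize(
    "LN,m,offset,expected", [(17, 6, 0, 11), (17, 6, 2, 13), (15, 5, 0, 10)]
)
def test_root_node_count_formula(LN, m, offset, expected):
    assert root_node_count(LN, m, offset) == expected


def test_root_node_count_monotonicity():
    assert root_node_count(18, 6) >= root_node_count(17, 6)
    assert root_node_count(17, 7) <= root_node_count(17, 6)


class TestFullSchedule:
    def test_emergence_strictly_increases_along_each_axis(self, cultivar, gdd_series):
        sched = build_schedule(cultivar, gdd_series)
        axes = {axis for axis, _ in sched.leaf_emerge}
        for axis in axes:
            times = [t for (a, r), t in sorted(sched.leaf_emerge.items()) if a == axis]
            assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_tiller_first_leaf_time_equals_trigger_leaf_emergence(self, cultivar, gdd_series):
        sched = build_schedule(cultivar, gdd_series)
        for node, t in sched.tiller_emerge.items():
            assert t == sched.leaf_emerge[("main", node + 3)]

    def test_no_internode_elongation_before_jointing(self, cultivar, gdd_series):
        sched = build_schedule(cultivar, gdd_series)
        jointing_gdd = jointing_leaf_age(cultivar.LN, cultivar.m).value * cultivar.phyllochron
        for (axis, rank), t in sched.internode_elongate.items():
            assert t >= jointing_gdd - 1e-9

    def test_exactly_m_elongating_internodes(self, cultivar, gdd_series):
        sched = build_schedule(cultivar, gdd_series)
        # ranks LN-m+1 .. LN-2 via the leaf rule, plus the top internode
        assert len(sched.internode_elongate) == cultivar.m - 1

    def test_root_branch_orders_lag_one_leaf_interval(self, cultivar, gdd_series):
        sched = build_schedule(cultivar, gdd_series)
        phy = cultivar.phyllochron
        for (seg, order), t in sched.root_branch_start.items():
            assert t == pytest.approx(sched.root_segment_start[seg] + order * phy)

    def test_schedule_csv_export(self, cultivar, gdd_series, tmp_path):
        sched = build_schedule(cultivar, gdd_series)
        path = sched.export_csv(tmp_path / "events.csv", gdd_series)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) == {"axis", "organ", "rank", "event", "gdd", "day"}
        assert len(df) > cultivar.LN
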