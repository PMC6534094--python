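"""Episode construction, supply accounting, and MPR, validated against a
brute-force daily-grid oracle that enumerates every calendar day."""

from collections import Counter
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthtraj.exposure import (
    PrescriptionRecord,
    build_episodes,
    episode_metrics,
    gap_allowance,
    mpr,
    prescribed_amount_per_dose,
    total_prescribed_amount,
)

ONE_DAY = timedelta(days=1)
WIDE_WINDOW = (date(2005, 1, 1), date(2016, 12, 31))


# ---------------------------------------------------------------------------
# daily-grid oracle: marks every calendar day and applies the rules by
# exhaustive enumeration
# ---------------------------------------------------------------------------

def iter_days(start: date, end: date):
    d = start
    while d <= end:
        yield d
        d += ONE_DAY


def oracle_episodes(prescriptions, drug_class, from_date):
    covered = sorted(
        {
            d
            for rx in prescriptions
            if rx.drug_class == drug_class
            for d in iter_days(rx.start_date, rx.end_date)
            if d >= from_date
        }
    )
    if not covered:
        return []
    episodes = []
    start = prev = covered[0]
    for d in covered[1:]:
        gap = (d - prev).days - 1
        if gap > 0 and gap > gap_allowance(prev + ONE_DAY, d - ONE_DAY):
            episodes.append((start, prev))
            start = d
        prev = d
    episodes.append((start, prev))
    return episodes


def oracle_total_amount(prescriptions, window):
    total = 0
    per_day_streams = Counter()
    for rx in prescriptions:
        stream = (rx.drug_name, rx.dose_label)
        for d in iter_days(rx.start_date, rx.end_date):
            if window[0] <= d <= window[1]:
                total += 1
                per_day_streams[(d, stream)] += 1
    day_counts = Counter()
    for (d, _stream) in per_day_streams:
        day_counts[d] += 1
    overlap = sum(c - 1 for c in day_counts.values() if c > 1)
    return total - max(0, overlap - 90)


def random_prescriptions(rng, patient="p1"):
    """Up to 20 records over a ~3-year span with mixed classes/doses."""
    n = int(rng.integers(1, 21))
    base = date(2009, 1, 1)
    out = []
    for _ in range(n):
        out.append(
            PrescriptionRecord(
                patient_id=patient,
                drug_name=str(rng.choice(["GXR", "MPH", "AMP"])),
                drug_class=str(rng.choice(["guanfacine", "stimulant"])),
                dose_label=str(rng.choice(["10", "20", "30"])) + " mg/day",
                start_date=base + timedelta(days=int(rng.integers(0, 1100))),
                days_supply=int(rng.integers(1, 95)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# gap allowance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "start,end,expected",
    [
        (date(2010, 10, 10), date(2010, 11, 20), 30),   # school-year gap
        (date(2010, 6, 15), date(2010, 9, 30), 121),    # summer gap
        (date(2010, 5, 20), date(2010, 6, 2), 121),     # touches June
        (date(2010, 9, 1), date(2011, 5, 31), 30),      # Sep-May only
        (date(2010, 12, 1), date(2011, 7, 1), 121),     # spans into summer
        (date(2010, 9, 1), date(2011, 9, 30), 121),     # >1 y always hits summer
    ],
)
def test_gap_allowance_by_season(start, end, expected):
    assert gap_allowance(start, end) == expected


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------

class TestEpisodes:
    def test_short_winter_gap_bridges_episode(self, make_rx):
        rxs = [make_rx(date(2010, 11, 1), 30), make_rx(date(2010, 12, 11), 30)]
        eps = build_episodes(rxs, "guanfacine", date(2010, 11, 1))
        assert len(eps) == 1
        assert eps[0].start_date == date(2010, 11, 1)
        assert eps[0].discontinuation_date == date(2011, 1, 9)

    def test_long_winter_gap_ends_on_last_covered_day(self, make_rx):
        first = make_rx(date(2010, 1, 1), 30)
        second = make_rx(date(2010, 3, 17), 30)  # 45 uncovered February days
        eps = build_episodes([first, second], "guanfacine", date(2010, 1, 1))
        assert len(eps) == 2
        assert eps[0].discontinuation_date == first.end_date

    def test_100_day_summer_gap_is_allowed(self, make_rx):
        first = make_rx(date(2010, 5, 1), 30)   # covered through May 30
        second = make_rx(date(2010, 9, 8), 30)  # 100-day gap within Jun-Aug+
        eps = build_episodes([first, second], "guanfacine", date(2010, 5, 1))
        assert len(eps) == 1

    def test_back_to_back_fills_create_no_gap(self, make_rx):
        rxs = [make_rx(date(2010, 1, 1), 30), make_rx(date(2010, 1, 31), 30)]
        eps = build_episodes(rxs, "guanfacine", date(2010, 1, 1))
        assert len(eps) == 1
        assert eps[0].length_days == 60

    def test_empty_prescription_list(self):
        assert build_episodes([], "guanfacine", date(2010, 1, 1)) == []

    def test_pre_anchor_coverage_ignored(self, make_rx):
        rxs = [make_rx(date(2008, 1, 1), 30), make_rx(date(2010, 6, 1), 30)]
        eps = build_episodes(rxs, "guanfacine", date(2010, 6, 1))
        assert len(eps) == 1
        assert eps[0].start_date == date(2010, 6, 1)

    def test_agrees_with_daily_grid_oracle_randomized(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            rxs = random_prescriptions(rng)
            for cls in ("guanfacine", "stimulant"):
                starts = [rx.start_date for rx in rxs if rx.drug_class == cls]
                if not starts:
                    continue
                anchor = min(starts)
                got = [
                    (ep.start_date, ep.discontinuation_date)
                    for ep in build_episodes(rxs, cls, anchor)
                ]
                assert got == oracle_episodes(rxs, cls, anchor)

    def test_removing_a_prescription_never_lengthens_first_episode(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            rxs = random_prescriptions(rng)
            gx = [rx for rx in rxs if rx.drug_class == "guanfacine"]
            if len(gx) < 2:
                continue
            anchor = min(rx.start_date for rx in gx)
            full = build_episodes(gx, "guanfacine", anchor)
            reduced_rxs = gx[1:]
            anchor2 = min(rx.start_date for rx in reduced_rxs)
            reduced = build_episodes(reduced_rxs, "guanfacine", max(anchor, anchor2))
            if not reduced:
                continue
            assert reduced[0].discontinuation_date <= full[-1].discontinuation_date


# ---------------------------------------------------------------------------
# prescribed amounts and MPR
# ---------------------------------------------------------------------------

class TestPrescribedAmount:
    def test_four_thirty_day_fills_give_120(self, make_rx):
        rxs = [make_rx(date(2010, 1, 1) + timedelta(days=30 * i), 30) for i in range(4)]
        assert prescribed_amount_per_dose(rxs, WIDE_WINDOW) == 120

    def test_empty_list_gives_zero(self):
        assert prescribed_amount_per_dose([], WIDE_WINDOW) == 0

    def test_same_day_duplicate_fills_sum_supplies(self, make_rx):
        rxs = [make_rx(date(2010, 1, 1), 30), make_rx(date(2010, 1, 1), 30)]
        assert prescribed_amount_per_dose(rxs, WIDE_WINDOW) == 60

    def test_window_clipping(self, make_rx):
        rxs = [make_rx(date(2010, 1, 1), 30)]
        assert prescribed_amount_per_dose(rxs, (date(2010, 1, 16), date(2011, 1, 1))) == 15

    def test_no_overlap_total_is_simple_sum(self, make_rx):
        rxs = [
            make_rx(date(2010, 1, 1), 30, dose="1 mg/day"),
            make_rx(date(2010, 2, 15), 30, dose="2 mg/day"),
        ]
        assert total_prescribed_amount(rxs, WIDE_WINDOW) == 60

    def test_overlap_within_90_days_not_reduced(self, make_rx):
        a = make_rx(date(2010, 1, 1), 100, drug="A", dose="x")
        b = make_rx(date(2010, 2, 10), 100, drug="B", dose="y")  # 60-day overlap
        assert total_prescribed_amount([a, b], WIDE_WINDOW) == 200

    def test_overlap_beyond_90_days_capped(self, make_rx):
        a = make_rx(date(2010, 1, 1), 200, drug="A", dose="x")
        b = make_rx(date(2010, 1, 1), 200, drug="B", dose="y")
        # T = 400, overlap O = 200 -> reduce by O - 90 = 110
        assert total_prescribed_amount([a, b], WIDE_WINDOW) == 290

    def test_total_agrees_with_daily_grid_oracle_randomized(self):
        rng = np.random.default_rng(4321)
        window = (date(2009, 6, 1), date(2012, 6, 1))
        for _ in range(300):
            rxs = random_prescriptions(rng)
            for cls in ("guanfacine", "stimulant"):
                sub = [rx for rx in rxs if rx.drug_class == cls]
                got = total_prescribed_amount(sub, window)
                assert got == oracle_total_amount(sub, window)

    @given(st.integers(0, 400), st.integers(1, 400))
    @settings(max_examples=100, deadline=None)
    def test_mpr_always_in_unit_interval(self, supply, length):
        assert 0.0 <= mpr(supply, length) <= 1.0

    @pytest.mark.parametrize(
        "supply,length,expected", [(120, 120, 1.0), (60, 120, 0.5), (150, 120, 1.0)]
    )
    def test_mpr_values_and_cap(self, supply, length, expected):
        assert mpr(supply, length) == pytest.approx(expected)

    def test_mpr_invalid_length(self):
        with pytest.raises(ValueError):
            mpr(10, 0)

    def test_gapless_single_stream_episode_has_full_mpr(self, make_rx):
        rxs = [make_rx(date(2010, 1, 1) + timedelta(days=30 * i), 30) for i in range(4)]
        ep = build_episodes(rxs, "guanfacine", date(2010, 1, 1))[0]
        m = episode_metrics(rxs, ep)
        assert m.mpr == pytest.approx(1.0)
        assert m.prescribed_amount_days == 120
        assert m.episode_length_days == 120
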