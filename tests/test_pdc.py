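"""PDC engine: formula, year-1 window rules, categories, interval windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from statin_adherence import (
    StudyWindow,
    apply_cohort_exclusions,
    categorize_pdc,
    compute_interval_pdc,
    compute_pdc,
    compute_pdc_year1,
)
from statin_adherence.pdc import CATEGORY_HIGH, CATEGORY_LOW, CATEGORY_MID

from conftest import rx_frame


def brute_force_pdc(days, tablets, start, end):
    """Independent oracle: explicit per-day tablet tally over the window."""
    offset = min(min(days, default=0), start)
    length = max(max(days, default=0), end) - offset + 1
    tally = np.zeros(length)
    for d, t in zip(days, tablets):
        tally[d - offset] += t
    return 100.0 * tally[start - offset : end - offset].sum() / (end - start)


class TestComputePdc:
    @pytest.mark.parametrize(
        "days, tablets, window, expected",
        [
            ([0, 28, 56], 28, (0, 84), 100.0),          # full coverage
            ([0, 40], 28, (0, 80), 70.0),               # 56 tablets / 80 days
            ([], 28, (0, 365), 0.0),                    # no records
            ([0, 28, 56], 28, (28, 56), 100.0),         # interior window
            ([-10, 5], [10, 20], (-10, 10), 150.0),     # negative days allowed
        ],
    )
    def test_examples(self, days, tablets, window, expected):
        assert compute_pdc(rx_frame(days, tablets), StudyWindow(*window)) == pytest.approx(
            expected
        )

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            compute_pdc(rx_frame([0], 28), StudyWindow(10, 10))
        with pytest.raises(ValueError):
            compute_pdc(rx_frame([0], 28), StudyWindow(10, 5))

    @given(
        records=st.lists(
            st.tuples(st.integers(-50, 800), st.integers(1, 120)), max_size=30
        ),
        start=st.integers(-50, 700),
        length=st.integers(1, 400),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_per_day_tally(self, records, start, length):
        days = [d for d, _ in records]
        tablets = [t for _, t in records]
        got = compute_pdc(rx_frame(days, tablets), StudyWindow(start, start + length))
        want = brute_force_pdc(days, tablets, start, start + length)
        assert got == pytest.approx(want, abs=1e-9)

    @given(
        records=st.lists(
            st.tuples(st.integers(0, 400), st.integers(1, 60)), min_size=1, max_size=20
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, records):
        days = [d for d, _ in records]
        tablets = [t for _, t in records]
        w = StudyWindow(0, 401)
        single = compute_pdc(rx_frame(days, tablets), w)
        double = compute_pdc(rx_frame(days, [2 * t for t in tablets]), w)
        assert double == pytest.approx(2 * single, abs=1e-9)

    @given(
        records=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=20
        ),
        cuts=st.tuples(st.integers(0, 100), st.integers(101, 200), st.integers(201, 301)),
    )
    @settings(max_examples=100, deadline=None)
    def test_window_additivity(self, records, cuts):
        """PDC over [a,c) is the length-weighted mean of PDC over [a,b) and [b,c)."""
        a, b, c = cuts
        days = [d for d, _ in records]
        tablets = [t for _, t in records]
        recs = rx_frame(days, tablets)
        left = compute_pdc(recs, StudyWindow(a, b))
        right = compute_pdc(recs, StudyWindow(b, c))
        whole = compute_pdc(recs, StudyWindow(a, c))
        assert whole == pytest.approx(
            (left * (b - a) + right * (c - b)) / (c - a), abs=1e-9
        )


class TestYear1:
    def test_trailing_script_dropped(self):
        # 12 monthly scripts then a final one at day 360 with no successor:
        # its supply is unobserved, so it is dropped and the window ends there
        recs = rx_frame(list(range(0, 331, 30)) + [360], 28)
        pdc1, flags = compute_pdc_year1(recs)
        assert pdc1 == pytest.approx(100 * 336 / 360)
        assert "trailing_script_dropped" in flags

    def test_window_extends_to_next_script(self):
        # 13 scripts within year 1, successor at day 370 extends the window
        recs = rx_frame(list(range(0, 337, 28)) + [370], 28)
        pdc1, flags = compute_pdc_year1(recs)
        assert pdc1 == pytest.approx(100 * 364 / 370)
        assert not flags

    def test_data_error_flagged_above_200(self):
        # 800 tablets inside a full 365-day window
        recs = rx_frame([0, 50, 365], [400, 400, 28])
        pdc1, flags = compute_pdc_year1(recs)
        assert pdc1 == pytest.approx(100 * 800 / 365)
        assert "pdc_gt_200" in flags

    def test_single_script_is_missing(self):
        pdc1, flags = compute_pdc_year1(rx_frame([0], 28))
        assert np.isnan(pdc1)
        assert "pdc1_missing" in flags

    def test_dates_rereferenced_to_first_script(self):
        base = rx_frame(list(range(0, 337, 28)) + [370], 28)
        shifted = rx_frame([d + 1000 for d in list(range(0, 337, 28)) + [370]], 28)
        assert compute_pdc_year1(base)[0] == pytest.approx(compute_pdc_year1(shifted)[0])


class TestCategories:
    @pytest.mark.parametrize(
        "pdc, expected",
        [
            (0.0, CATEGORY_LOW),
            (49.9, CATEGORY_LOW),
            (50.0, CATEGORY_MID),
            (95.0, CATEGORY_MID),
            (95.1, CATEGORY_HIGH),
            (150.0, CATEGORY_HIGH),
        ],
    )
    def test_boundaries(self, pdc, expected):
        assert categorize_pdc(pdc) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_pdc(-1.0)

    def test_total_with_two_breakpoints(self):
        grid = np.arange(0, 250, 0.1)
        cats = [categorize_pdc(p) for p in grid]
        changes = sum(a != b for a, b in zip(cats, cats[1:]))
        assert changes == 2
        assert set(cats) == {CATEGORY_LOW, CATEGORY_MID, CATEGORY_HIGH}


class TestIntervalPdc:
    def test_two_visit_windows(self):
        recs = rx_frame([0, 28, 56, 84], 28)
        out = compute_interval_pdc(recs, [56, 112], baseline_day=-10)
        assert out == [(1, pytest.approx(100.0)), (2, pytest.approx(100.0))]

    def test_empty_window_is_zero(self):
        recs = rx_frame([0, 28], 28)
        out = compute_interval_pdc(recs, [56, 112, 180], baseline_day=0)
        assert out[2] == (3, 0.0)

    def test_single_year_window_matches_compute_pdc(self):
        recs = rx_frame(list(range(0, 365, 28)), 28)
        (k, val), = compute_interval_pdc(recs, [365], baseline_day=0)
        assert val == pytest.approx(compute_pdc(recs, StudyWindow(0, 365)))

    def test_non_monotone_visits_rejected(self):
        with pytest.raises(ValueError):
            compute_interval_pdc(rx_frame([0], 28), [100, 90], baseline_day=0)


class TestCohortExclusions:
    @staticmethod
    def series(pdc1s):
        return pd.DataFrame({"patient_id": range(len(pdc1s)), "pdc1": pdc1s})

    @staticmethod
    def deaths(pairs):
        return pd.DataFrame(
            {
                "patient_id": [p for p, _ in pairs],
                "date_day": [d for _, d in pairs],
                "event_type": "death",
            }
        )

    def test_death_boundary(self):
        series = self.series([100.0, 100.0, 100.0])
        events = self.deaths([(0, 89), (1, 91), (2, 90)])
        kept, report = apply_cohort_exclusions(series, events)
        # "within 3 months" = before day 90: day 89 out, days 90/91 retained
        assert set(kept["patient_id"]) == {1, 2}
        assert report["died_lt_3mo"] == 1

    def test_pdc_above_200_excluded(self):
        kept, report = apply_cohort_exclusions(
            self.series([150.0, 200.0, 200.1]), pd.DataFrame(columns=["patient_id", "date_day", "event_type"])
        )
        assert set(kept["patient_id"]) == {0, 1}   # exactly 200 retained
        assert report["pdc_gt_200"] == 1

    def test_no_violations_is_identity(self):
        series = self.series([90.0, 95.0])
        kept, report = apply_cohort_exclusions(
            series, pd.DataFrame(columns=["patient_id", "date_day", "event_type"])
        )
        pd.testing.assert_frame_equal(kept, series)
        assert report["n_excluded"] == 0
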