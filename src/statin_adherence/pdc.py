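"""Proportion-of-days-covered (PDC) computation from prescription logs.

PDC over a study window is::

    PDC = 100 * (number of tablets prescribed in the window)
              / (length of the window in days)

assuming one tablet per day.  Values above 100% are retained (multi-tablet
regimens); values above 200% are flagged as likely data errors.  First-year
adherence (PDC_1) applies special window rules around the last prescription
of year 1; interval PDC_k covers the window between successive LDL-c
measurement visits.

All dates are integer day offsets from the patient's index date (first
prescription = day 0); windows are half-open ``[start, end)``, so a script
issued on a visit day belongs to the next window.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

YEAR_DAYS = 365
DEATH_WINDOW_DAYS = 90          # "died within 3 months of starting statins"
PDC_ERROR_THRESHOLD = 200.0     # values above this likely indicate data errors

CATEGORY_LOW = "<50"
CATEGORY_MID = "50-95"
CATEGORY_HIGH = ">95"


class StudyWindow(NamedTuple):
    """Half-open day window [start_day, end_day)."""

    start_day: int
    end_day: int


def _records_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["date_day"].to_numpy(), records["n_tablets"].to_numpy()
    days, tablets = records
    return np.asarray(days), np.asarray(tablets)


def compute_pdc(records, window: StudyWindow) -> float:
    """PDC (percent) of one patient's records over a half-open window.

    No capping is applied at this level; an empty window raises, no records
    in the window yields 0.
    """
    start, end = int(window[0]), int(window[1])
    if end <= start:
        raise ValueError(f"zero-length or inverted window [{start}, {end})")
    days, tablets = _records_arrays(records)
    in_window = (days >= start) & (days < end)
    return 100.0 * float(tablets[in_window].sum()) / (end - start)


def compute_pdc_year1(records) -> tuple[float, set[str]]:
    """First-year adherence PDC_1 with the trailing-prescription window rules.

    The index date is the first prescription (day 0 after re-referencing).
    If a prescription exists at day >= 365, the window runs to that
    prescription's date (coverage until the next supply is observed).  If
    the patient's final prescription falls before day 365 with no successor
    at all, that trailing script's supply is unobserved: its tablets are
    dropped and the window ends at its issue date (flag
    ``trailing_script_dropped``).  A patient whose only prescription is the
    trailing one has no observable coverage period: PDC_1 is returned as NaN
    with flag ``pdc1_missing``.  PDC_1 above 200% adds flag ``pdc_gt_200``.
    """
    days, tablets = _records_arrays(records)
    if len(days) == 0:
        raise ValueError("patient has no prescriptions")
    order = np.argsort(days, kind="stable")
    days = days[order] - days[order[0]]     # re-reference to first script
    tablets = tablets[order]

    flags: set[str] = set()
    later = days[days >= YEAR_DAYS]
    if len(later):
        end = int(later.min())
    else:
        last_day = int(days.max())
        if last_day == 0:
            return float("nan"), {"pdc1_missing"}
        flags.add("trailing_script_dropped")
        end = last_day
    pdc1 = compute_pdc((days, tablets), StudyWindow(0, end))
    if pdc1 > PDC_ERROR_THRESHOLD:
        flags.add("pdc_gt_200")
    return pdc1, flags


def categorize_pdc(pdc: float) -> str:
    """Three-band adherence category: ``<50``, ``50-95`` (closed), ``>95``."""
    if pdc < 0 or not np.isfinite(pdc):
        raise ValueError(f"PDC must be a finite non-negative percent, got {pdc}")
    if pdc < 50:
        return CATEGORY_LOW
    if pdc <= 95:
        return CATEGORY_MID
    return CATEGORY_HIGH


def compute_interval_pdc(
    records, visit_days: Iterable[int], baseline_day: int
) -> list[tuple[int, float]]:
    """Interval PDC_k over the windows between successive LDL visits.

    Window k runs ``[visit_{k-1}, visit_k)`` with the first window starting
    at ``max(baseline_day, first prescription day)``.  Values are not
    capped.
    """
    visit_days = np.asarray(list(visit_days), dtype=int)
    if np.any(np.diff(visit_days) <= 0):
        raise ValueError("visit days must be strictly increasing")
    days, tablets = _records_arrays(records)
    first_rx = int(days.min()) if len(days) else int(baseline_day)
    start = max(int(baseline_day), first_rx)
    if np.any(visit_days <= start):
        raise ValueError("all visit days must fall after the window start")

    out = []
    prev = start
    for k, v in enumerate(visit_days, start=1):
        out.append((k, compute_pdc((days, tablets), StudyWindow(prev, int(v)))))
        prev = int(v)
    return out


def apply_cohort_exclusions(
    series: pd.DataFrame, events: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Drop patients who died within 90 days of initiation or have PDC_1 > 200%.

    ``series`` needs columns ``patient_id`` and ``pdc1``; ``events`` is the
    clinical event table (``event_type == 'death'`` rows are used, dates
    relative to the index date).  Returns the filtered table and a report of
    counts per exclusion reason.
    """
    if len(events):
        deaths = events.loc[
            (events["event_type"] == "death") & (events["date_day"] < DEATH_WINDOW_DAYS),
            "patient_id",
        ].unique()
    else:
        deaths = np.array([], dtype=int)
    died = series["patient_id"].isin(deaths)
    high = series["pdc1"] > PDC_ERROR_THRESHOLD
    report = {
        "died_lt_3mo": int(died.sum()),
        "pdc_gt_200": int(high.sum()),
        "n_excluded": int((died | high).sum()),
    }
    return series.loc[~(died | high)].reset_index(drop=True), report


def build_adherence_table(
    prescriptions: pd.DataFrame, visits: pd.DataFrame, K: int | None = None
) -> pd.DataFrame:
    """Per-patient adherence series from a prescription log and visit table.

    ``visits`` needs ``patient_id``, ``baseline_day`` and ``visit_day_1`` ..
    ``visit_day_K`` columns (as produced by the trajectory builder).  Output
    columns: ``pdc1``, ``pdc1_category``, ``pdc_1`` .. ``pdc_K`` (interval
    PDCs) and a semicolon-joined ``flags`` string.
    """
    if K is None:
        K = sum(c.startswith("visit_day_") for c in visits.columns)
    visit_cols = [f"visit_day_{k}" for k in range(1, K + 1)]

    rows = []
    grouped = prescriptions.groupby("patient_id", sort=True)
    visits_idx = visits.set_index("patient_id")
    for pid, recs in grouped:
        row: dict = {"patient_id": pid}
        pdc1, flags = compute_pdc_year1(recs)
        row["pdc1"] = pdc1
        row["pdc1_category"] = categorize_pdc(pdc1) if np.isfinite(pdc1) else ""
        if pid in visits_idx.index:
            v = visits_idx.loc[pid]
            vdays = [int(v[c]) for c in visit_cols if pd.notna(v[c])]
            if vdays:
                days0 = recs["date_day"].to_numpy()
                rel = recs.assign(date_day=days0 - days0.min())
                for k, val in compute_interval_pdc(
                    rel, vdays, int(v["baseline_day"])
                ):
                    row[f"pdc_{k}"] = val
        row["flags"] = ";".join(sorted(flags))
        rows.append(row)
    return pd.DataFrame(rows)
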