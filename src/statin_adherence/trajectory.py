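"""LDL-c response trajectories: baseline/follow-up selection and validity filters.

Baseline LDL-c is the measure closest to (and at most 180 days before) the
first statin prescription.  Follow-ups are either the earliest measure
within 12 months (cross-sectional mode) or the first three post-statin
measures within a 10-year window (longitudinal mode; patients with fewer
than three are dropped).  Validity filters remove individual measures
outside (1, 8) mmol/L and patients whose first statin was prescribed within
90 days of a cardiovascular hospital discharge.

Outcome scales: ``Y = LDL1 / LDL0`` (the follow-up to baseline ratio) and
``LR_k = (LDL_k - LDL_0) / LDL_0`` (fractional reduction at visit k), so
``Y = 1 + LR_1`` identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASELINE_LOOKBACK_DAYS = 180
YEAR1_DAYS = 365
LONGITUDINAL_WINDOW_DAYS = 3652      # "10-year window"
POST_DISCHARGE_DAYS = 90
LDL_VALID_LOW = 1.0                  # exclusive bounds: <1 or >8 dropped
LDL_VALID_HIGH = 8.0


def select_baseline(measures: pd.DataFrame, first_rx_day: int = 0):
    """Baseline LDL-c: latest measure in [first_rx - 180 d, first_rx].

    Same-day duplicates are averaged (flag ``baseline_tie``).  A same-day
    (day of first prescription) measure counts as pre-treatment.  Returns
    ``(value, day, flags)`` or ``None`` when no qualifying measure exists.
    """
    rel = measures["date_day"].to_numpy() - first_rx_day
    ok = (rel >= -BASELINE_LOOKBACK_DAYS) & (rel <= 0)
    if not ok.any():
        return None
    day = rel[ok].max()
    vals = measures.loc[ok & (rel == day), "ldl_mmol_l"].to_numpy()
    flags = {"baseline_tie"} if len(vals) > 1 else set()
    return float(vals.mean()), int(day), flags


def select_followups(
    measures: pd.DataFrame, first_rx_day: int = 0, mode: str = "year1"
) -> pd.DataFrame | None:
    """Follow-up LDL-c measures after statin initiation.

    ``year1``: the earliest measure with 0 < day <= 365 (empty frame if
    none).  ``longitudinal``: the first three post-statin measures within
    10 years; ``None`` when fewer than three exist (the patient is dropped
    from the longitudinal analysis).
    """
    if mode not in ("year1", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    rel = measures["date_day"].to_numpy() - first_rx_day
    if mode == "year1":
        ok = (rel > 0) & (rel <= YEAR1_DAYS)
        sub = measures.loc[ok].sort_values("date_day", kind="stable")
        return sub.head(1)
    ok = (rel > 0) & (rel <= LONGITUDINAL_WINDOW_DAYS)
    sub = measures.loc[ok].sort_values("date_day", kind="stable").head(3)
    if len(sub) < 3:
        return None
    return sub


def apply_ldl_filters(
    measures: pd.DataFrame,
    events: pd.DataFrame,
    level: str = "patient",
) -> tuple[pd.DataFrame, set, dict]:
    """Validity filters on the measurement table.

    Drops individual measures outside (1, 8) mmol/L (bounds exclusive:
    exactly 1.0 or 8.0 is retained), then removes patients whose first
    statin falls within 90 days after a cardiovascular hospital discharge
    (``level='patient'``, the stricter default) or only their measures
    (``level='measure'`` behaves identically on this table).  Dates are
    relative to the index date, so a qualifying discharge lies in
    [-90, 0].  Returns (filtered measures, dropped patient ids, report).
    Applying the filters twice is a no-op.
    """
    if level not in ("patient", "measure"):
        raise ValueError(f"unknown level {level!r}")
    vals = measures["ldl_mmol_l"]
    low = vals < LDL_VALID_LOW
    high = vals > LDL_VALID_HIGH
    kept = measures.loc[~(low | high)]

    if len(events):
        discharges = events.loc[
            (events["event_type"] == "hospital_discharge_cvd")
            & (events["date_day"] >= -POST_DISCHARGE_DAYS)
            & (events["date_day"] <= 0),
            "patient_id",
        ].unique()
    else:
        discharges = np.array([], dtype=int)
    dropped = set(int(p) for p in discharges)
    kept = kept.loc[~kept["patient_id"].isin(discharges)].reset_index(drop=True)

    report = {
        "ldl_low": int(low.sum()),
        "ldl_high": int(high.sum()),
        "post_discharge": len(dropped),
    }
    return kept, dropped, report


def compute_y_and_lr(ldl0: float, followup_values) -> tuple[float, list[float]]:
    """Outcomes from a baseline value and ordered follow-up values.

    ``y_ratio`` = first follow-up / baseline; ``lr_k`` = (LDL_k - LDL_0)/LDL_0.
    """
    if ldl0 <= 0:
        raise ValueError("baseline LDL-c must be positive")
    followup_values = np.asarray(followup_values, dtype=float)
    if len(followup_values) == 0:
        raise ValueError("at least one follow-up measure is required")
    lr = ((followup_values - ldl0) / ldl0).tolist()
    return float(followup_values[0] / ldl0), lr


def build_trajectories(
    measures: pd.DataFrame,
    events: pd.DataFrame,
    mode: str = "longitudinal",
    level: str = "patient",
) -> tuple[pd.DataFrame, dict]:
    """Per-patient trajectory table after validity filtering.

    Measure-level validity filters run before baseline/follow-up selection
    (order matters: an extreme value must not be picked as baseline and
    then discarded patient-and-all).  Output columns: ``patient_id``,
    ``ldl0``, ``baseline_day``, ``visit_day_k`` / ``ldl_k`` / ``lr_k`` for
    each follow-up k, ``y_ratio`` and ``flags``; plus the filter report.
    """
    clean, _, report = apply_ldl_filters(measures, events, level=level)
    rows = []
    n_no_baseline = 0
    n_too_few = 0
    for pid, sub in clean.groupby("patient_id", sort=True):
        base = select_baseline(sub)
        if base is None:
            n_no_baseline += 1
            continue
        ldl0, base_day, flags = base
        # the baseline row must not double as a follow-up
        post = sub.loc[sub["date_day"] > 0]
        fups = select_followups(post, mode=mode)
        if fups is None or len(fups) == 0:
            n_too_few += 1
            continue
        y, lr = compute_y_and_lr(ldl0, fups["ldl_mmol_l"].to_numpy())
        row = {
            "patient_id": pid,
            "ldl0": ldl0,
            "baseline_day": base_day,
            "y_ratio": y,
            "flags": ";".join(sorted(flags)),
        }
        for k, (day, val, lrk) in enumerate(
            zip(fups["date_day"], fups["ldl_mmol_l"], lr), start=1
        ):
            row[f"visit_day_{k}"] = int(day)
            row[f"ldl_{k}"] = float(val)
            row[f"lr_{k}"] = lrk
        rows.append(row)
    report = dict(report)
    report["no_baseline"] = n_no_baseline
    report["insufficient_followups"] = n_too_few
    return pd.DataFrame(rows), report
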