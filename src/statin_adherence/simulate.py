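"""Synthetic statin cohort generator.

Generates cohorts with the causal structure the downstream analysis assumes:
fixed confounders influence both adherence (PDC) and LDL reduction (LR),
past reduction feeds back into future adherence, and each interval PDC has
an additive linear direct effect on the contemporaneous LR with carry-over
of past LR.  The latent panel is rendered into raw-style tables
(prescriptions, LDL measures, covariates, clinical events) so every
downstream stage runs on realistic input with known ground truth.

Dates are integer day offsets from the patient's first prescription
(day 0).  The baseline LDL-c measure is drawn shortly before day 0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig, ConfigurationError

PRESCRIPTION_COLUMNS = ["patient_id", "date_day", "n_tablets", "drug", "dose_band"]
LDL_COLUMNS = ["patient_id", "date_day", "ldl_mmol_l"]
EVENT_COLUMNS = ["patient_id", "date_day", "event_type"]
EVENT_TYPES = ("cvd_diagnosis", "hospital_discharge_cvd", "death")

# NICE dose-intensity mix for first statin prescriptions.
_DOSE_BANDS = ("low", "medium", "high")
_DOSE_PROBS = (0.08, 0.76, 0.16)


# ---------------------------------------------------------------------------
# latent panel
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    """Latent per-patient panel underlying a cohort (the ground truth)."""

    covariates: pd.DataFrame          # patient_id, age, female, ldl0, education, centre, genotype, prevalent_cvd
    pdc: np.ndarray                   # (n, K) latent interval PDC, percent
    lr: np.ndarray                    # (n, K) latent fractional LDL change
    visit_day: np.ndarray             # (n, K) integer follow-up measure days
    baseline_day: np.ndarray          # (n,) integer baseline measure day (< 0)
    ldl: np.ndarray                   # (n, K) emitted follow-up LDL-c, mmol/L
    config: SimulationConfig = field(repr=False, default=None)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _confounder_lp(cov: pd.DataFrame, coefs: dict, config: SimulationConfig) -> np.ndarray:
    """Linear predictor of the fixed confounders (age/LDL0 centred)."""
    edu = np.asarray(coefs["education"], dtype=float)[cov["education"].to_numpy()]
    cen = np.asarray(coefs["centre"], dtype=float)[cov["centre"].to_numpy()]
    return (
        coefs["age"] * (cov["age"].to_numpy() - config.age_mean)
        + coefs["female"] * cov["female"].to_numpy()
        + coefs["ldl0"] * (cov["ldl0"].to_numpy() - config.baseline_ldl_mean)
        + edu
        + cen
    )


def _draw_gaps(rng: np.random.Generator, law: dict, size) -> np.ndarray:
    if law["kind"] == "uniform":
        return rng.integers(int(law["low"]), int(law["high"]) + 1, size=size)
    if law["kind"] == "fixed":
        return np.full(size, int(law["value"]))
    raise ConfigurationError(f"unknown visit_gap_law kind {law['kind']!r}")


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> Panel:
    """Draw the latent cohort panel (confounders, PDCs, LRs, visit times).

    This is the fast path used by Monte-Carlo studies; :func:`generate_cohort`
    additionally renders the panel into raw prescription / measurement tables.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, K = config.n_patients, config.K

    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range, size=n)
    female = (rng.random(n) < config.female_prob).astype(int)
    ldl0 = _truncnorm(
        rng, config.baseline_ldl_mean, config.baseline_ldl_sd, *config.ldl0_range, size=n
    )
    education = rng.choice(len(config.education_probs), size=n, p=config.education_probs)
    centre = rng.choice(len(config.centre_probs), size=n, p=config.centre_probs)
    maf = config.genotype_maf
    genotype = rng.binomial(2, maf, size=n)
    prevalent_cvd = (rng.random(n) < config.prevalent_cvd_prob).astype(int)

    cov = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=int),
            "age": np.round(age, 1),
            "female": female,
            "ldl0": np.round(ldl0, 3),
            "education": education,
            "centre": centre,
            "genotype": genotype,
            "prevalent_cvd": prevalent_cvd,
        }
    )

    lp_pdc = _confounder_lp(cov, config.conf_coefs["pdc"], config)
    lp_lr = _confounder_lp(cov, config.conf_coefs["lr"], config)

    pdc = np.empty((n, K))
    lr = np.empty((n, K))
    lr_prev = np.zeros(n)
    for k in range(K):
        noise_p = rng.normal(0.0, config.pdc_noise_sd, n) if config.pdc_noise_sd else 0.0
        pdc[:, k] = np.clip(
            config.pdc_intercept + lp_pdc + config.feedback_coef * lr_prev + noise_p,
            0.0,
            150.0,
        )
        noise_l = rng.normal(0.0, config.lr_noise_sd, n) if config.lr_noise_sd else 0.0
        lr[:, k] = (
            config.beta_direct[k] * pdc[:, k]
            + config.carry_coef * lr_prev
            + lp_lr
            + config.lr_intercept
            + noise_l
        )
        lr_prev = lr[:, k]

    gaps = _draw_gaps(rng, config.visit_gap_law, (n, K))
    visit_day = np.cumsum(gaps, axis=1).astype(int)

    lo_b, hi_b = config.baseline_measure_day_range
    baseline_day = rng.integers(lo_b, hi_b + 1, size=n)

    ldl = np.clip(
        cov["ldl0"].to_numpy()[:, None] * (1.0 + lr), *config.ldl_emit_range
    )

    return Panel(
        covariates=cov,
        pdc=pdc,
        lr=lr,
        visit_day=visit_day,
        baseline_day=baseline_day,
        ldl=np.round(ldl, 3),
        config=config,
    )


# ---------------------------------------------------------------------------
# prescription rendering
# ---------------------------------------------------------------------------

def render_prescriptions(
    latent_pdcs,
    visit_days,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    start_day: int = 0,
):
    """Invert the PDC formula: emit scripts reproducing the latent interval PDCs.

    Within each inter-visit window [v_{k-1}, v_k) (v_0 = ``start_day``), the
    total tablet count is round(PDC_k/100 * window length); it is issued as
    full scripts of ``tablets_per_script`` tablets at spacing
    ``tablets_per_script / (PDC/100)`` days, plus one remainder script, so
    the interval PDC recomputed from the emitted records matches the latent
    value to within half a tablet per window (well inside +/-2 percentage
    points at zero jitter).  Optional Gaussian jitter perturbs issue dates;
    the very first script stays at day 0 (it defines the index date).

    Returns (days, tablets) integer arrays sorted by day.
    """
    latent_pdcs = np.asarray(latent_pdcs, dtype=float)
    visit_days = np.asarray(visit_days, dtype=int)
    if np.any(latent_pdcs > 150):
        raise ConfigurationError("latent PDC above 150 is outside the generative range")
    if np.any(latent_pdcs < 0):
        raise ConfigurationError("latent PDC must be >= 0")
    if len(visit_days) != len(latent_pdcs):
        raise ConfigurationError("latent_pdcs and visit_days length mismatch")
    if np.any(np.diff(np.concatenate([[start_day], visit_days])) <= 0):
        raise ConfigurationError("visit days must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(0)

    T = config.tablets_per_script
    days: list[int] = []
    tablets: list[int] = []
    prev = start_day
    for pdc_val, v in zip(latent_pdcs, visit_days):
        width = v - prev
        if pdc_val > 0:
            rate = pdc_val / 100.0
            n_tabs = int(round(rate * width))
            if n_tabs > 0:
                gap = T / rate
                n_full, rem = divmod(n_tabs, T)
                w_days = [prev + int(round(i * gap)) for i in range(n_full)]
                w_tabs = [T] * n_full
                if rem:
                    w_days.append(min(prev + int(round(n_full * gap)), v - 1))
                    w_tabs.append(rem)
                w_days = np.minimum(w_days, v - 1).astype(int)
                days.extend(w_days.tolist())
                tablets.extend(w_tabs)
        prev = v

    days = np.asarray(days, dtype=int)
    tablets = np.asarray(tablets, dtype=int)
    if config.jitter_sd > 0 and len(days) > 1:
        jitter = np.round(rng.normal(0.0, config.jitter_sd, len(days))).astype(int)
        jitter[0] = 0  # index date stays put
        days = np.clip(days + jitter, start_day, None)
    order = np.argsort(days, kind="stable")
    return days[order], tablets[order]


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Raw-style tables for one synthetic cohort plus the generating truth."""

    prescriptions: pd.DataFrame
    ldl_measures: pd.DataFrame
    covariates: pd.DataFrame
    events: pd.DataFrame
    truth: dict

    def table_hashes(self) -> dict[str, str]:
        out = {}
        for name in ("prescriptions", "ldl_measures", "covariates", "events"):
            df = getattr(self, name)
            out[name] = hashlib.sha256(
                df.to_csv(index=False).encode()
            ).hexdigest()
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False)
        self.ldl_measures.to_csv(out / "ldl.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)

    @classmethod
    def read(cls, in_dir) -> "CohortBundle":
        p = Path(in_dir)
        with open(p / "truth.json") as fh:
            truth = json.load(fh)
        return cls(
            prescriptions=pd.read_csv(p / "prescriptions.csv"),
            ldl_measures=pd.read_csv(p / "ldl.csv"),
            covariates=pd.read_csv(p / "covariates.csv"),
            events=pd.read_csv(p / "events.csv"),
            truth=truth,
        )


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort as raw tables with known truth."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    n, K = config.n_patients, config.K
    cov = panel.covariates

    drug = np.where(rng.random(n) < 0.5, "atorvastatin", "simvastatin")
    dose = rng.choice(_DOSE_BANDS, size=n, p=_DOSE_PROBS)

    rx_frames = []
    for i in range(n):
        d, t = render_prescriptions(
            panel.pdc[i], panel.visit_day[i], config, rng=rng
        )
        if len(d) == 0:
            # keep the index-date anchor: every patient has a first script
            d, t = np.array([0]), np.array([config.tablets_per_script])
        rx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": i,
                    "date_day": d,
                    "n_tablets": t,
                    "drug": drug[i],
                    "dose_band": dose[i],
                }
            )
        )
    prescriptions = pd.concat(rx_frames, ignore_index=True)

    ldl_rows = {
        "patient_id": np.concatenate(
            [cov["patient_id"].to_numpy(), np.repeat(cov["patient_id"].to_numpy(), K)]
        ),
        "date_day": np.concatenate([panel.baseline_day, panel.visit_day.ravel()]),
        "ldl_mmol_l": np.concatenate([cov["ldl0"].to_numpy(), panel.ldl.ravel()]),
    }
    ldl_measures = (
        pd.DataFrame(ldl_rows)
        .sort_values(["patient_id", "date_day"], kind="stable")
        .reset_index(drop=True)
    )

    cvd_ids = cov.loc[cov["prevalent_cvd"] == 1, "patient_id"].to_numpy()
    if len(cvd_ids):
        events = pd.DataFrame(
            {
                "patient_id": cvd_ids,
                "date_day": rng.integers(-500, -99, size=len(cvd_ids)),
                "event_type": "cvd_diagnosis",
            }
        )
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    truth = {
        "config": config.to_dict(),
        "true_effect_matrix": [
            [None if np.isnan(v) else v for v in row]
            for row in config.true_effect_matrix()
        ],
        "patient_id": cov["patient_id"].tolist(),
        "latent_pdc": np.round(panel.pdc, 6).tolist(),
        "latent_lr": np.round(panel.lr, 6).tolist(),
        "visit_day": panel.visit_day.tolist(),
        "baseline_day": panel.baseline_day.tolist(),
    }

    return CohortBundle(
        prescriptions=prescriptions,
        ldl_measures=ldl_measures,
        covariates=cov,
        events=events,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# violation planting
# ---------------------------------------------------------------------------

_VIOLATION_CLASSES = ("pdc_gt_200", "ldl_low", "died_lt_3mo", "post_discharge")


def plant_violations(
    bundle: CohortBundle, plan: dict, seed: int = 0
) -> tuple[CohortBundle, dict]:
    """Inject a known number of validity violations into a clean bundle.

    ``plan`` maps violation class to a count: ``pdc_gt_200`` (duplicate
    same-day scripts driving first-year PDC above 200%), ``ldl_low``
    (follow-up measures set to 0.5 mmol/L), ``died_lt_3mo`` (death recorded
    at day 45), ``post_discharge`` (cardiovascular hospital discharge 30
    days before the first prescription).  Patients are chosen disjointly at
    random.  Returns the modified bundle and a ledger of exactly which
    patients/measure rows were altered, so filter reports can be reconciled
    against known counts.
    """
    from .pdc import compute_pdc_year1  # local import: pdc does not import simulate

    unknown = set(plan) - set(_VIOLATION_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown violation classes: {sorted(unknown)}")
    total = sum(plan.values())
    ids = bundle.covariates["patient_id"].to_numpy()
    if total > len(ids):
        raise ConfigurationError("requested violation count exceeds n_patients")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(ids, size=total, replace=False)
    ledger: dict[str, list] = {c: [] for c in _VIOLATION_CLASSES}
    pos = 0

    rx = bundle.prescriptions.copy()
    ldl = bundle.ldl_measures.copy()
    events = bundle.events.copy()

    T = int(bundle.truth["config"]["tablets_per_script"]) if bundle.truth else 28

    for pid in chosen[pos : pos + plan.get("pdc_gt_200", 0)]:
        while True:
            sub = rx.loc[rx["patient_id"] == pid]
            pdc1, _ = compute_pdc_year1(sub)
            if np.isfinite(pdc1) and pdc1 > 200:
                break
            # top up with duplicate same-day scripts at day 1
            need = max(int(np.ceil((2.05 * 365 - sub["n_tablets"].sum()) / T)), 1)
            first = sub.iloc[0]
            add = pd.DataFrame(
                {
                    "patient_id": pid,
                    "date_day": 1,
                    "n_tablets": T,
                    "drug": first["drug"],
                    "dose_band": first["dose_band"],
                },
                index=range(need),
            )
            rx = pd.concat([rx, add], ignore_index=True)
        ledger["pdc_gt_200"].append(int(pid))
    pos += plan.get("pdc_gt_200", 0)

    n_low = plan.get("ldl_low", 0)
    for pid in chosen[pos : pos + n_low]:
        rows = ldl.index[(ldl["patient_id"] == pid) & (ldl["date_day"] > 0)]
        row = int(rows[0])
        ldl.loc[row, "ldl_mmol_l"] = 0.5
        ledger["ldl_low"].append({"patient_id": int(pid), "row": row})
    pos += n_low

    for pid in chosen[pos : pos + plan.get("died_lt_3mo", 0)]:
        events = pd.concat(
            [
                events,
                pd.DataFrame(
                    {"patient_id": [pid], "date_day": [45], "event_type": ["death"]}
                ),
            ],
            ignore_index=True,
        )
        ledger["died_lt_3mo"].append(int(pid))
    pos += plan.get("died_lt_3mo", 0)

    for pid in chosen[pos : pos + plan.get("post_discharge", 0)]:
        events = pd.concat(
            [
                events,
                pd.DataFrame(
                    {
                        "patient_id": [pid],
                        "date_day": [-30],
                        "event_type": ["hospital_discharge_cvd"],
                    }
                ),
            ],
            ignore_index=True,
        )
        ledger["post_discharge"].append(int(pid))

    rx = rx.sort_values(["patient_id", "date_day"], kind="stable").reset_index(drop=True)
    out = CohortBundle(
        prescriptions=rx,
        ldl_measures=ldl,
        covariates=bundle.covariates,
        events=events.reset_index(drop=True),
        truth=bundle.truth,
    )
    ledger["counts"] = {c: len(ledger[c]) for c in _VIOLATION_CLASSES}
    return out, ledger
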