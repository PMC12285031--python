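"""End-to-end glue: raw cohort tables -> adherence -> trajectories -> MSM.

Wires the PDC engine, trajectory builder and weighting/MSM stages together
on the four raw tables (prescriptions, LDL measures, covariates, events),
mirroring how the analysis runs on real primary-care extracts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .msm import MsmEstimate, fit_weighted_msm
from .pdc import apply_cohort_exclusions, build_adherence_table
from .simulate import CohortBundle
from .trajectory import build_trajectories
from .weights import BalanceReport, ConfounderMatrix, WeightSet, check_balance, estimate_weights

FIXED_CONFOUNDERS = ["age", "female", "ldl0"]
CATEGORICAL_CONFOUNDERS = ["education", "centre"]


def one_hot_confounders(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric fixed-confounder design: age, sex, LDL0 + one-hot education/centre."""
    out = covariates[FIXED_CONFOUNDERS].astype(float).copy()
    for col in CATEGORICAL_CONFOUNDERS:
        dummies = pd.get_dummies(covariates[col], prefix=col, drop_first=True)
        out = pd.concat([out, dummies.astype(float)], axis=1)
    return out


def build_msm_inputs(bundle: CohortBundle, K: int = 3) -> dict:
    """Assemble complete-case MSM inputs from raw tables.

    Runs the LDL validity filters and longitudinal follow-up selection,
    derives interval PDCs between the selected visits, applies the cohort
    exclusions (early death, PDC_1 > 200%), and joins the fixed
    confounders.  Returns exposures (n, K), outcomes (n, K), the
    :class:`ConfounderMatrix` and the intermediate tables/reports.
    """
    trajectories, traj_report = build_trajectories(
        bundle.ldl_measures, bundle.events, mode="longitudinal"
    )
    missing = [k for k in range(1, K + 1) if f"lr_{k}" not in trajectories.columns]
    if missing:
        raise ValueError(f"no patients with {K} follow-up measures (missing LR {missing})")
    adherence = build_adherence_table(bundle.prescriptions, trajectories, K=K)
    adherence, excl_report = apply_cohort_exclusions(adherence, bundle.events)

    pdc_cols = [f"pdc_{k}" for k in range(1, K + 1)]
    lr_cols = [f"lr_{k}" for k in range(1, K + 1)]
    visit_cols = [f"visit_day_{k}" for k in range(1, K + 1)]

    # the measured baseline (trajectory ldl0) is the confounder, not the
    # generator-side covariate copy
    cov_cols = [c for c in bundle.covariates.columns if c != "ldl0"]
    merged = trajectories.merge(
        adherence[["patient_id", "pdc1", "pdc1_category"] + pdc_cols],
        on="patient_id",
        how="inner",
    ).merge(bundle.covariates[cov_cols], on="patient_id", how="inner")
    merged = merged.dropna(subset=pdc_cols + lr_cols + visit_cols).reset_index(drop=True)

    conf = ConfounderMatrix(
        fixed=one_hot_confounders(merged),
        visit_day=merged[visit_cols].to_numpy(dtype=float),
        lr=merged[lr_cols].to_numpy(dtype=float),
    )
    return {
        "patient_id": merged["patient_id"].to_numpy(),
        "exposures": merged[pdc_cols].to_numpy(dtype=float),
        "lr": merged[lr_cols].to_numpy(dtype=float),
        "confounders": conf,
        "table": merged,
        "trajectories": trajectories,
        "adherence": adherence,
        "reports": {"trajectory": traj_report, "exclusions": excl_report},
    }


def forced_covariate_frame(
    balance: BalanceReport, conf: ConfounderMatrix, exposures: np.ndarray
) -> pd.DataFrame:
    """Resolve failed balance covariates to data columns for the regression.

    Lagged exposures are skipped (they already appear as regressors in the
    stage-2 fits); everything else failing the 0.1 criterion is forced in.
    """
    A = np.asarray(exposures, dtype=float)
    K = A.shape[1]
    cols = {}
    for name in balance.failed_covariates:
        if name in conf.fixed.columns:
            cols[name] = conf.fixed[name].to_numpy(dtype=float)
        elif name.startswith("visit_day_"):
            k = int(name.split("_")[-1])
            cols[name] = conf.visit_day[:, k - 1]
        elif name.startswith("lr_"):
            k = int(name.split("_")[-1])
            if k < K:
                cols[name] = conf.lr[:, k - 1]
        # pdc_lag_* intentionally skipped
    return pd.DataFrame(cols)


def run_msm_pipeline(
    bundle: CohortBundle,
    K: int = 3,
    method: str = "parametric_cbps",
    n_bootstrap: int = 500,
    seed: int | None = None,
    ci_method: str = "percentile",
    truncate: tuple[float, float] | None = None,
) -> dict:
    """Full stage-1 + stage-2 estimation on a raw cohort bundle.

    Returns the weight set, balance report, fitted :class:`MsmEstimate`
    (bootstrap re-estimates the weights inside every replicate) and the
    assembled inputs.
    """
    inputs = build_msm_inputs(bundle, K=K)
    A = inputs["exposures"]
    conf = inputs["confounders"]
    ws = estimate_weights(A, conf, method=method, truncate=truncate)
    balance = check_balance(ws, A, conf)
    forced = forced_covariate_frame(balance, conf, A)

    delta0 = ws.meta.get("delta")

    def weight_refit(idx: np.ndarray) -> np.ndarray:
        sub = conf.subset(idx)
        return estimate_weights(
            A[idx], sub, method=method, truncate=truncate, delta0=delta0
        ).w

    estimate = fit_weighted_msm(
        inputs["lr"],
        A,
        ws,
        forced_covariates=forced if len(forced.columns) else None,
        n_bootstrap=n_bootstrap,
        seed=seed,
        ci_method=ci_method,
        weight_refit=weight_refit,
    )
    return {
        "estimate": estimate,
        "weights": ws,
        "balance": balance,
        "inputs": inputs,
    }
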