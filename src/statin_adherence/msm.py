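"""Weighted outcome regressions and intervention contrasts.

Stage 2 of the IPTW procedure: for each time point k, LR_k is regressed on
PDC_1..PDC_k simultaneously by weighted OLS in the pseudo-population.  The
coefficient on the contemporaneous PDC_k is the direct effect; coefficients
on earlier PDCs are total effects that include transmission through the
intermediate LDL reductions.  Covariates that failed the balancing test are
forced into the regression.  Uncertainty comes from a nonparametric
patient-level bootstrap in which the weights are re-estimated inside every
replicate (the weights are themselves estimated, so their sampling
variability must propagate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .weights import WeightSet


@dataclass
class MsmEstimate:
    """Weighted-OLS coefficients of PDC_1..PDC_k on LR_k for each k.

    ``coef[k-1, j-1]`` is the effect of PDC_j on LR_k (LR units per PDC
    percentage point); the array is lower-triangular with NaN above the
    diagonal.  ``draws`` holds bootstrap replicates with the same layout.
    """

    coef: np.ndarray                      # (K, K)
    se: np.ndarray                        # (K, K)
    ci_low: np.ndarray                    # (K, K)
    ci_high: np.ndarray                   # (K, K)
    forced_covariates: list[str]
    n: int
    draws: np.ndarray | None = None       # (B, K, K)
    bootstrap: dict = field(default_factory=dict)
    forced_coef: pd.DataFrame | None = None

    @property
    def K(self) -> int:
        return self.coef.shape[0]


@dataclass
class Contrast:
    """LR difference between two adherence profiles, with bootstrap CI."""

    value: float
    ci_low: float
    ci_high: float
    k: int
    draws: np.ndarray | None = None


def _fit_all_k(
    lr: np.ndarray, A: np.ndarray, w: np.ndarray, forced: np.ndarray | None
) -> np.ndarray:
    """(K, K) lower-triangular coefficient matrix from per-k WLS fits."""
    n, K = A.shape
    coef = np.full((K, K), np.nan)
    for k in range(K):
        X = A[:, : k + 1]
        if forced is not None and forced.size:
            X = np.column_stack([X, forced])
        X = sm.add_constant(X, has_constant="add")
        res = sm.WLS(lr[:, k], X, weights=w).fit()
        coef[k, : k + 1] = res.params[1 : k + 2]
    return coef


def fit_weighted_msm(
    lr,
    exposures,
    weights,
    forced_covariates: pd.DataFrame | None = None,
    n_bootstrap: int = 500,
    seed: int | None = None,
    ci_method: str = "percentile",
    weight_refit: Callable[[np.ndarray], np.ndarray] | None = None,
    alpha: float = 0.05,
) -> MsmEstimate:
    """Weighted OLS of LR_k on PDC_1..PDC_k for every k, with bootstrap CIs.

    ``weights`` is a :class:`WeightSet` or plain array.  ``forced_covariates``
    (columns that failed the balance test, plus any user-forced columns) are
    appended to every regression.  ``weight_refit`` maps a bootstrap index
    vector to re-estimated weights for the resampled patients; when omitted
    the original weights are resampled (appropriate only when the weights
    are fixed/known).  ``ci_method`` is ``percentile`` or ``normal``
    (point estimate +/- z * bootstrap SD; usable at small bootstrap sizes).
    With ``n_bootstrap=0`` the per-fit WLS standard errors are reported.
    """
    lr = np.asarray(lr, dtype=float)
    A = np.asarray(exposures, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if lr.ndim == 1:
        lr = lr[:, None]
    n, K = A.shape
    if lr.shape[1] < K:
        raise ValueError(f"need LR columns for all K={K} time points, got {lr.shape[1]}")
    lr = lr[:, :K]
    w = weights.w if isinstance(weights, WeightSet) else np.asarray(weights, float)
    if ci_method not in ("percentile", "normal"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    forced_arr = None
    forced_names: list[str] = []
    if forced_covariates is not None and len(forced_covariates.columns):
        forced_arr = forced_covariates.to_numpy(dtype=float)
        forced_names = [str(c) for c in forced_covariates.columns]

    coef = _fit_all_k(lr, A, w, forced_arr)

    z = 1.959963984540054  # two-sided 95% normal quantile
    se = np.full_like(coef, np.nan)
    ci_low = np.full_like(coef, np.nan)
    ci_high = np.full_like(coef, np.nan)
    draws = None
    n_failed = 0

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = np.full((n_bootstrap, K, K), np.nan)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                wb = weight_refit(idx) if weight_refit is not None else w[idx]
                fb = forced_arr[idx] if forced_arr is not None else None
                draws[b] = _fit_all_k(lr[idx], A[idx], wb, fb)
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
        ok = ~np.isnan(draws[:, K - 1, K - 1])
        good = draws[ok]
        for k in range(K):
            for j in range(k + 1):
                cell = good[:, k, j]
                se[k, j] = cell.std(ddof=1)
                if ci_method == "percentile":
                    ci_low[k, j], ci_high[k, j] = np.percentile(cell, [
                        100 * alpha / 2, 100 * (1 - alpha / 2)
                    ])
                else:
                    ci_low[k, j] = coef[k, j] - z * se[k, j]
                    ci_high[k, j] = coef[k, j] + z * se[k, j]
    else:
        # analytic WLS intervals as a no-bootstrap fallback
        for k in range(K):
            X = A[:, : k + 1]
            if forced_arr is not None:
                X = np.column_stack([X, forced_arr])
            X = sm.add_constant(X, has_constant="add")
            res = sm.WLS(lr[:, k], X, weights=w).fit(cov_type="HC0")
            se[k, : k + 1] = res.bse[1 : k + 2]
            ci = res.conf_int(alpha=alpha)
            ci_low[k, : k + 1] = ci[1 : k + 2, 0]
            ci_high[k, : k + 1] = ci[1 : k + 2, 1]

    return MsmEstimate(
        coef=coef,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        forced_covariates=forced_names,
        n=n,
        draws=draws,
        bootstrap={
            "n_requested": n_bootstrap,
            "n_failed": n_failed,
            "seed": seed,
            "ci_method": ci_method,
        },
    )


def _contrast_from_coefs(coef_row: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float(np.nansum(coef_row * (a - b)))


def intervention_contrast(
    estimate: MsmEstimate, profile_a, profile_b, k: int | None = None
) -> Contrast:
    """Average LR difference under profile_a versus profile_b at time k.

    Profiles are PDC vectors of length k; the contrast is
    sum_j b_{k,j} (a_j - b_j), e.g. all-100 versus all-0 gives
    100 * sum_j b_{k,j}.  The CI propagates the bootstrap coefficient
    replicates through the same linear form.
    """
    if k is None:
        k = estimate.K
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if len(a) != k or len(b) != k:
        raise ValueError(f"profiles must have length k={k}")
    row = estimate.coef[k - 1, :k]
    value = _contrast_from_coefs(row, a, b)
    lo = hi = float("nan")
    cdraws = None
    if estimate.draws is not None:
        cdraws = np.nansum(estimate.draws[:, k - 1, :k] * (a - b), axis=1)
        cdraws = cdraws[np.isfinite(cdraws)]
        if len(cdraws):
            lo, hi = np.percentile(cdraws, [2.5, 97.5])
    return Contrast(value=value, ci_low=float(lo), ci_high=float(hi), k=k, draws=cdraws)


def personal_max_contrast(estimate: MsmEstimate, observed_pdcs) -> Contrast:
    """Cohort-mean LR gain from holding each patient at their own maximum PDC.

    For each patient the constant-at-personal-max profile is contrasted
    with the observed profile at the final time point; the cohort mean and
    a bootstrap CI (propagated through the coefficient replicates) are
    returned.  Patients already constant contribute zero.
    """
    P = np.asarray(observed_pdcs, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    K = estimate.K
    if P.shape[1] != K:
        raise ValueError(f"observed PDCs must have K={K} columns")
    delta = P.max(axis=1, keepdims=True) - P          # (n, K), >= 0
    mean_delta = delta.mean(axis=0)
    row = estimate.coef[K - 1, :K]
    value = float(np.nansum(row * mean_delta))
    lo = hi = float("nan")
    cdraws = None
    if estimate.draws is not None:
        cdraws = np.nansum(estimate.draws[:, K - 1, :K] * mean_delta, axis=1)
        cdraws = cdraws[np.isfinite(cdraws)]
        if len(cdraws):
            lo, hi = np.percentile(cdraws, [2.5, 97.5])
    return Contrast(value=value, ci_low=float(lo), ci_high=float(hi), k=K, draws=cdraws)
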