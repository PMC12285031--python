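"""Covariate-balancing inverse-probability weights for sequential continuous exposures.

The exposure at each visit k is the interval adherence PDC_k (continuous,
percent).  Weights are built in two stages:

1.  *Stabilized density-ratio weights.*  For each k the conditional law of
    PDC_k given the fixed confounders, the lagged exposure/outcome
    (PDC_{k-1}, LR_{k-1}) and the visit time is modelled as Gaussian-linear;
    the stabilizing numerator is the Gaussian law of PDC_k given past
    exposures only.  The patient weight is the product over k of
    numerator/denominator densities.

2.  *Balance calibration.*  The stabilized weights are exponentially tilted
    (entropy calibration) so the weighted cross-moments between every
    exposure and every confounding covariate are exactly zero in the
    pseudo-population — the covariate-balancing construction for continuous
    treatments.  The non-parametric variant applies the same tilt to
    uniform base weights, dispensing with the Gaussian density model.

Balance is then verified with weighted Pearson and Spearman correlations
between each exposure and covariate; a covariate whose average absolute
correlation stays below 0.1 is deemed sufficiently balanced, and failures
are routed into the outcome regression as adjustment covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

BALANCE_THRESHOLD = 0.1

WEIGHT_METHODS = ("parametric_cbps", "npcbps_fallback", "stabilized_ipw")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ConfounderMatrix:
    """Confounders aligned with the exposure matrix.

    ``fixed``: numeric DataFrame (categoricals one-hot encoded), one row per
    patient.  ``visit_day``: (n, K) visit times.  ``lr``: (n, K) observed
    LDL reductions LR_1..LR_K (the lagged value LR_{k-1} is derived
    internally, with LR_0 = 0).
    """

    fixed: pd.DataFrame
    visit_day: np.ndarray
    lr: np.ndarray

    def __post_init__(self):
        self.visit_day = np.asarray(self.visit_day, dtype=float)
        self.lr = np.asarray(self.lr, dtype=float)
        if self.visit_day.ndim == 1:
            self.visit_day = self.visit_day[:, None]
        if self.lr.ndim == 1:
            self.lr = self.lr[:, None]
        n = len(self.fixed)
        if self.visit_day.shape[0] != n or self.lr.shape[0] != n:
            raise ValueError("confounder blocks have inconsistent row counts")
        if self.fixed.isna().any().any():
            raise ValueError("confounders must be complete cases")

    def subset(self, idx) -> "ConfounderMatrix":
        return ConfounderMatrix(
            fixed=self.fixed.iloc[idx].reset_index(drop=True),
            visit_day=self.visit_day[idx],
            lr=self.lr[idx],
        )

    def lagged_lr(self, K: int) -> np.ndarray:
        """(n, K) matrix whose column k-1 is LR_{k-1} (zeros for k=1)."""
        n = len(self.fixed)
        out = np.zeros((n, K))
        out[:, 1:] = self.lr[:, : K - 1]
        return out


@dataclass
class WeightSet:
    """Estimated balancing weights with provenance."""

    w: np.ndarray                      # (n,) final weights, mean 1
    w_k: np.ndarray                    # (n, K) per-time-point density ratios
    method: str
    truncation: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.w)


@dataclass
class BalanceReport:
    """Weighted exposure-covariate correlations and the pass/fail verdict.

    ``table`` has one row per covariate with per-exposure Pearson and
    Spearman correlations, the averaged absolute correlation and a status in
    {'pass', 'fail', 'n/a'} ('n/a' marks zero-variance covariates, which are
    never counted as balanced).
    """

    table: pd.DataFrame
    threshold: float = BALANCE_THRESHOLD

    @property
    def failed_covariates(self) -> list[str]:
        return self.table.index[self.table["status"] == "fail"].tolist()

    @property
    def all_balanced(self) -> bool:
        return bool((self.table["status"] == "pass").all())


# ---------------------------------------------------------------------------
# weighted correlation utilities
# ---------------------------------------------------------------------------

def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation; NaN when either variable is degenerate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    if vx <= 0 or vy <= 0:
        return float("nan")
    cov = (w * (x - mx) * (y - my)).sum() / sw
    return float(cov / np.sqrt(vx * vy))


def weighted_spearman(x, y, w) -> float:
    """Weighted Spearman correlation: average ranks, then weighted Pearson."""
    return weighted_pearson(rankdata(x), rankdata(y), w)


# ---------------------------------------------------------------------------
# stage 1: Gaussian stabilized density-ratio weights
# ---------------------------------------------------------------------------

def _gaussian_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _fit_gaussian(y: np.ndarray, X: np.ndarray):
    """OLS fit returning (fitted mean, residual SD); degenerate fits -> None."""
    n, p = X.shape
    if n <= p + 1:
        return None
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ coef
    resid = y - mu
    dof = max(n - rank, 1)
    sd = float(np.sqrt((resid ** 2).sum() / dof))
    if sd <= 0 or not np.isfinite(sd):
        return None
    return mu, sd


def _stabilized_weights(
    A: np.ndarray, conf: ConfounderMatrix
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-k density-ratio weights; returns (w, w_k matrix, notes)."""
    n, K = A.shape
    Xfix = conf.fixed.to_numpy(dtype=float)
    lr_lag = conf.lagged_lr(K)
    ones = np.ones((n, 1))
    w_k = np.ones((n, K))
    notes: list[str] = []
    for k in range(K):
        past = A[:, :k]
        Xden = np.column_stack([ones, Xfix, past, lr_lag[:, [k]], conf.visit_day[:, [k]]])
        Xnum = np.column_stack([ones, past])
        den = _fit_gaussian(A[:, k], Xden)
        num = _fit_gaussian(A[:, k], Xnum)
        if den is None or num is None:
            notes.append(f"k={k + 1}: degenerate exposure model, unit weights")
            continue
        w_k[:, k] = np.exp(
            _gaussian_logpdf(A[:, k], num[0], num[1])
            - _gaussian_logpdf(A[:, k], den[0], den[1])
        )
    w = w_k.prod(axis=1)
    w = w / w.mean()
    return w, w_k, notes


# ---------------------------------------------------------------------------
# stage 2: entropy-tilt balance calibration
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd <= 0:
        return None
    return (x - x.mean()) / sd


def balance_design(A: np.ndarray, conf: ConfounderMatrix):
    """Moment matrix G whose zero weighted mean encodes covariate balance.

    Columns: standardized exposures, standardized unique covariates, and
    every exposure x covariate cross-product (fixed confounders for every k;
    lagged LR, lagged PDC and the visit time for their own k).  Zero
    weighted column means make every weighted exposure-covariate covariance
    vanish in the pseudo-population.
    """
    n, K = A.shape
    cols: list[np.ndarray] = []
    labels: list[str] = []

    a_std = []
    for k in range(K):
        s = _standardize(A[:, k])
        if s is None:
            continue
        a_std.append((k, s))
        cols.append(s)
        labels.append(f"pdc_{k + 1}")

    cov_cols: dict[str, np.ndarray] = {}
    for name in conf.fixed.columns:
        s = _standardize(conf.fixed[name].to_numpy(dtype=float))
        if s is not None:
            cov_cols[str(name)] = s
    lr_lag = conf.lagged_lr(K)
    per_k_cov: dict[int, list[tuple[str, np.ndarray]]] = {k: [] for k in range(K)}
    for k in range(K):
        s = _standardize(conf.visit_day[:, k])
        if s is not None:
            per_k_cov[k].append((f"visit_day_{k + 1}", s))
        if k >= 1:
            s = _standardize(lr_lag[:, k])
            if s is not None:
                per_k_cov[k].append((f"lr_{k}", s))
            s = _standardize(A[:, k - 1])
            if s is not None:
                per_k_cov[k].append((f"pdc_lag_{k}", s))

    for name, z in cov_cols.items():
        cols.append(z)
        labels.append(name)
    seen_tv = set()
    for k in range(K):
        for name, z in per_k_cov[k]:
            if name not in seen_tv and not name.startswith("pdc_lag"):
                cols.append(z)
                labels.append(name)
                seen_tv.add(name)

    for k, a in a_std:
        for name, z in cov_cols.items():
            cols.append(a * z)
            labels.append(f"pdc_{k + 1}*{name}")
        for name, z in per_k_cov[k]:
            cols.append(a * z)
            labels.append(f"pdc_{k + 1}*{name}")

    G = np.column_stack(cols) if cols else np.empty((n, 0))
    return G, labels


def entropy_tilt(
    G: np.ndarray,
    base_w: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-9,
    ridge: float = 1e-9,
    delta0: np.ndarray | None = None,
):
    """Exponential tilting of base weights to zero the weighted mean of G.

    Minimizes the convex dual f(d) = log(sum_i b_i exp(g_i'd)) by damped
    Newton iterations; at the optimum the tilted weights
    w_i = b_i exp(g_i'd) satisfy sum_i w_i g_i = 0 (exact balance).
    Returns (weights normalized to mean 1, info dict).
    """
    n, m = G.shape
    if m == 0:
        return base_w / base_w.mean(), {"converged": True, "iters": 0, "max_moment": 0.0}
    logb = np.log(np.maximum(base_w, 1e-300))
    delta = np.zeros(m) if delta0 is None else delta0.copy()

    def dual(d):
        eta = logb + G @ d
        mx = eta.max()
        return mx + np.log(np.exp(eta - mx).sum())

    f = dual(delta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = logb + G @ delta
        eta -= eta.max()
        w = np.exp(eta)
        w /= w.sum()
        grad = G.T @ w                        # weighted moment means
        if np.abs(grad).max() < tol:
            converged = True
            break
        Gw = G * w[:, None]
        H = G.T @ Gw - np.outer(grad, grad)
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        # backtracking line search on the dual
        t = 1.0
        for _ in range(30):
            cand = delta - t * step
            fc = dual(cand)
            if fc < f - 1e-12 * t:
                delta, f = cand, fc
                break
            t *= 0.5
        else:
            break
    eta = logb + G @ delta
    eta -= eta.max()
    w = np.exp(eta)
    w = w / w.mean()
    max_moment = float(np.abs(G.T @ (w / w.sum())).max())
    info = {
        "converged": bool(converged or max_moment < 1e-6),
        "iters": it,
        "max_moment": max_moment,
        "delta": delta,
    }
    return w, info


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def estimate_weights(
    exposures,
    confounders: ConfounderMatrix,
    method: str = "parametric_cbps",
    seed: int | None = None,
    truncate: tuple[float, float] | None = None,
    delta0: np.ndarray | None = None,
) -> WeightSet:
    """Balancing weights for sequential continuous exposures.

    ``exposures`` is the (n, K) matrix of interval PDCs.  ``method`` is one
    of ``parametric_cbps`` (Gaussian stabilized weights + exact-balance
    entropy calibration, the default), ``npcbps_fallback`` (entropy
    calibration of uniform weights, no parametric density) or
    ``stabilized_ipw`` (density ratios only).  ``truncate`` optionally caps
    weights at the given lower/upper percentiles.  If the balancing solve
    fails to converge the method falls back to plain stabilized weights and
    records a warning in the result.  ``seed`` is accepted for interface
    symmetry; the procedure is deterministic.
    """
    A = np.asarray(exposures, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    n, K = A.shape
    if len(confounders.fixed) != n:
        raise ValueError("exposures and confounders have different lengths")
    if method not in WEIGHT_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {WEIGHT_METHODS}")

    # collinearity guard: name the offending columns rather than failing late
    Xf = confounders.fixed.to_numpy(dtype=float)
    keep_var = Xf.std(axis=0) > 0
    if keep_var.any():
        Xnz = Xf[:, keep_var]
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xnz])) if n > 1 else 1
        if n > Xnz.shape[1] and rank < Xnz.shape[1] + 1:
            raise ValueError(
                "singular confounder matrix; collinear columns among "
                f"{list(confounders.fixed.columns)}"
            )

    meta: dict = {}
    if method == "npcbps_fallback":
        base = np.ones(n)
        w_k = np.ones((n, K))
    else:
        base, w_k, notes = _stabilized_weights(A, confounders)
        if notes:
            meta["notes"] = notes

    used = method
    if method in ("parametric_cbps", "npcbps_fallback") and n > K + 1:
        G, labels = balance_design(A, confounders)
        w, info = entropy_tilt(G, base, delta0=delta0)
        meta["balance_solve"] = {
            k: v for k, v in info.items() if k != "delta"
        }
        meta["delta"] = info["delta"]
        meta["moment_labels"] = labels
        if not info["converged"]:
            used = "stabilized_ipw"
            meta["warning"] = "balancing solve did not converge; fell back to stabilized IPW"
            w = base
    else:
        w = base

    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        w = np.clip(w, lo, hi)
        w = w / w.mean()

    return WeightSet(w=w, w_k=w_k, method=used, truncation=truncate, meta=meta)


def check_balance(
    weights,
    exposures,
    confounders: ConfounderMatrix,
    threshold: float = BALANCE_THRESHOLD,
) -> BalanceReport:
    """Weighted Pearson/Spearman balance diagnostics.

    For every (exposure k, covariate) pair both weighted correlations are
    computed; a covariate passes when the average of |r| across time points
    and the two correlation families falls below ``threshold`` (0.1 by
    default).  Time-varying covariates (visit time, lagged LR/PDC) are
    paired with their own time point.
    """
    w = weights.w if isinstance(weights, WeightSet) else np.asarray(weights, float)
    A = np.asarray(exposures, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    n, K = A.shape
    lr_lag = confounders.lagged_lr(K)

    pairs: dict[str, list[tuple[int, np.ndarray]]] = {}
    for name in confounders.fixed.columns:
        z = confounders.fixed[name].to_numpy(dtype=float)
        pairs[str(name)] = [(k, z) for k in range(K)]
    for k in range(K):
        pairs.setdefault(f"visit_day_{k + 1}", []).append((k, confounders.visit_day[:, k]))
        if k >= 1:
            pairs.setdefault(f"lr_{k}", []).append((k, lr_lag[:, k]))
            pairs.setdefault(f"pdc_lag_{k}", []).append((k, A[:, k - 1]))

    rows = {}
    for name, kz in pairs.items():
        row = {}
        abs_rs = []
        degenerate = False
        for k, z in kz:
            rp = weighted_pearson(A[:, k], z, w)
            rs = weighted_spearman(A[:, k], z, w)
            row[f"pearson_k{k + 1}"] = rp
            row[f"spearman_k{k + 1}"] = rs
            if np.isnan(rp) or np.isnan(rs):
                degenerate = True
            else:
                abs_rs.extend([abs(rp), abs(rs)])
        if degenerate or not abs_rs:
            row["avg_abs_corr"] = float("nan")
            row["status"] = "n/a"
        else:
            avg = float(np.mean(abs_rs))
            row["avg_abs_corr"] = avg
            row["status"] = "pass" if avg < threshold else "fail"
        rows[name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "covariate"
    return BalanceReport(table=table, threshold=threshold)
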