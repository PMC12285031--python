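"""Simulation configuration.

All data-generating parameters of the synthetic cohort live here: true
direct effects of interval adherence on LDL reduction, carry-over of past
reduction, fixed-confounder coefficients, the adherence feedback loop, and
the visit-time and prescription-rendering laws.  Defaults describe a cohort
of UK primary-care statin initiators: mean age 61 y (SD 7.3), 42.3% female,
baseline LDL-c 3.8 mmol/L (SD 1.05), mean time from initiation to the third
follow-up LDL-c measure around 3 years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _default_conf_coefs() -> dict[str, dict[str, Any]]:
    # Confounder effects on the two channels. The PDC channel follows the
    # observational gradients seen in primary-care statin users (per-year age
    # effect 0.34, male -0.64 i.e. female +0.64, 0.55 per mmol/L baseline
    # LDL-c, rising education gradient). The LR channel values are small
    # plausible effects on fractional LDL reduction (negative = deeper
    # reduction); they exist to make fixed confounding material.
    return {
        "pdc": {
            "age": 0.34,            # per year, centred at age_mean
            "female": 0.64,         # indicator
            "ldl0": 0.55,           # per mmol/L, centred at baseline_ldl_mean
            "education": [0.0, 0.17, 1.38, 1.24, 1.92, 2.52],
            "centre": [0.0, 0.5, -0.5, 0.3, -0.3, 0.0],
        },
        "lr": {
            "age": 0.0005,
            "female": 0.010,
            "ldl0": -0.015,
            "education": [0.0] * 6,
            "centre": [0.0] * 6,
        },
    }


def _default_visit_gap_law() -> dict[str, Any]:
    # Uniform inter-visit gaps with mean 365 d put the mean time to the third
    # follow-up measure at 3.0 years.
    return {"kind": "uniform", "low": 240, "high": 490}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic statin cohort.

    The structural equations are linear-Gaussian: for visit k = 1..K,

        PDC_k = clip(pdc_intercept + x'conf_pdc + feedback_coef * LR_{k-1}
                     + noise, 0, 150)
        LR_k  = beta_direct[k] * PDC_k + carry_coef * LR_{k-1}
                + x'conf_lr + lr_intercept + noise

    with LR_0 = 0.  PDC is in percent; LR is a fractional LDL change
    (negative = reduction).  Emitted follow-up LDL-c is
    LDL_k = LDL_0 * (1 + LR_k).
    """

    n_patients: int = 5000
    seed: int = 0
    K: int = 3

    # True direct effects of PDC_k on LR_k, LR units per PDC percentage
    # point. The sum times 100 is -0.35.
    beta_direct: tuple[float, ...] = (-0.0020, -0.0005, -0.0010)
    carry_coef: float = 0.4
    conf_coefs: dict[str, dict[str, Any]] = field(default_factory=_default_conf_coefs)
    feedback_coef: float = -30.0    # PDC percentage points per LR unit
    pdc_intercept: float = 88.0
    lr_intercept: float = -0.15
    pdc_noise_sd: float = 15.0
    lr_noise_sd: float = 0.08

    visit_gap_law: dict[str, Any] = field(default_factory=_default_visit_gap_law)

    # Fixed-confounder marginals
    age_mean: float = 61.0
    age_sd: float = 7.3
    age_range: tuple[float, float] = (40.0, 79.0)
    female_prob: float = 0.423
    baseline_ldl_mean: float = 3.8
    baseline_ldl_sd: float = 1.05
    ldl0_range: tuple[float, float] = (1.0, 8.0)
    # Six education categories (none, CSEs, GCSEs/O-levels, A-levels,
    # professional qualification, degree), frequencies as observed in UK
    # primary-care statin users.
    education_probs: tuple[float, ...] = (0.287, 0.029, 0.124, 0.173, 0.146, 0.241)
    centre_probs: tuple[float, ...] = (0.25, 0.20, 0.20, 0.15, 0.10, 0.10)
    genotype_maf: float = 0.15      # single biallelic covariate, allele dose 0/1/2
    prevalent_cvd_prob: float = 0.23

    # Prescription rendering
    tablets_per_script: int = 28
    jitter_sd: float = 2.0          # days, on script issue dates

    # Measurement plumbing
    baseline_measure_day_range: tuple[int, int] = (-60, -1)
    # Emitted follow-up LDL values are clamped inside the clinical validity
    # range so the base cohort carries no accidental validity-filter hits;
    # the latent truth is stored unclamped.
    ldl_emit_range: tuple[float, float] = (1.005, 7.995)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if len(self.beta_direct) != self.K:
            raise ConfigurationError(
                f"beta_direct must have length K={self.K}, got {len(self.beta_direct)}"
            )
        for name in ("pdc_noise_sd", "lr_noise_sd", "age_sd", "baseline_ldl_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.tablets_per_script < 1:
            raise ConfigurationError("tablets_per_script must be >= 1")
        if abs(sum(self.education_probs) - 1.0) > 1e-6:
            raise ConfigurationError("education_probs must sum to 1")
        if abs(sum(self.centre_probs) - 1.0) > 1e-6:
            raise ConfigurationError("centre_probs must sum to 1")
        law = self.visit_gap_law
        if law.get("kind") not in ("uniform", "fixed"):
            raise ConfigurationError(f"unknown visit_gap_law kind: {law.get('kind')!r}")
        for channel in ("pdc", "lr"):
            coefs = self.conf_coefs.get(channel)
            if coefs is None:
                raise ConfigurationError(f"conf_coefs missing channel {channel!r}")
            if len(coefs.get("education", [])) != len(self.education_probs):
                raise ConfigurationError("education coefficient length mismatch")
            if len(coefs.get("centre", [])) != len(self.centre_probs):
                raise ConfigurationError("centre coefficient length mismatch")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        kwargs = dict(d)
        for key in (
            "beta_direct", "age_range", "ldl0_range", "education_probs",
            "centre_probs", "baseline_measure_day_range", "ldl_emit_range",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def true_effect_matrix(self):
        """Lower-triangular matrix of true total effects of PDC_j on LR_k.

        Under a joint intervention on all PDCs the feedback path is blocked,
        so the effect of PDC_j on LR_k is beta_direct[j] * carry_coef**(k-j).
        Entry [k-1, j-1] is the effect of PDC_j on LR_k (j <= k).
        """
        import numpy as np

        B = np.full((self.K, self.K), np.nan)
        for k in range(1, self.K + 1):
            for j in range(1, k + 1):
                B[k - 1, j - 1] = self.beta_direct[j - 1] * self.carry_coef ** (k - j)
        return B
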