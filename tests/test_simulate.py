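"""Synthetic cohort generator: reproducibility, inversion, calibration, planting."""

import numpy as np
import pandas as pd
import pytest

from statin_adherence import (
    ConfigurationError,
    SimulationConfig,
    compute_interval_pdc,
    generate_cohort,
    plant_violations,
    render_prescriptions,
)
from statin_adherence.evaluation import null_confounding_config
from statin_adherence.simulate import simulate_panel


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"K": 0},
            {"pdc_noise_sd": -1.0},
            {"lr_noise_sd": -0.1},
            {"tablets_per_script": 0},
            {"K": 2},  # beta_direct length mismatch with default (len 3)
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_patients=10, seed=3)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_true_effect_matrix_is_lower_triangular(self):
        B = SimulationConfig(n_patients=1).true_effect_matrix()
        assert np.isnan(B[np.triu_indices(3, 1)]).all()
        assert np.isfinite(B[np.tril_indices(3)]).all()


class TestReproducibility:
    def test_identical_seed_identical_tables(self):
        cfg = SimulationConfig(n_patients=80, seed=99)
        h1 = generate_cohort(cfg).table_hashes()
        h2 = generate_cohort(cfg).table_hashes()
        assert h1 == h2

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=80, seed=1)).table_hashes()
        b = generate_cohort(SimulationConfig(n_patients=80, seed=2)).table_hashes()
        assert a != b


class TestStructuralEquations:
    def test_noise_free_propagation(self):
        # no noise, no confounding, no feedback, PDC pinned at 100:
        # LR_1 = beta_1 * 100 = -0.35 for every patient
        base = SimulationConfig(
            n_patients=50,
            seed=5,
            beta_direct=(-0.0035, 0.0, 0.0),
            carry_coef=0.0,
            pdc_noise_sd=0.0,
            lr_noise_sd=0.0,
            pdc_intercept=100.0,
            lr_intercept=0.0,
        )
        cfg = null_confounding_config(base)
        panel = simulate_panel(cfg)
        assert np.allclose(panel.pdc, 100.0)
        assert np.allclose(panel.lr[:, 0], -0.35)
        assert np.allclose(panel.lr[:, 1:], -0.35 * 0.0)  # later betas zero, carry zero

    def test_latent_pdc_within_generative_range(self, default_config):
        panel = simulate_panel(default_config)
        assert panel.pdc.min() >= 0.0
        assert panel.pdc.max() <= 150.0

    def test_followup_time_calibration(self):
        # mean time from initiation to the third LDL-c measure ~ 3 years
        panel = simulate_panel(SimulationConfig(n_patients=1000, seed=12))
        mean_years = panel.visit_day[:, 2].mean() / 365.25
        assert 2.5 <= mean_years <= 3.5

    def test_feedback_confounding_is_material(self, default_config):
        # past reduction must predict future adherence, otherwise the
        # weighting analysis tests nothing
        panel = simulate_panel(default_config)
        r = np.corrcoef(panel.pdc[:, 1], panel.lr[:, 0])[0, 1]
        assert abs(r) > 0.1

    def test_emitted_ldl_within_validity_range(self, small_bundle):
        vals = small_bundle.ldl_measures["ldl_mmol_l"]
        assert (vals >= 1.0).all() and (vals <= 8.0).all()


class TestRenderPrescriptions:
    @pytest.fixture
    def no_jitter(self):
        return SimulationConfig(n_patients=1, jitter_sd=0.0)

    @pytest.mark.parametrize(
        "pdc, window, expected_days",
        [
            (100.0, 84, [0, 28, 56]),
            (50.0, 112, [0, 56]),
            (70.0, 80, [0, 40]),
        ],
    )
    def test_exact_inversion_examples(self, no_jitter, pdc, window, expected_days):
        days, tablets = render_prescriptions([pdc], [window], no_jitter)
        assert days.tolist() == expected_days
        recs = (days, tablets)
        (_, got), = compute_interval_pdc(recs, [window], baseline_day=0)
        assert got == pytest.approx(pdc)

    @pytest.mark.parametrize("pdc", [10.0, 25.0, 50.0, 75.0, 100.0, 140.0])
    def test_roundtrip_within_two_points(self, no_jitter, pdc):
        visits = [365, 731, 1100]
        days, tablets = render_prescriptions([pdc] * 3, visits, no_jitter)
        got = compute_interval_pdc((days, tablets), visits, baseline_day=0)
        for _, val in got:
            assert val == pytest.approx(pdc, abs=2.0)

    def test_zero_pdc_emits_nothing(self, no_jitter):
        days, _ = render_prescriptions([0.0], [100], no_jitter)
        assert len(days) == 0

    def test_pdc_above_150_rejected(self, no_jitter):
        with pytest.raises(ConfigurationError):
            render_prescriptions([151.0], [100], no_jitter)

    def test_scripts_stay_inside_their_window(self):
        cfg = SimulationConfig(n_patients=1, jitter_sd=4.0)
        rng = np.random.default_rng(0)
        days, _ = render_prescriptions([90.0, 40.0], [300, 600], cfg, rng=rng)
        assert (days >= 0).all() and (days < 600).all()
        assert (np.diff(days) >= 0).all()


class TestBundleStructure:
    def test_every_patient_in_covariates(self, small_bundle):
        ids = set(small_bundle.covariates["patient_id"])
        assert set(small_bundle.prescriptions["patient_id"]) <= ids
        assert set(small_bundle.ldl_measures["patient_id"]) <= ids
        if len(small_bundle.events):
            assert set(small_bundle.events["patient_id"]) <= ids

    def test_dates_nondecreasing_per_patient(self, small_bundle):
        for _, sub in small_bundle.prescriptions.groupby("patient_id"):
            assert (np.diff(sub["date_day"]) >= 0).all()
        for _, sub in small_bundle.ldl_measures.groupby("patient_id"):
            assert (np.diff(sub["date_day"]) >= 0).all()

    def test_write_read_roundtrip(self, small_bundle, tmp_path):
        small_bundle.write(tmp_path)
        back = type(small_bundle).read(tmp_path)
        pd.testing.assert_frame_equal(back.prescriptions, small_bundle.prescriptions)
        assert back.truth["latent_pdc"] == small_bundle.truth["latent_pdc"]


class TestPlantViolations:
    def test_empty_plan_is_identity(self, small_bundle):
        planted, ledger = plant_violations(small_bundle, {})
        assert planted.table_hashes() == small_bundle.table_hashes()
        assert ledger["counts"] == {
            "pdc_gt_200": 0, "ldl_low": 0, "died_lt_3mo": 0, "post_discharge": 0
        }

    def test_planted_counts(self, small_bundle):
        plan = {"pdc_gt_200": 5, "ldl_low": 3, "died_lt_3mo": 2, "post_discharge": 2}
        planted, ledger = plant_violations(small_bundle, plan, seed=1)
        assert ledger["counts"] == plan
        # disjoint patients across classes
        ids = (
            ledger["pdc_gt_200"]
            + [e["patient_id"] for e in ledger["ldl_low"]]
            + ledger["died_lt_3mo"]
            + ledger["post_discharge"]
        )
        assert len(ids) == len(set(ids))
        assert (planted.events["event_type"] == "death").sum() == 2

    def test_overfull_plan_rejected(self, small_bundle):
        with pytest.raises(ConfigurationError):
            plant_violations(small_bundle, {"ldl_low": 10_000})
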