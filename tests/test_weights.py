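"""Balancing-weight estimation and weighted balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statin_adherence import (
    ConfounderMatrix,
    SimulationConfig,
    check_balance,
    estimate_weights,
    weighted_pearson,
    weighted_spearman,
)
from statin_adherence.evaluation import null_confounding_config, panel_confounders
from statin_adherence.simulate import simulate_panel
from statin_adherence.weights import balance_design, entropy_tilt


def toy_confounders(n, rng, K=1):
    return ConfounderMatrix(
        fixed=pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)}),
        visit_day=rng.integers(200, 500, size=(n, K)).astype(float),
        lr=rng.normal(-0.3, 0.05, size=(n, K)),
    )


class TestWeightedCorrelations:
    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=500), rng.normal(size=500)
        w = np.ones(500)
        assert weighted_pearson(x, y, w) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )
        assert weighted_spearman(x, y, w) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_degenerate_variable_is_nan(self):
        assert np.isnan(weighted_pearson(np.ones(10), np.arange(10), np.ones(10)))


class TestEstimateWeights:
    def test_null_confounding_weights_concentrate_near_one(self, default_config):
        panel = simulate_panel(null_confounding_config(default_config))
        ws = estimate_weights(panel.pdc, panel_confounders(panel))
        assert ws.method == "parametric_cbps"
        assert ws.w.std() < 0.1
        assert ws.w.mean() == pytest.approx(1.0)

    def test_single_patient_single_timepoint_unit_weight(self):
        rng = np.random.default_rng(1)
        conf = toy_confounders(1, rng)
        ws = estimate_weights(np.array([[80.0]]), conf)
        assert ws.w == pytest.approx([1.0])

    def test_weights_positive_and_mean_one(self, default_config):
        panel = simulate_panel(default_config)
        ws = estimate_weights(panel.pdc, panel_confounders(panel))
        assert (ws.w > 0).all()
        assert ws.w.mean() == pytest.approx(1.0)
        # stabilized weights should not be wildly dispersed before truncation
        assert 0.8 < np.mean(ws.w) / np.median(ws.w) < 1.5

    def test_truncation_caps_extremes(self, default_config):
        panel = simulate_panel(default_config)
        plain = estimate_weights(panel.pdc, panel_confounders(panel))
        trunc = estimate_weights(
            panel.pdc, panel_confounders(panel), truncate=(1.0, 99.0)
        )
        assert trunc.truncation == (1.0, 99.0)
        assert trunc.w.max() < plain.w.max() or plain.w.max() == pytest.approx(trunc.w.max())

    def test_collinear_confounders_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        conf = ConfounderMatrix(
            fixed=pd.DataFrame({"a": x, "b": 2 * x}),
            visit_day=np.full((100, 1), 300.0),
            lr=rng.normal(size=(100, 1)),
        )
        with pytest.raises(ValueError, match="collinear"):
            estimate_weights(rng.normal(80, 10, size=(100, 1)), conf)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(3)
        conf = toy_confounders(50, rng)
        with pytest.raises(ValueError, match="method"):
            estimate_weights(rng.normal(size=(50, 1)), conf, method="magic")

    def test_npcbps_also_balances(self, default_config):
        panel = simulate_panel(default_config)
        conf = panel_confounders(panel)
        ws = estimate_weights(panel.pdc, conf, method="npcbps_fallback")
        report = check_balance(ws, panel.pdc, conf)
        non_visit = report.table.loc[~report.table.index.str.startswith("visit_day")]
        assert (non_visit["status"] == "pass").all()


class TestEntropyTilt:
    def test_moments_driven_to_zero(self):
        rng = np.random.default_rng(4)
        G = rng.normal(size=(2000, 8))
        w, info = entropy_tilt(G, np.ones(2000))
        assert info["converged"]
        assert info["max_moment"] < 1e-6
        assert w.mean() == pytest.approx(1.0)

    def test_balance_design_zeroes_weighted_covariances(self, default_config):
        panel = simulate_panel(default_config.replace(n_patients=2000))
        conf = panel_confounders(panel)
        G, labels = balance_design(panel.pdc, conf)
        w, info = entropy_tilt(G, np.ones(len(G)))
        assert info["converged"]
        # exact balance: weighted corr between exposure and any confounder ~ 0
        r = weighted_pearson(panel.pdc[:, 2], conf.fixed["age"].to_numpy(), w)
        assert abs(r) < 1e-6


class TestCheckBalance:
    def test_equal_weights_equal_plain_correlations(self, default_config):
        panel = simulate_panel(default_config.replace(n_patients=1000))
        conf = panel_confounders(panel)
        report = check_balance(np.ones(1000), panel.pdc, conf)
        want = np.corrcoef(panel.pdc[:, 0], conf.fixed["age"])[0, 1]
        assert report.table.loc["age", "pearson_k1"] == pytest.approx(want, abs=1e-12)

    def test_independent_covariate_passes(self):
        rng = np.random.default_rng(5)
        n = 10_000
        conf = ConfounderMatrix(
            fixed=pd.DataFrame({"noise": rng.normal(size=n)}),
            visit_day=rng.integers(200, 500, (n, 1)).astype(float),
            lr=rng.normal(-0.3, 0.05, (n, 1)),
        )
        A = rng.normal(90, 15, size=(n, 1))
        report = check_balance(np.ones(n), A, conf)
        assert report.table.loc["noise", "status"] == "pass"

    def test_zero_variance_covariate_reported_na(self):
        rng = np.random.default_rng(6)
        n = 200
        conf = ConfounderMatrix(
            fixed=pd.DataFrame({"flat": np.ones(n)}),
            visit_day=rng.integers(200, 500, (n, 1)).astype(float),
            lr=rng.normal(-0.3, 0.05, (n, 1)),
        )
        report = check_balance(np.ones(n), rng.normal(90, 15, (n, 1)), conf)
        assert report.table.loc["flat", "status"] == "n/a"
        assert "flat" not in report.failed_covariates
        assert not report.all_balanced

    def test_confounded_unweighted_fails_weighted_passes(self, default_config):
        panel = simulate_panel(default_config)
        conf = panel_confounders(panel)
        raw = check_balance(np.ones(len(panel.pdc)), panel.pdc, conf)
        assert "lr_1" in raw.failed_covariates   # feedback confounding visible
        ws = estimate_weights(panel.pdc, conf)
        weighted = check_balance(ws, panel.pdc, conf)
        non_visit = weighted.table.loc[~weighted.table.index.str.startswith("visit_day")]
        assert (non_visit["status"] == "pass").all()
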