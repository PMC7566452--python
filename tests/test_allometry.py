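"""Model bank, AGB prediction, uncertainty propagation, new power-law fits."""

import math

import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from tlstree.allometry import (
    AllometricModel,
    fit_power_law,
    load_models,
    predict_agb,
    save_models,
    tls_agb,
)
from tlstree.exceptions import ConfigError, ParameterError, PredictorError
from tlstree.stem import StemMetrics

EXPECTED_PREDICTORS = {
    "parks": {"DBH", "H"},
    "fujimori": {"DBH", "H"},
    "sillett2015": {"DTB", "fDBH"},
    "sillett2019": {"DTB", "H"},
    "kizha_han": {"DBH"},
    "jenkins": {"DBH"},
    "chojnacky": {"DBH"},
}


@pytest.fixture(scope="module")
def bank():
    return {m.model_id: m for m in load_models()}


class TestModelBank:
    def test_seven_models_with_expected_predictor_sets(self, bank):
        assert set(bank) == set(EXPECTED_PREDICTORS)
        for mid, preds in EXPECTED_PREDICTORS.items():
            assert set(bank[mid].predictors) == preds

    def test_missing_coefficient_is_named_config_error(self, tmp_path):
        cfg = {"models": [dict(model_id="jenkins", form="log_log",
                               predictors=["DBH"], coefficients={"b0": -2.0})]}
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigError, match="jenkins.*b1"):
            load_models(path)

    def test_custom_model_round_trips(self, tmp_path):
        custom = AllometricModel(
            model_id="custom", form="power_product", predictors=("DBH", "H"),
            coefficients={"a": 0.1, "b_DBH": 2.1, "b_H": 0.7}, response="agb_t",
        )
        save_models([custom], tmp_path / "custom.yaml")
        (back,) = load_models(tmp_path / "custom.yaml")
        assert back == custom

    def test_agb_strictly_increasing_in_dbh(self, bank):
        grid = np.linspace(0.1, 3.5, 60)
        for mid in ("jenkins", "chojnacky", "kizha_han"):
            agb = [bank[mid].predict_t({"DBH": d}) for d in grid]
            assert all(b > a for a, b in zip(agb, agb[1:]))

    def test_missing_predictor_names_model(self, bank):
        met = StemMetrics(tree_id="t", height_m=50.0, dbh_m=1.0)
        with pytest.raises(PredictorError, match="sillett2015"):
            predict_agb(bank["sillett2015"], met, mc_n=100)


class TestPredictAGB:
    def test_zero_rmse_gives_zero_uncertainty(self, bank):
        met = StemMetrics(tree_id="t", height_m=50.0, dbh_m=1.0, dbh_rmse_m=0.0)
        est = predict_agb(bank["jenkins"], met, mc_n=500, seed=0)
        assert est.agb_sd_t == 0.0

    def test_monte_carlo_agrees_with_delta_method(self, bank):
        # log-log model: sigma_AGB ~ AGB * b1 * sigma_D / D
        met = StemMetrics(tree_id="t", height_m=50.0, dbh_m=1.0, dbh_rmse_m=0.02)
        est = predict_agb(bank["jenkins"], met, mc_n=4000, seed=1)
        delta = est.agb_t * bank["jenkins"].coefficients["b1"] * 0.02 / 1.0
        assert est.agb_sd_t == pytest.approx(delta, rel=0.20)

    def test_uncertainty_scales_linearly_in_small_noise_regime(self, bank):
        base = dict(tree_id="t", height_m=50.0, dbh_m=1.0)
        e1 = predict_agb(bank["jenkins"], StemMetrics(**base, dbh_rmse_m=0.01),
                         mc_n=6000, seed=2)
        e2 = predict_agb(bank["jenkins"], StemMetrics(**base, dbh_rmse_m=0.02),
                         mc_n=6000, seed=3)
        assert e2.agb_sd_t / e1.agb_sd_t == pytest.approx(2.0, rel=0.15)

    def test_fixed_seed_reproduces_uncertainty(self, bank):
        met = StemMetrics(tree_id="t", height_m=50.0, dbh_m=1.0, dbh_rmse_m=0.02)
        a = predict_agb(bank["jenkins"], met, mc_n=500, seed=4)
        b = predict_agb(bank["jenkins"], met, mc_n=500, seed=4)
        assert a.agb_sd_t == b.agb_sd_t


class TestTlsAgb:
    def test_arithmetic(self):
        est = tls_agb((100.0, 0.0), 400.0, tree_id="t")
        assert est.agb_t == pytest.approx(40.0, rel=1e-12)
        assert est.agb_sd_t == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(v=st.floats(0.1, 500), sd=st.floats(0, 10), k=st.floats(0.1, 10))
    def test_exactly_linear(self, v, sd, k):
        a = tls_agb((v, sd), 380.0, tree_id="t")
        b = tls_agb((k * v, k * sd), 380.0, tree_id="t")
        assert b.agb_t == pytest.approx(k * a.agb_t, rel=1e-9)
        assert b.agb_sd_t == pytest.approx(k * a.agb_sd_t, rel=1e-9, abs=1e-12)

    def test_preserves_volume_ordering(self):
        vols = np.sort(np.random.default_rng(0).uniform(1, 300, 20))
        agb = [tls_agb((v, 0.0), 380.0, tree_id="t").agb_t for v in vols]
        assert all(b > a for a, b in zip(agb, agb[1:]))


class TestFitPowerLaw:
    def test_exact_recovery_identity(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0.2, 3.0, 60)
        df = pd.DataFrame({"D": D, "agb": 0.37 * D**2.31})
        fit = fit_power_law(df, "agb", ("D",))
        assert fit.coefficients["a"] == pytest.approx(0.37, abs=1e-6)
        assert fit.coefficients["b_D"] == pytest.approx(2.31, abs=1e-6)
        assert fit.rmse_percent == pytest.approx(0.0, abs=1e-6)

    def test_recovery_under_lognormal_noise_within_2_se(self):
        rng = np.random.default_rng(0)
        n, a, b, sigma = 146, 0.37, 2.31, 0.10
        D = rng.uniform(0.15, 3.4, n)
        y = a * D**b * rng.lognormal(0.0, sigma, n)
        fit = fit_power_law(pd.DataFrame({"D": D, "agb": y}), "agb", ("D",),
                            weighting="relative")
        # parametric-bootstrap standard error of the same estimator
        mu = fit.predict({"D": D})
        boot = []
        for _ in range(60):
            yb = mu * rng.lognormal(0.0, sigma, n)
            fb = fit_power_law(pd.DataFrame({"D": D, "agb": yb}), "agb", ("D",),
                               weighting="relative")
            boot.append(fb.coefficients["b_D"])
        se_boot = float(np.std(boot, ddof=1))
        assert abs(fit.coefficients["b_D"] - b) < 2 * se_boot
        # the analytic (jacobian) SE agrees with the bootstrap to first order
        assert fit.se["b_D"] == pytest.approx(se_boot, rel=0.5)

    def test_h_only_fit_is_worse_than_two_predictor_fit(self):
        rng = np.random.default_rng(9)
        n = 146
        D = rng.uniform(0.2, 3.4, n)
        H = 50 * D**0.46 * rng.lognormal(0, 0.08, n)
        V = 0.42 * D**2.0 * H * rng.lognormal(0, 0.01, n)
        df = pd.DataFrame({"DTB": D, "H": H, "V": V})
        both = fit_power_law(df, "V", ("DTB", "H"))
        h_only = fit_power_law(df, "V", ("H",))
        assert h_only.rmse_percent > both.rmse_percent

    def test_too_few_or_nonpositive_records_rejected(self):
        df = pd.DataFrame({"D": [1.0] * 5, "y": [2.0] * 5})
        with pytest.raises(ParameterError):
            fit_power_law(df, "y", ("D",))
        df = pd.DataFrame({"D": np.linspace(-1, 2, 20), "y": np.ones(20)})
        with pytest.raises(ParameterError):
            fit_power_law(df, "y", ("D",))
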