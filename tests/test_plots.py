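"""Comparison regressions and plot-level biomass density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ols_oracle
from tlstree.exceptions import EmptyInputError, PairingError, ParameterError
from tlstree.plots import compare_regression, plot_agbd, table1_report, table2_report


@pytest.fixture(scope="module")
def cohort_agb():
    """Synthetic reference AGB with one dominant tree, and a 0.9x candidate."""
    rng = np.random.default_rng(21)
    ref = np.sort(rng.lognormal(2.0, 0.8, 40))
    ref[-1] = ref[-1] * 8  # dominant giant
    cand = 0.9 * ref + rng.normal(0, 0.5, 40)
    return ref, np.abs(cand)


class TestCompareRegression:
    def test_identity_candidate(self):
        ref = np.linspace(1.0, 100.0, 30)
        fit = compare_regression(ref, ref)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_t == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse_t == pytest.approx(0.0, abs=1e-9)
        assert fit.cv_percent == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_ols_oracle(self, cohort_agb):
        ref, cand = cohort_agb
        fit = compare_regression(ref, cand)
        slope, intercept, r2 = ols_oracle(ref, cand)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept_t == pytest.approx(intercept, abs=1e-9)
        assert fit.r2 == pytest.approx(r2, abs=1e-9)

    def test_recovers_generating_slope(self, cohort_agb):
        ref, cand = cohort_agb
        fit = compare_regression(ref, cand)
        assert fit.slope == pytest.approx(0.9, abs=0.02)

    def test_largest_tree_leverage_direction(self, cohort_agb):
        ref, cand = cohort_agb
        with_g = compare_regression(ref, cand, include_largest=True)
        without = compare_regression(ref, cand, include_largest=False)
        assert without.n == with_g.n - 1
        # the giant anchors the fit: r^2 higher and slope at least as close
        # to the generating 0.9 with it included
        assert with_g.r2 >= without.r2
        assert abs(with_g.slope - 0.9) <= abs(without.slope - 0.9) + 0.02

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-20, 20))
    def test_r2_invariant_under_affine_candidate_rescaling(self, scale, shift):
        rng = np.random.default_rng(2)
        ref = rng.uniform(1, 100, 30)
        cand = 0.7 * ref + rng.normal(0, 3, 30)
        a = compare_regression(ref, cand)
        b = compare_regression(ref, scale * cand + shift)
        assert b.r2 == pytest.approx(a.r2, rel=1e-9)
        assert b.slope == pytest.approx(scale * a.slope, rel=1e-9)

    def test_pairing_by_tree_id_and_mismatch_error(self):
        ref = {f"t{i}": float(i + 1) for i in range(12)}
        cand = {f"t{i}": 2.0 * (i + 1) for i in range(12)}
        fit = compare_regression(ref, cand)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        cand["extra"] = 1.0
        with pytest.raises(PairingError):
            compare_regression(ref, cand)


class TestPlotAgbd:
    def test_single_tree_arithmetic(self):
        s = plot_agbd([10.0], 0.25, [1.0])
        assert s.agbd_t_ha == pytest.approx(40.0, rel=1e-12)
        assert s.agbd_se_t_ha == pytest.approx(4.0, rel=1e-12)

    def test_duplicating_trees_doubles_density(self):
        agb = [3.0, 7.0, 11.0]
        one = plot_agbd(agb, 0.25)
        two = plot_agbd(agb + agb, 0.25)
        assert two.agbd_t_ha == pytest.approx(2 * one.agbd_t_ha, rel=1e-12)

    def test_equals_brute_force_sum(self):
        rng = np.random.default_rng(26)
        agb = rng.lognormal(2.0, 0.7, 26)
        s = plot_agbd(agb, 0.25)
        assert s.agbd_t_ha == pytest.approx(float(np.sum(agb)) / 0.25, rel=1e-9)

    def test_removing_largest_never_increases_total(self):
        rng = np.random.default_rng(3)
        agb = rng.lognormal(2.0, 0.7, 26)
        full = plot_agbd(agb, 0.25)
        rest = plot_agbd(np.delete(agb, np.argmax(agb)), 0.25)
        assert rest.agbd_t_ha <= full.agbd_t_ha

    def test_empty_plot_errors(self):
        with pytest.raises(EmptyInputError):
            plot_agbd([], 0.25)
        with pytest.raises(ParameterError):
            plot_agbd([1.0], 0.0)


class TestReports:
    def test_table1_has_two_rows_per_model_in_stable_order(self, cohort_agb):
        ref, cand = cohort_agb
        df = pd.DataFrame({"tls": ref})
        for i in range(7):
            df[f"m{i}"] = cand * (1 + 0.01 * i)
        t1 = table1_report(df)
        assert len(t1) == 14
        assert list(t1.columns) == ["model_id", "slope", "intercept_t", "r2",
                                    "rmse_t", "cv_percent", "includes_largest"]
        t1b = table1_report(df)
        pd.testing.assert_frame_equal(t1, t1b)

    def test_table2_aggregates_each_plot_and_method(self):
        rng = np.random.default_rng(4)
        per_tree = pd.DataFrame({
            "plot_id": ["A"] * 10 + ["B"] * 12,
            "tls": rng.lognormal(2, 0.5, 22),
            "tls_sd": rng.uniform(0.1, 1.0, 22),
            "jenkins": rng.lognormal(1.8, 0.5, 22),
        })
        t2 = table2_report(per_tree, area_ha=0.25)
        assert len(t2) == 4
        row = t2[(t2.plot_id == "A") & (t2.method_id == "tls")].iloc[0]
        grp = per_tree[per_tree.plot_id == "A"]
        assert row.agbd_t_ha == pytest.approx(grp.tls.sum() / 0.25, rel=1e-12)
        assert row.agbd_se_t_ha == pytest.approx(
            np.sqrt((grp.tls_sd**2).sum()) / 0.25, rel=1e-12)

    def test_end_to_end_slope_one_as_noise_vanishes(self):
        # reference = rho * true volume; candidate = the generating allometry
        rng = np.random.default_rng(6)
        D = rng.uniform(0.3, 3.0, 30)
        V = 0.42 * D**2.1 * (40 * D**0.5)
        ref = 380e-3 * V
        for noise, tol in ((0.05, 0.15), (0.005, 0.02)):
            cand = ref * rng.lognormal(0, noise, 30)
            fit = compare_regression(ref, cand)
            assert fit.slope == pytest.approx(1.0, abs=tol)
        assert fit.r2 > 0.99
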