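import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treeforage as tf
from treeforage.residence import (
    CoxFit,
    CoxGammaConfig,
    build_residence_records,
    candidate_set_selection,
    cox_linear_predictor,
    fit_cox_gamma,
    hazard_ratio,
    remaining_probability,
)

FAST = CoxGammaConfig(covariates=("dir",), include_rho=False, chains=2,
                      iterations=1500, burnin=700, thin=2)


class TestLinearPredictor:
    def test_zero_profile(self):
        assert cox_linear_predictor({}, {}) == 0.0

    def test_single_coefficient(self):
        lp = cox_linear_predictor({"dir": 1.0}, {"dir": -2.47})
        assert lp == pytest.approx(-2.47)

    def test_additivity(self):
        betas = {"dir": -2.0, "dis": -0.02}
        lp1 = cox_linear_predictor({"dir": 1.3}, betas)
        lp2 = cox_linear_predictor({"dis": 30.0}, betas)
        both = cox_linear_predictor({"dir": 1.3, "dis": 30.0}, betas)
        assert both == pytest.approx(lp1 + lp2)

    def test_species_offsets(self):
        lp = cox_linear_predictor({"species": "NANT"}, {}, {"NANT": 0.81})
        assert lp == pytest.approx(0.81)
        with pytest.raises(KeyError):
            cox_linear_predictor({"species": "OAK"}, {}, {"NANT": 0.81})


class TestHazardRatio:
    @pytest.mark.parametrize("beta,hr", [(-2.47, 0.08), (-2.33, 0.10), (0.0, 1.0)])
    def test_reference_values(self, beta, hr):
        value, _ = hazard_ratio(beta)
        assert round(value, 2) == hr

    def test_interpretive_flags(self):
        assert hazard_ratio(0.5)[1] == "leaves earlier"
        assert hazard_ratio(-0.5)[1] == "stays longer"
        assert hazard_ratio(0.0)[1] == "no effect"

    @given(st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_identity(self, beta):
        assert hazard_ratio(beta)[0] * hazard_ratio(-beta)[0] == pytest.approx(1.0)


class TestFit:
    def test_single_replicate_recovery(self):
        rec = tf.simulate_residence_records(400, (-2.5, 0, 0, 0),
                                            baseline_rate=0.2, seed=1)
        cfg = CoxGammaConfig(covariates=("dir",), include_rho=False, chains=3,
                             iterations=3000, burnin=1500, thin=2)
        fit = fit_cox_gamma(rec, cfg, seed=2)
        assert abs(fit.coef("beta_dir") - (-2.5)) < 0.5
        row = fit.summary.set_index("parameter").loc["beta_dir"]
        assert row["bci_2.5"] < -2.5 < row["bci_97.5"]

    def test_seeded_reproducibility(self):
        rec = tf.simulate_residence_records(120, (-1.0, 0, 0, 0), seed=3)
        f1 = fit_cox_gamma(rec, FAST, seed=4)
        f2 = fit_cox_gamma(rec, FAST, seed=4)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)
        np.testing.assert_allclose(f1.baseline_increments, f2.baseline_increments)

    def test_all_censored_rejected(self):
        rec = tf.simulate_residence_records(50, (0, 0, 0, 0), seed=5)
        rec["event"] = 0
        with pytest.raises(ValueError):
            fit_cox_gamma(rec, FAST, seed=6)

    def test_nelson_aalen_baseline_oracle(self):
        # null covariates: posterior-mean cumulative baseline should track
        # the Nelson-Aalen estimator (lifelines) on the same data
        from lifelines import NelsonAalenFitter

        rec = tf.simulate_residence_records(500, (0, 0, 0, 0),
                                            baseline_rate=0.3, dir_sd=0.0, seed=7)
        cfg = CoxGammaConfig(covariates=(), include_rho=False, chains=2,
                             iterations=1200, burnin=600, thin=2)
        fit = fit_cox_gamma(rec, cfg, seed=8)
        naf = NelsonAalenFitter()
        naf.fit(rec["T"], event_observed=rec["event"])
        cum = np.cumsum(fit.baseline_increments)
        t_grid = fit.event_times
        na = naf.cumulative_hazard_at_times(t_grid).to_numpy()
        mid = slice(len(t_grid) // 4, 3 * len(t_grid) // 4)
        assert np.max(np.abs(cum[mid] - na[mid]) / na[mid]) < 0.10

    def test_large_confidence_collapses_to_prior(self):
        rec = tf.simulate_residence_records(60, (0, 0, 0, 0), baseline_rate=0.5,
                                            seed=9)
        lam_star = 1.0 / rec["T"].mean()
        cfg = CoxGammaConfig(covariates=(), include_rho=False, confidence=1e6,
                             chains=2, iterations=600, burnin=300, thin=1)
        fit = fit_cox_gamma(rec, cfg, seed=10)
        delta_k = np.diff(np.concatenate([[0.0], fit.event_times]))
        np.testing.assert_allclose(fit.baseline_increments, lam_star * delta_k,
                                   rtol=0.05)


class TestRemainingProbability:
    @staticmethod
    def _manual_fit(h_rate, times):
        delta = np.diff(np.concatenate([[0.0], times]))
        return CoxFit(name="manual", n_obs=0, summary=pd.DataFrame({
            "parameter": [], "mean": []}), dic=np.nan, p_d=np.nan,
            deviance_draws=np.zeros(2), event_times=times,
            baseline_increments=h_rate * delta, draws={"beta": None, "names": []},
            converged=True, max_psrf=1.0, config=CoxGammaConfig())

    def test_unit_at_time_zero(self):
        fit = self._manual_fit(0.3, np.linspace(0.5, 10, 20))
        assert remaining_probability(fit, {}, np.array([0.0]))[0] == 1.0

    def test_closed_form_constant_baseline(self):
        times = np.linspace(0.1, 20, 200)
        fit = self._manual_fit(0.25, times)
        s = remaining_probability(fit, {}, times)
        np.testing.assert_allclose(s, np.exp(-0.25 * times), atol=1e-10)

    def test_monotone_and_bounded(self):
        rec = tf.simulate_residence_records(150, (-1.5, 0, 0, 0), seed=11)
        fit = fit_cox_gamma(rec, FAST, seed=12)
        t = np.linspace(0, 30, 100)
        s = remaining_probability(fit, {"dir": 1.0}, t)
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_lower_dir_lowers_survival_under_negative_beta(self):
        rec = tf.simulate_residence_records(300, (-2.0, 0, 0, 0), seed=13)
        fit = fit_cox_gamma(rec, FAST, seed=14)
        t = np.linspace(0.5, 20, 40)
        s_low = remaining_probability(fit, {"dir": 0.8}, t)
        s_high = remaining_probability(fit, {"dir": 1.8}, t)
        assert (s_low < s_high).all()

    def test_proportional_hazards_property(self):
        rec = tf.simulate_residence_records(200, (-1.0, 0, 0, 0), seed=15)
        fit = fit_cox_gamma(rec, FAST, seed=16)
        t = fit.event_times[5:]
        s1 = remaining_probability(fit, {"dir": 0.7}, t)
        s2 = remaining_probability(fit, {"dir": 1.6}, t)
        ratio = np.log(s1) / np.log(s2)  # = exp(lp1 - lp2), time-constant
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_unknown_species_rejected(self):
        rec = tf.simulate_residence_records(120, (0, 0, 0, 0), seed=17)
        cfg = CoxGammaConfig(covariates=("dir",), include_species=True,
                             include_rho=False, chains=2, iterations=600,
                             burnin=300, thin=1)
        fit = fit_cox_gamma(rec, cfg, seed=18)
        with pytest.raises(KeyError):
            remaining_probability(fit, {"dir": 1.0, "species": "OAK"},
                                  np.array([1.0]))

    def test_bad_times_rejected(self):
        fit = self._manual_fit(0.2, np.linspace(0.5, 5, 5))
        with pytest.raises(ValueError):
            remaining_probability(fit, {}, np.array([2.0, 1.0]))


class TestCandidateSelection:
    def test_single_candidate_weight_one(self):
        rec = tf.simulate_residence_records(120, (-1.0, 0, 0, 0), seed=19)
        table, _ = candidate_set_selection(
            rec, {"dir": {"covariates": ("dir",), "include_rho": False}},
            CoxGammaConfig(chains=2, iterations=600, burnin=300, thin=1), seed=20)
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_true_covariates_outrank_wrong_ones(self):
        wins = 0
        cfg = CoxGammaConfig(chains=2, iterations=1200, burnin=600, thin=2)
        cands = {
            "dis+dbh": {"covariates": ("dis", "dbh"), "include_rho": False},
            "dir": {"covariates": ("dir",), "include_rho": False},
            "null": {"covariates": (), "include_rho": False},
        }
        for rep in range(5):
            rec = tf.simulate_residence_records(
                300, (0.0, -0.04, -0.06, 0.0), baseline_rate=10.0, seed=100 + rep)
            table, _ = candidate_set_selection(rec, cands, cfg, seed=200 + rep)
            if table["model"].iloc[0] == "dis+dbh":
                wins += 1
        assert wins >= 4


class TestRecordBuilder:
    def test_foraging_only_and_covariates(self, small_world):
        rec = build_residence_records(small_world["dir_table"],
                                      small_world["routes"], small_world["trees"])
        assert (rec["T"] > 0).all()
        assert np.isfinite(rec[["dir", "dis", "dbh", "ht"]].to_numpy()).all()
        # only foraging periods with a disk enter
        routes = small_world["routes"]
        f_steps = routes[routes["behavior"] == "F"]
        assert len(rec) <= len(f_steps)

    def test_censor_last_flag(self, small_world):
        rec = build_residence_records(small_world["dir_table"],
                                      small_world["routes"], small_world["trees"],
                                      censor_last=True)
        assert (rec["event"] == 0).sum() >= 1
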