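"""Causal estimators: Wald-ratio identities, calibration, strata, sensitivity."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import wald_ratio_oracle
from prsmr import mr
from prsmr.simulate import simulate_iv_dataset


def _quiet(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", mr.WeakInstrumentWarning)
        return fn(*args, **kwargs)


class TestTSLS:
    def test_six_point_wald_example(self):
        z = np.array([0.0, 0, 1, 1, 2, 2])
        x = np.array([0.0, 1, 1, 2, 2, 3])
        y = np.array([0.0, 0, 1, 1, 2, 2])
        est, _ = _quiet(mr.tsls, y, x, z)
        assert est.estimate == pytest.approx(1.0, abs=1e-12)

    def test_instrument_equals_exposure_reduces_to_ols(self, rng):
        x = rng.normal(size=300)
        y = 0.7 * x + rng.normal(size=300)
        est, _ = _quiet(mr.tsls, y, x, x)
        ols = np.polyfit(x, y, 1)[0]
        assert est.estimate == pytest.approx(ols, abs=1e-10)

    def test_equals_residualized_wald_ratio(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = int(rng.integers(40, 200))
            d = simulate_iv_dataset(n, beta=rng.normal(), rng=rng,
                                    instrument_r2=0.2)
            est, _ = _quiet(mr.tsls, d["y"], d["x"], d["z"], d["covariates"])
            oracle = wald_ratio_oracle(d["y"], d["x"], d["z"], d["covariates"])
            assert est.estimate == pytest.approx(oracle, abs=1e-10)

    def test_ci_and_p_consistency(self, rng):
        d = simulate_iv_dataset(500, beta=0.5, rng=rng, instrument_r2=0.2)
        est, _ = _quiet(mr.tsls, d["y"], d["x"], d["z"], d["covariates"])
        lo, hi = est.ci95
        assert lo == pytest.approx(est.estimate - 1.96 * est.se, abs=1e-6)
        assert hi == pytest.approx(est.estimate + 1.96 * est.se, abs=1e-6)
        assert 0 <= est.p <= 1

    def test_zero_variance_instrument_raises(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        with pytest.raises(mr.EstimationError):
            mr.tsls(y, x, np.ones(100))

    def test_weak_instrument_flagged(self):
        rng = np.random.default_rng(8)
        d = simulate_iv_dataset(80, beta=0.0, rng=rng, instrument_r2=0.001)
        with pytest.warns(mr.WeakInstrumentWarning):
            est, diag = mr.tsls(d["y"], d["x"], d["z"], d["covariates"])
        assert est.weak_instrument
        assert diag.f_stat <= 10

    def test_recovers_truth_under_confounding(self):
        """2SLS is unbiased where OLS is not (the central MR property)."""
        rng = np.random.default_rng(2)
        iv_est, ols_est = [], []
        for _ in range(60):
            d = simulate_iv_dataset(2000, beta=0.5, confounding=0.4, rng=rng)
            est, _ = _quiet(mr.tsls, d["y"], d["x"], d["z"], d["covariates"])
            iv_est.append(est.estimate)
            ols_est.append(np.polyfit(d["x"], d["y"], 1)[0])
        assert abs(np.mean(iv_est) - 0.5) <= 0.05
        assert np.mean(ols_est) - 0.5 >= 0.1


class TestFirstStage:
    def test_scale_invariance(self, rng):
        d = simulate_iv_dataset(200, beta=0.3, rng=rng, instrument_r2=0.1)
        f1 = mr.first_stage_f(d["x"], d["z"], d["covariates"]).f_stat
        f2 = mr.first_stage_f(d["x"], 13.7 * d["z"], d["covariates"]).f_stat
        assert f1 == pytest.approx(f2, abs=1e-9 * max(f1, 1))

    def test_closed_form_no_covariates(self, rng):
        n = 20
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        diag = mr.first_stage_f(x, z)
        r2 = np.corrcoef(x, z)[0, 1] ** 2
        expect = (n - 2) * r2 / (1 - r2)
        assert diag.f_stat == pytest.approx(expect, abs=1e-9 * expect)

    def test_single_instrument_f_is_t_squared(self, rng):
        d = simulate_iv_dataset(150, beta=0.3, rng=rng, instrument_r2=0.1)
        diag = mr.first_stage_f(d["x"], d["z"], d["covariates"])
        assert diag.f_stat == pytest.approx(
            (diag.coefficient / diag.se) ** 2, abs=1e-9 * diag.f_stat)

    def test_null_rejection_rate_matches_f_distribution(self):
        from scipy import stats as sps
        rng = np.random.default_rng(5)
        n, reps = 120, 600
        crit = sps.f.ppf(0.95, 1, n - 2)
        rej = 0
        for _ in range(reps):
            z = rng.normal(size=n)
            x = rng.normal(size=n)
            rej += mr.first_stage_f(x, z).f_stat > crit
        assert 0.03 <= rej / reps <= 0.07


class TestGMMContinuous:
    def test_point_estimate_equals_tsls(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            d = simulate_iv_dataset(int(rng.integers(50, 300)),
                                    beta=rng.normal(), rng=rng,
                                    instrument_r2=0.2)
            a, _ = _quiet(mr.tsls, d["y"], d["x"], d["z"], d["covariates"])
            b, _ = _quiet(mr.gmm_continuous, d["y"], d["x"], d["z"],
                          d["covariates"])
            assert a.estimate == pytest.approx(b.estimate, abs=1e-8)

    def test_robust_se_close_to_tsls_when_homoskedastic(self):
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(30):
            d = simulate_iv_dataset(5000, beta=0.3, rng=rng, instrument_r2=0.1)
            a, _ = _quiet(mr.tsls, d["y"], d["x"], d["z"], d["covariates"])
            b, _ = _quiet(mr.gmm_continuous, d["y"], d["x"], d["z"],
                          d["covariates"])
            ratios.append(b.se / a.se)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_heteroskedastic_coverage(self):
        rng = np.random.default_rng(6)
        cover = 0
        reps = 100
        for _ in range(reps):
            d = simulate_iv_dataset(2000, beta=0.4, rng=rng,
                                    instrument_r2=0.1, heteroskedastic=True)
            est, _ = _quiet(mr.gmm_continuous, d["y"], d["x"], d["z"],
                            d["covariates"])
            lo, hi = est.ci95
            cover += lo <= 0.4 <= hi
        assert 0.91 <= cover / reps <= 0.98


class TestBinaryEstimators:
    def test_zero_weight_instrument_raises(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        x = rng.normal(size=200)
        with pytest.raises(mr.EstimationError, match="constant"):
            mr.two_stage_binary(y, x, np.zeros(200))

    def test_single_class_outcome_raises(self, rng):
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        with pytest.raises(mr.EstimationError, match="both classes"):
            mr.two_stage_binary(np.ones(100), x, z)

    def test_null_gmm_beta_within_two_se(self):
        rng = np.random.default_rng(12)
        d = simulate_iv_dataset(3000, beta=0.0, rng=rng, binary=True,
                                instrument_r2=0.1)
        est = _quiet(mr.gmm_binary, d["y"], d["x"], d["z"], d["covariates"])
        assert est.converged
        assert abs(est.estimate) <= 2 * est.se

    def test_protective_effect_direction(self):
        rng = np.random.default_rng(13)
        hits_ts = hits_gmm = 0
        reps = 40
        for _ in range(reps):
            d = simulate_iv_dataset(2500, beta=-0.5, rng=rng, binary=True,
                                    instrument_r2=0.1)
            ts = _quiet(mr.two_stage_binary, d["y"], d["x"], d["z"],
                        d["covariates"])
            gm = _quiet(mr.gmm_binary, d["y"], d["x"], d["z"], d["covariates"])
            hits_ts += ts.estimate < 0
            hits_gmm += gm.estimate < 0
        assert hits_ts >= 0.95 * reps
        assert hits_gmm >= 0.95 * reps

    def test_separated_outcome_flags_nonconvergence(self, rng):
        z = rng.normal(size=60)
        x = z + 0.01 * rng.normal(size=60)
        y = (x > 0).astype(float)        # perfectly separated
        est = _quiet(mr.gmm_binary, y, x, z)
        assert not est.converged
        assert "converge" in est.note

    def test_bootstrap_se_not_smaller_than_half_model_se(self):
        rng = np.random.default_rng(14)
        d = simulate_iv_dataset(800, beta=-0.3, rng=rng, binary=True,
                                instrument_r2=0.1)
        model = _quiet(mr.two_stage_binary, d["y"], d["x"], d["z"],
                       d["covariates"])
        boot = _quiet(mr.two_stage_binary, d["y"], d["x"], d["z"],
                      d["covariates"], bootstrap=200, seed=1)
        assert "bootstrap" in boot.note
        assert boot.se > 0.5 * model.se


class TestStratified:
    def _frame(self, rng, n=600, interaction=None):
        d = simulate_iv_dataset(n, beta=0.4, rng=rng, instrument_r2=0.15)
        df = pd.DataFrame({"bmi": rng.normal(27, 5, n),
                           "sex": rng.integers(0, 2, n),
                           "age": rng.normal(50, 8, n)})
        y = d["y"].copy()
        if interaction == "normal_weight_only":
            # causal effect confined to BMI < 25: remove it elsewhere
            heavy = df["bmi"] >= 25
            y[heavy] -= 0.4 * d["x"][heavy]
        return df, y, d

    def test_all_strata_present(self, rng):
        df, y, d = self._frame(rng)
        ests = mr.run_stratified(df, y, d["x"], d["z"], ["age", "sex"],
                                 mr.tsls, outcome="test")
        assert [e.stratum for e in ests] == list(mr.STRATA)
        assert all(e.outcome == "test" for e in ests)

    def test_sex_strata_drop_sex_covariate(self, rng):
        df, y, d = self._frame(rng)
        # degenerate sex column within stratum must not break the fit
        ests = mr.run_stratified(df, y, d["x"], d["z"], ["age", "sex"],
                                 mr.tsls)
        men = next(e for e in ests if e.stratum == "men")
        assert np.isfinite(men.estimate)

    def test_empty_stratum_reported_unavailable(self, rng):
        df, y, d = self._frame(rng)
        df["bmi"] = 20.0                 # nobody overweight
        ests = mr.run_stratified(df, y, d["x"], d["z"], ["age"], mr.tsls)
        over = next(e for e in ests if e.stratum == "overweight_obese")
        assert "unavailable" in over.note
        normal = next(e for e in ests if e.stratum == "normal_weight")
        assert np.isfinite(normal.estimate)

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(31)
        eff_a, eff_b = [], []
        for _ in range(40):
            df, y, d = self._frame(rng, n=2500,
                                   interaction="normal_weight_only")
            ests = mr.run_stratified(df, y, d["x"], d["z"], ["age"], mr.tsls,
                                     strata=("normal_weight",
                                             "overweight_obese"))
            eff_a.append(ests[0].estimate)
            eff_b.append(ests[1].estimate)
        assert abs(np.mean(eff_a) - 0.4) < 0.1
        assert abs(np.mean(eff_b)) < 0.1


class TestConfounderBalance:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        reps, n = 300, 400
        hits = np.zeros(3)
        for _ in range(reps):
            prs_score = rng.normal(size=n)
            cov = pd.DataFrame({"age": rng.normal(50, 8, n),
                                "bmi": rng.normal(27, 4, n),
                                "alcohol": rng.integers(0, 2, n)})
            tab = mr.confounder_balance(prs_score, cov)
            hits += (tab["p"] < 0.05).to_numpy()
        for frac in hits / reps:
            assert 0.02 <= frac <= 0.08

    def test_loaded_covariate_detected(self):
        rng = np.random.default_rng(18)
        detected = 0
        for _ in range(30):
            n = 3000
            bmi = rng.normal(27, 4, n)
            prs_score = 0.1 * (bmi - 27) / 4 + rng.normal(size=n)
            cov = pd.DataFrame({"age": rng.normal(50, 8, n), "bmi": bmi})
            tab = mr.confounder_balance(prs_score, cov).set_index("covariate")
            detected += tab.at["bmi", "p"] < 0.05
        assert detected >= 0.95 * 30

    def test_constant_covariate_gives_na_row(self, rng):
        tab = mr.confounder_balance(rng.normal(size=50),
                                    pd.DataFrame({"flat": np.ones(50)}))
        assert np.isnan(tab.loc[0, "p"])


class TestPleiotropyScatter:
    def _setup(self, rng, n=1500, m=60, pleio_idx=None, pleio_effect=0.0):
        import pandas as pd

        from prsmr.prs import PRSModel
        d = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        beta = rng.normal(0, 0.08, m)
        x = d @ beta + rng.normal(size=n) * 0.8
        y = 0.5 * x + rng.normal(size=n)
        if pleio_idx is not None:
            y = y + pleio_effect * d[:, pleio_idx]
        w = pd.DataFrame({"snp_id": [f"v{j}" for j in range(m)],
                          "effect_allele": "A", "beta": beta,
                          "p": np.full(m, 1e-4)})
        model = PRSModel(threshold=1e-4, weights=w, n_snps=m, fit_r2=0.1)
        idx = {f"v{j}": j for j in range(m)}
        return model, d, x, y, idx

    def test_null_yields_no_outliers(self):
        rng = np.random.default_rng(19)
        clean = 0
        for _ in range(20):
            model, d, x, y, idx = self._setup(rng)
            tab = mr.pleiotropy_scatter(model, d, x, y, None, idx)
            clean += int(tab["outlier"].sum() == 0)
        assert clean >= 18

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(20)
        flagged = 0
        for _ in range(20):
            model, d, x, y, idx = self._setup(rng, pleio_idx=7,
                                              pleio_effect=0.5)
            tab = mr.pleiotropy_scatter(model, d, x, y, None, idx)
            flagged += bool(tab.set_index("snp_id").at["v7", "outlier"])
        assert flagged >= 18

    def test_empty_model_raises(self, rng):
        from prsmr.prs import PRSModel
        model = PRSModel(threshold=1.0, weights=pd.DataFrame(
            columns=["snp_id", "effect_allele", "beta", "p"]),
            n_snps=0, fit_r2=0.0)
        with pytest.raises(ValueError, match="empty"):
            mr.pleiotropy_scatter(model, np.zeros((10, 1)),
                                  np.zeros(10), np.zeros(10), None, {})

    def test_monomorphic_snp_dropped_with_warning(self):
        rng = np.random.default_rng(21)
        model, d, x, y, idx = self._setup(rng, m=20)
        d[:, 4] = 1.0                   # monomorphic
        with pytest.warns(UserWarning, match="monomorphic"):
            tab = mr.pleiotropy_scatter(model, d, x, y, None, idx)
        assert "v4" not in set(tab["snp_id"])
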