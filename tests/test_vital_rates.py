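"""Design matrices, GLM fitting, AICc, all-subsets selection, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from polydem import (AICcUndefinedError, FitError, FittedVitalRate,
                     SchemaError, aicc, build_design, fit_seed_calibration,
                     fit_vital_rate, hierarchical_term_sets, predict_rate,
                     select_model)
from polydem.vital_rates import (GLOBAL_TERMS, RATE_SPECS, VitalRateSpec,
                                 VARIANCE_FLOOR)


def _frame(n=None, z=None, M=None, H=None, y=None, seed=0):
    rng = np.random.default_rng(seed)
    n = n or len(z)
    z = rng.uniform(0.5, 3.5, n) if z is None else np.asarray(z, float)
    M = rng.uniform(4, 20, n) if M is None else np.asarray(M, float)
    H = rng.uniform(0, 60, n) if H is None else np.asarray(H, float)
    df = pd.DataFrame({"size_t": z, "moisture_t": M, "herbivory_t": H})
    if y is not None:
        df["survived_t1"] = y
    return df


SURV = RATE_SPECS["s"]


class TestBuildDesign:
    def test_intercept_only(self):
        X = build_design(_frame(n=5), ())
        assert X.shape == (5, 1) and (X == 1).all()

    def test_interaction_is_elementwise_product(self):
        X = build_design(_frame(z=[2.0], M=[3.0], H=[0.0]), ("z", "M", "z:M"))
        assert X.tolist() == [[1.0, 2.0, 3.0, 6.0]]

    def test_full_global_model_has_8_columns(self):
        X = build_design(_frame(n=4), GLOBAL_TERMS)
        assert X.shape == (4, 8)

    def test_missing_values_rejected_with_rows(self):
        df = _frame(n=4)
        df.loc[2, "moisture_t"] = np.nan
        with pytest.raises(SchemaError, match="2"):
            build_design(df, ("M",))

    def test_column_order_is_canonical(self):
        z, M, H = [2.0], [3.0], [5.0]
        X = build_design(_frame(z=z, M=M, H=H), GLOBAL_TERMS)
        assert X.tolist() == [[1, 2, 3, 5, 6, 10, 15, 30]]


class TestAICc:
    @pytest.mark.parametrize("loglik,k,n,expected", [
        (-10.0, 3, 20, 27.5),
        (0.0, 1, 100, 2 + 4 / 98),
    ])
    def test_plug_in_values(self, loglik, k, n, expected):
        assert aicc(loglik, k, n) == pytest.approx(expected, abs=1e-12)

    def test_pole_at_n_equals_k_plus_1(self):
        with pytest.raises(AICcUndefinedError):
            aicc(-5.0, 4, 5)


class TestFitting:
    def test_gaussian_exact_line_recovered(self):
        df = _frame(n=50, seed=1)
        df["size_t1"] = 0.3 + 0.7 * df["size_t"] + 0.02 * df["moisture_t"]
        df["survived_t1"] = 1
        df["bolting_t"] = 0
        df["bolting_t1"] = 0
        fit = fit_vital_rate(RATE_SPECS["g00"], df, ("z", "M"))
        assert fit.params == pytest.approx([0.3, 0.7, 0.02], abs=1e-8)
        resid = df["size_t1"] - predict_rate(
            fit, df["size_t"], (df["moisture_t"], df["herbivory_t"]))
        assert float((resid ** 2).mean()) == pytest.approx(0.0, abs=1e-16)

    def test_binomial_balanced_noise(self):
        rng = np.random.default_rng(12345)  # independent of predictor draws
        df = _frame(n=4000, seed=2, y=(rng.random(4000) < 0.5).astype(int))
        fit = fit_vital_rate(SURV, df, ("z", "M"))
        prop = df["survived_t1"].mean()
        assert fit.params[0] == pytest.approx(np.log(prop / (1 - prop)),
                                              abs=0.5)
        assert np.abs(fit.params[1:]).max() < 0.1

    def test_logistic_slope_recovery_within_3_se(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(0.5, 3.5, 5000)
        eta = -3.0 + 1.5 * z
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(int)
        df = _frame(z=z, M=np.zeros(5000), H=np.zeros(5000), y=y)
        fit = fit_vital_rate(SURV, df, ("z",))
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.params[1] - 1.5) < 3 * se

    def test_separation_raises_fit_error(self):
        z = np.linspace(0, 1, 40)
        df = _frame(z=z, M=np.zeros(40), H=np.zeros(40),
                    y=(z > 0.5).astype(int))
        with pytest.raises(FitError) as err:
            fit_vital_rate(SURV, df, ("z",))
        assert "z" in err.value.terms

    def test_covariance_matches_numerical_hessian(self):
        """Reported binomial coefficient covariance equals the inverse
        observed information, checked against finite differences of an
        independently coded log-likelihood."""
        rng = np.random.default_rng(4)
        z = rng.uniform(0.5, 3.5, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-1 + 0.8 * z)))).astype(int)
        df = _frame(z=z, M=np.zeros(400), H=np.zeros(400), y=y)
        fit = fit_vital_rate(SURV, df, ("z",))
        X = np.column_stack([np.ones(400), z])

        def loglik(beta):
            eta = X @ beta
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        h = 1e-5
        H = np.empty((2, 2))
        for i, j in itertools.product(range(2), range(2)):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (loglik(fit.params + ei + ej)
                       - loglik(fit.params + ei - ej)
                       - loglik(fit.params - ei + ej)
                       + loglik(fit.params - ei - ej)) / (4 * h * h)
        cov_num = np.linalg.inv(-H)
        assert np.allclose(fit.cov, cov_num, rtol=1e-4, atol=1e-10)


class TestSelection:
    def test_candidate_count_matches_bruteforce_oracle(self):
        """The marginality-respecting candidate list equals an independent
        brute-force enumeration over all 128 subsets."""
        def closed(subset):
            # a set is admissible iff it is downward closed under taking
            # nonempty proper factor subsets
            fs = [frozenset(t.split(":")) for t in subset]
            have = set(fs)
            for s in fs:
                for r in range(1, len(s)):
                    for sub in itertools.combinations(sorted(s), r):
                        if frozenset(sub) not in have:
                            return False
            return True

        oracle = [c for r in range(8)
                  for c in itertools.combinations(GLOBAL_TERMS, r)
                  if closed(c)]
        got = hierarchical_term_sets()
        assert len(got) == len(oracle) == 19
        assert set(got) == set(oracle)

    def test_selected_aicc_close_to_minimum(self, census):
        fit = select_model(SURV, census[census.genotype == "BB"])
        table = fit.selection_table
        assert table["selected"].sum() == 1
        min_aicc = table.loc[table.converged, "aicc"].min()
        assert fit.aicc_value <= min_aicc + 2.0
        # global and intercept-only models are in the candidate table
        assert "1" in set(table["terms"])
        assert "+".join(GLOBAL_TERMS) in set(table["terms"])

    def test_strict_minimisation_mode(self, census):
        fit = select_model(SURV, census[census.genotype == "BB"],
                           parsimony_window=0.0)
        table = fit.selection_table
        assert fit.aicc_value == table.loc[table.converged, "aicc"].min()

    def test_nested_gaussian_loglik_monotone(self, census):
        sub = census[census.genotype == "BB"]
        nested = [(), ("z",), ("z", "M"), ("z", "M", "z:M")]
        lls = [fit_vital_rate(RATE_SPECS["g00"], sub, t).loglik
               for t in nested]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestPredict:
    def test_inverse_logit_at_zero_and_ln3(self):
        fit = FittedVitalRate(key="s", family="binomial", terms=(),
                              params=[0.0], cov=np.zeros((1, 1)))
        assert predict_rate(fit, 1.0, (0.0, 0.0)) == pytest.approx(0.5)
        fit3 = FittedVitalRate(key="s", family="binomial", terms=(),
                               params=[np.log(3)], cov=np.zeros((1, 1)))
        assert predict_rate(fit3, 1.0, (0.0, 0.0)) == pytest.approx(0.75)

    def test_variance_rate_floored(self):
        fit = FittedVitalRate(key="v00", family="gaussian", terms=("M",),
                              params=[0.01, -0.01], cov=np.zeros((2, 2)))
        assert predict_rate(fit, 1.0, (50.0, 0.0)) == VARIANCE_FLOOR

    def test_driver_override_pins_prediction(self):
        fit = FittedVitalRate(key="f", family="gaussian", terms=("M",),
                              params=[1.0, 2.0], cov=np.zeros((2, 2)),
                              driver_overrides={"M": 10.0})
        assert predict_rate(fit, 0.0, (99.0, 0.0)) == pytest.approx(21.0)


class TestSeedCalibration:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cal = fit_seed_calibration(x, 2 * x + 1)
        assert cal.slope == pytest.approx(2.0, abs=1e-10)
        assert cal.intercept == pytest.approx(1.0, abs=1e-10)

    def test_prediction_floored_at_zero(self):
        x = np.array([10.0, 20.0, 30.0])
        cal = fit_seed_calibration(x, 0.5 * x - 5)
        assert cal.predict(0.0) == 0.0

    def test_noisy_slope_within_3_se(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(5, 60, 200)
        y = 1.5 * x + 4 + rng.normal(0, 3, 200)
        cal = fit_seed_calibration(x, y)
        X = np.column_stack([np.ones(200), x])
        se = np.sqrt(np.linalg.inv(X.T @ X)[1, 1] * 9)
        assert abs(cal.slope - 1.5) < 3 * se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_seed_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(FitError, match="variance"):
            fit_seed_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
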