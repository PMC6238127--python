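import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sdmeval.rasters_io import GridRaster
from sdmeval.sdm_algorithms import (fit_bioclim, fit_domain, fit_glm,
                                    import_prediction, predict_bioclim,
                                    predict_domain, predict_glm)
from sdmeval.synthetic_world import WorldConfig, generate_predictors

from oracles import bioclim_oracle, domain_oracle


def presence_table(X, names):
    df = pd.DataFrame(X, columns=names)
    df["label"] = "presence"
    return df


def pa_table(X, y, names):
    df = pd.DataFrame(X, columns=names)
    df["label"] = np.where(y == 1, "presence", "absence")
    return df


class TestBioclim:
    def test_envelope(self):
        train = presence_table(np.arange(1, 101.0)[:, None], ["a"])
        m = fit_bioclim(train, ["a"])
        assert m.envelopes["a"] == (1.0, 100.0)

    def test_two_layers_independent_envelopes(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0) * 3 + 5])
        m = fit_bioclim(presence_table(X, ["a", "b"]), ["a", "b"])
        assert m.envelopes["a"] == (0.0, 9.0)
        assert m.envelopes["b"] == (5.0, 32.0)

    def test_refit_deterministic(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        t = presence_table(X, ["a", "b"])
        m1 = fit_bioclim(t, ["a", "b"])
        m2 = fit_bioclim(t, ["a", "b"])
        np.testing.assert_array_equal(m1.sorted_samples["a"], m2.sorted_samples["a"])

    def test_too_few_presences(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_bioclim(presence_table(np.zeros((4, 1)), ["a"]), ["a"])

    def test_median_scores_one(self, stack_factory):
        train = presence_table(np.arange(1, 102.0)[:, None], ["env01"])
        m = fit_bioclim(train, ["env01"])
        stack = stack_factory([np.full((3, 3), 51.0)])  # the median value
        s = predict_bioclim(m, stack)
        assert np.allclose(s.values, 1.0)

    def test_outside_envelope_zero(self, stack_factory):
        m = fit_bioclim(presence_table(np.arange(1, 11.0)[:, None], ["env01"]),
                        ["env01"])
        stack = stack_factory([np.full((3, 3), 0.5)])
        assert np.allclose(predict_bioclim(m, stack).values, 0.0)

    def test_min_over_layers_tail_arithmetic(self, stack_factory):
        # layer a at the 90th percentile (t = 0.2), layer b at the median
        a_train = np.arange(1, 11.0)        # F(9.x ... ) of value 9.5: 9/10 = 0.9
        b_train = np.arange(1, 12.0)
        X = np.column_stack([a_train, b_train[:10]])
        m = fit_bioclim(presence_table(X, ["a", "b"]), ["a", "b"])
        stack = stack_factory([np.full((2, 2), 9.5), np.full((2, 2), 5.5)],
                              names=["a", "b"])
        s = predict_bioclim(m, stack)
        np.testing.assert_allclose(s.values, 0.2)

    def test_oracle_equivalence(self, stack_factory):
        rng = np.random.default_rng(7)
        for trial in range(5):
            stack = generate_predictors(WorldConfig(
                n_rows=20, n_cols=20, n_predictors=3, autocorr_length=2,
                seed=100 + trial))
            X = rng.normal(size=(15, 3))
            m = fit_bioclim(presence_table(X, stack.names), stack.names)
            fast = predict_bioclim(m, stack).values
            slow = bioclim_oracle(m.sorted_samples, stack.names, stack)
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestDomain:
    def test_training_point_similarity_one(self, stack_factory):
        X = np.random.default_rng(0).normal(size=(10, 2))
        m = fit_domain(presence_table(X, ["a", "b"]), ["a", "b"])
        stack = stack_factory([np.full((2, 2), X[3, 0]), np.full((2, 2), X[3, 1])],
                              names=["a", "b"])
        assert np.allclose(predict_domain(m, stack).values, 1.0)

    def test_hand_gower_case(self, stack_factory):
        # ranges (10, 4); cell (2, 1); nearest point (7, 3) -> d = 0.5
        X = np.array([[7.0, 3.0], [17.0, 7.0], [12.0, 5.0], [9.0, 4.0],
                      [15.0, 6.0]])
        m = fit_domain(presence_table(X, ["a", "b"]), ["a", "b"])
        np.testing.assert_allclose(m.ranges, [10.0, 4.0])
        stack = stack_factory([np.full((1, 1), 2.0), np.full((1, 1), 1.0)],
                              names=["a", "b"])
        assert predict_domain(m, stack).values[0, 0] == pytest.approx(0.5)

    def test_far_cell_clamped_to_zero(self, stack_factory):
        X = np.column_stack([np.arange(5.0), np.arange(5.0)])
        m = fit_domain(presence_table(X, ["a", "b"]), ["a", "b"])
        stack = stack_factory([np.full((2, 2), 100.0), np.full((2, 2), 100.0)],
                              names=["a", "b"])
        assert np.allclose(predict_domain(m, stack).values, 0.0)

    def test_zero_range_layer_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="flat"):
            fit_domain(presence_table(X, ["a", "flat"]), ["a", "flat"])

    def test_oracle_equivalence(self, stack_factory):
        rng = np.random.default_rng(8)
        for trial in range(5):
            stack = generate_predictors(WorldConfig(
                n_rows=20, n_cols=20, n_predictors=3, autocorr_length=2,
                seed=200 + trial))
            X = rng.normal(size=(12, 3))
            m = fit_domain(presence_table(X, stack.names), stack.names)
            fast = predict_domain(m, stack).values
            slow = domain_oracle(m.train, m.ranges, stack.names, stack)
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestGlm:
    def test_intercept_only_logit_prevalence(self):
        y = np.array([1] * 25 + [0] * 75)
        # a pure-noise predictor with tiny influence; check the intercept
        # against the closed-form logit of prevalence using zero slopes:
        df = pa_table(np.zeros((100, 0)), y, [])
        df["label"] = np.where(y == 1, "presence", "absence")
        m = fit_glm(df, [])
        assert m.intercept == pytest.approx(math.log(0.25 / 0.75), abs=1e-6)

    def test_null_slopes_within_3se(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(3000, 2))
        y = (rng.random(3000) < 0.4).astype(int)  # independent of X
        m = fit_glm(pa_table(X, y, ["a", "b"]), ["a", "b"])
        assert (np.abs(m.coef[1:]) < 3 * m.std_errors[1:]).all()

    def test_separation_flagged(self):
        X = np.arange(10.0)[:, None]
        y = (X.ravel() > 4.5).astype(int)
        m = fit_glm(pa_table(X, y, ["a"]), ["a"])
        assert m.separation

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 1))
        with pytest.raises(ValueError, match="both presence and absence"):
            fit_glm(pa_table(X, np.ones(10), ["a"]), ["a"])

    def test_matches_statsmodels(self):
        # independent reference fit on a well-conditioned problem
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        X = rng.normal(size=(500, 2))
        eta = -0.3 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(500) < expit(eta)).astype(int)
        m = fit_glm(pa_table(X, y, ["a", "b"]), ["a", "b"])
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(m.std_errors, ref.bse, atol=1e-5)

    def test_predict_zero_coefs_half(self, stack_factory):
        from sdmeval.sdm_algorithms import GlmModel
        m = GlmModel(["env01", "env02"], np.zeros(3), np.zeros(3), 0.0, 1, True)
        stack = stack_factory([np.random.default_rng(0).normal(size=(3, 3))] * 1
                              + [np.random.default_rng(1).normal(size=(3, 3))])
        assert np.allclose(predict_glm(m, stack).values, 0.5)

    def test_predict_hand_case(self, stack_factory):
        from sdmeval.sdm_algorithms import GlmModel
        m = GlmModel(["env01", "env02"], np.array([0.0, 1.0, -1.0]),
                     np.zeros(3), 0.0, 1, True)
        stack = stack_factory([np.full((2, 2), 2.0), np.full((2, 2), 2.0)])
        assert np.allclose(predict_glm(m, stack).values, 0.5)

    def test_predict_monotone(self, stack_factory):
        from sdmeval.sdm_algorithms import GlmModel
        m = GlmModel(["env01"], np.array([0.2, 1.5]), np.zeros(2), 0.0, 1, True)
        lo = stack_factory([np.full((2, 2), 0.0)])
        hi = stack_factory([np.full((2, 2), 1.0)])
        assert (predict_glm(m, hi).values > predict_glm(m, lo).values).all()

    def test_parameter_recovery_replicates(self):
        # truth recovered within +-3 SE in >= 95% of seeded replicates
        true = np.array([-0.4, 1.0, -0.8])
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(2000, 2))
            eta = true[0] + X @ true[1:]
            y = (rng.random(2000) < expit(eta)).astype(int)
            m = fit_glm(pa_table(X, y, ["a", "b"]), ["a", "b"])
            if (np.abs(m.coef - true) <= 3 * m.std_errors).all():
                hits += 1
        assert hits / n_rep >= 0.95


class TestImportPrediction:
    def template(self, values):
        values = np.asarray(values, dtype=float)
        return GridRaster(values=values, x_origin=0, y_origin=values.shape[0],
                          cell_size=1)

    def test_no_rescale_unchanged(self):
        t = self.template(np.zeros((3, 3)))
        r = self.template(np.linspace(0, 1, 9).reshape(3, 3))
        out = import_prediction(r, t)
        np.testing.assert_array_equal(out.values, r.values)

    def test_constant_rescale_error(self):
        t = self.template(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="zero range"):
            import_prediction(self.template(np.full((3, 3), 4.0)), t, rescale=True)

    def test_rescale_extremes(self):
        t = self.template(np.zeros((3, 3)))
        r = self.template(np.linspace(0, 255, 9).reshape(3, 3))
        out = import_prediction(r, t, rescale=True)
        assert np.nanmin(out.values) == 0.0
        assert np.nanmax(out.values) == 1.0

    def test_misaligned_error_names_offsets(self):
        t = self.template(np.zeros((3, 3)))
        bad = GridRaster(values=np.zeros((3, 3)), x_origin=5.0, y_origin=3,
                         cell_size=1)
        with pytest.raises(ValueError, match="origin"):
            import_prediction(bad, t)


class TestSuitabilityInvariants:
    @pytest.mark.parametrize("algo", ["bioclim", "domain", "glm"])
    def test_range_and_nodata(self, algo):
        stack = generate_predictors(WorldConfig(n_rows=20, n_cols=20,
                                                n_predictors=2, seed=5))
        # punch a nodata hole into every layer
        for name in stack.names:
            stack[name].values[3:5, 3:5] = np.nan
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        if algo == "glm":
            y = (X[:, 0] > 0).astype(int)
            y[::7] = 1 - y[::7]  # avoid separation
            m = fit_glm(pa_table(X, y, stack.names), stack.names)
            s = predict_glm(m, stack)
        elif algo == "bioclim":
            m = fit_bioclim(presence_table(X, stack.names), stack.names)
            s = predict_bioclim(m, stack)
        else:
            m = fit_domain(presence_table(X, stack.names), stack.names)
            s = predict_domain(m, stack)
        valid = ~np.isnan(s.values)
        assert np.isnan(s.values[3:5, 3:5]).all()
        assert (s.values[valid] >= 0).all() and (s.values[valid] <= 1).all()
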