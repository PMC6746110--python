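import warnings

import numpy as np
import pandas as pd
import pytest

from anatidiv.env_drivers import (
    NDVIStack,
    _bootstrap_indices,
    fit_driver_model,
    importance_scaled,
    morans_i,
    ndvi_summaries,
    ndvi_summary_table,
    vif_screen,
)


class TestNDVISummaries:
    def test_constant_stack_is_exact(self):
        arr = np.full((4, 4, 10, 36), 0.5)
        s = ndvi_summaries(arr)
        assert s["mn"] == 0.5
        assert s["season"] == 0.0
        assert s["annvar"] == 0.0
        assert s["het"] == 0.0

    def test_identical_annual_sawtooth_has_zero_interannual_variation(self):
        saw = np.tile(np.linspace(-0.2, 0.6, 36), (1, 1, 10, 1)).reshape(1, 1, 10, 36)
        s = ndvi_summaries(saw)
        assert s["annvar"] == pytest.approx(0.0, abs=1e-12)
        assert s["season"] > 0

    def test_hand_fixture_season_matches_manual_sd(self):
        # 1 pixel, 2 years x 4 dekads; SD(0.1,0.2,0.3,0.4) = SD(0.2,...,0.5)
        # = sqrt(0.05/3) = 0.129099; season = their mean
        arr = np.array([[[[0.1, 0.2, 0.3, 0.4], [0.2, 0.3, 0.4, 0.5]]]])
        s = ndvi_summaries(arr)
        assert s["season"] == pytest.approx(np.sqrt(0.05 / 3), abs=1e-9)

    def test_small_pixel_grid_has_undefined_heterogeneity(self):
        arr = np.full((2, 2, 3, 6), 0.1)
        assert np.isnan(ndvi_summaries(arr)["het"])

    def test_invariance_to_pixel_and_year_ordering(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(-0.1, 0.8, (3, 3, 5, 12))
        s = ndvi_summaries(arr)
        flipped_years = arr[:, :, ::-1, :]
        s2 = ndvi_summaries(flipped_years)
        for k in ("mn", "season", "annvar", "het"):
            assert s[k] == pytest.approx(s2[k], abs=1e-12)
        # pixel reflection changes window contents ordering but not mn/season/annvar
        refl = arr[::-1, ::-1]
        s3 = ndvi_summaries(refl)
        for k in ("mn", "season", "annvar", "het"):
            assert s[k] == pytest.approx(s3[k], abs=1e-12)

    def test_summary_table_columns(self):
        rng = np.random.default_rng(1)
        stack = NDVIStack(rng.uniform(0, 0.5, (2, 3, 3, 2, 6)), ["c1", "c2"])
        tab = ndvi_summary_table(stack, "NDVI")
        assert list(tab.columns) == ["mn.NDVI", "season.NDVI", "annvar.NDVI", "het.NDVI"]


class TestVIF:
    def test_orthogonal_predictors_all_retained(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        cols, trace = vif_screen(X, 10)
        assert cols == list("abcd")
        assert trace.empty

    def test_duplicated_column_drops_the_later_copy(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["x1", "x2", "x3"])
        X["x1_copy"] = X["x1"]
        cols, trace = vif_screen(X, 10)
        assert "x1" in cols and "x1_copy" not in cols
        assert np.isinf(trace.iloc[0]["vif"])

    def test_near_linear_combination_drops_exactly_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=[f"x{i}" for i in range(1, 6)])
        X["x3"] = X["x1"] + X["x2"] + rng.normal(0, 1e-3, 300)
        cols, trace = vif_screen(X, 10)
        assert len(trace) == 1
        assert trace.iloc[0]["dropped"] in {"x1", "x2", "x3"}
        # survivors verified by direct OLS VIF
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        exog = sm.add_constant(X[cols]).to_numpy()
        for k in range(1, exog.shape[1]):
            assert variance_inflation_factor(exog, k) <= 10

    def test_retained_set_has_no_perfect_pairwise_correlation(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        X["dup"] = X["a"]
        cols, _ = vif_screen(X, 10)
        corr = X[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 1.0


class TestMoransI:
    def _lattice(self, n=10):
        return np.repeat(np.arange(float(n)), n), np.tile(np.arange(float(n)), n)

    def test_checkerboard_is_strongly_negative(self):
        lat, lon = self._lattice()
        z = ((lat + lon) % 2) * 2 - 1.0
        i, p = morans_i(z, lat, lon, rng=np.random.default_rng(6))
        assert i < 0
        assert p < 0.01

    def test_smooth_gradient_is_strongly_positive(self):
        lat, lon = self._lattice()
        z = lat + 0.05 * np.random.default_rng(7).normal(size=100)
        i, p = morans_i(z, lat, lon, rng=np.random.default_rng(8))
        assert i > 0
        assert p < 0.01

    def test_constant_values_undefined(self):
        lat, lon = self._lattice()
        i, p = morans_i(np.ones(100), lat, lon)
        assert np.isnan(i) and np.isnan(p)

    def test_iid_noise_rejected_near_nominal_rate(self):
        lat, lon = self._lattice()
        rng = np.random.default_rng(9)
        rej = 0
        n_draws = 60
        for k in range(n_draws):
            z = rng.normal(size=100)
            _, p = morans_i(z, lat, lon, n_perm=199, rng=np.random.default_rng(1000 + k))
            rej += p <= 0.05
        assert 0 <= rej / n_draws <= 0.15


@pytest.fixture(scope="module")
def linear_forest():
    rng = np.random.default_rng(10)
    n = 500
    X = pd.DataFrame({
        "signal": rng.uniform(0, 1, n),
        "noise1": rng.normal(size=n),
        "noise2": rng.normal(size=n),
        "lat": rng.uniform(-60, 60, n),
        "lon": rng.uniform(-180, 180, n),
    })
    y = pd.Series(3.0 * X["signal"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_driver_model(y, X, n_trees=300, mtry=3, seed=11)
    return model


class TestForest:
    def test_noiseless_monotone_signal_explains_most_variance(self, linear_forest):
        assert linear_forest.var_explained > 95

    def test_pure_noise_response_explains_nothing(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=[f"x{i}" for i in range(5)])
        y = pd.Series(rng.normal(size=300))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_driver_model(y, X, n_trees=200, seed=13)
        assert m.var_explained < 10  # OOB R^2 can be negative; reported as-is

    def test_fit_is_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(120, 4)), columns=list("abcd"))
        y = pd.Series(X["a"] + rng.normal(0, 0.2, 120))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fit_driver_model(y, X, n_trees=80, seed=15)
            m2 = fit_driver_model(y, X, n_trees=80, seed=15)
        assert np.array_equal(m1.forest.oob_prediction_, m2.forest.oob_prediction_)
        pd.testing.assert_series_equal(m1.raw_importance, m2.raw_importance)

    def test_bootstrap_index_reconstruction_matches_sklearn_oob(self, linear_forest):
        """Our per-tree OOB bookkeeping reproduces sklearn's own OOB predictions."""
        m = linear_forest
        Xv = m.X.to_numpy(float)
        n = Xv.shape[0]
        preds = np.zeros(n)
        counts = np.zeros(n)
        for est in m.forest.estimators_:
            oob = np.bincount(_bootstrap_indices(est, n), minlength=n) == 0
            preds[oob] += est.predict(Xv[oob])
            counts[oob] += 1
        assert (counts > 0).all()
        assert np.abs(preds / counts - m.forest.oob_prediction_).max() < 1e-10

    def test_importance_sums_to_100_and_hides_coordinates(self, linear_forest):
        imp = importance_scaled(linear_forest)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert "lat" not in imp.index and "lon" not in imp.index
        assert (imp >= 0).all()
        with_coords = importance_scaled(linear_forest, include_coordinates=True)
        assert "lat" in with_coords.index
        assert with_coords.sum() == pytest.approx(100.0, abs=1e-6)

    def test_signal_dominates_importance_and_minimal_depth(self, linear_forest):
        imp = importance_scaled(linear_forest)
        assert imp.idxmax() == "signal"
        md = linear_forest.minimal_depth_
        assert md.idxmin() == "signal"

    def test_partial_dependence_of_linear_term_is_monotone(self, linear_forest):
        curve = linear_forest.partial_dependence("signal", grid_size=15)
        assert list(curve.columns) == ["predictor", "x", "partial", "se"]
        assert (curve["se"] >= 0).all()
        # monotone up to the SE band
        vals = curve["partial"].to_numpy()
        se = curve["se"].to_numpy()
        assert ((np.diff(vals) > -2 * (se[:-1] + se[1:]))).all()
        assert vals[-1] > vals[0]

    def test_unknown_predictor_is_error(self, linear_forest):
        with pytest.raises(KeyError):
            linear_forest.partial_dependence("nope")
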