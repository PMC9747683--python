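"""The maximum-entropy core: fitting oracles, transforms, invariants."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import entniche as en
from entniche.features import FeatureDef
from entniche.model import default_beta, penalized_gain, training_gain


@pytest.fixture
def four_cell():
    """Single binary feature: background (1,1,0,0), both presences at 1."""
    pres = {"x": np.array([1.0, 1.0])}
    bg = {"x": np.array([1.0, 1.0, 0.0, 0.0])}
    feats = [FeatureDef("linear", ("x",), None, 0.0, 1.0)]
    return pres, bg, feats


class TestClosedFormInstance:
    def test_beta_ln3_at_lambda_quarter(self, four_cell):
        pres, bg, feats = four_cell
        model, _ = en.fit_maxent(pres, bg, features=feats, lam=0.25, tol=1e-12)
        # stationarity: e^b/(e^b+1) = 1 - lambda -> b = ln 3
        assert model.beta[0] == pytest.approx(np.log(3), abs=1e-6)
        raw = model.predict_env(bg, "raw")
        assert np.allclose(raw, [3 / 8, 3 / 8, 1 / 8, 1 / 8])

    def test_matches_grid_search_oracle(self, four_cell):
        pres, bg, feats = four_cell
        Xp = np.array([[1.0], [1.0]])
        Xb = np.array([[1.0], [1.0], [0.0], [0.0]])
        grid = np.linspace(-1, 3, 40001)
        gains = [penalized_gain(np.array([b]), Xp, Xb, np.array([0.25])) for b in grid]
        oracle = grid[int(np.argmax(gains))]
        model, _ = en.fit_maxent(pres, bg, features=feats, lam=0.25, tol=1e-12)
        assert abs(model.beta[0] - oracle) <= 1e-3

    @pytest.mark.parametrize("lam", [0.5, 0.7, 1.0])
    def test_subgradient_zero_at_large_lambda(self, four_cell, lam):
        pres, bg, feats = four_cell
        model, _ = en.fit_maxent(pres, bg, features=feats, lam=lam, tol=1e-12)
        assert model.beta[0] == 0.0
        assert np.allclose(model.predict_env(bg, "raw"), 0.25)

    def test_two_feature_instance_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        bg = {"x": rng.uniform(0, 1, 60), "y": rng.uniform(0, 1, 60)}
        pres = {"x": rng.uniform(0.4, 1, 10), "y": rng.uniform(0, 0.6, 10)}
        feats = [FeatureDef("linear", ("x",)), FeatureDef("linear", ("y",))]
        lam = np.array([0.05, 0.05])
        model, _ = en.fit_maxent(pres, bg, features=feats, lam=lam, tol=1e-14,
                                 tol_beta=1e-7, max_iter=20_000)
        Xp = np.column_stack([pres["x"], pres["y"]])
        Xb = np.column_stack([bg["x"], bg["y"]])
        bs = np.linspace(-7, 7, 281)
        best, arg = -np.inf, None
        for b1 in bs:
            for b2 in bs:
                g = penalized_gain(np.array([b1, b2]), Xp, Xb, lam)
                if g > best:
                    best, arg = g, (b1, b2)
        # refine the coarse grid around the argmax
        fine1 = np.linspace(arg[0] - 0.06, arg[0] + 0.06, 121)
        fine2 = np.linspace(arg[1] - 0.06, arg[1] + 0.06, 121)
        for b1 in fine1:
            for b2 in fine2:
                g = penalized_gain(np.array([b1, b2]), Xp, Xb, lam)
                if g > best:
                    best, arg = g, (b1, b2)
        assert abs(model.beta[0] - arg[0]) <= 1e-3
        assert abs(model.beta[1] - arg[1]) <= 1e-3


class TestFitInvariants:
    def test_raw_normalizes_over_training_background(self, fitted_model, fitted_env):
        model, _ = fitted_model
        _, bg, _ = fitted_env
        raw = model.predict_env(bg, "raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_kkt_moment_matching_unregularized(self):
        rng = np.random.default_rng(2)
        bg = {"x": rng.uniform(0, 1, 50)}
        pres = {"x": rng.uniform(0.3, 1, 8)}
        feats = [FeatureDef("linear", ("x",))]
        model, _ = en.fit_maxent(pres, bg, features=feats, lam=0.0,
                                 tol=1e-12, max_iter=5000)
        raw = model.predict_env(bg, "raw")
        model_mean = float(raw @ bg["x"])
        assert abs(model_mean - pres["x"].mean()) <= 1e-4

    def test_gain_non_decreasing(self, fitted_model):
        _, trace = fitted_model
        gains = np.array(trace.gains)
        assert np.all(np.diff(gains) >= -1e-12)

    def test_huge_rm_gives_uniform_model(self, fitted_env):
        pres, bg, _ = fitted_env
        model, _ = en.fit_maxent(pres, bg, rm=1e6, fc="LQ")
        n = len(next(iter(bg.values())))
        assert model.k == 0
        assert model.entropy_H == pytest.approx(np.log(n), abs=1e-9)

    def test_l1_norm_non_increasing_in_rm(self, fitted_env):
        pres, bg, _ = fitted_env
        norms = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            m, _ = en.fit_maxent(pres, bg, rm=rm, fc="LQ")
            norms.append(np.abs(m.beta).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_contributions_sum_to_100(self, fitted_model):
        _, trace = fitted_model
        assert sum(trace.percent_contributions().values()) == pytest.approx(100.0, abs=0.1)

    def test_parameter_recovery_on_synthetic_truth(self, fitted_model, fitted_env):
        model, trace = fitted_model
        _, bg, true_bg = fitted_env
        pred = model.predict_env(bg, "cloglog")
        assert spearmanr(pred, true_bg).statistic > 0.9


class TestPredict:
    def test_uniform_model_raw_and_entropy(self):
        rng = np.random.default_rng(0)
        bg = {"x": rng.uniform(0, 1, 100)}
        pres = {"x": rng.uniform(0, 1, 10)}
        model, _ = en.fit_maxent(pres, bg, features=[FeatureDef("linear", ("x",))],
                                 lam=10.0)
        assert np.allclose(model.predict_env(bg, "raw"), 0.01)
        assert model.entropy_H == pytest.approx(np.log(100), abs=1e-12)

    def test_cloglog_at_average_raw(self):
        rng = np.random.default_rng(0)
        bg = {"x": rng.uniform(0, 1, 100)}
        pres = {"x": rng.uniform(0, 1, 10)}
        model, _ = en.fit_maxent(pres, bg, features=[FeatureDef("linear", ("x",))],
                                 lam=10.0)
        # uniform: raw = 1/N, H = ln N -> cloglog = 1 - exp(-1)
        cll = model.predict_env(bg, "cloglog")
        assert np.allclose(cll, 1 - np.exp(-1))

    def test_logistic_in_unit_interval(self, fitted_model, fitted_env):
        model, _ = fitted_model
        _, bg, _ = fitted_env
        for t in ("cloglog", "logistic"):
            s = model.predict_env(bg, t)
            assert np.all((s >= 0) & (s <= 1))

    def test_clamped_projection_flat_beyond_training_max(self, fitted_model, fitted_env):
        model, _ = fitted_model
        pres, bg, _ = fitted_env
        v = model.variables[0]
        hi = model.clamp_ranges[v][1]
        env_hi = {u: np.array([np.mean(bg[u])]) for u in model.variables}
        env_hi[v] = np.array([hi])
        env_beyond = dict(env_hi, **{v: np.array([hi + 100.0])})
        assert model.predict_env(env_beyond, clamp=True) == pytest.approx(
            model.predict_env(env_hi, clamp=True))

    def test_missing_variable_named_in_error(self, fitted_model):
        model, _ = fitted_model
        env = {v: np.zeros(3) for v in model.variables[1:]}
        with pytest.raises(KeyError, match=model.variables[0]):
            model.predict_env(env)

    def test_predict_on_stack_propagates_nodata(self, stack, fitted_model):
        model, _ = fitted_model
        import copy
        st = en.EnvStack({n: r.copy_with(r.values.copy()) for n, r in stack.layers.items()})
        st.layers["bio1"].values[0, 0] = np.nan
        suit = model.predict(st)
        assert np.isnan(suit.values[0, 0])
        assert np.isfinite(suit.values[5, 5])


class TestResponseCurves:
    def test_positive_linear_monotone(self):
        rng = np.random.default_rng(1)
        bg = {"x": rng.uniform(0, 1, 200)}
        pres = {"x": rng.uniform(0.6, 1, 30)}
        model, _ = en.fit_maxent(pres, bg, features=[FeatureDef("linear", ("x",))],
                                 lam=0.01)
        assert model.beta[0] > 0
        xs, ys = model.response_curve("x", pres)
        assert np.all(np.diff(ys) >= -1e-12)
        assert np.all((ys >= 0) & (ys <= 1))

    def test_all_zero_model_flat(self, fitted_env):
        pres, bg, _ = fitted_env
        model, _ = en.fit_maxent(pres, bg, rm=1e6, fc="L")
        xs, ys = model.response_curve(model.variables[0], pres)
        assert np.allclose(ys, ys[0])

    def test_unused_variable_rejected(self, fitted_model, fitted_env):
        model, _ = fitted_model
        pres, _, _ = fitted_env
        with pytest.raises(KeyError):
            model.response_curve("nonexistent", pres)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, fitted_model, fitted_env, tmp_path):
        model, _ = fitted_model
        _, bg, _ = fitted_env
        p = tmp_path / "model.json"
        model.save(p)
        back = en.MaxentModel.load(p)
        assert np.array_equal(back.beta, model.beta)
        assert np.array_equal(back.predict_env(bg), model.predict_env(bg))
        assert back.clamp_ranges == model.clamp_ranges


@pytest.fixture(scope="module")
def jack_env():
    rng = np.random.default_rng(4)
    n_bg, n_p = 400, 60
    sig_bg = rng.uniform(0, 10, n_bg)
    sig_p = rng.uniform(6, 10, n_p)  # informative: presences at high values
    noise_bg = rng.normal(size=n_bg)
    noise_p = rng.normal(size=n_p)   # pure noise
    pres = {"signal": sig_p, "noise": noise_p, "dup": sig_p.copy()}
    bg = {"signal": sig_bg, "noise": noise_bg, "dup": sig_bg.copy()}
    return pres, bg


class TestJackknife:
    def test_noise_variable_has_near_zero_gain(self, jack_env):
        pres, bg = jack_env
        rows = en.jackknife_importance(pres, bg, ["signal", "noise"], fc="L", rm=1.0)
        by_var = {r["variable"]: r for r in rows}
        assert by_var["noise"]["gain_with_only"] <= 0.05
        assert by_var["signal"]["gain_with_only"] > 0.2

    def test_duplicated_variable_removal_costs_nothing(self, jack_env):
        pres, bg = jack_env
        rows = en.jackknife_importance(pres, bg, ["signal", "dup"], fc="L", rm=1.0)
        by_var = {r["variable"]: r for r in rows}
        full = by_var["_all_"]["gain_with_only"]
        assert by_var["dup"]["gain_without"] == pytest.approx(full, abs=0.02)
        # the lone informative variable carries the full gain by itself
        assert by_var["signal"]["gain_with_only"] == pytest.approx(full, abs=0.02)


def test_default_beta_interpolation_tables():
    assert default_beta("linear", 5) == 1.0
    assert default_beta("linear", 200) == 0.05
    assert default_beta("linear", 65) == pytest.approx((0.2 + 0.05) / 2)
    assert default_beta("forward_hinge", 50) == 0.5
    assert default_beta("threshold", 50) == pytest.approx(1.5)
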