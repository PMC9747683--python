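"""Metrics (AUC, OR10, CBI, AICc) and cross-validation partitions."""

import numpy as np
import pytest

import entniche as en
from entniche.evaluation import or10_threshold
from entniche.features import FeatureDef


def brute_force_auc(p, b):
    wins = sum((x > y) + 0.5 * (x == y) for x in p for y in b)
    return wins / (len(p) * len(b))


class TestAuc:
    @pytest.mark.parametrize("p,b,expected", [
        ([0.9, 0.8], [0.2, 0.1], 1.0),
        ([0.5], [0.5], 0.5),
        ([0.8, 0.3], [0.5, 0.1], 0.75),
    ])
    def test_known_values(self, p, b, expected):
        assert en.compute_auc(p, b) == pytest.approx(expected)

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            b = rng.uniform(size=rng.integers(1, 30))
            if rng.random() < 0.3:  # force ties sometimes
                b[: min(len(p), len(b))] = p[: min(len(p), len(b))]
            assert en.compute_auc(p, b) == pytest.approx(brute_force_auc(p, b), abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            en.compute_auc([], [0.5])


class TestOr10:
    def test_order_statistic_convention(self):
        train = np.arange(1, 11) / 10  # 0.1 .. 1.0
        assert or10_threshold(train) == pytest.approx(0.2)
        assert en.compute_or10(train, [0.15, 0.9]) == pytest.approx(0.5)

    def test_extremes(self):
        train = np.linspace(0.2, 0.9, 20)
        assert en.compute_or10(train, [0.95, 0.99]) == 0.0
        assert en.compute_or10(train, [0.01, 0.05]) == 1.0

    def test_training_self_omission_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            train = rng.uniform(size=rng.integers(5, 50))
            self_or = np.mean(train < or10_threshold(train))
            assert self_or <= 0.1 + 1.0 / train.size + 1e-12


class TestCbi:
    def test_monotone_ratio_gives_one(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(size=3000)
        p = rng.beta(4, 1.2, size=500)  # mass piled at high suitability
        assert en.compute_cbi(p, b) > 0.95

    def test_decreasing_ratio_gives_minus_one(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(size=3000)
        p = rng.beta(1.2, 4, size=500)
        assert en.compute_cbi(p, b) < -0.95

    def test_null_presences_from_background(self):
        # per-draw null s.d. is ~0.19, so the check is on the ensemble mean
        vals = []
        for s in range(10):
            b = np.random.default_rng(100 + s).uniform(size=4000)
            p = np.random.default_rng(200 + s).choice(b, size=500)
            vals.append(en.compute_cbi(p, b))
        assert abs(np.mean(vals)) < 0.15
        assert np.mean(np.abs(vals)) < 0.3

    def test_depends_only_on_window_mass_not_score_values(self):
        # the index is a rank correlation of window P/E ratios: a pure
        # relabelling of scores within each window cannot change it
        rng = np.random.default_rng(5)
        b = rng.uniform(size=2000)
        p = rng.beta(3, 2, size=300)
        base = en.compute_cbi(p, b)
        jitter = 1e-9 * rng.uniform(-1, 1, size=p.size)
        assert en.compute_cbi(np.clip(p + jitter, 0, 1), b) == pytest.approx(base, abs=0.02)

    def test_too_few_windows_error(self):
        with pytest.raises(ValueError, match="windows"):
            en.compute_cbi([0.5], [0.5], n_windows=3, window_width=0.01)


class TestAicc:
    def test_closed_form_value(self, fitted_env):
        # AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1): validated via a fitted model
        pres, bg, _ = fitted_env
        model, _ = en.fit_maxent(pres, bg, rm=1.0, fc="L")
        a = en.compute_aicc(model, pres, bg)
        from entniche.features import evaluate_features
        from scipy.special import logsumexp
        Xp = evaluate_features(model.features, pres)
        Xb = evaluate_features(model.features, bg)
        lnL = float(np.sum(Xp @ model.beta - logsumexp(Xb @ model.beta)))
        k, n = model.k, len(pres[next(iter(pres))])
        assert a == pytest.approx(2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1))

    def test_arithmetic_identity(self):
        # (k=3, n=20, lnL=-50) -> 107.5
        k, n, lnL = 3, 20, -50.0
        assert 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1) == 107.5

    def test_k_too_large_is_undefined(self):
        rng = np.random.default_rng(6)
        bg = {"x": rng.uniform(0, 1, 100), "y": rng.uniform(0, 1, 100)}
        pres = {"x": rng.uniform(0.5, 1, 3), "y": rng.uniform(0, 0.5, 3)}
        model, _ = en.fit_maxent(pres, bg, fc="L", lam=0.001)
        if model.k >= 3 - 1:
            assert np.isnan(en.compute_aicc(model, pres, bg))

    def test_zero_coefficients_reduce_to_minus_2lnl(self, fitted_env):
        pres, bg, _ = fitted_env
        model, _ = en.fit_maxent(pres, bg, rm=1e6, fc="L")
        assert model.k == 0
        n_bg = len(bg[next(iter(bg))])
        n = len(pres[next(iter(pres))])
        assert en.compute_aicc(model, pres, bg) == pytest.approx(2 * n * np.log(n_bg))


class TestPartitions:
    def test_block_quadrants_of_symmetric_points(self):
        lons = [-1, -1, 1, 1, -1, -1, 1, 1]
        lats = [-1, 1, -1, 1, -1, 1, -1, 1]
        part = en.make_partition(lons, lats, "block")
        sizes = np.bincount(part.folds)
        assert list(sizes) == [2, 2, 2, 2]

    def test_jackknife_has_n_folds(self):
        part = en.make_partition(np.arange(19), np.arange(19), "jackknife")
        assert len(part.splits()) == 19
        for train, test in part.splits():
            assert test.size == 1 and train.size == 18

    def test_random_split_deterministic_in_seed(self):
        lons = np.arange(40.0)
        a = en.make_partition(lons, lons, "random_split", seed=9)
        b = en.make_partition(lons, lons, "random_split", seed=9)
        c = en.make_partition(lons, lons, "random_split", seed=10)
        assert np.array_equal(a.folds, b.folds)
        assert not np.array_equal(a.folds, c.folds)
        assert (a.folds == 1).sum() == 10  # 25% of 40

    def test_block_needs_four_points(self):
        with pytest.raises(ValueError):
            en.make_partition([0, 1], [0, 1], "block")

    def test_bootstrap_oob_disjoint_from_none(self):
        part = en.make_partition(np.arange(30.0), np.arange(30.0),
                                 "bootstrap_replicate", seed=1, n_replicates=10)
        assert len(part.splits()) == 10
        for train, test in part.splits():
            assert train.size == 30
            assert np.intersect1d(np.unique(train), test).size == 0


class TestEvaluate:
    def test_separable_fixture_has_high_test_auc(self):
        rng = np.random.default_rng(7)
        bg = {"x": rng.uniform(0, 1, 600)}
        pres = {"x": rng.uniform(0.97, 1, 40)}  # near-perfect separation
        part = en.make_partition(np.arange(40.0), np.zeros(40), "random_split", seed=0)
        rep = en.evaluate(pres, bg, "L", 1.0, part)
        assert rep.auc_test >= 0.95

    def test_same_seed_identical_report(self, fitted_env):
        pres, bg, _ = fitted_env
        pres = {k: v[:40] for k, v in pres.items()}
        reports = []
        for _ in range(2):
            part = en.make_partition(np.arange(40.0), np.arange(40.0),
                                     "bootstrap_replicate", seed=3, n_replicates=3)
            reports.append(en.evaluate(pres, bg, "L", 1.0, part))
        assert reports[0].as_dict() == reports[1].as_dict()
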