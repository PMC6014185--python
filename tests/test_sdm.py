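import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from podomap import sdm
from podomap.raster import RasterStack

from conftest import make_grid


def pairwise_auc_oracle(y, scores):
    """Brute-force Mann-Whitney AUC: all presence/absence pairs, ties 0.5."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class FixedScoreLearner:
    """Deterministic learner mapping the first feature to the score."""

    feature_importances_ = np.array([1.0])

    def predict_proba(self, X):
        s = np.clip(X[:, 0], 0.0, 1.0)
        return np.column_stack([1 - s, s])


class TestEvaluate:
    def test_perfect_ranking(self):
        X = np.array([[0.9], [0.8], [0.1], [0.2]])
        y = np.array([1, 1, 0, 0])
        auc, tss, pcc = sdm.evaluate(FixedScoreLearner(), X, y)
        assert (auc, tss, pcc) == (1.0, 1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        X = np.full((10, 1), 0.5)
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        auc, _, _ = sdm.evaluate(FixedScoreLearner(), X, y)
        assert auc == pytest.approx(0.5)

    def test_auc_matches_all_pairs_oracle(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(50), 2)  # rounding forces ties
            y = (rng.random(50) < 0.4).astype(int)
            if y.sum() in (0, 50):
                continue
            auc, _, _ = sdm.evaluate(FixedScoreLearner(), scores[:, None], y)
            assert abs(auc - pairwise_auc_oracle(y, scores)) < 1e-12

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(60)
        y = (rng.random(60) < 0.5).astype(int)
        auc1, _, _ = sdm.evaluate(FixedScoreLearner(), scores[:, None], y)
        transformed = 1 / (1 + np.exp(-(3 * scores - 1)))  # strictly monotone
        auc2, _, _ = sdm.evaluate(FixedScoreLearner(), transformed[:, None], y)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_tss_equals_youden_j(self, rng):
        scores = rng.random(80)
        y = (scores + rng.normal(0, 0.3, 80) > 0.5).astype(int)
        if y.sum() in (0, 80):
            pytest.skip("degenerate draw")
        _, tss, _ = sdm.evaluate(FixedScoreLearner(), scores[:, None], y)
        # independent Youden J: exhaustive over thresholds at observed scores
        best = -np.inf
        for t in np.unique(scores):
            pred = scores >= t
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            best = max(best, sens + spec - 1)
        assert tss == pytest.approx(best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sdm.evaluate(FixedScoreLearner(), np.zeros((5, 1)), np.ones(5, dtype=int))


def separable_toy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, n)
    y = (x > 0).astype(int)
    return x[:, None], y


class TestLearners:
    def test_brt_separable_perfect_auc(self):
        X, y = separable_toy()
        model = sdm.fit_brt(X[:150], y[:150], max_trees=300, seed=0)
        auc, _, _ = sdm.evaluate(model, X[150:], y[150:])
        assert auc == 1.0

    def test_rf_separable_perfect_auc(self):
        X, y = separable_toy()
        model = sdm.fit_rf(X[:150], y[:150], n_trees=100, seed=0)
        auc, _, _ = sdm.evaluate(model, X[150:], y[150:])
        assert auc == 1.0

    @pytest.mark.parametrize("fitter,kw", [
        (sdm.fit_brt, {"max_trees": 200}),
        (sdm.fit_rf, {"n_trees": 100}),
    ])
    def test_permuted_labels_null_auc(self, fitter, kw):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = separable_toy(n=200, seed=seed)
            y = rng.permutation(y)
            if len(np.unique(y[150:])) < 2:
                continue
            model = fitter(X[:150], y[:150], seed=seed, **kw)
            auc, _, _ = sdm.evaluate(model, X[150:], y[150:])
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_weight_scale_invariance(self):
        X, y = separable_toy(n=120, seed=3)
        w = np.random.default_rng(3).uniform(0.5, 2.0, len(y))
        a = sdm.fit_brt(X, y, w, max_trees=150, seed=1).predict_proba(X)
        b = sdm.fit_brt(X, y, 2 * w, max_trees=150, seed=1).predict_proba(X)
        assert np.allclose(a, b)
        a = sdm.fit_rf(X, y, w, n_trees=50, seed=1).predict_proba(X)
        b = sdm.fit_rf(X, y, 2 * w, n_trees=50, seed=1).predict_proba(X)
        assert np.allclose(a, b)

    def test_rf_deterministic_given_seed(self):
        X, y = separable_toy(n=100, seed=5)
        a = sdm.fit_rf(X, y, seed=9).predict_proba(X)
        b = sdm.fit_rf(X, y, seed=9).predict_proba(X)
        assert np.array_equal(a, b)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sdm.fit_brt(np.zeros((10, 1)), np.zeros(10, dtype=int))


class TestChooseThreshold:
    def test_perfectly_separated_returns_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr, stats = sdm.choose_threshold(scores, labels)
        assert thr == pytest.approx(0.5)
        assert stats["sensitivity"] == stats["specificity"] == stats["pcc"] == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            scores = rng.random(40)
            labels = (rng.random(40) < 0.5).astype(int)
            if labels.sum() in (0, 40):
                continue
            thr, stats = sdm.choose_threshold(scores, labels)
            # exhaustive oracle over a fine threshold sweep
            best = -np.inf
            for t in np.linspace(-0.01, 1.01, 2000):
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / labels.sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                pcc = (pred == (labels == 1)).mean()
                best = max(best, (sens + spec + pcc) / 3)
            assert stats["criterion"] == pytest.approx(best, abs=1e-12)

    def test_inverted_single_presence_case(self):
        scores = np.array([0.1, 0.5, 0.6, 0.9])
        labels = np.array([1, 0, 0, 0])  # the presence scores lowest
        thr, stats = sdm.choose_threshold(scores, labels)
        # best achievable: threshold below everything (sens 1, spec 0) or
        # above (sens 0, spec 1, pcc .75); the scan must find the maximum
        assert stats["criterion"] >= 7 / 12 - 1e-12

    def test_near_separable_regime_hits_high_sens_spec(self, rng):
        # scores almost separated, mirroring a sharply discriminable ecology
        pres = rng.uniform(0.55, 1.0, 500)
        absn = rng.uniform(0.0, 0.45, 500)
        pres[0] = 0.2  # one mislabelled record
        scores = np.r_[pres, absn]
        labels = np.r_[np.ones(500), np.zeros(500)].astype(int)
        _, stats = sdm.choose_threshold(scores, labels)
        assert stats["sensitivity"] >= 0.99
        assert stats["specificity"] >= 0.99


class TestPartialDependence:
    def test_flat_for_ignored_covariate(self):
        X = np.random.default_rng(0).random((50, 2))
        curve = sdm.partial_dependence(FixedScoreLearner(), X, 1, np.linspace(0, 1, 9))
        assert curve.max() - curve.min() < 1e-6

    def test_single_covariate_identity(self):
        X = np.random.default_rng(0).random((30, 1))
        vals = np.linspace(0.05, 0.95, 7)
        curve = sdm.partial_dependence(FixedScoreLearner(), X, 0, vals)
        assert np.allclose(curve, vals, atol=1e-12)

    def test_matches_definition_level_averaging(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 2))
        y = ((X[:, 0] + X[:, 1]) > 1).astype(int)
        model = LogisticRegression().fit(X, y)
        vals = np.linspace(0, 1, 11)
        curve = sdm.partial_dependence(model, X, 0, vals)
        oracle = np.array([
            np.mean([model.predict_proba(np.r_[v, row[1]][None])[0, 1] for row in X])
            for v in vals
        ])
        assert np.allclose(curve, oracle, atol=1e-12)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            sdm.partial_dependence(FixedScoreLearner(), np.zeros((5, 2)), 4, [0.1])


class TestVariableContribution:
    def test_sums_to_hundred(self):
        X, y = separable_toy(n=150, seed=1)
        X = np.column_stack([X, np.random.default_rng(1).random(150)])
        model = sdm.fit_rf(X, y, n_trees=100, seed=0)
        contrib = sdm.variable_contribution(model)
        assert contrib.sum() == pytest.approx(100.0, abs=1e-9)
        assert (contrib >= 0).all()

    def test_noise_covariate_contributes_little(self):
        X, y = separable_toy(n=300, seed=2)
        X = np.column_stack([X, np.random.default_rng(99).random(300)])
        model = sdm.fit_brt(X, y, max_trees=3000, seed=0)
        contrib = sdm.variable_contribution(model)
        assert contrib[1] < 5.0

    def test_single_covariate_is_everything(self):
        X, y = separable_toy(n=100, seed=3)
        model = sdm.fit_rf(X, y, n_trees=50, seed=0)
        assert sdm.variable_contribution(model)[0] == pytest.approx(100.0)


def _ensemble_inputs(small_world):
    feats = small_world["features"].copy()
    feats["record"] = np.where(feats["label"] == 1, "presence", "absence")
    return feats, small_world["stack"], small_world["stack"].names


class TestRunEnsemble:
    def test_two_member_mean_is_cellwise_average(self, small_world):
        feats, stack, covs = _ensemble_inputs(small_world)
        res = sdm.run_ensemble(
            feats, stack, covs, n_reps=2, seed=0, algorithms=("rf",),
            rf_trees=50, auc_min=0.0, tss_min=-1.0,
        )
        assert len(res.selected_runs) == 2
        preds = np.stack([r.prediction for r in res.selected_runs])
        assert np.allclose(res.mean_suitability.data.ravel(), preds.mean(axis=0))
        # bands bracket the mean and the members bracket both
        assert (res.ci_low.data <= res.mean_suitability.data + 1e-12).all()
        assert (res.mean_suitability.data <= res.ci_high.data + 1e-12).all()
        assert (res.mean_suitability.data.ravel() >= preds.min(axis=0) - 1e-12).all()
        assert (res.mean_suitability.data.ravel() <= preds.max(axis=0) + 1e-12).all()

    def test_limits_map_is_threshold_exceedance(self, small_world):
        feats, stack, covs = _ensemble_inputs(small_world)
        res = sdm.run_ensemble(
            feats, stack, covs, n_reps=2, seed=0, algorithms=("rf",),
            rf_trees=50, auc_min=0.0, tss_min=-1.0,
        )
        assert np.array_equal(
            res.limits.data > 0.5, res.mean_suitability.data >= res.threshold
        )

    def test_impossible_selection_raises(self, small_world):
        feats, stack, covs = _ensemble_inputs(small_world)
        with pytest.raises(RuntimeError, match="AUC >= 1.01"):
            sdm.run_ensemble(
                feats, stack, covs, n_reps=2, seed=0, algorithms=("rf",),
                rf_trees=50, auc_min=1.01, tss_min=0.7,
            )

    def test_deterministic_given_seed(self, small_world):
        feats, stack, covs = _ensemble_inputs(small_world)
        kw = dict(n_reps=2, seed=5, algorithms=("rf",), rf_trees=50,
                  auc_min=0.0, tss_min=-1.0)
        a = sdm.run_ensemble(feats, stack, covs, **kw)
        b = sdm.run_ensemble(feats, stack, covs, **kw)
        assert np.array_equal(a.mean_suitability.data, b.mean_suitability.data)
        assert a.threshold == b.threshold
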