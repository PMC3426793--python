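"""ANOVA voxel ranking and penalized logistic regression."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from conftest import make_fm
from crossmvpa.bold_data import ValidationError
from crossmvpa.mvpa_core import (
    ClassifierModel,
    anova_rank,
    plr_objective,
    predict,
    select_top_k,
    train_plr,
)
from crossmvpa.synthetic_data import make_ground_truth, make_participant, DesignSpec, NoiseSpec
from crossmvpa.evaluation import prepare_session
from crossmvpa.preprocessing import extract_trials_boxcar


class TestAnovaRank:
    def test_hand_example_f_13_5(self):
        fm = make_fm([[1], [2], [3], [4], [5], [6]], ["a", "a", "a", "b", "b", "b"])
        r = anova_rank(fm)
        assert r.scores[0] == pytest.approx(13.5)

    def test_equal_means_give_zero_f(self):
        fm = make_fm([[1], [3], [1], [3]], ["a", "a", "b", "b"])
        assert anova_rank(fm).scores[0] == 0.0

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 12))
        y = np.array(["a"] * 14 + ["b"] * 16)
        scores = anova_rank(make_fm(X, y)).scores
        t = stats.ttest_ind(X[y == "a"], X[y == "b"], axis=0).statistic
        assert np.allclose(scores, t**2)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 8))
        y = np.array(["a"] * 10 + ["b"] * 10)
        scores = anova_rank(make_fm(X, y)).scores
        ref = stats.f_oneway(X[y == "a"], X[y == "b"], axis=0).statistic
        assert np.allclose(scores, ref)

    def test_tie_break_ascending_index(self):
        fm = make_fm(np.tile([[1.0, 1.0, 1.0]], (4, 1)) * np.array([[1], [2], [3], [4]]),
                     ["a", "a", "b", "b"])
        order = anova_rank(fm).order
        assert order.tolist() == [0, 1, 2]  # all-equal scores keep index order

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="class"):
            anova_rank(make_fm([[1], [2]], ["a", "a"]))


class TestSelectTopK:
    def test_k_equals_n_returns_all(self):
        fm = make_fm(np.random.default_rng(2).normal(size=(10, 5)),
                     ["a"] * 5 + ["b"] * 5)
        sel = select_top_k(anova_rank(fm), 5)
        assert sorted(sel.tolist()) == [0, 1, 2, 3, 4]

    def test_k_one_is_argmax(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        X[:10, 4] += 5.0  # voxel 4 strongly informative
        fm = make_fm(X, ["a"] * 10 + ["b"] * 10)
        assert select_top_k(anova_rank(fm), 1).tolist() == [4]

    def test_k_out_of_range(self):
        fm = make_fm([[1], [2], [3], [4]], ["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            select_top_k(anova_rank(fm), 2)

    def test_recovers_planted_informative_voxels(self, tiny_mask):
        strong_truth = make_ground_truth((8, 8, 4), 16, 16, effect_size=2.0, seed=7)
        strong, _ = make_participant(DesignSpec(), strong_truth,
                                     noise=NoiseSpec(sigma=0.5), seed=21)
        prep = prepare_session(strong, tiny_mask)
        fm = extract_trials_boxcar(prep.series, prep.events)
        n_info = 32
        sel = select_top_k(anova_rank(fm), n_info)
        selected = {tuple(c) for c in fm.voxel_coords[sel]}
        true_set = strong_truth.informative_coord_set("audio")
        assert len(selected & true_set) >= 0.9 * n_info


def _toy_set(seed=0, n=8, separable=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    if separable:
        y = np.where(X[:, 0] > 0, "a", "b")
    else:
        y = np.array(["a", "b"] * (n // 2))
    return make_fm(X, y)


class TestTrainPLR:
    def test_huge_lambda_shrinks_weights_to_prior(self):
        fm = _toy_set(seed=1)
        model = train_plr(fm, lam=1e9)
        assert np.linalg.norm(model.w) < 1e-4
        p, _ = predict(model, fm)
        prior = np.mean(fm.labels == model.positive_class)
        assert np.allclose(p, prior, atol=1e-3)

    def test_mirror_symmetric_set_zero_intercept(self):
        X = np.array([[1.0, 2.0], [-1.0, -2.0], [3.0, -1.0], [-3.0, 1.0]])
        fm = make_fm(X, ["a", "b", "a", "b"])
        model = train_plr(fm, lam=1.0)
        assert abs(model.intercept) < 1e-6

    def test_objective_matches_brute_force_minimum(self):
        """The Newton solution's objective equals an independent generic
        optimizer's minimum of the same stated convex objective."""
        fm = _toy_set(seed=2)
        lam = 1.0
        model = train_plr(fm, lam=lam)
        ours = plr_objective(fm.features, (fm.labels == model.positive_class).astype(float),
                             model.w, model.intercept, lam)

        def f(params):
            return plr_objective(fm.features,
                                 (fm.labels == model.positive_class).astype(float),
                                 params[:2], params[2], lam)

        ref = optimize.minimize(f, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert ours == pytest.approx(ref.fun, abs=1e-5)
        assert ours <= ref.fun + 1e-5

    def test_lambda_zero_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        fm = _toy_set(seed=3, n=24)
        model = train_plr(fm, lam=0.0)
        ref = sklearn.LogisticRegression(C=np.inf, tol=1e-12, max_iter=20000)
        ref.fit(fm.features, (fm.labels == model.positive_class).astype(int))
        assert np.allclose(model.w, ref.coef_[0], atol=1e-4)
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_ridge_matches_reference_implementation(self):
        # our sum-logloss + lam*||w||^2 equals sklearn's C = 1/(2*lam)
        sklearn = pytest.importorskip("sklearn.linear_model")
        fm = _toy_set(seed=4, n=24)
        lam = 1.0
        model = train_plr(fm, lam=lam)
        ref = sklearn.LogisticRegression(C=1.0 / (2 * lam), tol=1e-12, max_iter=20000)
        ref.fit(fm.features, (fm.labels == model.positive_class).astype(int))
        assert np.allclose(model.w, ref.coef_[0], atol=1e-4)

    def test_objective_monotone_and_converged(self):
        model = train_plr(_toy_set(seed=5, n=16), lam=1.0)
        path = np.asarray(model.objective_path)
        assert (np.diff(path) <= 1e-12).all()
        assert model.converged
        assert model.final_grad_norm <= 1e-6

    def test_prediction_invariant_to_trial_order(self):
        fm = _toy_set(seed=6, n=16)
        perm = np.random.default_rng(0).permutation(16)
        m1 = train_plr(fm, lam=1.0)
        m2 = train_plr(fm.subset_trials(perm), lam=1.0)
        assert np.allclose(m1.w, m2.w, atol=1e-8)

    def test_training_invariant_to_voxel_permutation(self):
        fm = _toy_set(seed=7, n=16)
        swapped = make_fm(fm.features[:, ::-1], fm.labels)
        m1 = train_plr(fm, lam=1.0)
        m2 = train_plr(swapped, lam=1.0)
        assert np.allclose(m1.w, m2.w[::-1], atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="class"):
            train_plr(make_fm([[1], [2]], ["a", "a"]))

    def test_serialization_round_trip(self, tmp_path):
        model = train_plr(_toy_set(seed=8), lam=1.0)
        model.to_json(tmp_path / "model.json")
        back = ClassifierModel.from_json(tmp_path / "model.json")
        assert np.allclose(back.w, model.w)
        assert back.intercept == pytest.approx(model.intercept)
        assert back.positive_class == model.positive_class


class TestPredict:
    def test_zero_model_ties_to_positive_class(self):
        fm = _toy_set(seed=9)
        model = train_plr(fm, lam=1e12)
        model.w[:] = 0.0
        model.intercept = 0.0
        p, labels = predict(model, fm)
        assert np.allclose(p, 0.5)
        assert (labels == model.positive_class).all()

    def test_hand_logistic_point(self):
        fm = _toy_set(seed=10)
        model = train_plr(fm, lam=1.0)
        model.w = np.array([1.0, -1.0])
        model.intercept = 0.0
        p, _ = predict(model, np.array([[2.0, 1.0]]))
        assert p[0] == pytest.approx(expit(1.0)) == pytest.approx(0.7311, abs=1e-4)

    def test_separable_training_data_reclassified_perfectly(self):
        fm = _toy_set(seed=11, n=20, separable=True)
        model = train_plr(fm, lam=0.01)
        _, labels = predict(model, fm)
        assert (labels == fm.labels).all()

    def test_feature_width_mismatch_rejected(self):
        fm = _toy_set(seed=12)
        model = train_plr(fm, lam=1.0)
        with pytest.raises(ValidationError, match="features"):
            predict(model, np.zeros((3, 7)))
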