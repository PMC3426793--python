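"""Fold schemes, decoding, significance, grids, profiles and gamma fits."""

import math

import numpy as np
import pytest

from crossmvpa.bold_data import ValidationError
from crossmvpa.evaluation import (
    TemporalProfile,
    binomial_threshold,
    chance_band,
    decode_feature_matrices,
    fit_gamma_profile,
    grid_search,
    make_within_folds,
    prepare_session,
    profile_correlation,
    run_decoding,
    temporal_profile,
)
from crossmvpa.preprocessing import BoxcarSpec, extract_trials_boxcar
from crossmvpa.synthetic_data import (
    DesignSpec,
    HRFParams,
    NoiseSpec,
    gamma_hrf,
    make_design,
    make_ground_truth,
    make_participant,
)


class TestWithinFolds:
    def test_default_design_six_folds_of_40(self):
        events = make_design(DesignSpec())
        scheme = make_within_folds(events)
        assert len(scheme.folds) == 6
        for train, test in scheme.folds:
            assert len(test) == 40
            assert len(train) == 200

    def test_test_sets_partition_all_trials(self):
        events = make_design(DesignSpec())
        scheme = make_within_folds(events)
        tested = np.concatenate([t for _, t in scheme.folds])
        assert sorted(tested.tolist()) == list(range(240))

    def test_train_partitions_have_five_of_each_stimulus(self):
        events = make_design(DesignSpec())
        scheme = make_within_folds(events)
        for train, _ in scheme.folds:
            counts = events.iloc[train].groupby("stimulus_id").size()
            assert (counts == 5).all()

    def test_unbalanced_repetition_names_stimulus(self):
        events = make_design(DesignSpec(n_stimuli_per_category=2, n_runs=3))
        broken = events.drop(events[events.stimulus_id == "axe"].index[:1])
        with pytest.raises(ValidationError, match="axe"):
            make_within_folds(broken.reset_index(drop=True))


class TestBinomialThreshold:
    def test_study_threshold_55_8(self):
        thr = binomial_threshold(240, 0.5, 0.05)
        assert thr.percent == 55.8
        assert thr.k == 134

    def test_n10_threshold_is_9_of_10(self):
        thr = binomial_threshold(10, 0.5, 0.05)
        assert thr.k == 9
        assert thr.fraction == pytest.approx(0.9)

    def test_single_trial_loose_alpha(self):
        thr = binomial_threshold(1, 0.5, 0.6)
        assert thr.k == 1
        assert thr.fraction == 1.0

    def test_agrees_with_exact_integer_enumeration(self):
        # independent oracle: exact tail comparison in integer arithmetic,
        # P(X >= k) < alpha  <=>  20 * sum_{j>=k} C(n, j) < 2^n at alpha=1/20
        for n in range(1, 151):
            tail = 0
            k_exact = n + 1
            for k in range(n, -1, -1):
                tail += math.comb(n, k)
                if 20 * tail >= 2**n:
                    break
                k_exact = k
            assert binomial_threshold(n, 0.5, 0.05).k == k_exact


class TestRunDecoding:
    def test_noiseless_separable_session_perfect(self):
        truth = make_ground_truth((6, 6, 3), 12, 0, effect_size=3.0, seed=1)
        audio, _ = make_participant(
            DesignSpec(n_stimuli_per_category=4, n_runs=6), truth,
            noise=NoiseSpec(sigma=0.02), seed=2,
        )
        prep = prepare_session(audio, np.ones((6, 6, 3), bool))
        res = run_decoding(prep, scheme="within", k=12)
        assert res.accuracy == 1.0
        assert res.p_value < 1e-10

    def test_accuracy_result_bookkeeping(self, prepared_pair):
        prep, _ = prepared_pair
        res = run_decoding(prep, scheme="within", k=64)
        assert res.n_total == 240
        assert res.n_correct == int(res.per_trial_outcomes.sum())
        assert res.accuracy == pytest.approx(res.n_correct / 240)

    def test_cross_session_decoding_works(self, prepared_pair):
        prep_a, prep_o = prepared_pair
        res = run_decoding(prep_a, prep_o, scheme="cross", k=64)
        # half the coding is shared at the fixture's overlap, so the
        # cross-session accuracy must be clearly above chance
        assert res.accuracy > binomial_threshold(240).fraction

    def test_permuted_labels_fall_to_chance(self, prepared_pair):
        prep, _ = prepared_pair
        rng = np.random.default_rng(0)
        shuffled = prep.events.copy()
        shuffled["category"] = rng.permutation(shuffled["category"].to_numpy())
        permuted = prep._replace(events=shuffled)
        res = run_decoding(permuted, scheme="within", k=64)
        lo, hi = chance_band(res.n_total)
        assert lo <= res.accuracy <= hi

    def test_shuffled_test_labels_do_not_change_weights(self, prepared_pair):
        """Leakage guard: the trained model must be identical whatever the
        test-session labels are."""
        prep_a, prep_o = prepared_pair
        fm_a = extract_trials_boxcar(prep_a.series, prep_a.events)
        fm_b = extract_trials_boxcar(prep_o.series, prep_o.events)
        _, models1 = decode_feature_matrices(fm_a, test_fm=fm_b, k=64,
                                             return_models=True)
        fm_b_shuffled = fm_b.subset_trials(np.arange(fm_b.n_trials))
        fm_b_shuffled.labels = np.random.default_rng(1).permutation(fm_b.labels)
        _, models2 = decode_feature_matrices(fm_a, test_fm=fm_b_shuffled, k=64,
                                             return_models=True)
        assert np.array_equal(models1[0].w, models2[0].w)
        assert models1[0].intercept == models2[0].intercept


class TestGridSearch:
    def test_default_cell_consistent_with_standalone_run(self, prepared_pair):
        prep, _ = prepared_pair
        manifest = []
        grid = grid_search(prep, scheme="within", delays=[4], widths=[4], k=64,
                           condition_tag="audio-audio", manifest=manifest)
        standalone = run_decoding(prep, scheme="within", boxcar=BoxcarSpec(4, 4), k=64)
        assert grid.accuracy[0, 0] == standalone.accuracy
        assert len(manifest) == 1
        assert manifest[0]["condition"] == "audio-audio"

    def test_grid_shape_and_range(self, prepared_pair):
        prep, _ = prepared_pair
        grid = grid_search(prep, scheme="within", delays=[2, 4], widths=[1, 4], k=32)
        assert grid.accuracy.shape == (2, 2)
        assert ((grid.accuracy >= 0) & (grid.accuracy <= 1)).all()


class TestTemporalProfile:
    def test_profile_against_width_one_boxcar(self, prepared_pair):
        prep, _ = prepared_pair
        lats = [4.0, 7.0]
        prof = temporal_profile(prep, latencies=lats, k=64)
        for lat, acc in zip(lats, prof.accuracy):
            box = run_decoding(prep, scheme="within",
                               boxcar=BoxcarSpec(delay=lat, width=1), k=64)
            assert acc == box.accuracy

    def test_onset_latency_at_chance_and_peak_maximal(self, prepared_pair):
        prep, _ = prepared_pair
        prof = temporal_profile(prep, latencies=[0, 1, 5, 6, 7, 8, 15, 20], k=64)
        lo, hi = chance_band(240)
        assert lo <= prof.accuracy[0] <= hi  # kernel is zero at onset
        best = prof.latencies[np.argmax(prof.accuracy)]
        assert best in (5, 6, 7, 8)


class TestGammaFit:
    def test_self_consistency_on_exact_curve(self):
        t = np.arange(21.0)
        curve = 0.5 + 0.4 * gamma_hrf(HRFParams(peak=7, fwhm=6), t)
        fit = fit_gamma_profile(TemporalProfile(latencies=t, accuracy=curve))
        assert fit.ok
        assert fit.peak == pytest.approx(7.0, abs=0.1)
        assert fit.fwhm == pytest.approx(6.0, abs=0.1)
        assert fit.amplitude == pytest.approx(0.4, abs=0.02)
        assert fit.baseline == pytest.approx(0.5, abs=0.02)

    def test_recovers_other_parameter_points(self):
        t = np.arange(21.0)
        curve = 0.52 + 0.3 * gamma_hrf(HRFParams(peak=5, fwhm=4), t)
        fit = fit_gamma_profile(TemporalProfile(latencies=t, accuracy=curve))
        assert fit.ok
        assert fit.peak == pytest.approx(5.0, abs=0.1)
        assert fit.fwhm == pytest.approx(4.0, abs=0.1)

    def test_flat_profile_flagged_degenerate(self):
        t = np.arange(21.0)
        fit = fit_gamma_profile(TemporalProfile(latencies=t, accuracy=np.full(21, 0.5)))
        assert not fit.ok


class TestProfileCorrelation:
    def _prof(self, acc):
        return TemporalProfile(latencies=np.arange(len(acc), dtype=float),
                               accuracy=np.asarray(acc, dtype=float))

    def test_identical_profiles(self):
        a = self._prof([0.5, 0.7, 0.9, 0.6])
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_mirrored_profiles(self):
        a = self._prof([0.5, 0.7, 0.9])
        b = self._prof([1 - x for x in [0.5, 0.7, 0.9]])
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_pearson_value(self):
        # r = 13/14 for these two profiles, computed by hand
        a = self._prof([0.5, 0.6, 0.8])
        b = self._prof([0.5, 0.7, 0.8])
        assert profile_correlation(a, b) == pytest.approx(13 / 14, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            profile_correlation(self._prof([0.5, 0.5]), self._prof([0.4, 0.6]))

    def test_different_grids_rejected(self):
        a = self._prof([0.5, 0.6])
        b = TemporalProfile(latencies=np.array([0.0, 2.0]),
                            accuracy=np.array([0.5, 0.6]))
        with pytest.raises(ValidationError, match="grid"):
            profile_correlation(a, b)
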