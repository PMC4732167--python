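"""Gait-phase HMM: emissions, state labelling, training, likelihoods."""

import numpy as np
import pytest
from hmmlearn.hmm import GMMHMM

import gaitclass as gc
from gaitclass.hmm import CHANNEL_NAMES, STANCE, SWING

from conftest import brute_force_log_likelihood, random_hmm


class TestApproxDerivative:
    def test_linear_ramp(self):
        np.testing.assert_allclose(
            gc.approx_derivative(np.array([0.0, 1, 2, 3]), fs=1.0), [1, 1, 1, 1]
        )

    def test_constant_is_zero(self):
        assert np.all(gc.approx_derivative(np.full(10, 2.5), fs=128.0) == 0)

    def test_sinusoid_close_to_analytic_derivative(self):
        """First-difference error for a tone is dominated by the half-sample
        phase shift: |error| <= 2*pi*f * sin(pi*f/fs) ~ amplitude * pi*f/fs."""
        fs, f = 128.0, 1.0
        t = np.arange(int(4 * fs)) / fs
        d = gc.approx_derivative(np.sin(2 * np.pi * f * t), fs)
        analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        amplitude = 2 * np.pi * f
        bound = 1.1 * amplitude * np.pi * f / fs
        assert np.max(np.abs(d[:-1] - analytic[:-1])) < bound

    def test_too_short(self):
        with pytest.raises(ValueError):
            gc.approx_derivative(np.array([1.0]), fs=1.0)


class TestEmissionMatrix:
    def test_channel_count_and_order(self, tiny_cohort):
        em = gc.build_emission_matrix(tiny_cohort.trials[0])
        assert em.data.shape == (tiny_cohort.trials[0].n_samples, 7)
        assert CHANNEL_NAMES[0] == "gyro_ml" and CHANNEL_NAMES[6] == "waist_acc_ml"

    def test_channels_match_sources(self, tiny_cohort):
        trial = tiny_cohort.trials[0]
        em = gc.build_emission_matrix(trial)
        np.testing.assert_array_equal(em.data[:, 0], trial.shank_gyro[:, 2])
        np.testing.assert_array_equal(em.data[:, 2], trial.shank_acc[:, 1])
        np.testing.assert_array_equal(
            em.data[:, 1], gc.approx_derivative(trial.shank_gyro[:, 2], trial.fs)
        )

    @pytest.mark.parametrize("side, sign", [("right", 1.0), ("left", -1.0)])
    def test_waist_ml_sign_convention(self, side, sign):
        T = 300
        waist = np.zeros((T, 3))
        waist[:2, 2] = [1.0, -2.0]
        trial = gc.IMUTrial(
            subject_id="S",
            trial_id="P",
            side=side,
            fs=128.0,
            shank_acc=np.zeros((T, 3)),
            shank_gyro=np.zeros((T, 3)),
            waist_acc=waist,
            events=gc.GaitEvents([0], [150]),
        )
        em = gc.build_emission_matrix(trial)
        np.testing.assert_array_equal(em.data[:2, 6], sign * np.array([1.0, -2.0]))


class TestEventsToStates:
    def test_definition_example(self):
        states = gc.events_to_states(gc.GaitEvents([0], [10]), 16)
        assert np.all(states[:10] == STANCE) and np.all(states[10:] == SWING)

    def test_boundary_extension(self):
        states = gc.events_to_states(gc.GaitEvents([5, 20], [12, 27]), 32)
        assert np.all(states[:5] == SWING)  # swing precedes a foot strike
        assert np.all(states[5:12] == STANCE)
        assert np.all(states[12:20] == SWING)
        assert np.all(states[27:] == SWING)

    def test_no_unlabelled_samples(self, tiny_cohort):
        for trial in tiny_cohort.trials:
            states = gc.events_to_states(trial.events, trial.n_samples)
            assert np.all((states == STANCE) | (states == SWING))

    def test_stance_fraction_matches_truth_table(self):
        from test_simulate import _zero_variance_config

        ds = gc.generate_cohort(_zero_variance_config())
        for trial in ds.trials:
            states = gc.events_to_states(trial.events, trial.n_samples)
            n_strides = len(trial.events.foot_strikes)
            stance = int(np.sum(states == STANCE))
            expected = gc.event_truth_table(gc.Dataset([trial]))["stance_samples"].sum()
            assert abs(stance - expected) <= n_strides  # <= 1 sample per stride

    def test_requires_one_pair(self):
        with pytest.raises(Exception):
            gc.events_to_states(gc.GaitEvents([3], []), 10)


class TestForwardAlgorithm:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            model = random_hmm(rng)
            T = int(rng.integers(1, 7))
            X, _ = model.sample(T, random_state=rng)
            expected = brute_force_log_likelihood(
                model.startprob_, model.transmat_, model.weights_,
                model.means_, model.covars_, X,
            )
            assert model.log_likelihood(X) == pytest.approx(expected, rel=1e-9)

    def test_single_sample_closed_form(self):
        rng = np.random.default_rng(1)
        model = random_hmm(rng)
        model.startprob_ = np.array([1.0, 0.0])
        x = rng.normal(size=(1, 7))
        expected = model._log_emission_probs(x)[0, STANCE]
        assert model.log_likelihood(x) == pytest.approx(expected, rel=1e-12)

    def test_scaled_logdomain_and_backward_agree(self):
        rng = np.random.default_rng(2)
        model = random_hmm(rng)
        X, _ = model.sample(400, random_state=rng)
        ll = model.log_likelihood(X)
        assert ll == pytest.approx(model._log_likelihood_logdomain(X), rel=1e-9)
        assert ll == pytest.approx(model._log_likelihood_backward(X), rel=1e-9)

    def test_matches_hmmlearn(self):
        rng = np.random.default_rng(3)
        model = random_hmm(rng)
        X, _ = model.sample(60, random_state=rng)
        ref = GMMHMM(n_components=2, n_mix=3, covariance_type="diag", init_params="")
        ref.startprob_ = model.startprob_
        ref.transmat_ = model.transmat_
        ref.weights_ = model.weights_
        ref.means_ = model.means_
        ref.covars_ = model.covars_
        assert model.log_likelihood(X) == pytest.approx(ref.score(X), rel=1e-9)

    def test_mixture_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        model = random_hmm(rng)
        perm = [2, 0, 1]
        permuted = gc.GaitPhaseHMM.from_params(
            model.startprob_, model.transmat_,
            model.weights_[:, perm], model.means_[:, perm], model.covars_[:, perm],
        )
        X, _ = model.sample(50, random_state=rng)
        assert model.log_likelihood(X) == pytest.approx(
            permuted.log_likelihood(X), rel=1e-12
        )

    def test_window_restriction_and_errors(self):
        rng = np.random.default_rng(5)
        model = random_hmm(rng)
        X, _ = model.sample(50, random_state=rng)
        assert model.log_likelihood(X, window_samples=20) == pytest.approx(
            model.log_likelihood(X[:20]), rel=1e-12
        )
        with pytest.raises(ValueError, match="shorter"):
            model.log_likelihood(X, window_samples=100)
        X[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.log_likelihood(X)


class TestSupervisedTraining:
    def test_start_and_transition_counts(self):
        rng = np.random.default_rng(6)
        X = [rng.normal(size=(6, 2)) for _ in range(2)]
        states = [np.array([0, 0, 1, 1, 0, 0]), np.array([1, 0, 0, 1, 1, 1])]
        model = gc.GaitPhaseHMM(
            n_mixtures=1, max_frames_per_state=None
        ).fit(X, states)
        np.testing.assert_allclose(model.startprob_, [0.5, 0.5])
        # pooled transitions: from 0: 0->0 x3, 0->1 x2; from 1: 1->1 x3, 1->0 x2
        np.testing.assert_allclose(model.transmat_, [[3 / 5, 2 / 5], [2 / 5, 3 / 5]])

    def test_trial_order_invariance(self, tiny_cohort):
        mats = [gc.build_emission_matrix(t).data for t in tiny_cohort.trials[:4]]
        states = [
            gc.events_to_states(t.events, t.n_samples) for t in tiny_cohort.trials[:4]
        ]
        a = gc.GaitPhaseHMM().fit(mats, states)
        b = gc.GaitPhaseHMM().fit(mats[::-1], states[::-1])
        np.testing.assert_array_equal(a.startprob_, b.startprob_)
        np.testing.assert_array_equal(a.transmat_, b.transmat_)

    def test_single_state_only_raises(self):
        X = [np.random.default_rng(0).normal(size=(100, 7))]
        with pytest.raises(ValueError, match="insufficient frames"):
            gc.GaitPhaseHMM().fit(X, [np.zeros(100, dtype=int)])

    def test_parameter_recovery_from_known_model(self):
        truth = gc.GaitPhaseHMM.from_params(
            startprob=[1.0, 0.0],
            transmat=[[0.97, 0.03], [0.05, 0.95]],
            weights=[[1.0], [1.0]],
            means=[[[0.0, 1.0, -1.0, 0.5, 2.0, -0.5, 0.3]],
                   [[1.5, -1.0, 0.0, -0.5, 0.0, 1.0, -0.3]]],
            covars=np.full((2, 1, 7), 0.5),
        )
        rng = np.random.default_rng(10)
        seqs, states = zip(*(truth.sample(300, random_state=rng) for _ in range(30)))
        fitted = gc.GaitPhaseHMM(max_frames_per_state=None).fit(list(seqs), list(states))
        np.testing.assert_allclose(fitted.transmat_, truth.transmat_, atol=0.02)
        frames = np.vstack(seqs)
        labels = np.concatenate(states)
        for s in (STANCE, SWING):
            n = int(np.sum(labels == s))
            se = np.sqrt(0.5 / n)
            # EM preserves the grand mean: weighted mixture mean == sample mean
            mix_mean = np.einsum("m,md->d", fitted.weights_[s], fitted.means_[s])
            assert np.all(np.abs(mix_mean - truth.means_[s, 0]) < 3 * se)

    def test_stochasticity_invariants(self, class_models):
        for model in class_models.values():
            assert model.startprob_.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(model.transmat_.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(model.weights_.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(model.covars_ > 0)


class TestClassification:
    def test_tie_breaks_to_first_class(self):
        rng = np.random.default_rng(7)
        model = random_hmm(rng)
        X, _ = model.sample(30, random_state=rng)
        assert gc.classify_max_likelihood(
            {g: model for g in gc.GROUP_LABELS}, X, window_samples=None
        ) == "EL"

    def test_missing_model_raises(self):
        rng = np.random.default_rng(8)
        model = random_hmm(rng)
        with pytest.raises(ValueError, match="missing"):
            gc.classify_max_likelihood({"EL": model}, np.zeros((10, 7)))

    def test_generating_model_wins_on_separated_classes(self, tiny_cohort, class_models):
        """Strongly separated synthetic classes are recovered from held-in
        trials in nearly every case."""
        hits = total = 0
        for trial in tiny_cohort.trials:
            em = gc.build_emission_matrix(trial)
            pred = gc.classify_max_likelihood(class_models, em, window_samples=256)
            hits += pred == trial.group_label
            total += 1
        assert hits / total >= 0.95

    def test_serialization_round_trip(self, class_models, tmp_path):
        model = class_models["EL"]
        path = tmp_path / "el.json"
        model.save(path)
        clone = gc.GaitPhaseHMM.load(path)
        X, _ = model.sample(40, random_state=0)
        assert clone.log_likelihood(X) == pytest.approx(
            model.log_likelihood(X), rel=1e-12
        )
        assert clone.class_label_ == "EL"


class TestHMMLikelihoodClassifier:
    def test_fit_predict_on_cohort(self, tiny_cohort):
        clf = gc.HMMLikelihoodClassifier().fit(tiny_cohort.trials)
        preds = clf.predict(tiny_cohort.trials)
        truth = np.array([t.group_label for t in tiny_cohort.trials])
        assert np.mean(preds == truth) >= 0.9

    def test_missing_class_raises(self, tiny_cohort):
        subset = [t for t in tiny_cohort.trials if t.group_label != "HD"]
        with pytest.raises(ValueError, match="HD"):
            gc.HMMLikelihoodClassifier().fit(subset)
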