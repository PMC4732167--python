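"""Hybrid feature set: values, identities, layout, and scaling behaviour."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import gaitclass as gc
from gaitclass.features import FEATURE_NAMES, FEATURE_SUBSETS, N_FEATURES

from conftest import random_hmm

FS = 128.0


class TestTimeFeatures:
    def test_constant(self):
        np.testing.assert_allclose(
            gc.time_features([1.0, 1, 1, 1]), [1, 0, 0, 1, 1, 0]
        )

    def test_two_values(self):
        t = gc.time_features([0.0, 2.0])
        assert (t[0], t[3], t[4], t[5]) == (1.0, 2.0, 0.0, 2.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gc.time_features([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=1, max_dims=1, min_side=2, max_side=64),
            elements=st.floats(-1e6, 1e6),
        )
    )
    def test_identities(self, x):
        t = gc.time_features(x)
        assert t[2] == pytest.approx(t[1] ** 2, rel=1e-9, abs=1e-12)
        assert t[5] == pytest.approx(t[3] - t[4], rel=1e-9, abs=1e-12)


class TestFreqFeatures:
    def test_single_tone_peak(self):
        t = np.arange(1024) / FS
        f = gc.freq_features(np.sin(2 * np.pi * 1.0 * t), FS)
        assert f[2] == pytest.approx(1.0, abs=FS / 1024)  # F3 within one bin
        assert 0 <= f[5] <= 1

    def test_two_tone_ordering(self):
        t = np.arange(2048) / FS
        x = 2 * np.sin(2 * np.pi * 1.0 * t) + 1 * np.sin(2 * np.pi * 3.0 * t)
        p1, p2, f1, f2, total, ratio = gc.freq_features(x, FS)
        assert f1 == pytest.approx(1.0, abs=0.1)
        assert f2 == pytest.approx(3.0, abs=0.1)
        assert p1 > p2 > 0
        assert total >= p1 + p2 - 1e-9
        assert 0 <= ratio <= 1

    def test_second_peak_respects_separation(self):
        # one broad peak only: its shoulder bins must not become "F4"
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 1.0 * t) * np.exp(-t / 8)
        _, p2, f1, f2, _, _ = gc.freq_features(x, FS)
        if p2 > 0:
            assert abs(f2 - f1) >= 0.2

    def test_constant_channel_warns_and_zeros(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gaitclass.features"):
            f = gc.freq_features(np.full(64, 3.0), FS)
        np.testing.assert_array_equal(f, np.zeros(6))
        assert any("constant" in rec.message for rec in caplog.records)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            gc.freq_features(np.zeros(16), FS)

    def test_f6_bounded_for_noise(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            f = gc.freq_features(rng.normal(size=256), FS)
            assert 0 <= f[5] <= 1


class TestScalingBehaviour:
    """Multiplying a channel by c > 0 scales moments and powers predictably."""

    def test_time_and_freq_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=512)
        c = 3.7
        t1, t2 = gc.time_features(x), gc.time_features(c * x)
        np.testing.assert_allclose(t2[[1, 3, 4, 5]], c * t1[[1, 3, 4, 5]], rtol=1e-9)
        np.testing.assert_allclose(t2[2], c**2 * t1[2], rtol=1e-9)
        f1, f2 = gc.freq_features(x, FS), gc.freq_features(c * x, FS)
        np.testing.assert_allclose(f2[[0, 1, 4]], c**2 * f1[[0, 1, 4]], rtol=1e-9)
        np.testing.assert_allclose(f2[[2, 3, 5]], f1[[2, 3, 5]], rtol=1e-9)


class TestHMMFeatures:
    def test_identical_models_zero_differences(self):
        rng = np.random.default_rng(2)
        model = random_hmm(rng)
        X, _ = model.sample(300, random_state=rng)
        h = gc.hmm_features({g: model for g in gc.GROUP_LABELS}, X, FS)
        assert h[3] == h[4] == h[5] == 0.0
        assert h[0] == h[1] == h[2] != 0.0

    def test_difference_identity(self, tiny_cohort, class_models):
        # H4 - H5 + H6 = (EL-PS) - (EL-HD) + (PS-HD) = 0 algebraically
        em = gc.build_emission_matrix(tiny_cohort.trials[0])
        h = gc.hmm_features(class_models, em, FS)
        assert h[3] - h[4] + h[5] == pytest.approx(0.0, abs=1e-6)

    def test_window_too_short_raises(self, class_models):
        with pytest.raises(ValueError, match="2-s window"):
            gc.hmm_features(class_models, np.zeros((100, 7)), FS)


class TestAssembledVector:
    def test_layout_counts(self):
        assert N_FEATURES == 90
        assert len([n for n in FEATURE_NAMES if n.startswith("H")]) == 6
        assert len([n for n in FEATURE_NAMES if n.startswith(("T", "F"))]) == 84
        assert FEATURE_SUBSETS["hmm"] == slice(0, 6)
        assert len(set(FEATURE_NAMES)) == 90  # bijective name -> index

    def test_vector_on_synthetic_trial(self, tiny_cohort, class_models):
        fv = gc.assemble_features(tiny_cohort.trials[0], class_models)
        assert fv.values.shape == (90,)
        assert np.all(np.isfinite(fv.values))
        # per-channel identities hold inside the assembled vector
        for ch in range(1, 8):
            assert fv[f"T3_ch{ch}"] == pytest.approx(
                fv[f"T2_ch{ch}"] ** 2, rel=1e-9, abs=1e-12
            )
            assert fv[f"T6_ch{ch}"] == pytest.approx(
                fv[f"T4_ch{ch}"] - fv[f"T5_ch{ch}"], rel=1e-9, abs=1e-12
            )
            assert 0 <= fv[f"F6_ch{ch}"] <= 1

    def test_determinism(self, tiny_cohort, class_models):
        a = gc.assemble_features(tiny_cohort.trials[0], class_models)
        b = gc.assemble_features(tiny_cohort.trials[0], class_models)
        np.testing.assert_array_equal(a.values, b.values)

    def test_transformer_matches_assemble(self, tiny_cohort, class_models):
        tr = gc.HybridFeatureTransformer()
        tr.models_ = class_models
        F = tr.transform(tiny_cohort.trials[:3])
        for i, trial in enumerate(tiny_cohort.trials[:3]):
            np.testing.assert_array_equal(
                F[i], gc.assemble_features(trial, class_models).values
            )
        names = tr.get_feature_names_out()
        assert list(names) == list(FEATURE_NAMES)

    def test_feature_frame_metadata(self, tiny_cohort, class_models):
        tr = gc.HybridFeatureTransformer()
        tr.models_ = class_models
        frame = tr.feature_frame(tiny_cohort.trials[:4])
        assert list(frame.columns[:4]) == ["subject_id", "trial_id", "side", "group_label"]
        assert frame.shape == (4, 4 + 90)
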