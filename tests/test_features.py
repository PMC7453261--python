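"""Epoching, spatial averaging, statistical features, set combinatorics."""

import numpy as np
import pandas as pd
import pytest

from corrbci.features import (PAIR_IDS, build_feature_sets, epoch_trials,
                              extract_features, minmax_normalize,
                              signal_kurtosis, signal_mean, signal_peak,
                              signal_skewness, spatial_average)
from corrbci.io import EventTable


def moment_oracle(x, order):
    """Direct standardized-moment computation (independent of the library)."""
    x = np.asarray(x, float)
    mu = sum(x) / len(x)
    sig = (sum((v - mu) ** 2 for v in x) / len(x)) ** 0.5
    return sum(((v - mu) / sig) ** order for v in x) / len(x)


def make_events(n, trial_s=12.0, task_s=6.0, labels=None):
    labels = labels or ["right_hand"] * n
    frame = pd.DataFrame({"onset": [i * trial_s for i in range(n)],
                          "duration": trial_s, "trial_type": labels})
    return EventTable(frame=frame, task_duration_s=task_s)


class TestEpoching:
    def test_epoch_count_and_length(self):
        fs = 10.0
        x = np.zeros((2, 1200))
        events = make_events(10)
        epochs = epoch_trials(x, fs, events, segment="task")
        assert len(epochs) == 10
        assert all(e.data.shape == (2, 60) for e in epochs)

    def test_rest_segment_labelled_rest(self):
        events = make_events(3, labels=["left_arm", "rest", "right_hand"])
        epochs = epoch_trials(np.zeros((1, 360)), 10.0, events, segment="rest")
        assert [e.label for e in epochs] == ["rest"] * 3
        assert all(e.data.shape[1] == 60 for e in epochs)

    def test_window_beyond_signal_rejected(self):
        events = make_events(10)
        with pytest.raises(ValueError, match="outside"):
            epoch_trials(np.zeros((1, 500)), 10.0, events)

    def test_labels_match_ground_truth(self, small_session):
        eeg, _, events, truth = small_session
        epochs = epoch_trials(eeg.data, eeg.fs, events, segment="task")
        assert [e.label for e in epochs] == truth.labels


class TestSpatialAverage:
    def test_samplewise_mean(self):
        x = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        np.testing.assert_array_equal(spatial_average(x, [0, 1]), [2, 2, 2])

    def test_single_channel_identity(self, rng):
        x = rng.normal(size=(4, 20))
        np.testing.assert_array_equal(spatial_average(x, [2]), x[2])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            spatial_average(np.ones((2, 5)), [])


class TestStatisticalFeatures:
    def test_mean(self):
        assert signal_mean([1, 2, 3]) == 2.0
        assert signal_mean(np.full(10, 3.3)) == pytest.approx(3.3)

    def test_mean_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=1000)
        assert signal_mean(x) == pytest.approx(sum(x) / len(x), abs=1e-12)

    def test_skewness_symmetric_zero(self):
        assert signal_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_skewness_odd_under_negation(self, rng):
        x = rng.gamma(2.0, size=500)
        assert signal_skewness(-x) == pytest.approx(-signal_skewness(x))

    def test_skewness_squared_normal_oracle(self, rng):
        x = rng.normal(size=100_000) ** 2   # chi-square(1), strongly skewed
        sk = signal_skewness(x)
        assert sk > 0
        assert sk == pytest.approx(moment_oracle(x, 3), rel=0.02)

    def test_kurtosis_two_point(self):
        assert signal_kurtosis([-1.0, 1.0, -1.0, 1.0]) == pytest.approx(1.0)

    def test_kurtosis_normal_is_three(self, rng):
        x = rng.normal(size=100_000)
        assert signal_kurtosis(x) == pytest.approx(3.0, rel=0.05)

    def test_kurtosis_scale_invariant(self, rng):
        x = rng.normal(size=300)
        assert signal_kurtosis(5.0 * x) == pytest.approx(signal_kurtosis(x))
        assert signal_kurtosis(-2.0 * x) == pytest.approx(signal_kurtosis(x))

    def test_peak_is_signed_maximum(self):
        assert signal_peak([-5.0, 2.0, 3.0]) == 3.0
        assert signal_peak([-3.0, -1.0, -2.0]) == -1.0
        assert signal_peak(np.full(5, 2.2)) == pytest.approx(2.2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            signal_mean([])
        with pytest.raises(ValueError):
            signal_skewness(np.ones(10))
        with pytest.raises(ValueError):
            signal_kurtosis(np.ones(10))


class TestMinmax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                                   [0.0, 0.5, 1.0])

    def test_endpoints_attained(self, rng):
        out = minmax_normalize(rng.normal(size=50))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_idempotent(self, rng):
        x = rng.normal(size=30)
        once = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="mycol"):
            minmax_normalize(np.ones(5), name="mycol")


@pytest.fixture(scope="module")
def tables(preprocessed_session):
    from corrbci.selection import select_channels
    eeg_p, fnirs_p, events, _ = preprocessed_session
    se = select_channels(eeg_p, 3, 3, events)
    sf = select_channels(fnirs_p, 5, 5, events)
    return (extract_features(eeg_p, events, se, "eeg"),
            extract_features(fnirs_p, events, sf, "fnirs"))


class TestFeatureSets:
    def test_pair_enumeration(self, tables):
        eeg, fnirs = tables
        assert set(PAIR_IDS) == {"MP", "MSK", "MKR", "PSK", "PKR", "SKKR"}
        assert len(build_feature_sets(eeg=eeg, mode="eeg")) == 6
        assert len(build_feature_sets(fnirs=fnirs, mode="fnirs")) == 6
        hybrid = build_feature_sets(eeg=eeg, fnirs=fnirs, mode="hybrid")
        assert len(hybrid) == 36
        assert len({sid for sid, _ in hybrid}) == 36   # no duplicates

    def test_hybrid_column_arithmetic(self, tables):
        eeg, fnirs = tables
        hybrid = build_feature_sets(eeg=eeg, fnirs=fnirs, mode="hybrid")
        for _, df in hybrid:
            feat_cols = [c for c in df.columns if c != "label"]
            # 2 features x 2 hemispheres x 2 modalities
            assert len(feat_cols) == 8

    def test_normalized_range_and_label_preserved(self, tables):
        eeg, fnirs = tables
        for sid, df in build_feature_sets(eeg=eeg, fnirs=fnirs, mode="hybrid"):
            vals = df.drop(columns="label").to_numpy()
            assert vals.min() >= 0.0 and vals.max() <= 1.0
            assert df["label"].tolist() == eeg["label"].tolist()

    def test_trial_mismatch_rejected(self, tables):
        eeg, fnirs = tables
        with pytest.raises(ValueError, match="trials|labels"):
            build_feature_sets(eeg=eeg, fnirs=fnirs.iloc[:-1], mode="hybrid")
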