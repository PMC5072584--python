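"""Filtering, epoching and TD/FD feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristspeed.features import (
    EpochFeatures,
    assemble_dataset,
    design_matrix,
    epoch_split,
    fd_features,
    feature_columns,
    lowpass_filter,
    mean_crossings,
    td_features,
)


def dft_amplitude_oracle(x, nfft=512, n_coeffs=40, include_dc=False):
    """O(N^2) direct-summation single-sided amplitude spectrum."""
    n = len(x)
    padded = np.zeros(nfft)
    padded[:n] = x
    first = 0 if include_dc else 1
    out = np.empty(n_coeffs)
    for i, k in enumerate(range(first, first + n_coeffs)):
        re = sum(padded[m] * np.cos(2 * np.pi * k * m / nfft)
                 for m in range(nfft))
        im = -sum(padded[m] * np.sin(2 * np.pi * k * m / nfft)
                  for m in range(nfft))
        out[i] = 2.0 * np.sqrt(re**2 + im**2) / n
    return out


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        y = lowpass_filter(x, 100.0)
        assert np.abs(y - 3.7).max() < 1e-9

    def test_passband_sinusoid_preserved(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass_filter(x, 100.0)
        # interior samples: edge effects excluded
        assert np.abs(y[200:-200] - x[200:-200]).max() < 0.01

    def test_stopband_attenuation_matches_butterworth(self):
        """A 40 Hz tone is attenuated at least as much as the analytic
        4th-order Butterworth magnitude response squared (zero-phase =
        forward + backward pass)."""
        t = np.arange(4000) / 100.0
        x = np.sin(2 * np.pi * 40.0 * t)
        y = lowpass_filter(x, 100.0)
        # |H(40Hz)|^2 for analog-prototype order 4, fc=20: 1/(1+(40/20)^8)
        analog_bound = 1.0 / (1.0 + (40.0 / 20.0) ** 8)
        measured = np.abs(y[500:-500]).max()
        assert measured <= analog_bound

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="short"):
            lowpass_filter(np.zeros(10), 100.0)


class TestEpochSplit:
    def test_thirty_seconds_gives_six_epochs(self):
        epochs = epoch_split(np.arange(3000), 100.0)
        assert len(epochs) == 6
        assert all(len(e) == 500 for e in epochs)

    def test_below_one_window_gives_none(self):
        assert epoch_split(np.arange(490), 100.0) == []

    def test_trailing_samples_dropped(self):
        epochs = epoch_split(np.arange(1234), 100.0)
        assert len(epochs) == 2
        np.testing.assert_array_equal(epochs[1], np.arange(500, 1000))


class TestTdFeatures:
    def test_constant_epoch(self):
        c, n = -2.5, 100
        td = td_features(np.full(n, c))
        np.testing.assert_allclose(
            td, [c, 0.0, c, c, abs(c), 0, n * abs(c), n * c * c]
        )

    def test_single_period_sine_crossings(self):
        t = np.arange(100) / 100.0
        td = td_features(np.sin(2 * np.pi * t + np.pi / 4))
        assert abs(td[0]) < 1e-12
        assert td[5] == 2  # one down- and one up-crossing per period

    def test_alternating_epoch(self):
        td = td_features(np.array([1.0, -1.0, 1.0, -1.0]))
        np.testing.assert_allclose(td[0], 0.0)
        np.testing.assert_allclose(td[1], np.std([1, -1, 1, -1], ddof=1))
        assert td[5] == 3
        assert td[6] == 4.0  # signal magnitude area
        assert td[7] == 4.0  # energy

    def test_zeros_counted_positive_in_crossings(self):
        # mean 0; signs (+,+,-,+): two changes
        assert mean_crossings(np.array([0.0, 1.0, -2.0, 1.0])) == 2

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_matches_direct_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        td = td_features(x)
        assert np.isclose(td[0], sum(x) / 50)
        assert np.isclose(td[4], sum(abs(v) for v in x) / 50)
        assert np.isclose(td[6], sum(abs(v) for v in x))
        assert np.isclose(td[7], sum(v * v for v in x))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            td_features(np.array([1.0]))
        with pytest.raises(ValueError):
            td_features(np.array([1.0, np.nan]))


class TestFdFeatures:
    def test_zero_epoch(self):
        np.testing.assert_array_equal(fd_features(np.zeros(500)),
                                      np.zeros(40))

    def test_bin_frequency_mapping(self):
        """A sinusoid exactly on bin 10 peaks there; the whole 40-vector
        matches the direct-summation DFT oracle."""
        fs, nfft = 100.0, 512
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * (10 * fs / nfft) * t)
        fd = fd_features(x)
        assert np.argmax(fd) == 10 - 1  # bins start at 1
        np.testing.assert_allclose(fd, dft_amplitude_oracle(x), atol=1e-9)

    def test_amplitude_ratio_two_tones(self):
        fs, nfft = 100.0, 512
        t = np.arange(500) / fs
        x = (1.0 * np.sin(2 * np.pi * (8 * fs / nfft) * t)
             + 2.0 * np.sin(2 * np.pi * (24 * fs / nfft) * t))
        fd = fd_features(x)
        oracle = dft_amplitude_oracle(x)
        np.testing.assert_allclose(fd, oracle, atol=1e-9)
        assert np.isclose(fd[23] / fd[7], oracle[23] / oracle[7])

    @settings(deadline=None, derandomize=True, max_examples=5)
    @given(st.integers(0, 10_000))
    def test_matches_dft_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(100, 512))
        np.testing.assert_allclose(
            fd_features(x), dft_amplitude_oracle(x), atol=1e-9
        )

    def test_include_dc_flag(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.3, size=500)
        with_dc = fd_features(x, include_dc=True)
        without = fd_features(x)
        # DC bin equals 2|sum(x)|/N; remaining bins shift down by one
        assert np.isclose(with_dc[0], 2.0 * abs(x.sum()) / len(x))
        np.testing.assert_allclose(with_dc[1:], without[:-1], atol=1e-12)

    def test_epoch_longer_than_nfft_raises(self):
        with pytest.raises(ValueError, match="nfft"):
            fd_features(np.zeros(600))


class TestAssembleDataset:
    def make_epoch(self, subj="S0", trial="T0", idx=0, label=100.0):
        rng = np.random.default_rng(idx)
        x = rng.normal(size=500)
        return EpochFeatures(
            trial_id=trial,
            subject_id=subj,
            epoch_index=idx,
            td=td_features(x),
            fd=fd_features(x),
            label=label,
            height=1.7,
            weight=65.0,
        )

    def test_column_counts(self):
        ds = assemble_dataset([self.make_epoch(idx=i) for i in range(3)])
        x_td, _, _ = design_matrix(ds, include_fd=False,
                                   include_anthro=False)
        assert x_td.shape == (3, 8)
        x_full, y, subj = design_matrix(ds, include_fd=True,
                                        include_anthro=True)
        assert x_full.shape == (3, 50)
        assert len(feature_columns(True, True)) == 50
        assert y.shape == (3,) and subj.shape == (3,)

    def test_empty_input(self):
        ds = assemble_dataset([])
        assert len(ds) == 0
        x, y, subj = design_matrix(ds)
        assert x.shape[0] == 0

    def test_deterministic_extraction(self, quiet_walk):
        from wristspeed.pipeline import extract_trial_features

        rec, truth = quiet_walk
        a = assemble_dataset(
            extract_trial_features(rec, truth.epoch_speeds, "pca_acc")
        )
        b = assemble_dataset(
            extract_trial_features(rec, truth.epoch_speeds, "pca_acc")
        )
        assert a.equals(b)


def test_epoch_overlap_fraction():
    epochs = epoch_split(np.arange(1500), 100.0, overlap=0.5)
    assert len(epochs) == 5
    np.testing.assert_array_equal(epochs[1][:250], epochs[0][250:])
    with pytest.raises(ValueError):
        epoch_split(np.arange(1500), 100.0, overlap=1.0)


def test_per_trial_pca_scope():
    from wristspeed.pipeline import variable_series
    from wristspeed.synthetic import (
        NoiseSpec, SubjectProfile, TrialPlan, simulate_trial,
    )

    plan = TrialPlan(segments=[(10.0, 120.0)], noise=NoiseSpec.zero())
    rec, _ = simulate_trial(SubjectProfile(), plan)
    per_epoch, n1 = variable_series(rec, "pca_acc", pca_scope="epoch")
    per_trial, n2 = variable_series(rec, "pca_acc", pca_scope="trial")
    assert n1 == n2 == 2
    assert all(len(e) == 500 for e in per_trial)
    with pytest.raises(ValueError, match="pca_scope"):
        variable_series(rec, "pca_acc", pca_scope="window")
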