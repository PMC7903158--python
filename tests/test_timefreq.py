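"""Moving-window decomposition, power/ITPC estimators, pair combination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import alpharhythm as ar
from alpharhythm.errors import ConfigurationError, DataError
from alpharhythm.timefreq import DEFAULT_FREQS

FS = 100.0


def _tfd_from_coeffs(coeffs):
    coeffs = np.asarray(coeffs, dtype=complex)
    return ar.TFDecomposition(
        coeffs=coeffs,
        freqs=np.arange(1.0, coeffs.shape[2] + 1),
        times=np.arange(coeffs.shape[3], dtype=float),
        channel_names=[f"ch{i}" for i in range(coeffs.shape[1])],
    )


class TestStft:
    def test_stationary_sinusoid_constant_magnitude(self):
        t = np.arange(0, 6, 1 / FS)
        x = np.cos(2 * np.pi * 10 * t)
        tfd = ar.stft_decompose(x[None, None, :], FS, t)
        i10 = list(tfd.freqs).index(10.0)
        mags = np.abs(tfd.coeffs[0, 0, i10])
        np.testing.assert_allclose(mags, 0.5, atol=1e-6)  # cosine splits +/- bins

    def test_power_scales_quadratically_with_amplitude(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.cos(2 * np.pi * 5 * t)
        a = ar.stft_decompose(x[None, None, :], FS, t)
        b = ar.stft_decompose(2 * x[None, None, :], FS, t)
        np.testing.assert_allclose(
            np.abs(b.coeffs) ** 2, 4 * np.abs(a.coeffs) ** 2, atol=1e-12
        )

    def test_chirp_tracked_within_one_bin_against_direct_dft(self):
        """Window-wise peak equals a brute-force DFT of each extracted segment."""
        from scipy.signal import chirp
        from scipy.signal.windows import hann

        t = np.arange(0, 8, 1 / FS)
        x = chirp(t, f0=4, f1=16, t1=8, method="linear")
        tfd = ar.stft_decompose(x[None, None, :], FS, t)
        n_win, hop, n_pad = 50, 5, 100
        w = hann(n_win, sym=False)
        bins = np.asarray(tfd.freqs, dtype=int)
        for k, center in enumerate(tfd.times[::10]):
            start = int(round((center - t[0]) * FS)) - n_win // 2
            seg = x[start : start + n_win]
            ref = np.fft.rfft(seg * w, n=n_pad) / w.sum()
            np.testing.assert_allclose(
                tfd.coeffs[0, 0, :, 10 * k], ref[bins], atol=1e-12
            )
            f_inst = 4 + (16 - 4) * center / 8
            peak = tfd.freqs[np.argmax(np.abs(tfd.coeffs[0, 0, :, 10 * k]))]
            assert abs(peak - f_inst) <= 1.0

    def test_off_grid_frequency_rejected_not_rounded(self):
        t = np.arange(0, 2, 1 / FS)
        with pytest.raises(ConfigurationError):
            ar.stft_decompose(np.zeros((1, 1, t.size)), FS, t, freqs=(2.5,))

    def test_windows_stay_inside_epoch(self):
        t = np.arange(0, 2, 1 / FS)
        tfd = ar.stft_decompose(np.zeros((1, 1, t.size)), FS, t)
        assert tfd.times[0] >= t[0] + 0.25 - 1e-9
        assert tfd.times[-1] <= t[-1] + 1 / FS - 0.25 + 1e-9


class TestPower:
    def test_single_trial_power_is_squared_magnitude(self):
        coeffs = np.array([[[[1 + 1j, 2j]]]])
        pm = ar.compute_power(_tfd_from_coeffs(coeffs))
        np.testing.assert_allclose(pm.power, [[[2.0, 4.0]]])

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(0)
        coeffs = rng.standard_normal((7, 2, 3, 4)) + 1j * rng.standard_normal((7, 2, 3, 4))
        pm = ar.compute_power(_tfd_from_coeffs(coeffs))
        brute = sum(np.abs(coeffs[i]) ** 2 for i in range(7)) / 7
        np.testing.assert_allclose(pm.power, brute)

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(1)
        coeffs = rng.standard_normal((5, 1, 2, 2)) + 1j * rng.standard_normal((5, 1, 2, 2))
        a = ar.compute_power(_tfd_from_coeffs(coeffs)).power
        b = ar.compute_power(_tfd_from_coeffs(coeffs[::-1])).power
        np.testing.assert_allclose(a, b)


class TestItpc:
    def test_identical_phases_give_unity(self):
        coeffs = 3.0 * np.exp(1j * 0.7) * np.ones((6, 1, 1, 1))
        itc = ar.compute_itpc(_tfd_from_coeffs(coeffs))
        np.testing.assert_allclose(itc.itpc, 1.0)

    def test_opposite_phases_cancel(self):
        coeffs = np.array([np.exp(1j * 0.3), np.exp(1j * (0.3 + np.pi))]).reshape(2, 1, 1, 1)
        itc = ar.compute_itpc(_tfd_from_coeffs(coeffs))
        np.testing.assert_allclose(itc.itpc, 0.0, atol=1e-12)

    def test_uniform_phase_expectation_matches_monte_carlo(self):
        """E[ITPC] for n uniform phases ~ sqrt(pi)/2/sqrt(n) ~ 0.886/sqrt(n)."""
        rng = np.random.default_rng(42)
        n = 100
        reps = 3000
        phases = rng.uniform(0, 2 * np.pi, size=(reps, n))
        mc = np.abs(np.exp(1j * phases).mean(axis=1)).mean()
        coeffs = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n, 1, 2, 500)))
        itc = ar.compute_itpc(_tfd_from_coeffs(coeffs))
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert mc == pytest.approx(expected, rel=0.02)
        assert itc.itpc.mean() == pytest.approx(expected, rel=0.03)

    def test_requires_two_trials(self):
        with pytest.raises(DataError):
            ar.compute_itpc(_tfd_from_coeffs(np.ones((1, 1, 1, 1))))

    def test_zero_coefficients_warn_and_count_in_n(self):
        coeffs = np.ones((4, 1, 1, 1), dtype=complex)
        coeffs[0] = 0.0
        with pytest.warns(UserWarning, match="zero-magnitude"):
            itc = ar.compute_itpc(_tfd_from_coeffs(coeffs))
        np.testing.assert_allclose(itc.itpc, 0.75)

    @given(
        rot=st.floats(-np.pi, np.pi),
        seed=st.integers(0, 2**16),
    )
    def test_bounds_and_common_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.standard_normal((5, 2, 2, 3)) + 1j * rng.standard_normal((5, 2, 2, 3))
        base = ar.compute_itpc(_tfd_from_coeffs(coeffs)).itpc
        rotated = ar.compute_itpc(_tfd_from_coeffs(coeffs * np.exp(1j * rot))).itpc
        assert np.all(base >= 0) and np.all(base <= 1 + 1e-12)
        np.testing.assert_allclose(base, rotated, atol=1e-12)


class TestCombinePairs:
    def test_power_summed_and_itpc_averaged(self):
        lay = ar.make_sensor_layout(1, 0, 0)
        pm = ar.PowerMap(
            power=np.array([[[1.0]], [[3.0]]]),
            freqs=np.array([10.0]), times=np.array([0.0]),
            channel_names=list(lay.channel_names), n_trials=5,
        )
        combined = ar.combine_pairs(pm, lay)
        np.testing.assert_allclose(combined.power, [[[4.0]]])
        im = ar.ITCMap(
            itpc=np.array([[[0.2]], [[0.4]]]),
            freqs=np.array([10.0]), times=np.array([0.0]),
            channel_names=list(lay.channel_names), n_trials=5,
        )
        np.testing.assert_allclose(ar.combine_pairs(im, lay).itpc, [[[0.3]]])

    def test_default_layout_yields_102_positions(self):
        lay = ar.make_sensor_layout()
        rng = np.random.default_rng(0)
        pm = ar.PowerMap(
            power=rng.random((204, 2, 3)),
            freqs=np.array([9.0, 10.0]), times=np.arange(3.0),
            channel_names=list(lay.channel_names), n_trials=2,
        )
        out = ar.combine_pairs(pm, lay)
        assert out.power.shape[0] == 102
        assert out.channel_names == list(lay.positions)

    def test_missing_channel_raises(self):
        lay = ar.make_sensor_layout(1, 1, 0)
        pm = ar.PowerMap(
            power=np.zeros((3, 1, 1)),
            freqs=np.array([10.0]), times=np.array([0.0]),
            channel_names=list(lay.channel_names)[:3], n_trials=1,
        )
        with pytest.raises(DataError):
            ar.combine_pairs(pm, lay)


def test_onset_locked_itpc_peaks_near_number_onsets(clean_recording):
    """1-5 Hz ITPC (sensor average) has local maxima within 0.25 s of onsets."""
    from alpharhythm import design

    rec = clean_recording
    tfd = ar.stft_decompose(
        rec.epochs, rec.sampling_rate, rec.time_axis, freqs=DEFAULT_FREQS,
        channel_names=rec.layout.channel_names,
    )
    import warnings

    with warnings.catch_warnings():
        # the noise-free fixture yields a few exactly-zero coefficients
        warnings.simplefilter("ignore", UserWarning)
        itc = ar.combine_pairs(ar.compute_itpc(tfd), rec.layout)
    fsel = (itc.freqs >= 1) & (itc.freqs <= 5)
    course = itc.itpc[:, fsel, :].mean(axis=(0, 1))
    for pos in range(1, 6):
        onset = design.number_onset(pos)
        near = np.abs(itc.times - onset) <= 0.25
        far = (np.abs(itc.times - onset) > 0.4) & (np.abs(itc.times - onset) < 0.6)
        assert course[near].max() > course[far].max()
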