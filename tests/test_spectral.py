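"""PSD estimator against an independent periodogram oracle, and the
band-power / relative-PSD / alpha-peak / TAR measures."""

import numpy as np
import pytest
from scipy.signal.windows import kaiser

import rseeg
from rseeg.spectral import (
    EpochPowerMatrix, SpectralConfig, band_power, global_psd, relative_psd,
    session_average_psd,
)

from conftest import sine_session


def periodogram_oracle(x_window, fs=256.0, beta=6.0):
    """Single-segment modified periodogram, coded directly from the
    definition: taper, FFT, psd(f) = 2|X(f)|^2 / (fs * sum(w^2))."""
    w = kaiser(len(x_window), beta)
    X = np.fft.rfft(x_window * w)
    return 2.0 * np.abs(X) ** 2 / (fs * np.sum(w**2))


def make_epm(linear, channels=("T3",)):
    """EpochPowerMatrix from hand-built linear powers (epochs x ch x bins)."""
    cfg = SpectralConfig()
    return EpochPowerMatrix(
        values=np.log10(np.asarray(linear, float)),
        channels=tuple(channels),
        config=cfg,
    )


class TestEpochPsd:
    def test_sinusoid_matches_periodogram_oracle_within_1pct(self):
        s = sine_session(10.0, amplitude=8.0)
        epm = rseeg.epoch_psd(s)
        # interior epoch 3 = mean of segments starting at 2.5, 3.0, 3.5 s
        fs = int(s.fs)
        segs = [s.samples[0, st:st + fs] for st in
                (int(2.5 * fs), 3 * fs, int(3.5 * fs))]
        oracle = np.mean([periodogram_oracle(seg)[1:41] for seg in segs], axis=0)
        got = epm.linear[3, 0]
        assert np.argmax(got) == np.argmax(oracle) == 9  # bin 10 -> index 9
        assert got[9] == pytest.approx(oracle[9], rel=0.01)

    def test_white_noise_spectrum_is_flat(self, rng):
        mont = rseeg.standard_1020(["Cz"])
        s = rseeg.RecordingSession(
            samples=rng.standard_normal((1, 400 * 256)), fs=256.0, montage=mont
        )
        lin = rseeg.epoch_psd(s).linear.mean(axis=(0, 1))
        sel = slice(4, 40)  # bins 5-40
        slope = np.polyfit(np.arange(5, 41), lin[sel], 1)[0]
        assert abs(slope * 36) < 0.10 * lin[sel].mean()

    def test_bins_are_integer_hz_1_to_40(self, hc_epm):
        assert list(hc_epm.bins) == list(range(1, 41))
        assert hc_epm.values.shape[2] == 40

    def test_epoch_count_matches_duration(self, hc_epm, hc_session):
        assert hc_epm.n_epochs == int(hc_session.duration_s)

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError, match="3 windows"):
            rseeg.epoch_psd(sine_session(10.0, duration_s=2.0))


class TestBandMeasures:
    def test_flat_spectrum_band_power_equals_bin_power(self):
        epm = make_epm(np.full((4, 1, 40), 2.5))
        for band in ("delta", "theta", "alpha"):
            assert 10 ** band_power(epm, band) == pytest.approx(2.5)

    def test_delta_band_is_arithmetic_mean_of_linear_powers(self):
        lin = np.ones((1, 1, 40))
        lin[0, 0, :3] = [1.0, 2.0, 3.0]  # bins 1, 2, 3
        epm = make_epm(lin)
        assert 10 ** band_power(epm, "delta")[0, 0] == pytest.approx(2.0)

    def test_band_definitions_match_clinical_ranges(self):
        cfg = SpectralConfig()
        assert cfg.bands["theta"] == (3, 4, 5, 6, 7)
        assert cfg.bands["delta"] == (1, 2, 3)
        assert cfg.bands["alpha"] == (8, 9, 10, 11, 12, 13)

    def test_unknown_band_errors(self, hc_epm):
        with pytest.raises(ValueError, match="unknown band"):
            band_power(hc_epm, "sigma")


class TestRelativePsd:
    def test_flat_spectrum_gives_1_over_40(self):
        rel = relative_psd(make_epm(np.full((2, 1, 40), 3.7)))
        assert rel == pytest.approx(0.025)

    def test_rows_sum_to_one(self, hc_epm):
        rel = relative_psd(hc_epm)
        assert np.abs(rel.sum(axis=-1) - 1.0).max() < 1e-9

    def test_scale_invariance(self, hc_session):
        doubled = hc_session.copy()
        doubled.samples *= 2.0
        r1 = relative_psd(rseeg.epoch_psd(hc_session))
        r2 = relative_psd(rseeg.epoch_psd(doubled))
        assert np.abs(r1 - r2).max() < 1e-12


class TestGlobalAndSessionAverage:
    def test_identical_channels_give_identical_global(self):
        lin = np.tile(np.linspace(1, 4, 40), (3, 2, 1))
        epm = make_epm(lin, channels=("O1", "O2"))
        assert global_psd(epm) == pytest.approx(epm.values[:, 0, :])

    def test_global_is_linear_mean_then_log(self):
        lin = np.ones((1, 2, 40))
        lin[0, 1] = 3.0
        epm = make_epm(lin, channels=("O1", "O2"))
        assert global_psd(epm)[0, 0] == pytest.approx(np.log10(2.0))

    def test_session_average_of_constant_epochs(self):
        lin = np.tile(np.linspace(1, 2, 40), (5, 1, 1))
        epm = make_epm(lin)
        assert session_average_psd(epm) == pytest.approx(epm.values[0])


class TestAlphaPeak:
    def _avg(self, values_6_to_13, base=-1.0):
        # channels x bins 1..40 with a controlled 6-13 Hz segment
        avg = np.full((1, 40), base)
        avg[0, 5:13] = values_6_to_13
        return avg

    def test_largest_of_two_local_peaks_wins(self):
        vals = [-0.5, -0.6, -0.4, -0.6, -0.3, -0.6, -0.7, -0.8]  # 9 and 11...
        # peaks at 8 (-0.4) and 10 (-0.3); 10 is larger
        apf = rseeg.alpha_peak_frequency(self._avg(vals))
        assert apf[0] == 10.0

    def test_monotone_spectrum_has_no_peak(self):
        vals = np.linspace(-0.2, -0.9, 8)
        apf = rseeg.alpha_peak_frequency(self._avg(vals, base=0.0))
        assert np.isnan(apf[0])

    @pytest.mark.parametrize("peak", [8, 9, 10, 11, 12])
    def test_generator_peak_recovered_exactly(self, peak, montage):
        from dataclasses import replace

        p = replace(
            rseeg.healthy_profile(), alpha_peak_hz=float(peak), subject_cv=0.0
        )
        s = rseeg.generate_subject(
            p, rseeg.standard_1020(["O1", "O2", "Oz"]), duration_s=30, seed=17
        )
        epm = rseeg.epoch_psd(s)
        apf = rseeg.alpha_peak_frequency(session_average_psd(epm), epm.config)
        assert (apf == peak).all()


class TestThetaAlphaRatio:
    def test_equal_band_powers_give_unit_tar(self):
        epm = make_epm(np.full((4, 1, 40), 1.3), channels=("T3",))
        tar, temporal = rseeg.theta_alpha_ratio(epm)
        assert tar[0] == pytest.approx(1.0)
        assert temporal == pytest.approx(1.0)

    def test_tar_linear_in_theta_power(self):
        lin = np.full((4, 1, 40), 2.0)
        epm1 = make_epm(lin)
        lin4 = lin.copy()
        lin4[:, :, 2:7] *= 4.0  # bins 3-7
        epm4 = make_epm(lin4)
        t1, _ = rseeg.theta_alpha_ratio(epm1)
        t4, _ = rseeg.theta_alpha_ratio(epm4)
        assert t4[0] == pytest.approx(4.0 * t1[0])

    def test_tar_scale_invariant(self, hc_epm):
        t1, _ = rseeg.theta_alpha_ratio(hc_epm)
        scaled = EpochPowerMatrix(
            values=hc_epm.values + np.log10(5.0),
            channels=hc_epm.channels,
            config=hc_epm.config,
        )
        t2, _ = rseeg.theta_alpha_ratio(scaled)
        assert t2 == pytest.approx(t1)

    def test_temporal_tar_averages_the_four_temporal_sites(self, hc_epm):
        tar, temporal = rseeg.theta_alpha_ratio(hc_epm)
        idx = [hc_epm.channels.index(c) for c in ("T3", "T4", "T5", "T6")]
        assert temporal == pytest.approx(tar[idx].mean())


def test_parseval_total_power_tracks_time_domain_variance(hc_session):
    """Summed linear PSD across 1-40 Hz follows the time-domain variance.

    For band-limited input the periodogram total over 1-40 Hz must follow
    the taper-weighted variance of the very samples each epoch averages
    (the segment aligned with the epoch and its two neighbours).
    """
    band_limited = rseeg.bandpass_filter(hc_session, 2.0, 39.0)
    epm = rseeg.epoch_psd(band_limited)
    total = epm.linear.sum(axis=2)[:, 0]  # epochs, channel 0
    fs = int(band_limited.fs)
    w2 = kaiser(fs, 6.0) ** 2
    x = band_limited.samples[0]

    def weighted_var(start):
        seg = x[start:start + fs]
        return float((w2 * seg * seg).sum() / w2.sum())

    refs = []
    n_seg = 2 * epm.n_epochs - 1
    for k in range(epm.n_epochs):
        ids = [j for j in (2 * k - 1, 2 * k, 2 * k + 1) if 0 <= j < n_seg]
        refs.append(np.mean([weighted_var(j * fs // 2) for j in ids]))
    assert np.corrcoef(total, refs)[0, 1] > 0.95
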