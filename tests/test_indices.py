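"""Index derivation: beat detection, CPP, PRx, xBRS and LF/HF oracles."""

from collections import Counter

import numpy as np
import pytest
from scipy import signal as sps

from brainheart import indices, synth
from brainheart.indices import BeatSeries, lomb_scargle_band_power, xbrs_segments
from brainheart.types import MinuteSeries, WaveformSignal


def _white_noise_beats(seed, n=3600, ibi_sd=25.0, sbp_sd=5.0):
    """Independent white SBP and IBI: the xBRS null."""
    rng = np.random.default_rng(seed)
    ibi = 1000 + rng.normal(0, ibi_sd, n)
    t = np.concatenate([[0.0], np.cumsum(ibi[:-1] / 1000)])
    sbp = 120 + rng.normal(0, sbp_sd, n)
    return BeatSeries(t, sbp, np.diff(t) * 1000.0, np.ones(n - 1, bool))


class TestPeakDetection:
    def test_beat_count_and_ibi_at_60_bpm(self):
        p = synth.SimPatientParams(hr_base=60, ibi_sd=0, lf_power=0, hf_power=0,
                                   baro_gain=0, sbp_osc_lf=0, sbp_osc_hf=0)
        abp, _ = synth.simulate_waveforms(p, 120 / 3600, fs=125, seed=0)
        beats = indices.detect_systolic_peaks(abp)
        assert abs(beats.peak_times.size - 120) <= 1
        assert abs(np.median(beats.ibi) - 1000) < 20

    def test_baroreflex_couples_ibi_to_sbp(self, short_waveforms):
        abp, _ = short_waveforms
        beats = indices.detect_systolic_peaks(abp)
        # positive gain: higher systolic pressure -> longer interval
        r = np.corrcoef(beats.sbp[:-1], beats.ibi)[0, 1]
        assert r > 0.5

    def test_flat_signal_errors(self):
        with pytest.raises(ValueError, match="peaks"):
            indices.detect_systolic_peaks(WaveformSignal(np.full(6000, 90.0), fs=60))


class TestCpp:
    def test_definition_and_missing_propagation(self):
        abp = MinuteSeries(np.array([80.0, 80.0, np.nan]))
        icp = MinuteSeries(np.array([10.0, np.nan, 10.0]))
        cpp = indices.compute_cpp(abp, icp)
        assert cpp.values[0] == 70.0
        assert cpp.missing[1] and cpp.missing[2]

    def test_matches_elementwise_subtraction(self):
        rng = np.random.default_rng(2)
        a = MinuteSeries(rng.normal(90, 5, 50))
        b = MinuteSeries(rng.normal(12, 2, 50))
        cpp = indices.compute_cpp(a, b)
        np.testing.assert_array_equal(cpp.values, a.values - b.values)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            indices.compute_cpp(MinuteSeries(np.ones(3)), MinuteSeries(np.ones(4)))


class TestPrx:
    def test_brute_force_equivalence_on_gap_free_input(self):
        p = synth.SimPatientParams(prx_target_sign=1, icp_slow_amp=3)
        abp, icp = synth.simulate_waveforms(p, 0.5, fs=100, seed=4)
        prx = indices.compute_prx(abp, icp)
        # independent recomputation: explicit 10-s means, explicit Pearson
        # over the 30 most recent pairs, minute = mean of 6 updates
        def bin_means(sig):
            n = int(sig.fs * 10)
            nb = sig.samples.size // n
            return sig.samples[: nb * n].reshape(nb, n).mean(axis=1)

        a, b = bin_means(abp), bin_means(icp)
        n = min(a.size, b.size)
        per = np.full(n, np.nan)
        for end in range(29, n):
            x, y = a[end - 29:end + 1], b[end - 29:end + 1]
            per[end] = np.corrcoef(x, y)[0, 1]
        for m in range(n // 6):
            seg = per[m * 6:(m + 1) * 6]
            if np.isfinite(seg).any():
                assert abs(prx.values[m] - np.nanmean(seg)) <= 1e-10

    @pytest.mark.parametrize("sign", [1, -1])
    def test_sign_recovery(self, sign):
        p = synth.SimPatientParams(prx_target_sign=sign, icp_slow_amp=3)
        abp, icp = synth.simulate_waveforms(p, 0.5, fs=100, seed=4 + sign)
        med = np.nanmedian(indices.compute_prx(abp, icp).masked())
        assert med > 0.5 if sign == 1 else med < -0.5

    def test_null_matches_pearson_sampling_distribution(self):
        # independent white 10-s means: per-update PRx should be centred on
        # 0 with the SD of a Pearson r at n=30 (1/sqrt(n-1))
        rng = np.random.default_rng(7)
        fs = 50
        n_updates = 1000
        ns = (n_updates + 30) * 10 * fs
        abp = WaveformSignal(90 + np.repeat(rng.normal(0, 3, ns // (10 * fs)), 10 * fs), fs=fs)
        icp = WaveformSignal(12 + np.repeat(rng.normal(0, 2, ns // (10 * fs)), 10 * fs), fs=fs)
        per = indices.prx_updates(abp, icp)
        vals = per[np.isfinite(per)]
        assert vals.size >= n_updates
        assert abs(vals.mean()) < 3 * 0.186 / np.sqrt(vals.size / 30)
        assert abs(vals.std() - 1 / np.sqrt(29)) < 0.03

    def test_zero_variance_window_is_missing_not_zero(self):
        fs = 50
        abp = WaveformSignal(np.full(fs * 400, 90.0), fs=fs)
        rng = np.random.default_rng(0)
        icp = WaveformSignal(12 + rng.normal(0, 1, fs * 400), fs=fs)
        prx = indices.compute_prx(abp, icp)
        assert prx.missing.all()


class TestBrs:
    def test_planted_gain_recovered_noise_free(self, short_waveforms):
        abp, _ = short_waveforms  # baro_gain 6, no noise
        brs = indices.compute_brs(indices.detect_systolic_peaks(abp))
        med = np.nanmedian(brs.masked())
        assert abs(med - 6.0) / 6.0 < 0.10

    def test_planted_gain_recovered_with_noise(self):
        p = synth.SimPatientParams(baro_gain=6.0, ibi_sd=10.0, lf_power=0,
                                   hf_power=0, baro_delay=0)
        abp, _ = synth.simulate_waveforms(p, 0.5, fs=125, seed=2)
        brs = indices.compute_brs(indices.detect_systolic_peaks(abp))
        med = np.nanmedian(brs.masked())
        assert abs(med - 6.0) / 6.0 < 0.25

    def test_delay_recovered_as_mode(self):
        p = synth.SimPatientParams(baro_gain=6.0, ibi_sd=0, lf_power=0,
                                   hf_power=0, baro_delay=2.0)
        abp, _ = synth.simulate_waveforms(p, 0.5, fs=125, seed=7)
        _, delay, slope, acc = xbrs_segments(indices.detect_systolic_peaks(abp))
        mode = Counter(delay[acc]).most_common(1)[0][0]
        assert mode == 2
        assert abs(np.median(slope[acc]) - 6.0) / 6.0 < 0.10

    def test_null_acceptance_rate_near_alpha(self):
        accepted, total = 0, 0
        for seed in range(5):
            _, _, _, acc = xbrs_segments(_white_noise_beats(100 + seed))
            accepted += acc.sum()
            total += acc.size
        rate = accepted / total
        # binomial 99.7% band around alpha=0.01 at this n
        band = 3 * np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < band + 0.005

    def test_brs_nonnegative_by_convention(self):
        _, _, slope, acc = xbrs_segments(_white_noise_beats(1))
        assert np.all(slope[acc] >= 0)


class TestLfhf:
    @pytest.mark.parametrize("target,lfp,hfp", [(0.5, 200, 400), (1.0, 400, 400), (2.0, 800, 400)])
    def test_power_ratio_recovery(self, target, lfp, hfp):
        p = synth.SimPatientParams(baro_gain=0, ibi_sd=0, lf_power=lfp,
                                   hf_power=hfp, sbp_osc_lf=0, sbp_osc_hf=0)
        abp, _ = synth.simulate_waveforms(p, 0.5, fs=125, seed=3)
        lfhf = indices.compute_lfhf(indices.detect_systolic_peaks(abp))
        med = np.nanmedian(lfhf.masked())
        assert abs(med - target) / target < 0.15

    def test_pure_lf_modulation_dominates(self):
        p = synth.SimPatientParams(baro_gain=0, ibi_sd=1.0, lf_power=400,
                                   hf_power=0, sbp_osc_lf=0, sbp_osc_hf=0)
        abp, _ = synth.simulate_waveforms(p, 0.25, fs=125, seed=5)
        med = np.nanmedian(indices.compute_lfhf(indices.detect_systolic_peaks(abp)).masked())
        assert med >= 10

    def test_hf_only_modulation_small_ratio(self):
        # modulation at 0.30 Hz only: all power in the HF band
        rng = np.random.default_rng(8)
        n = 1200
        t = np.cumsum(np.full(n, 0.8))
        ibi = 800 + 30 * np.sin(2 * np.pi * 0.30 * t) + rng.normal(0, 0.5, n)
        beats = BeatSeries(t, np.full(n, 120.0), np.diff(t) * 1000, np.ones(n - 1, bool))
        beats = BeatSeries(t, np.full(n, 120.0), ibi[1:], np.ones(n - 1, bool))
        med = np.nanmedian(indices.compute_lfhf(beats).masked())
        assert med <= 0.1

    def test_lomb_scargle_equals_classical_periodogram_even_sampling(self):
        rng = np.random.default_rng(9)
        n = 256
        t = np.arange(n) * 0.8
        y = rng.normal(0, 1, n)
        y -= y.mean()
        k = np.arange(8, 60)  # interior Fourier frequencies
        freqs = k / (n * 0.8)
        ls = sps.lombscargle(t, y, 2 * np.pi * freqs)
        C = np.array([np.sum(y * np.cos(2 * np.pi * f * t)) for f in freqs])
        S = np.array([np.sum(y * np.sin(2 * np.pi * f * t)) for f in freqs])
        classical = (C**2 + S**2) / n
        np.testing.assert_allclose(ls, classical, rtol=1e-6)

    def test_unstable_hf_floor_gives_missing(self):
        # constant IBI: no variability at all -> HF power below floor
        n = 600
        t = np.cumsum(np.full(n, 0.8))
        beats = BeatSeries(t, np.full(n, 120.0), np.full(n - 1, 800.0),
                           np.ones(n - 1, bool))
        lfhf = indices.compute_lfhf(beats)
        assert lfhf.missing.all()
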