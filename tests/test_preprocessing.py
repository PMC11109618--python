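"""Cleaning, filtering, segmentation, peak/rate extraction, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gma import (CohortSpec, FilterSpec, apply_filter, clean_missing,
                 detect_peaks, estimate_heart_rate, estimate_pulse_rate,
                 estimate_respiration_rate, generate_session,
                 generate_vital_trace, group_band, overlap_rate, pearson_r,
                 power_spectrum, segment_frames)
from gma.preprocessing import GroupBand, frame_count

FS = 30.0


class TestCleanMissing:
    @pytest.mark.parametrize("raw, expected", [
        ([1.0, np.nan, 3.0], [1.0, 2.0, 3.0]),
        ([0.0, np.nan, np.nan, 3.0], [0.0, 1.0, 2.0, 3.0]),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
    ])
    def test_linear_interpolation(self, raw, expected):
        np.testing.assert_allclose(clean_missing(np.array(raw)), expected)

    def test_edge_sentinels_extrapolate_flat(self):
        out = clean_missing(np.array([np.nan, 2.0, np.nan]))
        np.testing.assert_allclose(out, [2.0, 2.0, 2.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="entirely missing"):
            clean_missing(np.array([np.nan, np.nan]))


class TestApplyFilter:
    def test_dc_through_lowpass_unchanged(self):
        x = np.full(600, 3.7)
        out = apply_filter(x, FilterSpec(kind="lowpass", f_high=14.0), FS)
        np.testing.assert_allclose(out, x, atol=1e-9)

    @staticmethod
    def _zero_phase_gain(spec, freq):
        """Analytic squared Butterworth magnitude (forward-backward)."""
        from scipy import signal as sps
        if spec.kind == "lowpass":
            sos = sps.butter(spec.order, spec.f_high, btype="low", fs=FS,
                             output="sos")
        else:
            sos = sps.butter(spec.order, [spec.f_low, spec.f_high],
                             btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
        return np.abs(h[0]) ** 2

    def test_inband_tone_matches_butterworth_response(self):
        t = np.arange(120 * FS) / FS
        spec = FilterSpec(kind="bandpass", f_low=0.08, f_high=0.9)
        out = apply_filter(np.sin(2 * np.pi * 0.4 * t), spec, FS)
        core = slice(900, -900)  # avoid edge transients
        gain = np.abs(out[core]).max()
        assert gain == pytest.approx(self._zero_phase_gain(spec, 0.4), abs=0.02)
        assert gain > 0.9  # 0.4 Hz is well inside the respiration band

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        out = apply_filter(x, FilterSpec(kind="bandpass", f_low=1.0,
                                         f_high=5.0, order=4), FS)
        # steady-state response (edge transients ring for ~2 s at f_low)
        assert np.abs(out[90:-90]).max() < 0.05

    def test_length_preserved(self, rng):
        x = rng.standard_normal(733)
        out = apply_filter(x, FilterSpec(kind="lowpass", f_high=10.0), FS)
        assert out.shape == x.shape

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter(np.zeros(100), FilterSpec(kind="lowpass", f_high=15.0), FS)
        with pytest.raises(ValueError, match="f_low"):
            apply_filter(np.zeros(100),
                         FilterSpec(kind="bandpass", f_low=5.0, f_high=1.0), FS)


def _brute_force_frame_count(L, W, V):
    count, start, step = 0, 0, W - V
    while start + W <= L:
        count += 1
        start += step
    return count


class TestSegmentation:
    @given(st.integers(0, 5000), st.integers(2, 400), st.integers(0, 399))
    @settings(max_examples=200, deadline=None)
    def test_frame_count_closed_form(self, L, W, V):
        if V >= W:
            V = W - 1
        assert frame_count(L, W, V) == _brute_force_frame_count(L, W, V)

    def test_default_windowing_of_360s_session(self):
        spec = CohortSpec(duration_s=360.0, seed=0)
        sess = generate_session("Normal", spec, seed=1)
        fset = segment_frames(sess)
        assert len(fset) == 3
        assert [f.start_sample for f in fset] == [0, 3300, 6600]
        assert all(f.n_samples == 3600 for f in fset)
        assert all(f.label == sess.label for f in fset)

    def test_consecutive_frames_share_overlap(self):
        spec = CohortSpec(duration_s=360.0, seed=0)
        sess = generate_session("Normal", spec, seed=1)
        fset = segment_frames(sess)
        node = list(fset[0].nodes)[0]
        np.testing.assert_array_equal(fset[0].nodes[node][:, -300:],
                                      fset[1].nodes[node][:, :300])

    def test_short_session_yields_zero_frames_with_warning(self):
        spec = CohortSpec(duration_s=119.0, seed=0)
        sess = generate_session("Normal", spec, seed=1)
        with pytest.warns(UserWarning, match="shorter than one"):
            fset = segment_frames(sess)
        assert len(fset) == 0

    def test_bad_windowing_rejected(self):
        spec = CohortSpec(duration_s=130.0, seed=0)
        sess = generate_session("Normal", spec, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            segment_frames(sess, window_s=10.0, overlap_s=10.0)


class TestDetectPeaks:
    def test_sinusoid_peak_count(self):
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 0.4 * t)
        peaks = detect_peaks(x, FS, min_distance_s=1.0)
        assert len(peaks) == 24

    def test_constant_yields_no_peaks(self):
        assert len(detect_peaks(np.ones(300), FS)) == 0

    def test_merged_peaks_keep_the_higher(self):
        x = np.zeros(300)
        x[100], x[104] = 1.0, 2.0  # closer than min_distance
        peaks = detect_peaks(x, FS, min_prominence_sd=0.5, min_distance_s=1.0)
        assert peaks.indices.tolist() == [104]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            detect_peaks(np.array([0.0, np.nan, 1.0]), FS)


class TestRateEstimators:
    @pytest.mark.parametrize("rate", [12, 24])
    def test_respiration_recovery(self, rate):
        tr = generate_vital_trace("respiration", rate, 60.0, FS, 0.0, seed=7)
        est = estimate_respiration_rate(tr.values, FS)
        assert abs(est - tr.true_rate_per_min) <= 1.0

    @pytest.mark.parametrize("rate", [72, 120])
    def test_pulse_recovery(self, rate):
        tr = generate_vital_trace("pulse", rate, 60.0, FS, 0.0, seed=7)
        est = estimate_pulse_rate(tr.values, FS)
        assert abs(est - tr.true_rate_per_min) <= 2.0

    @pytest.mark.parametrize("rate", [72, 90])
    def test_heart_rate_recovery(self, rate):
        tr = generate_vital_trace("cardiac", rate, 60.0, FS, 0.0, seed=7)
        axes = np.vstack([tr.values * 2.0, tr.values * 0.3 + 0.1, tr.values])
        est = estimate_heart_rate(axes, FS)
        assert abs(est - 60.0 / np.median(np.diff(tr.event_times_s))) <= 2.0

    def test_heart_rate_invariant_to_axis_rescaling(self):
        tr = generate_vital_trace("cardiac", 80, 60.0, FS, 0.01, seed=7)
        axes = np.vstack([tr.values, tr.values * 0.5, tr.values * 2.0])
        scaled = axes.copy()
        scaled[0] *= 10.0
        assert estimate_heart_rate(axes, FS) == pytest.approx(
            estimate_heart_rate(scaled, FS))

    def test_out_of_band_input_undefined(self, rng):
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 10.0 * t)  # far above the respiration band
        assert np.isnan(estimate_respiration_rate(x, FS))
        assert np.isnan(estimate_pulse_rate(np.full(1800, 2.0), FS))
        assert np.isnan(estimate_heart_rate(np.full((3, 1800), 1.0), FS))


def _pearson_oracle(x, y):
    """Direct summation of the correlation formula."""
    xb, yb = sum(x) / len(x), sum(y) / len(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = (sum((xi - xb) ** 2 for xi in x)
           * sum((yi - yb) ** 2 for yi in y)) ** 0.5
    return num / den


class TestPearson:
    def test_self_and_negated_correlation(self, rng):
        x = rng.standard_normal(50)
        assert pearson_r(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(200):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100) + 0.3 * x
            assert pearson_r(x, y) == pytest.approx(
                _pearson_oracle(x.tolist(), y.tolist()), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(pearson_r(np.ones(10), np.arange(10.0)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.arange(5.0), np.arange(6.0))


class TestPowerSpectrum:
    def test_pure_tone_dominant_bin(self):
        t = np.arange(3600) / FS
        sp = power_spectrum(np.sin(2 * np.pi * 5.0 * t), FS)
        assert sp.freqs[np.argmax(sp.power)] == pytest.approx(5.0, abs=0.01)
        # essentially all power concentrates within the tone's leakage lobes
        near = np.abs(sp.freqs - 5.0) <= 0.05
        assert sp.power[near].sum() / sp.power.sum() > 0.99

    def test_parseval_consistency_boxcar(self, rng):
        x = rng.standard_normal(2048)
        sp = power_spectrum(x, FS, window="boxcar")
        df = sp.freqs[1] - sp.freqs[0]
        assert np.sum(sp.power) * df == pytest.approx(np.var(x), abs=1e-9)

    def test_white_noise_spectrum_flat(self, rng):
        # average many periodograms; compare low/high halves of the band
        acc = None
        for _ in range(40):
            sp = power_spectrum(rng.standard_normal(1024), FS)
            acc = sp.power if acc is None else acc + sp.power
        acc /= 40
        half = len(acc) // 2
        lo, hi = acc[1:half].mean(), acc[half:].mean()
        assert lo / hi == pytest.approx(1.0, abs=0.15)


class TestGroupBandAndOverlap:
    def test_identical_spectra_zero_sd(self, rng):
        x = rng.standard_normal(512)
        spectra = [power_spectrum(x, FS) for _ in range(3)]
        band = group_band(spectra)
        np.testing.assert_allclose(band.sd_db, 0.0, atol=1e-12)

    def test_two_point_mean_and_sample_sd(self):
        from gma.preprocessing import Spectrum
        freqs = np.arange(5.0)
        # linear powers chosen to give 0 dB and 2 dB exactly
        sp0 = Spectrum(freqs=freqs, power=np.full(5, 10 ** 0.0))
        sp2 = Spectrum(freqs=freqs, power=np.full(5, 10 ** 0.2))
        band = group_band([sp0, sp2])
        np.testing.assert_allclose(band.mean_db, 1.0, atol=1e-9)
        np.testing.assert_allclose(band.sd_db, np.sqrt(2.0), atol=1e-9)

    def test_overlap_of_band_with_itself_is_100(self):
        freqs = np.arange(10.0)
        band = GroupBand(freqs=freqs, mean_db=np.zeros(10), sd_db=np.ones(10))
        assert overlap_rate(band, band) == pytest.approx(100.0)

    def test_disjoint_bands_overlap_zero(self):
        freqs = np.arange(10.0)
        a = GroupBand(freqs=freqs, mean_db=np.zeros(10), sd_db=np.ones(10))
        b = GroupBand(freqs=freqs, mean_db=np.full(10, 10.0), sd_db=np.ones(10))
        assert overlap_rate(a, b) == 0.0

    def test_interval_arithmetic_one_third(self):
        # intervals [0, 2] and [1, 3] at every bin -> 1/3
        freqs = np.arange(4.0)
        a = GroupBand(freqs=freqs, mean_db=np.full(4, 1.0), sd_db=np.ones(4))
        b = GroupBand(freqs=freqs, mean_db=np.full(4, 2.0), sd_db=np.ones(4))
        assert overlap_rate(a, b) == pytest.approx(100.0 / 3.0)
        assert overlap_rate(b, a) == overlap_rate(a, b)

    def test_overlap_monotone_in_separation(self):
        freqs = np.arange(8.0)
        a = GroupBand(freqs=freqs, mean_db=np.zeros(8), sd_db=np.ones(8))
        rates = [overlap_rate(a, GroupBand(freqs=freqs,
                                           mean_db=np.full(8, sep),
                                           sd_db=np.ones(8)))
                 for sep in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(r1 >= r2 for r1, r2 in zip(rates, rates[1:]))

    def test_mismatched_grids_rejected(self):
        a = GroupBand(freqs=np.arange(5.0), mean_db=np.zeros(5),
                      sd_db=np.ones(5))
        b = GroupBand(freqs=np.arange(5.0) + 0.5, mean_db=np.zeros(5),
                      sd_db=np.ones(5))
        with pytest.raises(ValueError, match="grid"):
            overlap_rate(a, b)

    def test_group_of_normals_dominates_risky(self):
        spec = CohortSpec(duration_s=60.0, effect_scale=2.0, bulge_rate=0.0,
                          seed=0)
        from gma import PLACEMENTS
        def spectra(label, seeds):
            return [power_spectrum(
                generate_session(label, spec, seed=s).channel(
                    PLACEMENTS[3], "av_x"), FS) for s in seeds]
        bn = group_band(spectra("Normal", range(18)))
        br = group_band(spectra("HighRisk", range(18, 36)))
        inband = (bn.freqs > 0) & (bn.freqs <= 14.0)
        assert np.all(bn.mean_db[inband] > br.mean_db[inband])
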