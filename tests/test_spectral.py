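"""Spectral core: taper, periodogram, bands, band power, maps, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ocupulse as oc
from ocupulse import spectral as sp


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestHammingWeights:
    def test_n3_closed_form(self):
        np.testing.assert_allclose(sp.hamming_weights(3).w, [0.08, 1.0, 0.08])

    def test_n1_convention(self):
        taper = sp.hamming_weights(1)
        np.testing.assert_array_equal(taper.w, [1.0])
        assert taper.k_norm == 1.0

    def test_symmetry(self):
        w = sp.hamming_weights(10).w
        np.testing.assert_allclose(w, w[::-1])

    def test_k_norm_is_energy(self):
        taper = sp.hamming_weights(17)
        assert taper.k_norm == pytest.approx(np.sum(taper.w**2))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.hamming_weights(0)


class TestPeriodogram:
    def test_zero_trace_zero_spectrum(self):
        spec = oc.periodogram(
            oc.TimeTrace(np.zeros(100), fs=10.0), sp.SpectralConfig(nfft=256)
        )
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_unit_sinusoid_argmax_bin_205(self, sine_trace):
        trace = sine_trace(freq=1.0, fs=10.0, duration=90.0)  # 900 samples
        spec = oc.periodogram(trace, sp.SpectralConfig(nfft=2048))
        assert np.argmax(spec.power) == 205
        assert spec.freqs[205] == pytest.approx(1.0009765625)

    def test_delta_f_identities(self):
        spec = oc.periodogram(
            oc.TimeTrace(np.ones(100), fs=10.0), sp.SpectralConfig(nfft=2048)
        )
        assert round(spec.delta_f, 3) == 0.005
        vspec = oc.periodogram(
            oc.TimeTrace(np.ones(100), fs=30.0), sp.SpectralConfig(nfft=3000)
        )
        assert vspec.delta_f == pytest.approx(0.01)

    @pytest.mark.parametrize("n", [1, 7, 32, 64])
    def test_matches_brute_force_dft(self, n, rng, oracle_periodogram):
        x = rng.normal(size=n)
        nfft = max(64, n)
        p_oracle, f_oracle = oracle_periodogram(x, 10.0, nfft)
        spec = oc.periodogram(
            oc.TimeTrace(x, fs=10.0), sp.SpectralConfig(nfft=nfft)
        )
        scale = max(p_oracle.max(), 1e-30)
        np.testing.assert_allclose(spec.power, p_oracle, rtol=0, atol=1e-9 * scale)
        np.testing.assert_allclose(spec.freqs, f_oracle)

    @settings(derandomize=True, max_examples=20)
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_quadratic_scaling(self, c):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        base = oc.periodogram(oc.TimeTrace(x, fs=10.0), sp.SpectralConfig(nfft=256))
        scaled = oc.periodogram(
            oc.TimeTrace(c * x, fs=10.0), sp.SpectralConfig(nfft=256)
        )
        np.testing.assert_allclose(scaled.power, c**2 * base.power, rtol=1e-9)

    def test_peak_localization_random_tones(self, rng):
        """A pure tone lands its argmax at the nearest bin, 20 random draws."""
        fs, nfft = 10.0, 1024
        freqs = np.fft.rfftfreq(nfft, 1 / fs)
        for f0 in rng.uniform(0.3, 4.5, size=20):
            t = np.arange(800) / fs
            trace = oc.TimeTrace(np.sin(2 * np.pi * f0 * t), fs=fs)
            spec = oc.periodogram(trace, sp.SpectralConfig(nfft=nfft))
            peak_bin = np.argmax(spec.power)
            nearest = np.argmin(np.abs(freqs - f0))
            assert abs(int(peak_bin) - int(nearest)) <= 1, f"f0={f0}"
            assert abs(freqs[peak_bin] - f0) <= spec.delta_f

    def test_nfft_shorter_than_trace_rejected(self, rng):
        with pytest.raises(ValueError, match="nfft"):
            oc.periodogram(
                oc.TimeTrace(rng.normal(size=300), fs=10.0),
                sp.SpectralConfig(nfft=256),
            )


class TestRoiMeanSpectrum:
    def test_singleton(self, rng):
        spec = oc.periodogram(
            oc.TimeTrace(rng.normal(size=50), fs=10.0), sp.SpectralConfig(nfft=64)
        )
        out = oc.roi_mean_spectrum([spec])
        np.testing.assert_array_equal(out.power, spec.power)

    def test_pairwise_arithmetic(self, rng):
        config = sp.SpectralConfig(nfft=64)
        a = oc.periodogram(oc.TimeTrace(rng.normal(size=50), fs=10.0), config)
        b = oc.periodogram(oc.TimeTrace(rng.normal(size=50), fs=10.0), config)
        out = oc.roi_mean_spectrum([a, b])
        np.testing.assert_allclose(out.power, (a.power + b.power) / 2)

    def test_matches_loop_accumulation(self, rng):
        config = sp.SpectralConfig(nfft=128)
        series = oc.VolumeSeries(
            data=rng.random((3, 3, 1, 60)),
            meta=oc.AcquisitionMeta(tr=0.1, modality="fmreye", n_slices=1),
        )
        fast = oc.mean_power_spectrum(series, config)
        acc = np.zeros_like(fast.power)
        count = 0
        for i in range(3):
            for j in range(3):
                trace = oc.TimeTrace(series.data[i, j, 0, :], fs=10.0)
                acc += oc.periodogram(trace, config).power
                count += 1
        np.testing.assert_allclose(fast.power, acc / count, rtol=1e-9)

    def test_mismatched_grids_rejected(self, rng):
        a = oc.periodogram(
            oc.TimeTrace(rng.normal(size=50), fs=10.0), sp.SpectralConfig(nfft=64)
        )
        b = oc.periodogram(
            oc.TimeTrace(rng.normal(size=50), fs=10.0), sp.SpectralConfig(nfft=128)
        )
        with pytest.raises(ValueError, match="grid"):
            oc.roi_mean_spectrum([a, b])


def _spectrum_from_power(power, fs=10.0, nfft=None):
    nfft = nfft or 2 * (len(power) - 1)
    return sp.Spectrum(
        power=np.asarray(power, float),
        freqs=np.fft.rfftfreq(nfft, 1 / fs),
        fs=fs,
        config=sp.SpectralConfig(nfft=nfft),
    )


class TestSelectBand:
    def test_vlf_fixed_regardless_of_content(self, rng):
        spec = _spectrum_from_power(rng.random(1025))
        band = oc.select_band(spec, "vlf")
        assert (band.lo, band.hi) == (0.01, 0.1)
        assert band.peak is None

    def test_resp_peak_centering(self, sine_trace):
        trace = sine_trace(freq=0.25, fs=10.0, duration=180.0)
        spec = oc.periodogram(trace, sp.SpectralConfig(nfft=2048))
        band = oc.select_band(spec, "resp")
        assert round(band.peak, 2) == 0.25
        assert band.lo == pytest.approx(band.peak - 0.05)
        assert band.hi == pytest.approx(band.peak + 0.05)
        assert band.hi - band.lo == pytest.approx(0.1)

    def test_larger_of_two_card_maxima_wins(self):
        power = np.zeros(1025)
        freqs = np.fft.rfftfreq(2048, 1 / 10.0)
        i1 = np.argmin(np.abs(freqs - 0.9))
        i2 = np.argmin(np.abs(freqs - 1.2))
        power[i1], power[i2] = 5.0, 8.0
        # brute-force argmax over the card search bins
        in_range = (freqs >= 0.8) & (freqs <= 1.3)
        oracle_peak = freqs[in_range][np.argmax(power[in_range])]
        spec = _spectrum_from_power(power)
        band = oc.select_band(spec, "card")
        assert band.peak == pytest.approx(oracle_peak) == pytest.approx(freqs[i2])

    def test_tie_breaks_to_lower_frequency(self):
        power = np.zeros(1025)
        freqs = np.fft.rfftfreq(2048, 1 / 10.0)
        i1 = np.argmin(np.abs(freqs - 0.9))
        i2 = np.argmin(np.abs(freqs - 1.2))
        power[i1] = power[i2] = 5.0
        band = oc.select_band(_spectrum_from_power(power), "card")
        assert band.peak == pytest.approx(freqs[i1])

    def test_band_width_invariant(self, rng):
        for _ in range(10):
            spec = _spectrum_from_power(rng.random(1025))
            for name in ("resp", "card"):
                band = oc.select_band(spec, name)
                assert band.hi - band.lo == pytest.approx(0.1)

    def test_search_range_beyond_nyquist_rejected(self, rng):
        spec = _spectrum_from_power(rng.random(65), fs=1.0, nfft=128)
        with pytest.raises(ValueError, match="Nyquist"):
            oc.select_band(spec, "card")


class TestBandPower:
    def test_zero_spectrum(self):
        spec = _spectrum_from_power(np.zeros(1025))
        band = oc.select_band(spec, "vlf")
        assert oc.band_power(spec, band) == 0.0

    def test_single_bin(self):
        power = np.zeros(1025)
        freqs = np.fft.rfftfreq(2048, 1 / 10.0)
        idx = np.argmin(np.abs(freqs - 0.05))
        power[idx] = 3.5
        spec = _spectrum_from_power(power)
        assert oc.band_power(spec, oc.select_band(spec, "vlf")) == pytest.approx(3.5)

    def test_matches_loop_oracle(self, rng):
        power = rng.random(21)
        freqs = np.linspace(0, 1.0, 21)
        spec = sp.Spectrum(
            power=power, freqs=freqs, fs=2.0, config=sp.SpectralConfig(nfft=40)
        )
        band = sp.BandSpec(name="resp", lo=0.2, hi=0.6, search_lo=0.2, search_hi=0.6)
        total = 0.0
        for k in range(1, 21):  # DC excluded
            if band.lo <= freqs[k] <= band.hi:
                total += power[k]
        assert oc.band_power(spec, band) == pytest.approx(total)

    def test_dc_bin_never_counted(self):
        power = np.zeros(65)
        power[0] = 100.0
        freqs = np.fft.rfftfreq(128, 1 / 0.05)  # delta_f tiny: DC inside band?
        spec = sp.Spectrum(
            power=power, freqs=freqs, fs=0.05, config=sp.SpectralConfig(nfft=128)
        )
        band = sp.BandSpec(name="vlf", lo=0.0, hi=0.01, search_lo=0.0, search_hi=0.01)
        assert oc.band_power(spec, band) == 0.0

    def test_empty_bin_set_rejected(self):
        spec = _spectrum_from_power(np.ones(1025))
        band = sp.BandSpec(
            name="resp", lo=0.2501, hi=0.2502, search_lo=0.12, search_hi=0.35
        )
        with pytest.raises(ValueError, match="bins"):
            oc.band_power(spec, band)


class TestBandPowerMap:
    def test_constant_series_zero_map(self):
        series = oc.VolumeSeries(
            data=np.full((4, 4, 1, 50), 9.0),
            meta=oc.AcquisitionMeta(tr=0.1, modality="fmreye", n_slices=1),
        )
        pmap = oc.band_power_map(series, "vlf", sp.SpectralConfig(nfft=512))
        np.testing.assert_array_equal(pmap.values, 0.0)

    def test_map_shape_matches_input(self, rng):
        series = oc.VolumeSeries(
            data=rng.random((5, 6, 2, 40)),
            meta=oc.AcquisitionMeta(tr=0.1, modality="fmreye", n_slices=2),
        )
        pmap = oc.band_power_map(series, "resp", sp.SpectralConfig(nfft=64))
        assert pmap.values.shape == (5, 6, 2)

    def test_band_chosen_once_on_mean_spectrum(self, rng):
        """All map elements integrate the same band resolved on the mean."""
        series = oc.VolumeSeries(
            data=rng.random((3, 3, 1, 60)),
            meta=oc.AcquisitionMeta(tr=0.1, modality="fmreye", n_slices=1),
        )
        config = sp.SpectralConfig(nfft=128)
        pmap = oc.band_power_map(series, "resp", config)
        mean_spec = oc.mean_power_spectrum(series, config)
        shared_band = oc.select_band(mean_spec, "resp")
        assert pmap.band.peak == shared_band.peak
        for i in range(3):
            for j in range(3):
                trace = oc.TimeTrace(series.data[i, j, 0, :], fs=10.0)
                expected = oc.band_power(oc.periodogram(trace, config), shared_band)
                assert pmap.values[i, j, 0] == pytest.approx(expected, rel=1e-9)


class TestRemoveBins:
    def test_empty_set_identity(self, rng):
        spec = _spectrum_from_power(rng.random(1025))
        out = sp.remove_bins(spec, [])
        np.testing.assert_array_equal(out.power, spec.power)

    def test_band_power_drops_by_removed_sum(self, rng):
        spec = _spectrum_from_power(rng.random(1025) + 0.1)
        band = sp.BandSpec(name="card", lo=1.0, hi=1.2, search_lo=0.8, search_hi=1.3)
        before = oc.band_power(spec, band)
        target = 1.1
        hit = np.abs(spec.freqs - target) <= spec.delta_f / 2
        removed_sum = spec.power[hit].sum()
        assert removed_sum > 0
        after = oc.band_power(sp.remove_bins(spec, [target]), band)
        assert before - after == pytest.approx(removed_sum)

    def test_flicker_line_excised_from_single_slice_video(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, slice_mode=1, fec_duration=30.0)
        stack, _ = oc.generate_eye_video(cfg, "fec")
        spec = oc.periodogram(
            stack.global_mean_trace(), sp.SpectralConfig(nfft=sp.NFFT_VIDEO)
        )
        above5 = spec.freqs > 5.0
        assert spec.freqs[above5][np.argmax(spec.power[above5])] == pytest.approx(10.0)
        cleaned = sp.remove_bins(spec, [10.0], tol=0.05)
        flicker_zone = np.abs(spec.freqs - 10.0) <= 0.05
        assert cleaned.power[flicker_zone].max() == 0.0

    def test_missing_target_warns(self, rng):
        spec = _spectrum_from_power(rng.random(1025))
        with pytest.warns(UserWarning, match="nothing removed"):
            sp.remove_bins(spec, [4.9], tol=1e-9)


class TestNormalizeSpectrum:
    def test_closed_form(self):
        spec = _spectrum_from_power([2.0, 4.0, 6.0], nfft=4)
        np.testing.assert_allclose(
            sp.normalize_spectrum(spec).power, [0.0, 0.5, 1.0]
        )

    def test_range_exactly_unit(self, rng):
        spec = _spectrum_from_power(rng.random(1025) * 37.0)
        out = sp.normalize_spectrum(spec)
        assert out.power.min() == 0.0
        assert out.power.max() == 1.0

    def test_idempotent(self, rng):
        spec = _spectrum_from_power(rng.random(129), nfft=256)
        once = sp.normalize_spectrum(spec)
        twice = sp.normalize_spectrum(once)
        np.testing.assert_allclose(twice.power, once.power)

    def test_constant_spectrum_rejected(self):
        spec = _spectrum_from_power(np.full(65, 3.0), nfft=128)
        with pytest.raises(ValueError, match="degenerate"):
            sp.normalize_spectrum(spec)
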