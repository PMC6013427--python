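"""Wavelet power, log/z transforms, band averaging, window layouts."""

import numpy as np
import pandas as pd
import pytest

from navmem.spectral import (
    DEFAULT_BANDS,
    BandDef,
    FrequencyGrid,
    PowerTensor,
    baseline_normalize,
    band_power,
    log_and_zscore,
    mean_spectrum,
    morlet_power,
    morlet_wavelet,
    window_count,
)

FS = 500.0


def _sinusoid_epochs(freqs_amps, dur=12.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return np.asarray(sig)[None, None, :]


class TestFrequencyGrid:
    def test_default_grid_log_spacing(self):
        g = FrequencyGrid()
        f = g.frequencies
        assert f.size == 50 and f[0] == 1.0 and f[-1] == pytest.approx(200.0)
        ratios = f[1:] / f[:-1]
        assert np.ptp(ratios) < 1e-9

    def test_low_minimum_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(lo=0.5)

    def test_low_theta_membership_from_grid(self):
        g = FrequencyGrid()
        n_in_band = int(DEFAULT_BANDS["low_theta"].member_mask(g.frequencies).sum())
        # independent enumeration from the grid ratio
        expect = sum(1 for f in g.frequencies if 1.0 <= f <= 3.0)
        assert n_in_band == expect == 11


class TestMorletPower:
    def test_amplitude_scaling_is_quadratic(self):
        g = FrequencyGrid(n=10, lo=2.0, hi=50.0)
        x = _sinusoid_epochs([(10.0, 1.0)])
        p1 = morlet_power(x, FS, g, n_buffer=1000)
        p2 = morlet_power(2 * x, FS, g, n_buffer=1000)
        assert np.allclose(p2, 4 * p1, rtol=1e-10)

    def test_sinusoid_peaks_at_its_grid_frequency(self):
        g = FrequencyGrid(n=20, lo=1.0, hi=50.0)
        f0 = g.frequencies[12]
        p = morlet_power(_sinusoid_epochs([(f0, 1.0)]), FS, g, n_buffer=1500)
        spectrum = p[0, 0].mean(axis=-1)
        assert np.argmax(spectrum) == 12

    def test_separated_sinusoids_superpose(self):
        g = FrequencyGrid(n=12, lo=2.0, hi=60.0)
        fa, fb = 4.0, 40.0
        pa = morlet_power(_sinusoid_epochs([(fa, 1.0)]), FS, g, 1500)
        pb = morlet_power(_sinusoid_epochs([(fb, 1.0)]), FS, g, 1500)
        pab = morlet_power(_sinusoid_epochs([(fa, 1.0), (fb, 1.0)]), FS, g, 1500)
        for fi, f in enumerate(g.frequencies):
            if abs(f - fa) < 1 or abs(f - fb) < 1:
                both = pab[0, 0, fi].mean()
                summed = pa[0, 0, fi].mean() + pb[0, 0, fi].mean()
                assert both == pytest.approx(summed, rel=0.05)

    def test_buffer_doubling_leaves_core_power(self):
        """Edge-effect control: 3000 vs 6000 ms buffers agree for f >= 2 Hz."""
        rng = np.random.default_rng(8)
        g = FrequencyGrid(n=10, lo=2.0, hi=50.0)
        x = rng.normal(size=(1, 1, int(16 * FS)))
        nb3, nb6 = int(3 * FS), int(6 * FS)
        inner = x[..., nb6 - nb3 : x.shape[-1] - (nb6 - nb3)]
        p3 = morlet_power(inner, FS, g, n_buffer=nb3)
        p6 = morlet_power(x, FS, g, n_buffer=nb6)
        assert np.max(np.abs(p6 - p3) / p6) < 0.01

    def test_matches_mne_oracle_on_long_epoch(self):
        mne_tf = pytest.importorskip("mne.time_frequency")
        g = FrequencyGrid(n=8, lo=3.0, hi=40.0)
        rng = np.random.default_rng(9)
        x = rng.normal(size=(2, 1, int(20 * FS)))
        ours = morlet_power(x, FS, g, n_buffer=int(4 * FS))
        theirs = mne_tf.tfr_array_morlet(
            x, sfreq=FS, freqs=g.frequencies, n_cycles=g.wavenumber,
            output="power", zero_mean=True, verbose="error",
        )[..., int(4 * FS) : -int(4 * FS)]
        # normalizations differ by a frequency-dependent constant; compare
        # the per-frequency time course up to a scalar
        for fi in range(g.n):
            a, b = ours[..., fi, :].ravel(), theirs[..., fi, :].ravel()
            scale = (a @ b) / (b @ b)
            assert np.max(np.abs(a - scale * b)) < 0.02 * np.max(np.abs(a))

    def test_wavelet_is_unit_energy(self):
        w = morlet_wavelet(5.0, FS)
        assert np.sum(np.abs(w) ** 2) == pytest.approx(1.0)

    def test_fs_below_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_power(np.zeros((1, 1, 100)), 300.0, FrequencyGrid())


def _tensor(values, events=None, scale="raw", freqs=None):
    values = np.asarray(values, float)
    n_ev = values.shape[0]
    if events is None:
        events = pd.DataFrame({"event": ["encoding"] * n_ev})
    if freqs is None:
        freqs = np.logspace(0, 2, values.shape[2])
    channels = pd.DataFrame(
        {"channel": [f"c{i}" for i in range(values.shape[1])],
         "hemisphere": ["L"] * values.shape[1],
         "region": ["hippocampus"] * values.shape[1]}
    )
    return PowerTensor(values=values, freqs=np.asarray(freqs), events=events,
                       channels=channels, scale=scale)


class TestLogZscore:
    def test_two_event_group_closed_form(self):
        """Two events with log-powers {a, b} map to z = -1, +1."""
        p = _tensor(np.exp([[[1.0]], [[3.0]]]))
        z = log_and_zscore(p)
        assert np.allclose(z.values.ravel(), [-1.0, 1.0])

    def test_zero_group_sd_raises(self):
        p = _tensor(np.ones((3, 1, 1)))
        with pytest.raises(ValueError, match="SD"):
            log_and_zscore(p)

    def test_mean_zero_sd_one_over_normalization_events(self):
        rng = np.random.default_rng(10)
        p = _tensor(np.exp(rng.normal(size=(40, 3, 4))))
        z = log_and_zscore(p)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(z.values.std(axis=0), 1.0, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        raw = np.exp(rng.normal(size=(20, 2, 3)))
        za = log_and_zscore(_tensor(raw.copy()))
        zb = log_and_zscore(_tensor(raw * 37.5))
        assert np.allclose(za.values, zb.values)

    def test_no_item_normalized_but_excluded_from_stats(self):
        rng = np.random.default_rng(12)
        events = pd.DataFrame({"event": ["encoding"] * 20 + ["no_item"] * 5})
        raw = np.exp(rng.normal(size=(25, 1, 1)))
        z = log_and_zscore(_tensor(raw, events=events))
        norm = z.values[:20]
        assert np.allclose(norm.mean(axis=0), 0.0, atol=1e-6)
        # no_item values are on the same scale, not re-centered to zero
        ref_mean = np.log(raw[:20]).mean()
        ref_sd = np.log(raw[:20]).std()
        assert np.allclose(z.values[20:], (np.log(raw[20:]) - ref_mean) / ref_sd)


class TestBandPower:
    def test_zero_tensor_gives_zero(self):
        z = _tensor(np.zeros((4, 2, 10)), scale="z")
        assert np.all(band_power(z, DEFAULT_BANDS["low_theta"]) == 0)

    def test_full_band_equals_global_mean(self):
        rng = np.random.default_rng(13)
        z = _tensor(rng.normal(size=(5, 2, 10)), scale="z")
        full = BandDef("all", z.freqs[0], z.freqs[-1])
        assert np.allclose(band_power(z, full), z.values.mean(axis=2))

    def test_empty_band_raises(self):
        z = _tensor(np.zeros((2, 1, 5)), scale="z", freqs=[10, 20, 30, 40, 50])
        with pytest.raises(ValueError, match="no grid frequencies"):
            band_power(z, BandDef("low_theta", 1.0, 3.0))


class TestWindowCount:
    @pytest.mark.parametrize(
        "span,width,step,expect",
        [(3500, 100, 50, 69), (6000, 500, 100, 56), (100, 100, 50, 1)],
    )
    def test_bin_layouts(self, span, width, step, expect):
        count, edges = window_count(span, width, step)
        assert count == expect
        assert edges.shape == (expect, 2)
        assert edges[-1, 1] <= span + 1e-9

    def test_width_exceeding_span_raises(self):
        with pytest.raises(ValueError):
            window_count(100, 200, 50)


class TestBaselineNormalize:
    def _z(self):
        rng = np.random.default_rng(14)
        events = pd.DataFrame(
            {"event": ["encoding"] * 6 + ["baseline"] * 4 + ["navigation"] * 6}
        )
        return _tensor(rng.normal(size=(16, 2, 3)), events=events, scale="z")

    def test_baseline_mean_zero_after(self):
        out = baseline_normalize(self._z())
        base = out.values[(out.events["event"] == "baseline").to_numpy()]
        assert np.allclose(base.mean(axis=0), 0.0, atol=1e-12)

    def test_shift_invariance(self):
        z = self._z()
        shifted = z.copy_with(z.values + 3.7, "z")
        assert np.allclose(
            baseline_normalize(z).values, baseline_normalize(shifted).values
        )

    def test_no_baseline_raises(self):
        z = _tensor(np.zeros((3, 1, 2)), scale="z")
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(z)


class TestMeanSpectrum:
    def test_single_event_identity(self):
        raw = np.exp(np.random.default_rng(15).normal(size=(1, 2, 6)))
        p = _tensor(raw, freqs=[2, 4, 8, 16, 32, 48])
        freqs, spec_ = mean_spectrum(p, np.array([True]))
        assert np.allclose(spec_, np.log(raw[0]))

    def test_condition_partition_linearity(self):
        raw = np.exp(np.random.default_rng(16).normal(size=(8, 1, 5)))
        p = _tensor(raw, freqs=[2, 4, 8, 16, 32])
        half_a = np.arange(8) < 4
        _, sa = mean_spectrum(p, half_a)
        _, sb = mean_spectrum(p, ~half_a)
        _, pooled = mean_spectrum(p, np.ones(8, bool))
        assert np.allclose(pooled, (sa + sb) / 2)

    def test_powerlaw_recording_slope(self, small_session):
        """Mean spectrum of a pure power-law recording has slope ~ -exponent."""
        from navmem.preprocess import bipolar_reference, extract_epochs
        from navmem.spectral import event_power
        from navmem.synthetic import NeuralModel, default_montage, generate_recording

        nm = NeuralModel(burst_amp=0, line_noise_amp=0, artifact_rate_per_min=0)
        rec = generate_recording(small_session, default_montage(), nm, seed=17)
        bip = bipolar_reference(rec)
        nav = small_session.events.query("event == 'navigation'").head(12)
        es = extract_epochs(bip, nav, None)
        p = event_power({"navigation": es}, FrequencyGrid(n=14, lo=2.0, hi=50.0))
        freqs, spec_ = mean_spectrum(p, np.ones(p.values.shape[0], bool), (2.0, 50.0))
        slope = np.polyfit(np.log(freqs), spec_.mean(axis=0), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.35)

    def test_empty_condition_raises(self):
        p = _tensor(np.ones((3, 1, 5)))
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum(p, np.zeros(3, bool))
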