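"""Synthetic scan generator: pulse, references, echo structure, dataset design."""

import numpy as np
import pytest

import mwdiag as m
from mwdiag.errors import DataError, GeometryError
from mwdiag.geometry import path_length
from mwdiag.windowing import C_MM_PER_NS, roundtrip_delay

FS = 600.0


@pytest.fixture(scope="module")
def pulse():
    return m.Pulse()


@pytest.fixture(scope="module")
def breast():
    return m.BreastSpec(glandular_fraction=0.0)


class TestPulse:
    def test_odd_about_centre_and_zero_at_centre(self, pulse):
        t = np.linspace(-2.0, 2.0, 4001)
        w = m.pulse_waveform(t + 5.0, pulse, t0=5.0)
        assert w[2000] == 0.0
        assert np.allclose(w, -w[::-1], atol=1e-12)
        assert abs(np.trapezoid(w, t)) < 1e-12

    def test_spectral_peak_near_centre_frequency(self, pulse):
        n = 4096
        t = np.arange(n) / FS
        w = m.pulse_waveform(t, pulse, t0=2.0)
        f = np.fft.rfftfreq(n, 1.0 / FS)
        peak = f[np.argmax(np.abs(np.fft.rfft(w)))]
        assert abs(peak - pulse.centre_frequency) < 0.1 * pulse.centre_frequency

    def test_nonpositive_width_rejected(self):
        with pytest.raises(DataError):
            m.Pulse(width_tp=0.0)


class TestReference:
    def test_monostatic_self_coupling_at_zero_delay(self, ring12, channels12, pulse):
        ref = m.simulate_reference(channels12[0], ring12, pulse, n_samples=2048)
        # zero-delay differentiated Gaussian: value 0 at t=0, lobe within a pulse width
        assert ref[0] == 0.0
        assert np.argmax(np.abs(ref)) < pulse.width_tp * FS

    def test_equal_angle_channels_share_reference(self, ring12, channels12, pulse):
        by_angle = {}
        for ch in channels12:
            by_angle.setdefault(ch.angle_z, []).append(
                m.simulate_reference(ch, ring12, pulse, n_samples=1024)
            )
        for refs in by_angle.values():
            for r in refs[1:]:
                assert np.array_equal(refs[0], r)

    def test_diametric_delay_closed_form(self, ring12, channels12, pulse):
        ch = next(c for c in channels12 if (c.tx, c.rx) == (0, 6))
        ref = m.simulate_reference(ch, ring12, pulse, n_samples=4096)
        d = np.hypot(*(ring12.positions[0] - ring12.positions[6]))
        expected = d * np.sqrt(9.0) / C_MM_PER_NS
        # extremes of a differentiated Gaussian sit one sigma either side of the delay
        peak_t = np.argmax(np.abs(ref)) / FS
        assert abs(peak_t - expected) <= pulse.sigma + 1.0 / FS


class TestChannelSignal:
    def test_clean_benign_scan_is_single_exact_echo_in_window(self, ring12, channels12, pulse, breast):
        """s=0, no clutter, no noise: after artefact removal the tumour window
        holds exactly the scaled, delayed pulse copy, to machine precision."""
        tumour = m.TumourSpec(10.0, 0.0, (0.0, 0.0), "benign")
        ch = channels12[20]
        rng = np.random.default_rng(0)
        sig = m.simulate_channel_signal(breast, tumour, ch, ring12, pulse, 0.0, rng)
        ref = m.simulate_reference(ch, ring12, pulse)
        clean = m.remove_artifact(sig, ref)
        media = breast.media()
        delay = roundtrip_delay(tumour.position, ch, ring12, media)
        raw = m.window_tumour(clean, delay, pulse, FS)
        start = round((delay - 0.75 * pulse.width_tp) * FS)
        t_window = (start + np.arange(raw.size)) / FS
        amp = 100.0 / path_length(ch, np.array(tumour.position), ring12)
        expected = amp * m.pulse_waveform(t_window, pulse, delay)
        assert np.max(np.abs(raw - expected)) < 1e-12

    def test_principal_delay_matches_ray_oracle_within_one_sample(self, ring12, channels12, pulse, breast):
        from _oracles import oracle_roundtrip

        tumour = m.TumourSpec(10.0, 0.0, (12.0, -9.0), "benign")
        media = breast.media()
        for ch in channels12[::13]:
            rng = np.random.default_rng(1)
            sig = m.simulate_channel_signal(breast, tumour, ch, ring12, pulse, 0.0, rng)
            clean = sig - m.simulate_reference(ch, ring12, pulse)
            d_oracle = oracle_roundtrip(tumour.position, ch, ring12, media)
            # strongest sample of the echo sits within one sigma of the delay
            skin_end = int((d_oracle - 0.2) * FS)
            peak_t = (skin_end + np.argmax(np.abs(clean[skin_end:]))) / FS
            assert abs(peak_t - d_oracle) <= pulse.sigma + 1.0 / FS

    def test_skin_echo_dominates_principal_by_at_least_10x(self, ring12, channels12, pulse):
        breast = m.BreastSpec(glandular_fraction=0.05)
        tumour = m.TumourSpec(12.0, 0.8, (13.0, 13.0), "malignant")
        rng = np.random.default_rng(5)
        for ch in channels12[::11]:
            sig = m.simulate_channel_signal(breast, tumour, ch, ring12, pulse, 0.0, rng)
            clean = sig - m.simulate_reference(ch, ring12, pulse)
            amp_principal = 100.0 / path_length(ch, np.array(tumour.position), ring12)
            assert np.max(np.abs(clean)) >= 10.0 * amp_principal

    def test_spiculation_increases_windowed_peak_count(self, ring12, channels12, pulse, breast):
        """Malignant signatures show more detected peaks than benign ones
        (mean over 100 seeded draws)."""
        ch = channels12[3]
        media = breast.media()

        def mean_peaks(s, label):
            counts = []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                tum = m.TumourSpec(10.0, s, (13.25, 13.25), label)
                sig = m.simulate_channel_signal(breast, tum, ch, ring12, pulse, 0.0, rng)
                clean = sig - m.simulate_reference(ch, ring12, pulse)
                delay = roundtrip_delay(tum.position, ch, ring12, media)
                signature = m.align_and_downsample(m.window_tumour(clean, delay, pulse, FS))
                counts.append(len(m.detect_peaks(signature.samples, "positive")))
            return np.mean(counts)

        assert mean_peaks(0.9, "malignant") > mean_peaks(0.0, "benign")

    def test_geometry_violations_rejected(self, ring12, channels12, pulse, breast):
        rng = np.random.default_rng(0)
        outside = m.TumourSpec(10.0, 0.0, (60.0, 0.0), "benign")
        with pytest.raises(GeometryError):
            m.simulate_channel_signal(breast, outside, channels12[0], ring12, pulse, 0.0, rng)
        big_breast = m.BreastSpec(radius=80.0)
        tum = m.TumourSpec(10.0, 0.0, (0.0, 0.0), "benign")
        with pytest.raises(GeometryError):
            m.simulate_channel_signal(big_breast, tum, channels12[0], ring12, pulse, 0.0, rng)


class TestTumourSampling:
    def test_class_bands_respected_over_1000_draws(self):
        rng = np.random.default_rng(11)
        s_benign = [m.sample_tumour("benign", (0, 0), rng=rng).spiculation_s for _ in range(500)]
        s_malig = [m.sample_tumour("malignant", (0, 0), rng=rng).spiculation_s for _ in range(500)]
        assert 0.0 <= min(s_benign) and max(s_benign) <= 0.25
        assert 0.50 <= min(s_malig) and max(s_malig) <= 0.90

    def test_diameters_in_range(self):
        rng = np.random.default_rng(2)
        d = [m.sample_tumour("benign", (0, 0), rng=rng).diameter for _ in range(200)]
        assert 6.0 <= min(d) and max(d) <= 20.0

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            m.sample_tumour("unknown", (0, 0))


class TestDataset:
    def test_design_counts_and_balance(self, tiny_scanset):
        assert len(tiny_scanset.scans) == 1 * 8 * 2
        assert tiny_scanset.n_signals == 16 * 78
        labels = tiny_scanset.labels
        assert labels.count("benign") == labels.count("malignant") == 8
        for scan in tiny_scanset.scans:
            assert scan.signals.shape == (78, 2560)
            assert np.all(np.isfinite(scan.signals))

    def test_same_seed_bit_identical(self):
        kw = dict(
            design=m.DesignSpec(1, 2, 1), glandular_fractions=(0.05,), n_samples=512
        )
        a = m.generate_dataset(seed=9, **kw)
        b = m.generate_dataset(seed=9, **kw)
        c = m.generate_dataset(seed=10, **kw)
        for sa, sb in zip(a.scans, b.scans):
            assert np.array_equal(sa.signals, sb.signals)
        assert not np.array_equal(a.scans[0].signals, c.scans[0].signals)

    def test_odd_tumour_count_rejected(self):
        with pytest.raises(DataError):
            m.generate_dataset(m.DesignSpec(1, 3, 1), glandular_fractions=(0.05,), n_samples=256)
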