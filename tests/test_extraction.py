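import numpy as np
import pytest
from scipy import signal

from shapekit.data import RFDataset, ROI
from shapekit.extraction import FilterSpec, design_filter, extract, pi_combine
from shapekit.synth import ResponseModel, generate_dataset, sha_true

FS = 50e6
F0 = 4e6


def tone_gain_db(taps, freq, fs=FS, two_pass=True):
    """Measured gain of the (optionally forward-backward) filter on a tone."""
    t = np.arange(8192) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = signal.filtfilt(taps, [1.0], x) if two_pass else signal.lfilter(
        taps, [1.0], x)
    core = slice(2048, 6144)  # avoid edge transients
    return 20 * np.log10(np.sqrt(np.mean(y[core] ** 2) /
                                 np.mean(x[core] ** 2)))


class TestFilterDesign:
    def test_passband_edges(self):
        spec = FilterSpec(center=F0 / 2)
        assert spec.edges == pytest.approx((1.6e6, 2.4e6))

    def test_subharmonic_tone_passes_unchanged(self):
        taps = design_filter(FilterSpec(center=F0 / 2), FS)
        assert abs(tone_gain_db(taps, F0 / 2)) <= 0.5

    def test_fundamental_rejected_by_80_db(self):
        taps = design_filter(FilterSpec(center=F0 / 2), FS)
        assert tone_gain_db(taps, F0) <= -80.0

    def test_unmeetable_spec_suggests_taps(self):
        with pytest.raises(ValueError, match="n_taps"):
            design_filter(FilterSpec(center=F0 / 2, n_taps=31), FS)

    def test_passband_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_filter(FilterSpec(center=F0 / 2), fs=4.0e6)

    def test_even_taps_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(center=F0 / 2, n_taps=200)

    def test_zero_phase_preserves_pulse_centroid(self):
        """Forward-backward filtering adds no group delay."""
        taps = design_filter(FilterSpec(center=F0 / 2), FS)
        t = np.arange(4096) / FS
        centre = 2048 / FS
        env = np.exp(-((t - centre) ** 2) / (2 * (2e-6) ** 2))
        x = env * np.sin(2 * np.pi * (F0 / 2) * (t - centre))
        y = signal.filtfilt(taps, [1.0], x)
        com_x = np.sum(np.arange(x.size) * x**2) / np.sum(x**2)
        com_y = np.sum(np.arange(y.size) * y**2) / np.sum(y**2)
        assert abs(com_x - com_y) <= 1.0


class TestPiCombine:
    def test_pure_fundamental_pair_cancels(self):
        t = np.arange(1024) / FS
        line = np.sin(2 * np.pi * F0 * t)
        rf = np.stack([line, -line])[None, :, :]
        ds = RFDataset(rf=rf, meta={"polarity": [1, -1],
                                    "pi_combined": False})
        out = pi_combine(ds)
        assert np.max(np.abs(out.rf)) <= 1e-12
        assert out.meta["pi_combined"] is True
        assert out.n_lines == 1

    def test_bad_polarity_rejected(self):
        rf = np.zeros((1, 2, 64))
        ds = RFDataset(rf=rf, meta={"polarity": [1, 1],
                                    "pi_combined": False})
        with pytest.raises(ValueError, match="polarity"):
            pi_combine(ds)

    def test_double_combine_rejected(self, small_cfg, model):
        ds = generate_dataset(small_cfg, model, 0.0, 121.0, 0)
        with pytest.raises(ValueError):
            pi_combine(pi_combine(ds))

    def test_subharmonic_amplitude_preserved(self, model):
        """PI combination leaves the subharmonic level within 0.1 dB.

        The fundamental is silenced so the single-polarity reference is
        unbiased: with it on, burst sidelobes leak into the f0/2 passband
        with polarity-dependent sign — the very bias PI removes."""
        from shapekit.synth import AcquisitionConfig

        cfg = AcquisitionConfig(n_frames=1, n_lines=8, noise_sigma=0.0,
                                floor_sigma=0.0, fundamental_scale=0.0,
                                seed=0)
        ds = generate_dataset(cfg, model, 0.0, 121.0, 0)
        half = RFDataset(rf=ds.rf[:, 0::2, :],
                         meta={**ds.meta, "pi_combined": True,
                               "n_lines": ds.n_lines // 2})
        m_single = extract(half)
        m_comb = extract(pi_combine(ds))
        assert m_comb.sha_dB == pytest.approx(m_single.sha_dB, abs=0.1)


class TestExtract:
    def test_requires_pi_combined(self, small_cfg, model):
        ds = generate_dataset(small_cfg, model, 0.0, 121.0, 0)
        with pytest.raises(ValueError, match="PI-combined"):
            extract(ds)

    def test_recovers_programmed_level(self, small_cfg, model):
        ds = generate_dataset(small_cfg, model, 50.0, 121.0, 0)
        meas = extract(pi_combine(ds))
        assert meas.sha_dB == pytest.approx(sha_true(50.0, 121.0, model),
                                            abs=0.5)

    def test_estimator_linearity_in_scale(self, small_cfg, model):
        """Doubling the data raises the estimate by 6.02 dB."""
        ds = pi_combine(generate_dataset(small_cfg, model, 0.0, 121.0, 0))
        doubled = RFDataset(rf=2.0 * ds.rf, meta=dict(ds.meta))
        m1, m2 = extract(ds), extract(doubled)
        assert m2.sha_dB - m1.sha_dB == pytest.approx(20 * np.log10(2),
                                                      abs=0.01)

    def test_roi_split_pooling_matches_whole(self, small_cfg, model):
        """Envelope pooling over two ROI halves equals the whole-ROI mean."""
        ds = pi_combine(generate_dataset(small_cfg, model, 0.0, 121.0, 0))
        whole = ROI(10.0, 13.0)
        left = ROI(10.0, 11.5)
        right = ROI(11.5, 13.0)
        sl_w = whole.sample_slice(small_cfg.fs, small_cfg.c, ds.n_samples)
        sl_l = left.sample_slice(small_cfg.fs, small_cfg.c, ds.n_samples)
        sl_r = right.sample_slice(small_cfg.fs, small_cfg.c, ds.n_samples)
        taps = design_filter(FilterSpec(center=small_cfg.f0 / 2),
                             small_cfg.fs)
        env = np.abs(signal.hilbert(
            signal.filtfilt(taps, [1.0], ds.rf, axis=-1), axis=-1))
        pooled = np.concatenate([env[:, :, sl_l].ravel(),
                                 env[:, :, sl_r].ravel()])
        assert np.mean(pooled) == pytest.approx(
            float(env[:, :, sl_w].mean()), rel=1e-12)

    def test_noise_floor_below_signal(self, model):
        """A signal-free dataset measures well below a programmed signal."""
        from shapekit.synth import AcquisitionConfig

        cfg = AcquisitionConfig(n_frames=1, n_lines=8, noise_sigma=0.0,
                                floor_sigma=1e-4, seed=3)
        silent = ResponseModel(sha0=-300.0)
        m_noise = extract(pi_combine(generate_dataset(cfg, silent, 0., 121., 0)))
        m_sig = extract(pi_combine(generate_dataset(cfg, model, 0., 121., 0)))
        assert m_sig.sha_dB - m_noise.sha_dB >= 20.0

    def test_empty_roi_rejected(self, small_cfg, model):
        ds = pi_combine(generate_dataset(small_cfg, model, 0.0, 121.0, 0))
        with pytest.raises(ValueError):
            extract(ds, roi=ROI(200.0, 203.0))

    def test_averaging_mode_flag(self, small_cfg, model):
        ds = pi_combine(generate_dataset(small_cfg, model, 0.0, 121.0, 0))
        lin = extract(ds, averaging="linear").sha_dB
        db = extract(ds, averaging="db").sha_dB
        assert db <= lin + 1e-9  # Jensen: mean-of-dB never exceeds dB-of-mean
        with pytest.raises(ValueError):
            extract(ds, averaging="median")
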