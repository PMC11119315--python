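"""Hjorth parameters, wavelet trimming, channel weighting and fusion."""

import numpy as np
import pytest
import pywt

from nirsfuse.epochs import EventSchedule
from nirsfuse.features_fused import (
    FuseConfig,
    channel_weight,
    dwt_decompose,
    dwt_reconstruct,
    featurize_fused,
    fuse1,
    fuse2,
    fused_series,
    hilbert_stream,
    hjorth_activity,
    hjorth_mobility,
    symlet_stream,
    trim_coefficients,
)
from nirsfuse.synth import SynthConfig, simulate_session


class TestHjorth:
    def test_constant_vector_has_zero_activity(self):
        assert hjorth_activity([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_activity(self):
        # var([1,2,3,4]) with N-1 denominator = 5/3
        assert hjorth_activity([1, 2, 3, 4]) == pytest.approx(5.0 / 3.0)

    def test_activity_scales_quadratically(self, rng):
        x = rng.normal(size=100)
        assert hjorth_activity(3.0 * x) == pytest.approx(9.0 * hjorth_activity(x))

    def test_mobility_increases_with_frequency(self):
        fs = 12.5
        t = np.arange(2000) / fs
        slow = np.sin(2 * np.pi * 0.5 * t)
        fast = np.sin(2 * np.pi * 2.0 * t)
        assert hjorth_mobility(fast, fs) > hjorth_mobility(slow, fs)

    def test_mobility_continuous_limit_of_sine(self):
        # var(d/dt sin(2 pi f t)) / var(sin) -> (2 pi f)^2 as fs >> f
        fs, f0 = 200.0, 0.2
        t = np.arange(int(fs * 200)) / fs
        m = hjorth_mobility(np.sin(2 * np.pi * f0 * t), fs)
        assert m == pytest.approx((2 * np.pi * f0) ** 2, rel=0.02)

    def test_white_noise_more_mobile_than_smoothed(self, rng):
        x = rng.standard_normal(5000)
        smooth = np.convolve(x, np.ones(25) / 25, mode="same")
        assert hjorth_mobility(x, 12.5) > hjorth_mobility(smooth, 12.5)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError, match="zero activity"):
            hjorth_mobility(np.ones(10), 12.5)

    def test_sqrt_option_is_root_of_ratio(self, rng):
        x = rng.normal(size=500)
        assert hjorth_mobility(x, 12.5, sqrt=True) == pytest.approx(
            np.sqrt(hjorth_mobility(x, 12.5))
        )


class TestWaveletDecomposition:
    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=1000)
        d = dwt_decompose(x, "db4", 5)
        assert d.levels == 5
        np.testing.assert_allclose(dwt_reconstruct(d), x, atol=1e-10)

    def test_constant_signal_has_vanishing_details(self):
        d = dwt_decompose(np.full(512, 2.5), "db4", 5)
        for c in d.details:
            np.testing.assert_allclose(c, 0.0, atol=1e-10)

    def test_impulse_details_are_highpass_filter_taps(self):
        # level-1 detail of an impulse is the decimated highpass convolution:
        # every nonzero coefficient equals one filter tap (alternating phase)
        w = pywt.Wavelet("db4")
        n = 64
        x = np.zeros(n)
        x[31] = 1.0
        d = dwt_decompose(x, "db4", 1)
        taps = np.abs(np.asarray(w.dec_hi))
        got = np.abs(d.details[0])[np.abs(d.details[0]) > 1e-12]
        assert got.size == (taps > 1e-12).sum() / 2  # one phase of the taps
        for v in got:
            assert np.min(np.abs(taps - v)) < 1e-12

    def test_short_signal_reduces_levels_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            d = dwt_decompose(np.arange(32, dtype=float), "db4", 5)
        assert d.levels < 5
        assert "reducing wavelet levels" in caplog.text

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            dwt_decompose(np.arange(100, dtype=float), "db4", 0)


class TestTrimming:
    def test_trim_count_is_floor_of_fraction(self, rng):
        x = rng.normal(size=1024)
        t = trim_coefficients(dwt_decompose(x, "db4", 3), frac=0.25)
        for j, c in enumerate(t.decomp.details, start=1):
            n = c.size
            assert (c == 0).sum() >= int(np.floor(0.25 * n))
            assert t.zeroed[j].size == int(np.floor(0.25 * n))

    def test_eight_coefficients_quarter_zeroes_two(self):
        d = dwt_decompose(np.random.default_rng(0).normal(size=16), "db4", 1)
        assert d.details[0].size == 8
        t = trim_coefficients(d, frac=0.25)
        assert t.zeroed[1].size == 2

    def test_zero_fraction_is_identity(self, rng):
        x = rng.normal(size=256)
        d = dwt_decompose(x, "db4", 3)
        t = trim_coefficients(d, frac=0.0)
        for a, b in zip(d.details, t.decomp.details):
            np.testing.assert_array_equal(a, b)

    def test_largest_tail_removes_biggest_magnitude(self):
        from nirsfuse.features_fused import WaveletDecomp, _trim_indices

        c = np.array([5.0, -1.0, 0.5, -0.2])
        idx = _trim_indices(c, 1, "largest")
        assert list(idx) == [0]
        assert list(_trim_indices(c, 1, "smallest")) == [3]
        both = set(_trim_indices(c, 2, "both"))
        assert both == {0, 3}

    def test_tie_break_prefers_earlier_index(self):
        from nirsfuse.features_fused import _trim_indices

        c = np.array([2.0, -2.0, 2.0, 1.0])
        assert list(_trim_indices(c, 2, "largest")) == [0, 1]

    def test_invalid_fraction_rejected(self, rng):
        d = dwt_decompose(rng.normal(size=64), "db4", 1)
        with pytest.raises(ValueError, match="frac"):
            trim_coefficients(d, frac=1.0)


class TestChannelWeight:
    def test_uniform_magnitude_coefficients(self):
        from nirsfuse.features_fused import TrimmedDecomp, WaveletDecomp

        d = WaveletDecomp(
            approx=np.zeros(4),
            details=[np.array([2.0, -2.0, 2.0, -2.0])] * 4,
            wavelet="db4",
            levels=4,
            n_samples=64,
        )
        w, k = channel_weight(TrimmedDecomp(d), level=4)
        assert w == pytest.approx(2.0)
        assert k == 4

    def test_zero_signal_gives_zero_weight(self):
        t = trim_coefficients(dwt_decompose(np.zeros(512), "db4", 5))
        w, _ = channel_weight(t, level=4)
        assert w == 0.0

    def test_weight_scales_linearly_with_signal(self, rng):
        x = rng.normal(size=1024)
        w1, _ = channel_weight(trim_coefficients(dwt_decompose(x, "db4", 5)), 4)
        w2, _ = channel_weight(trim_coefficients(dwt_decompose(3.0 * x, "db4", 5)), 4)
        assert w2 == pytest.approx(3.0 * w1, rel=1e-9)

    def test_level_out_of_range_rejected(self, rng):
        t = trim_coefficients(dwt_decompose(rng.normal(size=512), "db4", 3))
        with pytest.raises(ValueError, match="level"):
            channel_weight(t, level=4)


class TestFusion:
    def test_fuse1_identity_injection(self, rng):
        f = rng.normal(size=(2, 50))
        out = fuse1(f, w=np.ones(2), activity=np.zeros(2), mobility=np.zeros(2))
        np.testing.assert_array_equal(out, f)

    def test_fuse1_hand_arithmetic(self):
        out = fuse1(
            np.array([[1.0, -1.0]]),
            w=np.array([0.5]),
            activity=np.array([2.0]),
            mobility=np.array([0.25]),
        )
        np.testing.assert_allclose(out, [[2.75, -2.75]])

    def test_fuse1_zero_signal(self):
        out = fuse1(np.zeros((3, 10)), np.ones(3), np.ones(3), np.ones(3))
        assert not out.any()

    def test_fuse2_hand_arithmetic(self):
        out = fuse2(np.array([2.0]), np.array([[1.0, 1.0]]), np.array([[0.5, -0.5]]))
        np.testing.assert_allclose(out, [[3.0, 1.0]])

    def test_fuse2_zero_weights(self, rng):
        h, s = rng.normal(size=(2, 20)), rng.normal(size=(2, 20))
        assert not fuse2(np.zeros(2), h, s).any()

    def test_fuse2_unit_weight_zero_symlet(self, rng):
        h = rng.normal(size=(1, 30))
        np.testing.assert_array_equal(fuse2(np.ones(1), h, np.zeros_like(h)), h)


class TestSymletStream:
    def test_dc_preservation(self):
        s = symlet_stream(np.full(200, 3.7))
        np.testing.assert_allclose(s, 3.7, atol=1e-8)

    def test_alternating_signal_attenuated(self):
        f = np.resize([1.0, -1.0], 400)
        s = symlet_stream(f)
        assert np.linalg.norm(s) < 0.1 * np.linalg.norm(f)

    def test_linearity(self, rng):
        f, g = rng.normal(size=300), rng.normal(size=300)
        lhs = symlet_stream(2.0 * f + 3.0 * g)
        rhs = 2.0 * symlet_stream(f) + 3.0 * symlet_stream(g)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_same_length_output(self, rng):
        assert symlet_stream(rng.normal(size=123)).size == 123

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            symlet_stream(np.arange(3, dtype=float))


class TestHilbertStream:
    def test_pure_tone_envelope_is_amplitude(self):
        fs, f0, A = 12.5, 1.5, 2.3
        t = np.arange(2000) / fs
        h = hilbert_stream(A * np.sin(2 * np.pi * f0 * t))
        core = h[200:-200]
        assert np.all(np.abs(core - A) < 0.02 * A)

    def test_am_demodulation(self):
        fs = 50.0
        t = np.arange(10000) / fs
        m = 1.0 + 0.5 * np.sin(2 * np.pi * 0.05 * t)
        x = m * np.sin(2 * np.pi * 5.0 * t)
        h = hilbert_stream(x)
        core = slice(500, -500)
        r = np.corrcoef(h[core], m[core])[0, 1]
        assert r >= 0.98

    def test_zero_signal_zero_envelope(self):
        assert not hilbert_stream(np.zeros(100)).any()

    def test_phase_output_mode(self):
        fs, f0 = 50.0, 2.0
        t = np.arange(5000) / fs
        ph = hilbert_stream(np.sin(2 * np.pi * f0 * t), output="phase")
        slope = np.polyfit(t[500:-500], ph[500:-500], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f0, rel=0.01)


class TestFusedSeries:
    def test_variance_and_weight_gains_amplify_active_channels(self):
        # only a known channel subset carries event-locked activity; the
        # activity (variance) and wavelet-weight parts of the fusion gain
        # must favour those channels by a clear factor.  The mobility ratio
        # is excluded here: var(fs*diff)/var rewards whichever channel has
        # the *smaller* variance under broadband noise, so it is not
        # activity-selective (see the methods note).
        cfg = SynthConfig(seed=3)
        raw, events, truth = simulate_session(cfg)
        from nirsfuse.beer_lambert import baseline_reference, intensity_to_od, od_to_hb

        od = intensity_to_od(raw, baseline_reference(raw, (0.0, 10.0)))
        hb = od_to_hb(od)
        fused = fused_series(hb.hbo, cfg.fs)
        active = sorted({c for chs in truth.active_channels.values() for c in chs})
        inactive = [c for c in range(cfg.n_channels) if c not in active]
        # activity is strictly selective channel by channel
        assert fused.activity[active].min() > fused.activity[inactive].max()
        # fnew restricted to the activity gain (w, beta injected as 0): the
        # event-locked response drives both the gain and the amplitude, so
        # active channels come out amplified by a clear factor
        zeros = np.zeros(cfg.n_channels)
        fnew_act = fuse1(hb.hbo, zeros, fused.activity, zeros)
        amp_active = np.mean(np.abs(fnew_act[active]))
        amp_inactive = np.mean(np.abs(fnew_act[inactive]))
        assert amp_active >= 2.0 * amp_inactive
        # the wavelet weight never reverses the ordering
        fnew_sel = fuse1(hb.hbo, fused.weights, fused.activity, zeros)
        assert np.mean(np.abs(fnew_sel[active])) > np.mean(np.abs(fnew_sel[inactive]))

    def test_zero_activity_channel_zeroed_not_fatal(self, rng):
        f = np.vstack([np.full(512, 1.0), rng.normal(size=512)])
        fused = fused_series(f, fs=12.5)
        assert not fused.fnew[0].any()
        assert not fused.fnew1[0].any()
        assert fused.fnew[1].any()

    def test_determinism_bit_for_bit(self, rng):
        f = rng.normal(size=(4, 600))
        a = fused_series(f, 12.5)
        b = fused_series(f.copy(), 12.5)
        np.testing.assert_array_equal(a.fnew, b.fnew)
        np.testing.assert_array_equal(a.fnew1, b.fnew1)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestFeaturizeFused:
    def test_feature_count_and_names(self, rng):
        f = rng.normal(size=(14, 1000))
        fused = fused_series(f, 12.5)
        events = EventSchedule([10.0, 30.0, 50.0], [10.0] * 3, [1, 2, 3])
        df = featurize_fused(fused, events, window_s=10.0, stream_tag="HbO")
        # 14 channels x 2 fused streams x 3 summaries = 84 features
        assert df.shape == (3, 84 + 1)
        names = [c for c in df.columns if c != "label"]
        assert len(set(names)) == 84
        df2 = featurize_fused(fused, events, window_s=10.0, stream_tag="HbO")
        assert list(df.columns) == list(df2.columns)

    def test_zero_series_gives_zero_features(self):
        fused = fused_series(np.zeros((2, 500)), 12.5)
        events = EventSchedule([5.0], [10.0], [2])
        df = featurize_fused(fused, events, window_s=10.0)
        assert not df.drop(columns="label").to_numpy().any()
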