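"""Spike-model landmarks and the 13 morphological features."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import neospike as ns
from neospike.features import _chord_excess_area


def triangle_signal():
    """Flat, then a linear rise 10→15 and fall 15→20, then flat."""
    x = np.zeros(40)
    x[10:16] = np.linspace(0.0, 5.0, 6)
    x[16:21] = np.linspace(4.0, 0.0, 5)
    return x


def toy_points():
    """The analytic toy: A=(0,0), P=(5,10), B=(10,0), piecewise linear,
    followed by a flat segment out to R so slow-wave features vanish."""
    x = np.zeros(31)
    x[0:6] = np.linspace(0.0, 10.0, 6)
    x[5:11] = np.linspace(10.0, 0.0, 6)
    pts = ns.FeaturePoints(
        a_idx=0, p_idx=5, b_idx=10, q_idx=15, r_idx=20,
        a_val=0.0, p_val=10.0, b_val=0.0, q_val=0.0, r_val=0.0,
    )
    return x, pts


class TestSpikeBounds:
    def test_triangle_bounds(self):
        assert ns.locate_spike_bounds(triangle_signal(), 15) == (10, 20)

    def test_symmetric_peak(self):
        x = np.concatenate([np.zeros(5), np.linspace(0, 1, 8), np.linspace(1, 0, 8)[1:], np.zeros(5)])
        p = int(np.argmax(x))
        a, b = ns.locate_spike_bounds(x, p)
        assert p - a == b - p

    def test_edge_peak_errors(self):
        x = np.array([1.0, 0.5, 0.2])
        with pytest.raises(ValueError, match="edge"):
            ns.locate_spike_bounds(x, 0)
        x2 = np.array([0.0, 1.0, 0.5, 0.2])  # descends to the trial end
        with pytest.raises(ValueError, match="unbounded"):
            ns.locate_spike_bounds(x2, 1)

    def test_not_a_peak_errors(self):
        with pytest.raises(ValueError, match="not an upward peak"):
            ns.locate_spike_bounds(triangle_signal(), 12)


class TestLowpass:
    def test_dc_preserved(self):
        trial = ns.Trial(np.full(2560, 7.0), fs=256.0)
        out = ns.lowpass_slow(trial, 5.0)
        np.testing.assert_allclose(out.samples, 7.0, atol=1e-6)

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [(2.0, 0.95, 1.05), (40.0, 0.0, 0.10)],
    )
    def test_frequency_response(self, freq, min_gain, max_gain):
        fs, n = 256.0, 2560
        t = np.arange(n) / fs
        trial = ns.Trial(np.sin(2 * np.pi * freq * t), fs=fs)
        out = ns.lowpass_slow(trial, 5.0).samples
        gain = out[n // 4 : -n // 4].std() / trial.samples[n // 4 : -n // 4].std()
        assert min_gain <= gain <= max_gain

    def test_20db_at_4x_cutoff(self):
        fs, n = 256.0, 2560
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 20.0 * t)
        out = ns.lowpass_slow(ns.Trial(x, fs=fs), 5.0).samples
        gain = out[n // 4 : -n // 4].std() / x[n // 4 : -n // 4].std()
        assert 20 * np.log10(1 / gain) >= 20.0

    def test_cutoff_above_nyquist_errors(self):
        with pytest.raises(ValueError):
            ns.lowpass_slow(ns.Trial(np.zeros(100) + 1e-9, fs=256.0), 128.0)


class TestSlowWave:
    def test_half_sine_bump_located(self):
        fs = 256.0
        x = np.zeros(1024)
        bump = ns.gen_slow_wave(200.0, 2.0, fs)
        b = 300
        x[b : b + bump.size] += bump
        q0 = b + int(np.argmax(bump))
        r0 = b + bump.size - 1
        xf = ns.lowpass_slow(ns.Trial(x, fs=fs), 5.0).samples
        q, r, truncated = ns.locate_slow_wave(xf, b - 10, b, 256)
        assert abs(q - q0) <= 5
        # R locks onto the filter's undershoot trough, which trails the true
        # bump end by up to the filter's settling width (~1/cutoff = 200 ms
        # at 5 Hz; in practice well under half of that)
        assert r0 - 10 <= r <= r0 + int(0.1 * fs)
        assert not truncated

    def test_monotone_decreasing_tail(self):
        xf = -np.arange(50.0)
        q, r, _ = ns.locate_slow_wave(xf, 5, 10, 20)
        assert q == 11  # first point of the window
        assert r == 30  # end of the window

    def test_argmax_tie_earliest(self):
        xf = np.zeros(40)
        xf[15] = xf[20] = 1.0
        q, _, _ = ns.locate_slow_wave(xf, 5, 10, 25)
        assert q == 15

    def test_window_truncated_at_trial_end(self):
        xf = np.sin(np.linspace(0, 3, 60))
        q, r, truncated = ns.locate_slow_wave(xf, 10, 40, 256)
        assert truncated and q < r <= 59

    def test_no_room_errors(self):
        with pytest.raises(ValueError, match="no slow-wave room"):
            ns.locate_slow_wave(np.zeros(30), 20, 28, 100)


class TestExtractFeatures:
    def test_analytic_toy(self):
        x, pts = toy_points()
        fv = ns.extract_features(x, pts)
        assert fv.dur_ap == 5 and fv.dur_pb == 5 and fv.dur_spike == 10
        assert fv.amp_ap == 10 and fv.amp_pb == 10 and fv.amp_spike == 10
        assert fv.slope_ap == 2 and fv.slope_pb == -2 and fv.slope_sharpness == 4
        # triangle over the zero chord: area = 10·10/2 = 50, chord area 0
        assert fv.area_spike == pytest.approx(50.0, abs=1e-12)
        assert fv.dur_slowwave == 10
        assert fv.amp_slowwave == 0 and fv.area_slowwave == 0

    def test_pure_triangle_area_is_half_base_times_height(self):
        x = np.zeros(21)
        x[0:6] = np.linspace(0.0, 10.0, 6)
        x[5:11] = np.linspace(10.0, 0.0, 6)
        assert _chord_excess_area(x, 0, 10) == pytest.approx(50.0, abs=1e-12)

    def test_definitional_identities(self):
        x, pts = toy_points()
        fv = ns.extract_features(x, pts)
        assert fv.dur_spike - (fv.dur_ap + fv.dur_pb) == 0.0
        assert fv.slope_sharpness - (fv.slope_ap - fv.slope_pb) == 0.0
        assert fv.amp_spike - (fv.amp_ap + fv.amp_pb) / 2.0 == 0.0

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            ns.FeaturePoints(5, 3, 8, 9, 12, 0.0, 1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="peak"):
            ns.FeaturePoints(0, 5, 10, 12, 15, 2.0, 1.0, 0.0, 0.0, 0.0)

    def test_time_shift_invariance(self):
        fs = 256.0
        base = np.zeros(2048)
        spike = ns.gen_spike_waveform(40.0, 5.0, fs)
        slow = ns.gen_slow_wave(250.0, 2.0, fs)
        start = 500
        base[start : start + spike.size] += spike
        b0 = start + spike.size - 1
        base[b0 : b0 + slow.size] += slow
        shift = 137
        shifted = np.roll(base, shift)
        fvs = []
        for x, p in ((base, start + int(np.argmax(spike))), (shifted, start + shift + int(np.argmax(spike)))):
            xf = ns.lowpass_slow(ns.Trial(x + 1e-9, fs=fs), 5.0).samples
            pts = ns.locate_feature_points(x, xf, p, 300)
            fvs.append(ns.extract_features(x, pts, xf))
        for name in ns.FEATURE_SETS["FS3"]:
            assert getattr(fvs[0], name) == pytest.approx(getattr(fvs[1], name), abs=1e-6)

    def test_vertical_scaling(self):
        """Scaling the waveform by a > 0 scales amplitudes, slopes and areas
        by a and leaves durations unchanged."""
        fs = 256.0
        a = 3.5
        x = np.zeros(1024)
        spike = ns.gen_spike_waveform(50.0, 4.0, fs)
        x[400 : 400 + spike.size] += spike
        p = 400 + int(np.argmax(spike))
        fv1, fva = [], None
        for scale in (1.0, a):
            xs = scale * x
            xf = ns.lowpass_slow(ns.Trial(xs + 1e-12, fs=fs), 5.0).samples
            pts = ns.locate_feature_points(xs, xf, p, 256)
            fv = ns.extract_features(xs, pts, xf)
            fv1.append(fv)
        base, scaled = fv1
        for name in ("dur_ap", "dur_pb", "dur_spike", "dur_slowwave"):
            assert getattr(base, name) == getattr(scaled, name)
        for name in ("amp_ap", "amp_pb", "amp_spike", "amp_slowwave",
                     "slope_ap", "slope_pb", "slope_sharpness",
                     "area_spike", "area_slowwave"):
            assert getattr(scaled, name) == pytest.approx(a * getattr(base, name), rel=1e-9, abs=1e-12)

    def test_durations_positive_slope_pb_nonpositive(self, default_feature_table):
        df = default_feature_table
        assert (df.dur_ap > 0).all() and (df.dur_pb > 0).all()
        assert (df.dur_slowwave > 0).all()
        assert (df.slope_pb <= 0).all()

    def test_trapezoid_matches_fine_grid_quadrature(self):
        """Chord-excess area agrees with dense numeric integration: exactly
        on piecewise-linear toys, and within the trapezoid-rule error bound
        (b−a)·h²·max|f''|/12 on a curved toy."""
        x = np.zeros(21)
        x[0:6] = np.linspace(0.0, 10.0, 6)
        x[5:11] = np.linspace(10.0, 0.0, 6)
        assert _chord_excess_area(x, 0, 10) == pytest.approx(50.0, abs=1e-12)

        lo, hi = 0, 40
        idx = np.arange(lo, hi + 1, dtype=float)
        f = lambda t: np.sin(t / 7.0) + 0.3 * np.cos(t / 3.0)
        coarse = _chord_excess_area(f(idx), lo, hi)
        t = np.linspace(lo, hi, 200001)
        chord = (f(float(lo)) + f(float(hi))) / 2.0 * (hi - lo)
        fine = np.trapezoid(f(t), t) - chord
        bound = (hi - lo) * (1 / 7.0**2 + 0.3 / 3.0**2) / 12.0
        assert abs(coarse - fine) <= bound


class TestSelectFeatures:
    @pytest.mark.parametrize("which,length", [("FS1", 6), ("FS2", 9), ("FS3", 13)])
    def test_cardinalities(self, which, length):
        x, pts = toy_points()
        fv = ns.extract_features(x, pts)
        assert ns.select_features(fv, which).shape == (length,)

    def test_nesting_and_order(self):
        x, pts = toy_points()
        fv = ns.extract_features(x, pts)
        fs1, fs2, fs3 = (ns.select_features(fv, w) for w in ("FS1", "FS2", "FS3"))
        np.testing.assert_array_equal(fs2[:6], fs1)
        np.testing.assert_array_equal(fs3[:9], fs2)
        np.testing.assert_array_equal(
            fs1, [fv.dur_ap, fv.dur_pb, fv.amp_ap, fv.amp_pb, fv.slope_ap, fv.slope_pb]
        )

    def test_unknown_set_rejected(self):
        x, pts = toy_points()
        with pytest.raises(ValueError, match="unknown feature set"):
            ns.select_features(ns.extract_features(x, pts), "FS4")
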