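import numpy as np
import pytest

from aisleep import features as feat
from aisleep.signal_io import EEGRecording, EpochedSignal
from aisleep.spectral import PSDMatrix, welch_psd_db
from tests.conftest import make_decomposition, make_grid, pink_noise

FS = 100.0


def brute_force_otsu(values, n_bins=256):
    """Exhaustive between-class-variance maximization over interior bin edges."""
    values = np.asarray(values, dtype=float)
    edges = np.linspace(values.min(), values.max(), n_bins + 1)[1:-1]
    best_t, best_v = None, -1.0
    n = values.size
    for t in edges:
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            v = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-15:  # strict improvement: ties keep the lowest edge
            best_t, best_v = t, v
    return best_t


class TestBandPower:
    def test_constant_matrix(self):
        grid = make_grid()
        values = np.full((4, grid.frequencies.size), 10.0)
        out = feat.band_power(values, grid, (25.0, 50.0))
        np.testing.assert_allclose(out, 10.0)

    def test_30hz_sine_gamma_exceeds_delta(self):
        t = np.arange(3000) / FS
        ep = EpochedSignal((20 * np.sin(2 * np.pi * 30 * t))[None, :], FS)
        psd = welch_psd_db(ep)
        gamma = feat.band_power(psd.values, psd.grid, (25.0, 50.0))
        delta = feat.band_power(psd.values, psd.grid, (1.0, 4.0))
        assert gamma[0] > delta[0]

    def test_reversed_band_rejected(self):
        grid = make_grid()
        with pytest.raises(ValueError, match="malformed band"):
            feat.band_power(np.zeros((1, grid.frequencies.size)), grid, (50.0, 25.0))

    def test_invariant_to_out_of_band_bins(self, rng):
        grid = make_grid()
        values = rng.normal(size=(6, grid.frequencies.size))
        before = feat.band_power(values, grid, (10.0, 20.0))
        values2 = values.copy()
        values2[:, grid.frequencies >= 20.0] += 100.0
        values2[:, grid.frequencies <= 10.0] -= 50.0
        after = feat.band_power(values2, grid, (10.0, 20.0))
        np.testing.assert_array_equal(before, after)


class TestOtsu:
    def test_two_gaussians(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(-5, 0.5, 500)
        hi = rng.normal(5, 0.5, 500)
        values = np.concatenate([lo, hi])
        th = feat.otsu_threshold(values)
        # the whole inter-cluster gap ties on between-class variance, and ties
        # resolve to the lowest edge: the threshold sits just above the low
        # cluster and separates the two components perfectly
        assert lo.max() < th < hi.min()
        assert th == pytest.approx(brute_force_otsu(values))

    def test_two_point_masses(self):
        values = np.array([0.0, 0, 0, 10, 10, 10])
        th = feat.otsu_threshold(values)
        assert 0 < th < 10
        assert th == pytest.approx(brute_force_otsu(values))

    def test_constant_input_rejected(self):
        with pytest.raises(feat.DegenerateDistributionError):
            feat.otsu_threshold(np.full(10, 2.0))

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1, n2 = rng.integers(5, 50, size=2)
            values = np.concatenate(
                [
                    rng.normal(rng.uniform(-10, 0), rng.uniform(0.1, 2), n1),
                    rng.normal(rng.uniform(0, 10), rng.uniform(0.1, 2), n2),
                ]
            )
            assert feat.otsu_threshold(values) == pytest.approx(
                brute_force_otsu(values)
            )


def _osc_with_bumps(peak_freqs, height=10.0, width_hz=1.0, res=0.2):
    """Rows of psd_osc with one Gaussian bump per epoch at the given peaks."""
    grid = make_grid(res=res)
    f = grid.frequencies
    rows = [height * np.exp(-0.5 * ((f - pf) / (width_hz / 2)) ** 2) for pf in peak_freqs]
    return make_decomposition(np.asarray(rows), grid)


class TestPersonalizedSpindleBand:
    def test_all_bumps_at_14(self):
        dec = _osc_with_bumps([14.0] * 30)
        band = feat.personalized_spindle_band(dec)
        assert band.f_peak == pytest.approx(14.0, abs=0.05)
        assert (band.low, band.high) == (band.f_peak - 1, band.f_peak + 1)

    def test_bimodal_prefers_closest_to_14(self):
        # 60% of epochs peak at 10 Hz (the global mode), 40% at 14 Hz
        rng = np.random.default_rng(5)
        peaks = np.concatenate(
            [10.0 + rng.normal(0, 0.2, 60), 14.0 + rng.normal(0, 0.2, 40)]
        )
        band = feat.personalized_spindle_band(_osc_with_bumps(peaks))
        assert 13.0 <= band.f_peak <= 15.0

    def test_single_bump_at_13(self):
        rng = np.random.default_rng(6)
        peaks = 13.0 + rng.normal(0, 0.15, 40)
        band = feat.personalized_spindle_band(_osc_with_bumps(peaks))
        assert band.f_peak == pytest.approx(13.0, abs=0.3)
        assert band.low == pytest.approx(band.f_peak - 1)
        assert band.high == pytest.approx(band.f_peak + 1)

    def test_no_interior_maximum_falls_back(self):
        # all peak frequencies pile up at the lower search edge: the density
        # curve decreases monotonically, so no interior local maximum exists
        rng = np.random.default_rng(7)
        peaks = 5.0 + rng.uniform(0, 0.03, 40)
        with pytest.warns(UserWarning, match="falling back"):
            band = feat.personalized_spindle_band(
                _osc_with_bumps(peaks, width_hz=0.05, res=0.01)
            )
        assert band.f_peak == 14.0
        assert band.fallback


class TestSpindlePower:
    def test_zero_in_band(self):
        dec = make_decomposition(np.zeros((5, 251)))
        out = feat.spindle_power(dec, feat.SpindleBand(14.0))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_constant_three_db(self):
        dec = make_decomposition(np.full((5, 251), 3.0))
        out = feat.spindle_power(dec, feat.SpindleBand(14.0))
        np.testing.assert_allclose(out.values, 3.0)

    def test_burst_epochs_strictly_higher(self):
        dec = _osc_with_bumps([14.0] * 10 + [0.0] * 10)  # bump at 0 Hz = flat in band
        out = feat.spindle_power(dec, feat.SpindleBand(14.0))
        assert out.values[:10].min() > out.values[10:].max()

    def test_psd_source_switch(self, rng):
        grid = make_grid()
        osc = rng.normal(size=(4, grid.frequencies.size))
        dec = make_decomposition(osc, grid)
        psd = PSDMatrix(osc + 5.0, grid)
        a = feat.spindle_power(dec, feat.SpindleBand(14.0), psd=psd, source="psd")
        b = feat.spindle_power(dec, feat.SpindleBand(14.0))
        np.testing.assert_allclose(a.values, b.values + 5.0)


class TestSlowOscillations:
    def _sine_rec(self, freq=0.9, ptp=160.0, duration=60.0):
        t = np.arange(int(duration * FS)) / FS
        return EEGRecording(-(ptp / 2) * np.sin(2 * np.pi * freq * t), FS)

    def test_one_event_per_cycle(self):
        rec = self._sine_rec()
        events = feat.detect_slow_oscillations(rec)
        n_cycles = int(0.9 * 60)
        assert abs(len(events) - n_cycles) <= 1

    def test_subthreshold_amplitude_rejected(self):
        events = feat.detect_slow_oscillations(self._sine_rec(ptp=70.0))
        assert events == []

    def test_alpha_rejected(self):
        events = feat.detect_slow_oscillations(self._sine_rec(freq=10.0, ptp=100.0))
        assert events == []

    def test_events_satisfy_all_criteria(self):
        rec = self._sine_rec()
        for ev in feat.detect_slow_oscillations(rec):
            assert ev.ptp_uv > 75.0
            assert 0.3 < ev.neg_duration_s < 1.5
            assert 0.1 < ev.pos_duration_s < 1.0
            assert ev.neg_peak_uv < -10.0
            assert ev.pos_peak_uv > 10.0

    def test_events_on_noisy_background_satisfy_criteria(self):
        rng = np.random.default_rng(11)
        t = np.arange(int(120 * FS)) / FS
        x = pink_noise(rng, t.size, scale=15.0) - 80 * np.sin(2 * np.pi * 0.8 * t)
        events = feat.detect_slow_oscillations(EEGRecording(x, FS))
        assert len(events) > 0
        for ev in events:
            assert ev.ptp_uv > 75.0
            assert 0.3 < ev.neg_duration_s < 1.5
            assert 0.1 < ev.pos_duration_s < 1.0
            assert ev.neg_peak_uv < -10.0 and ev.pos_peak_uv > 10.0

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="4 s"):
            feat.detect_slow_oscillations(EEGRecording(np.zeros(300), FS))


class TestSOPercentage:
    def _ep(self, n_epochs=4):
        return EpochedSignal(np.zeros((n_epochs, 3000)), FS)

    def test_no_events(self):
        out = feat.so_percentage([], self._ep())
        np.testing.assert_array_equal(out.values, 0.0)

    def test_half_epoch_coverage(self):
        ev = feat.SlowOscillationEvent(10.0, 25.0, -50, 60, 0.5, 0.5)
        out = feat.so_percentage([ev], self._ep())
        assert out.values[0] == pytest.approx(0.5)
        assert np.all(out.values[1:] == 0)

    def test_boundary_straddling_split(self):
        # event spans 28 s .. 33 s: 2 s in epoch 0, 3 s in epoch 1
        ev = feat.SlowOscillationEvent(28.0, 33.0, -50, 60, 0.5, 0.5)
        out = feat.so_percentage([ev], self._ep())
        assert out.values[0] == pytest.approx(2.0 / 30.0)
        assert out.values[1] == pytest.approx(3.0 / 30.0)

    def test_total_duration_conserved(self, rng):
        ep = self._ep(10)
        events = []
        for _ in range(20):
            start = rng.uniform(0, 290)
            events.append(
                feat.SlowOscillationEvent(start, start + rng.uniform(0.5, 5), -50, 60, 0.5, 0.5)
            )
        out = feat.so_percentage(events, ep)
        total = sum(ev.duration_s for ev in events)
        assert out.values.sum() * 30.0 == pytest.approx(total, rel=1e-9)


class TestStdOsc:
    def test_flat_row_is_zero(self):
        dec = make_decomposition(np.full((3, 251), 2.0))
        np.testing.assert_allclose(feat.std_osc(dec).values, 0.0, atol=1e-12)

    def test_bump_raises_std(self):
        with_bump = _osc_with_bumps([14.0] * 5)
        flat = make_decomposition(np.zeros((5, 251)))
        assert np.all(feat.std_osc(with_bump).values > feat.std_osc(flat).values)

    def test_std_overall_is_matrix_std(self, rng):
        osc = rng.normal(size=(7, 251))
        dec = make_decomposition(osc)
        assert feat.std_overall(dec) == pytest.approx(osc.std(ddof=0))


class TestArtifactGuard:
    def test_flags_large_amplitude_epochs(self):
        x = np.zeros((3, 3000))
        x[1, 100] = 600.0
        mask = feat.artifact_epochs(EpochedSignal(x, FS), amplitude_uv=500.0)
        np.testing.assert_array_equal(mask, [False, True, False])
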