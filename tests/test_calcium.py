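import numpy as np
import pytest

from ntpipe import calcium as ca
from ntpipe.calcium_sim import CalciumScenario, CellSpec, simulate_calcium_movie


def _movie(frames, stim_frame=110, background=0.0, frame_rate=10.0):
    return ca.CalciumMovie(
        frames=frames, stim_frame=stim_frame, background=background, frame_rate=frame_rate
    )


def _square(r0, c0, r1, c1):
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], float)


class TestNormalizeStack:
    def test_constant_movie_normalizes_to_zero(self):
        dff = ca.normalize_stack(_movie(np.full((150, 8, 8), 100.0)))
        assert np.allclose(dff.frames, 0.0)

    def test_peak_arithmetic(self):
        """Baseline 100 after background subtraction, peak frame 475:
        dF/F0 = 475/100 - 1 = 3.75."""
        frames = np.full((150, 4, 4), 110.0)
        frames[140] = 485.0
        dff = ca.normalize_stack(_movie(frames, background=10.0))
        assert dff.frames[140].max() == pytest.approx(3.75)

    def test_insufficient_baseline_rejected(self):
        frames = np.full((150, 4, 4), 50.0)
        with pytest.raises(ValueError, match="insufficient baseline"):
            ca.normalize_stack(_movie(frames), baseline_n=200)

    def test_zero_f0_pixels_flagged_invalid(self):
        frames = np.full((150, 4, 4), 100.0)
        frames[:, 0, 0] = 0.0
        dff = ca.normalize_stack(_movie(frames))
        assert not dff.valid[0, 0] and dff.valid[1, 1]
        with pytest.raises(ValueError, match="F0"):
            ca.normalize_stack(_movie(np.zeros((150, 4, 4))))

    def test_simulator_truth_recovered_to_machine_precision(self):
        """Noise-free simulated movie: normalization reproduces the
        generator's dF/F0 field exactly inside cells."""
        sc = CalciumScenario(
            cells=[CellSpec("c", (6.0, 6.0), 4.0, peak_dff=2.0, stimulated=True)],
            stim_frame=110,
            n_frames=200,
            shape=(72, 72),
            pixel_size=0.166,
        )
        movie, truth = simulate_calcium_movie(sc)
        dff = ca.normalize_stack(movie)
        assert dff.frames.max() == pytest.approx(2.0, abs=1e-9)
        pre = np.abs(dff.frames[:110]).max()
        assert pre < 1e-9


class TestRoiTrace:
    def test_uniform_value_inside_roi(self):
        frames = np.full((150, 10, 10), 100.0)
        frames[120] = 150.0
        dff = ca.normalize_stack(_movie(frames))
        tr = ca.roi_trace(dff, _square(2, 2, 7, 7))
        assert tr.trace[120] == pytest.approx(0.5)
        assert tr.trace[0] == pytest.approx(0.0)

    def test_two_region_mean(self):
        frames = np.full((150, 10, 10), 100.0)
        frames[120, :, :5] = 100.0 * (1 + 0.4)  # a = 0.4
        frames[120, :, 5:] = 100.0 * (1 + 0.8)  # b = 0.8
        dff = ca.normalize_stack(_movie(frames))
        tr = ca.roi_trace(dff, _square(0, 0, 10, 10))
        assert tr.trace[120] == pytest.approx(0.6, abs=1e-6)

    def test_roi_outside_image_rejected(self):
        dff = ca.normalize_stack(_movie(np.full((150, 8, 8), 100.0)))
        with pytest.raises(ValueError):
            ca.roi_trace(dff, _square(50, 50, 60, 60))


class TestPeakAndLag:
    def _trace_with_peak(self, peak_frame, amp=1.0, n=800):
        t = np.zeros(n)
        t[peak_frame] = amp
        t[peak_frame - 1] = t[peak_frame + 1] = amp * 0.6
        return ca.RoiTrace("r", _square(0, 0, 2, 2), t, 10.0, 110)

    def test_constructed_45s_lag(self):
        """Stimulated peak at 22 s + rise; responder peaking 45 s later
        reports lag = 45 s."""
        stim = self._trace_with_peak(270)
        resp = self._trace_with_peak(720)
        _, _, lag = ca.peak_and_lag(stim, resp)
        assert lag == pytest.approx(45.0)

    def test_identical_traces_zero_lag(self):
        a = self._trace_with_peak(300)
        b = self._trace_with_peak(300)
        _, _, lag = ca.peak_and_lag(a, b)
        assert lag == 0.0

    def test_flat_responder_lag_undefined(self):
        stim = self._trace_with_peak(300)
        flat = ca.RoiTrace("f", _square(0, 0, 2, 2), np.zeros(800), 10.0, 110)
        _, _, lag = ca.peak_and_lag(stim, flat)
        assert lag is None and flat.responder is False

    def test_argmax_tie_takes_earliest_frame(self):
        t = np.zeros(400)
        t[200] = t[250] = 2.0
        tr = ca.RoiTrace("r", _square(0, 0, 2, 2), t, 10.0, 110)
        amp, peak_t = ca.measure_peak(tr.trace, 110, 10.0)
        assert peak_t == pytest.approx(20.0)


class TestResponderClassification:
    def _noisy_trace(self, rng, sigma=0.05, n=400, stim=110):
        return ca.RoiTrace("r", _square(0, 0, 2, 2), rng.normal(0, sigma, n), 10.0, stim)

    def test_step_of_10_sigma_is_responder(self):
        rng = np.random.default_rng(0)
        tr = self._noisy_trace(rng)
        tr.trace[150:] += 0.5  # 10 sigma
        assert ca.classify_responder(tr) is True

    def test_single_frame_excursion_rejected_by_sustain_rule(self):
        tr = ca.RoiTrace("r", _square(0, 0, 2, 2), np.zeros(400), 10.0, 110)
        tr.trace[:110] = np.tile([0.01, -0.01], 55)  # nonzero baseline sd
        sd = tr.trace[:110].std(ddof=1)
        tr.trace[200] = tr.trace[:110].mean() + 5.0 * sd  # not above, 1 frame
        assert ca.classify_responder(tr) is False

    def test_null_false_positive_rate_below_1_percent(self):
        """Flat noisy traces: the 5-sigma/3-frame rule fires in < 1% of
        1000 simulated null movies."""
        rng = np.random.default_rng(123)
        fp = sum(
            ca.classify_responder(self._noisy_trace(rng)) for _ in range(1000)
        )
        assert fp / 1000 < 0.01


class TestKymograph:
    def _ramp_dff(self):
        frames = np.full((160, 32, 32), 100.0)
        ramp = np.linspace(0, 0.5, 50)
        frames[110:] *= (1.0 + ramp)[:, None, None]
        return ca.normalize_stack(_movie(frames))

    def test_uniform_ramp_rows_constant_increasing(self):
        dff = self._ramp_dff()
        kym = ca.kymograph(dff, np.array([[16.0, 4.0], [16.0, 28.0]]), width_px=5)
        assert np.allclose(kym.data[120], kym.data[120, 0])
        col = kym.data[110:, 3]
        assert np.all(np.diff(col) >= -1e-12) and col[-1] > col[0]

    def test_even_width_rejected(self):
        dff = self._ramp_dff()
        with pytest.raises(ValueError, match="odd"):
            ca.kymograph(dff, np.array([[16.0, 4.0], [16.0, 28.0]]), width_px=4)

    def test_band_width_15px_at_0166um_is_2_49um(self):
        """The standard 15-pixel band at 0.166 um/pixel spans 2.49 um,
        matching the ~2.4 um analysis band."""
        assert 15 * 0.166 == pytest.approx(2.49)

    def test_band_mean_matches_direct_mean(self):
        """Mean of the kymograph equals the mean dF/F0 over the same band
        computed directly (axis-aligned band, no interpolation error)."""
        dff = self._ramp_dff()
        kym = ca.kymograph(dff, np.array([[16.0, 4.0], [16.0, 28.0]]), width_px=5)
        direct = dff.frames[:, 14:19, 4:29].mean(axis=(1, 2))
        np.testing.assert_allclose(kym.data.mean(axis=1), direct, atol=1e-9)

    def test_wave_slope_matches_speed(self):
        """A wave crossing the band at speed v produces a kymograph ridge
        of slope 1/v."""
        h, w, n = 24, 120, 200
        pix, rate, v = 0.166, 10.0, 2.0  # um, Hz, um/s
        frames = np.full((n, h, w), 100.0)
        cols = np.arange(w) * pix
        for t in range(110, n):
            front = (t - 110) / rate * v
            frames[t, :, cols <= front] = 200.0
        dff = ca.normalize_stack(_movie(frames))
        kym = ca.kymograph(dff, np.array([[12.0, 0.0], [12.0, 119.0]]), width_px=5)
        onset_rows = np.argmax(kym.data > 0.5, axis=0)  # first frame > half rise
        cols_px = np.arange(kym.data.shape[1])
        sel = onset_rows > 110
        slope = np.polyfit(cols_px[sel] * kym.um_per_col, onset_rows[sel] * kym.s_per_row, 1)[0]
        assert slope == pytest.approx(1.0 / v, rel=0.05)


class TestInitiationDistance:
    def _scenario(self, offset_um):
        r = 8.0
        center = (10.0, 12.0)
        contact = (center[0], center[1] - r)
        init = (center[0], center[1] - r + offset_um)
        sc = CalciumScenario(
            cells=[
                CellSpec(
                    "resp", center, r, peak_dff=1.2, lag_s=10.0,
                    init_point_um=init, connected=True,
                )
            ],
            stim_frame=110,
            n_frames=300,
            shape=(124, 150),
        )
        return sc, contact

    def test_wave_seeded_at_contact_measures_zero(self):
        sc, contact = self._scenario(0.0)
        movie, truth = simulate_calcium_movie(sc)
        dff = ca.normalize_stack(movie)
        d, _ = ca.initiation_distance(dff, truth[0].polygon_px, contact)
        assert d <= 0.166

    def test_seeded_offset_recovered_within_one_pixel(self):
        sc, contact = self._scenario(6.18)
        movie, truth = simulate_calcium_movie(sc)
        dff = ca.normalize_stack(movie)
        d, diag = ca.initiation_distance(dff, truth[0].polygon_px, contact)
        assert d == pytest.approx(6.18, abs=0.166)
        assert not diag["ambiguous"]

    def test_no_threshold_crossing_raises(self):
        frames = np.full((150, 32, 32), 100.0)
        dff = ca.normalize_stack(_movie(frames))
        with pytest.raises(ValueError, match="no initiation site"):
            ca.initiation_distance(dff, _square(4, 4, 28, 28), (1.0, 1.0))


class TestPairedTTest:
    def test_identical_samples_convention(self):
        res = ca.paired_ttest(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        res = ca.paired_ttest(np.arange(4.0) + 1.0, np.arange(4.0))
        assert np.isinf(res.t) and res.p == 0.0 and res.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ca.paired_ttest(np.array([1.0]), np.array([2.0]))

    def test_matches_scipy_on_regular_data(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 12))
        res = ca.paired_ttest(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 11
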