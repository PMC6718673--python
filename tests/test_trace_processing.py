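"""Trace-processing chain: background subtraction, SWT denoising, dF*, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinsig as ts
from twinsig.errors import (
    CalibrationError,
    DegenerateBaselineError,
    IncompleteProtocolError,
    SchedulingError,
    StructuralError,
    TraceInputError,
)


def make_recording(cells, backgrounds, dt=0.5, events=None):
    return ts.ImagingRecording(
        sampling_interval=dt,
        cell_traces={f"c{i}": np.asarray(v, float) for i, v in enumerate(cells)},
        background_traces=[np.asarray(v, float) for v in backgrounds],
        events=events or [],
    )


class TestSubtractBackground:
    def test_zero_background_leaves_cells_unchanged(self):
        rec = make_recording([np.arange(10.0)], [np.zeros(10), np.zeros(10)])
        out = ts.subtract_background(rec)
        np.testing.assert_array_equal(out.cell_traces["c0"], np.arange(10.0))

    def test_constant_example(self):
        rec = make_recording([np.full(8, 5.0)],
                             [np.full(8, 1.0), np.full(8, 2.0), np.full(8, 3.0)])
        out = ts.subtract_background(rec)
        np.testing.assert_allclose(out.cell_traces["c0"], 3.0)
        # backgrounds retained for audit
        assert len(out.background_traces) == 3

    def test_matches_elementwise_loop_oracle(self, rng):
        cells = [rng.normal(size=40) for _ in range(4)]
        bgs = [rng.normal(size=40) for _ in range(3)]
        out = ts.subtract_background(make_recording(cells, bgs))
        for i, cell in enumerate(cells):
            expected = [cell[t] - sum(b[t] for b in bgs) / 3 for t in range(40)]
            np.testing.assert_allclose(out.cell_traces[f"c{i}"], expected, atol=1e-12)

    def test_length_mismatch_is_structural_error(self):
        with pytest.raises(StructuralError):
            make_recording([np.zeros(10)], [np.zeros(9)])


def naive_swt_denoise(x, level=3):
    """Independent stationary-Haar denoiser: explicit circular filtering,
    per-level universal soft thresholds, averaged redundant inverse."""
    x = np.asarray(x, float)
    n = len(x)
    a = x.copy()
    details = []
    for j in range(level):
        step = 2 ** j
        details.append(0.5 * (a - np.roll(a, -step)))
        a = 0.5 * (a + np.roll(a, -step))
    lam = math.sqrt(2 * math.log(n))
    shrunk = []
    for d in details:
        t = lam * np.median(np.abs(d)) / 0.6745
        shrunk.append(np.sign(d) * np.maximum(np.abs(d) - t, 0.0) if t > 0 else d)
    for j in reversed(range(level)):
        step = 2 ** j
        d = shrunk[j]
        a = 0.5 * ((a + d) + np.roll(a - d, step))
    return a


class TestDenoise:
    def test_zero_input_gives_zero_output(self):
        out = ts.denoise(np.zeros(100))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_perfect_reconstruction_with_thresholds_off(self, rng):
        x = rng.normal(size=333)  # odd length exercises the padding path
        out = ts.denoise(x, ts.DenoiseConfig(threshold_scale=0.0))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(size=1024)
        out = ts.denoise(x)
        assert np.var(out) < 0.15 * np.var(x)

    @pytest.mark.parametrize("n", [64, 256, 1024])
    def test_matches_independent_swt_oracle(self, rng, n):
        # lengths divisible by 2^level so both routes see the same series
        x = rng.normal(size=n) + np.sin(np.arange(n) / 9.0)
        np.testing.assert_allclose(ts.denoise(x), naive_swt_denoise(x), atol=1e-12)

    def test_single_level_rescaling_mode(self, rng):
        x = rng.normal(size=256)
        out = ts.denoise(x, ts.DenoiseConfig(rescaling="single-level"))
        assert out.shape == x.shape
        assert np.var(out) < np.var(x)

    def test_output_length_equals_input_length(self, rng):
        for n in (17, 100, 511):
            assert len(ts.denoise(rng.normal(size=n))) == n

    def test_nonfinite_input_rejected(self):
        with pytest.raises(TraceInputError):
            ts.denoise(np.array([1.0, np.nan, 2.0]))

    def test_idempotence_bound_on_white_noise(self, rng):
        x = rng.normal(size=512)
        once = ts.denoise(x)
        twice = ts.denoise(once)
        assert np.var(once - twice) <= np.var(x - once) + 1e-12


class TestComputeResponse:
    WINDOWS = ts.ResponseWindows(post_window=20.0, pre_window=50.0)

    def test_constant_series_gives_zero(self):
        x = np.full(300, 2.5)
        ev = ts.StimulusEvent("GABA", onset=60.0)
        m = ts.compute_response(x, ev, self.WINDOWS, sampling_interval=0.5)
        assert m.dF_star == 0.0

    def test_direct_substitution(self):
        # f0 = 1.0 before onset, max 3.0 inside the post window
        x = np.ones(300)
        x[130] = 3.0  # t = 65 s, within (60, 80]
        ev = ts.StimulusEvent("GABA", onset=60.0)
        m = ts.compute_response(x, ev, self.WINDOWS, sampling_interval=0.5)
        assert m.f == 3.0 and m.f0 == 1.0 and m.dF_star == 2.0

    def test_noiseless_transient_closed_form(self, noiseless_cfg):
        # amplitude A on baseline b -> dF* = A/b via brute-force extrema
        cfg = noiseless_cfg
        rec = ts.simulate_recording(cfg, [ts.StimulusEvent("GABA", 60.0)], seed=0)
        sub = ts.subtract_background(rec)
        trace = sub.cell_traces["cell_000"]
        den = ts.denoise(trace)
        m = ts.compute_response(den, rec.events[0], self.WINDOWS, cfg.sampling_interval)
        t = rec.times()
        post = trace[(t > 60.0) & (t <= 80.0)]
        pre = trace[(t >= 10.0) & (t <= 60.0)]
        brute = (post.max() - pre.min()) / pre.min()
        assert m.dF_star == pytest.approx(0.5 / 1.0, abs=1e-6)
        assert m.dF_star == pytest.approx(brute, abs=1e-6)

    def test_window_out_of_range_raises(self):
        x = np.ones(100)
        with pytest.raises(SchedulingError):
            ts.compute_response(x, ts.StimulusEvent("KCl", onset=10.0),
                                self.WINDOWS, sampling_interval=0.5)

    def test_nonpositive_baseline_raises(self):
        x = np.zeros(300)
        with pytest.raises(DegenerateBaselineError):
            ts.compute_response(x, ts.StimulusEvent("KCl", onset=60.0),
                                self.WINDOWS, sampling_interval=0.5)

    @given(c=st.floats(min_value=0.1, max_value=50.0),
           seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c, seed):
        # multiplying all traces by c > 0 leaves dF* unchanged
        rng = np.random.default_rng(seed)
        x = 1.0 + np.abs(rng.normal(0, 0.2, 300)) + 0.5 * rng.random()
        ev = ts.StimulusEvent("GABA", onset=60.0)
        m1 = ts.compute_response(x, ev, self.WINDOWS, 0.5)
        m2 = ts.compute_response(c * x, ev, self.WINDOWS, 0.5)
        assert m2.dF_star == pytest.approx(m1.dF_star, rel=1e-12)

    def test_shift_invariance(self, rng):
        # shifting event and series together by a whole number of frames
        x = 1.0 + np.abs(rng.normal(0, 0.2, 400))
        shift_frames = 40  # 20 s at 0.5 s sampling
        shifted = np.concatenate([np.full(shift_frames, x[0]), x])[: len(x)]
        m1 = ts.compute_response(x, ts.StimulusEvent("GABA", 60.0), self.WINDOWS, 0.5)
        m2 = ts.compute_response(shifted, ts.StimulusEvent("GABA", 80.0),
                                 self.WINDOWS, 0.5)
        assert m2.dF_star == pytest.approx(m1.dF_star, rel=1e-12)
        assert m2.f == pytest.approx(m1.f, rel=1e-12)
        assert m2.f0 == pytest.approx(m1.f0, rel=1e-12)


class TestClassifyAndCalibrate:
    def mk(self, agent, v):
        return ts.ResponseMeasure(agent=agent, dF_star=v, f=1 + v, f0=1.0)

    def test_zero_kcl_is_non_neuron(self):
        assert not ts.classify_neuron(self.mk("KCl", 0.0), self.mk("ionomycin", 2.0),
                                      min_ratio=0.01)

    def test_clear_neuron(self):
        assert ts.classify_neuron(self.mk("KCl", 1.0), self.mk("ionomycin", 2.0),
                                  min_ratio=0.1)

    def test_nonpositive_ionomycin_raises(self):
        with pytest.raises(CalibrationError):
            ts.classify_neuron(self.mk("KCl", 1.0), self.mk("ionomycin", 0.0))

    def test_classifier_recovers_simulated_labels(self, rng):
        cfg = ts.TraceSimConfig(noise_sd=0.0, neuron_fraction=0.8, n_cells=10)
        rec = ts.simulate_recording(cfg, seed=11)
        df = ts.process_recording(rec)
        got = df.groupby("roi_id")["is_neuron"].first()
        truth = dict(zip(sorted(rec.cell_traces), rec.metadata["is_neuron"]))
        for roi, flag in got.items():
            assert flag == truth[roi]

    def test_equal_responses_give_unit_final_ratios(self):
        summary = ts.calibrate_cell({a: 0.7 for a in ts.AGENTS})
        assert all(v == pytest.approx(1.0) for v in summary.final.values())

    def test_zero_gaba_stays_zero(self):
        raw = {"GABA": 0.0, "KCl": 1.0, "ionomycin": 2.0}
        assert ts.calibrate_cell(raw).final["GABA"] == 0.0

    def test_missing_calibrator_raises(self):
        with pytest.raises(IncompleteProtocolError):
            ts.calibrate_cell({"GABA": 0.5, "KCl": 1.0})

    @given(gaba=st.floats(0.0, 5.0), kcl=st.floats(0.05, 5.0),
           iono=st.floats(0.05, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_ionomycin_cancels_in_final_ratio(self, gaba, kcl, iono):
        raw = {"GABA": gaba, "KCl": kcl, "ionomycin": iono}
        summary = ts.calibrate_cell(raw)
        assert summary.final["GABA"] == pytest.approx(gaba / kcl, rel=1e-12)
        assert summary.iono_calibrated["GABA"] == pytest.approx(gaba / iono, rel=1e-12)
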