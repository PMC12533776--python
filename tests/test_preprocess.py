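import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilvr import GenerativeParams, PipelineConfig
from pupilvr.preprocess import (TraceUnusableError, baseline_correct,
                                compute_bps, crop_window, drop_first_trials,
                                extend_blink_margins, interpolate_marked,
                                preprocess_condition, qc_flag_condition,
                                qc_flag_trace, regrid_60hz,
                                smooth_moving_average)
from pupilvr.synth import make_schedule, simulate_trace

from conftest import make_trace, uniform_trace


class TestTraceQC:
    @pytest.mark.parametrize("n_marked,keep", [(180, True), (181, False), (0, True)])
    def test_20_percent_rule_is_strict(self, pipeline, n_marked, keep):
        """Exclusion requires strictly more than 20% marked samples."""
        n = 900
        marked = np.zeros(n, bool)
        marked[:n_marked] = True
        t = -3.0 + np.arange(n) / 125.0
        d = np.where(marked, np.nan, 4.0)
        tr = make_trace(t, d, marked)
        assert qc_flag_trace(tr, pipeline) is keep

    @pytest.mark.parametrize("n_bad,keep", [(5, True), (6, False), (30, False)])
    def test_condition_exclusion_at_six(self, pipeline, n_bad, keep):
        decisions = [False] * n_bad + [True] * (30 - n_bad)
        assert qc_flag_condition(decisions, pipeline) is keep


class TestBlinkMargins:
    def test_no_marks_unchanged(self, pipeline):
        tr = uniform_trace()
        out = extend_blink_margins(tr, pipeline)
        assert not out.marked.any()

    def test_margin_arithmetic(self, pipeline):
        """A run spanning [1.000, 1.050] marks everything in [0.917, 1.183]."""
        fs = 60.0
        tr = uniform_trace(fs=fs)
        run = (tr.t_s >= 1.0 - 1e-9) & (tr.t_s <= 1.05 + 1e-9)
        tr.marked[:] = False
        tr.marked |= run
        out = extend_blink_margins(tr, pipeline)
        lo = tr.t_s[run][0] - 0.083
        hi = tr.t_s[run][-1] + 0.133
        expect = (tr.t_s >= lo - 1e-9) & (tr.t_s <= hi + 1e-9)
        np.testing.assert_array_equal(out.marked, expect)

    def test_clipped_at_trace_start(self, pipeline):
        tr = uniform_trace()
        tr.marked[:3] = True
        out = extend_blink_margins(tr, pipeline)
        assert out.marked[0]  # no error, clipped at -3.0
        assert out.marked.sum() < out.marked.size

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.data())
    def test_marked_set_only_grows(self, data):
        pipeline = PipelineConfig()
        n = 200
        idx = data.draw(st.lists(st.integers(0, n - 1), max_size=30))
        marked = np.zeros(n, bool)
        marked[idx] = True
        t = -3.0 + np.arange(n) / 90.0
        tr = make_trace(t, np.where(marked, np.nan, 4.0), marked)
        out = extend_blink_margins(tr, pipeline)
        assert np.all(out.marked[marked])


class TestRegrid:
    def test_affine_signal_exact(self, pipeline):
        t = -3.0 + np.arange(700) / 90.0
        tr = make_trace(t, 4.0 + 0.1 * t)
        g = regrid_60hz(tr, pipeline)
        np.testing.assert_allclose(g.values_mm, 4.0 + 0.1 * g.grid_s, atol=1e-9)
        assert g.grid_s[0] == -3.0
        np.testing.assert_allclose(np.diff(g.grid_s), 1 / 60, atol=1e-12)

    def test_constant_signal(self, pipeline):
        g = regrid_60hz(uniform_trace(), pipeline)
        np.testing.assert_allclose(g.values_mm, 4.0)

    def test_mark_propagation(self, pipeline):
        tr = uniform_trace(fs=90.0)
        src_run = (tr.t_s >= 1.0) & (tr.t_s <= 1.2)
        tr.marked |= src_run
        tr.diameter_mm[src_run] = np.nan
        g = regrid_60hz(tr, pipeline)
        inside = (g.grid_s > 1.0) & (g.grid_s < 1.2)
        assert g.marked[inside].all()
        assert np.isnan(g.values_mm[inside]).all()
        far = np.abs(g.grid_s - 1.1) > 0.5
        assert not g.marked[far].any()

    def test_unusable_when_everything_marked(self, pipeline):
        tr = uniform_trace()
        tr.marked[:] = True
        tr.diameter_mm[:] = np.nan
        with pytest.raises(TraceUnusableError):
            regrid_60hz(tr, pipeline)


class TestInterpolate:
    def test_midpoint(self, pipeline):
        tr = uniform_trace(fs=60.0)
        g = regrid_60hz(tr, pipeline)
        g.values_mm[:] = 4.0
        g.values_mm[100] = np.nan
        g.marked[100] = True
        g.values_mm[99], g.values_mm[101] = 4.0, 5.0
        out = interpolate_marked(g)
        assert out.values_mm[100] == pytest.approx(4.5)

    def test_leading_run_held(self, pipeline):
        g = regrid_60hz(uniform_trace(fs=60.0), pipeline)
        g.marked[:2] = True
        g.values_mm[:2] = np.nan
        g.values_mm[2] = 4.2
        out = interpolate_marked(g)
        np.testing.assert_allclose(out.values_mm[:2], 4.2)

    def test_no_marks_identity(self, pipeline):
        g = regrid_60hz(uniform_trace(), pipeline)
        out = interpolate_marked(g)
        np.testing.assert_array_equal(out.values_mm, g.values_mm)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 400))
    def test_interior_runs_bounded_by_anchors(self, seed):
        pipeline = PipelineConfig()
        rng = np.random.default_rng(seed)
        g = regrid_60hz(uniform_trace(), pipeline)
        g.values_mm[:] = rng.uniform(3, 6, g.values_mm.size)
        start = int(rng.integers(1, g.values_mm.size - 20))
        length = int(rng.integers(1, 15))
        g.marked[start:start + length] = True
        g.values_mm[start:start + length] = np.nan
        out = interpolate_marked(g)
        lo = min(g.values_mm[start - 1], g.values_mm[start + length])
        hi = max(g.values_mm[start - 1], g.values_mm[start + length])
        seg = out.values_mm[start:start + length]
        assert np.all(seg >= lo - 1e-12) and np.all(seg <= hi + 1e-12)


class TestBPS:
    def test_constant(self, pipeline):
        g = interpolate_marked(regrid_60hz(uniform_trace(), pipeline))
        assert compute_bps(g, pipeline) == pytest.approx(4.0)

    def test_linear_ramp_matches_discrete_mean_oracle(self, pipeline):
        """BPS of a ramp equals the brute-force mean over the 60 grid points."""
        t = -3.0 + np.arange(700) / 90.0
        ramp = 4.0 + 1.0 * (t + 1.0)  # 4.0 at t=-1, 5.0 at t=0
        tr = make_trace(t, np.maximum(ramp, 0.1))
        g = interpolate_marked(regrid_60hz(tr, pipeline))
        expected = np.mean([4.0 + (1.0 + gt) for gt in g.grid_s
                            if -1.0 - 1e-9 <= gt < -1e-9])
        assert compute_bps(g, pipeline) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(4.5 - 1 / 120, abs=1e-6)

    def test_sentence_onset_sample_excluded(self, pipeline):
        g = interpolate_marked(regrid_60hz(uniform_trace(), pipeline))
        onset = np.argmin(np.abs(g.grid_s))
        g.values_mm[onset] = 100.0  # would shift the mean if included
        assert compute_bps(g, pipeline) == pytest.approx(4.0)


class TestBaselineAndSmooth:
    def test_baseline_zeroes_constant(self, pipeline):
        g = interpolate_marked(regrid_60hz(uniform_trace(), pipeline))
        out = baseline_correct(g, compute_bps(g, pipeline))
        np.testing.assert_allclose(out.values_mm, 0.0, atol=1e-12)
        assert compute_bps(out, pipeline) == pytest.approx(0.0, abs=1e-12)

    def test_double_correction_guarded(self, pipeline):
        g = interpolate_marked(regrid_60hz(uniform_trace(), pipeline))
        out = baseline_correct(g, 4.0)
        with pytest.raises(ValueError, match="already"):
            baseline_correct(out, 4.0)

    def test_smooth_constant_identity(self):
        np.testing.assert_allclose(smooth_moving_average(np.full(50, 3.3), 11), 3.3)

    def test_smooth_impulse_response(self):
        v = np.zeros(21)
        v[10] = 1.0
        out = smooth_moving_average(v, 11)
        np.testing.assert_allclose(out[5:16], 1 / 11)
        assert out[4] == 0.0 and out[16] == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_smooth_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=int(rng.integers(1, 80)))
        out = smooth_moving_average(v, 11)
        brute = np.empty_like(v)
        n = v.size
        for i in range(n):
            h = min(5, i, n - 1 - i)
            brute[i] = v[i - h:i + h + 1].mean()
        np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_smooth_shrinks_white_noise_variance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200_000)
        interior = smooth_moving_average(v, 11)[5:-5]
        assert interior.var() == pytest.approx(1 / 11, rel=0.05)


class TestDropCrop:
    def test_thirty_in_26_out(self, pipeline, gen_params, rng):
        plan = make_schedule(0, gen_params, rng)
        quiet = GenerativeParams(blink_rate_hz=0.0)
        traces = [simulate_trace(t, quiet, rng)
                  for t in plan.trials_of("single", "distractors")]
        kept = drop_first_trials(traces, pipeline)
        assert len(traces) == 30 and len(kept) == 26
        assert min(t.trial_index for t in kept) == 5
        assert drop_first_trials(kept, pipeline) == kept  # already dropped

    def test_crop_window_is_7_2_seconds(self, pipeline):
        g = regrid_60hz(uniform_trace(t1=5.0), pipeline)
        out = crop_window(g, pipeline)
        assert out.grid_s[0] == pytest.approx(-3.0)
        assert out.grid_s[-1] == pytest.approx(4.2)
        assert out.grid_s.size == 433  # 7.2 s at 60 Hz inclusive
        assert np.all(out.grid_s <= 4.2 + 1e-9)  # 4.21 would be dropped

    def test_short_trace_rejected(self, pipeline):
        g = regrid_60hz(uniform_trace(t1=3.0), pipeline)
        with pytest.raises(TraceUnusableError, match="before"):
            crop_window(g, pipeline)


class TestConditionPipeline:
    def _quiet_condition(self, rng, n=30):
        quiet = GenerativeParams(tau_bps_mm=0.0, sigma_bps_mm=0.0,
                                 tau_amp_mm=0.0, sigma_amp_mm=0.0,
                                 sample_noise_mm=0.0, blink_rate_hz=0.0,
                                 jitter_sd_s=0.0)
        plan = make_schedule(0, quiet, rng)
        return [simulate_trace(t, quiet, rng)
                for t in plan.trials_of("single", "distractors")[:n]], quiet

    def test_noise_free_end_to_end(self, pipeline, rng):
        traces, quiet = self._quiet_condition(rng)
        clean, report = preprocess_condition(traces, pipeline)
        assert len(clean) == 26
        assert not report.condition_excluded
        mu_b = quiet.bps_effects_mm[0]  # single/distractors reference cell
        for ct in clean:
            assert ct.bps_mm == pytest.approx(mu_b, abs=1e-9)
            assert ct.grid_s.size == 433

    def test_condition_with_six_bad_traces_excluded(self, pipeline, rng):
        traces, _ = self._quiet_condition(rng)
        for tr in traces[:6]:
            k = int(0.25 * tr.n_samples)
            tr.marked[:k] = True
            tr.diameter_mm[:k] = np.nan
        clean, report = preprocess_condition(traces, pipeline)
        assert clean == []
        assert report.condition_excluded
        assert any(stage == "condition_qc" for _, stage, _ in report.entries)

    def test_determinism(self, pipeline, rng):
        traces, _ = self._quiet_condition(rng)
        a, _ = preprocess_condition(traces, pipeline)
        b, _ = preprocess_condition(traces, pipeline)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values_mm, y.values_mm)

    def test_shift_equivariance(self, pipeline, rng):
        """Adding a constant to every raw diameter leaves the
        baseline-corrected output unchanged (BPS absorbs the shift)."""
        plan = make_schedule(0, GenerativeParams(), rng)
        params = GenerativeParams()
        traces = [simulate_trace(t, params, rng)
                  for t in plan.trials_of("dual", "agents")]
        shifted = []
        for tr in traces:
            shifted.append(dataclasses.replace(
                tr, t_s=tr.t_s.copy(), marked=tr.marked.copy(),
                diameter_mm=tr.diameter_mm + 2.5))
        a, _ = preprocess_condition(traces, pipeline)
        b, _ = preprocess_condition(shifted, pipeline)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.values_mm, y.values_mm, atol=1e-9)
            assert y.bps_mm == pytest.approx(x.bps_mm + 2.5, abs=1e-9)
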