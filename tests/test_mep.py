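"""MEP extraction, excitability maps, hotspot search, and RMT estimation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knobmap import mep
from knobmap.config import GeneratorConfig
from knobmap.errors import AnalysisError, InputError
from knobmap.synthcohort import (_rng, mep_template, simulate_emg_session,
                                 simulate_subject)

FS = 10_000.0
STIM = 1000


def make_trace(post=None, pre=None, muscle="FDI"):
    pre = np.zeros(STIM) if pre is None else pre
    post = np.zeros(600) if post is None else post
    return mep.EMGTrace(np.concatenate([pre, post]), FS, STIM, muscle)


def trace_with_template(amplitude=1.0, onset_ms=22.6, noise_sd=0.0, rng=None):
    cfg = GeneratorConfig()
    tmpl = mep_template(cfg) * amplitude
    samples = np.zeros(1600)
    if noise_sd and rng is not None:
        samples = rng.normal(0.0, noise_sd, 1600)
    i0 = STIM + int(round(onset_ms * 1e-3 * FS))
    samples[i0:i0 + len(tmpl)] += tmpl
    return mep.EMGTrace(samples, FS, STIM)


class TestArtifactRejection:
    def test_flat_zero_baseline_valid(self):
        assert mep.reject_artifact_trial(make_trace()) is True

    def test_constant_baseline_above_limit_invalid(self):
        tr = make_trace(pre=np.full(STIM, 0.05))
        assert mep.reject_artifact_trial(tr, 0.02) is False

    def test_gaussian_baseline_rarely_rejected(self, rng):
        """Baseline noise SD 0.01 mV concentrates its RMS near 0.01, far
        below the 0.02 mV limit; rejections should be (essentially) absent."""
        pre = rng.normal(0.0, 0.01, size=(10_000, STIM))
        rms = np.sqrt((pre ** 2).mean(axis=1))
        assert (rms > 0.02).mean() < 0.01

    def test_trace_too_short_rejected(self):
        with pytest.raises(InputError):
            mep.EMGTrace(np.zeros(700), FS, stimulus_index=100)


class TestAmplitude:
    def test_max_minus_min_in_window(self):
        post = np.zeros(600)
        post[150], post[200] = 0.8, -0.4
        assert mep.extract_amplitude(make_trace(post)) == pytest.approx(1.2)

    def test_all_zero_trace(self):
        assert mep.extract_amplitude(make_trace()) == 0.0

    def test_template_roundtrip(self):
        tr = trace_with_template(amplitude=1.0)
        assert mep.extract_amplitude(tr) == pytest.approx(1.0, abs=1e-3)

    @given(scale=st.floats(0.1, 10.0), offset=st.floats(-0.5, 0.5))
    @settings(deadline=None, max_examples=25)
    def test_offset_invariant_scale_equivariant(self, scale, offset):
        tr = trace_with_template(amplitude=1.0)
        base = mep.extract_amplitude(tr)
        tr2 = mep.EMGTrace(tr.samples * scale + offset, FS, STIM)
        assert mep.extract_amplitude(tr2) == pytest.approx(scale * base, rel=1e-9)


class TestLatency:
    def test_noise_free_onset_recovered_within_one_sample(self):
        tr = trace_with_template(amplitude=1.0, onset_ms=22.6)
        assert mep.estimate_latency(tr) == pytest.approx(22.6, abs=0.1)

    def test_all_zero_trace_absent(self):
        assert mep.estimate_latency(make_trace()) is None

    def test_latency_bounded_by_window(self, rng):
        for _ in range(50):
            tr = trace_with_template(amplitude=0.5,
                                     onset_ms=rng.uniform(12, 30),
                                     noise_sd=0.01, rng=rng)
            lat = mep.estimate_latency(tr)
            if lat is not None:
                assert 10.0 <= lat <= 40.0

    def test_snr_sweep_median_error(self, rng):
        """At 1 mV MEPs on 0.01 mV noise the onset error stays small."""
        errs = []
        for _ in range(1000):
            onset = rng.uniform(15.0, 30.0)
            tr = trace_with_template(1.0, onset, noise_sd=0.01, rng=rng)
            lat = mep.estimate_latency(tr)
            assert lat is not None
            errs.append(abs(lat - onset))
        assert np.median(errs) < 0.3


class TestMapAndHotspot:
    def test_identical_trials_mean(self, knob_grid):
        amps = np.full((5, 7, 20), np.nan)
        amps[2, 3] = 1.0
        emap = mep.build_map(amps)
        assert emap.mean_amplitude[2, 3] == pytest.approx(1.0)
        assert emap.n_valid_trials[2, 3] == 20
        assert emap.flagged.sum() == 34

    def test_two_trial_mean(self):
        amps = np.full((1, 1, 2), np.nan)
        amps[0, 0] = [0.5, 1.5]
        assert mep.build_map(amps).mean_amplitude[0, 0] == pytest.approx(1.0)

    def test_map_equals_bruteforce_average(self, rng, knob_grid):
        amps = rng.lognormal(0, 0.5, (5, 7, 20))
        invalid = rng.random((5, 7, 20)) < 0.1
        amps[invalid] = np.nan
        emap = mep.build_map(amps)
        for k in range(5):
            for i in range(7):
                good = amps[k, i][~np.isnan(amps[k, i])]
                if len(good):
                    assert emap.mean_amplitude[k, i] == pytest.approx(good.mean())

    def test_single_peak_hotspot(self, knob_grid):
        means = np.zeros((5, 7))
        means[2, 3] = 1.2
        emap = mep.ExcitabilityMap(means, np.full((5, 7), 20))
        hot = mep.find_hotspot(emap, knob_grid)
        assert (hot.line_index, hot.target_index) == (3, 4)
        assert hot.mean_amplitude == pytest.approx(1.2)

    def test_tie_breaks_posterior_then_medial(self, knob_grid):
        means = np.zeros((5, 7))
        means[1, 5] = means[3, 2] = 2.0
        hot = mep.find_hotspot(mep.ExcitabilityMap(means, np.full((5, 7), 20)),
                               knob_grid)
        assert (hot.line_index, hot.target_index) == (2, 6)
        assert hot.tie

    def test_all_sites_flagged_errors(self, knob_grid):
        emap = mep.ExcitabilityMap(np.full((5, 7), np.nan), np.zeros((5, 7)))
        with pytest.raises(AnalysisError):
            mep.find_hotspot(emap, knob_grid)

    def test_hotspot_invariant_under_monotone_rescale(self, rng, knob_grid):
        amps = rng.lognormal(0, 0.5, (5, 7, 20))
        h0 = mep.find_hotspot(mep.build_map(amps), knob_grid)
        h1 = mep.find_hotspot(mep.build_map(3.7 * amps ** 1.5), knob_grid)
        assert (h0.line_index, h0.target_index) == (h1.line_index, h1.target_index)

    def test_full_session_recovers_latency_and_amplitude(self, config, knob_grid):
        subj = simulate_subject(config, 11)
        traces = simulate_emg_session(subj, knob_grid, config, _rng(0, 11, 1),
                                      muscles=("FDI",))
        res = mep.analyze_session(traces["FDI"], knob_grid, stimulus_index=STIM)
        true_xy = np.array(subj.true_hotspot["FDI"])
        found_xy = res.hotspot.position[:2]
        assert np.linalg.norm(found_xy - true_xy) <= 5.0
        assert res.hotspot.shortest_latency == pytest.approx(
            subj.true_latency["FDI"], abs=1.5)


class TestRMT:
    def test_deterministic_step_responder(self):
        est = mep.estimate_rmt_pest(lambda i: i >= 58.0, n_trials=20)
        assert est.threshold == pytest.approx(58.0, abs=1.0)
        assert not est.flagged

    def test_logistic_responder_mae(self):
        model = mep.RecruitmentModel(58.0, 2.0)
        errs = [abs(mep.estimate_rmt_pest(
            model.responder(np.random.default_rng(i))).threshold - 58.0)
            for i in range(300)]
        assert np.mean(errs) <= 2.0

    def test_boundary_threshold_flagged(self):
        est = mep.estimate_rmt_pest(lambda i: False, n_trials=10)
        assert est.flagged
        est_hi = mep.estimate_rmt_pest(lambda i: True, n_trials=10)
        assert est_hi.flagged

    def test_invalid_recruitment_model(self):
        with pytest.raises(AnalysisError):
            mep.RecruitmentModel(0.0, 2.0)
        with pytest.raises(AnalysisError):
            mep.RecruitmentModel(58.0, -1.0)
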