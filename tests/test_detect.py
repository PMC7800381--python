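"""Spike detection: normalization contracts, dual-path candidates, merge
and artifact-rejection oracles, and the detector's statistical guarantees."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import match_events
from lfpburst import simulate
from lfpburst.detect import (
    SpikeTrain,
    compute_normalized_spectrogram,
    detect_amplitude_spikes,
    detect_spectral_spikes,
    detect_spikes,
    merge_and_sort,
    reject_stim_artifacts,
    robust_noise_sd,
)
from lfpburst.recording import StimulationProtocol


class TestNormalizedSpectrogram:
    fs = 1000.0

    def test_pure_tone_bin_saturates_while_tone_is_on(self):
        t = np.arange(0, 20, 1 / self.fs)
        x = np.sin(2 * np.pi * 10 * t)
        x[:5000] = 0.0   # tone off for the first 5 s
        spec = compute_normalized_spectrogram(x, self.fs, 0.5, 0.5)
        b = np.argmin(np.abs(spec.freqs - 10))
        on = spec.power[(spec.times > 6) & (spec.times < 19), b]
        off = spec.power[spec.times < 4, b]
        assert on.min() > 0.95
        assert off.max() < 0.05

    def test_constant_trace_normalizes_to_zero(self):
        spec = compute_normalized_spectrogram(np.full(5000, 3.7), self.fs)
        assert np.all(spec.power == 0)

    def test_every_varying_bin_attains_zero_and_one(self):
        rng = np.random.default_rng(0)
        spec = compute_normalized_spectrogram(rng.normal(size=20_000),
                                              self.fs)
        assert np.allclose(spec.power.min(axis=0), 0)
        assert np.allclose(spec.power.max(axis=0), 1)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(1)
        spec = compute_normalized_spectrogram(rng.normal(size=10_000),
                                              self.fs)
        lo = spec.power.min(axis=0)
        span = spec.power.max(axis=0) - lo
        again = np.where(span > 0, (spec.power - lo) / np.where(span, span, 1),
                         0.0)
        np.testing.assert_allclose(again, spec.power, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_normalized_spectrogram(np.zeros(100), self.fs, 0.25)


class TestSpectralPath:
    def test_flat_score_no_candidates(self):
        spec = compute_normalized_spectrogram(np.full(10_000, 1.0), 1000.0)
        out = detect_spectral_spikes(spec, np.full(10_000, 1.0), 1000.0)
        assert out.size == 0

    def test_single_spike_single_candidate(self):
        rec = simulate.generate_background(20, 2000.0, 0.0, seed=0)
        rec, gt = simulate.inject_burst(rec, 0, 10.0, 1, 0.5, 0, 5.0, seed=0)
        trace = rec.samples[0] + 1e-6 * np.random.default_rng(0).normal(
            size=rec.n_samples)
        spec = compute_normalized_spectrogram(trace, rec.fs)
        cand = detect_spectral_spikes(spec, trace, rec.fs)
        assert cand.size == 1
        assert abs(cand[0] - 10.0) <= 0.025

    def test_two_spikes_ordered(self):
        rec = simulate.generate_background(20, 2000.0, 0.0, seed=0)
        for t0 in (8.0, 12.0):
            rec, _ = simulate.inject_burst(rec, 0, t0, 1, 0.5, 0, 5.0, seed=0)
        trace = rec.samples[0] + 1e-6 * np.random.default_rng(0).normal(
            size=rec.n_samples)
        spec = compute_normalized_spectrogram(trace, rec.fs)
        cand = detect_spectral_spikes(spec, trace, rec.fs)
        assert cand.size == 2
        assert np.all(np.diff(cand) > 0)

    def test_band_outside_range_rejected(self):
        spec = compute_normalized_spectrogram(np.zeros(4000), 100.0)
        with pytest.raises(ValueError, match="band"):
            detect_spectral_spikes(spec, np.zeros(4000), 100.0,
                                   band_hz=(4, 400))


class TestAmplitudePath:
    def test_subthreshold_trace_empty(self):
        rng = np.random.default_rng(0)
        out = detect_amplitude_spikes(rng.normal(size=50_000) * 0.5, 1000.0,
                                      k_mad=8.0)
        assert out.size == 0

    def test_rectangular_pulse_detected_at_peak(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=20_000)
        sd = robust_noise_sd(trace)
        trace[10_000:10_050] += 10 * sd
        out = detect_amplitude_spikes(trace, 1000.0, k_mad=5.0,
                                      refractory_s=0.2)
        assert out.size == 1
        assert 10.0 <= out[0] <= 10.05

    def test_recall_on_injected_spikes(self):
        rec = simulate.generate_background(60, 2000.0, 1.0, seed=3)
        rec, gt = simulate.inject_burst(rec, 0, 5.0, 20, 2.5, 0.3, 6.0,
                                        seed=3)
        out = detect_amplitude_spikes(rec.samples[0], rec.fs, 5.0, 0.2)
        recall, _ = match_events(out, gt.spike_times["ch0"])
        assert recall >= 0.95

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_amplitude_spikes(np.empty(0), 1000.0)

    def test_monotone_in_k_mad(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(size=30_000)
        counts = [detect_amplitude_spikes(trace, 1000.0, k, 0.0).size
                  for k in (2.0, 3.0, 4.0, 5.0)]
        assert counts == sorted(counts, reverse=True)


def brute_force_merge(spectral, amplitude, window):
    """O(n^2) oracle: every amplitude time, plus spectral times farther than
    the window from every amplitude time, then collapse close pairs."""
    events = [(t, "amplitude") for t in amplitude]
    for t in spectral:
        if all(abs(t - a) > window for a in amplitude):
            events.append((t, "spectral"))
        # else absorbed into an amplitude event
    events.sort()
    out = []
    for t, src in events:
        if out and t - out[-1][0] <= window:
            continue
        out.append((t, src))
    return [t for t, _ in out]


class TestMergeAndArtifacts:
    def test_identical_lists_collapse_to_both(self):
        t = np.array([1.0, 2.0, 3.0])
        train = merge_and_sort(t, t, 0.05)
        assert train.times.tolist() == t.tolist()
        assert all(s == "both" for s in train.source)

    def test_disjoint_lists_concatenate(self):
        train = merge_and_sort(np.array([1.0, 5.0]), np.array([10.0, 20.0]),
                               0.05)
        assert train.n_spikes == 4
        assert set(train.source) == {"spectral", "amplitude"}

    def test_close_pair_collapses_to_amplitude_time(self):
        train = merge_and_sort(np.array([1.01]), np.array([1.0]), 0.05)
        assert train.times.tolist() == [1.0]
        assert train.source[0] == "both"

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_merge_matches_brute_force_times(self, data):
        n1 = data.draw(st.integers(0, 20))
        n2 = data.draw(st.integers(0, 20))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        spectral = np.sort(rng.uniform(0, 10, n1))
        amplitude = np.sort(rng.uniform(0, 10, n2))
        got = merge_and_sort(spectral, amplitude, 0.05).times
        expected = brute_force_merge(spectral, amplitude, 0.05)
        assert got.size == len(expected)
        np.testing.assert_allclose(got, expected)

    def test_empty_protocol_is_identity(self):
        train = SpikeTrain(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        out, removed = reject_stim_artifacts(train, None)
        assert removed == 0
        np.testing.assert_array_equal(out.times, train.times)

    def test_all_spikes_in_blank_windows_removed(self):
        protocol = StimulationProtocol(np.arange(10.0), 0.05, 1.0)
        train = SpikeTrain(np.arange(10) + 0.05,
                           np.ones(10))
        out, removed = reject_stim_artifacts(train, protocol, (0.01, 0.1))
        assert out.n_spikes == 0 and removed == 10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rejection_matches_interval_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.uniform(0, 100, 20))
        onsets = onsets[np.concatenate([[True], np.diff(onsets) > 0.3])]
        protocol = StimulationProtocol(onsets, 0.05)
        times = np.sort(rng.uniform(0, 100, 50))
        train = SpikeTrain(times, np.ones(times.size))
        pre, post = 0.02, 0.08
        out, removed = reject_stim_artifacts(train, protocol, (pre, post))
        keep = [t for t in times
                if not any(o - pre <= t <= o + post for o in onsets)]
        np.testing.assert_allclose(out.times, keep)
        assert removed == times.size - len(keep)


class TestFullDetector:
    def test_recall_precision_across_seeds(self):
        # SNR >= 6, ISIs >= 0.2 s, matching tolerance +-25 ms; rates are
        # pooled over the 10 seeds (single sessions hold only a few events)
        n_truth = n_det = tp_recall = tp_prec = 0
        for seed in range(10):
            plan = simulate.SessionPlan(
                [simulate.SubSessionPlan(
                    "pre", 240.0,
                    {"low": 0.008, "medium": 0.004, "high": 0.001})],
                seed=seed, fs=2000.0)
            rec, _, gt, _ = simulate.generate_session(plan)
            train = detect_spikes(rec.channel("idHC"), rec.fs)
            truth = gt.spike_times.get("idHC", np.empty(0))
            r, p = match_events(train.times, truth)
            n_truth += truth.size
            n_det += train.n_spikes
            tp_recall += r * truth.size
            tp_prec += p * train.n_spikes
        assert tp_recall / n_truth >= 0.9
        assert tp_prec / n_det >= 0.9

    def test_threshold_monotonicity(self):
        rec = simulate.generate_background(30, 2000.0, 1.0, seed=5)
        rec, _ = simulate.inject_burst(rec, 0, 5.0, 15, 1.0, 0.2, 7.0, seed=5)
        trace = rec.samples[0]
        n_low = detect_spikes(trace, rec.fs, prominence_thr=0.15,
                              k_mad=4.0).n_spikes
        n_high = detect_spikes(trace, rec.fs, prominence_thr=0.4,
                               k_mad=6.0).n_spikes
        assert n_high <= n_low

    def test_shift_equivariance(self):
        rec = simulate.generate_background(30, 2000.0, 1.0, seed=8)
        rec, _ = simulate.inject_burst(rec, 0, 10.0, 5, 1.0, 0.1, 8.0, seed=8)
        trace = rec.samples[0]
        shift = 400  # 0.2 s
        shifted = np.concatenate([trace[-shift:], trace[:-shift]])
        t1 = detect_spikes(trace, rec.fs).times
        t2 = detect_spikes(shifted, rec.fs).times
        # compare away from the wrap edges
        t1 = t1[(t1 > 1) & (t1 < 28)]
        t2 = t2[(t2 > 1.2) & (t2 < 28.2)]
        np.testing.assert_allclose(t2, t1 + shift / rec.fs, atol=1e-9)
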