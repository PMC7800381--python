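"""Epileptiform spike detection.

Dual-path detector: local maxima of the min–max-normalized spectrogram band
score (4–40 Hz) complemented by amplitude-based detection against a robust
(MAD) noise scale, followed by a plausibility-gated merge and optional
blanking of stimulation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import StimulationProtocol

#: Factor converting the median absolute deviation of a Gaussian to its SD.
MAD_TO_SD = 1.4826


@dataclass
class SpectrogramMatrix:
    """Short-time power spectrogram, optionally per-bin min–max normalized."""

    power: np.ndarray          # (n_times, n_freqs)
    times: np.ndarray          # frame centers, s
    freqs: np.ndarray          # bin centers, Hz
    normalized: bool = False


@dataclass
class SpikeTrain:
    """Detected spike times with peak amplitudes and per-spike provenance."""

    times: np.ndarray
    amplitudes: np.ndarray
    source: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.source is None or len(self.source) == 0:
            self.source = np.full(self.times.size, "both", dtype=object)
        self.source = np.asarray(self.source, dtype=object)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


def compute_normalized_spectrogram(trace: np.ndarray, fs: float,
                                   window_s: float = 0.25,
                                   overlap_frac: float = 0.9
                                   ) -> SpectrogramMatrix:
    """Hann-tapered power spectrogram with each frequency bin min–max
    normalized to [0, 1] over the whole recording (constant bins map to 0)."""
    trace = np.asarray(trace, dtype=float)
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    nperseg = int(round(window_s * fs))
    if nperseg < 8:
        raise ValueError("window_s*fs must be at least 8 samples")
    if trace.size < nperseg:
        raise ValueError("trace shorter than one spectrogram window")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, times, sxx = signal.spectrogram(
        trace, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", mode="psd")
    power = sxx.T  # (time, freq)
    lo = power.min(axis=0)
    span = power.max(axis=0) - lo
    norm = np.zeros_like(power)
    ok = span > 0
    norm[:, ok] = (power[:, ok] - lo[ok]) / span[ok]
    return SpectrogramMatrix(norm, times, freqs, normalized=True)


def _refine_to_extremum(trace: np.ndarray, fs: float, t: float,
                        half_window_s: float) -> tuple[float, float]:
    """Move a coarse candidate time to the nearest raw-signal |extremum|."""
    c = int(round(t * fs))
    h = int(round(half_window_s * fs))
    lo, hi = max(0, c - h), min(trace.size, c + h + 1)
    seg = trace[lo:hi]
    i = int(np.argmax(np.abs(seg)))
    return (lo + i) / fs, float(seg[i])


def detect_spectral_spikes(spec: SpectrogramMatrix, trace: np.ndarray,
                           fs: float, band_hz: tuple[float, float] = (4.0, 40.0),
                           prominence_thr: float = 0.25,
                           refine_half_window_s: float | None = None
                           ) -> np.ndarray:
    """Candidate spike times from the normalized 4–40 Hz band score.

    The per-frame score is the mean of the normalized bins inside
    ``band_hz``; local maxima with prominence above ``prominence_thr`` are
    candidates, each refined to the nearest raw-signal extremum within half
    a frame of the frame center.
    """
    if not spec.normalized:
        raise ValueError("spectrogram must be normalized")
    lo, hi = band_hz
    if lo < spec.freqs[0] - 1e-9 or hi > spec.freqs[-1] + 1e-9:
        raise ValueError(f"band {band_hz} outside spectrogram range "
                         f"[{spec.freqs[0]}, {spec.freqs[-1]}] Hz")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    score = spec.power[:, sel].mean(axis=1)
    peaks, _ = signal.find_peaks(score, prominence=prominence_thr)
    if refine_half_window_s is None:
        # half the frame spacing covers the coarseness of frame centers
        frame_dt = spec.times[1] - spec.times[0] if spec.times.size > 1 else 0.0
        refine_half_window_s = max(frame_dt, 0.5 * (spec.times[0] * 2))
    out = [
        _refine_to_extremum(trace, fs, spec.times[p], refine_half_window_s)[0]
        for p in peaks
    ]
    return np.unique(out)


def robust_noise_sd(trace: np.ndarray) -> float:
    """SD-equivalent noise scale from the median absolute deviation."""
    trace = np.asarray(trace, dtype=float)
    med = np.median(trace)
    return MAD_TO_SD * float(np.median(np.abs(trace - med)))


def detect_amplitude_spikes(trace: np.ndarray, fs: float, k_mad: float = 5.0,
                            refractory_s: float = 0.1) -> np.ndarray:
    """Candidate spike times from |trace| peaks above ``k_mad`` MAD-SDs.

    The refractory constraint keeps the larger of two conflicting peaks.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    if refractory_s < 0:
        raise ValueError("refractory_s must be non-negative")
    thr = k_mad * robust_noise_sd(trace)
    dist = max(1, int(round(refractory_s * fs)))
    peaks, _ = signal.find_peaks(np.abs(trace), height=thr, distance=dist)
    return peaks / fs


def merge_and_sort(spectral: np.ndarray, amplitude: np.ndarray,
                   merge_window_s: float = 0.05,
                   trace: np.ndarray | None = None,
                   fs: float | None = None,
                   amp_gate: float | None = None) -> SpikeTrain:
    """Union of the two candidate lists collapsed within ``merge_window_s``.

    A spectral candidate within the window of an amplitude candidate keeps
    the amplitude-path time (raw extremum). With ``trace``/``fs`` given,
    spike amplitudes are read from the trace; spectral-only candidates whose
    peak amplitude falls below ``amp_gate`` are discarded (amplitude
    plausibility gating of the spectral path).
    """
    spectral = np.asarray(spectral, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(np.diff(spectral) < 0) or np.any(np.diff(amplitude) < 0):
        raise ValueError("candidate lists must be sorted")
    events: list[tuple[float, str]] = []
    used_spec = np.zeros(spectral.size, dtype=bool)
    j = 0
    for t in amplitude:
        matched = False
        while j < spectral.size and spectral[j] < t - merge_window_s:
            j += 1
        k = j
        while k < spectral.size and spectral[k] <= t + merge_window_s:
            if not used_spec[k]:
                used_spec[k] = True
                matched = True
            k += 1
        events.append((t, "both" if matched else "amplitude"))
    for k in np.flatnonzero(~used_spec):
        events.append((float(spectral[k]), "spectral"))
    events.sort()
    # collapse residual near-duplicates within the merge window
    collapsed: list[tuple[float, str]] = []
    for t, src in events:
        if collapsed and t - collapsed[-1][0] <= merge_window_s:
            t0, s0 = collapsed[-1]
            collapsed[-1] = (t0, "both" if s0 != src else s0)
        else:
            collapsed.append((t, src))
    times = np.array([t for t, _ in collapsed])
    srcs = np.array([s for _, s in collapsed], dtype=object)
    if trace is not None and fs is not None:
        idx = np.clip(np.round(times * fs).astype(int), 0, len(trace) - 1)
        amps = np.asarray(trace)[idx]
        if amp_gate is not None:
            keep = (srcs != "spectral") | (np.abs(amps) >= amp_gate)
            times, srcs, amps = times[keep], srcs[keep], amps[keep]
    else:
        amps = np.full(times.size, np.nan)
    return SpikeTrain(times, amps, srcs)


def reject_stim_artifacts(train: SpikeTrain,
                          protocol: StimulationProtocol | None,
                          blank_window: tuple[float, float] = (0.01, 0.1)
                          ) -> tuple[SpikeTrain, int]:
    """Remove spikes inside [onset−pre, onset+post] of any pulse.

    Evoked responses to stimulation pulses must not be counted as epileptic
    spikes. Returns the filtered train and the number of removed spikes.
    """
    pre, post = blank_window
    if pre < 0 or post < 0:
        raise ValueError("blank window margins must be non-negative")
    if protocol is None or protocol.n_pulses == 0 or train.n_spikes == 0:
        return train, 0
    onsets = protocol.pulse_times
    idx = np.searchsorted(onsets, train.times)
    blocked = np.zeros(train.n_spikes, dtype=bool)
    prev_ok = idx > 0
    blocked[prev_ok] |= (train.times[prev_ok]
                         <= onsets[idx[prev_ok] - 1] + post)
    nxt_ok = idx < onsets.size
    blocked[nxt_ok] |= (train.times[nxt_ok] >= onsets[idx[nxt_ok]] - pre)
    kept = SpikeTrain(train.times[~blocked], train.amplitudes[~blocked],
                      train.source[~blocked])
    return kept, int(blocked.sum())


def detect_spikes(trace: np.ndarray, fs: float, *,
                  window_s: float = 0.25, overlap_frac: float = 0.9,
                  band_hz: tuple[float, float] = (4.0, 40.0),
                  prominence_thr: float = 0.25, k_mad: float = 5.0,
                  refractory_s: float = 0.1, merge_window_s: float = 0.05,
                  amp_gate_frac: float = 0.8,
                  protocol: StimulationProtocol | None = None,
                  blank_window: tuple[float, float] = (0.01, 0.1)
                  ) -> SpikeTrain:
    """Full dual-path detection on one channel.

    Runs the spectral and amplitude paths, merges with amplitude-gated
    plausibility (gate = ``amp_gate_frac``·``k_mad``·noise SD), and blanks
    stimulation windows when a protocol is supplied.
    """
    spec = compute_normalized_spectrogram(trace, fs, window_s, overlap_frac)
    spectral = detect_spectral_spikes(spec, trace, fs, band_hz, prominence_thr)
    amp = detect_amplitude_spikes(trace, fs, k_mad, refractory_s)
    gate = amp_gate_frac * k_mad * robust_noise_sd(trace)
    train = merge_and_sort(spectral, amp, merge_window_s, trace, fs, gate)
    train, _ = reject_stim_artifacts(train, protocol, blank_window)
    return train
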