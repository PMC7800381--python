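"""Stimulation-evoked response analysis.

Traces are smoothed with a 4th-order type-I Chebyshev low-pass (300 Hz
cut-off) applied forward–backward (zero phase). Per-pulse snippets are cut
relative to stimulus onset — −0.1 s to +0.2 s for low-frequency stimulation
(1, 0.5, 0.2 Hz) and −0.02 s to +0.06 s for 10 Hz trains — and quantified by
the integral of the trace over the window (AUC). Responses co-occurring with
high-load bursts get no AUC. The rundown of the response over the
stimulation period is summarized by 15-min mean waveforms and a polynomial
fit to the AUC series normalized to its first value (delta AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Peri-pulse analysis windows (pre_s, post_s) by protocol type.
LFS_WINDOW = (0.1, 0.2)
HF_WINDOW = (0.02, 0.06)


@dataclass
class EvokedSnippet:
    pulse_index: int
    onset_s: float
    waveform: np.ndarray
    window: tuple[float, float]        # (pre_s, post_s)
    fs: float
    auc: float | None = None
    in_high_load_burst: bool = False

    @property
    def span(self) -> tuple[float, float]:
        return (self.onset_s - self.window[0], self.onset_s + self.window[1])


@dataclass
class AUCSeries:
    """Per-pulse AUC values with the delta-AUC polynomial trend fit."""

    onsets_s: np.ndarray
    aucs: np.ndarray                    # NaN where undetermined
    anchor: float | None = None         # first defined AUC
    coefficients: np.ndarray | None = None  # polynomial, ascending powers
    degree: int | None = None
    residual_rms: float | None = None

    @property
    def delta(self) -> np.ndarray:
        return self.aucs / self.anchor if self.anchor else self.aucs * np.nan

    def fitted(self, t: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(t, self.coefficients)


def cheby1_sos(fs: float, order: int = 4, cutoff_hz: float = 300.0,
               ripple_db: float = 1.0):
    """Design the smoothing low-pass as second-order sections."""
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    return signal.cheby1(order, ripple_db, cutoff_hz, btype="lowpass",
                         fs=fs, output="sos")


def lowpass_cheby1(trace: np.ndarray, fs: float, order: int = 4,
                   cutoff_hz: float = 300.0,
                   ripple_db: float = 1.0) -> np.ndarray:
    """Zero-phase (forward–backward) Chebyshev-I low-pass.

    The bidirectional pass squares the magnitude response and cancels the
    phase, so peri-pulse peak times are preserved.
    """
    sos = cheby1_sos(fs, order, cutoff_hz, ripple_db)
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def extract_snippets(trace: np.ndarray, fs: float, pulse_times: np.ndarray,
                     window: tuple[float, float] = LFS_WINDOW
                     ) -> tuple[list[EvokedSnippet], list[str]]:
    """One sample-aligned snippet per pulse; out-of-range pulses dropped.

    The onset sample is ``round(onset·fs)``; the snippet covers
    ``[-pre_s, +post_s)`` around it. Returns ``(snippets, log)`` where the
    log lists dropped pulses.
    """
    trace = np.asarray(trace, dtype=float)
    pre, post = window
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    snippets, log = [], []
    for i, onset in enumerate(np.asarray(pulse_times, dtype=float)):
        c = int(round(onset * fs))
        lo, hi = c - n_pre, c + n_post
        if lo < 0 or hi > trace.size:
            log.append(f"pulse {i} at {onset:.3f}s dropped: window outside "
                       "recording")
            continue
        snippets.append(EvokedSnippet(i, onset, trace[lo:hi].copy(),
                                      window, fs))
    return snippets, log


def compute_auc(snippet: EvokedSnippet, mode: str = "baseline_subtracted_absolute"
                ) -> float:
    """Trapezoidal integral of the snippet over its window.

    Modes: ``signed`` (raw integral), ``absolute`` (integral of |v|), and
    ``baseline_subtracted_absolute`` (default; the mean of the pre-onset
    portion is removed before taking |v|). ``baseline_subtracted_signed``
    keeps the sign after baseline removal — the unbiased choice for trend
    fits, since rectification of noise inflates absolute integrals.
    """
    v = snippet.waveform
    if v.size == 0:
        raise ValueError("empty snippet waveform")
    dt = 1.0 / snippet.fs
    n_pre = int(round(snippet.window[0] * snippet.fs))
    if mode == "signed":
        y = v
    elif mode == "absolute":
        y = np.abs(v)
    elif mode == "baseline_subtracted_absolute":
        base = v[:n_pre].mean() if n_pre > 0 else 0.0
        y = np.abs(v - base)
    elif mode == "baseline_subtracted_signed":
        base = v[:n_pre].mean() if n_pre > 0 else 0.0
        y = v - base
    else:
        raise ValueError(f"unknown AUC mode {mode!r}")
    return float(np.trapezoid(y, dx=dt))


def mask_burst_cooccurrence(snippets: list[EvokedSnippet],
                            high_load_intervals: np.ndarray
                            ) -> list[EvokedSnippet]:
    """Flag snippets whose window overlaps any high-load burst interval.

    Flagged snippets carry no AUC (set to None).
    """
    iv = np.asarray(high_load_intervals, dtype=float).reshape(-1, 2)
    for s in snippets:
        lo, hi = s.span
        hit = bool(np.any((iv[:, 0] < hi) & (iv[:, 1] > lo))) if iv.size else False
        s.in_high_load_burst = hit
        if hit:
            s.auc = None
    return snippets


def auc_series(snippets: list[EvokedSnippet],
               mode: str = "baseline_subtracted_absolute") -> AUCSeries:
    """AUC per unflagged snippet, NaN where the burst mask applies."""
    onsets = np.array([s.onset_s for s in snippets])
    aucs = np.full(onsets.size, np.nan)
    for i, s in enumerate(snippets):
        if not s.in_high_load_burst:
            s.auc = compute_auc(s, mode)
            aucs[i] = s.auc
    return AUCSeries(onsets, aucs)


def mean_response_windows(snippets: list[EvokedSnippet],
                          window_min: float = 15.0
                          ) -> list[tuple[int, np.ndarray]]:
    """Pointwise mean of unflagged snippet waveforms per 15-min window.

    Snippets are grouped by onset time into consecutive windows counted from
    the first pulse; windows with no usable snippet are omitted. Returns
    ``(window_index, mean_waveform)`` pairs.
    """
    use = [s for s in snippets if not s.in_high_load_burst]
    if not use:
        return []
    t0 = min(s.onset_s for s in use)
    width = window_min * 60.0
    groups: dict[int, list[np.ndarray]] = {}
    for s in use:
        groups.setdefault(int((s.onset_s - t0) // width), []).append(s.waveform)
    return [(k, np.mean(np.vstack(v), axis=0))
            for k, v in sorted(groups.items())]


def delta_auc_fit(series: AUCSeries, degree: int = 3) -> AUCSeries:
    """Normalize AUCs to the first defined value and fit a polynomial trend.

    Flagged (NaN) pulses are excluded from the least-squares fit; the first
    defined delta-AUC equals 1 by construction. Coefficients are returned in
    ascending powers of time (s); residual RMS is over the fitted points.
    """
    ok = np.isfinite(series.aucs)
    if ok.sum() < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} defined AUC values, have {ok.sum()}")
    anchor = float(series.aucs[np.flatnonzero(ok)[0]])
    series.anchor = anchor
    delta = series.aucs / anchor
    t, d = series.onsets_s[ok], delta[ok]
    # numpy's Polynomial.fit works in a scaled domain; convert back
    poly = np.polynomial.Polynomial.fit(t, d, degree).convert()
    series.coefficients = poly.coef
    series.degree = degree
    resid = d - poly(t)
    series.residual_rms = float(np.sqrt(np.mean(resid ** 2)))
    return series
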