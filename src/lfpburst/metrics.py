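"""Seizure-burden and stimulation-efficacy metrics.

Per sub-session: the high-load burst ratio (fraction of recording time spent
in high-load bursts) and the epileptic spike rate. Per session: suppression
efficacy, (1 − stim/pre)·100, for both metrics, and the exclusion rule that
drops sessions whose 'pre' hour has a high-load burst ratio below 0.05.

Sub-sessions are half-open intervals [start, end); bursts spanning a
boundary are clipped, so the per-sub-session ratios are exactly additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bursts import Burst


def _clipped_overlap(start: float, end: float, lo: float, hi: float) -> float:
    return max(0.0, min(end, hi) - max(start, lo))


def high_load_burst_ratio(bursts: list[Burst], sub_session: tuple[float, float],
                          label: str = "high") -> float:
    """Sum of high-load burst durations within the sub-session, divided by
    the sub-session duration; bursts are clipped at the boundaries."""
    lo, hi = sub_session
    if hi <= lo:
        raise ValueError("sub-session duration must be positive")
    total = sum(_clipped_overlap(b.start_s, b.end_s, lo, hi)
                for b in bursts if b.label == label)
    return total / (hi - lo)


def epileptic_spike_rate(spike_times: np.ndarray,
                         sub_session: tuple[float, float]) -> float:
    """Spike count in the half-open sub-session [start, end), per second."""
    lo, hi = sub_session
    if hi <= lo:
        raise ValueError("sub-session duration must be positive")
    t = np.asarray(spike_times, dtype=float)
    n = int(np.count_nonzero((t >= lo) & (t < hi)))
    return n / (hi - lo)


def suppression_efficacy(pre_value: float, stim_value: float) -> float:
    """Percent reduction during stimulation: (1 − stim/pre)·100.

    Negative values mean worsening. Undefined (error) when the pre value is
    not positive; callers flag such sessions instead.
    """
    if pre_value <= 0:
        raise ValueError("suppression efficacy undefined for pre <= 0")
    return (1.0 - stim_value / pre_value) * 100.0


def fraction_above(efficacies, threshold_pct: float = 75.0) -> float:
    """Percent of sessions with suppression efficacy strictly above the
    threshold (75% by default)."""
    e = np.asarray(list(efficacies), dtype=float)
    if e.size == 0:
        raise ValueError("no sessions")
    return 100.0 * float(np.count_nonzero(e > threshold_pct)) / e.size


def average_burden(ratios, durations_s=None, duration_weighted: bool = True
                   ) -> float:
    """Mean high-load burst ratio over several reference recordings.

    Duration-weighted by default (recordings of mixed length enter in
    proportion to their time base); plain mean with
    ``duration_weighted=False``.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("no recordings")
    if not duration_weighted or durations_s is None:
        return float(r.mean())
    w = np.asarray(list(durations_s), dtype=float)
    return float(np.average(r, weights=w))


@dataclass
class SessionMetrics:
    """Per-sub-session burden metrics and session-level efficacy."""

    table: pd.DataFrame                     # one row per sub-session
    efficacy_ratio: float | None = None     # %, from high-load burst ratio
    efficacy_rate: float | None = None      # %, from epileptic spike rate
    excluded: bool = False
    exclusion_reason: str | None = None
    extra: dict = field(default_factory=dict)


def compute_session_metrics(bursts: list[Burst], spike_times: np.ndarray,
                            boundaries: pd.DataFrame,
                            pre_label: str = "pre",
                            stim_labels: tuple[str, ...] = ("stim", "oLFS",
                                                            "eLFS"),
                            min_pre_ratio: float = 0.05) -> SessionMetrics:
    """Metrics table for one session from its classified bursts and spikes.

    ``boundaries`` needs columns label / start_s / end_s. Suppression
    efficacies compare the stimulation sub-session against 'pre'; the
    session is flagged excluded when the pre high-load burst ratio falls
    below ``min_pre_ratio`` (strict <) or the pre sub-session is missing.
    """
    rows = []
    class_names = ("low", "medium", "high")
    for _, r in boundaries.iterrows():
        span = (float(r.start_s), float(r.end_s))
        counts = {
            f"n_{c}": sum(
                1 for b in bursts
                if b.label == c and _clipped_overlap(
                    b.start_s, b.end_s, *span) > 0)
            for c in class_names}
        rows.append({
            "sub_session": r.label,
            "start_s": span[0], "end_s": span[1],
            "high_load_burst_ratio": high_load_burst_ratio(bursts, span),
            "epileptic_spike_rate_hz": epileptic_spike_rate(spike_times, span),
            **counts,
        })
    table = pd.DataFrame(rows)
    m = SessionMetrics(table)
    by_label = table.set_index("sub_session")
    if pre_label not in by_label.index:
        m.excluded, m.exclusion_reason = True, "no-pre"
        return m
    pre_ratio = float(by_label.loc[pre_label, "high_load_burst_ratio"])
    pre_rate = float(by_label.loc[pre_label, "epileptic_spike_rate_hz"])
    stim = [s for s in stim_labels if s in by_label.index]
    if stim:
        stim_ratio = float(by_label.loc[stim[0], "high_load_burst_ratio"])
        stim_rate = float(by_label.loc[stim[0], "epileptic_spike_rate_hz"])
        if pre_ratio > 0:
            m.efficacy_ratio = suppression_efficacy(pre_ratio, stim_ratio)
        if pre_rate > 0:
            m.efficacy_rate = suppression_efficacy(pre_rate, stim_rate)
    if pre_ratio < min_pre_ratio:
        m.excluded = True
        m.exclusion_reason = (
            f"pre high-load burst ratio {pre_ratio:.4f} < {min_pre_ratio}")
    return m


def exclude_sessions(sessions: list[SessionMetrics],
                     min_pre_ratio: float = 0.05
                     ) -> tuple[list[SessionMetrics], list[SessionMetrics]]:
    """Partition sessions by the pre-ratio exclusion rule (strict <).

    Sessions without a 'pre' sub-session are excluded with reason "no-pre".
    """
    kept, dropped = [], []
    for s in sessions:
        by_label = s.table.set_index("sub_session")
        if "pre" not in by_label.index:
            s.excluded, s.exclusion_reason = True, "no-pre"
            dropped.append(s)
            continue
        pre = float(by_label.loc["pre", "high_load_burst_ratio"])
        if pre < min_pre_ratio:
            s.excluded = True
            s.exclusion_reason = (
                f"pre high-load burst ratio {pre:.4f} < {min_pre_ratio}")
            dropped.append(s)
        else:
            s.excluded, s.exclusion_reason = False, None
            kept.append(s)
    return kept, dropped
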