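"""Inter-site response latency.

Each pulse response is z-scored over its peri-pulse window; the response
onset at each site is the first sample after the pulse whose |z| exceeds a
threshold (default 2.0), searched inside a post-onset window that covers
the physiological 8–12 ms propagation range with margin while excluding the
stimulus onset itself. The per-pulse delay is the contralateral minus the
ipsilateral crossing time; sub-sessions are summarized by the median of the
defined delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evoked import EvokedSnippet


@dataclass
class LatencyResult:
    delays_s: np.ndarray           # NaN where either crossing is undefined
    median_s: float | None
    threshold_z: float
    n_defined: int


def zscore_snippet(waveform: np.ndarray) -> np.ndarray | None:
    """(x − mean)/SD over the snippet window; None for constant snippets."""
    x = np.asarray(waveform, dtype=float)
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def first_crossing(z: np.ndarray, fs: float, threshold_z: float = 2.0,
                   search_window: tuple[float, float] = (0.0, 0.05),
                   pre_s: float = 0.0, signed: bool = False) -> float | None:
    """Time (s, relative to pulse onset) of the earliest threshold crossing.

    ``z`` is indexed from the snippet start; ``pre_s`` is the pre-onset
    portion of the snippet. Magnitude mode (|z| >= threshold) by default;
    ``signed=True`` requires z >= threshold. None when nothing crosses.
    """
    lo_s, hi_s = search_window
    lo = int(np.ceil((pre_s + lo_s) * fs))
    hi = min(int(np.floor((pre_s + hi_s) * fs)) + 1, z.size)
    if lo >= hi:
        return None
    seg = z[lo:hi] if signed else np.abs(z[lo:hi])
    above = np.flatnonzero(seg >= threshold_z)
    if above.size == 0:
        return None
    return (lo + above[0]) / fs - pre_s


def pulse_delay(id_crossing: float | None,
                cd_crossing: float | None) -> float | None:
    """Contralateral minus ipsilateral crossing time; None if either is
    undefined. Negative delays are reported as-is."""
    if id_crossing is None or cd_crossing is None:
        return None
    return cd_crossing - id_crossing


def session_median(delays) -> tuple[float | None, int]:
    """Median over the defined delays; ``(None, 0)`` when none defined."""
    vals = np.asarray([d for d in delays if d is not None and np.isfinite(d)])
    if vals.size == 0:
        return None, 0
    return float(np.median(vals)), int(vals.size)


def estimate_latencies(id_snippets: list[EvokedSnippet],
                       cd_snippets: list[EvokedSnippet],
                       threshold_z: float = 2.0,
                       search_window: tuple[float, float] = (0.0, 0.05),
                       signed: bool = False) -> LatencyResult:
    """Per-pulse ipsi→contra delays and their sub-session median.

    Snippets are matched by pulse index; pulses with a constant snippet or
    no threshold crossing on either site yield an undefined delay.
    """
    cd_by_index = {s.pulse_index: s for s in cd_snippets}
    delays = []
    for s_id in id_snippets:
        s_cd = cd_by_index.get(s_id.pulse_index)
        if s_cd is None:
            delays.append(np.nan)
            continue
        d = None
        z_id = zscore_snippet(s_id.waveform)
        z_cd = zscore_snippet(s_cd.waveform)
        if z_id is not None and z_cd is not None:
            c_id = first_crossing(z_id, s_id.fs, threshold_z, search_window,
                                  s_id.window[0], signed)
            c_cd = first_crossing(z_cd, s_cd.fs, threshold_z, search_window,
                                  s_cd.window[0], signed)
            d = pulse_delay(c_id, c_cd)
        delays.append(np.nan if d is None else d)
    delays = np.asarray(delays, dtype=float)
    med, n = session_median(delays[np.isfinite(delays)])
    return LatencyResult(delays, med, threshold_z, n)
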