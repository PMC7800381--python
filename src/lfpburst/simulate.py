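"""Synthetic LFP generator.

Produces surrogate hippocampal recordings with the statistical structure the
analysis pipeline assumes: band-limited background noise emulating the
recording chain (1 Hz – 5 kHz bandpass before digitization), interictal
spikes of variable amplitude grouped into bursts whose spike count and
inter-spike-interval (ISI) statistics span low/medium/high spike loads,
stimulation-evoked response waveforms whose amplitude runs down over the
stimulation period, a fixed inter-site propagation delay between the two
channels, and the pre / stim / post 1 / post 2 session structure.

Everything is phenomenological signal synthesis — no biophysical modelling —
and every generator is a pure function of its parameters and seed.
Amplitudes are unitless; spike and evoked amplitudes are specified relative
to the background noise SD so that detector thresholds are scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import LFPRecording, StimulationProtocol

BURST_CLASSES = ("low", "medium", "high")

#: Minimum ISI allowed inside a burst (s); truncation floor of the ISI draw.
MIN_ISI_S = 0.001


@dataclass
class BurstClassParams:
    """Generating distribution of one burst-load class.

    Spike counts are log10-normal around ``count_median`` (floored at 3 so a
    feature vector exists), mean ISIs log10-normal around ``isi_median_s``,
    and the within-burst ISI SD normal around ``isi_sd_s`` (truncated > 0).
    """

    count_median: float
    count_log10_sd: float
    isi_median_s: float
    isi_log10_sd: float
    isi_sd_s: float
    isi_sd_rel_spread: float = 0.25


#: Default load-class mixture. Medians 5 / 30 / 180 spikes give three
#: well-separated modes on the log10-count axis; ISI medians slow enough
#: that every spike is individually resolvable by the detectors.
DEFAULT_CLASS_PARAMS: dict[str, BurstClassParams] = {
    "low": BurstClassParams(5, 0.12, 1.2, 0.08, 0.30),
    "medium": BurstClassParams(30, 0.12, 0.5, 0.08, 0.12),
    "high": BurstClassParams(180, 0.10, 0.25, 0.05, 0.05),
}


@dataclass
class BurstTruth:
    """Ground-truth record of one injected burst."""

    channel: str
    start_s: float
    end_s: float
    n_spikes: int
    intended_class: str
    sub_session: str | None = None


@dataclass
class GroundTruth:
    """Exact injected content of a synthetic recording."""

    spike_times: dict[str, np.ndarray] = field(default_factory=dict)
    spike_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    bursts: list[BurstTruth] = field(default_factory=list)
    evoked: dict = field(default_factory=dict)
    inter_channel_delay_s: float | None = None
    log: list[str] = field(default_factory=list)

    def burst_intervals(self, cls: str | None = None) -> np.ndarray:
        """(start, end) pairs of injected bursts, optionally one class only."""
        rows = [
            (b.start_s, b.end_s)
            for b in self.bursts
            if cls is None or b.intended_class == cls
        ]
        return np.asarray(rows, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# background noise


def background_sos(fs: float, low_hz: float = 1.0, high_hz: float = 5000.0,
                   order: int = 2):
    """Second-order sections of the background bandpass (recording chain).

    Upper edge is capped at 0.45·fs so the design is valid at any rate.
    """
    hi = min(high_hz, 0.45 * fs)
    return signal.butter(order, [low_hz, hi], btype="bandpass", fs=fs,
                         output="sos")


def generate_background(duration_s: float, fs: float, noise_sd: float,
                        seed: int | np.random.Generator,
                        low_hz: float = 1.0,
                        high_hz: float = 5000.0) -> LFPRecording:
    """Band-limited Gaussian background noise, single channel.

    White Gaussian noise with SD ``noise_sd`` passed once (causally) through
    the bandpass of :func:`background_sos`; the output SD is therefore
    ``noise_sd`` times the filter's RMS noise bandwidth gain, which callers
    can evaluate from the filter's frequency response.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        x = np.zeros(n)
    else:
        white = rng.normal(0.0, noise_sd, n)
        x = signal.sosfilt(background_sos(fs, low_hz, high_hz), white)
    return LFPRecording(x[np.newaxis, :], fs)


# ---------------------------------------------------------------------------
# interictal spike waveform


def spike_waveform(fs: float, amplitude: float = 1.0,
                   sharp_width_s: float = 0.004,
                   rebound_delay_s: float = 0.030,
                   rebound_width_s: float = 0.010,
                   rebound_frac: float = 0.4) -> tuple[np.ndarray, int]:
    """Biphasic interictal spike template.

    Sharp negative transient (Gaussian, SD ``sharp_width_s``) followed by a
    slower positive rebound — the classic interictal morphology, giving the
    detectors both a 4–40 Hz spectral signature and an amplitude signature.
    Returns ``(waveform, peak_index)`` with the negative extremum at
    ``peak_index`` (the injected spike time).
    """
    t_left = -4.0 * sharp_width_s
    t_right = rebound_delay_s + 3.0 * rebound_width_s
    t = np.arange(int(round(t_left * fs)), int(round(t_right * fs)) + 1) / fs
    w = -np.exp(-0.5 * (t / sharp_width_s) ** 2) + rebound_frac * np.exp(
        -0.5 * ((t - rebound_delay_s) / rebound_width_s) ** 2
    )
    peak = int(np.argmin(w))
    return amplitude * w, peak


def _add_waveform(trace: np.ndarray, fs: float, time_s: float,
                  waveform: np.ndarray, peak: int) -> None:
    """Add ``waveform`` to ``trace`` in place, peak sample at ``time_s``."""
    center = int(round(time_s * fs))
    lo = center - peak
    hi = lo + waveform.size
    wlo = max(0, -lo)
    whi = waveform.size - max(0, hi - trace.size)
    lo = max(lo, 0)
    trace[lo:lo + (whi - wlo)] += waveform[wlo:whi]


def draw_burst_spike_times(start_s: float, n_spikes: int, mean_isi_s: float,
                           isi_sd_s: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Spike times with truncated-normal ISIs (floor :data:`MIN_ISI_S`)."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if mean_isi_s <= 0:
        raise ValueError("mean_isi_s must be positive")
    if isi_sd_s == 0:
        isis = np.full(n_spikes - 1, mean_isi_s)
    else:
        isis = rng.normal(mean_isi_s, isi_sd_s, n_spikes - 1)
        for _ in range(1000):
            bad = isis <= MIN_ISI_S
            if not bad.any():
                break
            isis[bad] = rng.normal(mean_isi_s, isi_sd_s, int(bad.sum()))
        isis = np.clip(isis, MIN_ISI_S, None)
    return start_s + np.concatenate([[0.0], np.cumsum(isis)])


def inject_burst(recording: LFPRecording, channel: str | int, start_s: float,
                 n_spikes: int, mean_isi_s: float, isi_sd_s: float,
                 amplitude: float,
                 seed: int | np.random.Generator) -> tuple[LFPRecording, GroundTruth]:
    """Add one spike burst to a copy of ``recording``.

    Spike times start at ``start_s`` with truncated-normal ISIs; the exact
    injected times are returned in the ground-truth entry. Raises if the
    burst does not fit inside the recording span.
    """
    rng = np.random.default_rng(seed)
    times = draw_burst_spike_times(start_s, n_spikes, mean_isi_s, isi_sd_s, rng)
    if start_s < 0 or times[-1] > recording.duration:
        raise ValueError("burst exceeds recording span")
    out = recording.copy()
    label = (channel if isinstance(channel, str)
             else out.channel_labels[channel])
    trace = out.channel(label)
    wf, peak = spike_waveform(out.fs, amplitude)
    for t in times:
        _add_waveform(trace, out.fs, t, wf, peak)
    gt = GroundTruth()
    _record_spikes(gt, label, times, np.full(times.size, amplitude))
    gt.bursts.append(BurstTruth(label, float(times[0]), float(times[-1]),
                                n_spikes, "unspecified"))
    return out, gt


def _record_spikes(gt: GroundTruth, label: str, times: np.ndarray,
                   amps: np.ndarray) -> None:
    old_t = gt.spike_times.get(label, np.empty(0))
    old_a = gt.spike_amplitudes.get(label, np.empty(0))
    t = np.concatenate([old_t, times])
    a = np.concatenate([old_a, amps])
    order = np.argsort(t, kind="stable")
    gt.spike_times[label] = t[order]
    gt.spike_amplitudes[label] = a[order]


# ---------------------------------------------------------------------------
# evoked responses


def evoked_waveform(fs: float, amplitude: float = 1.0,
                    onset_delay_s: float = 0.004,
                    rise_width_s: float = 0.008,
                    rebound_width_s: float = 0.015,
                    rebound_frac: float = 0.3) -> np.ndarray:
    """Stereotyped stimulation-evoked field response, indexed from pulse onset.

    A negative population-spike-like deflection peaking
    ``onset_delay_s + 2·rise_width_s`` after the pulse, with a small positive
    rebound. The array starts at the pulse-onset sample.
    """
    t_peak = onset_delay_s + 2.0 * rise_width_s
    t_end = t_peak + 0.025 + 3.0 * rebound_width_s
    t = np.arange(int(round(t_end * fs))) / fs
    w = -np.exp(-0.5 * ((t - t_peak) / rise_width_s) ** 2) + rebound_frac * (
        np.exp(-0.5 * ((t - t_peak - 0.025) / rebound_width_s) ** 2)
    )
    w[t < onset_delay_s] = 0.0
    return amplitude * w


def exponential_plateau_decay(plateau: float, tau_pulses: float):
    """Decay schedule ``p + (1-p)·exp(-i/τ)`` over pulse index ``i``."""

    def decay(i: int | np.ndarray) -> float | np.ndarray:
        return plateau + (1.0 - plateau) * np.exp(-np.asarray(i) / tau_pulses)

    return decay


def inject_evoked_responses(recording: LFPRecording,
                            protocol: StimulationProtocol,
                            template_params: dict | None = None,
                            decay_fn=None,
                            delay_s: float | None = None,
                            ) -> tuple[LFPRecording, GroundTruth]:
    """Add an evoked response after each pulse onset, to a copy.

    The first channel receives the template scaled by ``decay_fn(pulse
    index)`` (default: constant 1); with ``delay_s`` given, the second
    channel receives the same waveform shifted by the propagation delay.
    """
    if delay_s is not None and recording.n_channels < 2:
        raise ValueError("delay_s requires a recording with >= 2 channels")
    params = dict(template_params or {})
    out = recording.copy()
    wf = evoked_waveform(out.fs, **params)
    if decay_fn is None:
        decay_fn = lambda i: 1.0  # noqa: E731
    scales = np.asarray([float(decay_fn(i)) for i in range(protocol.n_pulses)])
    for i, onset in enumerate(protocol.pulse_times):
        _add_waveform(out.samples[0], out.fs, onset, scales[i] * wf, 0)
        if delay_s is not None:
            _add_waveform(out.samples[1], out.fs, onset + delay_s,
                          scales[i] * wf, 0)
    gt = GroundTruth(
        evoked={"template_params": params, "scales": scales,
                "pulse_times": protocol.pulse_times.copy()},
        inter_channel_delay_s=delay_s,
    )
    return out, gt


# ---------------------------------------------------------------------------
# session assembly


@dataclass
class SubSessionPlan:
    """One annotated hour (or scaled-down span) of a session."""

    label: str
    duration_s: float
    burst_rates: dict[str, float] = field(default_factory=dict)  # bursts/s
    stimulated: bool = False


@dataclass
class SessionPlan:
    """Full session recipe: sub-sessions, stimulation, amplitudes, seed.

    Spike and evoked amplitudes are multiples of ``noise_sd``; interictal
    spike amplitudes vary uniformly over ``spike_amp_range``.
    """

    sub_sessions: list[SubSessionPlan]
    seed: int = 0
    fs: float = 10_000.0
    noise_sd: float = 1.0
    class_params: dict[str, BurstClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    stim_frequency_hz: float = 1.0
    pulse_duration_s: float = 0.05
    evoked_amplitude: float = 30.0
    evoked_plateau: float = 0.3
    evoked_decay_tau_frac: float = 0.1   # tau as fraction of stim duration
    inter_channel_delay_s: float | None = None
    spike_amp_range: tuple[float, float] = (6.0, 12.0)
    collision_margin_s: float = 4.0
    max_redraws: int = 100
    collision_policy: str = "error"    # or "skip": drop the burst, logged

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sub_sessions]
        if len(set(labels)) != len(labels):
            raise ValueError("sub-session labels must be unique")
        if any(s.duration_s <= 0 for s in self.sub_sessions):
            raise ValueError("sub-session durations must be positive")
        if self.collision_policy not in ("error", "skip"):
            raise ValueError("collision_policy must be 'error' or 'skip'")


def make_lfs_plan(seed: int = 0, sub_duration_s: float = 300.0,
                  fs: float = 10_000.0, stim_frequency_hz: float = 1.0,
                  pre_rates: dict[str, float] | None = None,
                  stim_suppression: float = 0.95,
                  inter_channel_delay_s: float | None = 0.009,
                  collision_policy: str = "skip",
                  **plan_kwargs) -> SessionPlan:
    """Standard pre / stim / post1 / post2 low-frequency-stimulation plan.

    ``stim_suppression`` scales every burst rate down during the stimulation
    sub-session (0.95 ≈ near-complete suppression); post rates return to the
    pre level, emulating the recovery within the post hours. Because this
    constructor is typically used with sub-sessions scaled well below an
    hour, bursts that find no collision-free slot are dropped with a log
    entry rather than raising (``collision_policy="skip"``).
    """
    if pre_rates is None:
        # ~0.2 high-load time fraction in 'pre' at the default class
        # parameters (high bursts last ~45 s): 5e-3 bursts/s -> an expected
        # 1.5 bursts per scaled hour, matching the pre-hour burden of
        # chronically epileptic reference recordings
        pre_rates = {"low": 6e-3, "medium": 3e-3, "high": 5e-3}
    stim_rates = {k: v * (1.0 - stim_suppression) for k, v in pre_rates.items()}
    subs = [
        SubSessionPlan("pre", sub_duration_s, dict(pre_rates)),
        SubSessionPlan("stim", sub_duration_s, stim_rates, stimulated=True),
        SubSessionPlan("post1", sub_duration_s, dict(pre_rates)),
        SubSessionPlan("post2", sub_duration_s, dict(pre_rates)),
    ]
    return SessionPlan(subs, seed=seed, fs=fs,
                       stim_frequency_hz=stim_frequency_hz,
                       inter_channel_delay_s=inter_channel_delay_s,
                       collision_policy=collision_policy,
                       **plan_kwargs)


def _draw_class_burst(params: BurstClassParams, rng: np.random.Generator
                      ) -> tuple[int, float, float]:
    """Draw (n_spikes, mean_isi_s, isi_sd_s) for one burst of a class."""
    n = max(3, int(round(10 ** rng.normal(np.log10(params.count_median),
                                          params.count_log10_sd))))
    isi = 10 ** rng.normal(np.log10(params.isi_median_s), params.isi_log10_sd)
    sd = abs(rng.normal(params.isi_sd_s,
                        params.isi_sd_rel_spread * params.isi_sd_s))
    return n, isi, max(sd, 1e-4)


def generate_session(plan: SessionPlan) -> tuple[
        LFPRecording, StimulationProtocol | None, GroundTruth, pd.DataFrame]:
    """Assemble a full synthetic session from a plan.

    Returns the recording (two channels when an inter-channel delay is
    planned), the stimulation protocol (or None when no sub-session is
    stimulated), the complete ground truth, and the sub-session boundary
    table (columns label, start_s, end_s). Deterministic per plan seed.

    Bursts are placed by a Poisson draw per (sub-session, class); onsets are
    re-drawn on collision (closer than the collision margin to an existing
    burst) up to ``plan.max_redraws`` times, then an error is raised; every
    re-draw round is noted in the ground-truth log.
    """
    ss = np.random.SeedSequence(plan.seed)
    rng_bursts, rng_bg0, rng_bg1 = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]
    total = sum(s.duration_s for s in plan.sub_sessions)
    n_channels = 2 if plan.inter_channel_delay_s is not None else 1
    labels = ["idHC", "cdHC"][:n_channels]

    chans = [generate_background(total, plan.fs, plan.noise_sd, r).samples[0]
             for r in (rng_bg0, rng_bg1)[:n_channels]]
    rec = LFPRecording(np.vstack(chans), plan.fs, labels)

    bounds = []
    t = 0.0
    for s in plan.sub_sessions:
        bounds.append({"label": s.label, "start_s": t,
                       "end_s": t + s.duration_s})
        t += s.duration_s
    boundaries = pd.DataFrame(bounds)

    gt = GroundTruth(inter_channel_delay_s=plan.inter_channel_delay_s)
    placed: list[tuple[float, float]] = []
    trace0 = rec.samples[0]
    # amplitudes are multiples of the noise SD; unit scale when noiseless
    amp_unit = plan.noise_sd if plan.noise_sd > 0 else 1.0

    for sub, row in zip(plan.sub_sessions, bounds):
        for cls in BURST_CLASSES:
            rate = sub.burst_rates.get(cls, 0.0)
            if rate <= 0:
                continue
            n_bursts = rng_bursts.poisson(rate * sub.duration_s)
            for _ in range(n_bursts):
                n, isi, sd = _draw_class_burst(plan.class_params[cls],
                                               rng_bursts)
                span = (n - 1) * isi + 4.0 * sd  # conservative length bound
                free = sub.duration_s - span - plan.collision_margin_s
                if free <= 0:
                    gt.log.append(
                        f"dropped {cls} burst in {sub.label}: span {span:.1f}s"
                        " exceeds sub-session")
                    continue
                for attempt in range(plan.max_redraws + 1):
                    start = row["start_s"] + rng_bursts.uniform(
                        plan.collision_margin_s / 2, free)
                    lo = start - plan.collision_margin_s
                    hi = start + span + plan.collision_margin_s
                    if all(e <= lo or b >= hi for b, e in placed):
                        break
                else:
                    if plan.collision_policy == "skip":
                        gt.log.append(
                            f"dropped {cls} burst in {sub.label}: no "
                            f"collision-free slot in {plan.max_redraws} "
                            "re-draws")
                        continue
                    raise RuntimeError(
                        f"could not place {cls} burst in {sub.label} after "
                        f"{plan.max_redraws} re-draws; lower the rates")
                if attempt:
                    gt.log.append(
                        f"{cls} burst in {sub.label}: {attempt} re-draw(s)")
                times = draw_burst_spike_times(start, n, isi, sd, rng_bursts)
                amps = rng_bursts.uniform(*plan.spike_amp_range, n) * amp_unit
                wfs = {}
                for ti, ai in zip(times, amps):
                    key = round(ai, 6)
                    if key not in wfs:
                        wfs[key] = spike_waveform(plan.fs, ai)
                    wf, peak = wfs[key]
                    _add_waveform(trace0, plan.fs, ti, wf, peak)
                placed.append((times[0], times[-1]))
                _record_spikes(gt, labels[0], times, amps)
                gt.bursts.append(BurstTruth(labels[0], float(times[0]),
                                            float(times[-1]), n, cls,
                                            sub.label))

    protocol = None
    stim_subs = [
        (s, b) for s, b in zip(plan.sub_sessions, bounds) if s.stimulated]
    if stim_subs:
        sub, row = stim_subs[0]
        period = 1.0 / plan.stim_frequency_hz
        onsets = np.arange(row["start_s"], row["end_s"] - 1e-9, period)
        protocol = StimulationProtocol(onsets, plan.pulse_duration_s,
                                       plan.stim_frequency_hz)
        tau = max(plan.evoked_decay_tau_frac * sub.duration_s
                  * plan.stim_frequency_hz, 1.0)
        decay = exponential_plateau_decay(plan.evoked_plateau, tau)
        rec, egt = inject_evoked_responses(
            rec, protocol,
            {"amplitude": plan.evoked_amplitude * amp_unit},
            decay, plan.inter_channel_delay_s)
        gt.evoked = egt.evoked
        gt.evoked["decay_plateau"] = plan.evoked_plateau
        gt.evoked["decay_tau_pulses"] = tau
    gt.bursts.sort(key=lambda b: b.start_s)
    return rec, protocol, gt, boundaries


# ---------------------------------------------------------------------------
# reference corpus


def generate_reference_corpus(
        n_bursts: int,
        class_mixture_params: dict[str, BurstClassParams] | None = None,
        seed: int | np.random.Generator = 0,
        weights: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw burst feature vectors drawn from the load-class mixture.

    Stands in for a reference corpus of classified bursts: rows are
    un-normalized feature vectors [log10 spike count, log10 mean ISI (s),
    SD of ISIs (s)] with their generating class labels. Used to fit the
    reference normalization and train / calibrate the SOM.
    """
    params = class_mixture_params or DEFAULT_CLASS_PARAMS
    classes = list(params)
    if weights is None:
        weights = {c: 1.0 / len(classes) for c in classes}
    rng = np.random.default_rng(seed)
    counts = {c: max(1, int(round(n_bursts * weights[c]))) for c in classes}
    for c, k in counts.items():
        if k < 3:
            raise ValueError(f"need >= 3 bursts per mixture component ({c})")
    rows, labels = [], []
    for c in classes:
        p = params[c]
        for _ in range(counts[c]):
            n, isi, sd = _draw_class_burst(p, rng)
            rows.append((np.log10(n), np.log10(isi), sd))
            labels.append(c)
    feats = pd.DataFrame(rows, columns=["log10_count", "log10_mean_isi",
                                        "isi_sd"])
    if np.allclose(feats.var(axis=0), 0.0):
        warnings.warn("degenerate reference mixture: zero variance in every "
                      "feature dimension", stacklevel=2)
    return feats, np.asarray(labels)
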