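"""Core containers for LFP recordings and stimulation protocols.

An :class:`LFPRecording` holds one or more equal-length voltage traces with a
common sampling rate. Amplitudes are unitless by convention (µV-scale in the
recordings this package emulates); every threshold downstream is defined
relative to a noise estimate, never in absolute volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LFPRecording:
    """Multi-channel local field potential recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel voltage traces.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel, e.g. ``["idHC", "cdHC"]``.
    t0 : float
        Start time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs

    def channel(self, label_or_index: str | int) -> np.ndarray:
        """Return one channel's trace by label or integer index."""
        if isinstance(label_or_index, str):
            try:
                idx = self.channel_labels.index(label_or_index)
            except ValueError:
                raise KeyError(
                    f"no channel {label_or_index!r}; have {self.channel_labels}"
                ) from None
        else:
            idx = int(label_or_index)
        return self.samples[idx]

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "LFPRecording":
        return LFPRecording(
            self.samples.copy(), self.fs, list(self.channel_labels), self.t0
        )


@dataclass
class StimulationProtocol:
    """Train of stimulation pulses.

    ``pulse_times`` are onset times in seconds, strictly increasing.
    ``frequency`` is the nominal pulse rate (Hz); successive onsets must be
    at least one period apart (within numerical tolerance) when declared.
    """

    pulse_times: np.ndarray
    pulse_duration: float
    frequency: float | None = None
    modality: str = "optical"

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.pulse_times.size and np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        if self.frequency is not None and self.pulse_times.size > 1:
            gaps = np.diff(self.pulse_times)
            if np.any(gaps < 1.0 / self.frequency - 1e-9):
                raise ValueError(
                    "pulse onsets closer than 1/frequency for declared frequency"
                )
        if self.modality not in ("optical", "electrical"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)
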