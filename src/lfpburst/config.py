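"""Pipeline configuration: validated parameter sets for every stage.

A :class:`PipelineConfig` collects all tunable parameters, loads from YAML
(unknown keys are rejected, ranges validated), and serializes itself into
every output directory so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class DetectionConfig:
    window_s: float = 0.25
    overlap_frac: float = 0.9
    band_low_hz: float = 4.0
    band_high_hz: float = 40.0
    prominence_thr: float = 0.25
    k_mad: float = 5.0
    refractory_s: float = 0.1
    merge_window_s: float = 0.05
    amp_gate_frac: float = 0.8
    blank_pre_s: float = 0.01
    blank_post_s: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("detection.overlap_frac must be in [0, 1)")
        if self.k_mad <= 0:
            raise ValueError("detection.k_mad must be positive")
        if self.prominence_thr <= 0:
            raise ValueError("detection.prominence_thr must be positive")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("detection band must be increasing")


@dataclass
class BurstConfig:
    max_isi_s: float = 2.5
    min_spikes: int = 3
    grid_rows: int = 10
    grid_cols: int = 10
    epochs: int = 50
    weights: tuple[float, float, float] = (2.0, 2.0, 1.0)
    count_thresholds: tuple[float, float] = (12.0, 80.0)
    reference_corpus_size: int = 300
    model_path: str | None = None

    def validate(self) -> None:
        if self.max_isi_s <= 0:
            raise ValueError("bursts.max_isi_s must be positive")
        if self.min_spikes < 1:
            raise ValueError("bursts.min_spikes must be >= 1")
        if min(self.grid_rows, self.grid_cols) < 2:
            raise ValueError("SOM grid must be at least 2x2")


@dataclass
class MetricsConfig:
    min_pre_ratio: float = 0.05
    efficacy_threshold_pct: float = 75.0

    def validate(self) -> None:
        if self.min_pre_ratio < 0:
            raise ValueError("metrics.min_pre_ratio must be >= 0")


@dataclass
class EvokedConfig:
    filter_order: int = 4
    cutoff_hz: float = 300.0
    ripple_db: float = 1.0
    auc_mode: str = "baseline_subtracted_absolute"
    fit_degree: int = 3
    mean_window_min: float = 15.0
    protocol_type: str = "lfs"      # lfs -> (-0.1, +0.2) s; 10hz -> (-0.02, +0.06)

    def validate(self) -> None:
        if self.protocol_type not in ("lfs", "10hz"):
            raise ValueError("evoked.protocol_type must be 'lfs' or '10hz'")

    @property
    def window(self) -> tuple[float, float]:
        return (0.1, 0.2) if self.protocol_type == "lfs" else (0.02, 0.06)


@dataclass
class LatencyConfig:
    threshold_z: float = 2.0
    search_lo_s: float = 0.0
    search_hi_s: float = 0.05
    signed: bool = False

    def validate(self) -> None:
        if self.threshold_z <= 0:
            raise ValueError("latency.threshold_z must be positive")
        if not 0 <= self.search_lo_s < self.search_hi_s:
            raise ValueError("latency search window must be increasing")


@dataclass
class PipelineConfig:
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bursts: BurstConfig = field(default_factory=BurstConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    evoked: EvokedConfig = field(default_factory=EvokedConfig)
    latency: LatencyConfig = field(default_factory=LatencyConfig)

    def validate(self) -> "PipelineConfig":
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "validate"):
                v.validate()
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, val in d.items():
            f = sections[name]
            if isinstance(val, dict):
                sub_cls = f.default_factory  # type: ignore[union-attr]
                sub_fields = {sf.name for sf in fields(sub_cls())}
                bad = set(val) - sub_fields
                if bad:
                    raise ValueError(
                        f"unknown config keys in {name}: {sorted(bad)}")
                val = {k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in val.items()}
                kwargs[name] = sub_cls(**val)
            else:
                kwargs[name] = val
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)

        def listify(x):
            if isinstance(x, tuple):
                return list(x)
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        Path(path).write_text(yaml.safe_dump(listify(d), sort_keys=False))
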