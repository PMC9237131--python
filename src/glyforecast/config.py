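"""Pipeline configuration: every tunable referenced by the other modules,
with defaults and YAML round-tripping. Unknown keys are rejected so a typo
in a config file cannot silently fall back to a default."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .datatypes import InvalidArgumentError


@dataclass
class SimulateConfig:
    n_subjects: int = 4
    days: int = 14
    wristband_excerpt_hours: float = 1.0
    cgm_gap_fraction: float = 0.0302
    wristband_gap_fraction: float = 0.2305
    apply_gaps: bool = True


@dataclass
class SignalsConfig:
    bvp_band_hz: list = field(default_factory=lambda: [0.5, 8.0])
    bvp_filter_order: int = 3
    ssf_window_s: float = 0.128
    beat_refractory_s: float = 0.3
    beat_threshold_frac: float = 0.5
    beat_median_window: int = 8
    eda_cutoff_hz: float = 0.01
    eda_filter_order: int = 2
    ibi_valid_range_s: list = field(default_factory=lambda: [0.3, 2.0])
    hrv_min_intervals: int = 10


@dataclass
class FeaturesConfig:
    iob_duration_h: float = 4.0
    iob_knots: list = field(default_factory=lambda: [[0.0, 1.0], [1.0, 0.9]])
    cob_rate_g_per_min: float = 2.5
    cob_delay_min: float = 15.0
    window_length: int = 12
    horizons_steps: list = field(default_factory=lambda: [3, 6, 9, 12])
    tail_mode: str = "carry_forward"
    time_encoding: str = "linear"
    selected: list = field(default_factory=lambda: [
        "glucose", "cob", "iob", "time_index", "ibi_mean", "scr_mean"])


@dataclass
class ModelSection:
    hidden: int = 16
    hidden2: int = 16
    v_dim: int = 16
    reg_coef: float = 0.01
    u_inverse: str = "scale"


@dataclass
class TrainSection:
    inner_lr: float = 0.01
    outer_lr: float = 0.002
    inner_steps: int = 2
    meta_batch: int = 3
    finetune_lr: float = 1e-3
    max_epochs: int = 25
    patience: int = 5
    batch_size: int = 64
    outer_steps: int = 50
    threshold_grid_max: float = 5.0
    threshold_grid_step: float = 0.25
    default_k: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    signals: SignalsConfig = field(default_factory=SignalsConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            if name not in data:
                continue
            if name == "seed":
                kwargs["seed"] = int(data["seed"])
                continue
            sub_cls = f.default_factory  # type: ignore[union-attr]
            sub_fields = {sf.name for sf in fields(sub_cls)}
            sub_data = data[name] or {}
            bad = set(sub_data) - sub_fields
            if bad:
                raise InvalidArgumentError(
                    f"unknown config keys in '{name}': {sorted(bad)}")
            kwargs[name] = sub_cls(**sub_data)
        return cls(**kwargs)


__all__ = ["PipelineConfig", "SimulateConfig", "SignalsConfig",
           "FeaturesConfig", "ModelSection", "TrainSection"]
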