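"""Pipeline configuration: one flat YAML file drives a whole run.

Keys are namespaced per module section.  Unknown keys are rejected at load
time, and a loaded config serializes back to an equivalent file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .synth import DEFAULT_OPTO_GAIN, DEFAULT_TAU_TONES, SynthParams


@dataclass
class StimulusConfig:
    rates_hz: list = field(default_factory=lambda: [1.0, 2.0, 4.0])
    n_standards: int = 10
    std_freq_hz: float = 8000.0
    dev_freq_hz: float = 16000.0
    tone_dur_s: float = 0.1
    ramp_s: float = 0.005
    last_window_s: float = 1.0


@dataclass
class SynthConfig:
    image_shape: list = field(default_factory=lambda: [150, 200])
    fps: float = 20.0
    baseline_f0: float = 1000.0
    blob_centers: list = field(default_factory=lambda: [[75.0, 60.0], [75.0, 140.0]])
    blob_sigma_px: float = 15.0
    a1: float = 0.08
    a_inf: float = 0.028
    tau_tones: dict = field(default_factory=lambda: dict(DEFAULT_TAU_TONES))
    dev_gain: float = 0.9
    opto_gain: dict = field(default_factory=lambda: dict(DEFAULT_OPTO_GAIN))
    tau_rise_s: float = 0.04
    tau_decay_s: float = 0.4
    noise_sd: float = 10.0
    anatomy_amp: float = 0.15
    anatomy_sigma_px: float = 3.0
    bleach_tau_s: float = 300.0
    pre_s: float = 1.2
    post_s: float = 1.5
    n_trials_per_condition: int = 5

    def to_params(self, seed: int) -> SynthParams:
        return SynthParams(
            image_shape=tuple(self.image_shape),
            fps=self.fps,
            baseline_f0=self.baseline_f0,
            blob_centers=tuple(tuple(c) for c in self.blob_centers),
            blob_sigma_px=self.blob_sigma_px,
            a1=self.a1,
            a_inf=self.a_inf,
            tau_tones={float(k): float(v) for k, v in self.tau_tones.items()},
            dev_gain=self.dev_gain,
            opto_gain={float(k): float(v) for k, v in self.opto_gain.items()},
            tau_rise_s=self.tau_rise_s,
            tau_decay_s=self.tau_decay_s,
            noise_sd=self.noise_sd,
            anatomy_amp=self.anatomy_amp,
            anatomy_sigma_px=self.anatomy_sigma_px,
            bleach_tau_s=self.bleach_tau_s,
            pre_s=self.pre_s,
            post_s=self.post_s,
            seed=seed,
        )


@dataclass
class PreprocessConfig:
    baseline_s: float = 1.0
    butter_order: int = 2
    butter_cutoff: float = 0.05
    locmap_frames: int = 10


@dataclass
class RoiConfig:
    threshold_frac: float = 0.5
    anterior_axis: str = "+col"
    motion_check: bool = True
    motion_threshold_px: float = 2.0
    motion_search_px: int = 5
    mask_path: str | None = None  # escape hatch: user-supplied ROI mask TIFF


@dataclass
class QuantifyConfig:
    amplitude_mode: str = "rise"  # or "minmax"
    average_order: str = "traces_first"  # or "amplitudes_first"
    modulation_method: str = "mean_of_ratios"  # or "ratio_of_means"


@dataclass
class StatsConfig:
    alpha: float = 0.05
    gate_alpha: float = 0.05
    lilliefors_mc: int = 10000


@dataclass
class PipelineConfig:
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build(cls, raw, "")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


def _build(dc_type, raw: dict, prefix: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"section {prefix or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} in section {prefix or '<root>'}"
        )
    kwargs = {}
    for name, f in fields.items():
        if name not in raw:
            continue
        value = raw[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Config")
        ):
            sub_type = _SECTION_TYPES[name]
            kwargs[name] = _build(sub_type, value, f"{prefix}{name}.")
        else:
            kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except TypeError as exc:  # wrong value shape
        raise ConfigError(str(exc)) from exc


_SECTION_TYPES = {
    "stimulus": StimulusConfig,
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "roi": RoiConfig,
    "quantify": QuantifyConfig,
    "stats": StatsConfig,
}
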