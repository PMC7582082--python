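"""Run configuration: a YAML-serializable bundle of model + experiment settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .network import ModelParams
from .protocol import ExperimentSpec, Intervention, preset, PRESET_NAMES


@dataclass
class RunConfig:
    preset: str | None = "a1"
    epochs_total: int | None = None          # override the preset's span
    interventions: list[dict] = field(default_factory=list)  # inline spec if no preset
    params: dict = field(default_factory=dict)               # ModelParams overrides
    seed: int = 0
    n_repeats: int = 1
    snapshot_pcts: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50,
                                                              60, 70, 80, 90, 100])
    detector: dict = field(default_factory=dict)             # detector overrides
    outdir: str = "results"

    def model_params(self) -> ModelParams:
        return ModelParams(**self.params)

    def experiment_spec(self) -> ExperimentSpec:
        if self.preset is not None:
            spec = preset(self.preset)
            if self.epochs_total is not None:
                from dataclasses import replace
                spec = replace(spec, epochs_total=self.epochs_total)
            return spec
        ivs = tuple(Intervention(d["kind"], d["at_pct"], d.get("params", {}))
                    for d in self.interventions)
        return ExperimentSpec(name="custom", epochs_total=self.epochs_total or 2000,
                              interventions=ivs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
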