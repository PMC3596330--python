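"""Run configuration: scenario presets, generator overrides, analysis
parameters, seed, output directory. Loaded from YAML; unknown keys are
rejected so typos fail loudly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .synthgen import GROUP_PRESETS

_GROUP_KEYS = {"preset", "n_recordings", "overrides", "spontaneous_fraction"}


@dataclass
class GroupSpec:
    preset: str
    n_recordings: int = 3
    overrides: dict = field(default_factory=dict)
    spontaneous_fraction: float | None = None  # default from the preset

    def __post_init__(self):
        if self.preset not in GROUP_PRESETS and self.preset != "custom":
            raise ParameterError(f"unknown preset {self.preset!r}")
        if self.n_recordings < 1:
            raise ParameterError("n_recordings must be >= 1")
        ar = self.overrides.get("anisotropy_ratio")
        if ar is not None and ar < 1:
            raise ParameterError(f"anisotropy_ratio must be >= 1, got {ar}")


@dataclass
class RunConfig:
    scenario: str = "demo"
    groups: dict = field(default_factory=lambda: {
        name: GroupSpec(preset=name) for name in GROUP_PRESETS
    })
    angle_step_deg: float = 5.0
    isochrone_spacing_ms: float = 5.0
    derivative_threshold: float = 0.1
    noise_sd: float = 0.05          # optical movies, fraction of APA
    trace_noise_sd: float = 0.005   # microelectrode traces (far higher SNR)
    seed: int = 0
    out_dir: str = "cardiomap_results"

    _TOP_KEYS = frozenset({
        "scenario", "groups", "angle_step_deg", "isochrone_spacing_ms",
        "derivative_threshold", "noise_sd", "trace_noise_sd", "seed", "out_dir",
    })

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._TOP_KEYS
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "groups" in d:
            groups = {}
            for name, spec in d["groups"].items():
                bad = set(spec) - _GROUP_KEYS
                if bad:
                    raise ParameterError(f"unknown keys in group {name!r}: {sorted(bad)}")
                groups[name] = GroupSpec(**spec)
            d["groups"] = groups
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = {k: asdict(v) if isinstance(v, GroupSpec) else v
                       for k, v in self.groups.items()}
        return d
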