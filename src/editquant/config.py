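"""Flat JSON run configuration with strict key validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parameters shared by the simulate/indel/lmupcr subcommands."""

    seed: int = 0
    arm_length: int = 900
    gsp3_offset: int = 120
    n_molecules: int = 1000
    read_length: int = 250
    amplicon_halfwidth: int = 216
    umi_length: int = 8
    duplication: str = "geometric"
    duplication_param: float = 5.0
    sub_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    f_parental: float = 1.0
    f_indel: float = 0.0
    f_hdr: float = 0.0
    f_vector_fragment: float = 0.0
    half_window: int = 20
    mapq_min: int = 20
    min_unaligned: int = 10
    arm_prefix_length: int = 10
    enzymes: list = field(default_factory=lambda: ["HaeIII", "TaqI"])

    @property
    def duplication_dist(self) -> tuple:
        return (self.duplication, self.duplication_param)


def load_config(path_or_dict) -> RunConfig:
    """Load a flat JSON config file (or dict); unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"invalid JSON config: {exc}") from exc
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
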