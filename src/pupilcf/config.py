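"""Pipeline configuration: defaults, YAML files and CLI overrides.

Defaults reproduce the reference analysis choices: moderate-difficulty
paradigm (30 s epochs), rank test on task vs pooled rest samples, two-sided
p-values with the explicit dilation-direction requirement, Bonferroni
adjustment over m = 5 tasks at adjusted alpha 0.01, and the >= 4-of-5
subject rule.  Artifact flagging is OFF by default (raw traces are
analysed).  Precedence: CLI flag > config file > default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Literal

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    variant: Literal["moderate", "simple"] = "moderate"
    task_duration_s: float | None = None  # None -> variant default
    rest_duration_s: float | None = None
    method: str = "rank_sum"
    alternative: Literal["two_sided", "greater"] = "two_sided"
    rest_pooling: Literal["pooled", "both"] = "pooled"
    alpha: float = 0.01
    m: int = 5
    k: int = 4
    flag_artifacts: bool = False
    min_diameter_mm: float = 1.0
    max_step_mm: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> PipelineConfig:
    """Resolve a configuration from defaults, an optional YAML file and overrides.

    ``overrides`` entries with value ``None`` are ignored (unset CLI flags).
    Unknown keys raise a :class:`ConfigurationError`.
    """
    values: dict[str, Any] = {}
    known = {f.name for f in fields(PipelineConfig)}
    if path is not None:
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config file must be a mapping")
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(data)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in known:
            raise ConfigurationError(f"unknown config key {key!r}")
        values[key] = val
    return PipelineConfig(**values)
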