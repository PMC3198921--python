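"""Run configuration: YAML/JSON loading, validation, round-trip dumping.

A configuration is a flat mapping.  CLI flags override file values; the
effective configuration is echoed next to every output so any run can be
reproduced exactly from its own artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ValidationError
from .model import CompetitionParams, DensityState


@dataclass
class RunConfig:
    variant: str = "classic"
    beta1: float = 0.2
    beta2: float = 0.8
    mu1: float = 0.1
    mu2: float = 0.1
    k: float = 1.0
    v: float = 0.0
    rho1_0: float = 0.6
    rho2_0: float = 0.0001
    t_max: float = 500.0
    grid_points: int = 1000
    lattice_sites: int = 10000
    replicates: int = 100
    record_every: float = 1.0
    seed: int = 0
    out_prefix: str = "run"
    verbosity: str = "info"

    def params(self) -> CompetitionParams:
        return CompetitionParams(
            beta1=self.beta1, beta2=self.beta2, mu1=self.mu1, mu2=self.mu2,
            k=self.k, v=self.v,
        )

    def initial(self) -> DensityState:
        return DensityState(self.rho1_0, self.rho2_0)

    def validate(self) -> "RunConfig":
        if self.variant not in ("classic", "general"):
            raise ValidationError(
                f"variant must be 'classic' or 'general', got {self.variant!r}"
            )
        self.params()
        self.initial()
        if self.t_max <= 0:
            raise ValidationError(f"t_max must be positive, got {self.t_max}")
        if self.grid_points < 2:
            raise ValidationError(f"grid_points must be >= 2, got {self.grid_points}")
        if self.lattice_sites < 1:
            raise ValidationError(f"lattice_sites must be >= 1, got {self.lattice_sites}")
        if self.record_every <= 0:
            raise ValidationError(f"record_every must be positive, got {self.record_every}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_FIELDS = {f.name for f in fields(RunConfig)}


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML/JSON file and/or overrides.

    Unknown keys are rejected by name; ``overrides`` (typically CLI flags,
    with None meaning "not given") win over file values.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)  # YAML superset: plain JSON also parses
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: val for k, val in overrides.items() if val is not None})
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data).validate()


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
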