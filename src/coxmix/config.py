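"""Run configuration: one validated dataclass, YAML-loadable, with every
module default in one place so logged manifests fully describe a run."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import CoxmixError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    grid_B: int = 100
    prior_kappa: float = 1.0
    prior_ridge: float = 1e-8
    laplace_tol: float = 1e-8
    laplace_max_iter: int = 100
    dp_m: float = 1.0
    mcmc_iters: int = 200
    mcmc_burn_in: int = 0
    seed: int = 0
    L: float = 50.0
    window_bp: int = 2000

    def __post_init__(self):
        if self.grid_B < 4:
            raise CoxmixError("grid_B must be >= 4")
        if self.prior_kappa <= 0 or self.prior_ridge <= 0:
            raise CoxmixError("prior_kappa and prior_ridge must be positive")
        if self.laplace_tol <= 0 or self.laplace_max_iter < 1:
            raise CoxmixError("invalid Laplace solver settings")
        if self.dp_m <= 0:
            raise CoxmixError("dp_m must be positive")
        if not (self.mcmc_iters > self.mcmc_burn_in >= 0):
            raise CoxmixError("require mcmc_iters > mcmc_burn_in >= 0")
        if self.L <= 0:
            raise CoxmixError("L must be positive")
        if self.window_bp <= 0:
            raise CoxmixError("window_bp must be positive")
        if not isinstance(self.seed, int):
            raise CoxmixError("seed must be an integer")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CoxmixError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise CoxmixError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return asdict(self)
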