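"""Flat key-value run configuration (YAML mapping, one key per symbol)."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .parameters import (Geometry, ModelParameters, Physiology,
                         molecules_from_molar)

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # geometry
    N: int = 20
    l: float = 100e-6
    w: float = 10e-6
    lambda_: float = 0.5e-6
    L_s: float = 2e-3
    # physiology
    P_diff: float = 5.6e-7
    P_PIN: float = 3.3e-6
    D: float = 6.7e-10
    pH_c: float = 7.2
    pH_a: float = 5.3
    pK: float = 4.8
    V: float = -0.120
    T: float = 295.15
    F_D: float = 96485.3399
    R: float = 8.314472
    # initial load: either a molecule count or a molar concentration
    C: int = 12044
    conc_molar: float = None
    # solver settings
    t_end: float = 24000.0
    dt_record: float = 10.0
    rtol: float = 1e-8
    n_runs: int = 100
    base_seed: int = 0
    include_pin_backflux_ssa: bool = False
    include_pin_backflux_ode: bool = True

    def model_parameters(self) -> ModelParameters:
        geom = Geometry(N=self.N, l=self.l, w=self.w, lambda_=self.lambda_,
                        L_s=self.L_s)
        phys = Physiology(P_diff=self.P_diff, P_PIN=self.P_PIN, D=self.D,
                          pH_c=self.pH_c, pH_a=self.pH_a, pK=self.pK,
                          V=self.V, T=self.T, F_D=self.F_D, R=self.R)
        C = self.C if self.conc_molar is None else \
            molecules_from_molar(self.conc_molar, geom)
        return ModelParameters(geometry=geom, physiology=phys, C=C)


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML configuration.

    Unknown keys are rejected; all problems are reported in one error.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    problems = [f"unknown key {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    for name in ("l", "w", "lambda_", "L_s"):
        if getattr(cfg, name) <= 0:
            problems.append(f"key {name!r} must be positive")
    if cfg.N < 1:
        problems.append("key 'N' must be >= 1")
    if cfg.C < 0:
        problems.append("key 'C' must be >= 0")
    if cfg.T <= 0:
        problems.append("key 'T' must be positive")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
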