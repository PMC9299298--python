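"""Run configuration: a flat, unit-checked surface over the model parameters,
the actin network specification, the schedule and the feature switches.

Configs load from YAML or JSON (YAML is a superset); unknown keys and
invariant violations raise :class:`ConfigError` naming the offending key.
Units are fixed throughout: nm, s, uM, per um^2, degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .actin import ActinNetworkSpec, projected_length
from .geometry import PeriodicDomain
from .state import KineticParams, SystemState, init_state

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # schedule
    seed: int = 0
    duration: float = 10.0  # s
    snapshot_interval: float = 1.0  # s
    trajectory_interval: float = 0.01  # s
    # domain
    domain_width: float = 1000.0  # nm
    domain_height: float = 1000.0  # nm
    # kinetics / geometry
    dt: float = 1e-5
    D: float = 1e5
    D_rot: Optional[float] = None
    r_cad: float = 2.5
    dc_trans: float = 1.5
    dc_cis: float = 3.0
    dc_cad_actin: float = 3.5
    a_c_deg: float = 30.0
    theta_trans_deg: float = 90.0
    theta_cis_deg: float = 180.0
    kass_trans: float = 1e5
    kdis_trans: float = 1.0
    kass_cis: float = 1e5
    kdis_cis: float = 1e3
    kass_cad_actin: float = 1e5
    kdis_cad_actin: float = 0.1
    cad_density: float = 1200.0
    # actin network
    actin_conc: float = 0.0
    h_actin: float = 100.0
    L_F: Optional[float] = 200.0  # explicit length wins over phi_deg
    phi_deg: Optional[float] = None
    binding_fraction: float = 0.2
    actin_lifetime: float = math.inf
    # switches
    actin_obstruction: bool = True
    actin_binding: bool = True
    angle_convention: str = "packing"
    # output
    out_dir: Optional[str] = None
    # optional convergence stop on cumulative binding events
    convergence_tol: Optional[float] = None
    convergence_window: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation / resolution -----------------------------------------
    def validate(self) -> None:
        if self.L_F is None and self.phi_deg is None:
            raise ConfigError("one of L_F or phi_deg must be set")
        if self.phi_deg is not None and not (0.0 <= self.phi_deg < 90.0):
            raise ConfigError(f"phi_deg must be in [0, 90), got {self.phi_deg}")
        for key in ("duration", "snapshot_interval", "trajectory_interval"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0, got {getattr(self, key)}")
        try:
            self.kinetic_params()
        except ValueError as e:
            raise ConfigError(str(e)) from e

    def resolved_L_F(self) -> float:
        if self.L_F is not None:
            return float(self.L_F)
        return projected_length(self.h_actin, self.phi_deg)

    def resolved_phi_deg(self) -> Optional[float]:
        """Tilt angle; back-computed from an explicit L_F for the record."""
        if self.phi_deg is not None and self.L_F is None:
            return self.phi_deg
        if self.h_actin <= 0:
            return None
        return math.degrees(math.atan(self.resolved_L_F() / self.h_actin))

    # -- views into the component types -----------------------------------
    def domain(self) -> PeriodicDomain:
        return PeriodicDomain(self.domain_width, self.domain_height)

    def kinetic_params(self) -> KineticParams:
        return KineticParams(
            dt=self.dt, D=self.D, D_rot=self.D_rot, r_cad=self.r_cad,
            dc_trans=self.dc_trans, dc_cis=self.dc_cis,
            dc_cad_actin=self.dc_cad_actin, a_c_deg=self.a_c_deg,
            theta_trans_deg=self.theta_trans_deg, theta_cis_deg=self.theta_cis_deg,
            kass_trans=self.kass_trans, kdis_trans=self.kdis_trans,
            kass_cis=self.kass_cis, kdis_cis=self.kdis_cis,
            kass_cad_actin=self.kass_cad_actin, kdis_cad_actin=self.kdis_cad_actin,
            h_actin=self.h_actin, L_F=self.resolved_L_F(),
            actin_conc=self.actin_conc, cad_density=self.cad_density,
            binding_fraction=self.binding_fraction,
            actin_lifetime=self.actin_lifetime,
            angle_convention=self.angle_convention,
        )

    def actin_spec(self) -> ActinNetworkSpec:
        return ActinNetworkSpec(
            phi_deg=self.phi_deg, h_actin=self.h_actin, L_F=self.L_F,
            actin_conc=self.actin_conc, binding_fraction=self.binding_fraction,
            lifetime=self.actin_lifetime,
        )

    def initial_state(self) -> SystemState:
        ss = np.random.SeedSequence(self.seed)
        init_ss, _ = ss.spawn(2)
        return init_state(self.domain(), self.kinetic_params(),
                          np.random.default_rng(init_ss))

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    # -- (de)serialisation -------------------------------------------------
    def resolved_dict(self) -> dict:
        d = asdict(self)
        d["L_F"] = self.resolved_L_F()
        d["phi_deg"] = self.resolved_phi_deg()
        d["D_rot"] = self.kinetic_params().D_rot
        if math.isinf(d["actin_lifetime"]):
            d["actin_lifetime"] = "inf"
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.resolved_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        # YAML 1.1 reads "1.0e4" (no signed exponent) as a string; coerce
        # numeric fields so scientific notation works either way
        string_fields = {"angle_convention", "out_dir", "actin_lifetime"}
        for key, val in data.items():
            if key not in string_fields and isinstance(val, str):
                try:
                    data[key] = float(val)
                except ValueError as e:
                    raise ConfigError(f"{key}: expected a number, got {val!r}") from e
        if "seed" in data:
            data["seed"] = int(data["seed"])
        if isinstance(data.get("actin_lifetime"), str):
            if data["actin_lifetime"].lower() in ("inf", "infinity"):
                data["actin_lifetime"] = math.inf
            else:
                raise ConfigError(
                    f"actin_lifetime must be a number or 'inf', got {data['actin_lifetime']!r}"
                )
        try:
            return cls(**data)
        except TypeError as e:
            raise ConfigError(str(e)) from e


def load_config(path) -> RunConfig:
    """Load, unit-check and resolve a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)
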