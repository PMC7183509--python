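"""Model parameters and run configuration.

Defaults are the reference operating point of the controller: 0.01 s Euler
steps, 300 agents (multi-agent) or 1 agent with 300 virtual particles
(single-entity), input gains summing to one, and spatial scales ``sigma``,
``kappa`` and ``D_max`` expressed in units of the arena's notional radius.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelParams", "RunConfig", "ConfigError", "load_params", "load_config"]


class ConfigError(ValueError):
    """Invalid parameter set or run configuration."""


@dataclass(frozen=True)
class ModelParams:
    """All tunable constants of the controller.

    Scaled parameters (``D_max``, ``sigma``, ``kappa``) are dimensionless
    multiples of the arena's notional radius; ``lambda_wall`` and ``d_rad``
    are absolute lengths in points; ``omega0``/``omegaI`` are in cycles/s and
    converted to radians internally by the phase update.
    """

    dt: float = 0.01            # s, integration time step
    duration: float = 180.0     # s, total simulated time
    N: int = 300                # physical agents (1 in single-entity mode)
    N_s: int = 300              # internal fields / virtual particles
    D_max: float = 1.0          # max inter-agent visibility range (scaled)
    E_max: float = 3e3          # kg point^2/s^2, kinetic energy cap
    mu: float = 0.9             # momentum coefficient in [0, 1]
    m_mean_multi: float = 0.3   # kg, mean agent mass (multi-agent)
    m_single: float = 3.0       # kg, agent mass (single-entity)
    sigma: float = 1.0          # swarm kernel scale (scaled)
    kappa: float = 1.0          # reward kernel scale (scaled)
    eta: float = 1.0            # swarm learning rate
    eta_r: float = 1.0          # reward learning rate
    omega0: float = 0.0         # cycles/s, baseline oscillation frequency
    omegaI: float = 1.0         # cycles/s, max activation-driven increase
    g_c: float = 0.4            # cue input gain
    g_r: float = 0.2            # reward input gain
    g_s: float = 0.4            # swarming input gain
    tau_c: float = 0.5          # s, cue input time constant
    tau_r: float = 0.5          # s, reward input time constant
    tau_q: float = 0.1          # s, recurrent input time constant
    d_rad: float = 0.0          # points, reward contact radius (<=0: no capture)
    alpha: float = 0.5          # swarm/reward offset mixing in [0, 1]
    lambda_wall: float = 20.0   # points, wall-proximity kernel scale
    # implementation conventions
    w_clamp_min: float = 1e-6   # weight floor so kernel inversion is defined
    sign_convention: str = "functional"   # or "as-printed"
    kernel_inverse: str = "exact"         # or "as-printed"
    mass_jitter: float = 0.5    # multi-agent masses ~ U[1-j, 1+j] * mean
    freeze_invisible_particles: bool = True

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if min(self.tau_c, self.tau_r, self.tau_q) <= 0:
            raise ConfigError("time constants must be positive")
        if self.dt >= min(self.tau_c, self.tau_r, self.tau_q):
            raise ConfigError("dt must be smaller than every time constant")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError("mu must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")
        if not 0.0 < self.w_clamp_min < 1.0:
            raise ConfigError("w_clamp_min must lie in (0, 1)")
        if abs(self.g_c + self.g_r + self.g_s - 1.0) > 1e-9:
            raise ConfigError("input gains g_c + g_r + g_s must sum to 1")
        if min(self.g_c, self.g_r, self.g_s) < 0:
            raise ConfigError("input gains must be non-negative")
        if self.sigma <= 0 or self.kappa <= 0:
            raise ConfigError("sigma and kappa must be positive")
        if self.E_max <= 0 or self.m_mean_multi <= 0 or self.m_single <= 0:
            raise ConfigError("E_max and masses must be positive")
        if not 0.0 <= self.mass_jitter < 1.0:
            raise ConfigError("mass_jitter must lie in [0, 1)")
        if self.sign_convention not in ("functional", "as-printed"):
            raise ConfigError(f"unknown sign_convention {self.sign_convention!r}")
        if self.kernel_inverse not in ("exact", "as-printed"):
            raise ConfigError(f"unknown kernel_inverse {self.kernel_inverse!r}")
        if self.N < 1 or self.N_s < 1:
            raise ConfigError("N and N_s must be at least 1")

    def replace(self, **kwargs) -> "ModelParams":
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        p = dataclasses.replace(self, **kwargs)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p


MODES = ("multi", "single")


@dataclass(frozen=True)
class RunConfig:
    """One simulation: parameters, mode, seed and recording cadence."""

    params: ModelParams
    mode: str = "multi"
    seed: int = 0
    record_every: int = 10

    def validate(self) -> None:
        self.params.validate()
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "multi" and self.params.N != self.params.N_s:
            raise ConfigError("multi-agent mode requires N == N_s")
        if self.mode == "single" and self.params.N != 1:
            raise ConfigError("single-entity mode requires N == 1")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "mode": self.mode,
            "seed": self.seed,
            "record_every": self.record_every,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {"params", "mode", "seed", "record_every"}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(
            params=ModelParams.from_dict(d.get("params", {})),
            mode=d.get("mode", "multi"),
            seed=int(d.get("seed", 0)),
            record_every=int(d.get("record_every", 10)),
        )
        cfg.validate()
        return cfg


def _read_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_params(path) -> ModelParams:
    """Read a YAML/JSON parameter file; unknown keys are errors."""
    return ModelParams.from_dict(_read_structured(path))


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration; a bare parameter mapping (no
    ``params`` key) is promoted to a default-mode config."""
    d = _read_structured(path)
    if "params" not in d:
        cfg = RunConfig(params=ModelParams.from_dict(d))
        cfg.validate()
        return cfg
    return RunConfig.from_dict(d)
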