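"""Simulation driver: initialization, the per-step update pipeline,
recording and parameter sweeps.

A step executes synchronously (all inputs read the previous step's phases
and positions): geometry couplings are refreshed, kernels rebuilt, the
cue/reward/recurrent integrators advanced, activation and phase updated,
weights perturbed once by the Oja rule and clamped, inverted to desired
distances, aggregated into barrier-aware offsets that move the internal
field locations, and finally the physical agents chase their fields through
the kinematic filter. Reward capture is checked at the new positions.

Everything random happens at initialization from one seeded generator, so a
(config, seed) pair reproduces a run bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import motion as mot
from .geometry import Arena
from .params import ConfigError, ModelParams, RunConfig

__all__ = [
    "SwarmState",
    "Scales",
    "SimulationError",
    "initialize",
    "step",
    "run",
    "sweep",
    "RunRecord",
]


class SimulationError(RuntimeError):
    """Non-finite state or a violated invariant during integration."""


@dataclass(frozen=True)
class Scales:
    """Arena-scaled lengths: sigma, kappa and D_max multiplied by the
    notional radius."""

    sigma_eff: float
    kappa_eff: float
    d_max_eff: float

    @classmethod
    def for_arena(cls, params: ModelParams, arena: Arena) -> "Scales":
        R = arena.notional_radius
        return cls(params.sigma * R, params.kappa * R, params.D_max * R)


@dataclass
class SwarmState:
    """Kinematic and neural per-agent state.

    ``x``/``v``/``m`` are physical agent arrays (N rows); ``theta``/``p``
    and the field locations ``x_s`` have N_s rows (equal to N in multi-agent
    mode). ``captured`` is (N, N_r) in multi-agent mode and (N_r,) in
    single-entity mode; ``capture_events`` collects (time, agent, reward)
    tuples as they happen.
    """

    x: np.ndarray
    v: np.ndarray
    m: np.ndarray
    theta: np.ndarray
    p: np.ndarray
    x_s: np.ndarray
    captured: np.ndarray
    capture_events: list = field(default_factory=list)


def _sample_in_disk(rng, arena: Arena, center, radius, n, max_tries=10000):
    """Uniform rejection sampling inside (disk ∩ allowable interior)."""
    out = np.empty((n, 2))
    cx, cy = center
    got = 0
    tries = 0
    while got < n:
        if tries >= max_tries + n * 100:
            raise ConfigError(
                f"spawn disk at {center} has (near-)empty allowable intersection"
            )
        tries += 1
        rad = radius * np.sqrt(rng.random())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        p = (cx + rad * np.cos(ang), cy + rad * np.sin(ang))
        if arena.point_allowable(p):
            out[got] = p
            got += 1
    return out


def _sample_allowable(rng, arena: Arena, n, max_tries=100000):
    """Uniform rejection sampling over the allowable interior."""
    xmin, ymin, xmax, ymax = arena.bounds
    out = np.empty((n, 2))
    got = 0
    tries = 0
    while got < n:
        if tries >= max_tries + n * 1000:
            raise ConfigError("could not sample allowable interior points")
        tries += 1
        p = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if arena.point_allowable(p):
            out[got] = p
            got += 1
    return out


def _spawn_positions(rng, arena: Arena, n):
    """Round-robin assignment of n positions to the arena's spawn disks."""
    disks = arena.spawn_disks
    if not disks:
        return _sample_allowable(rng, arena, n)
    out = np.empty((n, 2))
    for i in range(n):
        disk = disks[i % len(disks)]
        out[i] = _sample_in_disk(rng, arena, disk.center, disk.radius, 1)[0]
    return out


def initialize(arena: Arena, config: RunConfig) -> tuple[SwarmState, dyn.CouplingState]:
    """Build the initial state: zero velocities, inputs and activations;
    uniform random phases; spawn-disk positions; cue preferences from the
    cues visible at one random allowable location per unit."""
    config.validate()
    p = config.params
    rng = np.random.default_rng(config.seed)
    mode = config.mode
    n_units = p.N_s
    n_c = len(arena.cues)
    n_r = len(arena.rewards)

    x = _spawn_positions(rng, arena, p.N)
    if mode == "single":
        x_s = _spawn_positions(rng, arena, n_units)
        m = np.full(p.N, p.m_single)
        captured = np.zeros(n_r, dtype=bool)
    else:
        x_s = x.copy()
        j = p.mass_jitter
        m = p.m_mean_multi * rng.uniform(1.0 - j, 1.0 + j, p.N)
        captured = np.zeros((p.N, n_r), dtype=bool)

    theta = rng.uniform(0.0, 2.0 * np.pi, n_units)

    coup = dyn.CouplingState.zeros(n_units, n_c, n_r)
    if n_c:
        pref_pts = _sample_allowable(rng, arena, n_units)
        for i in range(n_units):
            for k in range(n_c):
                if arena.line_of_sight(pref_pts[i], arena.cues[k].xy):
                    coup.V_cstar[i, k] = 1.0

    state = SwarmState(
        x=x,
        v=np.zeros((p.N, 2)),
        m=m,
        theta=theta,
        p=np.zeros(n_units),
        x_s=x_s,
        captured=captured,
    )
    return state, coup


def step(
    state: SwarmState,
    coup: dyn.CouplingState,
    arena: Arena,
    params: ModelParams,
    mode: str,
    scales: Scales,
    t: float = 0.0,
) -> None:
    """Advance the simulation by one time step (in place)."""
    dt = params.dt
    units_pos = state.x_s if mode == "single" else state.x

    # (1) geometry couplings
    dyn.refresh_geometry_couplings(
        coup, units_pos, arena, scales.d_max_eff, state.captured, mode,
        agent_pos=state.x if mode == "single" else None,
    )
    # (2) kernels
    W = dyn.swarm_kernel(coup.V, coup.D, scales.sigma_eff)
    W_r = dyn.reward_kernel(coup.V_r, coup.D_r, scales.kappa_eff)
    # (3) input integrators (previous phases; synchronous update)
    coup.c = dyn.step_cue_inputs(coup.c, coup.V_c, coup.V_cstar, params.tau_c, dt)
    coup.r = dyn.step_reward_inputs(coup.r, coup.V_r, params.tau_r, dt)
    coup.q = dyn.step_recurrent_inputs(coup.q, coup.V, state.theta, params.tau_q, dt)
    # (4) activation and phase
    I_c, I_r, I_q = dyn.net_inputs(
        coup.c, coup.r, coup.q, W, W_r, coup.V_c, coup.V_r, coup.V,
        (params.g_c, params.g_r, params.g_s),
    )
    state.p = dyn.activation(I_c, I_r, I_q)
    state.theta = dyn.advance_phase(
        state.theta, state.p, params.omega0, params.omegaI, dt
    )
    # (5) learning (single-entity mode masks rows by particle visibility)
    mask = coup.V_delta if mode == "single" else None
    W_p = dyn.oja_update_swarm(W, state.p, coup.q, coup.V, params.eta, dt, mask)
    W_rp = dyn.oja_update_reward(W_r, state.p, coup.r, coup.V_r, params.eta_r, dt, mask)
    W_p = dyn.clamp_weights(W_p, params.w_clamp_min)
    W_rp = dyn.clamp_weights(W_rp, params.w_clamp_min)
    coup.W, coup.W_r = W_p, W_rp
    # (6) kernel inversion to desired distances
    D_p = mot.invert_swarm_kernel(W_p, scales.sigma_eff, params.kernel_inverse)
    D_rp = mot.invert_reward_kernel(W_rp, scales.kappa_eff)
    # (7) offsets, mixing, barrier embedding
    f = mot.swarm_offset(D_p, coup.D, coup.V, units_pos, params.sign_convention)
    f_r = mot.reward_offset(
        D_rp, coup.D_r, coup.V_r, units_pos, arena.reward_xy, params.sign_convention
    )
    dx = mot.combine_offsets(f, f_r, params.alpha)
    dx_b = mot.barrier_embed_offset(dx, state.x_s, arena, params.lambda_wall)
    # (8) move internal field locations (invisible particles optionally frozen)
    if mode == "single" and params.freeze_invisible_particles:
        dx_b = dx_b * (coup.V_delta > 0)[:, None]
    x_s_new, _ = mot.resolve_positions(arena, state.x_s, state.x_s + dx_b)
    state.x_s = x_s_new
    # (9) agent kinematics
    if mode == "single":
        v_s = mot.single_entity_guidance(
            coup.V_delta, state.p, state.x_s, state.x[0], dt
        ).reshape(1, 2)
        state.v, state.x = mot.filter_and_move(
            state.v, state.x, v_s, state.m, params, arena
        )
    else:
        state.v, state.x = mot.kinematic_update(
            state.v, state.x, state.x_s, state.m, params, arena
        )
    # (10) reward capture at the new positions
    if arena.reward_xy.shape[0] and params.d_rad > 0.0:
        dist = np.linalg.norm(
            state.x[:, None, :] - arena.reward_xy[None, :, :], axis=2
        )
        newly = dyn.apply_reward_capture(state.captured, dist, params.d_rad, mode)
        if newly.any():
            if mode == "single":
                for k in np.flatnonzero(newly):
                    state.capture_events.append((t, 0, int(k)))
            else:
                for i, k in zip(*np.nonzero(newly)):
                    state.capture_events.append((t, int(i), int(k)))


@dataclass
class RunRecord:
    """Time-indexed trajectory/state log plus run metadata."""

    times: np.ndarray          # (F,)
    x: np.ndarray              # (F, N, 2) agent positions
    v: np.ndarray              # (F, N, 2) agent velocities
    theta: np.ndarray          # (F, N_s) phases
    p: np.ndarray              # (F, N_s) activations
    x_s: np.ndarray            # (F, N_s, 2) field/particle locations
    captures: pd.DataFrame     # columns: time, agent, reward
    config: dict
    arena_name: str
    reward_ids: list
    invariants: dict

    @property
    def mode(self) -> str:
        return self.config["mode"]

    @property
    def seed(self) -> int:
        return self.config["seed"]

    def state_frame(self) -> pd.DataFrame:
        """Long-format per-(time, unit) table of the recorded neural state."""
        F, n_s = self.theta.shape
        t = np.repeat(self.times, n_s)
        unit = np.tile(np.arange(n_s), F)
        return pd.DataFrame(
            {
                "time": t,
                "unit": unit,
                "xs_x": self.x_s[:, :, 0].ravel(),
                "xs_y": self.x_s[:, :, 1].ravel(),
                "theta": self.theta.ravel(),
                "p": self.p.ravel(),
            }
        )

    def agent_frame(self) -> pd.DataFrame:
        F, n = self.x.shape[:2]
        t = np.repeat(self.times, n)
        agent = np.tile(np.arange(n), F)
        return pd.DataFrame(
            {
                "time": t,
                "agent": agent,
                "x": self.x[:, :, 0].ravel(),
                "y": self.x[:, :, 1].ravel(),
                "vx": self.v[:, :, 0].ravel(),
                "vy": self.v[:, :, 1].ravel(),
            }
        )

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config,
            "arena_name": self.arena_name,
            "reward_ids": self.reward_ids,
            "invariants": self.invariants,
        }
        (path / "config.json").write_text(json.dumps(meta, indent=2))
        self.agent_frame().to_csv(path / "agents.csv", index=False)
        self.state_frame().to_csv(path / "state.csv", index=False)
        self.captures.to_csv(path / "captures.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "RunRecord":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        agents = pd.read_csv(path / "agents.csv")
        statef = pd.read_csv(path / "state.csv")
        captures = pd.read_csv(path / "captures.csv")
        times = np.asarray(sorted(agents["time"].unique()))
        F = len(times)
        n = agents["agent"].nunique()
        n_s = statef["unit"].nunique()
        return cls(
            times=times,
            x=agents[["x", "y"]].to_numpy().reshape(F, n, 2),
            v=agents[["vx", "vy"]].to_numpy().reshape(F, n, 2),
            theta=statef["theta"].to_numpy().reshape(F, n_s),
            p=statef["p"].to_numpy().reshape(F, n_s),
            x_s=statef[["xs_x", "xs_y"]].to_numpy().reshape(F, n_s, 2),
            captures=captures,
            config=meta["config"],
            arena_name=meta["arena_name"],
            reward_ids=meta["reward_ids"],
            invariants=meta["invariants"],
        )


def run(arena: Arena, config: RunConfig) -> RunRecord:
    """Integrate a full simulation and return its record.

    Tracks running state-bound extrema (activation, integrator ranges,
    kinetic-energy ratio) in ``record.invariants``; raises
    :class:`SimulationError` with the step index on non-finite state.
    """
    config.validate()
    params = config.params
    scales = Scales.for_arena(params, arena)
    state, coup = initialize(arena, config)
    n_steps = int(round(params.duration / params.dt))

    frames_t = [0.0]
    frames = {key: [] for key in ("x", "v", "theta", "p", "x_s")}

    def snapshot():
        frames["x"].append(state.x.copy())
        frames["v"].append(state.v.copy())
        frames["theta"].append(state.theta.copy())
        frames["p"].append(state.p.copy())
        frames["x_s"].append(state.x_s.copy())

    snapshot()
    inv = {
        "p_min": 0.0, "p_max": 0.0,
        "c_min": 0.0, "c_max": 0.0,
        "r_min": 0.0, "r_max": 0.0,
        "q_min": 0.0, "q_max": 0.0,
        "energy_ratio_max": 0.0,
        "n_captured_monotone": True,
    }
    n_captured_prev = 0
    for k in range(1, n_steps + 1):
        t = k * params.dt
        step(state, coup, arena, params, config.mode, scales, t)
        if not (np.isfinite(state.x).all() and np.isfinite(state.p).all()):
            raise SimulationError(f"non-finite state at step {k}")
        inv["p_min"] = min(inv["p_min"], float(state.p.min()))
        inv["p_max"] = max(inv["p_max"], float(state.p.max()))
        if coup.c.size:
            inv["c_min"] = min(inv["c_min"], float(coup.c.min()))
            inv["c_max"] = max(inv["c_max"], float(coup.c.max()))
        if coup.r.size:
            inv["r_min"] = min(inv["r_min"], float(coup.r.min()))
            inv["r_max"] = max(inv["r_max"], float(coup.r.max()))
        inv["q_min"] = min(inv["q_min"], float(coup.q.min()))
        inv["q_max"] = max(inv["q_max"], float(coup.q.max()))
        energy = 0.5 * state.m * (state.v**2).sum(axis=1)
        inv["energy_ratio_max"] = max(
            inv["energy_ratio_max"], float((energy / params.E_max).max())
        )
        n_cap = int(np.count_nonzero(state.captured))
        if n_cap < n_captured_prev:
            inv["n_captured_monotone"] = False
        n_captured_prev = n_cap
        if k % config.record_every == 0:
            frames_t.append(t)
            snapshot()

    captures = pd.DataFrame(
        state.capture_events, columns=["time", "agent", "reward"]
    )
    return RunRecord(
        times=np.asarray(frames_t),
        x=np.stack(frames["x"]),
        v=np.stack(frames["v"]),
        theta=np.stack(frames["theta"]),
        p=np.stack(frames["p"]),
        x_s=np.stack(frames["x_s"]),
        captures=captures,
        config=config.to_dict(),
        arena_name=arena.name,
        reward_ids=arena.reward_ids,
        invariants=inv,
    )


def sweep(
    arena: Arena,
    base_config: RunConfig,
    param_name: str,
    values,
    n_seeds: int,
    seeds=None,
) -> pd.DataFrame:
    """Run ``len(values) * n_seeds`` simulations, reusing one common seed
    list across parameter values, and tabulate per-reward capture times and
    the all-rewards success flag."""
    from .metrics import capture_statistics

    if seeds is None:
        seeds = [base_config.seed + i for i in range(n_seeds)]
    else:
        seeds = list(seeds)[:n_seeds]
    rows = []
    for value in values:
        for s in seeds:
            cfg = RunConfig(
                params=base_config.params.replace(**{param_name: value}),
                mode=base_config.mode,
                seed=s,
                record_every=base_config.record_every,
            )
            record = run(arena, cfg)
            stats = capture_statistics(record)
            row = {param_name: value, "seed": s, "success": stats.success}
            for rid in record.reward_ids:
                row[f"t_capture_{rid}"] = stats.times[rid]
            row["n_captured"] = sum(
                1 for v in stats.times.values() if v is not None
            )
            rows.append(row)
    return pd.DataFrame(rows)
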