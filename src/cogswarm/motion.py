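"""From learned weights to motion: kernel inversion, offset aggregation,
barrier-aware embedding, kinematic filtering and single-entity guidance.

Learned weights are mapped back through the inverse spatial kernels to
desired distances; the discrepancy between desired and actual distances,
averaged over visible neighbors/rewards, yields a positional offset for each
agent's internal field location. Offsets are deflected near walls by an
exponential proximity kernel; agents then chase their internal fields
through a momentum filter, a kinetic-energy speed limit, a second wall
deflection and hard collision resolution.

Sign convention: the default "functional" convention moves an agent toward a
neighbor/reward when the desired distance is smaller than the actual one
(weight growth under synchrony => approach); the "as-printed" alternative
flips the sign of the offset terms.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as _k
from .geometry import Arena
from .params import ModelParams

__all__ = [
    "invert_swarm_kernel",
    "invert_reward_kernel",
    "swarm_offset",
    "reward_offset",
    "combine_offsets",
    "barrier_embed_offset",
    "speed_limit",
    "filter_and_move",
    "kinematic_update",
    "single_entity_guidance",
    "resolve_positions",
]

#: retraction (points) applied before a wall crossing when a step is stopped
COLLISION_RETRACT = 1e-3


def invert_swarm_kernel(
    W_prime: np.ndarray, sigma_eff: float, convention: str = "exact"
) -> np.ndarray:
    """Desired inter-agent distances from learned swarm weights.

    "exact" is the exact inverse of the Gaussian kernel,
    D' = sigma * sqrt(-log W'); "as-printed" uses D' = sqrt(-2 sigma^2 log W'),
    which differs by a sqrt(2) factor absorbed into the effective scale.
    """
    logw = np.log(W_prime)
    if convention == "exact":
        return sigma_eff * np.sqrt(-logw)
    if convention == "as-printed":
        return np.sqrt(-2.0 * sigma_eff**2 * logw)
    raise ValueError(f"unknown kernel_inverse convention {convention!r}")


def invert_reward_kernel(W_r_prime: np.ndarray, kappa_eff: float) -> np.ndarray:
    """Desired agent-reward distances: exact inverse of the exponential
    kernel, D_r' = -kappa * log W_r'."""
    return -kappa_eff * np.log(W_r_prime)


def _scaled_adjacency(V, delta, dist) -> np.ndarray:
    """B_ij = V_ij * delta_ij / dist_ij with coincident points (dist 0)
    contributing zero."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dist > 0, V * delta / dist, 0.0)


def swarm_offset(
    D_prime: np.ndarray,
    D: np.ndarray,
    V: np.ndarray,
    x: np.ndarray,
    sign_convention: str = "functional",
) -> np.ndarray:
    """Desired positional offset averaged over visible neighbors:
    f_i = 1/(2 sum_j V_ij) * sum_j V_ij (D_ij - D'_ij) u_{i->j}
    under the functional convention (approach j when D' < D).

    Computed in matrix form: with B_ij = V_ij (D_ij - D'_ij)/D_ij,
    sum_j B_ij (x_j - x_i) = (B x)_i - (sum_j B_ij) x_i.
    """
    delta = (D - D_prime) if sign_convention == "functional" else (D_prime - D)
    B = _scaled_adjacency(V, delta, D)
    cnt = V.sum(axis=1)
    f = B @ x - B.sum(axis=1)[:, None] * x
    out = np.zeros_like(f)
    nz = cnt > 0
    out[nz] = f[nz] / (2.0 * cnt[nz])[:, None]
    return out


def reward_offset(
    D_r_prime: np.ndarray,
    D_r: np.ndarray,
    V_r: np.ndarray,
    x: np.ndarray,
    reward_xy: np.ndarray,
    sign_convention: str = "functional",
) -> np.ndarray:
    """Reward-oriented offset averaged over visible rewards (no 1/2 factor):
    f_r_i = 1/(sum_k V_ik) * sum_k V_ik (D_ik - D'_ik) u_{i->k}."""
    n = x.shape[0]
    if reward_xy.shape[0] == 0:
        return np.zeros((n, 2))
    delta = (D_r - D_r_prime) if sign_convention == "functional" else (D_r_prime - D_r)
    B = _scaled_adjacency(V_r, delta, D_r)
    cnt = V_r.sum(axis=1)
    f = B @ reward_xy - B.sum(axis=1)[:, None] * x
    out = np.zeros_like(f)
    nz = cnt > 0
    out[nz] = f[nz] / cnt[nz][:, None]
    return out


def combine_offsets(f: np.ndarray, f_r: np.ndarray, alpha: float) -> np.ndarray:
    """Linear mix of swarm- and reward-driven offsets."""
    return alpha * f + (1.0 - alpha) * f_r


def barrier_embed_offset(
    dx: np.ndarray, x_s: np.ndarray, arena: Arena, lambda_wall: float
) -> np.ndarray:
    """Deflect offsets near walls: dx_b = (1-beta) dx + beta |dx| n with
    beta = exp(-d/lambda) from the wall query at the internal field
    location. Far from walls dx passes through; at a wall the offset turns
    fully into the interior normal."""
    d, n = arena.wall_query_batch(x_s)
    beta = np.exp(-d / lambda_wall)[:, None]
    mag = np.linalg.norm(dx, axis=1, keepdims=True)
    return (1.0 - beta) * dx + beta * mag * n


def speed_limit(v_mu: np.ndarray, m: np.ndarray, E_max: float) -> np.ndarray:
    """Kinetic-energy-capped speed: |v_k| = v_max tanh(|v_mu|/v_max) with
    v_max = sqrt(2 E_max / m); the tanh keeps 1/2 m |v|^2 strictly below
    E_max for any input speed."""
    v_max = np.sqrt(2.0 * E_max / np.asarray(m, dtype=np.float64))
    sp = np.linalg.norm(v_mu, axis=1)
    scale = np.zeros_like(sp)
    nz = sp > 0
    scale[nz] = v_max[nz] * np.tanh(sp[nz] / v_max[nz]) / sp[nz]
    return scale[:, None] * v_mu


def resolve_positions(
    arena: Arena, x0: np.ndarray, x1: np.ndarray, vel: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Collision-resolve motion segments (x0 -> x1) against the walls.

    A crossing stops at the wall retracted by ``COLLISION_RETRACT`` and
    zeroes the wall-normal velocity component; unresolvable corner cases
    revert to the start point (which is always allowable).
    """
    if vel is None:
        vel = np.zeros_like(x0)
    return _k.resolve_collisions(
        np.ascontiguousarray(x0, dtype=np.float64),
        np.ascontiguousarray(x1, dtype=np.float64),
        np.ascontiguousarray(vel, dtype=np.float64),
        arena.seg_a,
        arena.seg_b,
        COLLISION_RETRACT,
    )


def filter_and_move(
    v: np.ndarray,
    x: np.ndarray,
    v_s: np.ndarray,
    m: np.ndarray,
    params: ModelParams,
    arena: Arena,
) -> tuple[np.ndarray, np.ndarray]:
    """Momentum filter, speed limit, wall deflection, step, collision
    resolution. Returns (v_new, x_new)."""
    v_mu = params.mu * v + (1.0 - params.mu) * v_s
    v_k = speed_limit(v_mu, m, params.E_max)
    d, n = arena.wall_query_batch(x)
    beta = np.exp(-d / params.lambda_wall)[:, None]
    mag = np.linalg.norm(v_k, axis=1, keepdims=True)
    v_new = (1.0 - beta) * v_k + beta * mag * n
    x_target = x + v_new * params.dt
    x_new, v_new = resolve_positions(arena, x, x_target, v_new)
    return v_new, x_new


def kinematic_update(
    v: np.ndarray,
    x: np.ndarray,
    x_s: np.ndarray,
    m: np.ndarray,
    params: ModelParams,
    arena: Arena,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-agent kinematics: chase the internal field location at the
    instantaneous velocity v_s = (x_s - x)/dt, then filter and move."""
    v_s = (x_s - x) / params.dt
    return filter_and_move(v, x, v_s, m, params, arena)


def single_entity_guidance(
    V_delta: np.ndarray, p: np.ndarray, x_s: np.ndarray, x: np.ndarray, dt: float
) -> np.ndarray:
    """Cubic-activation-weighted chase velocity toward the visible virtual
    particles: v_s = sum_i Vd_i p_i^3 (x_s_i - x) / (dt * sum_j Vd_j p_j^3);
    zero when no visible particle is active."""
    w = V_delta * p**3
    s = w.sum()
    if s <= 0.0:
        return np.zeros(2)
    return (w[:, None] * (x_s - x.reshape(1, 2))).sum(axis=0) / (dt * s)
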