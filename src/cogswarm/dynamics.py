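"""Neural state of the swarm: couplings, kernels, inputs, activation, phase,
and the Oja-rule learning updates.

The swarm is treated as a recurrent spatial network: mutually visible agent
pairs are "synaptically" connected with a Gaussian weight of their distance
(``W``), rewards project feedforward exponential-kernel weights (``W_r``),
and cue/reward/recurrent inputs are leaky integrators stepped with forward
Euler. Activation is a rectified sum of gain-weighted, visibility-normalized
inputs; it drives both the shared oscillation's per-agent phase and the
two-factor (Oja) weight updates whose implicit normalization supplies a
baseline repulsion between agents.

Weight matrices are rebuilt from geometry every step and then perturbed once
by learning; they are not persistent state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .geometry import EPS_LOS, Arena

__all__ = [
    "CouplingState",
    "refresh_geometry_couplings",
    "swarm_kernel",
    "reward_kernel",
    "step_cue_inputs",
    "step_reward_inputs",
    "step_recurrent_inputs",
    "net_inputs",
    "activation",
    "advance_phase",
    "oja_update_swarm",
    "oja_update_reward",
    "clamp_weights",
    "apply_reward_capture",
]

TWO_PI = 2.0 * np.pi


@dataclass
class CouplingState:
    """Pairwise and feedforward coupling state.

    ``V``/``D`` are symmetric zero-diagonal agent-pair visibility/distance
    matrices; ``V_r``/``D_r`` and ``V_c`` the agent-reward and agent-cue
    analogues (line-of-sight only). ``c``, ``r``, ``q`` are the integrator
    states; ``V_cstar`` the fixed cue preferences assigned at initialization;
    ``V_delta`` the particle-to-agent visibility mask (single-entity mode).
    """

    V: np.ndarray
    D: np.ndarray
    V_r: np.ndarray
    D_r: np.ndarray
    V_c: np.ndarray
    V_cstar: np.ndarray
    c: np.ndarray
    r: np.ndarray
    q: np.ndarray
    W: np.ndarray | None = None
    W_r: np.ndarray | None = None
    V_delta: np.ndarray | None = None

    @classmethod
    def zeros(cls, n: int, n_c: int, n_r: int) -> "CouplingState":
        return cls(
            V=np.zeros((n, n)),
            D=np.zeros((n, n)),
            V_r=np.zeros((n, n_r)),
            D_r=np.zeros((n, n_r)),
            V_c=np.zeros((n, n_c)),
            V_cstar=np.zeros((n, n_c)),
            c=np.zeros((n, n_c)),
            r=np.zeros((n, n_r)),
            q=np.zeros((n, n)),
        )


def refresh_geometry_couplings(
    coup: CouplingState,
    positions: np.ndarray,
    arena: Arena,
    d_max_eff: float,
    captured: np.ndarray,
    mode: str,
    agent_pos: np.ndarray | None = None,
    eps: float = EPS_LOS,
) -> CouplingState:
    """Rebuild V, D, V_r, D_r, V_c (and V_delta) from current geometry.

    ``positions`` are the network units' locations: physical agents in
    multi-agent mode, virtual particles in single-entity mode. Agent-pair
    visibility needs both line of sight and range <= ``d_max_eff``; reward
    and cue visibility are line-of-sight only. Captured rewards stay masked
    out of ``V_r`` permanently.
    """
    P = np.ascontiguousarray(positions, dtype=np.float64)
    coup.V, coup.D = _k.pair_visibility(P, arena.seg_a, arena.seg_b, d_max_eff, eps)
    n = P.shape[0]
    rxy = arena.reward_xy
    cxy = arena.cue_xy
    if rxy.shape[0]:
        coup.V_r, coup.D_r = _k.cross_visibility(P, rxy, arena.seg_a, arena.seg_b, eps)
    else:
        coup.V_r = np.zeros((n, 0))
        coup.D_r = np.zeros((n, 0))
    if cxy.shape[0]:
        coup.V_c, _ = _k.cross_visibility(P, cxy, arena.seg_a, arena.seg_b, eps)
    else:
        coup.V_c = np.zeros((n, 0))
    # captured rewards never become visible again
    if captured.size:
        if mode == "single":
            coup.V_r[:, captured] = 0.0
        else:
            coup.V_r[captured] = 0.0
    if mode == "single":
        A = np.ascontiguousarray(np.asarray(agent_pos, dtype=np.float64).reshape(1, 2))
        Vd, _ = _k.cross_visibility(P, A, arena.seg_a, arena.seg_b, eps)
        coup.V_delta = Vd[:, 0]
    else:
        coup.V_delta = None
    return coup


def swarm_kernel(V: np.ndarray, D: np.ndarray, sigma_eff: float) -> np.ndarray:
    """Gaussian distance-to-weight kernel W_ij = V_ij exp(-D_ij^2/sigma^2)."""
    return V * np.exp(-(D**2) / sigma_eff**2)


def reward_kernel(V_r: np.ndarray, D_r: np.ndarray, kappa_eff: float) -> np.ndarray:
    """Exponential reward kernel W_r = V_r exp(-D_r/kappa); the heavier tail
    supports long-range approach."""
    return V_r * np.exp(-D_r / kappa_eff)


def step_cue_inputs(c, V_c, V_cstar, tau_c: float, dt: float):
    """Forward-Euler step of tau_c dc/dt = V_c * V_c* - c (elementwise)."""
    return c + (dt / tau_c) * (V_c * V_cstar - c)


def step_reward_inputs(r, V_r, tau_r: float, dt: float):
    """Forward-Euler step of tau_r dr/dt = V_r - r."""
    return r + (dt / tau_r) * (V_r - r)


def step_recurrent_inputs(q, V, theta, tau_q: float, dt: float):
    """Forward-Euler step of tau_q dq_ij/dt = V_ij cos(theta_j - theta_i) - q_ij."""
    target = V * np.cos(theta[None, :] - theta[:, None])
    return q + (dt / tau_q) * (target - q)


def _normalized_sum(values: np.ndarray, vis: np.ndarray) -> np.ndarray:
    """Row sums of ``values`` divided by the visible count; empty rows are 0."""
    cnt = vis.sum(axis=1)
    total = values.sum(axis=1)
    out = np.zeros_like(total)
    nz = cnt > 0
    out[nz] = total[nz] / cnt[nz]
    return out


def net_inputs(c, r, q, W, W_r, V_c, V_r, V, gains):
    """Gain-modulated, visibility-normalized net inputs (I_c, I_r, I_q).

    Each term averages the relevant drive over the currently visible set and
    is zero when that set is empty. The cue numerator is masked by ``V_c``
    (only visible cues contribute, mirroring how ``W`` and ``W_r`` carry the
    visibility factor in the recurrent and reward terms); this keeps every
    net input within its gain and hence the activation within [0, 1] even
    while occluded cue traces are still decaying.
    """
    g_c, g_r, g_s = gains
    I_c = g_c * _normalized_sum(V_c * c, V_c)
    I_r = g_r * _normalized_sum(W_r * r, V_r)
    I_q = g_s * _normalized_sum(W * q, V)
    return I_c, I_r, I_q


def activation(I_c, I_r, I_q) -> np.ndarray:
    """Linear rectification of the summed net inputs; bounded in [0, 1] when
    the gains sum to 1."""
    return np.maximum(0.0, I_c + I_r + I_q)


def advance_phase(theta, p, omega0: float, omegaI: float, dt: float) -> np.ndarray:
    """Advance the shared-oscillation phase by the activation-modulated
    frequency: theta += 2*pi*(omega0 + omegaI*p)*dt, wrapped to [0, 2*pi).
    Frequencies are in cycles/s."""
    return np.mod(theta + TWO_PI * (omega0 + omegaI * p) * dt, TWO_PI)


def oja_update_swarm(W, p, q, V, eta: float, dt: float, mask=None) -> np.ndarray:
    """Oja-rule update of the swarm weights:
    W'_ij = W_ij + dt * eta * V_ij * mask_i * p_i * (q_ij - p_i * W_ij).

    The quadratic -p_i^2 W term implicitly normalizes each agent's incoming
    weights, which translates into baseline inter-agent repulsion.
    """
    gate = p if mask is None else mask * p
    return W + dt * eta * V * gate[:, None] * (q - p[:, None] * W)


def oja_update_reward(W_r, p, r, V_r, eta_r: float, dt: float, mask=None) -> np.ndarray:
    """Oja-rule update of the reward weights (feedforward analogue)."""
    gate = p if mask is None else mask * p
    return W_r + dt * eta_r * V_r * gate[:, None] * (r - p[:, None] * W_r)


def clamp_weights(W: np.ndarray, w_min: float) -> np.ndarray:
    """Clamp learned weights to [w_min, 1] so kernel inversion is defined;
    the floor encodes a saturated maximal desired distance."""
    return np.clip(W, w_min, 1.0)


def apply_reward_capture(
    captured: np.ndarray,
    dist_to_rewards: np.ndarray,
    d_rad: float,
    mode: str,
) -> np.ndarray:
    """Return the boolean mask of newly captured rewards.

    ``d_rad <= 0`` disables capture (rewards stay fixed). Multi-agent mode
    captures per (agent, reward) pair when the agent is within ``d_rad``;
    single-entity mode captures reward columns when the physical agent is.
    The captured set is monotone: entries only turn on.
    """
    if d_rad <= 0.0:
        return np.zeros_like(captured)
    if mode == "single":
        within = dist_to_rewards.reshape(-1) <= d_rad
    else:
        within = dist_to_rewards <= d_rad
    newly = within & ~captured
    captured |= newly
    return newly
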