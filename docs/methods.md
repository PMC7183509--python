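# Methods

`cogswarm` simulates a swarm controller built on an analogy between mobile
agents and hippocampal place cells: each agent is a spatial "neuron" whose
preferred (internal field) location indicates where it wants to be, mutually
visible agent pairs are synaptically connected, and the synaptic weight of a
connection is a fixed kernel function of the inter-agent distance. Swarming
then *is* learning: Hebbian weight changes, pushed back through the inverse
kernel, become desired changes in distance and hence motion.

## Model

### State

For `N_s` network units (physical agents in multi-agent mode; virtual
particles owned by one physical agent in single-entity mode) the state
comprises positions, velocities and masses of the physical agents; a phase
`theta_i` in a shared oscillation; an activation `p_i in [0, 1]`; an
internal field location `x_s_i`; and leaky-integrator input traces for cues
(`c`, per agent-cue pair), rewards (`r`, per agent-reward pair) and
recurrent swarm coupling (`q`, per agent pair).

### One step

Each 10 ms step executes synchronously (all inputs read the previous step's
phases and positions):

1. **Geometry couplings.** Pairwise visibility `V` requires line of sight
   and range `D <= D_max * R` where `R` is the arena's *notional radius*
   (radius of the disk with the allowable interior's area); agent-reward
   and agent-cue visibility are line-of-sight only.
2. **Kernels.** Swarm weights `W = V exp(-D^2/sigma^2)` (Gaussian) and
   reward weights `W_r = V_r exp(-D_r/kappa)` (exponential; the heavier
   tail supports long-range reward approach). `sigma` and `kappa` are
   multiples of `R`. Weights are rebuilt from geometry every step; they are
   not persistent state.
3. **Input traces.** Forward-Euler steps of
   `tau_c dc/dt = V_c ∘ V_c* - c`, `tau_r dr/dt = V_r - r`,
   `tau_q dq_ij/dt = V_ij cos(theta_j - theta_i) - q_ij`. The cosine makes
   the recurrent drive positive for synchronized pairs and negative for
   anti-phase pairs.
4. **Activation and phase.** Net inputs are gain-weighted averages over the
   currently visible sets (empty sets contribute 0), rectified into
   `p = [I_c + I_r + I_q]_+`; the phase advances by
   `2*pi*(omega0 + omegaI * p) * dt` — an input-driven oscillator, the
   rate-to-phase coupling of phaser cells.
5. **Learning.** One Oja-rule perturbation per step:
   `W' = W + dt*eta*V*p_i*(q - p_i W)` and the reward analogue with `r` in
   place of `q`. The implicit `-p^2 W` normalization depresses weights,
   which after inversion is a baseline inter-agent repulsion; synchrony
   (`q -> 1`) raises weights and produces attraction. Updated weights are
   clamped to `[1e-6, 1]` so the inversions below are defined; the floor
   encodes a saturated maximal desired distance.
6. **Inversion and offsets.** Desired distances `D' = sigma*sqrt(-log W')`
   and `D_r' = -kappa*log W_r'`. Each unit's positional offset averages
   `(D - D') u_{i->j}` over visible neighbors (with a factor 1/2) and
   `(D_r - D_r') u_{i->k}` over visible rewards, mixed by `alpha`.
7. **Barrier embedding.** Near walls the offset is deflected along the
   inward wall normal: `dx_b = (1-beta) dx + beta |dx| n` with
   `beta = exp(-d/lambda)`, `lambda = 20` points. The internal fields move
   by `dx_b` (collision-resolved, see below).
8. **Kinematics.** Agents chase their internal fields at
   `v_s = (x_s - x)/dt` (multi-agent) or, in single-entity mode, at the
   cubic-activation-weighted average of visible particle displacements —
   the cube compresses low-activation particles toward zero so the agent
   follows the most activated group decisively. The chase velocity passes
   through a momentum filter (`mu`), a kinetic-energy speed limit
   `|v| <= v_max tanh(|v_mu|/v_max)` with `v_max = sqrt(2 E_max/m)` (the
   tanh keeps kinetic energy strictly below `E_max`), a second wall
   deflection, and hard collision resolution.
9. **Reward capture.** With contact radius `d_rad > 0`, an agent arriving
   within `d_rad` of a reward permanently removes that reward from its own
   visibility (multi-agent) or from all particles (single-entity). The
   captured set is monotone. `d_rad = 0` (default) disables capture.

### Single-entity mode

One physical agent owns `N_s` virtual particles that carry the full neural
dynamics among themselves (their positions are their field locations).
A visibility mask `V_delta` (agent-to-particle line of sight) gates the
learning updates, and — with the default `freeze_invisible_particles=True` —
also zeroes invisible particles' offsets, so unseen particles stay put.
Exploration therefore advances at the mutual-visibility frontier: particles
only move where the agent can see them, and the agent only moves toward
particles.

## Parameters

Defaults (changeable per run; scaled entries are multiples of `R`):

| name | default | units | meaning |
|---|---|---|---|
| `dt` | 0.01 | s | Euler step |
| `duration` | 180 | s | simulated time |
| `N`, `N_s` | 300 | – | agents / internal fields (N=1 single-entity) |
| `D_max` | 1.0 | ×R | visibility range |
| `E_max` | 3e3 | kg pt²/s² | kinetic-energy cap |
| `mu` | 0.9 | – | momentum coefficient |
| `m_mean_multi`, `m_single` | 0.3, 3.0 | kg | agent masses |
| `sigma`, `kappa` | 1.0, 1.0 | ×R | kernel scales |
| `eta`, `eta_r` | 1.0 | – | learning rates |
| `omega0`, `omegaI` | 0.0, 1.0 | cycles/s | baseline / activation-driven frequency |
| `g_c`, `g_r`, `g_s` | 0.4, 0.2, 0.4 | – | input gains (sum to 1) |
| `tau_c`, `tau_r`, `tau_q` | 0.5, 0.5, 0.1 | s | trace time constants |
| `d_rad` | 0.0 | points | reward contact radius |
| `alpha` | 0.5 | – | swarm/reward offset mix |
| `lambda_wall` | 20 | points | wall-proximity kernel scale |

Multi-agent masses are drawn uniformly from `[0.5, 1.5] × m_mean_multi`
(`mass_jitter=0.5`); set `mass_jitter=0` for identical masses.

## Design choices at genuinely open points

- **Kernel inversion factor.** The Gaussian kernel `exp(-D^2/sigma^2)` and
  the inversion `sqrt(-2 sigma^2 log W')` are mutually inconsistent by a
  factor `sqrt(2)`: composed as written they turn every desired distance
  into `sqrt(2) D` *before* any learning, i.e. an unconditional ~41%
  per-step radial expansion that swamps the learning signal and produces
  explosive repulsion (offsets are applied per step, not per unit time).
  The default `kernel_inverse="exact"` uses the exact inverse
  `sigma*sqrt(-log W')`, under which pre-learning offsets vanish
  identically and all motion is learning-driven; `"as-printed"` is
  available as a config switch. The two self-consistent conventions differ
  only by a `sqrt(2)` rescaling of the free parameter `sigma`.
- **Offset sign.** Taken literally, the offset term
  `(D' - D) u_{i->j}` moves an agent *toward* a neighbor whose desired
  distance *exceeds* the actual one. The default
  `sign_convention="functional"` uses `(D - D') u_{i->j}` — approach when
  the desired distance is smaller — which is what makes weight growth under
  synchrony attractive and weight depression repulsive, and what makes
  reward-weight growth an approach. `"as-printed"` flips the sign.
- **Cue net input.** The cue drive is the visibility-masked average
  `g_c * sum_k(V_c ∘ c)/sum_k V_c`: only currently visible cues
  contribute, exactly as the recurrent and reward terms only count visible
  partners through `W` and `W_r`. Without the mask, decaying traces of
  recently occluded cues are divided by the (smaller) visible count and
  the net input can exceed its gain, breaking the `p in [0, 1]` bound that
  justifies plain rectification.
- **Collision resolution.** The barrier kernels soften wall approach but
  cannot prevent finite-step penetration, so any motion segment that
  crosses a wall stops at the crossing retracted by 1e-3 points, with the
  wall-normal velocity component zeroed. Internal field locations are
  collision-resolved in both modes: a field that tunnels through a wall
  would drag its chasing agent into the wall and pin it there.
- **Boundary conventions.** Points exactly on walls are not allowable
  (even-odd rule); sight segments are shrunk inward by 1e-6 points before
  intersection testing so grazing contact at shared wall vertices does not
  spuriously block visibility. Ties in nearest-wall queries go to the
  lowest segment index. Coincident points contribute zero offset.
- **Zero-visibility convention.** Every visibility-normalized average over
  an empty visible set is 0, never NaN or an error.

## Synthetic environments

Arenas are JSON-serializable polygonal environments (outer ring, hole
rings, point cues and rewards, circular spawn disks; y up; units "points").
Three generators produce the study environments:

- **Multi-reward arena** (700×500): compartments in the NW, SW and SE
  corners formed by short wall stubs traced into the boundary, plus one
  free-standing central obstacle; 3 rewards (one per compartment), 7
  seeded-random cues, 3 spawn disks (SW first, so a lone agent spawns
  south-west). The stubs are deliberately short: each reward is occluded
  from the other compartments but visible from much of the central band,
  which is what lets the long-range reward kernel recruit particles across
  compartments. Deep occlusion (full-height dividers) kills cross-
  compartment navigation at these kernel scales.
- **Hairpin maze** (885×519, 5 hallways): divider walls with alternating
  top/bottom gaps; rewards near the occluded ends of hallways 0, 2, 4;
  7 cues; 4 spawn disks centered in the first four hallways.
- **Open single-reward arena** (500×500): no obstacles, central reward;
  used for ring-formation and reward-approach studies.

Wall layouts are deterministic; cue placement is seeded rejection sampling
with wall-clearance and separation constraints, so arenas are
bit-reproducible per seed.

What the generators do *not* emulate: the original environments were
irregular blob-shaped vector drawings; these generators reproduce the
described topology (compartment counts, reward/cue/spawn counts,
dimensions), not exact coordinates. Passing tests therefore establish that
the controller's emergent behaviors arise in environments of the described
class, not that any particular trajectory is reproduced.

## Numerical notes

- Forward Euler at `dt = 0.01 s`; all trace updates are convex combinations
  for `dt < tau`, so `c, r in [0, 1]` and `q in [-1, 1]` are invariant.
- With frozen `p, q`, the Oja iteration contracts geometrically to
  `W = q/p` with ratio `1 - dt*eta*p^2` per step.
- All randomness (spawn positions, phases, masses, cue-preference sites)
  comes from one `numpy` generator seeded per run; a `(config, seed)` pair
  reproduces records bit for bit.
- Geometry hot paths (pairwise line of sight, wall distance/normal queries,
  collision resolution, point-in-polygon) are numba-compiled kernels with
  on-disk caching; a full 100-unit step costs ~1.5 ms on one core.

## Scaled-down study sizes

The packaged tests and the acceptance script run reduced problem sizes
chosen to preserve the phenomena: bound checks use N=50 for 30 s; ring
formation uses N=100 for 60 s; capture-radius sweeps use 100 virtual
particles (the reference configuration used 300). Horizon matters for
capture chains: in successful 180 s runs the three rewards fall at roughly
5–40 s, 50–130 s and 80–145 s, so a 60 s horizon shows the capture-count
trend across contact radii but essentially never an all-three success;
the acceptance script therefore runs its d_rad comparison at the full
180 s duration with 6 seeds per condition.

## Known limitations

- The shared oscillation is global and noiseless; no drift or independent
  perturbations.
- Agents are point particles: no agent-agent collision, heading dynamics or
  actuation noise.
- Line-of-sight visibility is binary and instantaneous; no sensing noise or
  field-of-view limits.
- Learning acts directly on rebuilt kernel weights each step; there is no
  persistent weight memory beyond the input traces.
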