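# cogswarm

A hippocampally inspired swarm controller in which **swarming is learning**:
each mobile agent is treated as a spatial neuron (a "place cell") whose
preferred location is its internal place field, mutually visible agent
pairs are synaptically connected, and the synaptic weight of a pair is a
spatial kernel of their distance. Oscillatory Hebbian learning (Oja's rule)
modifies those weights, and inverting the kernels turns the learned weights
back into desired distances — and hence motion. The same mechanism runs in
two modes:

- **multi-agent**: N agents swarm, synchronize phases, form rings and
  phase-sorted line segments, and navigate to rewards;
- **single-entity**: one physical agent is guided by an internal "cognitive
  swarm" of virtual particles, a model of spatial planning with remote
  internal representations.

The package is for computational neuroscientists and swarm-robotics
researchers who want a tested, deterministic simulator of these dynamics
with synthetic polygonal environments and quantitative structure metrics.

## Model core

With inter-agent visibility `V` and distances `D` (and agent–reward
analogues `V^r`, `D^r`), each step rebuilds

    W   = V ∘ exp(−D² / σ²)          (Gaussian swarm kernel)
    W^r = V^r ∘ exp(−D^r / κ)        (exponential reward kernel)

integrates cue/reward/recurrent input traces (`τ_c ċ = V^c∘V^c* − c`,
`τ_r ṙ = V^r − r`, `τ_q q̇ᵢⱼ = Vᵢⱼ cos(θⱼ−θᵢ) − qᵢⱼ`), rectifies the
gain-weighted visible-set averages into activation `p`, advances phases by
`θ̇ = 2π(ω₀ + ω_I p)`, applies one Oja update

    W′ᵢⱼ = Wᵢⱼ + Δt η Vᵢⱼ pᵢ (qᵢⱼ − pᵢ Wᵢⱼ)

(and the reward analogue with `r`), inverts the kernels to desired
distances `D′ = σ√(−log W′)`, `D^r′ = −κ log W^r′`, and moves each agent's
internal field by the visible-neighbor average of `(D − D′) û`, deflected
near walls by `β = exp(−d/λ)`. Agents chase their fields through a momentum
filter and a kinetic-energy speed limit `v_max = √(2E_max/m)`. Synchronized
pairs (`q → 1`) attract; the Oja normalization supplies baseline repulsion;
rewards attract at long range. Optionally, rewards are *captured* (stop
attracting) on contact within radius `d_rad`. See `docs/methods.md` for the
full update pipeline and design choices.

## Worked example

```python
import numpy as np
import cogswarm as cs

arena = cs.make_multireward_arena(seed=7)    # 700x500, 3 rewards, 7 cues
params = cs.ModelParams(N=1, N_s=100, duration=180.0, d_rad=15.0,
                        sigma=4.0, kappa=1.5, g_c=0.2, g_r=0.3, g_s=0.5)
rec = cs.run(arena, cs.RunConfig(params=params, mode="single", seed=103))

from cogswarm.metrics import capture_statistics
print(capture_statistics(rec).times)
```

prints

```
{'NW': 81.68, 'SW': 16.95, 'SE': 48.53}
```

— the single-entity agent, spawned in the south-west compartment and guided
by its 100-particle cognitive swarm, captures the south-west reward at
~17 s, crosses to the south-east compartment by ~49 s, and reaches the
occluded north-west reward at ~82 s. With `d_rad=0.0` (fixed rewards) the
same seed typically stays trapped at the first reward attractor it meets —
capture is what releases the agent to keep exploring.

The same API drives multi-agent swarms:

```python
arena = cs.make_open_arena(seed=11)          # one central reward
params = cs.ModelParams(N=100, N_s=100, duration=60.0,
                        sigma=1.5, g_c=0.2, g_r=0.3, g_s=0.5)
rec = cs.run(arena, cs.RunConfig(params=params, mode="multi", seed=2))

from cogswarm.metrics import ring_phase_score
R = arena.notional_radius
scores = [ring_phase_score(rec.x[f], rec.theta[f], arena.reward_xy[0], 0, 0.15 * R)
          for f in range(len(rec.times))]
best = max((s for s in scores if s is not None), key=abs)
print(round(best, 3))
```

prints `0.997` — a near-perfectly phase-sorted ring of agents around the
reward (bearing angle and oscillation phase circularly correlated), one of
the model's signature emergent formations.

A CLI wraps the same functionality:

```
cogswarm make-env multireward --seed 7 --out arena.json
cogswarm run --arena arena.json --mode single --seed 103 --out rec/
cogswarm sweep --arena arena.json --mode single --param d_rad \
               --values 0,15 --n-seeds 6 --out sweep.csv
cogswarm analyze --record rec/ --arena arena.json --out report.json
```

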