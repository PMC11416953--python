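# mbcx

Reinforcement-learning navigation circuits for insect-like agents, built
from the two brain regions that insect navigation runs on: the **central
complex** (CX), which carries vector computations — compass heading, path
integration, vector memories — as phasor population codes, and the
**mushroom body** (MB), which learns values over sparse visual codes
through dopamine-gated synaptic depression.

The package is for computational neuroscientists and bio-roboticists who
want a tested, rate-based implementation of this architecture: each circuit
is usable on its own, and they compose into a full hierarchical forager
that learns multi-feeder routes from external reward alone.

## The model in brief

- **Phasor codes.** A 2D vector (angle `a`, length `m`) is the amplitude
  and phase of a sinusoid across `N = 8` columns with preferred directions
  45° apart: `rate_i = baseline + m·cos(a − θ_i)`. Vector addition is
  element-wise rate addition, so path integration (`h ← h + v·dt`) and the
  shortcut computation (`goal = m − h`, from the stored negative imprint of
  a CPU4 snapshot) are exact.
- **MB value learning.** Kenyon cells give a sparse random code of the
  visual input; each action is a valence pair of output neurons with
  `Q(s,a) = M₊(a) − M₋(a)`. Dopaminergic neurons carry, depending on the
  wiring, direct reinforcement `R`, the prediction error `R − Q` (via
  same-timestep opposite-valence feedback), or the full one-step TD error

      Δ_t = R + γ·Q(s_t, a_t) − Q(s_{t−1}, a_{t−1})

  via a latency split: low-latency same-valence feedback carries `γ·Q(t)`,
  a one-step-delayed opposite-valence trace carries `Q(t−1)`. Plasticity is
  depression of the opposite-valence pathway by the phasic population
  signal; with one-hot coding the circuit *is* tabular SARSA (equal to
  1e-12 over 5000 steps, tested).
- **Visual homing.** Two hemispheric MB circuits associate panoramic
  skylines with steer-left/steer-right, trained off-policy by an internal
  CX reward that signals whether the goal lies left or right of the current
  heading (`r_l/r_r` from `sin δ`). The hemibrain difference is the turn
  command; either hemisphere alone preserves its sign.
- **Hierarchy.** A meta-level MB TD learner selects among stored vector
  memories (+ home) from a rotation-invariant place signature of the
  current view, under external reward, as a semi-MDP with
  duration-discounted returns `γ^(τ/τ₀)`. The chosen memory drives the CX
  shortcut; every memory's steering circuit keeps learning off-policy from
  its own internal reward at all times.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Train the double-opponent homing circuit on a scripted learning walk and
test visual-only homing (no path integration) from 11 units out:

```python
import numpy as np
from mbcx import world as wd, homing as hm

world = wd.generate_world({"preset": "homing"}, seed=3)
circuits = hm.make_homing_circuits(n_pn=3 * 72, seed=3)
walk = wd.scripted_learning_walk(world, n_loops=8, max_radius=15.0,
                                 steps_per_loop=150, seed=3)
hm.train_homing(circuits, world, walk)

rng = np.random.default_rng(0)
wins = 0
for t in range(20):
    ang = rng.uniform(-np.pi, np.pi)
    start = wd.Pose(11 * np.cos(ang), 11 * np.sin(ang),
                    rng.uniform(-np.pi, np.pi))
    log = hm.run_homing_trial(circuits, world, start, use_pi=False,
                              max_steps=800, seed=100 + t)
    wins += bool(log.meta["success"])
print(f"visual-only homing success: {wins}/20")

log = hm.run_homing_trial(None, world, wd.Pose(10.0, 0.0, 0.0),
                          use_pi=True, seed=1)
print(f"PI homing: success={log.meta['success']} "
      f"path_length={log.meta['path_length']:.2f}")
```

prints

```
visual-only homing success: 20/20
PI homing: success=True path_length=10.50
```

— the trained circuit brings the agent home from every seeded start using
vision alone, and the path-integration channel homes along an essentially
straight line (10.5 units travelled for a 10-unit displacement; the last
unit falls inside the nest capture radius).

The foraging experiments live in `mbcx.hierarchy` (single protocols) and
`mbcx.studies` (multi-seed studies): `run_trapline_study`,
`run_displacement_study`, `run_shortcut_study`,
`run_adaptation_comparison`. A thin CLI wraps the presets:

```
mbcx simulate --experiment traplining --seed 1
mbcx train-homing --seed 3
mbcx evaluate --seed 3
mbcx plot --csv runs/episode.csv
```

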