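# Methods

`mbcx` simulates a rate-based model of insect visual navigation in which the
central complex (CX) supplies vector computations — compass heading, path
integration (PI), vector memories — and the mushroom body (MB) supplies
associative and reinforcement learning over visual states. This note
documents the model equations, the synthetic worlds, the numerical choices,
and what the simulations do and do not show.

## Phasor codes (CX substrate)

A planar vector with angle `a` and length `m` is carried by `N` columnar
units (default `N = 8`, matching the protocerebral-bridge compartment count)
with evenly spaced preferred directions `theta_i = 2*pi*i/N`:

    rate_i = baseline + m * cos(a - theta_i)

Encoding requires `m <= baseline` so rates stay non-negative; violating this
raises rather than clipping (failures should be loud). Decoding projects
`rates - baseline` onto the fundamental Fourier harmonic, which is also the
least-squares sinusoid fit; a numerically zero vector decodes to a flagged
`(angle=0, magnitude=0)` since a zero home vector at the nest is legitimate.
Vector addition is element-wise rate addition minus one redundant baseline —
exact for sinusoids of a common period, which is why PI (a running vector
sum) and the shortcut computation are algebraically exact in this code.

Angles are radians, counter-clockwise positive, 0 = allocentric east.
A single population stands in for the bilateral pair; the anatomical
redundancy is not used computationally.

## Path integration, vector memories, internal reward

- The compass is ground truth plus Gaussian angular noise (`noise_sd`,
  radians; default 0). No ring-attractor dynamics are simulated.
- The CPU4-like home vector accumulates the executed movement chord each
  timestep: direction = chord compass direction (plus compass noise),
  magnitude = odometric step length. Its baseline is arena-scaled
  (`max_length`, default 100 distance units) and exceeding the representable
  length raises a saturation error.
- A vector memory is the negative of the CPU4 deviation snapshot
  (`w_m = -(cpu4 - baseline)`), stored one-shot at a rewarded location.
  Applying it as inhibition leaves activity encoding `home - memory`; the
  negation, `memory - home`, is the direct shortcut agent→goal. Capacity
  overflow raises — no eviction or re-assignment mechanism is modelled,
  since none is biologically established.
- The internal left/right reward compares the goal-vector angle with the
  heading: `delta = wrap(goal_angle - kappa)`. Binary mode emits a unit
  reward on the goal's side; graded mode emits `max(0, ±sin delta)`. Dead
  ahead and dead behind emit nothing on either channel; the dead-behind tie
  is broken downstream by the controller's turn dynamics.

## Mushroom-body circuit

Sensory input reaches Kenyon cells (KCs) through a fixed binary random
projection (`fan_in` synapses per KC, chosen without replacement); a
k-winners-take-all threshold keeps a fraction `f` of KCs active. Each
discrete action is a *conjugate pair* of output neurons (MBONs) of opposite
valence; the action value is the valence difference of the pair's mean
active-KC synaptic weight:

    Q(s, a_i) = M+(i) - M-(i),   M±(i) = w±[:, i] · kc / k_active

Both matrices start at a common baseline `w0`, so Q = 0 before learning and
signed values are realised purely by depression.

Dopaminergic signals come in three wirings:

- direct reinforcement: `D± = R±` (the classical conditioning circuit);
- reward-prediction error: same-timestep recurrent MBON→DAN feedback of
  opposite valence, `D+ = R+ + Q-`, `D- = R- + Q+`, so the population
  difference is the Rescorla–Wagner error `R - Q`;
- temporal-difference error: a latency split in the recurrent feedback.
  The low-latency same-valence pathway carries the current prediction with
  gain `gamma`; a one-timestep-delayed opposite-valence trace carries the
  previous prediction. The population difference is then exactly the SARSA
  error `R + gamma*Q(s_t, a_t) - Q(s_{t-1}, a_{t-1})`.

Two representational choices matter and were genuinely open:

1. **Predictions as depression.** The value rates fed back to DANs are
   `Q+ = w0 - M-` and `Q- = w0 - M+`: an appetitive prediction is carried by
   depression of the aversive MBON. These are non-negative, zero before
   learning, and satisfy `Q+ - Q- = Q`, keeping all DAN inputs valid rates.
2. **Plasticity gated by the phasic DAN signal.** The 3-factor rule reads
   the joint population signal `D = D+ - D-`: a net-appetitive error
   depresses the previously active KCs' synapses onto the selected action's
   aversive MBON by `alpha*D` (and symmetrically for net-aversive), clipped
   at zero, with clip events counted. If instead each channel's raw rate
   gated depression separately, the tonic prediction components (which
   cancel in the population signal) would drain both matrices to zero
   within O(1/alpha) visits of any state — the circuit would forget at the
   rate it predicts. Gating on the phasic signal gives
   `dQ(s̄, ā) = alpha * D` exactly whenever no clipping occurs, which is
   what makes the one-hot circuit identical to tabular SARSA to 1e-12 over
   thousands of steps.

Latency is a one-timestep buffer (`t' = t-1`), the minimal mechanism that
yields the SARSA error exactly; `gamma` sits on the low-latency pathway
because any other placement fails to reduce to the standard error. The
buffer is re-primed with the post-update prediction so self-transitions
match the tabular update order. A Q-learning variant reads the winner's
prediction instead of the selected action's (off-policy); an accumulating
eligibility trace (decay `lambda`) is available behind a flag and off by
default. Action selection is winner-take-all (greedy argmax, lowest index
on ties), softened to epsilon-greedy or softmax where exploration is
needed.

Defaults: `alpha = 0.1`, `gamma = 0.9`, `w0 = 0.5` for desk-scale
conditioning examples; equivalence tests use larger `w0` (10) because a
gridworld with terminal reward 1 and `gamma = 0.9` needs |Q| headroom near
1 on both valence channels.

## Synthetic worlds and vision

Worlds are discs (`arena_radius`, default 50 units) with a nest, point
feeders (capture radius 1, depletable, replenished between bouts) and
opaque cylinder landmarks scattered in an annulus, with clearance around
nest and feeders. Vision is a 72-bin egocentric skyline: per azimuth bin,
the maximum angular elevation subtended by any cylinder, zero for open sky.
PN features for steering are the elevations plus both rectified circular
first differences (edge-like preprocessing).

The generator emulates the structure of flight-cage layouts, not any real
site: views contain no texture, colour, depth or motion cues, lighting is
implicit, and feeders are invisible to the skyline. Passing tests therefore
show the circuits work given a view code that discriminates place and
direction at the tested signal-to-noise, not that they would work on real
imagery. Two ecology choices were made after probing the representation's
limits (before running the behavioural protocols): the landmark forest is
kept in the outer annulus (0.55–0.95 arena radii) because goals inside a
forest have near-chance left/right visual discriminability under the
skyline code, and experiment feeders sit in the open interior.

Scripted learning walks are expanding loops around a centre (nest or a
newly found feeder) with goal-facing turn-backs, lateral segments and
free-heading scanning, covering all azimuthal sectors — a parametric
stand-in for recorded learning walks, supplying the off-policy behaviour
for steering training.

## Double-opponent visual homing

Each hemisphere holds a KC population and steer-left/steer-right MBON pairs
(one pair per goal slot). Both hemispheres receive copies of both internal
reward channels; within a hemisphere the left-reward DAN depresses the
steer-right synapses and vice versa (direct reinforcement — the internal
reward is dense, so no prediction error is needed, and a TD objective on
the internal reward would be actively wrong: its cumulative maximisation
rewards being off-target). Downstream integration inverts valence between
hemibrains: net turn = gain × (left-hemibrain steer-left drive −
right-hemibrain steer-right drive), clipped at `max_turn`. Either
hemisphere alone preserves the steering sign (lesion-tested).

Homing-controller defaults (`n_kc = 4000`, `f = 0.005`, `fan_in = 6`,
`w0 = 2`, `alpha = 0.02`) were sized so that a full training walk neither
saturates weights (clip-free) nor exhausts pattern capacity; with them the
steering sign matches the comparator on ~95% of clearly lateral poses
(|sin delta| ≥ 0.5) and visual-only nest capture succeeds from across the
learning-walk catchment. Sign agreement is evaluated on clearly lateral
poses because the internal reward itself vanishes toward dead-ahead and
dead-behind, where the sign is behaviourally irrelevant noise.

## Hierarchical agent

The meta-controller is an MB TD circuit whose action space is the vector
memory store plus "home" (always action 0). Decisions fire at bout start,
sub-goal arrival and timeout (`timeout_steps`, default 500 low-level steps;
protocol configs use leg-scale values). Between decisions the external
reward accumulates; the update treats the segment as one semi-MDP
transition with duration discounting

    Q(s, a) <- Q(s, a) + alpha * (gamma_eff * (r + Q(s', a')) - Q(s, a)),
    gamma_eff = gamma ** (tau / tau0)

where `tau` is the segment's low-level step count and `tau0 =
discount_steps` (default 40). Rewards are collected at arrival, so they
carry the same delay discount as the bootstrap; chained segments compose
to `gamma ** (total_time/tau0)`, the standard continuous-time semi-MDP
return. A flat per-decision discount was rejected because every full-visit
feeder order then earns an identical return and route length can never be
optimised.

Design choices the source material leaves open, resolved here:

- **Meta-state is a place signature.** The sub-goal selector's PN input is
  the rotation-invariant low-harmonic amplitude spectrum of the skyline
  (and its edge profile), not the raw egocentric panorama: the raw view
  confounds position with heading, which makes a view-conditioned sub-goal
  policy heading-dependent and destroys displacement behaviour. The
  steering circuits keep the retinotopic view (they need egocentric
  left/right). Measured on the study worlds, same-place KC overlap is ~0.75
  vs ~0.23 across places.
- **Nest reward.** Completing a bout pays a meta-level reward of 0.3
  (crop delivery). Without it Q(home) stays 0 and a converged policy never
  goes home; it is kept below `gamma * r_feeder` so foraging continues
  while feeders remain, and above the discounted value of visiting an empty
  feeder first. It enters only the meta update, not the external-reward
  accounting.
- **Crop capacity.** After `crop_capacity` rewarded captures (protocol
  configs: the number of feeders for traplining, 1 for the shortcut
  protocol) only "home" is selectable — the termination side of foraging
  motivation, which the model otherwise lacks.
- **Already-there veto.** A sub-goal whose goal vector has collapsed below
  the capture radius is masked at decisions: selecting the spot one stands
  on is a zero-duration self-transition that would bootstrap undiscounted
  and parasitically inherit the best next action's value.
- **One-shot memory acquisition** stores the current home vector when
  external reward arrives and no memory decodes within `merge_radius`
  (default 3); a capture "lands" the agent on the feeder so the imprint is
  the feeder's location. Capacity overflow raises (no eviction).
- **Concurrent view learning**: every low-level step, every stored memory's
  steering slot receives its own internal reward from its own goal vector
  and updates off-policy, sharing each hemisphere's KC encoding across
  slots. Steering-circuit parameters in the hierarchy (`n_kc = 4000`,
  `f = 0.004`, `alpha = 0.004`, `w0 = 10`) are sized for tens of thousands
  of concurrent updates without weight saturation.
- **Bootstrap exploration**: the memory store is seeded by a scripted
  survey — an outward-and-back spiral with pitch below the capture diameter
  (guaranteeing feeder discovery inside its radius) followed by orientation
  walks around each discovered site. The meta-policy explores only over
  stored memories (softmax with a per-bout ramped determinism parameter
  `beta`), never in space.
- **Close-range beaconing**: within `beacon_radius` (4 units) of an active
  feeder, visual steering heads at the feeder itself. The skyline field
  reliably brings the agent into a few-unit orbit of a goal but cannot
  resolve a 1-unit target for terminal docking; food items advertise
  themselves at close range. PI steering never needs it.
- **Casting**: the visual channel superimposes a slow lateral scan
  (`cast_amplitude` 6 rad/s, `cast_period` 40 steps) on the learned drive.
  The learned steering field has occasional spurious fixed points; the
  oscillation prevents lock-in there, at the cost of slightly longer visual
  paths — the scanning behaviour insects show under uncertain visual
  guidance.
- The executor prefers PI whenever it is available (under the simulated
  zero/low compass noise it is the precise channel); vision takes over when
  PI is disabled or wiped, as in the displacement protocol.

## Experiment protocols and baselines

- **Traplining** (3 feeders, arena 40, 60 bouts, softmax beta ramp
  ×1.08/bout): the acceptance layout `[(8.5,1.9), (3.9,-9.1), (8.7,15.3)]`
  was constructed by enumerating all three tours so that nearest-neighbour
  (NN) differs from the optimal tour (NN/optimal ≈ 1.2) *and* the
  duration-discounted return is maximised by the optimal tour — a world
  where route optimisation is decidable. The asymptotic route is the modal
  full-visit order of the last ten bouts; its length is measured by driving
  that order through the same executor, and compared against the NN and
  optimal orders driven identically (executed-vs-executed; geometric tour
  lengths are reported alongside).
- **Displacement**: a trained forager is released at the first feeder of
  its learned route with the home vector wiped; success is capturing the
  route's next feeder by visual sub-goal selection plus visual steering.
  The vector-sequence baseline replays the stored goal vector through PI
  from the same wiped state, which points to the wrong place by
  construction.
- **Shortcut** (feeders B far, C near; single-capture bouts): after
  training prefers C, C is permanently depleted; logged are the bout at
  which the greedy choice (at the nest or at C) switches to B, and whether
  a B-bound leg departs from a location no training B-leg ever started
  from (the novel C→B shortcut). `beta` is capped at 8 in this protocol so
  residual exploration can re-evaluate B. The control (C still rewarded)
  must not switch.
- **Flat-agent comparison**: the hierarchical bouts-to-switch is compared
  with a tabular SARSA agent on a 9×9 grid abstraction of the same arena
  with per-step moves (300 pre-training episodes, then episodes counted
  until its greedy rollout reaches B). The grid abstraction is this
  package's construction for the comparison.

Problem sizes were chosen to keep the full test suite and the acceptance
script at desk scale: 20 seeds per behavioural protocol in the test suite,
12 in the acceptance script, 60 traplining bouts, 25+25 shortcut bouts,
15–20 displacement trials per seed.

## Numerical conventions

Angles wrap to `(-pi, pi]`. Ties break toward the lowest index everywhere
(argmax, k-WTA threshold). One top-level seed fans out to named substreams
(projections, policy, environment) via `SeedSequence`. Zero-magnitude
phasors decode flagged, not raised. The k-WTA uses a partition-based
threshold with exact lowest-index tie-filling. The arena boundary is
reflective; cylinder collisions push the agent to the surface with a
deflected heading, and PI integrates executed chords so deflections do not
corrupt the home vector.

## Known limitations

- No spiking, no continuous-time synapse dynamics, no multi-compartment
  DANs; the compass and odometry are given, not computed from imagery.
- The skyline view code limits visual steering: left/right-of-goal
  discrimination tops out around 90% even with ample KC capacity, and
  goals adjacent to the landmark forest approach chance — visual homing
  here is a catchment-plus-beacon mechanism, not precision guidance.
- The meta-policy sees only the current place signature: depletion state
  within a bout is unobservable (no crop or short-term memory state), so
  route consistency must emerge from value differences under aliasing.
- Behavioural modes (learning walks, survey spirals, foraging bouts) are
  scripted switches, not learned; vector-memory eviction is absent, so
  long-running agents in feeder-rich worlds will hit the capacity error.
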