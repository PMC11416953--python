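"""Hierarchical MB/CX navigation agent and its experiment protocols.

An MB TD-RL *meta-controller* learns, from the current panoramic view and
external reward only, a policy over navigational sub-goals: the vector
memories acquired one-shot at rewarded locations, plus "home" (always action
0).  The selected memory is loaded into the CX, which computes the shortcut
goal vector; a low-level executor steers toward it with PI when the vector
signal is trustworthy and with the double-opponent visual circuit otherwise.
While any one goal is pursued, *every* stored memory's steering circuit
keeps learning off-policy from its own internal left/right reward — the
dense-reward trick that lets views acquired on one errand serve all goals.

Meta-decisions fire at bout start, on sub-goal arrival, and on timeout; the
external reward accumulated over the segment is the meta-reward of a
semi-MDP transition with duration discounting gamma**(tau/tau0), so travel
time is costed and shorter routes earn more.  A bout ends when "home" is
selected and the nest is reached.

Experiments: repeated-bout traplining with route-order/length logging and
brute-force optimal and nearest-neighbour baselines, the zero-PI
displacement test against a vector-sequence-only baseline, and the
feeder-depletion shortcut test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import cx as cxm
from . import mb as mbm
from . import phasor as ph
from . import world as wd
from .exceptions import CapacityError
from .homing import make_homing_circuits, train_homing_step
from .log import EpisodeLog

__all__ = [
    "MetaAgent",
    "ExperimentResult",
    "mbon_budget",
    "route_baselines",
    "run_traplining_experiment",
    "run_displacement_test",
    "run_shortcut_test",
    "run_flat_adaptation",
    "executed_route_length",
]


@dataclass
class ExperimentResult:
    """Per-bout records of a protocol run."""

    route_orders: list[list[int]] = field(default_factory=list)
    route_lengths: list[float] = field(default_factory=list)
    rewards: list[float] = field(default_factory=list)
    success: list[bool] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def mbon_budget(n_locations: int, budget: int = 200) -> dict:
    """Per-hemisphere MBON accounting for the memorised locations.

    Each location costs one selection MBON plus two steering MBONs per
    hemisphere; one extra selection MBON serves the ever-present "home"
    action.  Raises `CapacityError` when the per-location total exceeds the
    biological budget (~200 MBONs per hemisphere in the honeybee).
    """
    counts = {
        "locations": n_locations,
        "selection": n_locations,
        "steering": 2 * n_locations,
        "total": 3 * n_locations,
        "home_selection": 1,
        "budget": budget,
    }
    if counts["total"] > budget:
        raise CapacityError(
            f"{n_locations} locations need {counts['total']} MBONs per hemisphere, "
            f"budget is {budget}"
        )
    return counts


class MetaAgent:
    """The full hierarchical forager for a given world."""

    def __init__(
        self,
        world: wd.World,
        capacity: int = 6,
        n_azimuth: int = 72,
        n_kc_meta: int = 1000,
        meta_sparsity: float = 0.02,
        n_kc_steer: int = 4000,
        sparsity: float = 0.004,
        fan_in: int = 12,
        alpha_meta: float = 0.2,
        gamma_meta: float = 0.5,
        discount_steps: int = 40,
        w0_meta: float = 4.0,
        alpha_steer: float = 0.004,
        w0_steer: float = 10.0,
        beta0: float = 2.0,
        beta_ramp: float = 1.05,
        beta_max: float = 40.0,
        timeout_steps: int = 500,
        merge_radius: float = 3.0,
        beacon_radius: float = 4.0,
        cast_amplitude: float = 6.0,
        cast_period: int = 40,
        nest_reward: float = 0.3,
        speed: float = 5.0,
        dt: float = 0.1,
        heading_noise_sd: float = 0.0,
        mbon_budget_limit: int = 200,
        seed: int = 0,
    ):
        mbon_budget(capacity, budget=mbon_budget_limit)  # construction-time check
        self.world = world
        self.capacity = capacity
        self.n_azimuth = n_azimuth
        self.timeout_steps = timeout_steps
        self.discount_steps = discount_steps
        self.merge_radius = merge_radius
        self.beacon_radius = beacon_radius
        self.cast_amplitude = cast_amplitude
        self.cast_period = cast_period
        self._cast_step = 0
        self.nest_reward = nest_reward
        self.speed = speed
        self.dt = dt
        self.heading_noise_sd = heading_noise_sd
        self.beta = beta0
        self.beta_ramp = beta_ramp
        self.beta_max = beta_max

        ss = np.random.SeedSequence(seed).spawn(4)
        self.rng = np.random.default_rng(ss[0])
        n_pn = 3 * n_azimuth  # elevations + both rectified edge channels

        # the sub-goal selector reads a rotation-invariant place signature;
        # the steering circuits read the retinotopic panorama
        self.n_place = 38
        self.proj_meta = mbm.KCProjection.create(
            self.n_place, n_kc=n_kc_meta, fan_in=fan_in,
            seed=int(ss[1].generate_state(1)[0] % 2**31),
        )
        self.sparsity = sparsity
        self.meta_sparsity = meta_sparsity
        mb_meta = mbm.MBState(
            n_kc=n_kc_meta, n_actions=capacity + 1, w0=w0_meta,
            alpha=alpha_meta, gamma=gamma_meta,
        )
        self.meta = mbm.MBAgent(
            mb_meta, policy="softmax", beta=beta0,
            rng=np.random.default_rng(ss[2]),
        )
        # steering circuits: slot 0 = home, slot j = memory j-1
        self.circuits = make_homing_circuits(
            n_pn, n_kc=n_kc_steer, fan_in=6, sparsity=sparsity,
            w0=w0_steer, alpha=alpha_steer, n_slots=capacity + 1,
            seed=int(ss[3].generate_state(1)[0] % 2**31),
        )
        self.store = cxm.VectorMemoryStore(capacity=capacity)
        self.home = cxm.HomeVectorState.zero(max_length=4.0 * world.arena_radius)
        self.active_memory: int | None = None  # action index; 0 = home

    # ------------------------------------------------------------------ CX

    def _pi_update(self, prev: wd.Pose, pose: wd.Pose) -> float:
        """Integrate one executed movement chord into the home vector.

        The compass direction of the chord (plus Gaussian compass noise, if
        configured) modulates the odometric step length; obstacle deflections
        are thereby integrated faithfully.  Returns the chord length.
        """
        step_len = float(np.hypot(pose.x - prev.x, pose.y - prev.y))
        if step_len <= 0:
            return 0.0
        ang = float(np.arctan2(pose.y - prev.y, pose.x - prev.x))
        if self.heading_noise_sd > 0:
            ang += float(self.rng.normal(0.0, self.heading_noise_sd))
        travel = ph.encode(ang, 1.0, self.home.cpu4.n_columns, baseline=1.0)
        self.home = cxm.pi_step(self.home, travel, dt=step_len)
        return step_len

    def reset_pi(self) -> None:
        """Zero the home vector (start of a bout at the nest, or displacement)."""
        self.home = cxm.HomeVectorState.zero(max_length=self.home.max_length)

    def believed_position(self) -> tuple[float, float]:
        v = self.home.vector
        return (self.world.nest[0] + v.xy[0], self.world.nest[1] + v.xy[1])

    def _imprint_for_action(self, action: int) -> np.ndarray | None:
        return None if action == 0 else self.store.memories[action - 1]

    def action_mask(self) -> np.ndarray:
        mask = np.zeros(self.capacity + 1, dtype=bool)
        mask[0] = True
        mask[1 : 1 + len(self.store)] = True
        return mask

    # ------------------------------------------------------- memory storage

    def acquire_memory_on_reward(self, r_plus: float) -> int | None:
        """One-shot vector-memory storage at a rewarded location.

        Fires only when external reward arrives and no stored memory decodes
        within the merge radius of the current (believed) position; raises at
        capacity — no eviction.  Returns the new memory's action index.
        """
        if r_plus <= 0:
            return None
        here = self.believed_position()
        for j in range(len(self.store)):
            v = self.store.memory_vector(j, self.home)
            mx = self.world.nest[0] + v.xy[0]
            my = self.world.nest[1] + v.xy[1]
            if np.hypot(here[0] - mx, here[1] - my) <= self.merge_radius:
                return None
        cxm.store_vector_memory(self.store, self.home)
        return len(self.store)  # action index of the new memory

    # ------------------------------------------------- concurrent learning

    def concurrent_view_learning(self, pose: wd.Pose, features: np.ndarray) -> None:
        """Off-policy steering updates for every goal, active or not.

        Each stored memory (and home) gets its own internal left/right reward
        from its own goal vector; the per-hemisphere KC encoding is shared
        across slots.
        """
        kcs = tuple(h.encode(features) for h in self.circuits)
        for action in range(len(self.store) + 1):
            gv = cxm.goal_vector(self.home, self._imprint_for_action(action))
            reward = cxm.internal_lr_reward(pose.kappa, gv, mode="graded")
            train_homing_step(self.circuits, features, reward, slot=action, kcs=kcs)

    # --------------------------------------------------------- l0 executor

    def _steer_toward(
        self, pose: wd.Pose, features: np.ndarray, action: int,
        use_pi: bool, use_vision: bool, gain: float = 40.0,
    ) -> float:
        """Low-level steering command toward the active sub-goal.

        The vector channel is preferred whenever PI is available (under the
        simulated zero/low compass noise it is the trustworthy channel and
        supports precise docking); the visual double-opponent channel takes
        over when PI is disabled or the goal vector is degenerate.
        """
        gv = cxm.goal_vector(self.home, self._imprint_for_action(action))
        dec = ph.decode(gv)
        max_turn = np.pi / self.dt
        if use_pi and not dec.undefined:
            # proportional heading controller; per-step correction 4*err*dt
            # keeps the closed loop contractive for dt <= 0.25
            err = cxm.wrap_angle(dec.angle - pose.kappa)
            return float(np.clip(4.0 * err, -max_turn, max_turn))
        if use_vision:
            # close-range beaconing: an active feeder in sight is a salient
            # local cue the skyline code cannot resolve; steer at it directly
            for f in self.world.feeders:
                d_f = np.hypot(pose.x - f.x, pose.y - f.y)
                if f.active and self.world.capture_radius < d_f <= self.beacon_radius:
                    bear = cxm.wrap_angle(
                        float(np.arctan2(f.y - pose.y, f.x - pose.x)) - pose.kappa
                    )
                    return float(np.clip(4.0 * bear, -max_turn, max_turn))
            left, right = self.circuits
            l_drive = left.drive(features, action)
            r_drive = -right.drive(features, action)
            turn = gain * (l_drive - r_drive)
            # casting: a slow lateral scan superimposed on the visual drive;
            # prevents lock-in at spurious fixed points of the learned field
            self._cast_step += 1
            turn += self.cast_amplitude * np.sin(
                2 * np.pi * self._cast_step / self.cast_period
            )
            return float(np.clip(turn, -max_turn, max_turn))
        return 0.0

    def _goal_reached(self, pose: wd.Pose, action: int) -> bool:
        if action == 0:
            gx, gy = self.world.nest
        else:
            v = self.store.memory_vector(action - 1, self.home)
            gx = self.world.nest[0] + v.xy[0]
            gy = self.world.nest[1] + v.xy[1]
        # arrival judged on the CX signal: goal vector shrunk well inside the
        # capture zone (tighter than the capture radius so that docking at a
        # memory imprinted just inside a feeder's rim still pays)
        tol = 0.6 * self.world.capture_radius
        gv = cxm.goal_vector(self.home, self._imprint_for_action(action))
        dec = ph.decode(gv)
        near_belief = dec.undefined or dec.magnitude <= tol
        near_true = np.hypot(pose.x - gx, pose.y - gy) <= tol
        return near_belief or near_true

    # -------------------------------------------------------- exploration

    def explore(
        self,
        r_max: float | None = None,
        pitch: float = 1.8,
        concurrent: bool = True,
    ) -> list[int]:
        """Survey the arena with an outward spiral (a learning-flight stand-in).

        The spiral's radial pitch is kept below the feeder capture diameter,
        so every feeder inside ``r_max`` is discovered and imprinted as a
        vector memory; steering circuits learn concurrently along the way.
        Returns the feeder indices discovered.  This scripted behavioural
        mode bootstraps the memory store — the meta-policy itself never
        explores in space, only over stored memories.
        """
        world = self.world
        r_max = r_max or 0.6 * world.arena_radius
        pitch = min(pitch, 1.8 * world.capture_radius)
        self.reset_pi()
        found: list[int] = []
        ds = self.speed * self.dt
        prev = wd.Pose(world.nest[0], world.nest[1], 0.0)

        def spiral_poses():
            # outward pass, then the same track retraced inward — every
            # position is visited under two opposite headings
            pts = []
            phi, r = 0.0, 0.5
            while r < r_max:
                dphi = ds / max(r, ds)
                phi += dphi
                r = 0.5 + pitch * phi / (2 * np.pi)
                pts.append((r, phi))
            yield from pts
            yield from reversed(pts[:-1])

        for r, phi in spiral_poses():
            x = world.nest[0] + r * np.cos(phi)
            y = world.nest[1] + r * np.sin(phi)
            kappa = float(np.arctan2(y - prev.y, x - prev.x))
            pose = wd.resolve_collision(world, wd.Pose(float(x), float(y), kappa))
            self._pi_update(prev, pose)
            view, r_plus, _ = wd.sense_and_reward(world, pose, self.n_azimuth)
            if r_plus > 0:
                # land on the feeder: capture ends with the agent at the
                # food item itself, so the vector memory imprints its location
                just_captured = [
                    i for i, f in enumerate(world.feeders)
                    if not f.active and i not in found
                ]
                if just_captured:
                    f = world.feeders[just_captured[0]]
                    landed = wd.Pose(f.x, f.y, pose.kappa)
                    self._pi_update(pose, landed)
                    pose = landed
                found.extend(just_captured)
                self.acquire_memory_on_reward(r_plus)
            if concurrent and len(self.store) > 0:
                self.concurrent_view_learning(pose, wd.view_features(view))
            prev = pose

        # orientation walks around each discovered site: dense, all-heading
        # view coverage in exactly the regions where sub-goal decisions and
        # visual approaches will happen
        if concurrent:
            for j in range(len(self.store)):
                v = self.store.memory_vector(j, self.home)
                c = (world.nest[0] + v.xy[0], world.nest[1] + v.xy[1])
                walk = wd.scripted_learning_walk(
                    world, n_loops=4, max_radius=8.0, steps_per_loop=110,
                    seed=int(self.rng.integers(2**31)), center=c,
                )
                pcur = prev
                for pose in walk:
                    self._pi_update(pcur, pose)
                    view = wd.render_panorama(world, pose, self.n_azimuth)
                    self.concurrent_view_learning(pose, wd.view_features(view))
                    pcur = pose
                prev = pcur
        world.reset_feeders()
        return found

    # -------------------------------------------------------------- bouts

    def run_bout(
        self,
        start_pose: wd.Pose | None = None,
        max_steps: int = 4000,
        use_pi: bool = True,
        use_vision: bool = True,
        reset_pi: bool = True,
        crop_capacity: int | None = None,
        learn: bool = True,
        concurrent: bool = True,
        log: EpisodeLog | None = None,
    ) -> ExperimentResult:
        """One foraging bout: nest → (sub-goals) → nest.

        Returns a single-bout `ExperimentResult`; the meta-policy is updated
        at every decision point when ``learn`` is on.  ``crop_capacity``
        models the forager's crop: once that many rewards have been imbibed,
        the only selectable action is home.
        """
        world = self.world
        pose = start_pose or wd.Pose(world.nest[0], world.nest[1], self.rng.uniform(-np.pi, np.pi))
        if reset_pi:
            self.reset_pi()
        else:
            self.home = cxm.HomeVectorState(
                ph.phasor_add(
                    cxm.HomeVectorState.zero(max_length=self.home.max_length).cpu4,
                    ph.encode_xy(
                        pose.x - world.nest[0], pose.y - world.nest[1],
                        baseline=self.home.cpu4.baseline,
                    ),
                ),
                max_length=self.home.max_length,
            )
        self.meta.begin_episode()
        self.meta.beta = self.beta

        result = ExperimentResult()
        route: list[int] = []
        bout_reward = 0.0
        segment_reward = 0.0
        seg_starts: list[tuple[int, float, float]] = []  # (action, x, y)
        path_len = 0.0
        crop = 0

        view, _, _ = wd.sense_and_reward(world, pose, self.n_azimuth)
        features = wd.view_features(view)
        # at bout start the forager leaves the nest: "home" is not on offer
        # (an empty store makes the bout a no-op; bootstrap with explore())
        action = self._decide(
            view, 0.0, terminal=False, forced_home=False, learn=learn,
            exclude_home=len(self.store) > 0,
        )
        seg_starts.append((action, pose.x, pose.y))
        steps_in_segment = 0

        for _step in range(max_steps):
            turn = self._steer_toward(pose, features, action, use_pi, use_vision)
            new_pose = wd.resolve_collision(world, wd.step_kinematics(
                pose, turn, self.speed, self.dt, 0.0, self.rng,
                arena_radius=world.arena_radius,
            ))
            path_len += self._pi_update(pose, new_pose)
            pose = new_pose
            steps_in_segment += 1

            view, r_plus, r_minus = wd.sense_and_reward(world, pose, self.n_azimuth)
            features = wd.view_features(view)
            if log is not None:
                log.append(_step * self.dt, pose.x, pose.y, pose.kappa,
                           action=action, r_plus=r_plus, r_minus=r_minus)
            if r_plus > 0:
                bout_reward += r_plus
                segment_reward += r_plus
                crop += 1
                captured = [
                    i for i, f in enumerate(world.feeders)
                    if not f.active and np.hypot(pose.x - f.x, pose.y - f.y)
                    <= world.capture_radius
                ]
                for i in captured:
                    if i not in route:
                        route.append(i)
                if captured:
                    # land on the feeder itself (see explore())
                    f = world.feeders[captured[0]]
                    landed = wd.Pose(f.x, f.y, pose.kappa)
                    path_len += self._pi_update(pose, landed)
                    pose = landed
                if learn:
                    self.acquire_memory_on_reward(r_plus)
            if learn and concurrent and len(self.store) > 0:
                self.concurrent_view_learning(pose, features)

            arrived = self._goal_reached(pose, action)
            timed_out = steps_in_segment >= self.timeout_steps
            if arrived and action == 0 and np.hypot(
                pose.x - world.nest[0], pose.y - world.nest[1]
            ) <= world.capture_radius:
                # bout complete: terminal meta-update.  Nest return with a
                # full crop is itself rewarding — without this the learned
                # policy would never select "home"
                self._decide(view, segment_reward + self.nest_reward,
                             terminal=True, forced_home=False, learn=learn,
                             duration=steps_in_segment)
                result.route_orders.append(route)
                result.route_lengths.append(path_len)
                result.rewards.append(bout_reward)
                result.success.append(True)
                result.extra["segment_starts"] = seg_starts
                self.beta = min(self.beta * self.beta_ramp, self.beta_max)
                return result
            if arrived or timed_out:
                action = self._decide(
                    view, segment_reward, terminal=False,
                    forced_home=crop_capacity is not None and crop >= crop_capacity,
                    learn=learn, duration=steps_in_segment,
                )
                segment_reward = 0.0
                steps_in_segment = 0
                seg_starts.append((action, pose.x, pose.y))

        # ran out of steps: close the episode without reward
        self._decide(view, segment_reward, terminal=True, forced_home=False,
                     learn=learn, duration=steps_in_segment)
        result.route_orders.append(route)
        result.route_lengths.append(path_len)
        result.rewards.append(bout_reward)
        result.success.append(False)
        result.extra["segment_starts"] = seg_starts
        self.beta = min(self.beta * self.beta_ramp, self.beta_max)
        return result

    def meta_kc(self, view: wd.PanoramicView) -> mbm.KCActivation:
        """KC encoding of the rotation-invariant place signature."""
        return mbm.kc_encode(
            wd.place_signature(view), self.proj_meta, self.meta_sparsity
        )

    def _decide(
        self, view: wd.PanoramicView, reward: float, terminal: bool,
        forced_home: bool, learn: bool, exclude_home: bool = False,
        duration: int = 0,
    ) -> int:
        kc = self.meta_kc(view)
        mask = self.action_mask()
        if forced_home:
            mask[1:] = False
        elif exclude_home and mask[1:].any():
            mask[0] = False
        # a sub-goal whose CX goal vector has already collapsed to zero is
        # the spot the agent stands on: selecting it is a zero-duration
        # self-transition that would bootstrap undiscounted, so the CX
        # vetoes it (at least one action always stays available)
        for a in np.flatnonzero(mask):
            gv = ph.decode(cxm.goal_vector(self.home, self._imprint_for_action(int(a))))
            if gv.undefined or gv.magnitude <= self.world.capture_radius:
                if mask.sum() > 1:
                    mask[a] = False
        if not learn:
            q = mbm.q_forward(kc, self.meta.mb)
            q = np.where(mask, q, -np.inf)
            return int(np.argmax(q))
        # semi-MDP discount: the elapsed low-level duration scales the
        # effective per-decision discount, costing travel time.  Rewards are
        # collected at segment end (feeder capture = arrival), so the reward
        # carries the same delay discount as the bootstrap:
        # Q(s,a) <- gamma_eff * (r + Q(s',a'))
        gamma_eff = float(self.meta.mb.gamma ** (duration / self.discount_steps))
        action = self.meta.step(kc, gamma_eff * reward, 0.0, terminal=terminal,
                                action_mask=mask, gamma_override=gamma_eff)
        self.active_memory = None if terminal else action
        return action

    def greedy_meta_action(self, pose: wd.Pose) -> int:
        """Greedy sub-goal choice at a pose (no learning, no exploration)."""
        view = wd.render_panorama(self.world, pose, self.n_azimuth)
        kc = self.meta_kc(view)
        q = mbm.q_forward(kc, self.meta.mb)
        return int(np.argmax(np.where(self.action_mask(), q, -np.inf)))


# ------------------------------------------------------------------ routes


def route_baselines(world: wd.World) -> dict:
    """Brute-force optimal and nearest-neighbour closed-route lengths over
    the world's feeders (nest → all feeders → nest).  k <= 8 enforced."""
    pts = [(f.x, f.y) for f in world.feeders]
    if len(pts) > 8:
        raise CapacityError("brute-force route enumeration limited to 8 feeders")
    nest = world.nest

    def tour_length(order: tuple[int, ...]) -> float:
        nodes = [nest] + [pts[i] for i in order] + [nest]
        return float(
            sum(np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(nodes, nodes[1:]))
        )

    best = min(
        (tour_length(p), p) for p in itertools.permutations(range(len(pts)))
    )
    # nearest-neighbour heuristic from the nest
    remaining = set(range(len(pts)))
    cur = nest
    nn_order = []
    nn_len = 0.0
    while remaining:
        j = min(remaining, key=lambda i: np.hypot(cur[0] - pts[i][0], cur[1] - pts[i][1]))
        nn_len += float(np.hypot(cur[0] - pts[j][0], cur[1] - pts[j][1]))
        cur = pts[j]
        nn_order.append(j)
        remaining.discard(j)
    nn_len += float(np.hypot(cur[0] - nest[0], cur[1] - nest[1]))
    return {
        "optimal_length": best[0],
        "optimal_order": list(best[1]),
        "nn_length": nn_len,
        "nn_order": nn_order,
    }


def executed_route_length(
    world: wd.World,
    order: list[int],
    speed: float = 5.0,
    dt: float = 0.1,
    max_steps: int = 4000,
) -> float:
    """Path length of a scripted tour visiting the feeders in ``order``.

    Runs the same proportional-heading executor and kinematics as the
    agent's PI channel, so geometric baselines (nearest-neighbour, optimal)
    become comparable with executed route lengths, including turning and
    docking overhead.
    """
    rng = np.random.default_rng(0)
    targets = [(world.feeders[i].x, world.feeders[i].y) for i in order]
    targets.append(world.nest)
    pose = wd.Pose(world.nest[0], world.nest[1], 0.0)
    total = 0.0
    steps = 0
    for (gx, gy) in targets:
        while steps < max_steps:
            if np.hypot(pose.x - gx, pose.y - gy) <= world.capture_radius:
                break
            err = cxm.wrap_angle(float(np.arctan2(gy - pose.y, gx - pose.x)) - pose.kappa)
            turn = float(np.clip(4.0 * err, -np.pi / dt, np.pi / dt))
            new = wd.resolve_collision(world, wd.step_kinematics(
                pose, turn, speed, dt, 0.0, rng, arena_radius=world.arena_radius))
            total += float(np.hypot(new.x - pose.x, new.y - pose.y))
            pose = new
            steps += 1
    return total


# -------------------------------------------------------------- protocols


def run_traplining_experiment(
    world: wd.World,
    n_bouts: int = 40,
    seed: int = 0,
    timeout_steps: int = 60,
    agent_kwargs: dict | None = None,
) -> tuple[MetaAgent, ExperimentResult]:
    """Repeated foraging bouts on a replenishing multi-feeder world.

    Feeders replenish between bouts; the softmax determinism parameter beta
    ramps per bout, moving the agent from exploratory to exploitative routes.
    Route order, length and reward are logged per bout; the brute-force
    optimum and nearest-neighbour baselines are attached to the result.
    """
    agent = MetaAgent(world, timeout_steps=timeout_steps, seed=seed,
                      **(agent_kwargs or {}))
    result = ExperimentResult(extra=route_baselines(world))
    survey_r = max(np.hypot(f.x - world.nest[0], f.y - world.nest[1])
                   for f in world.feeders) + 2.0
    result.extra["discovered"] = agent.explore(r_max=survey_r)
    k = len(world.feeders)
    for _ in range(n_bouts):
        world.reset_feeders()
        bout = agent.run_bout(crop_capacity=k)
        result.route_orders += bout.route_orders
        result.route_lengths += bout.route_lengths
        result.rewards += bout.rewards
        result.success += bout.success
    return agent, result


def run_displacement_test(
    agent: MetaAgent,
    start_xy: tuple[float, float],
    target_feeder: int,
    n_trials: int = 20,
    max_steps: int = 400,
    seed: int = 0,
) -> dict:
    """Zero-PI displacement: does vision alone carry the route onward?

    The trained agent is released at a visually familiar location with its
    home vector zeroed and PI steering disabled; success means capturing the
    target feeder by visual meta-selection plus visual steering.  The
    vector-sequence baseline executes the stored goal vector through PI from
    the same zeroed state — its shortcut arithmetic now points to the wrong
    place, so it should perform at chance.
    """
    world = agent.world
    rng = np.random.default_rng(seed)
    tgt = world.feeders[target_feeder]

    def trial(use_vision: bool, use_pi: bool) -> bool:
        world.reset_feeders()
        # the forager is released where it has just fed: that feeder is empty
        for f in world.feeders:
            if np.hypot(f.x - start_xy[0], f.y - start_xy[1]) <= world.capture_radius:
                f.active = False
        pose = wd.Pose(start_xy[0], start_xy[1], rng.uniform(-np.pi, np.pi))
        agent.reset_pi()  # the displacement: PI state wiped
        view = wd.render_panorama(world, pose, agent.n_azimuth)
        features = wd.view_features(view)
        if use_vision:
            kc = agent.meta_kc(view)
            q = mbm.q_forward(kc, agent.meta.mb)
            action = int(np.argmax(np.where(agent.action_mask(), q, -np.inf)))
            if action == 0:  # greedy says home: fall back to best memory
                q[0] = -np.inf
                action = int(np.argmax(np.where(agent.action_mask(), q, -np.inf)))
        else:
            # vector-sequence baseline: replay the stored vector to the target
            action = target_feeder_action(agent, target_feeder)
        for step in range(max_steps):
            turn = agent._steer_toward(
                pose, features, action, use_pi=use_pi, use_vision=use_vision
            )
            prev_pose = pose
            pose = wd.resolve_collision(world, wd.step_kinematics(
                pose, turn, agent.speed, agent.dt, 0.0, rng,
                arena_radius=world.arena_radius,
            ))
            if use_pi:
                agent._pi_update(prev_pose, pose)
            if np.hypot(pose.x - tgt.x, pose.y - tgt.y) <= world.capture_radius:
                return True
            # feeders passed en route are drunk dry, releasing the beacon
            view, _, _ = wd.sense_and_reward(world, pose, agent.n_azimuth)
            features = wd.view_features(view)
        return False

    visual = sum(trial(use_vision=True, use_pi=False) for _ in range(n_trials))
    baseline = sum(trial(use_vision=False, use_pi=True) for _ in range(n_trials))
    return {
        "visual_capture_rate": visual / n_trials,
        "vector_baseline_capture_rate": baseline / n_trials,
        "n_trials": n_trials,
    }


def target_feeder_action(agent: MetaAgent, feeder_index: int) -> int:
    """Action index of the stored memory closest to a feeder's location."""
    f = agent.world.feeders[feeder_index]
    best, best_d = 1, np.inf
    for j in range(len(agent.store)):
        v = agent.store.memory_vector(j, agent.home)
        mx = agent.world.nest[0] + v.xy[0]
        my = agent.world.nest[1] + v.xy[1]
        d = np.hypot(f.x - mx, f.y - my)
        if d < best_d:
            best, best_d = j + 1, d
    return best


def run_shortcut_test(
    world: wd.World,
    n_train_bouts: int = 30,
    n_test_bouts: int = 25,
    seed: int = 0,
    timeout_steps: int = 60,
    deplete: bool = True,
    agent_kwargs: dict | None = None,
) -> tuple[MetaAgent, dict]:
    """Feeder-depletion shortcut protocol on the A/B/C triangle world.

    Training: repeated single-capture bouts (crop capacity: after one
    rewarded capture only "home" is selectable) with both feeders active;
    the near feeder C comes to dominate the policy.  Test: C is permanently
    depleted (if ``deplete``); bouts continue and we log (i) the bout at
    which the greedy meta-choice — at the nest or at C — switches to B, and
    (ii) whether the first B-directed leg departs from a location with no
    previous B-bound traversal (the novel-route flag).
    """
    B, C = 0, 1
    # keep the softmax determinism parameter bounded: residual exploration is
    # what lets the policy re-evaluate B after C's depletion
    kwargs = {"beta_max": 8.0, **(agent_kwargs or {})}
    agent = MetaAgent(world, timeout_steps=timeout_steps, seed=seed, **kwargs)
    agent.explore(r_max=max(np.hypot(f.x - world.nest[0], f.y - world.nest[1])
                            for f in world.feeders) + 2.0)
    def b_leg_starts_of(bout_log: EpisodeLog, b_action: int) -> list[tuple[float, float]]:
        """Departure points of B-directed segments in a bout log."""
        df = bout_log.to_dataframe()
        starts = []
        prev = None
        for _, row in df.iterrows():
            if row["action"] != prev:
                if row["action"] == b_action:
                    starts.append((float(row["x"]), float(row["y"])))
                prev = row["action"]
        return starts

    train_b_starts: list[tuple[float, float]] = []
    target_b_action = None

    for _ in range(n_train_bouts):
        world.reset_feeders()
        log = EpisodeLog()
        agent.run_bout(crop_capacity=1, log=log)
        if target_b_action is None and len(agent.store) >= 1:
            target_b_action = target_feeder_action(agent, B)
        if target_b_action is not None:
            train_b_starts += b_leg_starts_of(log, target_b_action)

    nest_pose = wd.Pose(world.nest[0], world.nest[1], 0.0)
    pre_choice = agent.greedy_meta_action(nest_pose)

    switch_bout = None
    novel_route = None
    novel_b_start = None
    c_pose = wd.Pose(world.feeders[C].x, world.feeders[C].y, 0.0)
    for bout_i in range(n_test_bouts):
        world.reset_feeders()
        if deplete:
            world.feeders[C].active = False
            world.feeders[C].magnitude = 0.0
        log = EpisodeLog()
        agent.run_bout(crop_capacity=1, log=log)
        if target_b_action is None:
            continue
        if switch_bout is None:
            greedy_nest = agent.greedy_meta_action(nest_pose)
            greedy_c = agent.greedy_meta_action(c_pose)
            if target_b_action in (greedy_nest, greedy_c):
                switch_bout = bout_i + 1
        if novel_route is None:
            # a B-bound leg departing where no training B-leg ever started
            # is the novel-route event (typically C -> B after finding C dry)
            for (x, y) in b_leg_starts_of(log, target_b_action):
                dists = [np.hypot(x - tx, y - ty) for (tx, ty) in train_b_starts]
                if not dists or min(dists) > 2.0 * world.capture_radius:
                    novel_route = True
                    novel_b_start = (x, y)
                    break

    return agent, {
        "pre_depletion_choice": pre_choice,
        "b_action": target_b_action,
        "c_action": None if len(agent.store) < 2 else target_feeder_action(agent, C),
        "switch_bout": switch_bout,
        "novel_route": bool(novel_route),
        "novel_b_start": novel_b_start,
    }


# ------------------------------------------------- flat-agent comparison


def run_flat_adaptation(
    world: wd.World,
    n_cells: int = 9,
    pre_episodes: int = 300,
    max_episodes: int = 300,
    seed: int = 0,
) -> int:
    """Bouts-to-switch for a flat per-step TD agent on a grid abstraction.

    The arena is tiled into an ``n_cells x n_cells`` grid; a tabular SARSA
    agent with 4 move actions learns per-step from the same feeder layout
    (B and C of the shortcut world).  After pre-training with both feeders,
    C is depleted and we count episodes from the nest until the greedy
    policy's rollout reaches B.  This is the non-hierarchical reference for
    the adaptation-speed comparison: every grid step is a decision, so the
    reward change at C must propagate through many more states.
    """
    from . import rl as rlm

    R = world.arena_radius

    def cell_of(x: float, y: float) -> int:
        i = int(np.clip((y + R) / (2 * R) * n_cells, 0, n_cells - 1))
        j = int(np.clip((x + R) / (2 * R) * n_cells, 0, n_cells - 1))
        return i * n_cells + j

    def build(active_feeders: list[int]) -> rlm.MDPSpec:
        n_states = n_cells * n_cells
        moves = [(0, 1), (-1, 0), (0, -1), (1, 0)]
        P = np.zeros((n_states, 4, n_states))
        Rtab = np.zeros((n_states, 4))
        terminal = np.zeros(n_states, dtype=bool)
        goal_cells = {cell_of(world.feeders[i].x, world.feeders[i].y): world.feeders[i].magnitude
                      for i in active_feeders}
        for s in goal_cells:
            terminal[s] = True
        for i in range(n_cells):
            for j in range(n_cells):
                s = i * n_cells + j
                if terminal[s]:
                    P[s, :, s] = 1.0
                    continue
                for a, (di, dj) in enumerate(moves):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < n_cells and 0 <= jj < n_cells):
                        ii, jj = i, j
                    s2 = ii * n_cells + jj
                    P[s, a, s2] = 1.0
                    if s2 in goal_cells:
                        Rtab[s, a] = goal_cells[s2]
        return rlm.MDPSpec(P, Rtab, gamma=0.95, terminal=terminal)

    rng = np.random.default_rng(seed)
    nest_cell = cell_of(*world.nest)
    b_cell = cell_of(world.feeders[0].x, world.feeders[0].y)

    mdp_both = build([0, 1])
    q = np.zeros((mdp_both.n_states, 4))

    def episode(mdp: rlm.MDPSpec, q: np.ndarray, eps: float) -> None:
        env = rlm.TabularEnv(mdp, rng, start_states=np.array([nest_cell]))
        s = env.reset()
        a = rlm._epsilon_greedy(q[s], eps, rng)
        for _ in range(200):
            s2, r, done = env.step(a)
            a2 = rlm._epsilon_greedy(q[s2], eps, rng)
            q[s, a] += 0.3 * rlm.sarsa_delta(q, s, a, r, s2, a2, mdp.gamma, done)
            if done:
                break
            s, a = s2, a2

    for k in range(pre_episodes):
        episode(mdp_both, q, eps=0.3 * 0.99**k)

    # depletion: C's cell no longer rewarded or terminal
    mdp_depleted = build([0])

    def greedy_reaches_b() -> bool:
        s = nest_cell
        for _ in range(4 * n_cells):
            a = int(np.argmax(q[s]))
            s = int(np.argmax(mdp_depleted.transition[s, a]))
            if s == b_cell:
                return True
        return False

    for ep in range(1, max_episodes + 1):
        episode(mdp_depleted, q, eps=0.1)
        if greedy_reaches_b():
            return ep
    return max_episodes
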