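"""Double-opponent visual steering: two hemispheric MB circuits trained
off-policy with internal left/right rewards.

Each hemisphere holds a copy of the canonical (direct-reinforcement) MB
circuit whose two output neurons are a "steer left" / "steer right" pair
(M_l, M_r).  Both hemispheres receive copies of both internal reward
channels from the CX comparator: within a hemisphere, r_left reinforces M_l
and r_right reinforces M_r through the depressive cross-pathway rule (the
DAN for one side depresses the other side's synapses).  Downstream (SIP)
integration inverts valence between hemispheres — the left hemibrain drives
"steer left", the right hemibrain "steer right" — and the net turn command
is the difference of the two drives.  The redundancy means either hemisphere
alone still carries the correct steering sign.

Training is off-policy: the behaviour is a scripted learning walk, not the
learned policy, and no prediction error is computed — the internal reward is
dense, so direct reinforcement suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import cx as cxm
from . import mb as mbm
from . import phasor as ph
from . import world as wd
from .log import EpisodeLog

__all__ = [
    "HemisphereCircuit",
    "SteeringCommand",
    "make_homing_circuits",
    "train_homing",
    "train_homing_step",
    "steer",
    "run_homing_trial",
]


@dataclass
class HemisphereCircuit:
    """One hemibrain's MB: a shared KC population plus steer-left/right MBON
    pairs, one pair per goal slot.

    Slot ``j``'s MBON pair is column ``j`` of a valence-pair `MBState`:
    ``w_plus[:, j]`` are the KC→M_l synapses, ``w_minus[:, j]`` the KC→M_r
    ones, so the hemisphere's signed drive for that goal (left positive) is
    the usual valence-difference readout.  A standalone homing controller
    uses a single slot; the hierarchical agent allocates one slot per vector
    memory over the same KC population.
    """

    side: str  # "left" | "right"
    proj: mbm.KCProjection
    mb: mbm.MBState
    sparsity: float = 0.05

    def encode(self, features: np.ndarray) -> mbm.KCActivation:
        return mbm.kc_encode(features, self.proj, self.sparsity)

    def drive(self, features: np.ndarray, slot: int = 0) -> float:
        """Signed M_l - M_r activity for a PN feature vector (left > 0)."""
        kc = self.encode(features)
        return float(mbm.q_forward(kc, self.mb)[slot])

    def drive_kc(self, kc: mbm.KCActivation, slot: int = 0) -> float:
        return float(mbm.q_forward(kc, self.mb)[slot])


@dataclass(frozen=True)
class SteeringCommand:
    """Bounded turn-rate command (radians per unit time, CCW positive)."""

    turn_rate: float
    max_turn: float = np.pi / 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "turn_rate", float(np.clip(self.turn_rate, -self.max_turn, self.max_turn))
        )


def make_homing_circuits(
    n_pn: int,
    n_kc: int = 4000,
    fan_in: int = 6,
    sparsity: float = 0.005,
    w0: float = 2.0,
    alpha: float = 0.02,
    n_slots: int = 1,
    seed: int = 0,
) -> tuple[HemisphereCircuit, HemisphereCircuit]:
    """Construct the symmetric untrained left/right hemisphere pair.

    The hemispheres get independent random KC projections (independent
    hemibrains) but identical symmetric initial weights, so the untrained net
    steering command is exactly zero.  ``n_slots`` steering-MBON pairs are
    allocated per hemisphere (one per prospective goal).
    """
    seq = np.random.SeedSequence(seed).spawn(2)
    circuits = []
    for side, ss in zip(("left", "right"), seq):
        proj = mbm.KCProjection.create(
            n_pn, n_kc=n_kc, fan_in=fan_in, seed=int(ss.generate_state(1)[0] % 2**31)
        )
        mb = mbm.MBState(n_kc=n_kc, n_actions=n_slots, w0=w0, alpha=alpha, gamma=0.0)
        circuits.append(HemisphereCircuit(side=side, proj=proj, mb=mb, sparsity=sparsity))
    return circuits[0], circuits[1]


def train_homing_step(
    circuits: tuple[HemisphereCircuit, HemisphereCircuit],
    features: np.ndarray,
    reward: cxm.InternalReward,
    slot: int = 0,
    kcs: tuple[mbm.KCActivation, mbm.KCActivation] | None = None,
) -> None:
    """One off-policy association: current view with steer-left/right.

    Both hemispheres receive copies of both reward channels; r_left excites
    the D_l DAN (appetitive for M_l, depressing M_r synapses) and symmetric
    for r_right.  ``kcs`` lets callers reuse per-hemisphere KC encodings when
    several slots are trained on the same view.
    """
    if reward.r_left == 0.0 and reward.r_right == 0.0:
        return
    dan = mbm.dan_direct(reward.r_left, reward.r_right)
    for i, hemi in enumerate(circuits):
        kc = kcs[i] if kcs is not None else hemi.encode(features)
        mbm.apply_plasticity(hemi.mb, kc, slot, dan)


def train_homing(
    circuits: tuple[HemisphereCircuit, HemisphereCircuit],
    world: wd.World,
    walk: list[wd.Pose],
    goal_source: Callable[[wd.Pose], ph.PhasorActivity] | None = None,
    mode: str = "graded",
    n_azimuth: int = 72,
) -> tuple[HemisphereCircuit, HemisphereCircuit]:
    """Train the steering circuits along a scripted walk.

    At each pose the view is rendered, the CX comparator turns the goal
    vector (default: the nest direction from ground-truth PI along the walk)
    into internal left/right rewards, and the association is reinforced.
    Poses where the goal vector is flagged zero are skipped.
    """
    if goal_source is None:
        def goal_source(pose: wd.Pose) -> ph.PhasorActivity:
            # ground-truth home vector along the scripted walk: nest - agent
            return ph.encode_xy(
                world.nest[0] - pose.x, world.nest[1] - pose.y, baseline=100.0
            )

    for pose in walk:
        goal = goal_source(pose)
        if ph.decode(goal).undefined:
            continue
        reward = cxm.internal_lr_reward(pose.kappa, goal, mode=mode)
        view = wd.render_panorama(world, pose, n_azimuth)
        train_homing_step(circuits, wd.view_features(view), reward)
    return circuits


def steer(
    circuits: tuple[HemisphereCircuit, HemisphereCircuit],
    view: wd.PanoramicView,
    gain: float = 8.0,
    max_turn: float = np.pi / 2,
    lesion: str | None = None,
    slot: int = 0,
) -> SteeringCommand:
    """Deterministic visual steering from the two hemibrain drives.

    Left hemibrain outputs the steer-left drive, right hemibrain the
    steer-right drive (SIP sign inversion); ``turn = gain * (L - R)``, CCW
    positive, clipped to ``max_turn``.  ``lesion`` silences one hemisphere.
    """
    left, right = circuits
    features = wd.view_features(view)
    l_drive = left.drive(features, slot) if lesion != "left" else 0.0
    # right hemibrain: steer-right drive = M_r - M_l = -(signed drive)
    r_drive = -right.drive(features, slot) if lesion != "right" else 0.0
    return SteeringCommand(gain * (l_drive - r_drive), max_turn=max_turn)


def run_homing_trial(
    circuits: tuple[HemisphereCircuit, HemisphereCircuit] | None,
    world: wd.World,
    start_pose: wd.Pose,
    goal_xy: tuple[float, float] | None = None,
    max_steps: int = 600,
    use_pi: bool = True,
    pi_blend_scale: float = 5.0,
    speed: float = 5.0,
    dt: float = 0.1,
    heading_noise_sd: float = 0.0,
    motor_noise_sd: float = 0.0,
    gain: float = 8.0,
    seed: int = 0,
    capture_radius: float | None = None,
    n_azimuth: int = 72,
) -> EpisodeLog:
    """Closed-loop trial: sense → steer (visual, PI, or blended) → move.

    The PI channel maintains a phasor home vector from the true kinematics
    (plus optional compass noise) and steers proportionally toward the goal
    vector; the visual channel uses the trained double-opponent circuit.
    When both are enabled they are blended convexly with PI weight
    ``min(1, |goal| / pi_blend_scale)`` — a long vector is trusted, a short
    one defers to vision.  Terminates on goal capture or ``max_steps``.
    """
    rng = np.random.default_rng(seed)
    goal = world.nest if goal_xy is None else goal_xy
    capture = world.capture_radius if capture_radius is None else capture_radius
    pose = wd.Pose(start_pose.x, start_pose.y, start_pose.kappa)

    # home-vector state seeded with the true displacement at trial start
    home = cxm.HomeVectorState.zero(max_length=4.0 * world.arena_radius)
    home = cxm.HomeVectorState(
        ph.phasor_add(
            home.cpu4,
            ph.encode_xy(
                pose.x - world.nest[0], pose.y - world.nest[1], baseline=home.cpu4.baseline
            ),
        ),
        max_length=home.max_length,
    )
    goal_offset = (goal[0] - world.nest[0], goal[1] - world.nest[1])
    goal_imprint = -(
        ph.encode_xy(*goal_offset, baseline=home.cpu4.baseline).rates - home.cpu4.baseline
    )

    log = EpisodeLog()
    success = False
    for t in range(max_steps):
        gv = cxm.goal_vector(home, goal_imprint)
        dec = ph.decode(gv)
        turn = 0.0
        w_pi = 0.0
        if use_pi and not dec.undefined:
            err = cxm.wrap_angle(dec.angle - pose.kappa)
            turn_pi = np.clip(4.0 * err, -np.pi / dt, np.pi / dt)
            w_pi = min(1.0, dec.magnitude / pi_blend_scale)
            turn += w_pi * turn_pi
        if circuits is not None and w_pi < 1.0:
            view = wd.render_panorama(world, pose, n_azimuth)
            cmd = steer(circuits, view, gain=gain, max_turn=np.pi / dt)
            turn += (1.0 - w_pi) * cmd.turn_rate
        log.append(t * dt, pose.x, pose.y, pose.kappa)
        if np.hypot(pose.x - goal[0], pose.y - goal[1]) <= capture:
            success = True
            break
        new_pose = wd.step_kinematics(
            pose, turn, speed, dt, motor_noise_sd, rng, arena_radius=world.arena_radius
        )
        new_pose = wd.resolve_collision(world, new_pose)
        # PI update: integrate the executed chord's compass direction (plus
        # compass noise, which corrupts PI while the body moves truly) with
        # the odometric step length
        step_len = float(np.hypot(new_pose.x - pose.x, new_pose.y - pose.y))
        if step_len > 0:
            ang = float(np.arctan2(new_pose.y - pose.y, new_pose.x - pose.x))
            if heading_noise_sd > 0:
                ang += float(rng.normal(0.0, heading_noise_sd))
            travel = ph.encode(ang, 1.0, home.cpu4.n_columns, baseline=1.0)
            home = cxm.pi_step(home, travel, dt=step_len)
        pose = new_pose
    log.meta.update(success=success, steps=t + 1, path_length=log.path_length)
    return log
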