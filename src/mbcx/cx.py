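"""Central-complex computations: heading, path integration, vector memories.

The CX maintains a compass heading (TB1-like unit phasor), accumulates the
agent's displacement from the nest in a CPU4-like phasor (the *home vector*,
stored as the nest→agent vector; the homing drive is its negation), stores
snapshots of that displacement as *vector memories* (per-column inhibitory
imprints, the negative of a CPU4 snapshot), and compares a goal vector with
the current heading to produce the internal left/right reward used by the
visual steering circuit.

The compass is modelled as ground truth plus Gaussian angular noise; no
ring-attractor dynamics are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import phasor as ph
from .exceptions import CapacityError, SaturationError

__all__ = [
    "wrap_angle",
    "HeadingState",
    "HomeVectorState",
    "VectorMemoryStore",
    "InternalReward",
    "update_heading",
    "travel_direction",
    "pi_step",
    "store_vector_memory",
    "goal_vector",
    "internal_lr_reward",
]

#: angular tolerance within which a goal dead behind counts as the tie case
_BEHIND_TOL = 1e-9


def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    w = float((-a + np.pi) % (2.0 * np.pi))
    return np.pi - w


@dataclass(frozen=True)
class HeadingState:
    """Compass heading and its unit-magnitude phasor representation."""

    kappa: float
    tb1: ph.PhasorActivity
    noise_sd: float = 0.0


@dataclass(frozen=True)
class HomeVectorState:
    """Accumulated nest→agent displacement as a columnar phasor.

    ``max_length`` scales the representable range: a decoded length beyond it
    raises `SaturationError` in `pi_step` (arena-scaled by the caller).  The
    phasor baseline is set to ``max_length`` so rates stay non-negative over
    the whole representable range.
    """

    cpu4: ph.PhasorActivity
    max_length: float = 100.0

    @classmethod
    def zero(cls, n_columns: int = 8, max_length: float = 100.0) -> "HomeVectorState":
        return cls(
            ph.encode(0.0, 0.0, n_columns=n_columns, baseline=max_length),
            max_length=max_length,
        )

    @property
    def vector(self) -> ph.DecodedVector:
        """Decoded home vector: angle Pi and length of nest→agent."""
        return ph.decode(self.cpu4)


@dataclass
class VectorMemoryStore:
    """Ordered store of vector-memory imprints.

    Each imprint is a per-column synaptic weight vector ``w_m``, the negative
    of the CPU4 deviation snapshot at storage time: applied as inhibition on
    CPU4 it leaves activity encoding (home − memory), whose negation is the
    shortcut drive.  Capacity overflow raises: no eviction or re-assignment
    mechanism is modelled.
    """

    capacity: int = 8
    memories: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.memories)

    def memory_vector(self, index: int, reference: HomeVectorState) -> ph.DecodedVector:
        """Decode imprint ``index`` back to the nest→memory displacement."""
        p = ph.PhasorActivity(
            reference.cpu4.baseline - self.memories[index], reference.cpu4.baseline
        )
        return ph.decode(p)


@dataclass(frozen=True)
class InternalReward:
    """Left/right goal-direction reward computed by the CX comparator."""

    r_left: float
    r_right: float


def update_heading(
    pose, noise_sd: float = 0.0, rng: np.random.Generator | None = None, n_columns: int = 8
) -> HeadingState:
    """Read the sky compass: true heading plus Gaussian angular noise.

    The noisy value is both stored in ``kappa`` and encoded in the TB1 phasor,
    so everything downstream sees a consistent (noisy) compass.
    """
    eps = 0.0
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        eps = float(rng.normal(0.0, noise_sd))
    kappa = wrap_angle(pose.kappa + eps)
    return HeadingState(
        kappa=kappa,
        tb1=ph.encode(kappa, 1.0, n_columns=n_columns, baseline=1.0),
        noise_sd=noise_sd,
    )


def travel_direction(
    heading: HeadingState, ego_flow_angle: float, ego_speed: float
) -> ph.PhasorActivity:
    """Allocentric travel direction from heading plus egocentric drift.

    The heading phasor is rotated by the egocentric optic-flow angle and its
    amplitude scaled to the travel speed, yielding a phasor that decodes to
    angle ``kappa + ego_flow_angle`` with magnitude ``ego_speed``.
    """
    if ego_speed < 0:
        raise ValueError(f"ego_speed must be >= 0, got {ego_speed}")
    rotated = ph.phasor_rotate(heading.tb1, ego_flow_angle)
    return ph.phasor_scale(rotated, ego_speed)


def pi_step(
    state: HomeVectorState, travel: ph.PhasorActivity, dt: float = 1.0
) -> HomeVectorState:
    """Accumulate one timestep of travel into the home vector.

    The travel phasor (unit baseline) is rebased onto the CPU4 baseline before
    integration so the column sum stays a faithful vector sum.
    """
    step = ph.PhasorActivity(
        state.cpu4.baseline + dt * (travel.rates - travel.baseline),
        state.cpu4.baseline,
    )
    cpu4 = ph.phasor_add(state.cpu4, step)
    new = replace(state, cpu4=cpu4)
    length = new.vector.magnitude
    if length > state.max_length:
        raise SaturationError(
            f"home vector length {length:.3f} exceeds representable {state.max_length}"
        )
    return new


def store_vector_memory(
    store: VectorMemoryStore, home: HomeVectorState, label: str = ""
) -> VectorMemoryStore:
    """One-shot storage: imprint the negative of the current CPU4 snapshot.

    Mutates and returns ``store``.  Raises `CapacityError` at capacity —
    eviction of existing memories is deliberately not modelled.
    """
    if len(store) >= store.capacity:
        raise CapacityError(
            f"vector memory store full ({store.capacity}); eviction is not modelled"
        )
    imprint = -(home.cpu4.rates - home.cpu4.baseline)
    store.memories.append(imprint)
    store.labels.append(label or f"m{len(store.memories) - 1}")
    return store


def goal_vector(
    home: HomeVectorState, imprint: np.ndarray | None = None
) -> ph.PhasorActivity:
    """Shortcut computation: phasor decoding to agent→goal.

    Applying the stored inhibitory imprint ``w_m = -(m)`` to the CPU4
    deviations leaves activity encoding ``h - m``; the steering drive is its
    negation, ``m - h`` (agent→memory).  With no imprint the goal is the nest
    and the result decodes to ``-h`` (pure homing).
    """
    dev = home.cpu4.rates - home.cpu4.baseline
    if imprint is not None:
        if imprint.shape != dev.shape:
            from .exceptions import ConfigurationError

            raise ConfigurationError("imprint column count does not match CPU4")
        dev = dev + imprint
    return ph.PhasorActivity(home.cpu4.baseline - dev, home.cpu4.baseline)


def internal_lr_reward(
    kappa: float, goal: ph.PhasorActivity, mode: str = "binary"
) -> InternalReward:
    """Does the goal lie to the left or the right of the current heading?

    Let ``delta = wrap(goal_angle - kappa)``.  Binary mode emits a unit reward
    on the side the goal lies (left for ``delta > 0``); graded mode emits
    ``max(0, ±sin delta)``.  A flagged-zero goal, or a goal dead ahead or dead
    behind (``delta`` in {0, pi}), yields zero on both channels — the dead-
    behind tie is resolved by a controller-injected turn bias, not here.
    """
    if mode not in ("binary", "graded"):
        raise ValueError(f"mode must be 'binary' or 'graded', got {mode!r}")
    v = ph.decode(goal)
    if v.undefined:
        return InternalReward(0.0, 0.0)
    delta = wrap_angle(v.angle - kappa)
    # dead ahead / dead behind are tie cases: both channels silent (the
    # comparator's phasor arithmetic leaves ~1e-16 residues at exactly pi)
    if abs(delta) <= _BEHIND_TOL or abs(abs(delta) - np.pi) <= _BEHIND_TOL:
        return InternalReward(0.0, 0.0)
    if mode == "binary":
        return InternalReward(1.0, 0.0) if delta > 0 else InternalReward(0.0, 1.0)
    s = float(np.sin(delta))
    return InternalReward(max(0.0, s), max(0.0, -s))
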