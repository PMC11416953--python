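"""Mushroom-body learning circuit: sparse coding, valence-paired values,
dopaminergic error signals, and depressive 3-factor plasticity.

The circuit realises value-based TD learning with biological parts:

* Projection neurons (PN) feed Kenyon cells (KC) through a fixed, sparse,
  random binary projection; a k-winners-take-all threshold keeps a fraction
  ``f`` of KCs active, giving a decorrelated state code.
* Each discrete action ``a_i`` is represented by a *conjugate pair* of output
  neurons (MBONs) of opposite valence, M+(i) and M-(i), whose KC synapses
  hold the appetitive/aversive halves of the action value:
  ``Q(s, a_i) = M+(i) - M-(i)`` with MBON activity read out as the mean
  synaptic weight over active KCs.
* Dopaminergic neurons (DANs) carry the reinforcement term.  Three wirings
  are provided: direct reinforcement (``D = R``), a reward-prediction error
  via same-timestep recurrent MBON→DAN feedback of opposite valence
  (``D = R - Q``, Rescorla-Wagner), and the full TD error via a latency
  split: low-latency same-valence feedback carries ``gamma * Q(t)`` and a
  one-timestep-delayed opposite-valence trace carries ``Q(t-1)``, so the
  combined DAN rate equals the SARSA error
  ``R + gamma*Q(s_t, a_t) - Q(s_{t-1}, a_{t-1})``.
* Plasticity is depressive and cross-valence: appetitive DAN activity
  depresses aversive MBON synapses of the previously active KCs and selected
  action, and vice versa, clipped at zero.  Without clipping the net change
  of Q(s̄, ā) is exactly ``alpha * (D+ - D-)``.

Action selection models winner-take-all lateral inhibition between MBON
pairs (greedy argmax), optionally softened into epsilon-greedy or softmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, EmptyTraceError, ValenceError

__all__ = [
    "KCProjection",
    "KCActivation",
    "MBState",
    "DANSignal",
    "TraceBuffer",
    "kc_encode",
    "one_hot_kc",
    "q_forward",
    "q_forward_split",
    "select_action",
    "dan_direct",
    "dan_rpe",
    "dan_td",
    "apply_plasticity",
    "MBAgent",
]


@dataclass(frozen=True)
class KCProjection:
    """Fixed binary sparse PN→KC projection.

    Each KC receives exactly ``fan_in`` presynaptic inputs chosen uniformly at
    random (without replacement) at construction; the matrix is non-plastic
    afterwards.
    """

    weights: np.ndarray  # (n_pn, n_kc) binary
    fan_in: int
    seed: int

    @classmethod
    def create(cls, n_pn: int, n_kc: int = 1000, fan_in: int = 10, seed: int = 0) -> "KCProjection":
        if fan_in > n_pn:
            raise ConfigurationError(f"fan_in {fan_in} exceeds n_pn {n_pn}")
        rng = np.random.default_rng(seed)
        w = np.zeros((n_pn, n_kc))
        for k in range(n_kc):
            w[rng.choice(n_pn, size=fan_in, replace=False), k] = 1.0
        return cls(weights=w, fan_in=fan_in, seed=seed)

    @property
    def n_pn(self) -> int:
        return self.weights.shape[0]

    @property
    def n_kc(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class KCActivation:
    """Binary KC activity pattern from k-winners-take-all thresholding.

    ``silent`` flags an all-zero pattern (no sensory drive); learning steps
    are skipped on silent activations.
    """

    active: np.ndarray  # (n_kc,) binary
    sparsity: float
    silent: bool = False

    @property
    def k_active(self) -> int:
        return int(self.active.sum())

    @property
    def indices(self) -> np.ndarray:
        """Indices of active KCs (cached after first use)."""
        idx = getattr(self, "_indices", None)
        if idx is None:
            idx = np.flatnonzero(self.active)
            object.__setattr__(self, "_indices", idx)
        return idx


def kc_encode(features: np.ndarray, proj: KCProjection, f: float = 0.05) -> KCActivation:
    """Sparse recoding of a PN feature vector.

    The ``ceil(f * n_kc)`` KCs with the largest synaptic drive win; ties are
    broken toward the lowest KC index.  All-zero input yields a flagged
    silent activation.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (proj.n_pn,):
        raise ConfigurationError(
            f"expected {proj.n_pn} PN features, got shape {features.shape}"
        )
    if not 0.0 < f <= 1.0:
        raise ConfigurationError(f"sparsity f must be in (0, 1], got {f}")
    if not np.any(features):
        return KCActivation(np.zeros(proj.n_kc), f, silent=True)
    drive = features @ proj.weights
    k = math.ceil(f * proj.n_kc)
    n = proj.n_kc
    # k-WTA with lowest-index tie-break at the threshold, without a full sort
    vk = np.partition(drive, n - k)[n - k]
    active = np.zeros(n)
    winners = drive > vk
    need = k - int(winners.sum())
    if need > 0:
        winners[np.flatnonzero(drive == vk)[:need]] = True
    active[winners] = 1.0
    return KCActivation(active, f)


def one_hot_kc(index: int, n_kc: int) -> KCActivation:
    """One-hot KC pattern for tabular-equivalence testing (one KC per state)."""
    active = np.zeros(n_kc)
    active[index] = 1.0
    return KCActivation(active, 1.0 / n_kc)


@dataclass
class MBState:
    """KC→MBON weight matrices for the valence pairs, plus learning params.

    ``w_plus``/``w_minus`` are (n_kc, n_actions) non-negative matrices holding
    the appetitive/aversive value halves.  Both start at the common baseline
    ``w0`` so Q is zero everywhere before learning; signed values are realised
    by depressing one side below the other.
    """

    n_kc: int
    n_actions: int
    w0: float = 0.5
    alpha: float = 0.1
    gamma: float = 0.9
    w_plus: np.ndarray = field(init=False)
    w_minus: np.ndarray = field(init=False)
    clip_events: int = field(default=0, init=False)
    update_count: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must be in [0,1], got {self.gamma}")
        self.w_plus = np.full((self.n_kc, self.n_actions), float(self.w0))
        self.w_minus = np.full((self.n_kc, self.n_actions), float(self.w0))

    @property
    def clip_fraction(self) -> float:
        return self.clip_events / self.update_count if self.update_count else 0.0


def q_forward_split(kc: KCActivation, mb: MBState) -> tuple[np.ndarray, np.ndarray]:
    """MBON activities (M+, M-) per action: mean active-KC synaptic weight."""
    if kc.active.shape != (mb.n_kc,):
        raise ConfigurationError("KC pattern size does not match MBState")
    k = kc.k_active
    if k == 0:
        z = np.zeros(mb.n_actions)
        return z, z.copy()
    idx = kc.indices
    m_plus = mb.w_plus[idx].sum(axis=0) / k
    m_minus = mb.w_minus[idx].sum(axis=0) / k
    return m_plus, m_minus


def q_forward(kc: KCActivation, mb: MBState) -> np.ndarray:
    """Action values Q(s, a_i) = M+(i) - M-(i)."""
    m_plus, m_minus = q_forward_split(kc, mb)
    return m_plus - m_minus


def value_split(kc: KCActivation, mb: MBState) -> tuple[np.ndarray, np.ndarray]:
    """Valence-split value predictions (Q+, Q-) per action as DAN-visible
    rates.

    Because plasticity is depressive, an appetitive prediction is carried by
    *depression of the aversive MBON*: Q+(i) = w0 - M-(i) and symmetrically
    Q-(i) = w0 - M+(i).  Both are non-negative (weights never exceed w0),
    zero before learning, and satisfy Q+ - Q- = M+ - M- = Q.
    """
    m_plus, m_minus = q_forward_split(kc, mb)
    if kc.k_active == 0:
        return np.zeros(mb.n_actions), np.zeros(mb.n_actions)
    return mb.w0 - m_minus, mb.w0 - m_plus


def select_action(
    q: np.ndarray,
    policy: str = "greedy",
    rng: np.random.Generator | None = None,
    epsilon: float = 0.0,
    beta: float = 1.0,
) -> int:
    """Winner-take-all action selection, optionally noise-softened.

    ``greedy``: argmax with lowest-index tie-break (lateral inhibition).
    ``epsilon_greedy``: uniform with probability epsilon.
    ``softmax``: Boltzmann with inverse temperature beta.
    """
    q = np.asarray(q, dtype=float)
    if q.size < 1:
        raise ConfigurationError("empty action-value vector")
    if policy == "greedy":
        return int(np.argmax(q))
    if rng is None:
        raise ConfigurationError(f"policy {policy!r} requires an rng")
    if policy == "epsilon_greedy":
        if not 0.0 <= epsilon <= 1.0:
            raise ConfigurationError(f"epsilon must be in [0,1], got {epsilon}")
        if rng.random() < epsilon:
            return int(rng.integers(q.size))
        return int(np.argmax(q))
    if policy == "softmax":
        if beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {beta}")
        logits = beta * (q - np.max(q))
        p = np.exp(logits)
        p /= p.sum()
        return int(rng.choice(q.size, p=p))
    raise ConfigurationError(f"unknown policy {policy!r}")


@dataclass(frozen=True)
class DANSignal:
    """Appetitive/aversive dopaminergic rates; their difference is the
    reinforcement term (direct R, RPE, or TD error by wiring)."""

    d_plus: float
    d_minus: float

    @property
    def combined(self) -> float:
        return self.d_plus - self.d_minus


@dataclass
class TraceBuffer:
    """One timestep of history for the high-latency MBON→DAN pathway."""

    prev_kc: KCActivation | None = None
    prev_action: int | None = None
    prev_q_plus: float = 0.0
    prev_q_minus: float = 0.0

    @property
    def empty(self) -> bool:
        return self.prev_kc is None

    def prime(self, kc: KCActivation, action: int, q_plus: float, q_minus: float) -> None:
        self.prev_kc = kc
        self.prev_action = action
        self.prev_q_plus = float(q_plus)
        self.prev_q_minus = float(q_minus)

    def clear(self) -> None:
        self.prev_kc = None
        self.prev_action = None
        self.prev_q_plus = 0.0
        self.prev_q_minus = 0.0


def dan_direct(r_plus: float, r_minus: float) -> DANSignal:
    """Canonical wiring: DANs relay the valence-split external reward."""
    if r_plus < 0 or r_minus < 0:
        raise ValenceError("rewards must arrive valence-split and non-negative")
    return DANSignal(float(r_plus), float(r_minus))


def dan_rpe(r_plus: float, r_minus: float, q_plus: float, q_minus: float) -> DANSignal:
    """Reward-prediction-error wiring: same-timestep opposite-valence
    MBON→DAN feedback adds the prediction of the other channel, so
    ``combined = (R+ - R-) - (Q+ - Q-)``."""
    if min(r_plus, r_minus, q_plus, q_minus) < 0:
        raise ValenceError("all DAN inputs must be non-negative rates")
    return DANSignal(float(r_plus + q_minus), float(r_minus + q_plus))


def dan_td(
    r_plus: float,
    r_minus: float,
    q_plus_now: float,
    q_minus_now: float,
    trace: TraceBuffer,
    gamma: float,
) -> DANSignal:
    """Latency-split TD wiring.

    Low-latency same-valence feedback carries the current prediction with
    gain ``gamma``; the high-latency opposite-valence pathway carries the
    previous timestep's prediction, so
    ``combined = (R+ - R-) + gamma*(Q+ - Q-)(t) - (Q+ - Q-)(t-1)``,
    the SARSA error of the previous transition.  Raises on an unprimed trace
    (the first transition only primes it).
    """
    if trace.empty:
        raise EmptyTraceError("TD DAN output undefined before the trace is primed")
    d_plus = r_plus + gamma * q_plus_now + trace.prev_q_minus
    d_minus = r_minus + gamma * q_minus_now + trace.prev_q_plus
    return DANSignal(float(d_plus), float(d_minus))


def apply_plasticity(
    mb: MBState,
    kc: KCActivation,
    action: int,
    dan: DANSignal,
) -> MBState:
    """DAN-gated depressive 3-factor update at the KC→MBON synapse.

    Only synapses from the given (previously active) KCs onto the given
    action's MBON pair change, and only in response to the *phasic* joint
    DAN signal ``D = D+ - D-`` (the tonic prediction components carried by
    the recurrent feedback cancel in the population signal and do not gate
    plasticity — otherwise both matrices would drain to zero at the tonic
    rate).  A net appetitive signal depresses the aversive MBON's synapses
    and vice versa, clipped at zero.  Because the MBON readout averages over
    the active KCs, a per-synapse step of ``alpha * |D|`` moves Q(s̄, ā) by
    exactly ``alpha * D`` when no clipping occurs.  Clip events are counted
    on ``mb``; a run where more than 1% of updates clip warrants attention
    (see ``MBState.clip_fraction``).
    """
    if kc.silent:
        return mb
    idx = kc.indices
    mb.update_count += 1
    d = dan.combined
    if d > 0:
        new_minus = mb.w_minus[idx, action] - mb.alpha * d
        if np.any(new_minus < 0):
            mb.clip_events += 1
            np.maximum(new_minus, 0.0, out=new_minus)
        mb.w_minus[idx, action] = new_minus
    elif d < 0:
        new_plus = mb.w_plus[idx, action] + mb.alpha * d
        if np.any(new_plus < 0):
            mb.clip_events += 1
            np.maximum(new_plus, 0.0, out=new_plus)
        mb.w_plus[idx, action] = new_plus
    return mb


class MBAgent:
    """Closed-loop MB learner over a discrete action set.

    Wires the pieces above into the per-step protocol:

    1. encode the state, read out Q, select an action;
    2. if the trace is primed, emit the TD DAN signal for the *previous*
       state-action (using the pre-update current prediction) and apply
       plasticity to it;
    3. re-read the (possibly just-updated) prediction of the current
       state-action and prime the trace with it.

    ``variant`` chooses what the low-latency pathway reads: the selected
    action's prediction (``sarsa``, on-policy, default — the circuit reads
    out the experienced action) or the winner-take-all maximum
    (``q_learning``, off-policy).  ``mode='rpe'`` disables the trace pathway
    and applies the same-timestep Rescorla-Wagner error to the *current*
    state-action instead (the gamma=0 associative limit).

    An optional accumulating eligibility trace (``lam > 0``) broadens the
    update to recently visited state-actions; off by default.
    """

    def __init__(
        self,
        mb: MBState,
        policy: str = "epsilon_greedy",
        epsilon: float = 0.1,
        beta: float = 1.0,
        variant: str = "sarsa",
        mode: str = "td",
        lam: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        if variant not in ("sarsa", "q_learning"):
            raise ConfigurationError(f"unknown variant {variant!r}")
        if mode not in ("td", "rpe"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        self.mb = mb
        self.policy = policy
        self.epsilon = epsilon
        self.beta = beta
        self.variant = variant
        self.mode = mode
        self.lam = lam
        self.rng = rng or np.random.default_rng(0)
        self.trace = TraceBuffer()
        self._elig: np.ndarray | None = (
            np.zeros((mb.n_kc, mb.n_actions)) if lam > 0 else None
        )
        self.last_dan: DANSignal | None = None

    def begin_episode(self) -> None:
        self.trace.clear()
        if self._elig is not None:
            self._elig[:] = 0.0

    def _apply(self, kc: KCActivation, action: int, dan: DANSignal) -> None:
        if self._elig is None:
            apply_plasticity(self.mb, kc, action, dan)
            return
        # accumulating eligibility trace over (KC, action) pairs
        self._elig *= self.lam * self.mb.gamma
        self._elig[kc.active.astype(bool), action] += 1.0
        self.mb.update_count += 1
        d = self.mb.alpha * (dan.d_plus - dan.d_minus)
        self.mb.w_minus = np.maximum(self.mb.w_minus - np.maximum(d, 0) * self._elig, 0.0)
        self.mb.w_plus = np.maximum(self.mb.w_plus - np.maximum(-d, 0) * self._elig, 0.0)

    def step(
        self,
        kc: KCActivation,
        r_plus: float,
        r_minus: float,
        terminal: bool = False,
        action_mask: np.ndarray | None = None,
        gamma_override: float | None = None,
    ) -> int:
        """Observe the current state (post-transition) and pick the next action.

        ``r_plus``/``r_minus`` are the valence-split rewards collected on the
        transition *into* this state; ``terminal`` forces the bootstrap
        prediction to zero and closes the episode.  ``action_mask`` restricts
        the selectable actions (True = available).  ``gamma_override``
        replaces the per-step discount for this one update — used by
        semi-MDP callers whose decision intervals span variable durations
        (effective discount gamma**(tau/tau0)).
        """
        q = q_forward(kc, self.mb)
        q_sel = q
        if action_mask is not None:
            q_sel = np.where(action_mask, q, -np.inf)
        action = select_action(q_sel, self.policy, self.rng, self.epsilon, self.beta)

        if self.mode == "rpe":
            q_plus, q_minus = value_split(kc, self.mb)
            dan = dan_rpe(r_plus, r_minus, q_plus[action], q_minus[action])
            self.last_dan = dan
            if not kc.silent:
                self._apply(kc, action, dan)
            return action

        if not self.trace.empty:
            if terminal:
                qp_now, qm_now = 0.0, 0.0
            elif self.variant == "q_learning":
                i_star = int(np.argmax(q_sel))
                q_plus, q_minus = value_split(kc, self.mb)
                qp_now, qm_now = q_plus[i_star], q_minus[i_star]
            else:
                q_plus, q_minus = value_split(kc, self.mb)
                qp_now, qm_now = q_plus[action], q_minus[action]
            gamma = self.mb.gamma if gamma_override is None else gamma_override
            dan = dan_td(r_plus, r_minus, qp_now, qm_now, self.trace, gamma)
            self.last_dan = dan
            self._apply(self.trace.prev_kc, self.trace.prev_action, dan)
        else:
            self.last_dan = None

        if terminal:
            self.trace.clear()
        elif not kc.silent:
            # prime with the post-update prediction of the chosen pair, so the
            # high-latency pathway carries the value the next error compares to
            q_plus, q_minus = value_split(kc, self.mb)
            self.trace.prime(kc, action, q_plus[action], q_minus[action])
        return action
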