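"""Tabular reinforcement learning: MDPs, TD errors, value iteration, agents.

This module is the textbook ground truth the mushroom-body circuit is tested
against: finite discrete MDPs, the SARSA and Q-learning one-step errors,
value iteration for the optimal policy, and seeded tabular agents.  It also
builds the small synthetic environments (gridworld and the visual-gradient
virtual world) used throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "MDPSpec",
    "QTable",
    "TabularEnv",
    "sarsa_delta",
    "q_learning_delta",
    "value_iteration",
    "run_tabular_agent",
    "make_gridworld",
    "make_gradient_world",
    "coarse_code",
]


@dataclass
class MDPSpec:
    """A finite MDP: transition tensor P(s'|s,a), reward table R(s,a).

    Terminal states self-loop with zero reward; ``horizon`` is optional and
    only used by episodic rollouts.
    """

    transition: np.ndarray  # (S, A, S')
    reward: np.ndarray  # (S, A)
    gamma: float = 0.9
    terminal: np.ndarray | None = None  # (S,) bool
    horizon: int | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.reward = np.asarray(self.reward, dtype=float)
        if self.transition.ndim != 3 or self.transition.shape[0] != self.transition.shape[2]:
            raise ConfigurationError("transition must have shape (S, A, S)")
        if self.reward.shape != self.transition.shape[:2]:
            raise ConfigurationError("reward must have shape (S, A)")
        row_sums = self.transition.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ConfigurationError("each P(.|s,a) must sum to 1")
        if self.terminal is None:
            self.terminal = np.zeros(self.n_states, dtype=bool)
        else:
            self.terminal = np.asarray(self.terminal, dtype=bool)
        for s in np.flatnonzero(self.terminal):
            if not np.allclose(self.transition[s, :, s], 1.0) or not np.allclose(
                self.reward[s], 0.0
            ):
                raise ConfigurationError(
                    f"terminal state {s} must self-loop with zero reward"
                )

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transition.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "transition": self.transition.tolist(),
                "reward": self.reward.tolist(),
                "gamma": self.gamma,
                "terminal": self.terminal.astype(int).tolist(),
                "horizon": self.horizon,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MDPSpec":
        d = json.loads(text)
        return cls(
            transition=np.array(d["transition"]),
            reward=np.array(d["reward"]),
            gamma=d["gamma"],
            terminal=np.array(d["terminal"], dtype=bool),
            horizon=d.get("horizon"),
        )


@dataclass
class QTable:
    """State-action value table with the policy-averaged state value."""

    q: np.ndarray  # (S, A)

    def v(self, policy: np.ndarray) -> np.ndarray:
        """V(s) = sum_a pi(a|s) Q(s,a) for a (S, A) policy matrix."""
        policy = np.asarray(policy, dtype=float)
        if not np.allclose(policy.sum(axis=1), 1.0):
            raise ConfigurationError("policy rows must sum to 1")
        return np.einsum("sa,sa->s", policy, self.q)

    def greedy(self) -> np.ndarray:
        """Greedy action per state (lowest index on ties)."""
        return np.argmax(self.q, axis=1)


def sarsa_delta(
    q: np.ndarray,
    s: int,
    a: int,
    r: float,
    s_next: int,
    a_next: int,
    gamma: float,
    terminal: bool = False,
) -> float:
    """On-policy one-step TD error: r + gamma*Q(s',a') - Q(s,a).

    ``terminal`` marks s' as absorbing, in which case Q(s',.) is taken as 0.
    """
    boot = 0.0 if terminal else q[s_next, a_next]
    return float(r + gamma * boot - q[s, a])


def q_learning_delta(
    q: np.ndarray,
    s: int,
    a: int,
    r: float,
    s_next: int,
    gamma: float,
    terminal: bool = False,
) -> float:
    """Off-policy one-step TD error: r + gamma*max_a Q(s',a) - Q(s,a)."""
    boot = 0.0 if terminal else np.max(q[s_next])
    return float(r + gamma * boot - q[s, a])


def value_iteration(
    mdp: MDPSpec, tol: float = 1e-10, max_iter: int = 100_000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the Bellman optimality equation by successive sweeps.

    Returns (V*, Q*, pi*) with ties in pi* broken toward the lowest index.
    Requires gamma < 1 or a finite horizon for convergence.
    """
    if mdp.gamma >= 1.0 and mdp.horizon is None:
        raise ConfigurationError("gamma >= 1 requires a finite horizon")
    v = np.zeros(mdp.n_states)
    sweeps = max_iter if mdp.horizon is None else mdp.horizon
    for _ in range(sweeps):
        q = mdp.reward + mdp.gamma * np.einsum("sap,p->sa", mdp.transition, v)
        q[mdp.terminal] = 0.0
        v_new = np.max(q, axis=1)
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    q = mdp.reward + mdp.gamma * np.einsum("sap,p->sa", mdp.transition, v)
    q[mdp.terminal] = 0.0
    return v, q, np.argmax(q, axis=1)


class TabularEnv:
    """Sampling interface over an `MDPSpec` for agent rollouts."""

    def __init__(
        self,
        mdp: MDPSpec,
        rng: np.random.Generator,
        start_states: np.ndarray | None = None,
    ):
        self.mdp = mdp
        self.rng = rng
        if start_states is None:
            start_states = np.flatnonzero(~mdp.terminal)
        self.start_states = np.asarray(start_states)
        self.state = int(self.start_states[0])

    def reset(self) -> int:
        self.state = int(self.rng.choice(self.start_states))
        return self.state

    def step(self, action: int) -> tuple[int, float, bool]:
        s = self.state
        r = float(self.mdp.reward[s, action])
        s_next = int(self.rng.choice(self.mdp.n_states, p=self.mdp.transition[s, action]))
        self.state = s_next
        return s_next, r, bool(self.mdp.terminal[s_next])


def _epsilon_greedy(q_row: np.ndarray, eps: float, rng: np.random.Generator) -> int:
    if rng.random() < eps:
        return int(rng.integers(q_row.size))
    return int(np.argmax(q_row))


def run_tabular_agent(
    mdp: MDPSpec,
    algo: str = "sarsa",
    alpha: float = 0.1,
    episodes: int = 500,
    epsilon0: float = 0.5,
    epsilon_decay: float = 0.999,
    max_steps: int = 1000,
    seed: int = 0,
    q_init: np.ndarray | None = None,
) -> tuple[QTable, dict]:
    """Run a seeded tabular SARSA / Q-learning agent with decaying epsilon.

    The exploration schedule is exponential per episode:
    ``eps_k = epsilon0 * epsilon_decay**k``.  Returns the learned table and a
    small log of per-episode returns.
    """
    if algo not in ("sarsa", "q_learning"):
        raise ConfigurationError(f"unknown algo {algo!r}")
    rng = np.random.default_rng(seed)
    env = TabularEnv(mdp, rng)
    q = np.zeros((mdp.n_states, mdp.n_actions)) if q_init is None else q_init.copy()
    returns = []
    for k in range(episodes):
        eps = epsilon0 * epsilon_decay**k
        s = env.reset()
        a = _epsilon_greedy(q[s], eps, rng)
        total = 0.0
        for _ in range(max_steps):
            s_next, r, done = env.step(a)
            total += r
            # next action is committed before the update in both algorithms,
            # so greedy SARSA and Q-learning share trajectories seed-for-seed
            a_next = _epsilon_greedy(q[s_next], eps, rng)
            if algo == "sarsa":
                delta = sarsa_delta(q, s, a, r, s_next, a_next, mdp.gamma, done)
            else:
                delta = q_learning_delta(q, s, a, r, s_next, mdp.gamma, done)
            q[s, a] += alpha * delta
            if done:
                break
            s, a = s_next, a_next
        returns.append(total)
    return QTable(q), {"returns": returns}


def make_gridworld(
    n_rows: int = 5,
    n_cols: int = 5,
    goal: tuple[int, int] = (4, 4),
    goal_reward: float = 1.0,
    step_reward: float = 0.0,
    gamma: float = 0.9,
) -> MDPSpec:
    """Deterministic 4-action gridworld with one absorbing rewarded goal.

    Actions are (E, N, W, S) in the allocentric angle convention; moves into
    walls leave the state unchanged.  The reward is paid on the transition
    into the goal cell.
    """
    n_states = n_rows * n_cols
    moves = [(0, 1), (-1, 0), (0, -1), (1, 0)]  # E, N(up a row), W, S
    goal_s = goal[0] * n_cols + goal[1]
    P = np.zeros((n_states, 4, n_states))
    R = np.full((n_states, 4), step_reward)
    terminal = np.zeros(n_states, dtype=bool)
    terminal[goal_s] = True
    for r in range(n_rows):
        for c in range(n_cols):
            s = r * n_cols + c
            if terminal[s]:
                P[s, :, s] = 1.0
                R[s] = 0.0
                continue
            for a, (dr, dc) in enumerate(moves):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    rr, cc = r, c
                s_next = rr * n_cols + cc
                P[s, a, s_next] = 1.0
                if s_next == goal_s:
                    R[s, a] = goal_reward
    return MDPSpec(P, R, gamma=gamma, terminal=terminal)


def coarse_code(
    values: np.ndarray, n_channels: int = 8, lo: float = 0.0, hi: float = 1.0
) -> np.ndarray:
    """Gaussian radial-basis coarse coding of scalar features.

    Maps each scalar to ``n_channels`` overlapping tuning curves with centres
    evenly spaced on [lo, hi]; used to turn the gradient world's visual
    intensity into a PN-like population input.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    centers = np.linspace(lo, hi, n_channels)
    width = (hi - lo) / max(n_channels - 1, 1)
    return np.exp(-0.5 * ((values[:, None] - centers[None, :]) / width) ** 2)


def make_gradient_world(
    shape: int | tuple[int, int] = 10,
    reward_states: tuple[int, ...] = (9,),
    reward: float = 1.0,
    gamma: float = 0.9,
) -> tuple[MDPSpec, np.ndarray]:
    """Virtual-reality gradient world: uniform visual states on a chain/grid.

    Each state carries a scalar "visual intensity" that varies strictly
    monotonically along the gradient axis (normalised position), emulating a
    closed-loop paradigm where uniform visual input changes with walking
    direction.  Transitions are deterministic; rewards are delivered on
    entering the listed reward states, which are absorbing.

    Returns the MDP and the (n_states, 1) intensity feature column.
    """
    if isinstance(shape, int):
        n_rows, n_cols = 1, shape
    else:
        n_rows, n_cols = shape
    n_states = n_rows * n_cols
    for s in reward_states:
        if not 0 <= s < n_states:
            raise ConfigurationError(f"reward state {s} outside the grid")
    if n_rows == 1:
        moves = [(0, 1), (0, -1)]  # right, left
    else:
        moves = [(0, 1), (-1, 0), (0, -1), (1, 0)]
    P = np.zeros((n_states, len(moves), n_states))
    R = np.zeros((n_states, len(moves)))
    terminal = np.zeros(n_states, dtype=bool)
    terminal[list(reward_states)] = True
    for r in range(n_rows):
        for c in range(n_cols):
            s = r * n_cols + c
            if terminal[s]:
                P[s, :, s] = 1.0
                continue
            for a, (dr, dc) in enumerate(moves):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    rr, cc = r, c
                s_next = rr * n_cols + cc
                P[s, a, s_next] = 1.0
                if terminal[s_next]:
                    R[s, a] = reward
    # intensity increases along columns, with a small row offset in 2D so
    # every state has a unique value
    cols = np.tile(np.arange(n_cols), n_rows)
    rows = np.repeat(np.arange(n_rows), n_cols)
    intensity = (cols + rows * n_cols * 0.0 + rows * 0.3) / max(
        n_cols - 1 + 0.3 * (n_rows - 1), 1
    )
    features = intensity[:, None]
    return MDPSpec(P, R, gamma=gamma, terminal=terminal), features
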