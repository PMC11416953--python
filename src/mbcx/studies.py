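"""Multi-seed behavioural studies: the experiment protocols at paper scale.

These drivers run the hierarchical-agent protocols across seeds and reduce
them to the summary quantities the package reports: asymptotic traplining
route length against nearest-neighbour and optimal baselines, zero-PI
displacement capture rates against the vector-sequence baseline, shortcut
switching statistics, and the flat-agent adaptation comparison.

Problem sizes (arena, feeder layout, bout counts, seed counts) are the
study conditions; they are fixed here so tests and the acceptance script
measure the same experiment.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from . import hierarchy as hr
from . import world as wd

__all__ = [
    "TRAPLINE_FEEDERS",
    "trapline_world",
    "shortcut_world",
    "run_trapline_study",
    "run_displacement_study",
    "run_shortcut_study",
    "run_adaptation_comparison",
]

#: Acceptance feeder layout: chosen by brute-force tour enumeration so that
#: the nearest-neighbour order differs from the optimal tour (NN/optimal
#: ratio ~1.2) while the optimal tour also maximises the duration-discounted
#: return — i.e. the route-optimisation question is decidable.
TRAPLINE_FEEDERS = [(6.8, 7.1), (4.9, -12.8), (8.5, -2.3)]

_ARENA = {
    "arena_radius": 40.0,
    # landmark forest in the outer annulus; feeders in the open interior
    # where the skyline resolves left/right of every goal
    "landmark_annulus": (0.55, 0.95),
}


def trapline_world(seed: int) -> wd.World:
    return wd.generate_world(
        {"preset": "traplining", "feeder_positions": TRAPLINE_FEEDERS, **_ARENA},
        seed=seed,
    )


def shortcut_world(seed: int) -> wd.World:
    return wd.generate_world({"preset": "shortcut", **_ARENA}, seed=seed)


def _modal_late_order(result: hr.ExperimentResult, k: int, last: int = 10):
    """Most common full-visit route order among the last ``last`` bouts."""
    orders = [
        tuple(o)
        for o, r in zip(result.route_orders[-last:], result.rewards[-last:])
        if r >= k
    ]
    if not orders:
        return None
    return list(Counter(orders).most_common(1)[0][0])


def run_trapline_study(
    n_seeds: int = 20,
    n_bouts: int = 60,
    base_seed: int = 0,
    keep_agents: bool = False,
) -> dict:
    """Repeated-bout traplining across seeds.

    Per seed: train, take the modal full-visit route order of the late bouts
    as the asymptotic policy's route, and measure its executed length with
    the same executor that drives the agent.  Baselines: the
    nearest-neighbour and brute-force-optimal orders through that executor,
    plus the geometric tour lengths.
    """
    per_seed = []
    agents = []
    for i in range(n_seeds):
        seed = base_seed + i
        world = trapline_world(seed)
        base = hr.route_baselines(world)
        agent, res = hr.run_traplining_experiment(
            world, n_bouts=n_bouts, seed=seed, timeout_steps=80,
            agent_kwargs={"beta_ramp": 1.08},
        )
        k = len(world.feeders)
        modal = _modal_late_order(res, k)
        full_lens = [
            l for l, r in zip(res.route_lengths[-10:], res.rewards[-10:]) if r >= k
        ]
        rec = {
            "seed": seed,
            "modal_order": modal,
            "learned_len": (
                hr.executed_route_length(world, modal) if modal else float("inf")
            ),
            "late_bout_median_len": float(np.median(full_lens)) if full_lens else float("inf"),
            "full_visit_late_fraction": len(full_lens) / 10.0,
            "nn_len": hr.executed_route_length(world, base["nn_order"]),
            "opt_len": hr.executed_route_length(world, base["optimal_order"]),
            "nn_geometric": base["nn_length"],
            "opt_geometric": base["optimal_length"],
        }
        per_seed.append(rec)
        if keep_agents:
            agents.append((world, agent, res))
    out = {
        "per_seed": per_seed,
        "median_learned_len": float(np.median([r["learned_len"] for r in per_seed])),
        "median_nn_len": float(np.median([r["nn_len"] for r in per_seed])),
        "median_opt_len": float(np.median([r["opt_len"] for r in per_seed])),
        "nn_geometric": per_seed[0]["nn_geometric"],
        "opt_geometric": per_seed[0]["opt_geometric"],
    }
    if keep_agents:
        out["agents"] = agents
    return out


def run_displacement_study(
    trapline_out: dict | None = None,
    n_seeds: int = 20,
    n_trials: int = 15,
    base_seed: int = 0,
) -> dict:
    """Zero-PI displacement on trained traplining agents.

    Each trained agent is released at the first feeder of its learned route
    with the home vector wiped; the target is the next feeder of that route.
    Compared against the vector-sequence baseline executing the stored goal
    vector through (corrupted) PI from the same state.
    """
    if trapline_out is None or "agents" not in trapline_out:
        trapline_out = run_trapline_study(
            n_seeds=n_seeds, base_seed=base_seed, keep_agents=True
        )
    visual, baseline = [], []
    for (world, agent, res) in trapline_out["agents"]:
        modal = _modal_late_order(res, len(world.feeders))
        if not modal or len(modal) < 2:
            continue
        start = (world.feeders[modal[0]].x, world.feeders[modal[0]].y)
        out = hr.run_displacement_test(
            agent, start, modal[1], n_trials=n_trials, seed=10_000 + world.seed
        )
        visual.append(out["visual_capture_rate"])
        baseline.append(out["vector_baseline_capture_rate"])
    return {
        "visual_rates": visual,
        "baseline_rates": baseline,
        "mean_visual": float(np.mean(visual)),
        "mean_baseline": float(np.mean(baseline)),
        "n_seeds": len(visual),
    }


def run_shortcut_study(
    n_seeds: int = 20,
    n_control: int = 5,
    n_train_bouts: int = 25,
    n_test_bouts: int = 25,
    base_seed: int = 0,
) -> dict:
    """Depletion-driven shortcut switching across seeds, with controls."""
    switches, novels, pre_ok = [], [], []
    for i in range(n_seeds):
        seed = base_seed + i
        world = shortcut_world(seed)
        _, out = hr.run_shortcut_test(
            world, n_train_bouts=n_train_bouts, n_test_bouts=n_test_bouts, seed=seed
        )
        pre_ok.append(out["pre_depletion_choice"] == out["c_action"])
        switches.append(out["switch_bout"])
        novels.append(bool(out["novel_route"]))
    control_switches = []
    for i in range(n_control):
        seed = base_seed + i
        world = shortcut_world(seed)
        _, out = hr.run_shortcut_test(
            world, n_train_bouts=n_train_bouts, n_test_bouts=n_test_bouts,
            seed=seed, deplete=False,
        )
        control_switches.append(out["switch_bout"])
    switched = [s for s in switches if s is not None]
    return {
        "switch_bouts": switches,
        "switch_fraction": len(switched) / len(switches),
        "median_switch_bout": float(np.median(switched)) if switched else None,
        "novel_route_fraction": float(np.mean(novels)),
        "pre_depletion_prefers_near": float(np.mean(pre_ok)),
        "control_switch_bouts": control_switches,
        "control_switch_fraction": float(
            np.mean([s is not None for s in control_switches])
        ),
    }


def run_adaptation_comparison(
    shortcut_out: dict | None = None, n_seeds: int = 20, base_seed: int = 0
) -> dict:
    """Hierarchy speeds up adaptation: bouts-to-switch for the hierarchical
    agent vs episodes-to-switch for a flat per-step TD agent on a grid
    abstraction of the same worlds."""
    if shortcut_out is None:
        shortcut_out = run_shortcut_study(n_seeds=n_seeds, base_seed=base_seed)
    flat = []
    for i in range(n_seeds):
        seed = base_seed + i
        world = shortcut_world(seed)
        flat.append(hr.run_flat_adaptation(world, seed=seed))
    hier = [s for s in shortcut_out["switch_bouts"] if s is not None]
    return {
        "hierarchical_median_bouts": float(np.median(hier)) if hier else None,
        "flat_median_episodes": float(np.median(flat)),
        "flat_episodes": flat,
    }
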