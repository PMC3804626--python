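"""Trial runner: randomized scheduling, daily clock and trajectory recording.

A trial simulates one group of identical agents on a resource landscape for
a number of days.  Each day has ``steps_per_day`` half-hour steps; within a
step the agents act one by one in a freshly shuffled order, then the
landscape regrows, then the group centre is recorded.  Everything draws
from a single seeded generator, so a (config, seed) pair reproduces a trial
exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import agent as ag
from . import landscape as ls
from . import memory as mem

SOCIAL_RULES = (ag.INDEPENDENT, ag.LEADER)
MEMORY_MODES = (mem.EUCLIDEAN, mem.LANDMARK)
RETENTIONS = (20, 60, 100)

#: All 12 agent types: social rule x memory mode x retention.
AGENT_TYPES = tuple(
    f"{s}:{m}:{r}"
    for s, m, r in itertools.product(SOCIAL_RULES, MEMORY_MODES, RETENTIONS)
)

GROUP_CENTER_BUFFER = 100.0
GROUP_CENTER_QUORUM = 0.80


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one trial."""

    social_rule: str = ag.INDEPENDENT
    memory_mode: str = mem.EUCLIDEAN
    retention: int = 20
    group_size: int = 70
    days: int = 180            # "6 months"
    seed: int = 0
    params: ag.BehaviorParams = field(default_factory=ag.BehaviorParams)
    # landscape
    n_cols: int = ls.DEFAULT_N_COLS
    n_rows: int = ls.DEFAULT_N_ROWS
    n_hotspots: int = 12
    hotspot_intensity: float = 8.0
    total_resources: float = ls.DEFAULT_TOTAL_RESOURCES
    grow_back_rate: float = ls.DEFAULT_GROW_BACK_RATE
    initial_desired_neighbors: int = 5
    record_agents: bool = False

    def __post_init__(self):
        if self.social_rule not in SOCIAL_RULES:
            raise ValueError(f"unknown social rule {self.social_rule!r}")
        if self.memory_mode not in MEMORY_MODES:
            raise ValueError(f"unknown memory mode {self.memory_mode!r}")
        if self.retention <= 0:
            raise ValueError("retention must be positive")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")

    @property
    def agent_type(self) -> str:
        return f"{self.social_rule}:{self.memory_mode}:{self.retention}"

    @property
    def steps_per_day(self) -> int:
        return self.params.steps_per_day

    @property
    def n_steps(self) -> int:
        return self.days * self.steps_per_day


def parse_agent_type(spec: str) -> tuple[str, str, int]:
    """Parse ``"leader:landmark:20"`` into (social_rule, memory_mode, retention)."""
    try:
        rule, mode, retention = spec.split(":")
        retention = int(retention)
    except ValueError as exc:
        raise ValueError(
            f"agent type must look like 'leader:landmark:20', got {spec!r}"
        ) from exc
    if rule not in SOCIAL_RULES:
        raise ValueError(f"unknown social rule {rule!r}")
    if mode not in MEMORY_MODES:
        raise ValueError(f"unknown memory mode {mode!r}")
    return rule, mode, retention


def config_for(agent_type: str, **kwargs) -> SimulationConfig:
    rule, mode, retention = parse_agent_type(agent_type)
    return SimulationConfig(
        social_rule=rule, memory_mode=mode, retention=retention, **kwargs
    )


@dataclass
class TrialResult:
    config: SimulationConfig
    trajectory: pd.DataFrame        # step, day, x, y, spread, n_in_center, quorum_met
    agents: list
    landscape: ls.ResourceLandscape
    weights: ls.WeightGrid
    agent_snapshots: pd.DataFrame | None = None


def group_center(
    positions: np.ndarray,
    buffer: float = GROUP_CENTER_BUFFER,
    quorum: float = GROUP_CENTER_QUORUM,
):
    """Recursive majority centre of a (possibly fissioned) group.

    Starting from all members, the centroid is accepted once at least
    ``quorum`` of the *original* group lies within ``buffer`` of it;
    otherwise the subset member farthest from the centroid is dropped and
    the centroid recomputed.  Returns ``(center, member_indices, quorum_met)``;
    if the subset empties before the quorum is met the last centre is
    returned flagged.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) == 0:
        raise ValueError("positions must be a non-empty (n, 2) array")
    n = len(positions)
    need = quorum * n
    members = np.arange(n)
    center = positions.mean(axis=0)
    while True:
        sub = positions[members]
        center = sub.mean(axis=0)
        d_all = np.hypot(positions[:, 0] - center[0], positions[:, 1] - center[1])
        if np.count_nonzero(d_all <= buffer) >= need:
            return (float(center[0]), float(center[1])), members, True
        if len(members) == 1:
            return (float(center[0]), float(center[1])), members, False
        d_sub = d_all[members]
        members = np.delete(members, int(np.argmax(d_sub)))


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a point set (0 for degenerate sets)."""
    if len(points) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(points).volume)  # in 2-D, volume is area
    except QhullError:
        return 0.0


def run_trial(config: SimulationConfig) -> TrialResult:
    """Run one full trial; fully reproducible from ``config`` (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    params = config.params

    weights = ls.synthesize_weights(
        config.n_cols, config.n_rows, config.n_hotspots,
        config.hotspot_intensity, seed=rng.integers(2**31),
    )
    land = ls.build_landscape(weights, config.total_resources, config.grow_back_rate)

    site_table = mem.build_site_table(land, config.retention)

    # cohesive start: scatter everyone within 100 m of one hotspot cell
    hotspots = weights.hotspot_cells()
    if hotspots:
        home_col, home_row = hotspots[rng.integers(len(hotspots))]
    else:
        home_row, home_col = np.unravel_index(
            int(np.argmax(land.max_level)), land.max_level.shape
        )
    hx, hy = land.cell_centre(home_col, home_row)

    n = config.group_size
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    radii = 100.0 * np.sqrt(rng.random(size=n))
    pos = np.empty((n, 2))
    pos[:, 0] = np.clip(hx + radii * np.cos(angles), 0.0, land.width - 1e-9)
    pos[:, 1] = np.clip(hy + radii * np.sin(angles), 0.0, land.height - 1e-9)

    leader_rule = config.social_rule == ag.LEADER
    agents = []
    for i in range(n):
        memory = mem.initialize_memory(
            land, config.retention, mode=config.memory_mode, site_table=site_table
        )
        a = ag.PrimateAgent(
            id=i, x=float(pos[i, 0]), y=float(pos[i, 1]),
            energy=params.target_energy,
            desired_neighbors=min(config.initial_desired_neighbors, n - 1),
            memory=memory,
            is_leader=(leader_rule and i == 0),
        )
        # seed the landmark / beliefs from the starting viewpoint
        mem.update_memory(a.memory, land, a.position, params.visual_range, step=0)
        agents.append(a)

    steps_per_day = params.steps_per_day
    n_steps = config.n_steps
    rec_step = np.empty(n_steps, dtype=np.int64)
    rec_day = np.empty(n_steps, dtype=np.int64)
    rec_x = np.empty(n_steps)
    rec_y = np.empty(n_steps)
    rec_spread = np.empty(n_steps)
    rec_ncenter = np.empty(n_steps, dtype=np.int64)
    rec_quorum = np.empty(n_steps, dtype=bool)
    snapshots: list[str] | None = [] if config.record_agents else None

    order = np.arange(n)
    mate_idx = [np.delete(np.arange(n), i) for i in range(n)]

    for step in range(n_steps):
        rng.shuffle(order)
        for i in order:
            a = agents[i]
            ag.adapt_safety(a, n, params)
            mates = pos[mate_idx[i]]
            leader_pos = None
            if leader_rule and not a.is_leader:
                leader_pos = (pos[0, 0], pos[0, 1])
            action, dest = ag.movement_choice(a, land, mates, params, rng, leader_pos)
            if action == "move":
                a.x, a.y = dest
                pos[i, 0] = a.x
                pos[i, 1] = a.y
            ag.energetics_step(a, land, params)
            mem.update_memory(a.memory, land, a.position, params.visual_range, step)
            mem.mental_regrow(a.memory, config.grow_back_rate, a.position,
                              params.visual_range)

        ls.regrow_step(land)

        (cx, cy), members, ok = group_center(pos)
        rec_step[step] = step
        rec_day[step] = step // steps_per_day
        rec_x[step] = cx
        rec_y[step] = cy
        rec_spread[step] = _hull_area(pos)
        rec_ncenter[step] = len(members)
        rec_quorum[step] = ok
        if snapshots is not None:
            for a in agents:
                snapshots.append(ag.snapshot_row(step, a))

    trajectory = pd.DataFrame({
        "step": rec_step, "day": rec_day, "x": rec_x, "y": rec_y,
        "spread": rec_spread, "n_in_center": rec_ncenter, "quorum_met": rec_quorum,
    })
    snap_df = None
    if snapshots is not None:
        from io import StringIO

        snap_df = pd.read_csv(
            StringIO(ag.snapshot_header() + "\n" + "\n".join(snapshots))
        )
    return TrialResult(
        config=config, trajectory=trajectory, agents=agents,
        landscape=land, weights=weights, agent_snapshots=snap_df,
    )


def write_trajectory(trajectory: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        trajectory.to_csv(fh, index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def calibration_sweep(
    totals,
    rates,
    template: SimulationConfig,
    subsample_seed: int | None = None,
) -> pd.DataFrame:
    """Grid search over (total resources, grow-back rate).

    Each grid point runs one trial from ``template`` with the two parameters
    replaced, and reports the three calibration summaries: mean daily step
    length, mean monthly home range and mean group spread (all computed on
    the field-schedule subsample of the trajectory).
    """
    from . import metrics

    rows = []
    for total in totals:
        for rate in rates:
            cfg = replace(template, total_resources=float(total),
                          grow_back_rate=float(rate))
            result = run_trial(cfg)
            sub = metrics.subsample_observation(
                result.trajectory,
                steps_per_day=cfg.steps_per_day,
                seed=cfg.seed if subsample_seed is None else subsample_seed,
            )
            daily = metrics.daily_metrics(sub)
            hr = metrics.home_range(sub, cell_size=result.landscape.cell_size)
            rows.append({
                "total_resources": float(total),
                "grow_back_rate": float(rate),
                "mean_daily_step": float(daily["d_total"].mean()) if len(daily) else float("nan"),
                "home_range_ha": float(hr.mean()) if len(hr) else float("nan"),
                "mean_spread": float(sub["spread"].mean()) if len(sub) else float("nan"),
            })
    return pd.DataFrame(rows)
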