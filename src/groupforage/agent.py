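"""Per-agent behaviour: energetics, adaptive safety and movement choice.

Each agent balances two needs every step.  Safety: enough group mates (or,
under the leader rule, the leader) within a safe radius.  Feeding: keep its
energy at a target level by visiting resource cells.  The resolution order
within one agent turn is

    adapt_safety -> movement_choice -> energetics_step -> memory update

An unsafe agent moves towards group mates; a safe, sated agent rests; a
safe, hungry agent picks a food destination by ranking candidate sites with
the food-site index (distance divided by expected resources — lower is
better) over both visible cells and recalled memory sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import ResourceLandscape, harvest
from .memory import LANDMARK, SpatialMemory, recall_candidates

INDEPENDENT = "independent"
LEADER = "leader"

#: Tiny inset used when clamping positions to the landscape extent so that
#: points stay inside the half-open cell decomposition.
_EDGE = 1e-9


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioural constants shared by every agent of a group.

    ``steps_per_day`` follows from a 13-hour active day at half-hour
    resolution; ``feed_fraction`` is the share of the day spent feeding,
    which fixes both the per-step energy decay and the intake per feeding
    event so that a full feeding day exactly balances a full day's decay.
    """

    visual_range: float = 50.0     # m, distance to sense food
    social_range: float = 200.0    # m, distance to sense group mates
    safe_radius: float = 50.0      # m, mates within this count towards safety
    max_step: float = 100.0        # m, displacement cap per step
    target_energy: float = 100.0   # energy units the agent tries to hold
    steps_per_day: int = 26        # 13 h at 30-minute steps
    feed_fraction: float = 0.43    # share of the day spent feeding

    @property
    def feeding_steps_per_day(self) -> int:
        """Feeding-step budget implied by the feeding-time fraction."""
        return round(self.feed_fraction * self.steps_per_day)

    @property
    def energy_decay(self) -> float:
        """Constant energy loss per step (target / steps per day)."""
        return self.target_energy / self.steps_per_day

    @property
    def gain_per_feed(self) -> float:
        """Intake per feeding event (target / feeding-step budget)."""
        return self.target_energy / self.feeding_steps_per_day


@dataclass
class PrimateAgent:
    """State of one foraging agent."""

    id: int
    x: float
    y: float
    energy: float
    desired_neighbors: int
    memory: SpatialMemory
    is_leader: bool = False
    fed_last_step: bool = False

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


# ---------------------------------------------------------------------------
# food-site index
# ---------------------------------------------------------------------------

def food_site_index(distance: float, resources: float) -> float:
    """Rank value of a candidate food site: distance / expected resources.

    Lower is better.  Sites with non-positive expected resources are not
    rankable and must be excluded by the caller.
    """
    if resources <= 0:
        raise ValueError("food_site_index requires positive expected resources")
    return distance / resources


def rank_food_sites(
    distances: np.ndarray,
    resources: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
) -> int:
    """Index of the best candidate under the food-site index.

    Ties break by smaller distance, then (row, col) lexical order, making
    the choice deterministic.  Candidates must already have resources > 0.
    """
    idx = distances / resources
    order = np.lexsort((cols, rows, distances, idx))
    return int(order[0])


# ---------------------------------------------------------------------------
# safety
# ---------------------------------------------------------------------------

def count_within(point, positions: np.ndarray, radius: float) -> int:
    d = np.hypot(positions[:, 0] - point[0], positions[:, 1] - point[1])
    return int(np.count_nonzero(d <= radius))


def is_safe_at(
    point,
    mate_positions: np.ndarray,
    desired_neighbors: int,
    params: BehaviorParams,
    leader_position=None,
    leader_sensed: bool = False,
) -> bool:
    """Safety test for an agent standing (or landing) at ``point``.

    Independent rule: at least ``desired_neighbors`` mates within the safe
    radius.  Leader rule (``leader_position`` given): the leader must be
    within the safe radius of ``point``; if the leader is not sensed at all
    the agent falls back to the independent rule.  ``desired_neighbors == 0``
    is always safe under either rule.
    """
    if desired_neighbors <= 0:
        return True
    if leader_position is not None and leader_sensed:
        dx = leader_position[0] - point[0]
        dy = leader_position[1] - point[1]
        return math.hypot(dx, dy) <= params.safe_radius
    if len(mate_positions) == 0:
        return False
    return count_within(point, mate_positions, params.safe_radius) >= desired_neighbors


def is_safe(
    agent: PrimateAgent,
    mate_positions: np.ndarray,
    params: BehaviorParams,
    leader_position=None,
) -> bool:
    """Safety of the agent at its current position (self excluded from mates)."""
    sensed = False
    if leader_position is not None:
        d = math.hypot(leader_position[0] - agent.x, leader_position[1] - agent.y)
        sensed = d <= params.social_range
    return is_safe_at(
        agent.position, mate_positions, agent.desired_neighbors, params,
        leader_position=leader_position, leader_sensed=sensed,
    )


def adapt_safety(
    agent: PrimateAgent,
    group_size: int,
    params: BehaviorParams,
) -> PrimateAgent:
    """Adjust the desired-neighbour count at the start of the agent's turn.

    At target energy the agent prioritises safety (+1 desired neighbour,
    capped at group size − 1); below target after a step without food it
    prioritises feeding (−1, floored at 0); otherwise unchanged.
    """
    if agent.energy >= params.target_energy:
        agent.desired_neighbors = min(agent.desired_neighbors + 1, group_size - 1)
    elif not agent.fed_last_step:
        agent.desired_neighbors = max(agent.desired_neighbors - 1, 0)
    return agent


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def _clamp_to_extent(x: float, y: float, landscape: ResourceLandscape) -> tuple[float, float]:
    x = min(max(x, 0.0), landscape.width - _EDGE)
    y = min(max(y, 0.0), landscape.height - _EDGE)
    return x, y


def _capped_move(origin, target, max_step: float) -> tuple[float, float]:
    dx = target[0] - origin[0]
    dy = target[1] - origin[1]
    d = math.hypot(dx, dy)
    if d <= max_step or d == 0.0:
        return (target[0], target[1])
    f = max_step / d
    return (origin[0] + dx * f, origin[1] + dy * f)


def visible_cells(landscape: ResourceLandscape, x: float, y: float, radius: float):
    """Cells whose centre lies within ``radius`` of ``(x, y)``.

    Returns ``(rows, cols, cx, cy, current, dist)`` flat arrays.
    """
    cs = landscape.cell_size
    c0 = max(int((x - radius) // cs), 0)
    c1 = min(int((x + radius) // cs), landscape.n_cols - 1)
    r0 = max(int((y - radius) // cs), 0)
    r1 = min(int((y + radius) // cs), landscape.n_rows - 1)
    cx = landscape.centre_x[c0:c1 + 1]
    cy = landscape.centre_y[r0:r1 + 1]
    dist = np.hypot(cx[None, :] - x, cy[:, None] - y)
    mask = dist <= radius
    rr, cc = np.nonzero(mask)
    rows = rr + r0
    cols = cc + c0
    return (
        rows,
        cols,
        cx[cc],
        cy[rr],
        landscape.current[rows, cols],
        dist[rr, cc],
    )


def _rally_target(agent, mate_positions, d_mates, params, leader_position, leader_sensed):
    """Where an unsafe agent heads: the leader if sensed (leader rule),
    else the mean position of the nearest desired mates within social range."""
    if leader_position is not None and leader_sensed:
        return leader_position
    sensed = d_mates <= params.social_range
    n_sensed = int(np.count_nonzero(sensed))
    if n_sensed == 0:
        return None  # nobody to rally to: rest
    pos = mate_positions[sensed]
    d = d_mates[sensed]
    k = agent.desired_neighbors
    if 0 < k < n_sensed:
        nearest = np.argpartition(d, k - 1)[:k]
        pos = pos[nearest]
    return (float(pos[:, 0].mean()), float(pos[:, 1].mean()))


def choose_destination(
    agent: PrimateAgent,
    landscape: ResourceLandscape,
    mate_positions: np.ndarray,
    params: BehaviorParams,
    rng: np.random.Generator,
    leader_position=None,
    leader_sensed: bool = False,
):
    """Destination for a safe, hungry agent; ``None`` means stay put.

    The candidate set is the union of visible cells holding resources
    (ranked by their true current level) and recallable memory sites with a
    positive believed level (ranked by belief; sites within visual range are
    covered by the visible set).  The goal is the food-site-index argmin.
    If the goal is visible, reachable in one step and safe to land on, the
    agent moves to a uniform-random point inside the goal cell.  Otherwise
    it advances as far as it can: among the cells reachable in one step
    that are safe to stand in, it picks the one closest to the goal.  With
    no candidates at all the agent takes an exploratory random step.
    """
    x, y = agent.x, agent.y
    v_rows, v_cols, v_cx, v_cy, v_cur, v_dist = visible_cells(
        landscape, x, y, params.visual_range
    )
    has_food = v_cur > 0
    cand_rows = v_rows[has_food]
    cand_cols = v_cols[has_food]
    cand_cx = v_cx[has_food]
    cand_cy = v_cy[has_food]
    cand_res = v_cur[has_food]
    cand_dist = v_dist[has_food]

    mem = agent.memory
    recall = recall_candidates(mem, (x, y))
    if len(recall):
        sx = mem.sites.x[recall]
        sy = mem.sites.y[recall]
        sd = np.hypot(sx - x, sy - y)
        keep = (sd > params.visual_range) & (mem.believed[recall] > 0)
        if keep.any():
            ri = recall[keep]
            cand_rows = np.concatenate([cand_rows, mem.sites.rows[ri]])
            cand_cols = np.concatenate([cand_cols, mem.sites.cols[ri]])
            cand_cx = np.concatenate([cand_cx, sx[keep]])
            cand_cy = np.concatenate([cand_cy, sy[keep]])
            cand_res = np.concatenate([cand_res, mem.believed[ri]])
            cand_dist = np.concatenate([cand_dist, sd[keep]])

    if len(cand_rows) == 0:
        # exploration: nothing visible, nothing recalled
        heading = rng.uniform(0.0, 2.0 * math.pi)
        length = params.max_step * (1.0 - rng.random())  # (0, max_step]
        return _clamp_to_extent(
            x + length * math.cos(heading), y + length * math.sin(heading), landscape
        )

    best = rank_food_sites(cand_dist, cand_res, cand_rows, cand_cols)
    g_dist = cand_dist[best]
    goal = (cand_cx[best], cand_cy[best])
    goal_cell = (int(cand_cols[best]), int(cand_rows[best]))

    if (
        g_dist <= params.visual_range
        and g_dist <= params.max_step
        and is_safe_at(goal, mate_positions, agent.desired_neighbors, params,
                       leader_position, leader_sensed)
    ):
        return _land_in_cell(goal_cell, (x, y), landscape, params, rng)

    # indirect: safe cell closest to the goal among those reachable in one
    # step (the agent moves as far as possible towards the desired site)
    r_rows, r_cols, r_cx, r_cy, _, r_dist = visible_cells(
        landscape, x, y, params.max_step
    )
    reach = r_dist <= params.max_step
    if not reach.any():
        return None
    rx = r_cx[reach]
    ry = r_cy[reach]
    if agent.desired_neighbors <= 0:
        safe = np.ones(len(rx), dtype=bool)
    elif leader_position is not None and leader_sensed:
        safe = np.hypot(rx - leader_position[0], ry - leader_position[1]) <= params.safe_radius
    elif len(mate_positions) == 0:
        safe = np.zeros(len(rx), dtype=bool)
    else:
        dmat = np.hypot(
            rx[:, None] - mate_positions[None, :, 0],
            ry[:, None] - mate_positions[None, :, 1],
        )
        safe = (dmat <= params.safe_radius).sum(axis=1) >= agent.desired_neighbors
    if not safe.any():
        return None
    to_goal = np.hypot(rx - goal[0], ry - goal[1])
    to_goal[~safe] = np.inf
    order = np.lexsort((r_cols[reach], r_rows[reach], r_dist[reach], to_goal))
    j = order[0]
    cell = (int(r_cols[reach][j]), int(r_rows[reach][j]))
    return _land_in_cell(cell, (x, y), landscape, params, rng)


def _land_in_cell(cell, origin, landscape, params, rng) -> tuple[float, float]:
    """Uniform-random landing point inside a cell, displacement capped."""
    cs = landscape.cell_size
    px = (cell[0] + rng.random()) * cs
    py = (cell[1] + rng.random()) * cs
    return _capped_move(origin, (px, py), params.max_step)


def movement_choice(
    agent: PrimateAgent,
    landscape: ResourceLandscape,
    mate_positions: np.ndarray,
    params: BehaviorParams,
    rng: np.random.Generator,
    leader_position=None,
):
    """One movement decision; returns ``("rest", None)`` or ``("move", point)``.

    Unsafe agents rally towards mates (leader if sensed under the leader
    rule); safe agents rest when sated and forage when hungry.
    """
    d_mates = np.hypot(mate_positions[:, 0] - agent.x, mate_positions[:, 1] - agent.y) \
        if len(mate_positions) else np.empty(0)
    leader_sensed = False
    if leader_position is not None:
        leader_sensed = (
            math.hypot(leader_position[0] - agent.x, leader_position[1] - agent.y)
            <= params.social_range
        )

    safe = is_safe_at(
        agent.position, mate_positions, agent.desired_neighbors, params,
        leader_position, leader_sensed,
    )
    if not safe:
        target = _rally_target(agent, mate_positions, d_mates, params,
                               leader_position, leader_sensed)
        if target is None:
            return ("rest", None)
        dest = _capped_move(agent.position, target, params.max_step)
        return ("move", _clamp_to_extent(dest[0], dest[1], landscape))

    if agent.energy >= params.target_energy:
        return ("rest", None)

    dest = choose_destination(
        agent, landscape, mate_positions, params, rng, leader_position, leader_sensed
    )
    if dest is None:
        return ("rest", None)
    return ("move", dest)


def energetics_step(
    agent: PrimateAgent,
    landscape: ResourceLandscape,
    params: BehaviorParams,
) -> bool:
    """Apply the constant per-step decay, then feed if hungry and food is here.

    Returns True when the agent actually obtained food this step; the flag
    is also stored on the agent for the next turn's safety adaptation.
    """
    agent.energy = max(agent.energy - params.energy_decay, 0.0)
    fed = False
    if agent.energy < params.target_energy:
        col, row = landscape.point_to_cell(agent.x, agent.y)
        removed = harvest(landscape, col, row, params.gain_per_feed)
        if removed > 0:
            agent.energy += removed
            fed = True
    agent.fed_last_step = fed
    return fed


def snapshot_header() -> str:
    return "step,id,x,y,energy,desired_neighbors"


def snapshot_row(step: int, agent: PrimateAgent) -> str:
    return (
        f"{step},{agent.id},{float(agent.x)!r},{float(agent.y)!r},"
        f"{float(agent.energy)!r},{agent.desired_neighbors}"
    )
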