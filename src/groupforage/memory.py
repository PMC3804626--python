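"""Spatial-memory models for foraging agents.

Two recall modes are implemented:

* ``euclidean`` — the agent can recall every remembered site from anywhere
  (a global cognitive map of distances and directions).
* ``landmark`` — the agent can only recall sites associated with the last
  landmark it saw.  Every remembered site acts as a landmark, and two sites
  are associated when their cell centres lie within ``landmark_radius``
  (association is symmetric and includes the site itself).

Memory size ("retention") is fixed for a whole trial: sites are never
forgotten.  Believed resource levels are dynamic: they are synchronised with
the true landscape whenever the site is within visual range, and otherwise
advance by the global grow-back rate each step (a mental model of regrowth),
capped at the site's true ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import ResourceLandscape

#: Landmark association radius (metres, centre-to-centre).
LANDMARK_RADIUS = 100.0

#: Sentinel for "never seen".
NEVER = -1

EUCLIDEAN = "euclidean"
LANDMARK = "landmark"


@dataclass(frozen=True)
class SiteTable:
    """Geometry of the remembered sites, shared by every agent in a group.

    Sites are grid cells; ``x``/``y`` are cell-centre coordinates.  The
    landmark association graph (``adjacency``) is precomputed once.
    """

    cols: np.ndarray       # (R,) int
    rows: np.ndarray       # (R,) int
    x: np.ndarray          # (R,) float, cell centres
    y: np.ndarray          # (R,) float
    max_level: np.ndarray  # (R,) float
    adjacency: tuple       # tuple of index arrays: sites within landmark radius

    def __len__(self) -> int:
        return len(self.cols)


@dataclass
class SpatialMemory:
    """One agent's memory: shared site table plus private beliefs."""

    mode: str
    sites: SiteTable
    believed: np.ndarray   # (R,) believed resource level per site
    last_seen: np.ndarray  # (R,) int step index, NEVER if unseen
    landmark_radius: float = LANDMARK_RADIUS
    current_landmark: int | None = None  # index into sites, None before first sighting

    @property
    def retention(self) -> int:
        return len(self.sites)


def top_sites(landscape: ResourceLandscape, retention: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices ``(rows, cols)`` of the ``retention`` highest-ceiling cells.

    Ties in ``max_level`` break by (row, col) lexical order so membership is
    deterministic.
    """
    mx = landscape.max_level
    rr, cc = np.indices(mx.shape)
    flat_rank = np.lexsort((cc.ravel(), rr.ravel(), -mx.ravel()))
    chosen = flat_rank[:retention]
    return rr.ravel()[chosen], cc.ravel()[chosen]


def build_site_table(landscape: ResourceLandscape, retention: int,
                     landmark_radius: float = LANDMARK_RADIUS) -> SiteTable:
    rows, cols = top_sites(landscape, retention)
    x = (cols + 0.5) * landscape.cell_size
    y = (rows + 0.5) * landscape.cell_size
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    within = np.hypot(dx, dy) <= landmark_radius
    adjacency = tuple(np.nonzero(within[i])[0] for i in range(len(rows)))
    return SiteTable(
        cols=cols, rows=rows, x=x, y=y,
        max_level=landscape.max_level[rows, cols].astype(float),
        adjacency=adjacency,
    )


def initialize_memory(
    landscape: ResourceLandscape,
    retention: int,
    mode: str = EUCLIDEAN,
    landmark_radius: float = LANDMARK_RADIUS,
    site_table: SiteTable | None = None,
) -> SpatialMemory:
    """Memory of the ``retention`` top resource cells, beliefs set to truth.

    ``site_table`` may be passed to share the (identical) geometry between
    the agents of one group instead of recomputing it per agent.
    """
    if retention <= 0:
        raise ValueError("retention must be positive")
    if retention > landscape.n_cells:
        raise ValueError("retention exceeds the number of cells")
    if mode not in (EUCLIDEAN, LANDMARK):
        raise ValueError(f"unknown memory mode {mode!r}")
    if site_table is None:
        site_table = build_site_table(landscape, retention, landmark_radius)
    believed = landscape.current[site_table.rows, site_table.cols].astype(float)
    return SpatialMemory(
        mode=mode,
        sites=site_table,
        believed=believed,
        last_seen=np.full(len(site_table), NEVER, dtype=np.int64),
        landmark_radius=landmark_radius,
    )


def recall_candidates(memory: SpatialMemory, agent_position=None) -> np.ndarray:
    """Indices of the sites the agent can currently recall.

    Euclidean mode recalls everything; landmark mode recalls the sites
    associated with the current landmark (including the landmark itself), or
    nothing if no landmark has been seen yet.
    """
    if memory.mode == EUCLIDEAN:
        return np.arange(len(memory.sites))
    if memory.current_landmark is None:
        return np.empty(0, dtype=np.intp)
    return memory.sites.adjacency[memory.current_landmark]


def site_distances(memory: SpatialMemory, position) -> np.ndarray:
    x, y = position
    return np.hypot(memory.sites.x - x, memory.sites.y - y)


def update_memory(
    memory: SpatialMemory,
    landscape: ResourceLandscape,
    agent_position,
    visual_range: float = 50.0,
    step: int = 0,
) -> SpatialMemory:
    """Synchronise beliefs for sites within visual range; update the landmark.

    In landmark mode the current landmark becomes the nearest remembered
    site within visual range (if any is visible); otherwise it persists.
    """
    d = site_distances(memory, agent_position)
    visible = d <= visual_range
    if visible.any():
        memory.believed[visible] = landscape.current[
            memory.sites.rows[visible], memory.sites.cols[visible]
        ]
        memory.last_seen[visible] = step
        if memory.mode == LANDMARK:
            masked = np.where(visible, d, np.inf)
            memory.current_landmark = int(np.argmin(masked))
    return memory


def mental_regrow(
    memory: SpatialMemory,
    grow_back_rate: float,
    agent_position=None,
    visual_range: float = 50.0,
) -> SpatialMemory:
    """Advance beliefs of out-of-sight sites by the grow-back rate (capped).

    When ``agent_position`` is given, sites within ``visual_range`` are left
    untouched (vision overrides the mental model); with no position every
    site regrows.
    """
    if agent_position is None:
        np.minimum(memory.believed + grow_back_rate, memory.sites.max_level,
                   out=memory.believed)
        return memory
    d = site_distances(memory, agent_position)
    hidden = d > visual_range
    memory.believed[hidden] = np.minimum(
        memory.believed[hidden] + grow_back_rate, memory.sites.max_level[hidden]
    )
    return memory


def memory_to_csv(memory: SpatialMemory, path, agent_id: int = 0) -> None:
    """Dump one agent's memory as CSV (debugging / fixtures)."""
    with open(path, "w") as fh:
        fh.write("agent_id,col,row,believed,last_seen\n")
        for i in range(len(memory.sites)):
            fh.write(
                f"{agent_id},{memory.sites.cols[i]},{memory.sites.rows[i]},"
                f"{float(memory.believed[i])!r},{memory.last_seen[i]}\n"
            )


def memory_from_csv(path, landscape: ResourceLandscape, mode: str = EUCLIDEAN,
                    landmark_radius: float = LANDMARK_RADIUS) -> SpatialMemory:
    import pandas as pd

    df = pd.read_csv(path, float_precision='round_trip')
    cols = df["col"].to_numpy(dtype=np.int64)
    rows = df["row"].to_numpy(dtype=np.int64)
    x = (cols + 0.5) * landscape.cell_size
    y = (rows + 0.5) * landscape.cell_size
    within = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :]) <= landmark_radius
    table = SiteTable(
        cols=cols, rows=rows, x=x, y=y,
        max_level=landscape.max_level[rows, cols].astype(float),
        adjacency=tuple(np.nonzero(within[i])[0] for i in range(len(rows))),
    )
    return SpatialMemory(
        mode=mode,
        sites=table,
        believed=df["believed"].to_numpy(dtype=float),
        last_seen=df["last_seen"].to_numpy(dtype=np.int64),
        landmark_radius=landmark_radius,
    )
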