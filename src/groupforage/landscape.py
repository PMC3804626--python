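"""Gridded resource surface: synthetic weight generation, depletion and regrowth.

The surface is a rectangular grid of square cells.  Each cell carries a
current resource level and a fixed ceiling (``max_level``); foraging removes
resources and a uniform per-step regrowth restores them up to the ceiling.
Cell ``(col, row)`` spans ``[cell_size*col, cell_size*(col+1)) x
[cell_size*row, cell_size*(row+1))`` in metres, origin at the south-west
corner.  Arrays are indexed ``[row, col]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Side length of one grid cell in metres.
CELL_SIZE = 30.0

#: Default grid geometry: 40 x 30 cells of 30 m tiles 108 ha exactly.
DEFAULT_N_COLS = 40
DEFAULT_N_ROWS = 30

#: Default resource budget (energy units) spread over the whole grid.
DEFAULT_TOTAL_RESOURCES = 168_000.0

#: Default uniform regrowth (energy units per step per cell).
DEFAULT_GROW_BACK_RATE = 8.0

#: Background weights are drawn from (0, BACKGROUND_WEIGHT_MAX].
BACKGROUND_WEIGHT_MAX = 0.25


@dataclass(frozen=True)
class WeightGrid:
    """Relative per-cell weights used to distribute the resource budget."""

    weights: np.ndarray  # shape (n_rows, n_cols), strictly positive, finite

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D array")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.weights.shape[1]

    def hotspot_cells(self, threshold: float = 1.0) -> list[tuple[int, int]]:
        """Return ``(col, row)`` of every cell with weight >= ``threshold``."""
        rr, cc = np.nonzero(self.weights >= threshold)
        return [(int(c), int(r)) for r, c in zip(rr, cc)]


@dataclass
class ResourceLandscape:
    """Resource grid with per-cell current level, ceiling and regrowth."""

    current: np.ndarray    # (n_rows, n_cols) energy units
    max_level: np.ndarray  # (n_rows, n_cols) energy units
    cell_size: float = CELL_SIZE
    grow_back_rate: float = DEFAULT_GROW_BACK_RATE
    # cached cell-centre coordinates, filled in __post_init__
    centre_x: np.ndarray = field(init=False, repr=False)
    centre_y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        self.max_level = np.asarray(self.max_level, dtype=float)
        if self.current.shape != self.max_level.shape:
            raise ValueError("current and max_level must have the same shape")
        self.centre_x = (np.arange(self.n_cols) + 0.5) * self.cell_size
        self.centre_y = (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def n_rows(self) -> int:
        return self.current.shape[0]

    @property
    def n_cols(self) -> int:
        return self.current.shape[1]

    @property
    def n_cells(self) -> int:
        return self.current.size

    @property
    def width(self) -> float:
        """Extent along x in metres."""
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        """Extent along y in metres."""
        return self.n_rows * self.cell_size

    @property
    def area_ha(self) -> float:
        return self.width * self.height / 10_000.0

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its containing cell ``(col, row)`` (half-open)."""
        col = int(x // self.cell_size)
        row = int(y // self.cell_size)
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(f"point ({x}, {y}) outside landscape extent")
        return col, row

    def cell_centre(self, col: int, row: int) -> tuple[float, float]:
        return (col + 0.5) * self.cell_size, (row + 0.5) * self.cell_size


def synthesize_weights(
    n_cols: int,
    n_rows: int,
    n_hotspots: int,
    hotspot_intensity: float = 8.0,
    seed: int | None = None,
) -> WeightGrid:
    """Generate a synthetic weight surface: low uniform background plus
    clustered high-weight hotspots.

    Background cells draw weights from Uniform(0, 0.25].  Each hotspot seeds
    one cell and adds an exponentially distance-decayed weight
    ``intensity * exp(-d)`` (d in cell units, decay length one cell) to
    neighbouring cells; the kernel is truncated where a single hotspot's
    contribution drops below 1, so exactly the hotspot-cluster cells end up
    with weight >= 1.

    Parameters
    ----------
    n_cols, n_rows
        Grid shape; must be positive.
    n_hotspots
        Number of hotspot seed cells (distinct, uniformly scattered).
    hotspot_intensity
        Peak added weight per hotspot; must be >= 1 when hotspots are present.
    seed
        Seed for the generator; fixed seed gives identical grids.
    """
    if n_cols <= 0 or n_rows <= 0:
        raise ValueError("grid dimensions must be positive")
    if n_hotspots < 0:
        raise ValueError("n_hotspots must be non-negative")
    n_cells = n_cols * n_rows
    if n_hotspots > n_cells:
        raise ValueError("n_hotspots exceeds the number of cells")
    if n_hotspots > 0 and hotspot_intensity < 1.0:
        raise ValueError("hotspot_intensity must be >= 1 so hotspot cells reach weight 1")

    rng = np.random.default_rng(seed)
    # (0, 0.25]: flip the half-open uniform so zero is excluded
    weights = BACKGROUND_WEIGHT_MAX * (1.0 - rng.random((n_rows, n_cols)))

    if n_hotspots > 0:
        flat = rng.choice(n_cells, size=n_hotspots, replace=False)
        seed_rows, seed_cols = np.divmod(flat, n_cols)
        # kernel support: contribution >= 1  <=>  d <= ln(intensity)
        radius = int(math.floor(math.log(hotspot_intensity))) + 1
        rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        dist = np.hypot(rr, cc)
        contrib = hotspot_intensity * np.exp(-dist)
        support = contrib >= 1.0
        for r0, c0 in zip(seed_rows, seed_cols):
            for dr, dc, w in zip(rr[support], cc[support], contrib[support]):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < n_rows and 0 <= c < n_cols:
                    weights[r, c] += w

    return WeightGrid(weights)


def build_landscape(
    weights: WeightGrid,
    total_resources: float = DEFAULT_TOTAL_RESOURCES,
    grow_back_rate: float = DEFAULT_GROW_BACK_RATE,
    cell_size: float = CELL_SIZE,
) -> ResourceLandscape:
    """Distribute ``total_resources`` over cells proportionally to weight.

    ``max_level_i = total * w_i / sum(w)``; the landscape starts saturated
    (``current == max_level``).
    """
    if total_resources <= 0:
        raise ValueError("total_resources must be positive")
    w = weights.weights
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not be all zero")
    max_level = total_resources * (w / s)
    return ResourceLandscape(
        current=max_level.copy(),
        max_level=max_level,
        cell_size=cell_size,
        grow_back_rate=grow_back_rate,
    )


def regrow_step(landscape: ResourceLandscape) -> ResourceLandscape:
    """Uniform regrowth: ``current <- min(current + rate, max_level)``.

    Mutates and returns the landscape.
    """
    np.minimum(
        landscape.current + landscape.grow_back_rate,
        landscape.max_level,
        out=landscape.current,
    )
    return landscape


def harvest(landscape: ResourceLandscape, col: int, row: int, amount: float) -> float:
    """Remove up to ``amount`` from one cell; return what was actually removed."""
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if not (0 <= col < landscape.n_cols and 0 <= row < landscape.n_rows):
        raise ValueError(f"cell ({col}, {row}) out of bounds")
    removed = min(amount, landscape.current[row, col])
    landscape.current[row, col] -= removed
    return float(removed)


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def weights_to_csv(weights: WeightGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("col,row,weight\n")
        for r in range(weights.n_rows):
            for c in range(weights.n_cols):
                fh.write(f"{c},{r},{float(weights.weights[r, c])!r}\n")


def weights_from_csv(path) -> WeightGrid:
    import pandas as pd

    df = pd.read_csv(path, float_precision='round_trip')
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    w = np.zeros((n_rows, n_cols))
    w[df["row"].to_numpy(), df["col"].to_numpy()] = df["weight"].to_numpy()
    return WeightGrid(w)


def landscape_to_csv(landscape: ResourceLandscape, path) -> None:
    with open(path, "w") as fh:
        fh.write("col,row,current,max\n")
        for r in range(landscape.n_rows):
            for c in range(landscape.n_cols):
                fh.write(
                    f"{c},{r},{float(landscape.current[r, c])!r},{float(landscape.max_level[r, c])!r}\n"
                )


def landscape_from_csv(path, cell_size: float = CELL_SIZE,
                       grow_back_rate: float = DEFAULT_GROW_BACK_RATE) -> ResourceLandscape:
    import pandas as pd

    df = pd.read_csv(path, float_precision='round_trip')
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    cur = np.zeros((n_rows, n_cols))
    mx = np.zeros((n_rows, n_cols))
    rows = df["row"].to_numpy()
    cols = df["col"].to_numpy()
    cur[rows, cols] = df["current"].to_numpy()
    mx[rows, cols] = df["max"].to_numpy()
    return ResourceLandscape(cur, mx, cell_size=cell_size, grow_back_rate=grow_back_rate)


def write_ascii_grid(values: np.ndarray, path, cell_size: float = CELL_SIZE,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array in the ESRI ASCII raster dialect (row 0 = south)."""
    values = np.asarray(values)
    n_rows, n_cols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for r in range(n_rows - 1, -1, -1):  # top row first
            fh.write(" ".join(repr(float(v)) for v in values[r]) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII raster; return ``(values, cell_size)`` with row 0 = south."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows[::-1])  # file is top-down; flip to row 0 = south
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("raster body does not match header dimensions")
    return values, header.get("cellsize", CELL_SIZE)
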