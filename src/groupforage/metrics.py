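"""Movement-pattern statistics for group-centre trajectories.

Covers the field-schedule subsampling of simulated trajectories, per-day
travel summaries (step length, net displacement, tortuosity), distribution
descriptors (sample skewness), instantaneous group spread, grid-based home
range, the beta-binomial spatio-temporal aggregation index and two-sample
distribution comparisons (Kolmogorov–Smirnov and Welch's t).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Days per aggregation period ("month").
PERIOD_DAYS = 30

#: Field observation schedule: 5 days per month, 7 hours per day, starting
#: one hour into the active day (08:00 when the day starts at 07:00).
OBS_DAYS_PER_MONTH = 5
OBS_HOURS_PER_DAY = 7
OBS_START_STEP = 2


def subsample_observation(
    trajectory: pd.DataFrame,
    days_per_month: int = OBS_DAYS_PER_MONTH,
    hours_per_day: int = OBS_HOURS_PER_DAY,
    seed: int | None = None,
    steps_per_day: int | None = None,
    start_step: int = OBS_START_STEP,
) -> pd.DataFrame:
    """Thin a trajectory to the field data-collection intensity.

    Per 30-day period, ``days_per_month`` days are drawn without replacement
    (seeded); within each selected day the ``2 * hours_per_day`` consecutive
    half-hour steps starting at ``start_step`` are kept.  Months with fewer
    days than requested keep all their days.  Adds a ``period`` column.
    """
    rng = np.random.default_rng(seed)
    if steps_per_day is None:
        counts = trajectory.groupby("day")["step"].count()
        steps_per_day = int(counts.max())
    step_of_day = trajectory["step"].to_numpy() - trajectory["day"].to_numpy() * steps_per_day
    n_window = 2 * hours_per_day
    window = (step_of_day >= start_step) & (step_of_day < start_step + n_window)

    days = np.unique(trajectory["day"].to_numpy())
    chosen: list[int] = []
    for period in np.unique(days // PERIOD_DAYS):
        pdays = days[days // PERIOD_DAYS == period]
        if len(pdays) <= days_per_month:
            chosen.extend(pdays.tolist())
        else:
            pick = rng.choice(pdays, size=days_per_month, replace=False)
            chosen.extend(sorted(int(d) for d in pick))
    day_mask = trajectory["day"].isin(chosen).to_numpy()
    out = trajectory.loc[window & day_mask].copy()
    out["period"] = out["day"] // PERIOD_DAYS
    return out.sort_values("step").reset_index(drop=True)


@dataclass(frozen=True)
class DailySummary:
    day: int
    d_total: float      # summed consecutive displacements (m)
    d_net: float        # straight-line start-to-end (m)
    tortuosity: float   # ln(d_total / d_net**2); NaN when d_net == 0
    spread_mean: float  # mean instantaneous spread over the day (m^2)


def path_tortuosity(d_total: float, d_net: float) -> float:
    """``ln(d_total / d_net**2)`` — undefined (ValueError) when d_net == 0."""
    if d_net <= 0:
        raise ValueError("tortuosity undefined for zero net displacement")
    return math.log(d_total / d_net**2)


def daily_metrics(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Per-day travel summaries of a (possibly subsampled) trajectory.

    Days with a single point are dropped with a warning; days with zero net
    displacement get NaN tortuosity.
    """
    rows = []
    for day, grp in trajectory.groupby("day", sort=True):
        grp = grp.sort_values("step")
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        if len(x) < 2:
            warnings.warn(f"day {day}: single observation, dropped", stacklevel=2)
            continue
        d_total = float(np.hypot(np.diff(x), np.diff(y)).sum())
        d_net = float(math.hypot(x[-1] - x[0], y[-1] - y[0]))
        tort = math.log(d_total / d_net**2) if (d_net > 0 and d_total > 0) else float("nan")
        spread = float(grp["spread"].mean()) if "spread" in grp else float("nan")
        rows.append({
            "day": int(day), "d_total": d_total, "d_net": d_net,
            "tortuosity": tort, "spread_mean": spread,
        })
    return pd.DataFrame(rows, columns=["day", "d_total", "d_net", "tortuosity",
                                       "spread_mean"])


def skewness(sample) -> float:
    """Adjusted Fisher–Pearson sample skewness (bias-corrected)."""
    a = np.asarray(sample, dtype=float)
    if len(a) < 3:
        raise ValueError("skewness requires at least 3 observations")
    if np.allclose(a, a[0]):
        raise ValueError("skewness undefined for zero variance")
    return float(stats.skew(a, bias=False))


def group_spread(positions) -> float:
    """Convex-hull area (m^2) of member positions; 0 for degenerate sets."""
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0


def home_range(trajectory: pd.DataFrame, cell_size: float = 30.0) -> pd.Series:
    """Visited-cell home range per 30-day period, in hectares.

    Counts the distinct ``cell_size``-square cells the centre visited in
    each period and scales by the cell area.
    """
    if len(trajectory) == 0:
        return pd.Series(dtype=float, name="home_range_ha")
    df = trajectory
    period = (df["period"] if "period" in df else df["day"] // PERIOD_DAYS)
    col = (df["x"] // cell_size).astype(np.int64)
    row = (df["y"] // cell_size).astype(np.int64)
    key = pd.DataFrame({"period": period.to_numpy(), "col": col, "row": row})
    counts = key.drop_duplicates().groupby("period").size()
    ha = counts * (cell_size * cell_size / 10_000.0)
    ha.name = "home_range_ha"
    return ha


# ---------------------------------------------------------------------------
# spatio-temporal beta-binomial aggregation index
# ---------------------------------------------------------------------------

def _betabinom_nll(log_ab: np.ndarray, k: np.ndarray, n: int) -> float:
    a, b = np.exp(log_ab)
    return float(-stats.betabinom.logpmf(k, n, a, b).sum())


def fit_beta_binomial(k, n: int = 9) -> tuple[float, float, float]:
    """Maximum-likelihood beta-binomial fit to counts ``k`` out of ``n``.

    Returns ``(alpha, beta, theta)`` where ``theta = 1 / (alpha + beta + 1)``
    is the intraclass correlation (the aggregation index).  Binomial data
    drives ``alpha + beta`` large and hence ``theta`` towards 0.
    """
    k = np.asarray(k, dtype=np.int64)
    if np.any((k < 0) | (k > n)):
        raise ValueError(f"counts must lie in [0, {n}]")
    if np.all(k == 0):
        raise ValueError("all counts zero: aggregation index undefined")
    best = None
    for start in ((0.0, 0.0), (math.log(0.2), math.log(0.2)), (2.0, 2.0)):
        res = optimize.minimize(
            _betabinom_nll, np.asarray(start), args=(k, n),
            method="L-BFGS-B", bounds=[(-10.0, 12.0)] * 2,
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = np.exp(best.x)
    theta = 1.0 / (alpha + beta + 1.0)
    return float(alpha), float(beta), float(theta)


def visit_counts(
    points_x: np.ndarray,
    points_y: np.ndarray,
    extent: tuple[float, float, float, float],
    quadrat_size: float = 30.0,
    subcell_size: float = 10.0,
) -> np.ndarray:
    """Per-quadrat count of distinct visited subcells.

    ``extent`` is ``(xmin, ymin, xmax, ymax)``; every quadrat inside it is
    counted, visited or not.  A subcell is "visited" when at least one point
    falls inside it.  Points outside the extent are ignored.
    """
    xmin, ymin, xmax, ymax = extent
    n_qx = int(math.ceil((xmax - xmin) / quadrat_size))
    n_qy = int(math.ceil((ymax - ymin) / quadrat_size))
    per_side = int(round(quadrat_size / subcell_size))
    inside = (
        (points_x >= xmin) & (points_x < xmax)
        & (points_y >= ymin) & (points_y < ymax)
    )
    sx = ((points_x[inside] - xmin) // subcell_size).astype(np.int64)
    sy = ((points_y[inside] - ymin) // subcell_size).astype(np.int64)
    sub_ids = np.unique(sx * 1_000_003 + sy)
    # recover subcell coords, then owning quadrat
    sx_u, sy_u = np.divmod(sub_ids, 1_000_003)[0], sub_ids % 1_000_003
    qx = sx_u // per_side
    qy = sy_u // per_side
    counts = np.zeros((n_qy, n_qx), dtype=np.int64)
    np.add.at(counts, (qy, qx), 1)
    return counts.ravel()


def stbbd_theta(
    trajectory: pd.DataFrame,
    quadrat_size: float = 30.0,
    subcell_size: float = 10.0,
    extent: tuple[float, float, float, float] | None = None,
):
    """Monthly aggregation index from a subsampled trajectory.

    Space is divided into ``quadrat_size`` quadrats of
    ``(quadrat_size/subcell_size)**2`` subcells; per 30-day period each
    quadrat scores how many of its subcells were visited at least once, and
    a beta-binomial fit to those counts yields the period's index
    ``theta``.  Returns ``(per_period_table, mean_theta, (ci_lo, ci_hi))``
    with a t-based 95% CI of the mean across periods.  Periods with no
    visits at all are skipped with a warning.
    """
    df = trajectory
    period = (df["period"] if "period" in df else df["day"] // PERIOD_DAYS).to_numpy()
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if extent is None:
        xmin = math.floor(x.min() / quadrat_size) * quadrat_size
        ymin = math.floor(y.min() / quadrat_size) * quadrat_size
        xmax = math.floor(x.max() / quadrat_size + 1) * quadrat_size
        ymax = math.floor(y.max() / quadrat_size + 1) * quadrat_size
        extent = (xmin, ymin, xmax, ymax)
    n_sub = int(round(quadrat_size / subcell_size)) ** 2

    rows = []
    for p in np.unique(period):
        sel = period == p
        k = visit_counts(x[sel], y[sel], extent, quadrat_size, subcell_size)
        if np.all(k == 0):
            warnings.warn(f"period {p}: no visits, skipped", stacklevel=2)
            continue
        alpha, beta, theta = fit_beta_binomial(k, n=n_sub)
        rows.append({"period": int(p), "theta": theta, "alpha": alpha,
                     "beta": beta, "n_quadrats": len(k)})
    table = pd.DataFrame(rows, columns=["period", "theta", "alpha", "beta",
                                        "n_quadrats"])
    if len(table) == 0:
        return table, float("nan"), (float("nan"), float("nan"))
    thetas = table["theta"].to_numpy()
    mean = float(thetas.mean())
    if len(thetas) > 1:
        half = float(
            stats.t.ppf(0.975, len(thetas) - 1)
            * thetas.std(ddof=1) / math.sqrt(len(thetas))
        )
    else:
        half = float("nan")
    return table, mean, (mean - half, mean + half)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def compare_distributions(simulated, observed, center: bool = False) -> dict:
    """Two-sample KS (asymptotic p) and Welch's t between two samples.

    With ``center=True`` both samples are mean-centred first (used for step
    lengths, whose means were consumed by calibration).
    """
    a = np.asarray(simulated, dtype=float)
    b = np.asarray(observed, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if center:
        a = a - a.mean()
        b = b - b.mean()
    ks = stats.ks_2samp(a, b, method="asymp")
    tt = stats.ttest_ind(a, b, equal_var=False)
    return {
        "ks_d": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "welch_t": float(tt.statistic),
        "welch_p": float(tt.pvalue),
    }
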