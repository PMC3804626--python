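"""Experiment battery: run agent types x replicates, aggregate and rank.

A plan names a subset of the 12 agent types, a replicate count and a base
seed; replicate ``j`` of every type runs with seed ``base_seed + j`` so that
types are compared on matched landscapes and schedules.  Each trial is
subsampled to the field schedule before metrics are computed.  When an
observed group-centre trajectory is supplied, per-type distribution
comparisons (KS, Welch) are produced and the types are ranked by fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from . import simulation as sim

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentPlan:
    agent_types: tuple = sim.AGENT_TYPES
    replicates: int = 1
    base_seed: int = 0
    days: int = 180
    group_size: int = 70
    n_cols: int = 40
    n_rows: int = 30
    n_hotspots: int = 12
    hotspot_intensity: float = 8.0
    total_resources: float = 168_000.0
    grow_back_rate: float = 8.0
    observed_path: str | None = None

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "agent_types", tuple(self.agent_types))
        for t in self.agent_types:
            sim.parse_agent_type(t)

    def seeds(self) -> list[int]:
        return [self.base_seed + j for j in range(self.replicates)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @staticmethod
    def from_yaml(path) -> "ExperimentPlan":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "agent_types" in raw:
            raw["agent_types"] = tuple(raw["agent_types"])
        return ExperimentPlan(**raw)


@dataclass
class TrialRecord:
    agent_type: str
    replicate: int
    seed: int
    daily: pd.DataFrame
    theta_table: pd.DataFrame
    theta_mean: float
    theta_ci: tuple
    home_range_ha: float
    mean_spread: float


@dataclass
class ExperimentBundle:
    plan: ExperimentPlan
    trials: list
    features: pd.DataFrame   # one row per trial
    aggregate: pd.DataFrame  # one row per agent type
    comparisons: pd.DataFrame | None = None  # per type vs observed


def _trial_metrics(plan: ExperimentPlan, agent_type: str, replicate: int) -> TrialRecord:
    seed = plan.base_seed + replicate
    cfg = sim.config_for(
        agent_type, seed=seed, days=plan.days, group_size=plan.group_size,
        n_cols=plan.n_cols, n_rows=plan.n_rows, n_hotspots=plan.n_hotspots,
        hotspot_intensity=plan.hotspot_intensity,
        total_resources=plan.total_resources, grow_back_rate=plan.grow_back_rate,
    )
    result = sim.run_trial(cfg)
    sub = metrics.subsample_observation(
        result.trajectory, steps_per_day=cfg.steps_per_day, seed=seed
    )
    daily = metrics.daily_metrics(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theta_table, theta_mean, theta_ci = metrics.stbbd_theta(sub)
    hr = metrics.home_range(sub)
    rec = TrialRecord(
        agent_type=agent_type, replicate=replicate, seed=seed,
        daily=daily, theta_table=theta_table, theta_mean=theta_mean,
        theta_ci=theta_ci,
        home_range_ha=float(hr.mean()) if len(hr) else float("nan"),
        mean_spread=float(sub["spread"].mean()) if "spread" in sub else float("nan"),
    )
    rec.trajectory = result.trajectory  # kept for bundle writers
    return rec


def run_experiment(plan: ExperimentPlan, out_dir=None) -> ExperimentBundle:
    """Run the whole battery; optionally write the bundle under ``out_dir``."""
    if plan.observed_path is not None and not Path(plan.observed_path).exists():
        raise FileNotFoundError(f"observed trajectory not found: {plan.observed_path}")

    trials: list[TrialRecord] = []
    feature_rows = []
    for agent_type in plan.agent_types:
        for rep in range(plan.replicates):
            log.info("trial %s replicate %d (seed %d)", agent_type, rep,
                     plan.base_seed + rep)
            rec = _trial_metrics(plan, agent_type, rep)
            trials.append(rec)
            rule, mode, retention = sim.parse_agent_type(agent_type)
            d = rec.daily
            feature_rows.append({
                "agent_type": agent_type,
                "social_rule": rule,
                "memory_mode": mode,
                "retention": retention,
                "replicate": rep,
                "seed": rec.seed,
                "mean_step": float(d["d_total"].mean()) if len(d) else float("nan"),
                "step_skew": (metrics.skewness(d["d_total"])
                              if len(d) >= 3 and d["d_total"].nunique() > 1
                              else float("nan")),
                "mean_tortuosity": float(d["tortuosity"].mean()),
                "mean_spread": rec.mean_spread,
                "theta_mean": rec.theta_mean,
                "home_range_ha": rec.home_range_ha,
            })
    features = pd.DataFrame(feature_rows)

    agg = (
        features.groupby("agent_type", sort=False)
        .agg(
            social_rule=("social_rule", "first"),
            memory_mode=("memory_mode", "first"),
            retention=("retention", "first"),
            n_replicates=("replicate", "count"),
            mean_step=("mean_step", "mean"),
            sd_step=("mean_step", "std"),
            step_skew=("step_skew", "mean"),
            mean_tortuosity=("mean_tortuosity", "mean"),
            mean_spread=("mean_spread", "mean"),
            theta_mean=("theta_mean", "mean"),
            home_range_ha=("home_range_ha", "mean"),
        )
        .reset_index()
    )

    comparisons = None
    if plan.observed_path is not None:
        observed = load_observed_trajectory(plan.observed_path)
        comparisons = compare_to_observed(plan, trials, observed)

    bundle = ExperimentBundle(
        plan=plan, trials=trials, features=features,
        aggregate=agg, comparisons=comparisons,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def load_observed_trajectory(path) -> pd.DataFrame:
    """Read an observed centre trajectory CSV (columns step/day/x/y at least)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"observed trajectory needs columns {sorted(required)}")
    if "day" not in df.columns:
        df["day"] = 0
    if "step" not in df.columns:
        df["step"] = np.arange(len(df))
    return df


def observed_metrics(observed: pd.DataFrame) -> dict:
    daily = metrics.daily_metrics(observed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, theta_mean, theta_ci = metrics.stbbd_theta(observed)
    return {"daily": daily, "theta_mean": theta_mean, "theta_ci": theta_ci}


def compare_to_observed(plan, trials, observed: pd.DataFrame) -> pd.DataFrame:
    obs = observed_metrics(observed)
    obs_daily = obs["daily"]
    rows = []
    for agent_type in plan.agent_types:
        recs = [t for t in trials if t.agent_type == agent_type]
        daily = pd.concat([t.daily for t in recs], ignore_index=True)
        step_cmp = metrics.compare_distributions(
            daily["d_total"], obs_daily["d_total"], center=True
        )
        tort_cmp = metrics.compare_distributions(
            daily["tortuosity"].dropna(), obs_daily["tortuosity"].dropna()
        )
        theta_mean = float(np.nanmean([t.theta_mean for t in recs]))
        rows.append({
            "agent_type": agent_type,
            "ks_d_step": step_cmp["ks_d"], "ks_p_step": step_cmp["ks_p"],
            "ks_d_tort": tort_cmp["ks_d"], "ks_p_tort": tort_cmp["ks_p"],
            "welch_t_tort": tort_cmp["welch_t"], "welch_p_tort": tort_cmp["welch_p"],
            "theta_mean": theta_mean,
            "theta_abs_diff": abs(theta_mean - obs["theta_mean"]),
        })
    return pd.DataFrame(rows)


def rank_hypotheses(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Order agent types by fit to the observed data.

    Lexicographic key: KS-D on tortuosity, then KS-D on centred step length,
    then |theta difference|.  Exact ties on the full key are flagged.
    """
    key_cols = ["ks_d_tort", "ks_d_step", "theta_abs_diff"]
    ranked = comparisons.sort_values(
        key_cols + ["agent_type"], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    dup = ranked.duplicated(subset=key_cols, keep=False)
    ranked["tied"] = dup
    return ranked


def write_bundle(bundle: ExperimentBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# plan_hash={bundle.plan.config_hash()} base_seed={bundle.plan.base_seed}\n"

    def _write(df: pd.DataFrame, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    _write(bundle.features, out / "features.csv")
    _write(bundle.aggregate, out / "aggregate.csv")
    if bundle.comparisons is not None:
        _write(bundle.comparisons, out / "comparisons.csv")
        _write(rank_hypotheses(bundle.comparisons), out / "ranking.csv")
    for rec in bundle.trials:
        tdir = out / rec.agent_type.replace(":", "_") / f"rep{rec.replicate}"
        tdir.mkdir(parents=True, exist_ok=True)
        _write(rec.daily, tdir / "daily_metrics.csv")
        _write(rec.theta_table, tdir / "theta.csv")
        if hasattr(rec, "trajectory"):
            sim.write_trajectory(rec.trajectory, tdir / "trajectory.csv", seed=rec.seed)
        with open(tdir / "trial.log", "w") as fh:
            fh.write(
                f"agent_type={rec.agent_type} replicate={rec.replicate} "
                f"seed={rec.seed} theta_mean={rec.theta_mean!r} "
                f"home_range_ha={rec.home_range_ha!r}\n"
            )
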