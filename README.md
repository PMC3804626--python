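# groupforage

Agent-based simulation of group foraging in a social primate, with the
movement-pattern metrics and statistical comparisons needed to discriminate
between foraging hypotheses.

A group of identical agents forages on a gridded resource landscape
(30 × 30 m cells, depletion plus uniform regrowth). Twelve agent types cross
three behavioural axes:

* **social rule** — `independent` (safety counted over any nearby group
  mates) vs `leader` (followers keep one fixed leader nearby);
* **memory type** — `euclidean` (all remembered sites recallable from
  anywhere) vs `landmark` (only sites within 100 m of the last-seen
  landmark are recallable);
* **memory retention** — 20 / 60 / 100 remembered sites.

Each trial records the group-centre trajectory (a recursive 80%-quorum
centre robust to fission), which is subsampled to a field observation
schedule (5 days/month, 7 h/day) and summarised as daily step length and
skew, path tortuosity `ln(D_total / D_net²)`, convex-hull group spread,
grid-cell home range, and a monthly beta-binomial spatio-temporal
aggregation index θ. Simulated and observed distributions are compared with
two-sample Kolmogorov–Smirnov and Welch tests.

## Command line

```sh
# one trial (trajectory + daily metrics)
groupforage simulate --agent-type leader:landmark:20 --seed 7 --days 180 --out run/

# calibration sweep over resource totals and grow-back rates
groupforage sweep --total 84000,168000,336000 --rate 4,8,16 --days 30 --out sweep.csv

# multi-type replicate battery from a YAML plan, then ranking against
# an observed group-centre trajectory (CSV with step,day,x,y columns)
groupforage experiment run plan.yaml --out battery/
groupforage experiment rank battery/ --observed observed.csv
```

A minimal `plan.yaml`:

```yaml
agent_types: [leader:landmark:20, independent:euclidean:60]
replicates: 5
base_seed: 100
days: 60
group_size: 70
```

Replicate `j` of every type runs with seed `base_seed + j`, so types are
compared on matched landscapes and schedules.

## Library layout

| module | contents |
|---|---|
| `groupforage.landscape` | synthetic weight surfaces, resource grid, harvest/regrowth, CSV + ASCII-raster IO |
| `groupforage.memory` | Euclidean / landmark spatial memory, believed-resource bookkeeping |
| `groupforage.agent` | energetics, adaptive safety, food-site index, movement decision tree |
| `groupforage.simulation` | trial scheduler, recursive group centre, calibration sweep |
| `groupforage.metrics` | subsampling, daily summaries, skewness, spread, home range, θ, KS/Welch |
| `groupforage.experiment` | experiment plans, replicate batteries, aggregation, hypothesis ranking |

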