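# swdopt

Design-optimization toolkit for **incomplete stepped wedge cluster-randomized
trials** with continuous, repeated cross-sectional outcomes. Given a trial
configuration, correlation assumptions and cost parameters, it:

- computes the GLS variance of the treatment-effect estimator for any
  complete or incomplete sequence-by-period design, under discrete-time
  decay, block-exchangeable or exchangeable within-cluster correlation;
- computes asymptotic power of the two-sided Wald test (normal critical
  values);
- computes total trial cost, including per-cluster, per-condition,
  per-participant and data-collection *restart* costs incurred when a
  sequence resumes measurement after a gap;
- runs a deterministic greedy search that removes one sequence-period cell
  at a time, each time choosing the removal that maximizes cost efficiency
  `CE = 1 / (variance x cost)`, until the treatment effect stops being
  estimable; the optimal design is the trace member with maximal CE
  relative to the complete design (RCE) among those meeting a minimum
  power constraint;
- handles correlation-parameter uncertainty by running the search over an
  (ICC, CAC) grid and unioning the per-point optimal designs into a
  "superset" design that keeps the power guarantee at every grid point.

## Library quick start

```python
import swdopt as sw

design = sw.make_complete_stepped_wedge(5, [8, 7, 7, 7, 8], cluster_period_size=7)
corr   = sw.CorrelationSpec(icc=0.05, cac=0.95)              # discrete-time decay
costs  = sw.CostSpec(cost_per_cluster=2500,
                     participant_cost_intervention=140,
                     participant_cost_control=80,
                     restart_cost_intervention=230)
pw     = sw.PowerSpec(effect_size=0.26, alpha=0.05, min_power=0.80)

sw.total_cost(design, costs)          # 263440
sw.power(design, corr, pw)            # ~0.897

trace = sw.greedy_removal_search(design, corr, costs, pw)
best_design, metrics, iteration = sw.select_optimal(trace, pw)
print(sw.to_schematic(best_design))   # staircase-like design
print(metrics.rce, metrics.power, metrics.cost)   # ~1.35, ~0.83, 160260
```

Grid/superset procedure:

```python
grid = sw.CorrelationGrid((0.01, 0.05, 0.1), (0.8, 0.9, 0.95))
result = sw.superset_search(design, grid, costs, pw)
result.cost, result.min_power        # 208630, ~0.812
```

## CLI

Configuration is a small YAML file; the packaged fixtures are complete
worked examples (`swdopt fixtures alliance` prints one). Cost keys use the
conventional symbols: `c` (per cluster), `k`/`kp` (per-cluster
intervention/control implementation), `p`/`pp` (per participant), `g`/`gp`
(restart). Giving `icc`/`cac` as lists turns the config into a grid.

```bash
swdopt fixtures                      # list packaged example configs
swdopt fixtures alliance --out my.yaml
swdopt search   --config my.yaml --out out/       # greedy removal search
swdopt superset --config <grid config> --out out/ # grid-union procedure
swdopt evaluate --config my.yaml                  # metrics only, no search
```

`search` writes `trace.csv` (iteration, removed cell, variance, power,
cost, CE, RCE per design), per-iteration design schematics (`0` measured
control, `1` measured intervention, `.` unmeasured), the optimal design and
`summary.json`. `superset` writes per-grid-point and per-cell reports plus
the superset schematic. `--plots` adds RCE/power/cost curves. Outputs are
byte-reproducible; exit status 0 = success, 1 = bad config, 2 = design not
estimable, 3 = no design meets the power constraint (use the complete
design).

Indices in all files and messages are 1-based. Ties in the greedy candidate
ranking (CE within 1e-12 relative) are broken toward the smallest sequence,
then smallest period index; the rule is echoed in every run log since tied
removals could in principle make endpoints rule-dependent.

## Scope notes

Cluster-period sizes are constant, time effects are categorical, outcomes
are continuous with repeated cross-sectional sampling, and power uses
normal (not t) critical values. Restart costs depend on the number of gaps,
not their length. The search removes sequence-period cells (all clusters in
a sequence share one observation pattern); cluster-period-level removal,
cohort sampling and budget-constrained formulations are out of scope.
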