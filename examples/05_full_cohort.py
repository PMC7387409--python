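"""Run the full synthetic three-arm study end to end.

Simulates a vehicle-control arm and two treated arms (slower, more
numerous cells), renders and analyzes every movie (projection, debleach,
registration, detection, tracking, metrics, quadrants, spatial summary),
and prints the cohort-level report. Writes tables and figures to
./scratch/full_cohort. Runtime is about half a minute.
"""

from ivmotility import demo_config, run_pipeline

result = run_pipeline(demo_config(seed=1), out_dir="scratch/full_cohort")

print(f"tracks analyzed: {len(result.metrics)}")
print(f"thresholds: v* = {result.thresholds['v_star']:.3f} um/min, "
      f"MI* = {result.thresholds['mi_star']:.3f}")
print("\narm-level mean velocity (um/min, mean +/- SEM):")
for arm in result.arm_stats["velocity_mean_um_min"]:
    mu = result.arm_stats["velocity_mean_um_min"][arm]
    sem = result.arm_stats["velocity_sem_um_min"][arm]
    n = result.arm_stats["n_tracks"][arm]
    print(f"  {arm:<12} {mu:.3f} +/- {sem:.3f}  (n = {n})")

kw = result.arm_stats["kruskal_wallis"]
print(f"\nKruskal-Wallis: H = {kw['H']:.2f}, p = {kw['p']:.2e}")
if kw["posthoc"]:
    for row in kw["posthoc"]:
        print(f"  Dunn {row['group_i']} vs {row['group_j']}: "
              f"p_adj = {row['p_adjusted']:.3g}")
print(f"\nspatial kurtosis of final cell positions: "
      f"{result.spatial['kurtosis']:.3f}; region counts: "
      f"{result.spatial['region_counts']}")
print("\nThe control arm is fastest by construction; treated arms show the "
      "lower-velocity, higher-cell-count pattern of checkpoint blockade.")
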