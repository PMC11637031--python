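"""Compare optimizers over repeated paired runs with Friedman ranking.

Runs plain SHO and the SHOSCA hybrid 10 times each on the planted-feature
table, sharing the per-run 80/20 splits so the runs form paired blocks,
then ranks the algorithms with the Friedman test on per-run best fitness.
(The full study protocol uses 25 runs; 10 keeps this example quick.)
"""

from msfs.feature_selection import compare_algorithms
from msfs.synthetic_data import TableSpec, make_feature_table

df, _ = make_feature_table(TableSpec(seed=42))
reports, friedman = compare_algorithms(df, ["sho", "shosca"], runs=10, base_seed=0)

print(f"{'algorithm':>10} {'mean fitness':>13} {'mean acc':>9} {'mean size':>10}")
for rep in reports:
    a = rep.aggregates
    print(f"{rep.algorithm:>10} {a['fitness_mean']:13.4f} "
          f"{a['accuracy_mean']:9.3f} {a['feat_size_mean']:10.1f}")
res = friedman["fitness"]
print(f"Friedman on per-run fitness: chi2 = {res.chi_square:.2f}, "
      f"p = {res.p_value:.2e}, mean ranks = {res.mean_ranks}")
print("rank 1 = best; a small p-value means the ordering is systematic.")
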