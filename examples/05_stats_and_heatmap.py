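"""Group comparisons and the row z-score interaction heatmap.

Simulates per-sample corrected microenvironment percentages for three
gestational-age groups, standardizes each interaction row across samples,
renders the clustered heatmap, and runs the rank-based group tests.
"""

import numpy as np
import pandas as pd

from imcmicro.stats_viz import clustered_heatmap, compare_groups, row_zscores

rng = np.random.default_rng(9)
samples = [f"s{i}" for i in range(12)]
trimester = np.repeat(["first", "second", "term"], 4)
pairs = ["myeloid→T", "myeloid→NK", "NK→trophoblast", "T→myeloid"]

# corrected percentages: NK→trophoblast declines with gestational age
base = rng.normal(0.05, 0.02, size=(len(pairs), len(samples)))
base[2] += np.where(trimester == "first", 0.15, np.where(trimester == "second", 0.05, -0.05))
matrix = pd.DataFrame(base, index=pairs, columns=samples)

z = row_zscores(matrix)
print("row z-scores (mean 0, sd 1 per row):")
print(z.round(2).to_string())

grid = clustered_heatmap(matrix, out="heatmap.png")
print("\nwrote heatmap.png (rows clustered by average linkage)")

res = compare_groups(
    matrix.loc["NK→trophoblast"].to_numpy(), trimester, design="k_group_independent"
)
for r in res:
    print(f"{r.test:>15} {str(r.groups):<30} p_raw={r.p_raw:.4f} p_adj={r.p_adjusted:.4f}")
print("Kruskal-Wallis + Dunn: the first-vs-term contrast drives the signal")
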