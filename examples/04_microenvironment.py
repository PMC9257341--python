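"""Detect a planted spatial attraction with the microenvironment statistic.

Two phenotypes, A and B, are planted as co-located pairs (parent points
with Gaussian σ = 3 μm offspring displacement); a third phenotype C fills
the rest at random. The observed percentage of A cells with a B cell
within 10 μm is compared with the frequency-product expectation and with
the permutation null (labels shuffled over fixed positions).
"""

import numpy as np
import pandas as pd

from imcmicro.microenv import analyze_microenvironment
from imcmicro.synth import Interaction, simulate_pattern

inter = Interaction("attract", pair=("A", "B"), sigma=3.0, n_parents=220)
pattern = simulate_pattern(
    2000, {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, field=(500, 500),
    interaction=inter, seed=7,
)
cells = pd.DataFrame(
    {"cell_id": np.arange(pattern.n) + 1,
     "x": pattern.points[:, 0], "y": pattern.points[:, 1]}
)
result = analyze_microenvironment(
    cells, pd.Series(pattern.labels), radius=10, mode="centroid",
    n_perm=1000, seed=8,
)
print(result.round(3).to_string(index=False))
planted = result[(result.cluster_a == "A") & (result.cluster_b == "B")].iloc[0]
print(
    f"\nplanted pair A→B: observed {planted.observed:.3f}, expected "
    f"{planted.expected:.3f}, corrected {planted.corrected:+.3f}, z = {planted.z:.1f}"
)
print("corrected > 0 and |z| ≥ 1.96 ⇒ attraction detected beyond random mixing")
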