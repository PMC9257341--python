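# imcmicro

Single-cell quantification and spatial microenvironment statistics for
imaging mass cytometry (IMC) of tissue sections, built around the analysis
style used for human decidua: segmentation-mask cell quantification on
binarized marker channels, hierarchical phenotype gating, and a
radius-based co-localization statistic with a permutation null.

IMC produces one image channel per metal-tagged antibody at ~1 μm
resolution (1 px = 1 μm²). `imcmicro` takes such multichannel stacks —
or generates synthetic ones with known ground truth — and answers two
questions: *what phenotypes are present, and at what frequencies?* and
*which phenotypes sit next to each other more (or less) often than random
mixing would produce?*

## The method

**Quantification.** Nuclei are segmented as connected components of the
thresholded DNA channel and every label is expanded by 2 px so membrane
signal is captured. Marker channels are binarized, and each cell's
expression of marker *m* is its positive-pixel fraction
`f = (positive pixels of m in cell) / (cell area)` — a cell with half its
pixels positive scores 0.5. Cells are then gated top-down through a rule
hierarchy (background → trophoblast → stromal → CD45⁺ lineages → myeloid /
NK / T / granulocyte subclusters) with a positivity cutoff on the
fraction (default 0.25); clusters with ≤ 100 cells merge into their
parents.

**Microenvironment statistic.** For ordered phenotype pair (A, B) in a
sample (all ROIs pooled, radius r = 10 px):

- observed(A,B) = fraction of A cells with ≥ 1 B cell within r;
- expected(A,B) = f_A · f_B, the product of the clusters' frequencies over
  the immune + trophoblast denominator;
- corrected(A,B) = observed − expected;
- permutation z: labels are shuffled within each ROI over fixed positions,
  observed(A,B) is recomputed per shuffle, and
  z = (observed − mean_perm)/sd_perm, with |z| ≥ 1.96 (two-sided p < 0.05)
  flagged significant.

Group-level analyses use Mann-Whitney (Bonferroni over the declared
family), Kruskal-Wallis + Dunn, or Friedman + Dunn, and row z-score
clustered heatmaps of the corrected percentages.

## Worked example

```python
import numpy as np, pandas as pd
from imcmicro.synth import Interaction, simulate_pattern
from imcmicro.microenv import analyze_microenvironment

inter = Interaction("attract", pair=("A", "B"), sigma=3.0, n_parents=220)
pat = simulate_pattern(2000, {"A": 1/3, "B": 1/3, "C": 1/3},
                       field=(500, 500), interaction=inter, seed=7)
cells = pd.DataFrame({"cell_id": np.arange(pat.n) + 1,
                      "x": pat.points[:, 0], "y": pat.points[:, 1]})
res = analyze_microenvironment(cells, pd.Series(pat.labels),
                               radius=10, mode="centroid", n_perm=1000, seed=8)
print(res[(res.cluster_a == "A") & (res.cluster_b == "B")].iloc[0])
```

prints, for the planted pair,

```
observed 0.724, expected 0.134, corrected +0.590, z = 5.1
```

meaning 72.4% of A cells have a B cell within 10 μm against a 13.4%
frequency-product expectation, and the excess is far outside the
permutation null (z = 5.1 ≥ 1.96): the planted attraction is detected.
The `examples/` directory holds one short script per capability
(simulation, segmentation + quantification, gating, microenvironment,
statistics/heatmaps); each prints the numbers it computes and what they
mean. A thin CLI mirrors the stages:
`imcmicro synth|segment|quantify|phenotype|microenv|heatmap`.

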