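# Methods

## Data model

One ROI is a set of co-registered 2-D channels at 1 px = 1 μm²: a DNA
(nuclear) channel plus one channel per marker. After binarization every
channel is {0, 1}; all per-cell "expression" values are positive-pixel
fractions in [0, 1], never intensities. A sample comprises several ROIs;
frequency and microenvironment analyses pool ROIs per sample, while
neighbor relations never cross ROI boundaries.

## Segmentation

Primary objects are connected components (8-connectivity) of the
thresholded DNA channel; components under `min_area` px (default 10) are
discarded as debris. The threshold is either user-fixed or derived by
Otsu's criterion; there is deliberately no interactive, trained pixel
classifier in the loop, so a given image always yields the same mask.
Labels are then expanded by a Euclidean distance of 2 px (2 μm) to admit
membrane signal: each background pixel within the distance of a labeled
pixel is claimed by its *nearest* labeled pixel, ties broken toward the
lower label id. The implementation sweeps integer offset rings in order of
increasing squared distance, which makes the rule exact (it is tested
against a per-pixel brute-force oracle) and guarantees that labels can
abut but never merge and that original pixels never change. Touching
nuclei are not split (no watershed): on dense tissue this merges contacts,
a documented limitation; the synthetic defaults keep nuclei disjoint so
recovery statements are exact.

## Quantification

For cell *k* and marker *m*: `fraction = positive px of m inside k / area(k)`.
Fractions are computed on the *expanded* mask — the point of the 2-px
expansion is precisely that membrane markers be counted. The identity
`Σ_cells fraction × area = total positive pixels under the mask` holds
exactly and is asserted in the tests. Tables export as CSV or FCS 3.0
(float32 list mode; a purpose-written minimal codec, since no installed
library writes FCS) with one event per cell.

## Gating

Cells route top-down through a rule tree; a rule matches when all
`all_of` markers are positive (fraction ≥ threshold, default 0.25, the
comparison inclusive), at least one `any_of` marker is positive, and no
`none_of` marker is. First matching sibling wins; non-matching cells take
the level's fallback label. The default tree: background (no marker) →
trophoblast (keratin/HLA-G) → stromal (vimentin/αSMA, CD45⁻) → CD45⁺
lineages (myeloid by CD14/CD68/CD163; NK by CD56/CD7 without myeloid
markers; T by CD3 with CD4/CD8 split; granulocyte by CD66b/CD15), and
myeloid subclusters on HLA-DR × DC-SIGN plus CD14⁺CD56⁺ and
CD14⁻CD204⁺HLA-DR⁺CD11c⁺ phenotypes. The mapping of the HLA-DR⁻DC-SIGN⁺ /
⁻⁻ / ⁺⁺ / ⁺⁻ quadrants to the dMØ1/4/2/5 names is a configurable label
map: the quadrant definitions are robust, the numbering is convention.
The positivity threshold of 0.25 was fixed a priori from the geometry of
the synthetic cells (a fully positive nucleus footprint dilutes to ≈ 0.43
of the expanded area, while per-channel false-positive noise stays near
the noise rate), leaving a wide margin on both sides; it is exposed as a
parameter for real panels.

Clusters holding ≤ 100 cells (pooled over samples) are not considered
reliably defined: they merge into their parent node, deepest labels
first so sibling fragments can accumulate into a surviving parent, and the
process repeats until stable. `background` and `unknown` are terminal
sinks and never merge further.

## Microenvironment statistic

Within a sample, for ordered pair (A, B): `observed` is the fraction of A
cells having at least one B neighbor; `expected = f_A × f_B` with
frequencies over the declared denominator (immune + trophoblast by
default); `corrected = observed − expected`. The frequency product is kept
exactly in this form deliberately — it is the field's established
correction — even though it is *not* the null expectation of
P(A has ≥ 1 B neighbor); consequently `corrected` need not vanish under
random labels, and the calibrated inference tool is the permutation test,
not the sign of `corrected`. The test suite asserts calibration of the
permutation z, and only power statements use `corrected > 0`.

Neighbors default to *boundary* mode — an edge when the minimum distance
between two cells' mask pixels is ≤ r (attained on boundary pixels, which
is what the implementation searches) — because the statistic targets
touching/adjacent cells; *centroid* mode serves mask-free tables. The
radius comparison is inclusive (≤ 10 px), matching "within a 10-pixel
radius". Graphs carry no self-loops and are symmetric.

Permutations shuffle labels uniformly within each ROI (preserving per-ROI
composition and density) over the fixed geometry; observed percentages are
recomputed per permutation with counts pooled per sample. z uses the
sample standard deviation of the permuted observeds; a degenerate null
(sd = 0, e.g. an empty graph) yields z = 0, a conservative convention.
Default `n_perm` = 1000; every stochastic entry point takes an explicit
seed and is bitwise reproducible under it. The adjacency × one-hot-label
formulation makes one permutation two small sparse-dense products, so
thousands of permutations on thousands of cells run in milliseconds.

## Group statistics and heatmaps

Row z-scores standardize each interaction row across samples with the
n−1 denominator; missing entries are excluded from the moments and
propagated; constant rows map to zeros (flagged by construction rather
than NaN). Two-group comparisons use Mann-Whitney U (exact for ≤ 8 per
group without ties, else the tie-corrected normal approximation) with
Bonferroni over the declared family; k independent groups use
Kruskal-Wallis with Dunn's rank-sum post-hoc (pooled-rank variance with
tie correction); repeated measures over complete blocks use Friedman with
the within-block-rank Dunn statistic. The Dunn post-hoc family is
Holm-adjusted by default (configurable), a choice made where the
convention is genuinely open. Heatmaps cluster rows/columns by average
linkage on Euclidean distance of row z-scores with a diverging blue-red
palette centered at 0.

## Synthetic data

The generator emulates what matters to the pipeline: nucleated cells as
radius-4 px disks (49 px) in 500×500 px (0.25 mm², the small end of
realistic ROI areas) fields, binarized channels where a cluster's positive
markers cover exactly its cell footprint, per-channel independent
false-positive/false-negative pixel noise, controlled cluster frequencies,
and planted pairwise structure: CSR (uniform positions, multinomial
labels), attraction (two-type Thomas-style parent/offspring pairs with
Gaussian σ displacement; remaining cells CSR), and hard-core repulsion
between a designated pair. An optional global `min_spacing` (11 px keeps
radius-4 nuclei disjoint under 8-connectivity) supports exact
segmentation-recovery statements. Ground truth — label mask by
nearest-center assignment within the disk union (ties to the lower id),
true cluster per cell — accompanies every rasterization. Coordinates are
continuous μm floored to 0-based row-major pixel indices.

Not emulated: spillover/isotope crosstalk, autofluorescence, intensity
gradients, irregular cell shapes, nucleus overlap in the default
configurations, and tissue architecture (vessel walls, fibrinoid). Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under the stated noise model, not robustness to real staining
artefacts; on real data the binarization and gating thresholds carry the
burden the simulation sidesteps.

Default experiment sizes — 2000 cells per replicate, 200 replicates at 500
permutations for null calibration, 100 replicates for power, 220 planted
pairs at σ = 3 μm — were chosen as the package's standard validation
conditions: large enough that the binomial error on a 5% rate over ~1800
tests is ±0.5%, and that per-replicate graphs remain millisecond-scale.

## Known limitations

- No nucleus splitting: touching nuclei merge into one cell.
- The FCS writer covers only float list-mode data (no compensation or
  analysis segments).
- `expected = f_A × f_B` is a convention, not a calibrated null (see
  above); cross-study comparability of `corrected` depends on comparable
  denominators.
- Boundary-mode neighbor detection scales with boundary pixel count; for
  very large ROIs centroid mode is markedly faster.
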