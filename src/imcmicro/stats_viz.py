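"""Row z-score heatmaps and nonparametric group comparisons.

Heatmaps standardize each row of a samples × interaction-pairs matrix of
corrected microenvironment percentages: the z-score is the number of
(sample) standard deviations a value sits above or below its row mean.
Group comparisons are rank-based throughout: Mann-Whitney U for two groups
(with Bonferroni over the declared family), Kruskal-Wallis with Dunn's
post-hoc for k independent groups, and Friedman with Dunn's post-hoc for k
repeated measures over the same blocks. Dunn statistics are computed from
rank sums with tie correction; post-hoc p-values are Holm-adjusted by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "row_zscores",
    "compare_groups",
    "clustered_heatmap",
]


@dataclass
class GroupComparison:
    """Result of one (pairwise or omnibus) hypothesis test."""

    variable: str
    groups: tuple
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str


def row_zscores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row: z = (x − row mean) / row sd (ddof=1).

    Missing values are excluded from mean/sd and propagated. Constant rows
    (sd = 0) become all zeros. Rows with fewer than 2 non-missing values
    are an error.
    """
    matrix = pd.DataFrame(matrix).astype(float)
    n_valid = matrix.notna().sum(axis=1)
    if (n_valid < 2).any():
        bad = list(matrix.index[n_valid < 2])
        raise ValueError(f"rows with fewer than 2 non-missing values: {bad}")
    mean = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    z = matrix.sub(mean, axis=0).div(sd, axis=0)
    constant = sd == 0
    if constant.any():
        z.loc[constant] = z.loc[constant].where(matrix.loc[constant].isna(), 0.0)
    return z


def _dunn_independent(values: np.ndarray, groups: np.ndarray) -> list[tuple]:
    """Dunn's pairwise z-statistics after Kruskal-Wallis (tie-corrected)."""
    ranks = sps.rankdata(values)
    n = len(values)
    uniq = list(pd.unique(groups))
    mean_rank = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int((groups == g).sum()) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a, b = uniq[i], uniq[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            out.append(((a, b), z, p))
    return out


def _dunn_repeated(block_matrix: np.ndarray, names: list) -> list[tuple]:
    """Dunn's pairwise z-statistics after Friedman (within-block ranks)."""
    n_blocks, k = block_matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, block_matrix)
    mean_rank = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_rank[i] - mean_rank[j]) / se
            p = 2 * sps.norm.sf(abs(z))
            out.append(((names[i], names[j]), z, p))
    return out


def compare_groups(
    values,
    groups,
    design: str = "k_group_independent",
    adjust: str | None = None,
    blocks=None,
    variable: str = "value",
    family_size: int | None = None,
    exact_threshold: int = 8,
) -> list[GroupComparison]:
    """Nonparametric comparison of per-sample values across groups.

    Parameters
    ----------
    design
        ``"two_group"``: Mann-Whitney U, two-sided (exact when both groups
        have at most ``exact_threshold`` observations and no ties, normal
        approximation with tie correction otherwise), Bonferroni-adjusted
        over ``family_size`` declared comparisons.
        ``"k_group_independent"``: Kruskal-Wallis omnibus plus Dunn's
        pairwise post-hoc tests.
        ``"k_group_repeated"``: Friedman omnibus over complete blocks
        (``blocks`` required) plus Dunn's pairwise post-hoc tests.
    adjust
        Adjustment for the post-hoc/pairwise family. Defaults: bonferroni
        for two_group, holm for the Dunn families.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups length mismatch")
    uniq = list(pd.unique(groups))
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    results: list[GroupComparison] = []
    if design == "two_group":
        if len(uniq) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        adjust = adjust or "bonferroni"
        a = values[groups == uniq[0]]
        b = values[groups == uniq[1]]
        no_ties = len(np.unique(values)) == len(values)
        method = (
            "exact"
            if no_ties and max(len(a), len(b)) <= exact_threshold
            else "asymptotic"
        )
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        m = family_size if family_size is not None else 1
        if adjust != "bonferroni":
            raise ValueError("two_group design supports bonferroni adjustment only")
        results.append(
            GroupComparison(
                variable,
                (uniq[0], uniq[1]),
                f"mann-whitney ({method})",
                float(res.statistic),
                float(res.pvalue),
                min(1.0, m * float(res.pvalue)),
                f"bonferroni (m={m})",
            )
        )
        return results

    if design == "k_group_independent":
        adjust = adjust or "holm"
        stat, p = sps.kruskal(*[values[groups == g] for g in uniq])
        results.append(
            GroupComparison(
                variable, tuple(uniq), "kruskal-wallis", float(stat), float(p),
                float(p), "none (omnibus)",
            )
        )
        pairs = _dunn_independent(values, groups)
    elif design == "k_group_repeated":
        if blocks is None:
            raise ValueError("repeated design requires block labels")
        adjust = adjust or "holm"
        blocks = np.asarray(blocks)
        pivot = pd.DataFrame(
            {"value": values, "group": groups, "block": blocks}
        ).pivot_table(index="block", columns="group", values="value", aggfunc="first")
        if pivot.isna().any().any():
            raise ValueError("incomplete blocks: every block needs every group")
        mat = pivot[uniq].to_numpy()
        stat, p = sps.friedmanchisquare(*[mat[:, i] for i in range(len(uniq))])
        results.append(
            GroupComparison(
                variable, tuple(uniq), "friedman", float(stat), float(p),
                float(p), "none (omnibus)",
            )
        )
        pairs = _dunn_repeated(mat, uniq)
    else:
        raise ValueError(f"unknown design {design!r}")

    raw_ps = [p for _, _, p in pairs]
    if raw_ps:
        adj_ps = multipletests(raw_ps, method=adjust)[1]
    else:
        adj_ps = []
    for ((a, b), z, p), p_adj in zip(pairs, adj_ps):
        results.append(
            GroupComparison(
                variable, (a, b), "dunn", float(z), float(p), float(p_adj), adjust
            )
        )
    return results


def clustered_heatmap(
    matrix: pd.DataFrame,
    out: str | None = None,
    zscore_rows: bool = True,
    **kwargs,
):
    """Hierarchically clustered heatmap of (row z-scored) corrected values.

    Average linkage on Euclidean distance of the row z-scores, diverging
    blue–red palette centered at 0. Returns the seaborn ClusterGrid; writes
    PNG/SVG when ``out`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns

    data = row_zscores(matrix) if zscore_rows else pd.DataFrame(matrix)
    grid = sns.clustermap(
        data.fillna(0.0),
        method="average",
        metric="euclidean",
        cmap="RdBu_r",
        center=0,
        **kwargs,
    )
    if out:
        grid.savefig(out)
    return grid
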