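"""Radius-based microenvironment (co-localization) statistics.

For every ordered phenotype pair (A, B) within a sample, the observed
microenvironment percentage is the fraction of A cells that have at least
one B cell within the proximity radius (10 px = 10 μm by default). The
expected percentage under random co-localization is taken as the product of
the two clusters' frequencies f_A × f_B over a stated denominator
(immune + trophoblast cells in the decidual analysis), and the corrected
percentage is observed − expected. Because the frequency product is not the
exact null expectation of "A has ≥1 B neighbor", a permutation test over
phenotype labels — positions held fixed, labels shuffled within each ROI —
provides the calibrated significance measure: the permutation z-score, with
|z| ≥ 1.96 (two-sided p < 0.05) as cutoff. Analyses pool all ROIs of a
sample; neighbor edges never cross ROI boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "microenvironment_matrix",
    "permutation_z",
    "analyze_microenvironment",
    "Z_CUTOFF",
]

#: Two-sided standard-normal cutoff at p < 0.05.
Z_CUTOFF = 1.96


@dataclass
class NeighborGraph:
    """Geometry-only proximity graph over cells of one or more ROIs.

    ``cells`` must carry cell_id, roi_id, sample_id, x, y; ``edges`` holds
    positional index pairs (i < j), only within the same ROI. Adjacency is
    symmetric with no self-loops and depends only on positions, never on
    phenotype labels.
    """

    cells: pd.DataFrame
    edges: np.ndarray  # (m, 2) int
    radius: float
    mode: str

    @property
    def n(self) -> int:
        return len(self.cells)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean adjacency as CSR."""
        n = self.n
        if len(self.edges) == 0:
            return sparse.csr_matrix((n, n), dtype=np.int8)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i), dtype=np.int8)
        return sparse.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )


def _boundary_pixels(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(coords, labels) of mask pixels with a 4-neighbor of different value."""
    m = mask
    edge = np.zeros(m.shape, dtype=bool)
    edge[:-1, :] |= m[:-1, :] != m[1:, :]
    edge[1:, :] |= m[1:, :] != m[:-1, :]
    edge[:, :-1] |= m[:, :-1] != m[:, 1:]
    edge[:, 1:] |= m[:, 1:] != m[:, :-1]
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    edge &= m > 0
    ys, xs = np.nonzero(edge)
    return np.column_stack([xs, ys]).astype(float), m[ys, xs]


def build_neighbor_graph(
    cells: pd.DataFrame,
    radius: float = 10.0,
    mode: str = "boundary",
    masks: dict | np.ndarray | None = None,
) -> NeighborGraph:
    """Build the proximity graph for a cell table.

    Parameters
    ----------
    cells
        Cell table with cell_id, roi_id, x, y (sample_id optional,
        defaulted). Coordinates in μm (= px).
    radius
        Proximity radius; the comparison is inclusive (distance ≤ radius).
    mode
        ``"boundary"``: two cells are neighbors when the minimum distance
        between their mask pixels is within the radius — the default, since
        the statistic targets touching/adjacent cells. Requires ``masks``.
        ``"centroid"``: Euclidean centroid distance, for mask-free tables.
    masks
        Label mask per ROI (dict roi_id → 2-D array, or a single array when
        there is one ROI); required for boundary mode.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("centroid", "boundary"):
        raise ValueError(f"unknown neighbor mode {mode!r}")
    cells = cells.reset_index(drop=True)
    if "sample_id" not in cells:
        cells = cells.assign(sample_id="sample0")
    if "roi_id" not in cells:
        cells = cells.assign(roi_id="roi0")
    if mode == "centroid" and cells[["x", "y"]].isna().any().any():
        raise ValueError("cells with missing coordinates")

    edge_parts: list[np.ndarray] = []
    for roi, sub in cells.groupby("roi_id", sort=False):
        idx = sub.index.to_numpy()
        if mode == "centroid":
            tree = cKDTree(sub[["x", "y"]].to_numpy())
            pairs = tree.query_pairs(radius, output_type="ndarray")
            if len(pairs):
                edge_parts.append(idx[pairs])
        else:
            if masks is None:
                raise ValueError("boundary mode requires label masks")
            mask = masks[roi] if isinstance(masks, dict) else masks
            coords, px_labels = _boundary_pixels(np.asarray(mask))
            tree = cKDTree(coords)
            pairs = tree.query_pairs(radius, output_type="ndarray")
            if len(pairs) == 0:
                continue
            la = px_labels[pairs[:, 0]]
            lb = px_labels[pairs[:, 1]]
            keep = la != lb
            lab_pairs = np.sort(
                np.column_stack([la[keep], lb[keep]]), axis=1
            )
            lab_pairs = np.unique(lab_pairs, axis=0)
            # map mask labels back to table rows
            row_of = dict(zip(sub["cell_id"].to_numpy(), idx))
            rows = np.array(
                [
                    (row_of[a], row_of[b])
                    for a, b in lab_pairs
                    if a in row_of and b in row_of
                ],
                dtype=int,
            ).reshape(-1, 2)
            if len(rows):
                edge_parts.append(np.sort(rows, axis=1))
    edges = (
        np.vstack(edge_parts) if edge_parts else np.empty((0, 2), dtype=int)
    )
    return NeighborGraph(cells=cells, edges=edges, radius=radius, mode=mode)


def _one_hot(labels_idx: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((len(labels_idx), k), dtype=np.int32)
    L[np.arange(len(labels_idx)), labels_idx] = 1
    return L


def _observed_matrix(
    adj: sparse.csr_matrix, labels_idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """(numerator, counts): numerator[a, b] = #A cells with ≥1 B neighbor."""
    L = _one_hot(labels_idx, k)
    M = (adj @ L) > 0  # M[i, b]: cell i has a B neighbor
    numer = L.T @ M.astype(np.int64)
    counts = L.sum(axis=0)
    return numer, counts


def _cluster_index(labels: pd.Series, clusters: list[str] | None):
    if clusters is None:
        clusters = sorted(labels.unique())
    lut = {c: i for i, c in enumerate(clusters)}
    missing = set(labels.unique()) - set(clusters)
    if missing:
        raise ValueError(f"labels outside cluster list: {sorted(missing)}")
    return clusters, labels.map(lut).to_numpy()


def microenvironment_matrix(
    graph: NeighborGraph,
    labels: pd.Series,
    denominator_freqs: pd.DataFrame | None = None,
    clusters: list[str] | None = None,
) -> pd.DataFrame:
    """Observed / expected / corrected percentages per sample and pair.

    ``labels`` is positionally aligned with ``graph.cells``. Expected
    percentages need per-sample cluster frequencies over the analysis
    denominator; pass them as ``denominator_freqs`` (clusters × samples,
    e.g. from :func:`imcmicro.phenotype.compute_frequencies`). When omitted,
    frequencies are computed over all graphed cells. Pairs whose A cluster
    has no cells in a sample get NaN observed (flagged by NaN, not zero).

    Returns a long-format frame: sample_id, cluster_a, cluster_b, observed,
    expected, corrected.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    if len(labels) != graph.n:
        raise ValueError("labels length must match graph cell count")
    clusters, labels_idx = _cluster_index(labels, clusters)
    k = len(clusters)
    adj = graph.adjacency()
    rows = []
    for s, sub in graph.cells.groupby("sample_id", sort=False):
        idx = sub.index.to_numpy()
        numer, counts = _observed_matrix(
            adj[idx][:, idx], labels_idx[idx], k
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            observed = numer / counts[:, None]
        if denominator_freqs is not None:
            f = np.array(
                [
                    denominator_freqs.loc[c, s] if c in denominator_freqs.index else np.nan
                    for c in clusters
                ]
            )
        else:
            f = counts / counts.sum()
        expected = np.outer(f, f)
        for a in range(k):
            for b in range(k):
                obs = observed[a, b] if counts[a] > 0 else np.nan
                rows.append(
                    {
                        "sample_id": s,
                        "cluster_a": clusters[a],
                        "cluster_b": clusters[b],
                        "observed": obs,
                        "expected": expected[a, b],
                        "corrected": obs - expected[a, b],
                    }
                )
    return pd.DataFrame(rows)


def permutation_z(
    graph: NeighborGraph,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    clusters: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation z-scores of the observed microenvironment percentages.

    Cell positions (the graph) are fixed; phenotype labels are shuffled
    uniformly at random within each ROI, preserving each ROI's label
    composition. Observed percentages are recomputed per permutation and
    pooled per sample; z = (observed − mean_perm) / sd_perm (sample sd).
    Degenerate nulls (sd = 0) give z = 0, a deliberately conservative
    convention. Deterministic under ``seed``.

    Returns a long frame: sample_id, cluster_a, cluster_b, z, significant
    (|z| ≥ 1.96), n_perm, seed.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    labels = pd.Series(np.asarray(labels, dtype=object))
    if len(labels) != graph.n:
        raise ValueError("labels length must match graph cell count")
    clusters, labels_idx = _cluster_index(labels, clusters)
    k = len(clusters)
    adj = graph.adjacency()
    rng = np.random.default_rng(seed)
    rows = []
    for s, sub in graph.cells.groupby("sample_id", sort=False):
        idx = sub.index.to_numpy()
        adj_s = adj[idx][:, idx].tocsr()
        lab_s = labels_idx[idx]
        roi_groups = [
            np.flatnonzero((sub["roi_id"] == roi).to_numpy())
            for roi in pd.unique(sub["roi_id"])
        ]
        numer_real, counts = _observed_matrix(adj_s, lab_s, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs_real = numer_real / counts[:, None]
        perm_obs = np.empty((n_perm, k, k))
        lab_perm = lab_s.copy()
        for p in range(n_perm):
            for g in roi_groups:
                lab_perm[g] = lab_s[g][rng.permutation(len(g))]
            numer_p, _ = _observed_matrix(adj_s, lab_perm, k)
            with np.errstate(invalid="ignore", divide="ignore"):
                perm_obs[p] = numer_p / counts[:, None]
        mean_p = perm_obs.mean(axis=0)
        sd_p = perm_obs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (obs_real - mean_p) / sd_p
        z = np.where(sd_p == 0, 0.0, z)
        for a in range(k):
            for b in range(k):
                zz = z[a, b] if counts[a] > 0 else np.nan
                rows.append(
                    {
                        "sample_id": s,
                        "cluster_a": clusters[a],
                        "cluster_b": clusters[b],
                        "z": zz,
                        "significant": bool(abs(zz) >= Z_CUTOFF)
                        if np.isfinite(zz)
                        else False,
                        "n_perm": n_perm,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def analyze_microenvironment(
    cells: pd.DataFrame,
    labels: pd.Series,
    radius: float = 10.0,
    mode: str = "centroid",
    masks=None,
    denominator_freqs: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    clusters: list[str] | None = None,
) -> pd.DataFrame:
    """One-call pipeline: graph → observed/expected/corrected → z-scores."""
    graph = build_neighbor_graph(cells, radius=radius, mode=mode, masks=masks)
    mat = microenvironment_matrix(
        graph, labels, denominator_freqs=denominator_freqs, clusters=clusters
    )
    zs = permutation_z(graph, labels, n_perm=n_perm, seed=seed, clusters=clusters)
    return mat.merge(zs, on=["sample_id", "cluster_a", "cluster_b"])
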