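"""Synthetic multiplexed-imaging data with known ground truth.

Generates marked point patterns — cell centers with phenotype labels — under
controlled cluster frequencies and pairwise spatial structure, and
rasterizes them into IMC-like binary image stacks (1 px = 1 μm²): a DNA
channel positive on nucleus disks, and one channel per marker positive on
the footprints of cells whose phenotype carries that marker, optionally
corrupted by per-channel pixel noise. Every stage returns ground truth
(label mask, true cluster per cell), so segmentation, quantification,
gating and spatial statistics can all be validated end to end.

Spatial structure modes
-----------------------
``csr``
    Complete spatial randomness: uniform independent positions, independent
    multinomial labels. The calibration regime for the permutation test.
``attract``
    A two-type Thomas-style construction: Poisson parents each spawn one
    cell of each member of a designated pair, displaced by isotropic
    Gaussian(σ); remaining cells are CSR. Produces tunable pairwise
    enrichment at short range.
``repel``
    Sequential hard-core rejection between the designated pair: no member
    of one type is placed within the hard-core radius of the other type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import quantify_cells
from .stacks import ImageStack, write_label_mask, write_stack

__all__ = [
    "Interaction",
    "PointPattern",
    "PanelSpec",
    "simulate_pattern",
    "rasterize_pattern",
    "run_config",
]


@dataclass(frozen=True)
class Interaction:
    """Planted pairwise spatial structure.

    mode ``csr`` ignores the other fields. ``attract`` needs ``pair`` and
    ``sigma`` (μm) plus either ``n_parents`` or ``parent_intensity``
    (parents per μm²). ``repel`` needs ``pair`` and ``hardcore_radius`` (μm).
    """

    mode: str = "csr"
    pair: tuple[str, str] | None = None
    sigma: float | None = None
    n_parents: int | None = None
    parent_intensity: float | None = None
    hardcore_radius: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("csr", "attract", "repel"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.mode != "csr" and (self.pair is None or len(self.pair) != 2):
            raise ValueError(f"mode {self.mode!r} requires a cluster pair")
        if self.mode == "attract":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("attract mode requires sigma > 0")
            if self.n_parents is None and self.parent_intensity is None:
                raise ValueError("attract mode requires n_parents or parent_intensity")
        if self.mode == "repel" and (
            self.hardcore_radius is None or self.hardcore_radius <= 0
        ):
            raise ValueError("repel mode requires hardcore_radius > 0")


CSR = Interaction("csr")


@dataclass
class PointPattern:
    """Marked point pattern for one synthetic ROI."""

    points: np.ndarray  # (n, 2) float, columns x, y in μm
    labels: np.ndarray  # (n,) cluster name per point
    field: tuple[int, int]  # (width_px, height_px)
    seed: int
    interaction: Interaction = CSR

    @property
    def n(self) -> int:
        return len(self.points)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        w, h = self.field
        if self.n and (
            (self.points[:, 0] < 0).any()
            or (self.points[:, 1] < 0).any()
            or (self.points[:, 0] >= w).any()
            or (self.points[:, 1] >= h).any()
        ):
            raise ValueError("points outside field")


@dataclass
class PanelSpec:
    """Marker panel and phenotype→marker map for rasterization.

    ``clusters`` maps each cluster name to its positive marker set; markers
    not listed positive are negative for that cluster (explicit negative
    sets may be given and must be disjoint from the positives). ``noise``
    maps channel name → (false-positive rate, false-negative rate) applied
    per pixel after painting; unlisted channels are noise-free.
    """

    markers: list[str]
    clusters: dict[str, set]
    nucleus_radius: int = 4
    noise: dict[str, tuple[float, float]] = field(default_factory=dict)
    negatives: dict[str, set] | None = None
    dna_channel: str = "DNA"

    def __post_init__(self) -> None:
        self.clusters = {k: set(v) for k, v in self.clusters.items()}
        for name, pos in self.clusters.items():
            unknown = pos - set(self.markers)
            if unknown:
                raise ValueError(f"cluster {name!r} uses unknown markers {unknown}")
        if self.negatives is not None:
            for name, neg in self.negatives.items():
                if set(neg) & self.clusters.get(name, set()):
                    raise ValueError(f"cluster {name!r}: positive/negative overlap")
        for ch, (fp, fn) in self.noise.items():
            if not (0 <= fp < 1 and 0 <= fn < 1):
                raise ValueError(f"noise rates for {ch!r} must be in [0, 1)")
        if self.nucleus_radius < 1:
            raise ValueError("nucleus_radius must be >= 1")


def _uniform_in(rng, n, lo_x, hi_x, lo_y, hi_y):
    xs = rng.uniform(lo_x, hi_x, size=n)
    ys = rng.uniform(lo_y, hi_y, size=n)
    return np.column_stack([xs, ys])


def _draw_labels(rng, n: int, freqs: dict[str, float]) -> np.ndarray:
    names = list(freqs)
    probs = np.array([freqs[k] for k in names], dtype=float)
    return np.array(names, dtype=object)[rng.choice(len(names), size=n, p=probs)]


def simulate_pattern(
    n_cells: int,
    freqs: dict[str, float],
    field: tuple[int, int] = (500, 500),
    interaction: Interaction = CSR,
    seed: int = 0,
    margin: float = 8.0,
    min_spacing: float | None = None,
    max_tries: int = 200,
) -> PointPattern:
    """Simulate a marked point pattern.

    Parameters
    ----------
    n_cells
        Total number of cells (planted pairs included).
    freqs
        Cluster → probability; must sum to 1 (1e-9 tolerance). Used for the
        CSR portion of every mode.
    field
        (width, height) in px; 1 px = 1 μm.
    margin
        Minimum distance from cell centers to the field edge, so that
        nucleus disks fit when the pattern is rasterized.
    min_spacing
        Optional global hard-core distance between *all* cells (sequential
        rejection), used to generate non-overlapping nuclei.
    max_tries
        Rejection budget per point for hard-core placement.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cluster frequencies must sum to 1, got {total}")
    w, h = field
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be positive")
    if 2 * margin >= min(w, h):
        raise ValueError("margin too large for field")
    rng = np.random.default_rng(seed)
    lo_x, hi_x, lo_y, hi_y = margin, w - margin, margin, h - margin

    if n_cells == 0:
        return PointPattern(
            np.empty((0, 2)), np.empty(0, dtype=object), field, seed, interaction
        )

    points_list: list[np.ndarray] = []
    labels_list: list[np.ndarray] = []

    if interaction.mode == "attract":
        if interaction.n_parents is not None:
            n_parents = int(interaction.n_parents)
        else:
            area = (hi_x - lo_x) * (hi_y - lo_y)
            n_parents = int(rng.poisson(interaction.parent_intensity * area))
        if 2 * n_parents > n_cells:
            raise ValueError(
                f"{n_parents} parents need {2 * n_parents} cells but n_cells={n_cells}"
            )
        parents = _uniform_in(rng, n_parents, lo_x, hi_x, lo_y, hi_y)
        for member in interaction.pair:
            pts = np.empty((n_parents, 2))
            for i, parent in enumerate(parents):
                for _ in range(max_tries):
                    cand = parent + rng.normal(0.0, interaction.sigma, size=2)
                    if lo_x <= cand[0] < hi_x and lo_y <= cand[1] < hi_y:
                        pts[i] = cand
                        break
                else:
                    raise RuntimeError(
                        "could not place offspring inside field; "
                        "sigma too large for margin?"
                    )
            points_list.append(pts)
            labels_list.append(np.full(n_parents, member, dtype=object))
        n_rest = n_cells - 2 * n_parents
        points_list.append(_uniform_in(rng, n_rest, lo_x, hi_x, lo_y, hi_y))
        labels_list.append(_draw_labels(rng, n_rest, freqs))
        points = np.vstack(points_list)
        labels = np.concatenate(labels_list)

    elif interaction.mode == "repel":
        labels = _draw_labels(rng, n_cells, freqs)
        a, b = interaction.pair
        r2 = interaction.hardcore_radius**2
        points = np.empty((n_cells, 2))
        for i in range(n_cells):
            other = b if labels[i] == a else (a if labels[i] == b else None)
            for attempt in range(max_tries):
                cand = _uniform_in(rng, 1, lo_x, hi_x, lo_y, hi_y)[0]
                if other is None:
                    break
                prev = points[:i][labels[:i] == other]
                if prev.size == 0 or (((prev - cand) ** 2).sum(axis=1) > r2).all():
                    break
            else:
                raise RuntimeError(
                    f"hard-core placement failed for point {i} after "
                    f"{max_tries} tries (radius {interaction.hardcore_radius} μm "
                    f"infeasible at this density)"
                )
            points[i] = cand

    else:  # csr
        points = _uniform_in(rng, n_cells, lo_x, hi_x, lo_y, hi_y)
        labels = _draw_labels(rng, n_cells, freqs)

    if min_spacing is not None:
        points = _enforce_spacing(
            rng, points, (lo_x, hi_x, lo_y, hi_y), min_spacing, max_tries
        )

    return PointPattern(points, labels, field, seed, interaction)


def _enforce_spacing(rng, points, bounds, min_spacing, max_tries):
    """Sequentially re-draw positions so all pairwise distances exceed
    ``min_spacing`` (labels and planted displacements are kept for points
    that already satisfy the constraint)."""
    lo_x, hi_x, lo_y, hi_y = bounds
    s2 = min_spacing**2
    out = np.empty_like(points)
    for i, cand in enumerate(points):
        for attempt in range(max_tries):
            if i == 0 or (((out[:i] - cand) ** 2).sum(axis=1) > s2).all():
                break
            cand = _uniform_in(rng, 1, lo_x, hi_x, lo_y, hi_y)[0]
        else:
            raise RuntimeError(
                f"min_spacing={min_spacing} infeasible after {max_tries} tries "
                f"at point {i} (density too high)"
            )
        out[i] = cand
    return out


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dx * dx + dy * dy <= r * r
    return np.column_stack([dy[keep], dx[keep]])


def rasterize_pattern(
    pattern: PointPattern,
    panel: PanelSpec,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray, pd.DataFrame]:
    """Render a point pattern as binary channels plus ground truth.

    Returns ``(stack, label_mask, cell_table)``: the stack holds the DNA
    channel and one binary channel per panel marker (noise applied); the
    label mask assigns each nucleus-disk pixel to the nearest cell center
    (ties → lower cell id); the cell table is quantified on the ground-truth
    mask against the (noisy) channels and carries a ``true_cluster`` column.
    """
    missing = set(pattern.labels) - set(panel.clusters)
    if missing:
        raise ValueError(f"panel missing clusters {sorted(missing)}")
    w, h = pattern.field
    r = panel.nucleus_radius
    centers_px = np.floor(pattern.points).astype(int)
    if pattern.n:
        if (
            (centers_px[:, 0] - r < 0).any()
            or (centers_px[:, 1] - r < 0).any()
            or (centers_px[:, 0] + r >= w).any()
            or (centers_px[:, 1] + r >= h).any()
        ):
            raise ValueError("nucleus disks do not fit in field; increase margin")

    mask = np.zeros((h, w), dtype=np.int32)
    best_d2 = np.full((h, w), np.inf)
    offsets = _disk_offsets(r)
    for cid in range(pattern.n):
        cx, cy = centers_px[cid]
        ys = cy + offsets[:, 0]
        xs = cx + offsets[:, 1]
        d2 = (xs - pattern.points[cid, 0]) ** 2 + (ys - pattern.points[cid, 1]) ** 2
        better = d2 < best_d2[ys, xs]  # strict: ties keep the earlier (lower) id
        mask[ys[better], xs[better]] = cid + 1
        best_d2[ys[better], xs[better]] = d2[better]

    channels: dict[str, np.ndarray] = {panel.dna_channel: (mask > 0).astype(np.uint8)}
    for m in panel.markers:
        lut = np.zeros(pattern.n + 1, dtype=np.uint8)
        for cid in range(pattern.n):
            if m in panel.clusters[pattern.labels[cid]]:
                lut[cid + 1] = 1
        channels[m] = lut[mask]

    rng = np.random.default_rng(seed)
    for name in channels:
        fp, fn = panel.noise.get(name, (0.0, 0.0))
        if fp == 0 and fn == 0:
            continue
        img = channels[name]
        u = rng.random(img.shape)
        flip_on = (img == 0) & (u < fp)
        flip_off = (img == 1) & (u < fn)
        img = img.copy()
        img[flip_on] = 1
        img[flip_off] = 0
        channels[name] = img

    stack = ImageStack(channels)
    marker_stack = ImageStack({m: channels[m] for m in panel.markers})
    table = quantify_cells(mask, marker_stack)
    table["true_cluster"] = [pattern.labels[int(c) - 1] for c in table["cell_id"]]
    return stack, mask, table


def run_config(config_path: str | Path, out_dir: str | Path) -> None:
    """Generate one synthetic ROI from a YAML config and write it to disk.

    Config keys: ``panel`` (markers, clusters, nucleus_radius, noise),
    ``clusters`` (name → frequency), ``field``, ``n_cells``,
    ``interaction`` (mode + parameters) and ``seed``.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    seed = int(cfg.get("seed", 0))
    freqs = {k: float(v) for k, v in cfg["clusters"].items()}
    inter_cfg = cfg.get("interaction", {"mode": "csr"})
    pair = inter_cfg.get("pair")
    interaction = Interaction(
        mode=inter_cfg.get("mode", "csr"),
        pair=tuple(pair) if pair else None,
        sigma=inter_cfg.get("sigma"),
        n_parents=inter_cfg.get("n_parents"),
        parent_intensity=inter_cfg.get("parent_intensity"),
        hardcore_radius=inter_cfg.get("hardcore_radius"),
    )
    panel_cfg = cfg["panel"]
    panel = PanelSpec(
        markers=list(panel_cfg["markers"]),
        clusters={k: set(v) for k, v in panel_cfg["positive"].items()},
        nucleus_radius=int(panel_cfg.get("nucleus_radius", 4)),
        noise={k: tuple(v) for k, v in panel_cfg.get("noise", {}).items()},
    )
    pattern = simulate_pattern(
        n_cells=int(cfg.get("n_cells", 1000)),
        freqs=freqs,
        field=tuple(cfg.get("field", (500, 500))),
        interaction=interaction,
        seed=seed,
        min_spacing=cfg.get("min_spacing"),
    )
    stack, mask, table = rasterize_pattern(pattern, panel, seed=seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out / "stack.tiff")
    write_label_mask(mask, out / "mask.tiff")
    table.to_csv(out / "cells.csv", index=False)
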