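"""Hierarchical phenotype gating on binarized marker fractions.

Cells are assigned top-down through a tree of rules. A rule matches when
all of its ``all_of`` markers are positive, at least one ``any_of`` marker
is positive, and no ``none_of`` marker is positive, where "positive" means
the cell's positive-pixel fraction for that marker reaches the positivity
threshold (default 0.25). At each level the first matching sibling wins;
cells matching none fall to the level's fallback label. The default
hierarchy mirrors the decidual compartment structure: cells with no marker
signal are background; keratin/HLA-G cells are (extravillous) trophoblasts;
vimentin/αSMA cells without CD45 are maternal stromal cells; CD45⁺ cells
split into myeloid (CD14/CD68/CD163), NK (CD56/CD7 without myeloid
markers), T (CD3, further split on CD4/CD8) and granulocyte (CD66b/CD15)
lineages; the myeloid lineage splits into decidual-macrophage subclusters
on HLA-DR × DC-SIGN plus the CD14⁺CD56⁺ (dMØ3) and CD14⁻CD204⁺HLA-DR⁺CD11c⁺
(monocyte-derived DC-like) phenotypes.

A cluster is only considered reliably defined when it holds more than a
minimum number of cells (default 100, pooled across samples); smaller
leaves are merged into their parent by :func:`enforce_min_cluster_size`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import marker_columns

__all__ = [
    "GatingRule",
    "GatingConfig",
    "PhenotypeAssignment",
    "default_gating_config",
    "gate_cells",
    "enforce_min_cluster_size",
    "compute_frequencies",
    "immune_trophoblast_ratio",
    "ratio_from_counts",
]


@dataclass
class GatingRule:
    """One node of the gating tree.

    ``none_of`` may be the string ``"*"``, meaning every marker referenced
    anywhere in the configuration (used by the background gate).
    """

    name: str
    all_of: list[str] = field(default_factory=list)
    any_of: list[str] = field(default_factory=list)
    none_of: list[str] | str = field(default_factory=list)
    children: list["GatingRule"] = field(default_factory=list)
    fallback: str | None = None  # label for cells matching this node but no child

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if self.all_of:
            d["all_of"] = list(self.all_of)
        if self.any_of:
            d["any_of"] = list(self.any_of)
        if self.none_of:
            d["none_of"] = self.none_of if self.none_of == "*" else list(self.none_of)
        if self.fallback:
            d["fallback"] = self.fallback
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GatingRule":
        return cls(
            name=d["name"],
            all_of=list(d.get("all_of", [])),
            any_of=list(d.get("any_of", [])),
            none_of=d.get("none_of", []),
            fallback=d.get("fallback"),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )


@dataclass
class GatingConfig:
    """A gating tree plus the positivity threshold on marker fractions."""

    root: GatingRule
    threshold: float = 0.25

    def __post_init__(self) -> None:
        seen: set[str] = set()

        def _walk(rule: GatingRule) -> None:
            if rule.name in seen:
                raise ValueError(f"duplicate rule name {rule.name!r}")
            seen.add(rule.name)
            for c in rule.children:
                _walk(c)

        _walk(self.root)

    def markers(self) -> list[str]:
        """All marker names referenced by any rule (excluding '*')."""
        out: list[str] = []

        def _walk(rule: GatingRule) -> None:
            for m in list(rule.all_of) + list(rule.any_of):
                if m not in out:
                    out.append(m)
            if rule.none_of != "*":
                for m in rule.none_of:
                    if m not in out:
                        out.append(m)
            for c in rule.children:
                _walk(c)

        _walk(self.root)
        return out

    def parent_map(self) -> dict[str, str | None]:
        """Map every node name (and fallback label) to its parent node name."""
        parents: dict[str, str | None] = {self.root.name: None}

        def _walk(rule: GatingRule) -> None:
            if rule.fallback and rule.fallback not in parents:
                parents[rule.fallback] = rule.name if rule.fallback != rule.name else (
                    parents.get(rule.name)
                )
            for c in rule.children:
                parents[c.name] = rule.name
                _walk(c)

        _walk(self.root)
        return parents

    def ancestors(self, label: str) -> list[str]:
        """Ancestor chain of a label, nearest first, label itself included."""
        parents = self.parent_map()
        chain = [label]
        cur = label
        while parents.get(cur) is not None:
            cur = parents[cur]
            chain.append(cur)
        return chain

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"threshold": self.threshold, "hierarchy": self.root.to_dict()},
                sort_keys=False,
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            root=GatingRule.from_dict(d["hierarchy"]),
            threshold=float(d.get("threshold", 0.25)),
        )


def _prune(rule: GatingRule, available: set[str]) -> GatingRule | None:
    """Drop rules whose required markers are absent; filter optional lists."""
    all_of = list(rule.all_of)
    if any(m not in available for m in all_of):
        return None
    any_of = [m for m in rule.any_of if m in available]
    if rule.any_of and not any_of:
        return None
    none_of = rule.none_of if rule.none_of == "*" else [
        m for m in rule.none_of if m in available
    ]
    children = [c for c in (_prune(c, available) for c in rule.children) if c]
    return GatingRule(rule.name, all_of, any_of, none_of, children, rule.fallback)


def default_gating_config(
    markers: list[str] | None = None,
    threshold: float = 0.25,
    include_nk_subclusters: bool = False,
) -> GatingConfig:
    """The decidual gating hierarchy, pruned to the available marker panel.

    With ``markers`` given, rules that require absent markers are dropped,
    so the same hierarchy works on reduced synthetic panels.
    """
    nk_children = (
        [
            GatingRule("dNK1a", all_of=["CD69", "CD103"]),
            GatingRule("dNK1b", all_of=["CD69"], none_of=["CD103"]),
        ]
        if include_nk_subclusters
        else []
    )
    myeloid_children = [
        GatingRule("dMO3", all_of=["CD14", "CD56"]),
        GatingRule("MoDC", all_of=["CD204", "HLA-DR", "CD11c"], none_of=["CD14"]),
        GatingRule("dMO2", all_of=["HLA-DR", "DC-SIGN"]),
        GatingRule("dMO5", all_of=["HLA-DR"], none_of=["DC-SIGN"]),
        GatingRule("dMO1", all_of=["DC-SIGN"], none_of=["HLA-DR"]),
        GatingRule("dMO4", none_of=["HLA-DR", "DC-SIGN"]),
    ]
    root = GatingRule(
        "all_cells",
        fallback="unknown",
        children=[
            GatingRule("background", none_of="*"),
            GatingRule(
                "trophoblast",
                any_of=["keratin", "HLA-G"],
            ),
            GatingRule("stromal", any_of=["vimentin", "aSMA"], none_of=["CD45"]),
            GatingRule(
                "immune",
                any_of=["CD45"],
                fallback="immune_other",
                children=[
                    GatingRule(
                        "myeloid",
                        any_of=["CD14", "CD68", "CD163"],
                        fallback="myeloid",
                        children=myeloid_children,
                    ),
                    GatingRule(
                        "NK",
                        any_of=["CD56", "CD7"],
                        none_of=["CD14", "CD68", "CD163"],
                        fallback="NK",
                        children=nk_children,
                    ),
                    GatingRule(
                        "T",
                        any_of=["CD3"],
                        fallback="T",
                        children=[
                            GatingRule("T_CD4", all_of=["CD4"], none_of=["CD8a"]),
                            GatingRule("T_CD8", all_of=["CD8a"], none_of=["CD4"]),
                            GatingRule("T_DN", none_of=["CD4", "CD8a"]),
                        ],
                    ),
                    GatingRule("granulocyte", any_of=["CD66b", "CD15"]),
                ],
            ),
        ],
    )
    if markers is not None:
        pruned = _prune(root, set(markers))
        if pruned is None:  # pragma: no cover - root has no requirements
            raise ValueError("no gating rules applicable to the given markers")
        root = pruned
    return GatingConfig(root=root, threshold=threshold)


@dataclass
class PhenotypeAssignment:
    """Cell → cluster labels plus the config that produced them."""

    labels: pd.Series  # aligned with the cell table index
    sample_ids: pd.Series
    config: GatingConfig

    def counts(self) -> pd.Series:
        """Pooled cluster counts across all samples."""
        return self.labels.value_counts()

    def counts_by_sample(self) -> pd.DataFrame:
        """Clusters × samples count table."""
        return (
            pd.crosstab(self.labels, self.sample_ids)
            .rename_axis(index="cluster", columns="sample_id")
        )

    def in_group(self, names) -> pd.Series:
        """Boolean mask: label's ancestor chain intersects ``names``."""
        names = set([names] if isinstance(names, str) else names)
        member = {
            lab: bool(set(self.config.ancestors(lab)) & names)
            for lab in self.labels.unique()
        }
        return self.labels.map(member)


def gate_cells(table: pd.DataFrame, config: GatingConfig) -> PhenotypeAssignment:
    """Assign every cell to exactly one leaf of the gating hierarchy."""
    markers = set(marker_columns(table))
    missing = [m for m in config.markers() if m not in markers]
    if missing:
        raise ValueError(f"gating config references markers absent from table: {missing}")

    all_markers = config.markers()
    positive = {m: table[m].to_numpy() >= config.threshold for m in all_markers}
    n = len(table)
    labels = np.empty(n, dtype=object)

    def _match(rule: GatingRule, idx: np.ndarray) -> np.ndarray:
        m = np.ones(len(idx), dtype=bool)
        for mk in rule.all_of:
            m &= positive[mk][idx]
        if rule.any_of:
            any_m = np.zeros(len(idx), dtype=bool)
            for mk in rule.any_of:
                any_m |= positive[mk][idx]
            m &= any_m
        neg = all_markers if rule.none_of == "*" else rule.none_of
        for mk in neg:
            m &= ~positive[mk][idx]
        return m

    def _assign(rule: GatingRule, idx: np.ndarray) -> None:
        if not rule.children:
            labels[idx] = rule.name
            return
        remaining = idx
        for child in rule.children:
            if len(remaining) == 0:
                break
            hit = _match(child, remaining)
            _assign(child, remaining[hit])
            remaining = remaining[~hit]
        labels[remaining] = rule.fallback or rule.name

    _assign(config.root, np.arange(n))
    sample_ids = (
        table["sample_id"]
        if "sample_id" in table
        else pd.Series("sample0", index=table.index)
    )
    return PhenotypeAssignment(
        labels=pd.Series(labels, index=table.index, name="cluster"),
        sample_ids=sample_ids,
        config=config,
    )


_TERMINAL = {"unknown", "background"}  # fallback sinks, never merged upward


def enforce_min_cluster_size(
    assign: PhenotypeAssignment, min_cells: int = 100
) -> PhenotypeAssignment:
    """Merge under-sized leaves into their parents until stable.

    A cluster needs more than ``min_cells`` cells (pooled across samples) to
    stand on its own; labels at or below the threshold are relabeled to
    their parent node, repeatedly, so sibling fragments can accumulate into
    a surviving parent.
    """
    parents = assign.config.parent_map()
    root = assign.config.root.name
    labels = assign.labels.copy()
    while True:
        counts = labels.value_counts()
        candidates: dict[str, str] = {}
        for lab, cnt in counts.items():
            if cnt > min_cells or lab in _TERMINAL:
                continue
            parent = parents.get(lab)
            if parent is None or lab == root:
                continue
            if parent == root:
                parent = assign.config.root.fallback or "unknown"
            candidates[lab] = parent
        if not candidates:
            break
        # merge the deepest labels first, so sibling fragments can pool in a
        # parent before the parent itself is judged
        depth = {lab: len(assign.config.ancestors(lab)) for lab in candidates}
        deepest = max(depth.values())
        relabel = {lab: p for lab, p in candidates.items() if depth[lab] == deepest}
        labels = labels.replace(relabel)
    return PhenotypeAssignment(labels, assign.sample_ids, assign.config)


def compute_frequencies(
    assign: PhenotypeAssignment,
    denominator,
    clusters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample cluster frequencies over a stated denominator.

    ``denominator`` is a set of node names (leaves or internal, e.g.
    ``{"immune", "trophoblast"}``); a cell is in the denominator when any
    node on its label's ancestor chain is in the set. Frequencies are
    returned as a clusters × samples table; a sample whose denominator is
    empty gets NaN frequencies and a warning.
    """
    denom_mask = assign.in_group(denominator)
    if clusters is None:
        clusters = sorted(assign.labels[denom_mask].unique())
    samples = pd.unique(assign.sample_ids)
    out = pd.DataFrame(index=clusters, columns=samples, dtype=float)
    for s in samples:
        in_sample = assign.sample_ids == s
        denom = int((in_sample & denom_mask).sum())
        if denom == 0:
            warnings.warn(f"sample {s!r}: empty denominator, frequencies undefined")
            out[s] = np.nan
            continue
        for c in clusters:
            out.loc[c, s] = int(
                (in_sample & denom_mask & assign.in_group(c)).sum()
            ) / denom
    out.index.name = "cluster"
    out.columns.name = "sample_id"
    return out


def ratio_from_counts(immune: int, trophoblasts: int) -> float:
    """Immune-to-trophoblast cell count ratio, reported to 3 decimals."""
    if trophoblasts <= 0:
        raise ValueError("trophoblast count must be positive for a defined ratio")
    return round(immune / trophoblasts, 3)


def immune_trophoblast_ratio(
    assign: PhenotypeAssignment,
    immune_group: str = "immune",
    trophoblast_group: str = "trophoblast",
) -> pd.Series:
    """Per-sample ratio of immune cells to trophoblasts (3 decimals).

    Samples without trophoblasts get NaN and a warning rather than an
    error, so one degenerate ROI does not abort a cohort run.
    """
    imm = assign.in_group(immune_group)
    tro = assign.in_group(trophoblast_group)
    out = {}
    for s in pd.unique(assign.sample_ids):
        in_sample = assign.sample_ids == s
        n_tro = int((in_sample & tro).sum())
        n_imm = int((in_sample & imm).sum())
        if n_tro == 0:
            warnings.warn(f"sample {s!r}: zero trophoblasts, ratio undefined")
            out[s] = np.nan
        else:
            out[s] = ratio_from_counts(n_imm, n_tro)
    return pd.Series(out, name="immune_trophoblast_ratio")
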