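"""Default synthetic study conditions for a decidua-like tissue.

A reduced marker panel (14 of the full 42 channels) and a phenotype mix
that mirrors the decidual compartment structure: two decidual-macrophage
subclusters (together 40% of cells), NK cells (30%), CD4 T cells (10%) and
trophoblasts (20%) over the immune+trophoblast denominator, with nucleus
radius 4 px in a 500×500 px (0.25 mm²) ROI — the scale of the smallest
regions acquired in decidual IMC studies. These constants are the single
source of the conditions used by the examples and the validation suite.
"""

from __future__ import annotations

from .synth import PanelSpec

__all__ = [
    "DEMO_MARKERS",
    "DEMO_CLUSTERS",
    "DEMO_FREQS",
    "DEMO_FIELD",
    "MIN_NUCLEUS_SPACING",
    "demo_panel",
]

DEMO_MARKERS = [
    "CD45",
    "CD14",
    "CD68",
    "HLA-DR",
    "DC-SIGN",
    "CD56",
    "CD7",
    "CD3",
    "CD4",
    "CD8a",
    "CD15",
    "keratin",
    "HLA-G",
    "vimentin",
]

#: Cluster → positive marker set. Names are gating-hierarchy leaves, so the
#: default gating config recovers them exactly on clean data.
DEMO_CLUSTERS: dict[str, set] = {
    "dMO2": {"CD45", "CD14", "CD68", "HLA-DR", "DC-SIGN"},
    "dMO4": {"CD45", "CD14", "CD68"},
    "NK": {"CD45", "CD56", "CD7"},
    "T_CD4": {"CD45", "CD3", "CD4"},
    "trophoblast": {"keratin", "HLA-G"},
}

#: Planted cluster frequencies: 40% myeloid (split over two subclusters),
#: 30% NK, 10% T, 20% trophoblast.
DEMO_FREQS: dict[str, float] = {
    "dMO2": 0.2,
    "dMO4": 0.2,
    "NK": 0.3,
    "T_CD4": 0.1,
    "trophoblast": 0.2,
}

#: Default ROI size, px (1 px = 1 μm): 0.25 mm².
DEMO_FIELD: tuple[int, int] = (500, 500)

#: Center spacing guaranteeing radius-4 nuclei stay 8-connectivity-separate.
MIN_NUCLEUS_SPACING: float = 11.0


def demo_panel(
    noise: dict[str, tuple[float, float]] | None = None,
    marker_noise: float | None = None,
    nucleus_radius: int = 4,
) -> PanelSpec:
    """The demo panel; ``marker_noise`` sets fp=fn on every marker channel
    (DNA stays clean unless given explicitly in ``noise``)."""
    if noise is None:
        noise = {}
    if marker_noise is not None:
        noise = {m: (marker_noise, marker_noise) for m in DEMO_MARKERS} | dict(noise)
    return PanelSpec(
        markers=list(DEMO_MARKERS),
        clusters={k: set(v) for k, v in DEMO_CLUSTERS.items()},
        nucleus_radius=nucleus_radius,
        noise=noise,
    )
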