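"""Gating hierarchy, cluster-size rule, frequencies and ratios."""

import numpy as np
import pandas as pd
import pytest

from imcmicro.phenotype import (
    GatingConfig,
    GatingRule,
    compute_frequencies,
    default_gating_config,
    enforce_min_cluster_size,
    gate_cells,
    immune_trophoblast_ratio,
    ratio_from_counts,
)
from imcmicro.presets import DEMO_MARKERS


def _table(rows: list[dict], markers=DEMO_MARKERS) -> pd.DataFrame:
    base = {m: 0.0 for m in markers}
    recs = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec.update(row)
        rec.update(
            cell_id=i + 1,
            roi_id=row.get("roi_id", "r1"),
            sample_id=row.get("sample_id", "s1"),
            x=0.0,
            y=0.0,
            area=10,
        )
        recs.append(rec)
    return pd.DataFrame(recs)


def test_no_marker_cell_is_background():
    table = _table([{}])
    assign = gate_cells(table, default_gating_config(DEMO_MARKERS))
    assert assign.labels.iloc[0] == "background"


def test_myeloid_dr_negative_sign_positive_subcluster():
    """CD45⁺CD14⁺ HLA-DR⁻ DC-SIGN⁺ lands in the DR⁻SIGN⁺ macrophage leaf."""
    table = _table([{"CD45": 0.9, "CD14": 0.8, "HLA-DR": 0.0, "DC-SIGN": 0.8}])
    assign = gate_cells(table, default_gating_config(DEMO_MARKERS))
    assert assign.labels.iloc[0] == "dMO1"


@pytest.mark.parametrize(
    "row,expected",
    [
        ({"keratin": 0.5, "HLA-G": 0.6}, "trophoblast"),
        ({"vimentin": 0.5}, "stromal"),
        ({"CD45": 0.9, "CD56": 0.5, "CD7": 0.5}, "NK"),
        ({"CD45": 0.9, "CD3": 0.5, "CD4": 0.5}, "T_CD4"),
        ({"CD45": 0.9, "CD3": 0.5, "CD8a": 0.5}, "T_CD8"),
        ({"CD45": 0.9, "CD3": 0.5}, "T_DN"),
        ({"CD45": 0.9, "CD15": 0.5}, "granulocyte"),
        ({"CD45": 0.9, "CD14": 0.5, "CD56": 0.5}, "dMO3"),
        ({"CD45": 0.9, "CD14": 0.5, "HLA-DR": 0.5, "DC-SIGN": 0.5}, "dMO2"),
        ({"CD45": 0.9, "CD14": 0.5}, "dMO4"),
        ({"CD45": 0.9}, "immune_other"),
    ],
)
def test_default_hierarchy_routes(row, expected):
    table = _table([row])
    assign = gate_cells(table, default_gating_config(DEMO_MARKERS))
    assert assign.labels.iloc[0] == expected


def test_positivity_threshold_is_inclusive_quarter():
    table = _table([{"CD45": 0.25, "CD14": 0.24}])
    assign = gate_cells(table, default_gating_config(DEMO_MARKERS))
    assert assign.labels.iloc[0] == "immune_other"  # CD45 at 0.25 positive, CD14 not


def test_gating_is_a_partition():
    rng = np.random.default_rng(0)
    table = _table([
        {m: rng.random() for m in DEMO_MARKERS} for _ in range(300)
    ])
    assign = gate_cells(table, default_gating_config(DEMO_MARKERS))
    assert assign.labels.notna().all()
    assert len(assign.labels) == 300


def test_missing_marker_rejected():
    table = _table([{}], markers=["CD45"])
    with pytest.raises(ValueError, match="absent"):
        gate_cells(table, default_gating_config(DEMO_MARKERS))


def test_config_yaml_round_trip(tmp_path):
    cfg = default_gating_config(DEMO_MARKERS, threshold=0.3)
    path = tmp_path / "gating.yaml"
    cfg.to_yaml(path)
    back = GatingConfig.from_yaml(path)
    assert back.threshold == 0.3
    assert back.root.to_dict() == cfg.root.to_dict()


def _assignment(labels, config, samples=None):
    labels = pd.Series(labels, dtype=object)
    samples = pd.Series(samples if samples is not None else ["s1"] * len(labels))
    from imcmicro.phenotype import PhenotypeAssignment

    return PhenotypeAssignment(labels, samples, config)


def test_min_cluster_size_no_op_when_all_large():
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["NK"] * 150 + ["trophoblast"] * 150
    out = enforce_min_cluster_size(_assignment(labels, cfg), 100)
    assert out.counts()["NK"] == 150


def test_small_t_subleaf_merges_into_parent():
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["T_CD4"] * 40 + ["T"] * 80 + ["T_CD8"] * 150 + ["NK"] * 200
    out = enforce_min_cluster_size(_assignment(labels, cfg), 100)
    counts = out.counts()
    assert "T_CD4" not in counts
    assert counts["T"] == 120  # 40 merged cells join the 80 already at the T level
    assert counts["T_CD8"] == 150


def test_sibling_fragments_accumulate_in_parent():
    """Two 60-cell siblings merge upward and survive as a 120-cell parent."""
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["T_CD4"] * 60 + ["T_CD8"] * 60 + ["NK"] * 500
    out = enforce_min_cluster_size(_assignment(labels, cfg), 100)
    counts = out.counts()
    assert counts["T"] == 120
    assert "T_CD4" not in counts and "T_CD8" not in counts


def test_frequencies_normalize_and_flag_empty():
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["NK"] * 30 + ["trophoblast"] * 70
    freqs = compute_frequencies(
        _assignment(labels, cfg), {"immune", "trophoblast"}
    )
    assert freqs.loc["NK", "s1"] == pytest.approx(0.3)
    assert freqs.loc["trophoblast", "s1"] == pytest.approx(0.7)
    assert freqs["s1"].sum() == pytest.approx(1.0, abs=1e-12)
    # a sample with no denominator cells is NaN, not zero
    labels2 = ["background"] * 10
    with pytest.warns(UserWarning, match="empty denominator"):
        freqs2 = compute_frequencies(
            _assignment(labels2, cfg), {"immune", "trophoblast"}
        )
    assert freqs2.isna().all().all() or freqs2.empty


def test_frequencies_invariant_to_cell_order():
    cfg = default_gating_config(DEMO_MARKERS)
    rng = np.random.default_rng(1)
    labels = rng.choice(["NK", "T_CD4", "dMO2", "trophoblast"], size=400)
    samples = rng.choice(["s1", "s2"], size=400)
    f1 = compute_frequencies(
        _assignment(labels, cfg, samples), {"immune", "trophoblast"}
    )
    perm = rng.permutation(400)
    f2 = compute_frequencies(
        _assignment(labels[perm], cfg, samples[perm]), {"immune", "trophoblast"}
    )
    pd.testing.assert_frame_equal(f1.sort_index(), f2[f1.columns].sort_index())


def test_lineage_frequencies_sum_over_subclusters():
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["dMO2"] * 20 + ["dMO4"] * 30 + ["NK"] * 50
    freqs = compute_frequencies(
        _assignment(labels, cfg), {"immune"}, clusters=["myeloid", "NK"]
    )
    assert freqs.loc["myeloid", "s1"] == pytest.approx(0.5)


@pytest.mark.parametrize(
    "immune,troph,expected",
    [
        (5926, 5225, 1.134),
        (7326, 6680, 1.097),
        (10190, 4390, 2.321),
        (2514, 1003, 2.506),
        (1820, 5856, 0.311),
        (100, 100, 1.000),
    ],
)
def test_immune_trophoblast_ratio_from_counts(immune, troph, expected):
    assert ratio_from_counts(immune, troph) == expected


def test_ratio_per_sample_and_zero_trophoblast_flag():
    cfg = default_gating_config(DEMO_MARKERS)
    labels = ["NK"] * 30 + ["trophoblast"] * 20 + ["NK"] * 10
    samples = ["s1"] * 50 + ["s2"] * 10
    assign = _assignment(labels, cfg, samples)
    with pytest.warns(UserWarning, match="zero trophoblasts"):
        ratios = immune_trophoblast_ratio(assign)
    assert ratios["s1"] == 1.5
    assert np.isnan(ratios["s2"])


def test_planted_frequency_recovery_through_full_pipeline():
    """Image → mask → fractions → gating recovers planted lineage mix."""
    from imcmicro.validation import phenotype_recovery  # noqa: F401 - chain check below
    from imcmicro.presets import DEMO_FREQS, MIN_NUCLEUS_SPACING, demo_panel
    from imcmicro.quantify import binarize_stack, quantify_cells
    from imcmicro.segment import expand_labels, segment_nuclei
    from imcmicro.stacks import ImageStack
    from imcmicro.synth import rasterize_pattern, simulate_pattern

    panel = demo_panel(marker_noise=0.05)
    pat = simulate_pattern(
        5000, DEMO_FREQS, field=(1500, 1500), seed=21, min_spacing=MIN_NUCLEUS_SPACING
    )
    stack, _, _ = rasterize_pattern(pat, panel, seed=22)
    mask = expand_labels(segment_nuclei(stack["DNA"], 0.5, min_area=5), 2)
    table = quantify_cells(
        mask, binarize_stack(ImageStack({m: stack[m] for m in panel.markers}), "identity")
    )
    assign = gate_cells(table, default_gating_config(panel.markers, threshold=0.25))
    n = len(table)
    planted = {"myeloid": 0.4, "NK": 0.3, "T": 0.1, "trophoblast": 0.2}
    for group, f in planted.items():
        recovered = assign.in_group(group).sum() / n
        assert abs(recovered - f) <= 0.03, (group, recovered)
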