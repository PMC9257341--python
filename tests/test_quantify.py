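"""Binarization and per-cell positive-pixel fractions."""

import numpy as np
import pandas as pd
import pytest

from imcmicro.quantify import (
    binarize_stack,
    marker_columns,
    quantify_cells,
    read_cell_table,
    write_cell_table,
)
from imcmicro.stacks import ImageStack

from .oracles import brute_fractions


def test_binarize_blank_and_identity():
    stack = ImageStack({"a": np.zeros((8, 8)), "b": np.eye(8)})
    out = binarize_stack(stack, "identity")
    assert out["a"].sum() == 0
    assert np.array_equal(out["b"], np.eye(8))


def test_binarize_identity_rejects_non_binary():
    stack = ImageStack({"a": np.full((4, 4), 2.0)})
    with pytest.raises(ValueError, match="not binary"):
        binarize_stack(stack, "identity")


def test_binarize_unknown_method():
    with pytest.raises(ValueError, match="unknown"):
        binarize_stack(ImageStack({"a": np.zeros((4, 4))}), "magic")


def test_binarize_otsu_separates_bimodal():
    """Clean 0/100 bimodal channel: Otsu binary equals (pixel > 0)."""
    rng = np.random.default_rng(0)
    ch = np.where(rng.random((32, 32)) < 0.3, 100.0, 0.0)
    out = binarize_stack(ImageStack({"a": ch}), "otsu")
    assert np.array_equal(out["a"], (ch > 0).astype(np.uint8))
    # exhaustive threshold search maximizing between-class variance agrees
    best_thr, best_var = None, -1.0
    flat = ch.ravel()
    for t in np.unique(flat)[:-1]:
        w0 = (flat <= t).mean()
        w1 = 1 - w0
        var = w0 * w1 * (flat[flat > t].mean() - flat[flat <= t].mean()) ** 2
        if var > best_var:
            best_thr, best_var = t, var
    assert np.array_equal(out["a"], (ch > best_thr).astype(np.uint8))


def test_half_positive_cell_scores_half():
    """A cell with exactly half its pixels positive has fraction 0.5."""
    mask = np.zeros((4, 4), dtype=int)
    mask[:2, :2] = 1  # 4-pixel cell
    ch = np.zeros((4, 4), dtype=np.uint8)
    ch[0, :2] = 1  # 2 of its 4 pixels positive
    table = quantify_cells(mask, ImageStack({"m": ch}))
    assert table.loc[0, "m"] == 0.5


def test_saturated_cell_scores_one():
    mask = np.zeros((4, 4), dtype=int)
    mask[1:3, 1:3] = 1
    ch = np.ones((4, 4), dtype=np.uint8)
    table = quantify_cells(mask, ImageStack({"m": ch}))
    assert table.loc[0, "m"] == 1.0
    assert table.loc[0, "area"] == 4


def test_fractions_match_bruteforce_tally():
    rng = np.random.default_rng(3)
    mask = rng.integers(0, 21, size=(40, 40))
    ch = (rng.random((40, 40)) < 0.4).astype(np.uint8)
    table = quantify_cells(mask, ImageStack({"m": ch}))
    expected = brute_fractions(mask, ch)
    got = dict(zip(table["cell_id"], table["m"]))
    assert got == pytest.approx(expected)


def test_positive_pixel_conservation():
    """Σ_cells fraction × area = total positive pixels inside the mask."""
    rng = np.random.default_rng(4)
    mask = rng.integers(0, 10, size=(30, 30))
    ch = (rng.random((30, 30)) < 0.5).astype(np.uint8)
    table = quantify_cells(mask, ImageStack({"m": ch}))
    total = (table["m"] * table["area"]).sum()
    assert total == int(ch[mask > 0].sum())


def test_fractions_invariant_to_label_renumbering():
    rng = np.random.default_rng(5)
    mask = rng.integers(0, 6, size=(20, 20))
    ch = (rng.random((20, 20)) < 0.5).astype(np.uint8)
    perm = np.array([0, 3, 5, 1, 4, 2])  # relabeling
    t1 = quantify_cells(mask, ImageStack({"m": ch}))
    t2 = quantify_cells(perm[mask], ImageStack({"m": ch}))
    f1 = {perm[c]: v for c, v in zip(t1["cell_id"], t1["m"])}
    f2 = dict(zip(t2["cell_id"], t2["m"]))
    assert f1 == pytest.approx(f2)


def test_empty_mask_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="empty mask"):
        table = quantify_cells(np.zeros((8, 8), dtype=int), ImageStack({"m": np.zeros((8, 8), dtype=np.uint8)}))
    assert len(table) == 0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        quantify_cells(np.zeros((4, 4), dtype=int), ImageStack({"m": np.zeros((5, 5), dtype=np.uint8)}))


def test_csv_round_trip(tmp_path):
    table = pd.DataFrame(
        {
            "cell_id": [1, 2],
            "roi_id": "r1",
            "sample_id": "s1",
            "x": [1.5, 2.5],
            "y": [0.5, 3.5],
            "area": [4, 6],
            "CD45": [0.25, 1.0],
        }
    )
    path = tmp_path / "cells.csv"
    write_cell_table(table, path, "csv")
    back = read_cell_table(path, "csv")
    pd.testing.assert_frame_equal(back, table)


def test_fcs_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(50) + 1,
            "area": rng.integers(10, 100, 50),
            "CD45": rng.random(50),
            "CD3": rng.random(50),
        }
    )
    path = tmp_path / "cells.fcs"
    write_cell_table(table, path, "fcs")
    back = read_cell_table(path, "fcs")
    assert list(back.columns) == ["cell_id", "area", "CD45", "CD3"]
    assert np.allclose(back["CD45"], table["CD45"], atol=1e-6)
    assert np.allclose(back["CD3"], table["CD3"], atol=1e-6)


def test_fcs_zero_events(tmp_path):
    table = pd.DataFrame({"CD45": pd.Series([], dtype=float)})
    path = tmp_path / "empty.fcs"
    write_cell_table(table, path, "fcs")
    back = read_cell_table(path, "fcs")
    assert len(back) == 0
    assert list(back.columns) == ["CD45"]


def test_unsupported_format():
    with pytest.raises(ValueError, match="unsupported"):
        write_cell_table(pd.DataFrame({"a": [1.0]}), "x.bin", "parquet")


def test_marker_columns_helper():
    table = pd.DataFrame(
        {"cell_id": [1], "roi_id": "r", "sample_id": "s", "x": [0.0], "y": [0.0], "area": [1], "CD45": [0.5]}
    )
    assert marker_columns(table) == ["CD45"]
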