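"""Per-cell marker quantification on binarized channels.

The per-cell "expression" value is the relative frequency of positive
pixels: for cell *k* and marker *m*, the number of positive pixels of *m*
inside the cell's mask divided by the cell's area. A cell with half of its
pixels positive for a marker therefore scores 0.5 for that marker. This
binarized readout deliberately discards staining intensity, which varies
with acquisition conditions, and keeps only spatial signal extent.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .fcs import read_fcs, write_fcs
from .stacks import ImageStack

__all__ = [
    "META_COLUMNS",
    "marker_columns",
    "binarize_stack",
    "quantify_cells",
    "write_cell_table",
    "read_cell_table",
]

#: Non-marker columns of a cell table; everything else is a marker fraction.
META_COLUMNS = ("cell_id", "roi_id", "sample_id", "x", "y", "area", "true_cluster")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker (positive-pixel-fraction) columns of a cell table."""
    return [c for c in table.columns if c not in META_COLUMNS]


def binarize_stack(
    stack: ImageStack,
    method: str | float | dict[str, str | float] = "otsu",
) -> ImageStack:
    """Map every channel to {0, 1}.

    ``method`` may be a single spec applied to all channels or a per-channel
    dict. Specs: ``"otsu"`` (histogram threshold, pixels strictly above are
    positive), ``"identity"`` (channel already binary; validated), or a
    number (fixed threshold, strictly-above rule). The chosen threshold per
    channel is recorded in ``out.meta["thresholds"]``.
    """
    out: dict[str, np.ndarray] = {}
    thresholds: dict[str, float | None] = {}
    for name, ch in stack.channels.items():
        spec = method[name] if isinstance(method, dict) else method
        if spec == "identity":
            vals = np.unique(ch)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"channel {name!r} is not binary; cannot use 'identity'")
            out[name] = ch.astype(np.uint8)
            thresholds[name] = None
        elif spec == "otsu":
            if ch.max() == ch.min():
                thr = float(ch.max())  # flat channel: nothing is above it
            else:
                thr = float(threshold_otsu(ch))
            out[name] = (ch > thr).astype(np.uint8)
            thresholds[name] = thr
        elif isinstance(spec, str):
            raise ValueError(f"unknown binarization method {spec!r}")
        else:
            thr = float(spec)
            out[name] = (ch > thr).astype(np.uint8)
            thresholds[name] = thr
    result = ImageStack(out, dict(stack.meta))
    result.meta["thresholds"] = thresholds
    return result


def quantify_cells(
    mask: np.ndarray,
    binary: ImageStack,
    roi_id: str = "roi0",
    sample_id: str = "sample0",
) -> pd.DataFrame:
    """Compute the per-cell positive-pixel fraction of every channel.

    Returns a cell table with one row per label in ``mask``: cell_id,
    roi_id, sample_id, centroid (x, y in μm = px), area (px), and one
    column per channel holding its fraction in [0, 1].
    """
    mask = np.asarray(mask)
    if mask.shape != binary.shape:
        raise ValueError(f"mask shape {mask.shape} != channel shape {binary.shape}")

    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        warnings.warn("empty mask: returning 0-row cell table", stacklevel=2)
        cols = ["cell_id", "roi_id", "sample_id", "x", "y", "area", *binary.names]
        return pd.DataFrame(columns=cols)

    nmax = int(labels.max())
    flat = mask.ravel()
    areas = np.bincount(flat, minlength=nmax + 1)
    yy, xx = np.indices(mask.shape)
    sum_y = np.bincount(flat, weights=yy.ravel(), minlength=nmax + 1)
    sum_x = np.bincount(flat, weights=xx.ravel(), minlength=nmax + 1)

    data = {
        "cell_id": labels,
        "roi_id": roi_id,
        "sample_id": sample_id,
        "x": sum_x[labels] / areas[labels],
        "y": sum_y[labels] / areas[labels],
        "area": areas[labels],
    }
    for name, ch in binary.channels.items():
        vals = np.unique(ch)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"channel {name!r} is not binary; binarize first")
        pos = np.bincount(flat, weights=ch.ravel().astype(float), minlength=nmax + 1)
        data[name] = pos[labels] / areas[labels]
    return pd.DataFrame(data)


def write_cell_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a cell table as CSV or FCS 3.0 (one event per cell)."""
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "fcs":
        numeric = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
        ]
        if not numeric:
            raise ValueError("no numeric columns to export")
        write_fcs(path, numeric, table[numeric].to_numpy(dtype=np.float32))
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_cell_table(path: str | Path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        return pd.read_csv(path)
    if format == "fcs":
        names, data = read_fcs(path)
        return pd.DataFrame(data, columns=names)
    raise ValueError(f"unsupported format {format!r}")
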