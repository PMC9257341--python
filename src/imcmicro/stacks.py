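"""Multichannel image container and TIFF I/O.

An :class:`ImageStack` holds one 2-D plane per marker channel for a single
ROI, at 1 pixel = 1 μm². Channels are named; the DNA (nuclear) channel is
just another named channel. Stacks are written as multipage TIFFs with the
channel name stored in each page's description, so they round-trip without
side-car files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "read_label_mask", "write_label_mask"]


@dataclass
class ImageStack:
    """Named 2-D channels for one ROI.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D array. All channels must share a shape.
    meta
        Free-form metadata (e.g. per-channel binarization thresholds).
    """

    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D (ndim={ch.ndim})")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def astype(self, dtype) -> "ImageStack":
        return ImageStack(
            {k: v.astype(dtype) for k, v in self.channels.items()}, dict(self.meta)
        )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write one multipage TIFF, one page per channel, name in page description."""
    with tifffile.TiffWriter(str(path)) as tif:
        for name, ch in stack.channels.items():
            tif.write(ch, description=name, contiguous=False)


def read_stack(path: str | Path) -> ImageStack:
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(str(path)) as tif:
        for i, page in enumerate(tif.pages):
            name = page.description or f"channel_{i}"
            channels[name] = page.asarray()
    return ImageStack(channels)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit single-page TIFF (labels must fit uint16)."""
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)
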