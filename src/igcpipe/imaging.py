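"""Fluorescence slide segmentation and single-cell morphometry.

Multi-channel immunofluorescence slides (DAPI nuclear stain, an epithelial
marker cocktail, CD45 leukocyte exclusion, and a variable fourth channel)
are segmented channel by channel with adaptive thresholding; the per-channel
masks are merged into a cell mask, and the DAPI mask restricted to each cell
defines its nucleus.  Per-cell morphometric features (areas, equivalent
diameters) and per-channel intensity statistics are extracted into a flat
table, one row per detected cell.

The nuclear *equivalent diameter* — the diameter of the circle with the same
area as the nuclear mask, reported in micrometres — is the size statistic the
downstream increased-genomic-content (IGC) call is based on.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk

__all__ = [
    "SlideImage",
    "ChannelMask",
    "equivalent_diameter",
    "segment_channel",
    "merge_masks",
    "extract_cells",
    "read_slide",
    "write_slide",
    "CELL_TABLE_COLUMNS",
]

DEFAULT_CHANNELS = ("DAPI", "EPI", "CD45", "VAR")


@dataclasses.dataclass
class SlideImage:
    """A multi-channel fluorescence slide.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``) to a 2-D non-negative
        intensity array. All channels must share one shape.
    pixel_size
        Physical size of one pixel in micrometres.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SlideImage needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} missing; have {sorted(self.channels)}")
        return self.channels[name]


@dataclasses.dataclass
class ChannelMask:
    """Binary foreground mask for one channel plus its provenance."""

    mask: np.ndarray
    channel: str = ""
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


def equivalent_diameter(area: float | np.ndarray, pixel_size: float = 1.0) -> float | np.ndarray:
    """Diameter (µm) of the circle whose area equals ``area`` (px²).

    ``d = pixel_size * sqrt(4 * area / pi)``.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    out = pixel_size * np.sqrt(4.0 * area / np.pi)
    return float(out) if out.ndim == 0 else out


def segment_channel(
    channel: np.ndarray,
    block_size: int = 51,
    offset: float = 10.0,
    min_area: int = 20,
    open_radius: int = 1,
    channel_name: str = "",
) -> ChannelMask:
    """Adaptive-threshold segmentation of one fluorescence channel.

    A pixel is foreground iff its intensity exceeds the local arithmetic mean
    over a ``block_size`` window by more than ``offset``.  The raw mask is
    cleaned by a morphological opening with a disk of radius ``open_radius``
    and components smaller than ``min_area`` px² are dropped.

    ``block_size`` must be odd and >= 3 (the local window needs a centre).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("channel must be a 2-D array")
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    if channel.size == 0:
        return ChannelMask(np.zeros(channel.shape, bool), channel_name, {})
    # skimage's convention is foreground = image > (local stat - offset);
    # a positive `offset` here raises the threshold *above* the local mean.
    thresh = threshold_local(channel, block_size=block_size, method="mean", offset=-offset)
    mask = channel > thresh
    if open_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(open_radius))
    if min_area > 1:
        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            mask = sizes[labels] >= min_area
            mask[labels == 0] = False
    params = dict(
        block_size=block_size, offset=offset, min_area=min_area, open_radius=open_radius
    )
    return ChannelMask(mask, channel_name, params)


def merge_masks(masks: Sequence[ChannelMask | np.ndarray]) -> np.ndarray:
    """Pixel-wise union of per-channel masks into one cell mask."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    arrays = [m.mask if isinstance(m, ChannelMask) else np.asarray(m, bool) for m in masks]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"mask shape mismatch: {a.shape} vs {shape}")
    out = arrays[0].copy()
    for a in arrays[1:]:
        out |= a
    return out


#: Stable column order of the cell table written by :func:`extract_cells`.
CELL_TABLE_COLUMNS = [
    "cell_id",
    "centroid_row",
    "centroid_col",
    "cell_area",
    "nuclear_area",
    "d_cell_um",
    "d_nuc_um",
    "anucleate",
    "border",
]


def extract_cells(
    cell_mask: np.ndarray | ChannelMask,
    dapi_mask: np.ndarray | ChannelMask,
    image: SlideImage,
) -> pd.DataFrame:
    """Extract per-cell morphometry and intensity statistics.

    Connected components of ``cell_mask`` define cells; each cell's nuclear
    region is the intersection of its component with ``dapi_mask``.  Cells
    whose nuclear region is empty are kept with ``d_nuc_um = 0`` and flagged
    ``anucleate``; components touching the image border are kept and flagged
    ``border``.

    Returns a DataFrame with one row per cell: the columns in
    :data:`CELL_TABLE_COLUMNS` followed by ``{channel}_{region}_{stat}`` for
    every channel, region in (``cell``, ``nuc``) and stat in
    (``mean``, ``max``, ``total``).
    """
    cmask = cell_mask.mask if isinstance(cell_mask, ChannelMask) else np.asarray(cell_mask, bool)
    nmask = dapi_mask.mask if isinstance(dapi_mask, ChannelMask) else np.asarray(dapi_mask, bool)
    if cmask.shape != image.shape or nmask.shape != image.shape:
        raise ValueError("mask shapes must match the image")

    labels = sk_label(cmask, connectivity=2)
    n_cells = int(labels.max())
    ch_names = list(image.channels)
    stat_cols = [
        f"{ch}_{region}_{stat}"
        for ch in ch_names
        for region in ("cell", "nuc")
        for stat in ("mean", "max", "total")
    ]
    columns = CELL_TABLE_COLUMNS + stat_cols
    if n_cells == 0:
        return pd.DataFrame(columns=columns)

    stack = np.stack([image.channels[ch] for ch in ch_names], axis=-1)
    nuc_labels = np.where(nmask, labels, 0)
    h, w = cmask.shape
    px = image.pixel_size

    rows = []
    cell_props = regionprops(labels, intensity_image=stack)
    # nuclear regions carry the *same* label ids as their parent cells
    nuc_props = {p.label: p for p in regionprops(nuc_labels, intensity_image=stack)}
    for p in cell_props:
        nuc = nuc_props.get(p.label)
        nuc_area = float(nuc.area) if nuc is not None else 0.0
        minr, minc, maxr, maxc = p.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        rec = {
            "cell_id": p.label,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "cell_area": float(p.area),
            "nuclear_area": nuc_area,
            "d_cell_um": equivalent_diameter(p.area, px),
            "d_nuc_um": equivalent_diameter(nuc_area, px),
            "anucleate": nuc is None,
            "border": bool(border),
        }
        for ci, ch in enumerate(ch_names):
            cmean = p.intensity_mean[ci]
            cmax = p.intensity_max[ci]
            rec[f"{ch}_cell_mean"] = float(cmean)
            rec[f"{ch}_cell_max"] = float(cmax)
            rec[f"{ch}_cell_total"] = float(cmean * p.area)
            if nuc is not None:
                nmean = nuc.intensity_mean[ci]
                nmax = nuc.intensity_max[ci]
            else:
                nmean = nmax = 0.0
            rec[f"{ch}_nuc_mean"] = float(nmean)
            rec[f"{ch}_nuc_max"] = float(nmax)
            rec[f"{ch}_nuc_total"] = float(nmean * nuc_area)
        rows.append(rec)
    return pd.DataFrame(rows, columns=columns)


def estimate_background(image: SlideImage, cell_mask: np.ndarray, pad: int = 3):
    """Per-channel (mean, sd) of background pixels (outside the dilated mask)."""
    bg = ~ndimage.binary_dilation(np.asarray(cell_mask, bool), iterations=pad)
    if not bg.any():
        raise ValueError("no background pixels outside the cell mask")
    return {ch: (float(arr[bg].mean()), float(arr[bg].std())) for ch, arr in image.channels.items()}


def write_slide(image: SlideImage, path) -> None:
    """Write a slide as a multi-page TIFF, one page per channel.

    The channel name and pixel size are stored in each page's ImageDescription
    tag as JSON so the file round-trips through :func:`read_slide`.
    """
    with tifffile.TiffWriter(str(path)) as tw:
        for name, arr in image.channels.items():
            desc = json.dumps({"channel": name, "pixel_size_um": image.pixel_size})
            tw.write(arr.astype(np.float32), description=desc, contiguous=False)


def read_slide(path) -> SlideImage:
    """Read a multi-page TIFF written by :func:`write_slide`."""
    channels: dict[str, np.ndarray] = {}
    pixel_size = 1.0
    with tifffile.TiffFile(str(path)) as tf:
        for i, page in enumerate(tf.pages):
            desc = page.tags.get("ImageDescription")
            meta = {}
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, ValueError):
                    meta = {}
            name = meta.get("channel", f"channel_{i}")
            pixel_size = float(meta.get("pixel_size_um", pixel_size))
            channels[name] = page.asarray().astype(float)
    return SlideImage(channels=channels, pixel_size=pixel_size)
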