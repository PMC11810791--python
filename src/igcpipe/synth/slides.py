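"""Synthetic fluorescence slide rendering with planted ground truth.

Slides emulate the immunofluorescence assay: a dense background of white
blood cells (DAPI+/CD45+), a handful of circulating tumor cells
(DAPI+/EPI+/CD45-), and optionally CTC-IGC cells whose nuclear diameter is
at least double a typical CTC's, plus EPI-negative variable-marker-positive
large cells.  Each cell is a hard disk (cytoplasmic markers over the cell
disk, DAPI over a concentric nuclear disk) softened by a 1-px Gaussian blur;
Gaussian read noise and a flat background level are added per channel.
Cells are placed by rejection sampling so no two disks overlap — splitting
touching cells is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from igcpipe.imaging import SlideImage

__all__ = ["CellClassSpec", "SlideSpec", "render_slide"]

CHANNELS = ("DAPI", "EPI", "CD45", "VAR")
#: labels a cell class may carry on a synthetic slide
CLASS_LABELS = ("WBC", "CTC", "CTC_IGC", "EPI_NEG_IGC")

# minimum clearance between cell disk edges, px; keeps blurred edges separate
MIN_GAP_PX = 4.0
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclasses.dataclass
class CellClassSpec:
    """Planted population of one cell class on a slide.

    ``channel_intensity`` maps channel name to the disk's mean intensity
    (arbitrary 16-bit-style units); DAPI paints the nuclear disk, all other
    channels paint the full cell disk.
    """

    label: str
    count: int
    nuclear_diameter_mean: float  # µm
    nuclear_diameter_sd: float
    cell_diameter_mean: float  # µm
    cell_diameter_sd: float
    channel_intensity: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown cell class label {self.label!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.nuclear_diameter_mean <= 0 or self.cell_diameter_mean <= 0:
            raise ValueError("diameters must be positive")
        self.channel_intensity = dict(self.channel_intensity)


@dataclasses.dataclass
class SlideSpec:
    """Full description of one synthetic slide."""

    width: int
    height: int
    cell_classes: Sequence[CellClassSpec]
    pixel_size: float = 1.0  # µm / px
    background_level: float = 200.0
    noise_sd: float = 5.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ctc = {c.label: c for c in self.cell_classes}
        if "CTC" in ctc and "CTC_IGC" in ctc:
            if ctc["CTC_IGC"].nuclear_diameter_mean < 2 * ctc["CTC"].nuclear_diameter_mean:
                raise ValueError(
                    "CTC_IGC nuclear_diameter_mean must be >= 2x the CTC nuclear_diameter_mean"
                )


GROUND_TRUTH_COLUMNS = [
    "cell_id",
    "label",
    "centroid_row",
    "centroid_col",
    "nuclear_diameter_um",
    "cell_diameter_um",
]


def _stamp_disk(arr: np.ndarray, row: float, col: float, radius_px: float, value: float) -> None:
    """Add `value` over the disk of `radius_px` centred at (row, col).

    The edge is antialiased with a 1-px linear coverage ramp so the disk's
    effective radius is sub-pixel accurate regardless of centre placement.
    """
    h, w = arr.shape
    r0 = max(int(np.floor(row - radius_px)) - 2, 0)
    r1 = min(int(np.ceil(row + radius_px)) + 3, h)
    c0 = max(int(np.floor(col - radius_px)) - 2, 0)
    c1 = min(int(np.ceil(col + radius_px)) + 3, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    coverage = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    arr[r0:r1, c0:c1] += value * coverage


def render_slide(spec: SlideSpec) -> tuple[SlideImage, pd.DataFrame]:
    """Render a slide and return it with its planted ground-truth table.

    Raises ``RuntimeError`` if non-overlapping placement fails (too many
    cells for the slide area).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    channels = {ch: np.zeros((h, w), dtype=float) for ch in CHANNELS}

    placed_r: list[float] = []
    placed_c: list[float] = []
    placed_rad: list[float] = []
    records = []
    cell_id = 0
    for cls in spec.cell_classes:
        for _ in range(cls.count):
            d_nuc = max(rng.normal(cls.nuclear_diameter_mean, cls.nuclear_diameter_sd), 1.0)
            d_cell = max(rng.normal(cls.cell_diameter_mean, cls.cell_diameter_sd), d_nuc)
            r_cell_px = d_cell / 2.0 / spec.pixel_size
            r_nuc_px = d_nuc / 2.0 / spec.pixel_size
            margin = r_cell_px + MIN_GAP_PX
            if 2 * margin >= min(h, w):
                raise RuntimeError("cell too large for slide")
            for attempt in range(MAX_PLACEMENT_ATTEMPTS):
                row = rng.uniform(margin, h - margin)
                col = rng.uniform(margin, w - margin)
                if placed_r:
                    dr = np.asarray(placed_r) - row
                    dc = np.asarray(placed_c) - col
                    min_sep = np.asarray(placed_rad) + r_cell_px + MIN_GAP_PX
                    if np.any(dr * dr + dc * dc < min_sep * min_sep):
                        continue
                break
            else:
                raise RuntimeError(
                    f"could not place cell {cell_id} ({cls.label}) without overlap "
                    f"after {MAX_PLACEMENT_ATTEMPTS} attempts; slide too crowded"
                )
            placed_r.append(row)
            placed_c.append(col)
            placed_rad.append(r_cell_px)
            for ch, intensity in cls.channel_intensity.items():
                if intensity <= 0:
                    continue
                radius = r_nuc_px if ch == "DAPI" else r_cell_px
                _stamp_disk(channels[ch], row, col, radius, intensity)
            records.append(
                {
                    "cell_id": cell_id,
                    "label": cls.label,
                    "centroid_row": row,
                    "centroid_col": col,
                    "nuclear_diameter_um": d_nuc,
                    "cell_diameter_um": d_cell,
                }
            )
            cell_id += 1

    for ch in CHANNELS:
        img = channels[ch]
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma)
        img = img + spec.background_level
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0.0, None)

    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return SlideImage(channels=channels, pixel_size=spec.pixel_size), truth
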