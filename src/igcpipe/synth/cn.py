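"""Simulation of single-cell low-pass WGS bin counts from planted copy number.

Ground truth is an integer copy-number state per genomic bin, optionally
multiplied by a uniform whole-genome-doubling factor.  Per cell, a Poisson
total read count is distributed over bins by a multinomial whose
probabilities are proportional to copy state x bin length (x an optional
GC bias curve).  Because the probabilities are renormalized, a uniform WGD
factor leaves them — and hence the expected ratio profile — exactly
unchanged: WGD is invisible to ratio-normalized profiles by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from igcpipe.cnv import BinGrid

__all__ = ["CNGroundTruth", "simulate_cn_cells", "quadratic_gc_bias"]


@dataclasses.dataclass
class CNGroundTruth:
    """Planted per-bin copy-number states over a bin grid."""

    grid: BinGrid
    cn_states: np.ndarray
    wgd_factor: int = 1
    reads_per_cell: float = 500_000.0

    def __post_init__(self) -> None:
        self.cn_states = np.asarray(self.cn_states, dtype=np.int64)
        if len(self.cn_states) != len(self.grid):
            raise ValueError("cn_states length must match grid")
        if np.any(self.cn_states < 0):
            raise ValueError("cn_states must be >= 0")
        if self.wgd_factor < 1:
            raise ValueError("wgd_factor must be an integer >= 1")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")

    def bin_probabilities(self, gc_bias: Callable[[np.ndarray], np.ndarray] | None = None) -> np.ndarray:
        weights = self.cn_states.astype(float) * self.wgd_factor * self.grid.lengths
        if gc_bias is not None:
            weights = weights * np.clip(gc_bias(self.grid.gc), 0.0, None)
        total = weights.sum()
        if total <= 0:
            raise ValueError("all-zero copy-number states: no reads can be placed")
        return weights / total


def quadratic_gc_bias(peak_gc: float = 0.45, strength: float = 0.5) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone-in-|gc - peak| quadratic coverage bias curve (1 at the peak)."""

    def bias(gc: np.ndarray) -> np.ndarray:
        return np.clip(1.0 - strength * ((np.asarray(gc) - peak_gc) / 0.25) ** 2, 0.05, None)

    return bias


def simulate_cn_cells(
    truth: CNGroundTruth,
    n_cells: int,
    seed: int = 0,
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate per-cell bin counts (cells x bins DataFrame).

    Each cell's total read count is Poisson around ``truth.reads_per_cell``
    and is spread over bins multinomially with probabilities proportional to
    copy state x bin length (x optional GC bias).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    probs = truth.bin_probabilities(gc_bias)
    counts = np.empty((n_cells, len(truth.grid)), dtype=np.int64)
    for i in range(n_cells):
        total = rng.poisson(truth.reads_per_cell)
        counts[i] = rng.multinomial(total, probs)
    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    bins = [f"{c}:{s}-{e}" for c, s, e in zip(truth.grid.chrom, truth.grid.start, truth.grid.end)]
    return pd.DataFrame(counts, index=cells, columns=bins)
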