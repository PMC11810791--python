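"""Negative-binomial scRNA-seq count simulation with planted gene programs.

Emulates plate-based single-cell RNA-seq of drug-survivor cells: several
conditions (cell line x treatment), negative-binomial counts with a common
dispersion, log-normal baseline relative expression per gene, and planted
*programs* — gene sets whose relative expression is shifted by a fixed log2
fold change in a subset of conditions.  A shared "survivor" program active
in every treated condition plus line-specific programs reproduces the
nested intersection structure of a multi-condition differential-expression
analysis.

Program genes are given deliberately modest baseline expression so that
boosting them does not inflate a treated cell's library composition enough
to erode the measured CPM-scale fold change of other program genes; the
planted log2 fold change is a floor on the recoverable effect, not an exact
prediction of the CPM-scale estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Program", "RNAPreset", "simulate_rna_counts", "write_counts_mtx", "read_counts_mtx"]

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "TEC")


@dataclasses.dataclass
class Program:
    """A planted gene program: which genes, how strong, in which conditions."""

    name: str
    genes: np.ndarray  # integer gene indices
    lfc: float  # planted log2 fold change in affected conditions
    conditions: Sequence[str]

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)
        if len(self.genes) == 0:
            raise ValueError("program gene set is empty")
        if abs(self.lfc) < 3.0:
            raise ValueError(
                "planted |LFC| must be >= 3.0 so threshold recovery has no borderline cases"
            )


@dataclasses.dataclass
class RNAPreset:
    """Full specification of a synthetic scRNA-seq experiment."""

    n_genes: int
    conditions: Mapping[str, int]  # condition label -> cell count
    programs: Sequence[Program]
    dispersion: float = 0.1
    libsize_mean: float = 20_000.0
    libsize_sd: float = 2_000.0
    n_batches: int = 2
    biotype_table: pd.Series | None = None
    # baseline relative expression: lognormal for background genes,
    # uniform(low, high) for program genes (kept low; see module docstring)
    baseline_sigma: float = 1.2
    program_baseline: tuple[float, float] = (0.3, 0.8)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for cond, n in self.conditions.items():
            if n < 20:
                raise ValueError(f"condition {cond!r} has {n} cells; need >= 20")
        known = set(self.conditions)
        for prog in self.programs:
            if prog.genes.max(initial=-1) >= self.n_genes or prog.genes.min(initial=0) < 0:
                raise ValueError(f"program {prog.name!r} has genes outside the universe")
            unknown = set(prog.conditions) - known
            if unknown:
                raise ValueError(f"program {prog.name!r} names unknown conditions {unknown}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{i:05d}" for i in range(self.n_genes)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + np.clip(mean, 1e-12, None))
    return rng.negative_binomial(size, p)


def simulate_rna_counts(
    preset: RNAPreset, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts for all conditions of a preset.

    Returns ``(counts, cell_meta, gene_meta)``: a genes x cells integer
    DataFrame, per-cell metadata (``condition``, ``batch``), and per-gene
    metadata (``biotype`` plus planted-program membership).
    """
    rng = np.random.default_rng(seed)
    n_genes = preset.n_genes

    base = rng.lognormal(mean=0.0, sigma=preset.baseline_sigma, size=n_genes)
    program_genes = np.unique(np.concatenate([p.genes for p in preset.programs])) if preset.programs else np.array([], dtype=np.int64)
    if program_genes.size:
        lo, hi = preset.program_baseline
        base[program_genes] = rng.uniform(lo, hi, size=program_genes.size)

    # per-condition relative expression with planted boosts
    cond_expr = {}
    for cond in preset.conditions:
        expr = base.copy()
        for prog in preset.programs:
            if cond in prog.conditions:
                expr[prog.genes] = expr[prog.genes] * 2.0**prog.lfc
        cond_expr[cond] = expr

    gene_ids = preset.gene_ids
    all_counts, cells, conds, batches = [], [], [], []
    cell_idx = 0
    for cond, n_cells in preset.conditions.items():
        expr = cond_expr[cond]
        probs = expr / expr.sum()
        for _ in range(n_cells):
            lib = max(rng.normal(preset.libsize_mean, preset.libsize_sd), 1000.0)
            batch = cell_idx % preset.n_batches
            # mild batch effect on depth only; composition is batch-free
            lib = lib * (1.0 + 0.15 * batch)
            counts = _nb_sample(rng, lib * probs, preset.dispersion)
            all_counts.append(counts)
            cells.append(f"cell_{cell_idx:04d}")
            conds.append(cond)
            batches.append(batch)
            cell_idx += 1

    counts = pd.DataFrame(np.column_stack(all_counts), index=gene_ids, columns=cells)
    cell_meta = pd.DataFrame({"cell_id": cells, "condition": conds, "batch": batches}).set_index(
        "cell_id"
    )
    if preset.biotype_table is not None:
        biotypes = preset.biotype_table.reindex(gene_ids).fillna("TEC")
    else:
        biotypes = pd.Series("protein_coding", index=gene_ids)
    gene_meta = pd.DataFrame({"biotype": biotypes})
    in_prog = np.zeros(n_genes, dtype=object)
    in_prog[:] = ""
    for prog in preset.programs:
        for g in prog.genes:
            in_prog[g] = (in_prog[g] + "+" + prog.name) if in_prog[g] else prog.name
    gene_meta["program"] = in_prog
    return counts, cell_meta, gene_meta


def write_counts_mtx(counts: pd.DataFrame, cell_meta: pd.DataFrame,
                     gene_meta: pd.DataFrame, outdir) -> None:
    """Write counts as MatrixMarket with genes.tsv / cells.tsv sidecars."""
    from pathlib import Path

    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    gene_meta.reindex(counts.index).to_csv(outdir / "genes.tsv", sep="\t")
    cell_meta.reindex(counts.columns).to_csv(outdir / "cells.tsv", sep="\t")


def read_counts_mtx(indir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a counts directory written by :func:`write_counts_mtx`."""
    from pathlib import Path

    from scipy import io as spio

    indir = Path(indir)
    gene_meta = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    cell_meta = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    mat = spio.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    counts = pd.DataFrame(mat, index=gene_meta.index, columns=cell_meta.index)
    return counts, cell_meta, gene_meta
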