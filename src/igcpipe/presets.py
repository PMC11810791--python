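"""Named presets: fixed study conditions for the synthetic generators.

Presets are YAML files shipped with the package (``igcpipe/presets/``).
Each loader turns a preset (by name or path) into the generator objects the
analysis runs on.  The headline counts — 3/31 and 25/31 IGC-positive
samples, program sizes 309/1282/869, biotype split 238+53+12+6 — are fixed
here; they are the unique integer compositions consistent with the cohort
percentages (9.7%, 80.6%) and intersection sizes (1591, 1178, 309) the
analysis is designed to recover.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from igcpipe.cnv import BinGrid
from igcpipe.synth.cn import CNGroundTruth
from igcpipe.synth.cohort import CohortPreset
from igcpipe.synth.rna import Program, RNAPreset

__all__ = [
    "load_preset",
    "cohort_preset",
    "cohort_preset_A",
    "signature_preset",
    "signature_preset_A",
    "signature_lines",
    "signature_controls",
    "pc3_cn_preset",
    "rna_null_preset",
    "autosome_grid",
]

#: Approximate autosome lengths in Mb (GRCh38 scale), chr1..chr22.
AUTOSOME_MB = [
    248, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135,
    133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51,
]


def load_preset(name_or_path: str) -> dict:
    """Load a preset YAML by shipped name (e.g. ``cohort_preset_A``) or path."""
    p = Path(str(name_or_path))
    if p.suffix in {".yaml", ".yml"} and p.exists():
        text = p.read_text()
    else:
        res = importlib.resources.files("igcpipe") / "presets" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(f"unknown preset {name_or_path!r}")
        text = res.read_text()
    return yaml.safe_load(text)


def cohort_preset(name_or_path: str = "cohort_preset_A") -> CohortPreset:
    """Build a cohort preset from a shipped name or a YAML path."""
    cfg = load_preset(name_or_path)
    if cfg.pop("kind", "cohort") != "cohort":
        raise ValueError(f"{name_or_path!r} is not a cohort preset")
    return CohortPreset(**cfg)


def cohort_preset_A() -> CohortPreset:
    """The matched 31 + 13 patient cohort with 3 blood / 25 marrow positives."""
    return cohort_preset("cohort_preset_A")


def autosome_grid(bin_size: int = 600_000) -> BinGrid:
    """A uniform bin grid over the 22 autosomes with smooth synthetic GC."""
    chroms, starts, ends = [], [], []
    for i, mb in enumerate(AUTOSOME_MB, start=1):
        length = mb * 1_000_000
        n_bins = length // bin_size
        s = np.arange(n_bins) * bin_size
        chroms.extend([f"chr{i}"] * n_bins)
        starts.extend(s.tolist())
        ends.extend((s + bin_size).tolist())
    idx = np.arange(len(chroms))
    gc = 0.45 + 0.05 * np.sin(idx / 37.0)  # smooth, deterministic GC track
    return BinGrid(np.array(chroms, dtype=object), np.array(starts), np.array(ends), gc)


def pc3_cn_preset(wgd_factor: int | None = None, name_or_path: str = "pc3_cn_preset") -> CNGroundTruth:
    """PC3-like ground truth: chr1 state 3, chr10 state 1, 2 elsewhere."""
    cfg = load_preset(name_or_path)
    grid = autosome_grid(cfg["bin_size"])
    states = np.full(len(grid), cfg["baseline_state"], dtype=np.int64)
    states[grid.chrom == "chr1"] = cfg["chr1_state"]
    states[grid.chrom == "chr10"] = cfg["chr10_state"]
    return CNGroundTruth(
        grid=grid,
        cn_states=states,
        wgd_factor=wgd_factor if wgd_factor is not None else cfg["wgd_factor"],
        reads_per_cell=cfg["reads_per_cell"],
    )


def _biotype_table(cfg: dict, n_genes: int, shared: np.ndarray) -> pd.Series:
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    biotypes = pd.Series("protein_coding", index=gene_ids)
    # the rest of the transcriptome: a plausible Gencode-like mixture
    rest = np.setdiff1d(np.arange(n_genes), shared)
    n_rest = len(rest)
    rest_bt = np.array(
        ["protein_coding"] * int(0.55 * n_rest)
        + ["lncRNA"] * int(0.30 * n_rest)
        + ["pseudogene"] * int(0.10 * n_rest)
    )
    rest_bt = np.concatenate([rest_bt, ["TEC"] * (n_rest - len(rest_bt))])
    biotypes.iloc[rest] = rest_bt
    # the shared survivor program gets the fixed 238/53/12/6 composition
    assign = []
    for bt, n in cfg["shared_biotypes"].items():
        assign.extend([bt] * n)
    if len(assign) != len(shared):
        raise ValueError("shared_biotypes must sum to the shared program size")
    biotypes.iloc[shared] = assign
    return biotypes


def signature_preset(name_or_path: str = "signature_preset_A") -> RNAPreset:
    """Two lines x two drugs with nested shared/line-specific programs."""
    cfg = load_preset(name_or_path)
    n_genes = cfg["n_genes"]
    n_shared = cfg["shared_program_size"]
    n_mda = cfg["mda_specific_size"]
    n_pc3 = cfg["pc3_specific_size"]
    shared = np.arange(0, n_shared)
    mda = np.arange(n_shared, n_shared + n_mda)
    pc3 = np.arange(n_shared + n_mda, n_shared + n_mda + n_pc3)
    lfc = cfg["planted_lfc"]
    treated = {line: list(comps) for line, comps in cfg["lines"].items()}
    programs = [
        Program("shared_survivor", shared, lfc, treated["MDA"] + treated["PC3"]),
        Program("mda_specific", mda, lfc, treated["MDA"]),
        Program("pc3_specific", pc3, lfc, treated["PC3"]),
    ]
    return RNAPreset(
        n_genes=n_genes,
        conditions={c: cfg["cells_per_condition"] for c in cfg["conditions"]},
        programs=programs,
        dispersion=cfg["dispersion"],
        libsize_mean=cfg["libsize_mean"],
        libsize_sd=cfg["libsize_sd"],
        n_batches=cfg["n_batches"],
        biotype_table=_biotype_table(cfg, n_genes, shared),
    )


def signature_preset_A() -> RNAPreset:
    return signature_preset("signature_preset_A")


def signature_lines(name_or_path: str = "signature_preset_A") -> dict:
    """Comparison-key grouping (line -> treated conditions) for the preset."""
    cfg = load_preset(name_or_path)
    return {line: list(c) for line, c in cfg["lines"].items()}


def signature_controls(name_or_path: str = "signature_preset_A") -> dict:
    cfg = load_preset(name_or_path)
    return dict(cfg["controls"])


def rna_null_preset(n_genes: int = 2000, n_cells: int = 40) -> RNAPreset:
    """Two identical conditions, no programs: the null for FDR calibration."""
    return RNAPreset(
        n_genes=n_genes,
        conditions={"CTRL": n_cells, "TREAT": n_cells},
        programs=[],
        dispersion=0.1,
        libsize_mean=20_000.0,
        libsize_sd=2_000.0,
        n_batches=2,
    )
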