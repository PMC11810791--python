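"""End-to-end orchestration: generation -> imaging -> classification ->
copy number -> transcriptome -> survival, with a validated configuration
and a JSON report.

The stages are independently importable; this module wires them together
for the full synthetic study run and for the numbered analysis scripts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from igcpipe import classify, cnv, imaging, presets, survival, transcriptome
from igcpipe.synth import simulate_cn_cells, simulate_cohort, simulate_rna_counts
from igcpipe.synth.slides import SlideSpec, render_slide

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_slide",
    "process_slide_spec",
    "run_cohort_stage",
    "run_cn_stage",
    "run_rna_stage",
    "PipelineReport",
]

log = logging.getLogger("igcpipe")


# --------------------------------------------------------------------------
# configuration

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "cohort_preset",
    "signature_preset",
    "cn_preset",
    "cn_cells_per_group",
    "segmentation",
    "classification",
    "de",
}
_KNOWN_SEGMENTATION = {"block_size", "offset", "min_area", "open_radius"}
_KNOWN_CLASSIFICATION = {"k", "igc_factor", "reference"}
_KNOWN_DE = {"lfc_thresh", "fdr_thresh", "min_detect"}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 17
    outdir: str | None = None
    cohort_preset: str = "cohort_preset_A"
    signature_preset: str = "signature_preset_A"
    cn_preset: str = "pc3_cn_preset"
    cn_cells_per_group: int = 3
    segmentation: dict = dataclasses.field(default_factory=dict)
    classification: dict = dataclasses.field(default_factory=dict)
    de: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, block, known in [
            ("segmentation", self.segmentation, _KNOWN_SEGMENTATION),
            ("classification", self.classification, _KNOWN_CLASSIFICATION),
            ("de", self.de, _KNOWN_DE),
        ]:
            unknown = set(block) - known
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# report schema

class CohortSection(BaseModel):
    n_matched: int
    n_marrow_only: int
    blood_positive: int
    marrow_positive_matched: int
    blood_positive_pct: float
    marrow_positive_pct: float
    detection_errors: int
    logrank_chi2: float
    logrank_p: float
    km_median_pos: float | None
    km_median_neg: float | None


class CNSection(BaseModel):
    n_cells: int
    wgd_concordance_min: float
    chr1_segment_ratio_mean: float
    chr10_segment_ratio_mean: float
    group_medians: dict[str, float]


class RNASection(BaseModel):
    comparison_up_sizes: dict[str, int]
    line_set_sizes: dict[str, int]
    survivor_set_size: int
    biotype_percent: dict[str, int]


class PipelineReport(BaseModel):
    """Schema of the end-to-end run report (also shipped as JSON schema)."""

    config: dict
    seeds: dict[str, int]
    timings_s: dict[str, float]
    cohort: CohortSection
    copy_number: CNSection
    transcriptome: RNASection


# --------------------------------------------------------------------------
# slide-level workflow

def analyze_slide(
    image: imaging.SlideImage,
    segmentation: dict | None = None,
    classification: dict | None = None,
) -> pd.DataFrame:
    """Segment one slide, extract cells, and call classes + IGC flags.

    The default threshold offset is calibrated to the synthetic presets'
    stain contrast (~1/3 of the 3000-unit signal) so the adaptive threshold
    crosses at the disk edge and equivalent diameters are sub-pixel
    accurate; pass ``segmentation={"offset": ...}`` for other contrasts.
    """
    seg = {"offset": 1000.0, **(segmentation or {})}
    cls_cfg = dict(classification or {})
    masks = {
        ch: imaging.segment_channel(image.channel(ch), channel_name=ch, **seg)
        for ch in image.channels
    }
    cell_mask = imaging.merge_masks(list(masks.values()))
    records = imaging.extract_cells(cell_mask, masks["DAPI"], image)
    background = imaging.estimate_background(image, cell_mask)
    thresholds = classify.PositivityThresholds.from_background(
        background, k=cls_cfg.pop("k", 5.0)
    )
    calls = classify.call_cells(records, thresholds)
    calls = classify.flag_igc(
        calls,
        factor=cls_cfg.pop("igc_factor", 2.0),
        reference=cls_cfg.pop("reference", "median"),
    )
    return calls


def process_slide_spec(
    spec: SlideSpec,
    segmentation: dict | None = None,
    classification: dict | None = None,
) -> tuple[bool, pd.DataFrame, pd.DataFrame]:
    """Render one slide spec and run the detection pipeline on it.

    Returns ``(igc_positive, calls, ground_truth)``.
    """
    image, truth = render_slide(spec)
    calls = analyze_slide(image, segmentation, classification)
    return classify.sample_positivity(calls), calls, truth


# --------------------------------------------------------------------------
# stages

def run_cohort_stage(config: RunConfig, seed: int) -> dict:
    """Cohort generation + imaging pipeline + positivity + survival."""
    preset = presets.cohort_preset(config.cohort_preset)
    cohort, slides = simulate_cohort(preset, seed=seed)
    det_blood, det_marrow, errors = {}, {}, 0
    for pid, comp in slides.items():
        if comp["blood"] is not None:
            pos, _, _ = process_slide_spec(comp["blood"], config.segmentation, config.classification)
            det_blood[pid] = pos
        pos, _, _ = process_slide_spec(comp["marrow"], config.segmentation, config.classification)
        det_marrow[pid] = pos
    cohort = cohort.copy()
    cohort["blood_igc_detected"] = cohort["patient_id"].map(det_blood)
    cohort["marrow_igc_detected"] = cohort["patient_id"].map(det_marrow)
    errors += int(
        (cohort["marrow_igc_detected"] != cohort["marrow_igc_truth"]).sum()
    )
    matched = cohort[cohort["matched"]]
    errors += int(
        (matched["blood_igc_detected"] != matched["blood_igc_truth"]).sum()
    )
    n_matched = len(matched)
    blood_pos = int(matched["blood_igc_detected"].sum())
    marrow_pos = int(matched["marrow_igc_detected"].sum())

    chi2, p = survival.logrank_test(
        cohort["pfs_months"], cohort["event"], cohort["marrow_igc_detected"].astype(bool)
    )
    curves = survival.km_by_group(
        cohort.rename(
            columns={"marrow_igc_detected": "group", "pfs_months": "time"}
        )[["group", "time", "event"]]
    )

    def _median(curve: survival.KMCurve) -> float | None:
        below = curve.times[curve.survival <= 0.5]
        return float(below[0]) if below.size else None

    return {
        "cohort_table": cohort,
        "curves": curves,
        "summary": {
            "n_matched": n_matched,
            "n_marrow_only": int((~cohort["matched"]).sum()),
            "blood_positive": blood_pos,
            "marrow_positive_matched": marrow_pos,
            "blood_positive_pct": round(100.0 * blood_pos / n_matched, 1),
            "marrow_positive_pct": round(100.0 * marrow_pos / n_matched, 1),
            "detection_errors": errors,
            "logrank_chi2": chi2,
            "logrank_p": p,
            "km_median_pos": _median(curves[True]) if True in curves else None,
            "km_median_neg": _median(curves[False]) if False in curves else None,
        },
    }


def run_cn_stage(config: RunConfig, seed: int) -> dict:
    """Copy-number stage: diploid-scale vs WGD cells, ratios, concordance."""
    truth = presets.pc3_cn_preset(name_or_path=config.cn_preset)
    truth_wgd = presets.pc3_cn_preset(wgd_factor=2, name_or_path=config.cn_preset)
    n = config.cn_cells_per_group
    counts = simulate_cn_cells(truth, n_cells=n, seed=seed)
    counts_wgd = simulate_cn_cells(truth_wgd, n_cells=n, seed=seed + 1)
    profiles, labels = [], []
    for name, frame, lab in [("base", counts, "typical"), ("wgd", counts_wgd, "wgd")]:
        for cell, row in frame.iterrows():
            prof = cnv.normalize_ratios(row.to_numpy(), truth.grid, cell_id=f"{name}_{cell}")
            profiles.append(cnv.segment_profile(prof, seed=seed))
            labels.append(lab)
    mat = cnv.concordance_matrix(profiles, labels)
    gtest = cnv.group_concordance_test(mat, "typical", "wgd")
    chr1 = truth.grid.chrom == "chr1"
    chr10 = truth.grid.chrom == "chr10"
    chr1_mean = float(np.mean([p.segment_ratio[chr1].mean() for p in profiles]))
    chr10_mean = float(np.mean([p.segment_ratio[chr10].mean() for p in profiles]))
    # paired WGD invariance: a cell vs its exactly doubled self
    doubled = cnv.normalize_ratios(2 * counts.iloc[0].to_numpy(), truth.grid, cell_id="doubled")
    doubled = cnv.segment_profile(doubled, seed=seed)
    paired = cnv.concordance(profiles[0], doubled)
    return {
        "matrix": mat,
        "group_test": gtest,
        "summary": {
            "n_cells": 2 * n,
            "wgd_concordance_min": float(paired),
            "chr1_segment_ratio_mean": chr1_mean,
            "chr10_segment_ratio_mean": chr10_mean,
            "group_medians": gtest["medians"],
        },
    }


def run_rna_stage(config: RunConfig, seed: int) -> dict:
    """Transcriptome stage: DE per comparison, intersections, biotypes."""
    preset = presets.signature_preset(config.signature_preset)
    lines = presets.signature_lines(config.signature_preset)
    controls = presets.signature_controls(config.signature_preset)
    counts, cell_meta, gene_meta = simulate_rna_counts(preset, seed=seed)
    de_cfg = dict(config.de)
    lfc_thresh = de_cfg.pop("lfc_thresh", 1.5)
    fdr_thresh = de_cfg.pop("fdr_thresh", 0.01)
    de_results = {}
    for line, comps in lines.items():
        for comp in comps:
            de_results[comp] = transcriptome.de_test(
                counts,
                cell_meta["condition"],
                controls[line],
                comp,
                batch=cell_meta["batch"],
                **de_cfg,
            )
    shared = transcriptome.shared_upregulated(de_results, lines, lfc_thresh, fdr_thresh)
    bt = transcriptome.biotype_breakdown(shared.survivor_set, gene_meta["biotype"])
    bt_pct = dict(zip(bt["biotype"], bt["percent_int"].astype(int)))
    return {
        "de_results": de_results,
        "shared": shared,
        "biotypes": bt,
        "summary": {
            "comparison_up_sizes": {k: len(v) for k, v in shared.up_sets.items()},
            "line_set_sizes": {k: len(v) for k, v in shared.line_sets.items()},
            "survivor_set_size": len(shared.survivor_set),
            "biotype_percent": bt_pct,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(["cohort", "cn", "rna"], ss.spawn(3))
    }
    log.info("effective config: %s", json.dumps(config.to_dict()))
    log.info("stage seeds: %s", stage_seeds)
    timings: dict[str, float] = {}
    results: dict[str, Any] = {}
    for name, fn in [
        ("cohort", run_cohort_stage),
        ("cn", run_cn_stage),
        ("rna", run_rna_stage),
    ]:
        t0 = _time.perf_counter()
        try:
            results[name] = fn(config, stage_seeds[name])
        except Exception as exc:  # noqa: BLE001 - aborting with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(_time.perf_counter() - t0, 3)
        log.info("stage %s finished in %.1fs", name, timings[name])

    report = PipelineReport(
        config=config.to_dict(),
        seeds=stage_seeds,
        timings_s=timings,
        cohort=CohortSection(**results["cohort"]["summary"]),
        copy_number=CNSection(**results["cn"]["summary"]),
        transcriptome=RNASection(**results["rna"]["summary"]),
    )
    out = {"report": report, **results}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.model_dump()
        # the written report is the reproducible part: wall-clock timings and
        # the output path itself are excluded so re-runs are byte-identical
        payload.pop("timings_s", None)
        payload["config"] = {k: v for k, v in payload["config"].items() if k != "outdir"}
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        (outdir / "report.txt").write_text(_human_report(report))
        results["cohort"]["cohort_table"].to_csv(outdir / "cohort_table.csv", index=False)
    return out


def _human_report(report: PipelineReport) -> str:
    c, cn, rna = report.cohort, report.copy_number, report.transcriptome
    lines = [
        "igcpipe end-to-end run",
        "======================",
        f"matched patients: {c.n_matched} (+{c.n_marrow_only} marrow-only)",
        f"blood IGC positivity: {c.blood_positive}/{c.n_matched} = {c.blood_positive_pct}%",
        f"marrow IGC positivity: {c.marrow_positive_matched}/{c.n_matched} = {c.marrow_positive_pct}%",
        f"detection errors vs planted truth: {c.detection_errors}",
        f"log-rank (marrow IGC+ vs IGC-): chi2 = {c.logrank_chi2:.2f}, p = {c.logrank_p:.2e}",
        "",
        f"copy number ({cn.n_cells} cells): paired WGD concordance = {cn.wgd_concordance_min:.4f}",
        f"  chr1 segment ratio mean = {cn.chr1_segment_ratio_mean:.3f} (planted 1.5)",
        f"  chr10 segment ratio mean = {cn.chr10_segment_ratio_mean:.3f} (planted 0.5)",
        "",
        f"survivor signature: line sets {rna.line_set_sizes}, shared {rna.survivor_set_size} genes",
        f"  biotypes of shared set (%): {rna.biotype_percent}",
    ]
    return "\n".join(lines) + "\n"


def export_report_schema(path) -> None:
    """Write the pipeline report's JSON schema next to the package docs."""
    Path(path).write_text(json.dumps(PipelineReport.model_json_schema(), indent=2))
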