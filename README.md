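# igcpipe

Analysis pipeline for **polyploid circulating tumor cells with increased
genomic content (CTC-IGC)** in liquid biopsies, for researchers studying
chemotherapy-surviving polyploid/giant cancer cells. The package covers the
full computational chain around this cell state:

1. **Slide morphometry** — multi-channel immunofluorescence slides
   (DAPI / epithelial cocktail / CD45 / variable marker) are segmented per
   channel with adaptive thresholding, merged into a cell mask, and each
   cell's nucleus (its component ∩ the DAPI mask) is measured by the
   *equivalent diameter* `d = s·√(4A/π)` (pixel size `s`, nuclear area `A`).
2. **CTC-IGC calling** — cells are classed as WBC (CD45⁺), CTC (EPI⁺ CD45⁻),
   marker-only (EPI⁻ CD45⁻ VAR⁺), or other; a CTC is flagged *IGC* when
   `d_nuc ≥ 2·d_ref`, where `d_ref` is the median nuclear diameter of the
   sample's CTC population. A sample is IGC-positive when it holds ≥1
   flagged CTC.
3. **Copy-number ratio profiles** — single-cell low-pass WGS bin counts are
   length-normalized and scaled to genome-median 1, segmented by recursive
   binary splitting with permutation testing, and compared cell-to-cell by
   Pearson concordance of log₂ segmented ratios. Ratio profiles are
   invariant to whole-genome doubling by construction, which is exactly why
   WGD cells look copy-number-normal in this representation.
4. **Survivor signature** — per treated condition, differential expression
   vs control (stratified Wilcoxon rank-sum on log₂ CPM, batches combined by
   Stouffer, Benjamini–Hochberg FDR); up-gene sets at `LFC > 1.5, FDR < 0.01`
   are intersected across drugs within each cell line and then across lines
   into a shared *survivor set*, characterized by biotype, Fisher
   over-representation, and a rank-based per-cell signature score.
5. **Survival** — Kaplan–Meier + two-group log-rank association of IGC
   positivity with progression-free survival.

Because patient slides and sequencing are not redistributable, a first-class
**synthetic data generator** (`igcpipe.synth`) produces slides, bin counts,
scRNA counts and cohorts with planted ground truth, under fixed named
presets, so every stage is tested by exact recovery of known structure.

## Worked example

```bash
python analysis/01_cohort_igc_positivity.py
```

prints (seed 17):

```
Matched patients: 31 | marrow-only: 13
Blood CTC-IGC positivity:  3/31 = 9.7%
Marrow CTC-IGC positivity: 25/31 = 80.6%
Detection errors vs planted truth: 0
Log-rank, marrow IGC+ vs IGC- PFS: chi2 = 7.08, p = 7.80e-03
```

Three of 31 matched patients carry a planted IGC cell on their blood slide
and 25 of 31 on their marrow slide; the imaging → classification pipeline
re-detects *exactly* those samples from pixels alone (0 errors), and the
marrow-positive group shows significantly shorter progression-free survival.
`analysis/02_copy_number_wgd.py` and `analysis/03_survivor_signature.py`
likewise report recovered segment ratios (1.49 / 0.50 against planted
1.5 / 0.5, doubled-cell concordance 1.0000) and the survivor-signature
intersection (line sets 1591 and 1178 genes, shared set 309, 77% protein
coding / 17% lncRNA). `analysis/04_full_report.py` chains everything into
one schema-validated JSON report under `results/full_run/`.

## Layout

- `src/igcpipe/` — library: `synth`, `imaging`, `classify`, `cnv`,
  `transcriptome`, `survival`, `pipeline`, `presets` (+ shipped YAML presets)
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property and end-to-end recovery suites
- `docs/methods.md` — models, parameter choices, and known limitations
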