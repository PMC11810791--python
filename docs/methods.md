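# Methods

This note documents the models implemented in `igcpipe`, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Slide model and segmentation

A slide is a set of co-registered 2-D intensity channels (DAPI, an
epithelial antibody cocktail "EPI", CD45, and a variable marker channel
"VAR") with a physical pixel size in µm. Segmentation is per channel:
a pixel is foreground when its intensity exceeds the local arithmetic mean
over a `block_size` window by more than `offset`; the mask is cleaned by a
morphological opening (disk radius `open_radius`, default 1 px) and
components below `min_area` (default 20 px²) are dropped. Defaults
`block_size = 51`, `offset = 10` suit flat-background fluorescence at low
contrast. Per-channel masks are merged by pixel-wise union into the cell
mask; connected components of that union are cells; each cell's nuclear
region is its component intersected with the DAPI mask (no watershed
splitting — the generator guarantees non-touching cells, and splitting
overlapping cells is out of scope). Cells with an empty nuclear region are
kept and flagged anucleate; border-touching components are kept and
flagged, since dropping them would bias size statistics.

The size statistic is the *equivalent diameter* of the nuclear area,
`d = pixel_size · sqrt(4·A/π)`, i.e. the diameter of the circle with that
area, reported in µm so downstream thresholds are magnification-free.

**Operating point for the synthetic presets.** The presets render stains at
~3000 intensity units over a 200-unit background. At that contrast the
1-px-blurred disk edge crosses `local mean + offset` well outside the true
edge when `offset` is small, inflating diameters by ~3 px; the pipeline's
slide-analysis entry point therefore uses `offset = 1000` (≈ one third of
the stain signal), where the threshold crosses at the disk edge. Measured
per-cell nuclear-diameter error is then ≤ 0.9 px (6,156 cells, 12 slides)
at the presets' noise level. For other data the offset is a config knob
(`segmentation: {offset: ...}`); the rule of thumb is one third of the
stain-to-background contrast.

## Cell classification and the IGC rule

Positivity per channel is background-relative — mean intensity above
`background mean + k·SD` with `k = 5` — because absolute units are
scanner-specific. Class rules, in order: DAPI⁻ → OTHER; CD45⁺ → WBC
(exclusion marker dominates); EPI⁺ → CTC; VAR⁺ → MARKER_ONLY; else OTHER.

A CTC is *IGC* ("increased genomic content") when its nuclear equivalent
diameter is at least `2×` a reference diameter for the sample's CTC
population. The reference is the **median** over all CTC-class cells of
the sample (including candidate IGC cells): a plain mean is dragged upward
by the very cells the rule should detect, making "double the average"
ill-posed without iteration; the median is stable in the realistic regime
where IGC cells are a minority. A 20%-trimmed-mean dialect is provided
(`reference="trimmed_mean"`). The reference is computed per sample (one
patient compartment), not per cohort. MARKER_ONLY cells passing the size
rule are reported but never count toward sample positivity — a cell
positive only for the variable marker cannot be conclusively called
tumor-derived. The flag is scale-invariant by construction.

Size-gated sorting (`select_largest_fraction`) keeps records at or above
the `1 − fraction` quantile of cell equivalent diameter, ties included, so
a 15% gate on equal-sized cells keeps everything rather than an arbitrary
subset.

## Copy-number ratios, segmentation, concordance

Bin counts over a fixed grid (0-based half-open, with GC fraction) are
divided by bin length and scaled so the genome-wide median is 1: ratio 1 is
copy-neutral *relative to the cell's own genome*. This makes profiles
invariant to depth and to uniform whole-genome doubling — the representation
in which WGD cells are indistinguishable from their diploid-scale parents,
which is the analysis's central observation. An optional coarse GC
correction divides by a GC-decile median curve before scaling.

Segmentation is recursive binary splitting per chromosome on
`log2(ratio + 0.01)` (the pseudo-ratio keeps empty bins finite): the
candidate breakpoint maximizes the pooled two-sample t statistic (computed
by cumulative sums; a numerically-cancelled zero pooled variance is clamped
to 0 so a perfect split ranks as t = ∞), and is accepted when a
1,000-permutation within-segment test gives p < `alpha` (default 0.01) with
both sides ≥ `min_bins` (default 5). Segment ratios are segment means of
the linear ratio. On noise-free steps the breakpoint is exact; on simulated
reads at ≥100 reads/bin, planted 3:2 and 1:2 segment ratios are recovered
within a few percent.

Concordance between two cells is the Pearson correlation of per-bin log₂
segmented ratios (Spearman available as a dialect); it is symmetric,
invariant to per-profile uniform scaling, and undefined (NaN) for flat
profiles. Group comparisons test within-A, within-B and cross-group
pairwise concordance distributions by two-sided Wilcoxon rank-sum with Holm
correction across the three comparisons (only 3 tests; conservative and
simple). All-tied comparisons are reported as p = 1.

## Differential expression and the survivor intersection

Counts are normalized to `log2(1 + CPM)`. Per comparison
(treated vs its line's control), per gene:

- **LFC** = difference of group means of log₂(CPM+1) (pseudocount 1 keeps
  it finite);
- **p** from a two-sided Wilcoxon rank-sum with tie correction, computed
  within each sequencing-batch stratum and combined by Stouffer weighting
  √n (how batches were "controlled for" is an open choice; stratification
  makes the test valid under any batch-specific location shift);
- **q** by Benjamini–Hochberg over tested genes; genes expressed in <10%
  of cells in both groups are excluded before testing (standard sparsity
  guard).

This self-contained rank-based procedure deliberately replaces
quasi-likelihood count-model pipelines: the analysis is designed around
clearly separated planted effects (|LFC| ≥ 3), where threshold recovery is
insensitive to the choice of test, and a rank test needs no dispersion
estimation. "LFC > 1.5" is interpreted on the log₂ scale (≈2.8-fold); a
linear fold-change dialect is available via the threshold argument.

Up-sets (`LFC > 1.5` and `q < 0.01`) are intersected across the two drugs
within each line, then across lines into the survivor set. The operation is
order-invariant and monotone: relaxing either threshold never shrinks a
reported set. Biotype breakdown reports percentages (unannotated genes
count as TEC); over-representation is a one-sided Fisher exact test per
library set against the user-supplied universe with BH across sets.

**Signature scoring** follows the structure of rank-based single-cell
gene-set scoring: per cell, among expressed genes (count > 0), the mean
rank of expressed signature genes divided by the number of expressed genes;
and the odds ratio of being expressed for signature vs non-signature genes
(Haldane-corrected with +0.5 so empty cells stay finite). Each component is
min–max scaled across cells and the two are averaged, giving a score in
[0, 1]. Degenerate scaling (constant component, or a single cell) fixes the
component at 0.5 with a warning.

## Survival

Kaplan–Meier product-limit estimation with Greenwood pointwise variance and
the standard two-group log-rank test (hypergeometric variance, 1-df
chi-square) are implemented directly; ties at an event time use the
simultaneous-death convention and censoring at an event time is placed
after the event. With no censoring the estimator equals the empirical
survival function exactly; under equal hazards the log-rank p-value is
uniform (checked by simulation against a KS test). A median-split utility
supports binary expression grouping. Cox regression and multivariable
adjustment are out of scope.

## Synthetic generators: what they emulate, what they do not

All generators are fully determined by their seeds (fixed seed ⇒
byte-identical output).

**Slides.** Cells are hard disks (cytoplasmic stains over the cell disk,
DAPI over a concentric nuclear disk) with 1-px antialiased edges, softened
by a σ = 1 px Gaussian blur, over a flat background with Gaussian read
noise — deterministic and fast, sufficient to exercise thresholding and
morphometry. No realistic PSF, no illumination gradients, no overlapping or
doublet cells (placement is rejection sampling with a 10,000-attempt cap
and a 4-px clearance; overcrowded specs fail loudly). Default morphologies:
WBC nuclei 8 µm, typical CTC nuclei 12 µm, IGC nuclei 30 µm (2.5× the CTC
mean, comfortably above the 2× rule so planted and detected sets coincide),
stains at 3000 units over background 200, noise SD 5. The 500 WBC per
slide is an arbitrary plating-density placeholder. Passing tests show the
pipeline recovers planted geometry under these idealized optics — not that
it would segment real scanner images without retuning.

**Cohort (`cohort_preset_A`).** 31 matched patients (blood + marrow
slides) and 13 marrow-only patients. Exactly 3 of 31 blood and 25 of 31
marrow slides carry planted IGC cells — the unique integer counts whose
percentages round to 9.7% and 80.6% — with blood positives a subset of
marrow positives (marrow is the more sensitive compartment). Ten of the 13
marrow-only patients are positive (a chosen value in the same high-marrow
range; nothing downstream pins it). PFS is exponential per positivity
group (0.12 vs 0.04 progressions/month, a hazard ratio of 3 in the regime
where n = 44 gives good log-rank power); with probability `censor_rate`
(0.2) a patient is instead censored at a uniform time before their event.
This is the simplest model exposing the KM/log-rank contract — no accrual,
no competing risks, no informative censoring.

**Copy number (`pc3_cn_preset`).** ~4,800 bins of 600 kb over the 22
autosomes (GRCh38-scale lengths), planted states: chromosome 1 at copy 3,
chromosome 10 at copy 1, diploid elsewhere, matching the cell line's known
FISH ploidies; 500,000 reads per cell (≈100 per bin). Reads are multinomial
over bins with probabilities ∝ state × length (× an optional quadratic GC
bias used only to test the correction), totals Poisson. Because
probabilities are renormalized, the WGD factor cancels exactly — the
generator enforces, not merely suggests, the ratio-invariance the analysis
relies on.

**scRNA (`signature_preset_A`).** Negative-binomial counts
(dispersion 0.1, library size ~N(20,000, 2,000), 2 depth-shifted batches)
over 6,000 genes and six conditions (two lines × {control, docetaxel-like,
cisplatin-like}, 60 cells each). Planted programs at log₂ FC 3.0: a
309-gene program up in all four treated conditions, a 1,282-gene MDA-only
program and an 869-gene PC3-only program, giving line intersections
309+1282 = 1591 and 309+869 = 1178 and a cross-line survivor set of 309.
Program-gene baselines are kept deliberately modest (relative expression
U(0.3, 0.8) vs log-normal background) so that boosting ~1,600 genes does
not inflate treated-cell library composition enough to erode other program
genes' CPM-scale fold changes below the 1.5 threshold; the planted LFC is
an effect-size floor, not an exact prediction of the CPM-scale estimate.
The shared program's biotype table fixes 238 protein-coding and 53 lncRNA
genes (77% and 17% of 309), the remainder pseudogene/TEC. The generator
does not emulate dropout beyond NB sampling, gene–gene correlation, or
cell-cycle structure; recovery results show the intersection logic and
thresholds behave correctly, not that the rank test matches count-model
pipelines on marginal real-data effects.

## Orchestration and determinism

`RunConfig` validates its keys strictly (unknown keys are errors, nested
blocks included) and the effective config is echoed to the log and written
next to outputs. `run_pipeline` derives one child seed per stage from the
run seed, logs it, and aborts with the stage name on any stage failure. The
written `report.json` excludes wall-clock timings and the output path, so a
re-run with the same config and seed is byte-identical; its schema is
shipped as `report_schema.json` (generated from the pydantic model). The
default stage sizes (full 62-slide matched cohort; 4 DE comparisons at 360
cells; a handful of CN cells per group) were chosen so the complete run
finishes in about a minute on one CPU.

## Known limitations

- The imaging model is idealized (disks, flat background); threshold
  defaults must be re-tuned for real microscopy.
- The segmentation permutation test is per-split and unadjusted across the
  recursion, as in classic recursive binary segmentation; `alpha` trades
  sensitivity against over-segmentation.
- The DE procedure tests location shift on ranks; it does not model
  mean–variance relationships and is not a drop-in for count-model
  inference on weak effects.
- Whole-genome doubling is *invisible* to ratio profiles by design; the
  package deliberately has no absolute-ploidy caller (image-based FISH
  ploidy appears only as generator ground truth).
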