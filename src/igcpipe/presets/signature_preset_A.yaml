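# Two cell lines (MDA-like, PC3-like) x two drugs (docetaxel-like,
# cisplatin-like) vs per-line DMSO controls.  Planted programs:
#   - shared survivor program, 309 genes, up in all four treated conditions
#   - MDA-specific program, 1282 genes, up in both MDA treatments
#   - PC3-specific program,  869 genes, up in both PC3 treatments
# so the per-line drug intersections are 309+1282=1591 and 309+869=1178 and
# the cross-line survivor set is 309.  Of the 309, 238 are protein_coding
# (77%) and 53 lncRNA (17%); the remainder split pseudogene / TEC (~6%).
kind: rna
n_genes: 6000
cells_per_condition: 60
n_batches: 2
dispersion: 0.1
libsize_mean: 20000.0
libsize_sd: 2000.0
planted_lfc: 3.0
shared_program_size: 309
mda_specific_size: 1282
pc3_specific_size: 869
shared_biotypes:
  protein_coding: 238
  lncRNA: 53
  pseudogene: 12
  TEC: 6
conditions: [MDA_DMSO, MDA_DOC, MDA_CIS, PC3_DMSO, PC3_DOC, PC3_CIS]
lines:
  MDA: [MDA_DOC, MDA_CIS]
  PC3: [PC3_DOC, PC3_CIS]
controls:
  MDA: MDA_DMSO
  PC3: PC3_DMSO
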