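# PC3-like copy-number ground truth on a ~4800-bin autosome grid (600 kb
# bins): chromosome 1 at copy state 3, chromosome 10 at state 1, baseline 2
# elsewhere — matching the FISH ploidies of the PC3 line (chr1 = 3, chr10 = 1).
kind: cn
bin_size: 600000
chr1_state: 3
chr10_state: 1
baseline_state: 2
wgd_factor: 1
reads_per_cell: 500000
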