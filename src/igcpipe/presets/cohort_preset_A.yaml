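# Matched liquid-biopsy cohort: 31 patients with blood + marrow slides and
# 13 marrow-only patients (44 marrow samples in total).  3 of 31 blood slides
# and 25 of 31 marrow slides carry planted CTC-IGC cells, giving cohort
# positivity of 9.7% (blood) and 80.6% (marrow) among matched patients.
kind: cohort
n_matched: 31
n_marrow_only: 13
blood_igc_positive: 3
marrow_igc_positive: 25
marrow_only_igc_positive: 10
hazard_pos: 0.12        # progressions / month, IGC-positive
hazard_neg: 0.04
censor_rate: 0.2
slide_width: 800
slide_height: 800
pixel_size: 1.0         # µm / px
background_level: 200.0
noise_sd: 5.0
wbc_per_slide: 500      # WBC background density per slide (placeholder; arbitrary)
ctc_per_slide: 12
igc_per_positive_slide: 2
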