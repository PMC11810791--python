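{
  "$defs": {
    "CNSection": {
      "properties": {
        "n_cells": {
          "title": "N Cells",
          "type": "integer"
        },
        "wgd_concordance_min": {
          "title": "Wgd Concordance Min",
          "type": "number"
        },
        "chr1_segment_ratio_mean": {
          "title": "Chr1 Segment Ratio Mean",
          "type": "number"
        },
        "chr10_segment_ratio_mean": {
          "title": "Chr10 Segment Ratio Mean",
          "type": "number"
        },
        "group_medians": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Group Medians",
          "type": "object"
        }
      },
      "required": [
        "n_cells",
        "wgd_concordance_min",
        "chr1_segment_ratio_mean",
        "chr10_segment_ratio_mean",
        "group_medians"
      ],
      "title": "CNSection",
      "type": "object"
    },
    "CohortSection": {
      "properties": {
        "n_matched": {
          "title": "N Matched",
          "type": "integer"
        },
        "n_marrow_only": {
          "title": "N Marrow Only",
          "type": "integer"
        },
        "blood_positive": {
          "title": "Blood Positive",
          "type": "integer"
        },
        "marrow_positive_matched": {
          "title": "Marrow Positive Matched",
          "type": "integer"
        },
        "blood_positive_pct": {
          "title": "Blood Positive Pct",
          "type": "number"
        },
        "marrow_positive_pct": {
          "title": "Marrow Positive Pct",
          "type": "number"
        },
        "detection_errors": {
          "title": "Detection Errors",
          "type": "integer"
        },
        "logrank_chi2": {
          "title": "Logrank Chi2",
          "type": "number"
        },
        "logrank_p": {
          "title": "Logrank P",
          "type": "number"
        },
        "km_median_pos": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Km Median Pos"
        },
        "km_median_neg": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Km Median Neg"
        }
      },
      "required": [
        "n_matched",
        "n_marrow_only",
        "blood_positive",
        "marrow_positive_matched",
        "blood_positive_pct",
        "marrow_positive_pct",
        "detection_errors",
        "logrank_chi2",
        "logrank_p",
        "km_median_pos",
        "km_median_neg"
      ],
      "title": "CohortSection",
      "type": "object"
    },
    "RNASection": {
      "properties": {
        "comparison_up_sizes": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Comparison Up Sizes",
          "type": "object"
        },
        "line_set_sizes": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Line Set Sizes",
          "type": "object"
        },
        "survivor_set_size": {
          "title": "Survivor Set Size",
          "type": "integer"
        },
        "biotype_percent": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Biotype Percent",
          "type": "object"
        }
      },
      "required": [
        "comparison_up_sizes",
        "line_set_sizes",
        "survivor_set_size",
        "biotype_percent"
      ],
      "title": "RNASection",
      "type": "object"
    }
  },
  "description": "Schema of the end-to-end run report (also shipped as JSON schema).",
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "seeds": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Seeds",
      "type": "object"
    },
    "timings_s": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Timings S",
      "type": "object"
    },
    "cohort": {
      "$ref": "#/$defs/CohortSection"
    },
    "copy_number": {
      "$ref": "#/$defs/CNSection"
    },
    "transcriptome": {
      "$ref": "#/$defs/RNASection"
    }
  },
  "required": [
    "config",
    "seeds",
    "timings_s",
    "cohort",
    "copy_number",
    "transcriptome"
  ],
  "title": "PipelineReport",
  "type": "object"
}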