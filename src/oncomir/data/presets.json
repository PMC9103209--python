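{
  "version": 1,
  "description": "Published oncomiR index presets: per-miRNA coefficients of the weighted linear index and the ROC-selected decision thresholds (raw scale, with the printed log2 value) for CNS-involvement calls, per B-NHL subtype and compartment.",
  "presets": [
    {
      "name": "DLBCL-CSF",
      "diagnosis": "DLBCL",
      "compartment": "CSF",
      "coefficients": {"miR-21": 1.83, "miR-20a": 1.31, "miR-155": 1.78},
      "threshold_raw": 8.42,
      "threshold_log2": 3.07
    },
    {
      "name": "MCL-CSF",
      "diagnosis": "MCL",
      "compartment": "CSF",
      "coefficients": {"miR-21": 1.36, "miR-20a": 0.83, "miR-92a": 1.30, "miR-155": 1.84},
      "threshold_raw": 8.86,
      "threshold_log2": 3.15
    },
    {
      "name": "BL-CSF",
      "diagnosis": "BL",
      "compartment": "CSF",
      "coefficients": {"miR-21": 1.57, "miR-155": 1.75},
      "threshold_raw": 6.83,
      "threshold_log2": 2.77
    },
    {
      "name": "B-NHL-NOS-CSF",
      "diagnosis": "B-NHL-NOS",
      "compartment": "CSF",
      "coefficients": {"miR-21": 1.10, "miR-155": 1.64},
      "threshold_raw": 7.14,
      "threshold_log2": 2.84
    },
    {
      "name": "DLBCL-plasma",
      "diagnosis": "DLBCL",
      "compartment": "plasma",
      "coefficients": {"miR-21": 0.07, "miR-19a": 0.03, "miR-20a": 6.93, "miR-155": 0.43},
      "threshold_raw": 6.13,
      "threshold_log2": 2.62
    },
    {
      "name": "MCL-plasma",
      "diagnosis": "MCL",
      "compartment": "plasma",
      "coefficients": {"miR-21": 2.42, "miR-19a": 0.15, "miR-155": 1.25},
      "threshold_raw": 5.82,
      "threshold_log2": 2.54
    },
    {
      "name": "BL-plasma",
      "diagnosis": "BL",
      "compartment": "plasma",
      "coefficients": {"miR-21": 2.12, "miR-19a": 0.08, "miR-155": 0.10},
      "threshold_raw": 3.68,
      "threshold_log2": 1.88
    },
    {
      "name": "B-NHL-NOS-plasma",
      "diagnosis": "B-NHL-NOS",
      "compartment": "plasma",
      "coefficients": {"miR-19a": 5.85, "miR-155": 0.45},
      "threshold_raw": 3.20,
      "threshold_log2": 1.68
    }
  ]
}
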