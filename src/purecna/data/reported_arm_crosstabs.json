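{
  "_comment": "Reported arm-level CNA call cross-tabulations from the FOCUS (N=288) and GRAMPIAN (N=74) colorectal cohorts. Rows: reference call (SoftCTM on H&E section 1) in order loss/neutral/gain; columns: comparator call, same order. Comparators: SoftCTM on the serial H&E section 2, transcriptome-based ESTIMATE, methylation-based InfiniumPurify, and conventional pathology (CP).",
  "focus": {
    "n_samples": 288,
    "softctm_he2": [[2066, 23, 1], [72, 6662, 74], [0, 22, 2312]],
    "estimate": [[1340, 749, 1], [0, 6808, 0], [0, 675, 1659]],
    "infiniumpurify": [[1622, 466, 2], [19, 6761, 28], [0, 458, 1876]],
    "cp": [[2034, 55, 1], [416, 6008, 384], [0, 43, 2291]]
  },
  "grampian": {
    "n_samples": 74,
    "softctm_he2": [[474, 15, 0], [6, 1865, 8], [0, 14, 504]],
    "estimate": [[363, 126, 0], [0, 1878, 1], [1, 118, 399]],
    "infiniumpurify": [[456, 33, 0], [56, 1760, 63], [2, 26, 490]],
    "cp": [[489, 0, 0], [197, 1455, 227], [3, 2, 513]]
  }
}
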