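{
  "note": "Published four-component gamma-mixture fit for the 12-gene AT flower network (shapes alpha_ij, rates beta_ij per attractor). The source table does not report mixture weights; uniform weights 1/4 are an assumption of this fixture.",
  "weights": [0.25, 0.25, 0.25, 0.25],
  "shapes": [
    [1, 2.25, 2.22, 1, 2.23, 2.24, 2.24, 2.23, 2.24, 2.24, 2.26, 1],
    [5.83, 5.79, 1, 5.82, 5.82, 5.74, 1, 5.66, 1, 5.69, 1, 5.78],
    [1, 1, 2.21, 2.21, 2.22, 2.22, 2.21, 1, 2.21, 1, 2.22, 2.22],
    [2.21, 1, 2.21, 2.23, 1, 1, 1, 2.19, 2.24, 2.24, 1, 2.22]
  ],
  "rates": [
    [0.91, 0.64, 0.64, 0.89, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.64, 0.91],
    [1.88, 1.87, 0.95, 1.86, 1.87, 1.86, 0.93, 1.85, 0.94, 1.85, 0.94, 1.87],
    [0.92, 0.93, 0.67, 0.67, 0.67, 0.67, 0.67, 0.94, 0.67, 0.94, 0.66, 0.67],
    [0.63, 0.89, 0.63, 0.63, 0.9, 0.92, 0.89, 0.64, 0.63, 0.63, 0.89, 0.63]
  ],
  "gene_names": ["EMF1", "TFL1", "LFY", "AP1", "CAL", "LUG", "UFO", "BFU", "AG", "AP3", "PI", "SUP"]
}
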