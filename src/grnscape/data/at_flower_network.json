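{
  "note": "12-gene Arabidopsis thaliana flower morphogenesis GRN: published integer weight matrix W (row i = target gene i) and activation thresholds theta.",
  "genes": ["EMF1", "TFL1", "LFY", "AP1", "CAL", "LUG", "UFO", "BFU", "AG", "AP3", "PI", "SUP"],
  "W": [
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [1, 0, -2, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [-2, -1, 0, 2, 1, 0, 0, 0, 0, 0, 0, 0],
    [-1, 0, 5, 0, 0, 0, 0, 0, -1, 0, 0, 0],
    [0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0],
    [0, -2, 1, -2, 0, -1, 0, 0, 0, 0, 0, 0],
    [0, 0, 3, 0, 0, 0, 2, 1, 0, 0, 0, -2],
    [0, 0, 4, 0, 0, 0, 1, 1, 0, 0, 0, -1],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
  ],
  "theta": [0, 0, 3, -1, 1, 0, 0, 1, -1, 0, 0, 0]
}
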