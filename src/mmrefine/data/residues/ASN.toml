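name = "ASN"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp2",   0.55],
  ["OD1", "O", "sp2",  -0.55],
  ["ND2", "N", "sp2",  -0.62],
]
bonds = [
  ["N",  "CA",  1.458],
  ["CA", "C",   1.525],
  ["C",  "O",   1.231],
  ["CA", "CB",  1.530],
  ["CB", "CG",  1.516],
  ["CG", "OD1", 1.231],
  ["CG", "ND2", 1.328],
]
hydrogens = [
  ["H",    "N",   0.31],
  ["HA",   "CA",  0.09],
  ["HB2",  "CB",  0.09],
  ["HB3",  "CB",  0.09],
  ["HD21", "ND2", 0.32],
  ["HD22", "ND2", 0.30],
]
planes = [["CB", "CG", "OD1", "ND2", "HD21", "HD22"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "OD1"]]
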