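# Default protonation: charged guanidinium (+1).
name = "ARG"
formal = { CZ = 1 }
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp3",  -0.18],
  ["CD",  "C", "sp3",   0.20],
  ["NE",  "N", "sp2",  -0.70],
  ["CZ",  "C", "sp2",   0.64],
  ["NH1", "N", "sp2",  -0.80],
  ["NH2", "N", "sp2",  -0.80],
]
bonds = [
  ["N",  "CA",  1.458],
  ["CA", "C",   1.525],
  ["C",  "O",   1.231],
  ["CA", "CB",  1.530],
  ["CB", "CG",  1.520],
  ["CG", "CD",  1.520],
  ["CD", "NE",  1.460],
  ["NE", "CZ",  1.329],
  ["CZ", "NH1", 1.326],
  ["CZ", "NH2", 1.326],
]
hydrogens = [
  ["H",    "N",   0.31],
  ["HA",   "CA",  0.09],
  ["HB2",  "CB",  0.09],
  ["HB3",  "CB",  0.09],
  ["HG2",  "CG",  0.09],
  ["HG3",  "CG",  0.09],
  ["HD2",  "CD",  0.09],
  ["HD3",  "CD",  0.09],
  ["HE",   "NE",  0.44],
  ["HH11", "NH1", 0.46],
  ["HH12", "NH1", 0.46],
  ["HH21", "NH2", 0.46],
  ["HH22", "NH2", 0.46],
]
planes = [["CD", "NE", "HE", "CZ", "NH1", "NH2", "HH11", "HH12", "HH21", "HH22"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD"], ["CB", "CG", "CD", "NE"], ["CG", "CD", "NE", "CZ"]]
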