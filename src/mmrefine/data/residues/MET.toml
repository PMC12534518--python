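name = "MET"
heavy = [
  ["N",  "N", "sp2",  -0.47],
  ["CA", "C", "sp3",   0.07],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
  ["CB", "C", "sp3",  -0.18],
  ["CG", "C", "sp3",  -0.14],
  ["SD", "S", "sp3",  -0.09],
  ["CE", "C", "sp3",  -0.22],
]
bonds = [
  ["N",  "CA", 1.458],
  ["CA", "C",  1.525],
  ["C",  "O",  1.231],
  ["CA", "CB", 1.530],
  ["CB", "CG", 1.520],
  ["CG", "SD", 1.803],
  ["SD", "CE", 1.791],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
  ["HG2", "CG", 0.09],
  ["HG3", "CG", 0.09],
  ["HE1", "CE", 0.09],
  ["HE2", "CE", 0.09],
  ["HE3", "CE", 0.09],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "SD"], ["CB", "CG", "SD", "CE"]]
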