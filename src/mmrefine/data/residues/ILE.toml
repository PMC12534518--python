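name = "ILE"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.09],
  ["CG1", "C", "sp3",  -0.18],
  ["CG2", "C", "sp3",  -0.27],
  ["CD1", "C", "sp3",  -0.27],
]
bonds = [
  ["N",   "CA",  1.458],
  ["CA",  "C",   1.525],
  ["C",   "O",   1.231],
  ["CA",  "CB",  1.540],
  ["CB",  "CG1", 1.530],
  ["CB",  "CG2", 1.521],
  ["CG1", "CD1", 1.513],
]
hydrogens = [
  ["H",    "N",   0.31],
  ["HA",   "CA",  0.09],
  ["HB",   "CB",  0.09],
  ["HG12", "CG1", 0.09],
  ["HG13", "CG1", 0.09],
  ["HG21", "CG2", 0.09],
  ["HG22", "CG2", 0.09],
  ["HG23", "CG2", 0.09],
  ["HD11", "CD1", 0.09],
  ["HD12", "CD1", 0.09],
  ["HD13", "CD1", 0.09],
]
planes = []
chirality = [["CA", "N", "C", "CB"], ["CB", "CA", "CG1", "CG2"]]
chi = [["N", "CA", "CB", "CG1"], ["CA", "CB", "CG1", "CD1"]]
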