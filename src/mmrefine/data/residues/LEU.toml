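name = "LEU"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp3",  -0.09],
  ["CD1", "C", "sp3",  -0.27],
  ["CD2", "C", "sp3",  -0.27],
]
bonds = [
  ["N",  "CA",  1.458],
  ["CA", "C",   1.525],
  ["C",  "O",   1.231],
  ["CA", "CB",  1.530],
  ["CB", "CG",  1.530],
  ["CG", "CD1", 1.521],
  ["CG", "CD2", 1.521],
]
hydrogens = [
  ["H",    "N",   0.31],
  ["HA",   "CA",  0.09],
  ["HB2",  "CB",  0.09],
  ["HB3",  "CB",  0.09],
  ["HG",   "CG",  0.09],
  ["HD11", "CD1", 0.09],
  ["HD12", "CD1", 0.09],
  ["HD13", "CD1", 0.09],
  ["HD21", "CD2", 0.09],
  ["HD22", "CD2", 0.09],
  ["HD23", "CD2", 0.09],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD1"]]
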