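name = "TYR"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp2",   0.00],
  ["CD1", "C", "sp2",  -0.115],
  ["CD2", "C", "sp2",  -0.115],
  ["CE1", "C", "sp2",  -0.115],
  ["CE2", "C", "sp2",  -0.115],
  ["CZ",  "C", "sp2",   0.11],
  ["OH",  "O", "sp3",  -0.54],
]
bonds = [
  ["N",   "CA",  1.458],
  ["CA",  "C",   1.525],
  ["C",   "O",   1.231],
  ["CA",  "CB",  1.530],
  ["CB",  "CG",  1.500],
  ["CG",  "CD1", 1.390],
  ["CG",  "CD2", 1.390],
  ["CD1", "CE1", 1.390],
  ["CD2", "CE2", 1.390],
  ["CE1", "CZ",  1.390],
  ["CE2", "CZ",  1.390],
  ["CZ",  "OH",  1.376],
]
hydrogens = [
  ["H",   "N",   0.31],
  ["HA",  "CA",  0.09],
  ["HB2", "CB",  0.09],
  ["HB3", "CB",  0.09],
  ["HD1", "CD1", 0.115],
  ["HD2", "CD2", 0.115],
  ["HE1", "CE1", 0.115],
  ["HE2", "CE2", 0.115],
  ["HH",  "OH",  0.43],
]
planes = [["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH", "HD1", "HD2", "HE1", "HE2"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD1"]]
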