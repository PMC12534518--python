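name = "TRP"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp2",  -0.03],
  ["CD1", "C", "sp2",   0.035],
  ["CD2", "C", "sp2",  -0.02],
  ["NE1", "N", "sp2",  -0.61],
  ["CE2", "C", "sp2",   0.13],
  ["CE3", "C", "sp2",  -0.115],
  ["CZ2", "C", "sp2",  -0.115],
  ["CZ3", "C", "sp2",  -0.115],
  ["CH2", "C", "sp2",  -0.115],
]
bonds = [
  ["N",   "CA",  1.458],
  ["CA",  "C",   1.525],
  ["C",   "O",   1.231],
  ["CA",  "CB",  1.530],
  ["CB",  "CG",  1.500],
  ["CG",  "CD1", 1.365],
  ["CG",  "CD2", 1.433],
  ["CD1", "NE1", 1.374],
  ["NE1", "CE2", 1.370],
  ["CE2", "CD2", 1.409],
  ["CD2", "CE3", 1.398],
  ["CE3", "CZ3", 1.382],
  ["CZ3", "CH2", 1.400],
  ["CH2", "CZ2", 1.368],
  ["CZ2", "CE2", 1.394],
]
hydrogens = [
  ["H",   "N",   0.31],
  ["HA",  "CA",  0.09],
  ["HB2", "CB",  0.09],
  ["HB3", "CB",  0.09],
  ["HD1", "CD1", 0.115],
  ["HE1", "NE1", 0.38],
  ["HE3", "CE3", 0.115],
  ["HZ2", "CZ2", 0.115],
  ["HZ3", "CZ3", 0.115],
  ["HH2", "CH2", 0.115],
]
planes = [["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2", "HD1", "HE1", "HE3", "HZ2", "HZ3", "HH2"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD1"]]
angle_overrides = [
  ["CG",  "CD1", "CD2", 106.3],
  ["CG",  "CB",  "CD1", 126.9],
  ["CG",  "CB",  "CD2", 126.8],
  ["CD1", "CG",  "NE1", 110.1],
  ["NE1", "CD1", "CE2", 109.0],
  ["CE2", "NE1", "CD2", 107.3],
  ["CE2", "NE1", "CZ2", 130.4],
  ["CE2", "CD2", "CZ2", 122.3],
  ["CD2", "CG",  "CE2", 107.3],
  ["CD2", "CG",  "CE3", 133.9],
  ["CD2", "CE2", "CE3", 118.8],
]
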