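name = "GLU"
formal = { OE2 = -1 }
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.18],
  ["CG",  "C", "sp3",  -0.28],
  ["CD",  "C", "sp2",   0.62],
  ["OE1", "O", "sp2",  -0.76],
  ["OE2", "O", "sp2",  -0.76],
]
bonds = [
  ["N",  "CA",  1.458],
  ["CA", "C",   1.525],
  ["C",  "O",   1.231],
  ["CA", "CB",  1.530],
  ["CB", "CG",  1.520],
  ["CG", "CD",  1.516],
  ["CD", "OE1", 1.249],
  ["CD", "OE2", 1.249],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
  ["HG2", "CG", 0.09],
  ["HG3", "CG", 0.09],
]
planes = [["CG", "CD", "OE1", "OE2"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD"], ["CB", "CG", "CD", "OE1"]]
angle_overrides = [
  ["CD", "CG",  "OE1", 118.3],
  ["CD", "CG",  "OE2", 118.3],
  ["CD", "OE1", "OE2", 123.4],
]

[variants.protonated]
add_hydrogens = [["HE2", "OE2", 0.44]]
charges = { CG = -0.21, CD = 0.75, OE1 = -0.55, OE2 = -0.61 }
formal = { OE2 = 0 }
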