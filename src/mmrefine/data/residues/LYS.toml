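# Default protonation: charged (NZ with three hydrogens, +1).
name = "LYS"
formal = { NZ = 1 }
heavy = [
  ["N",  "N", "sp2",  -0.47],
  ["CA", "C", "sp3",   0.07],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
  ["CB", "C", "sp3",  -0.18],
  ["CG", "C", "sp3",  -0.18],
  ["CD", "C", "sp3",  -0.18],
  ["CE", "C", "sp3",   0.21],
  ["NZ", "N", "sp3",  -0.30],
]
bonds = [
  ["N",  "CA", 1.458],
  ["CA", "C",  1.525],
  ["C",  "O",  1.231],
  ["CA", "CB", 1.530],
  ["CB", "CG", 1.520],
  ["CG", "CD", 1.520],
  ["CD", "CE", 1.520],
  ["CE", "NZ", 1.489],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
  ["HG2", "CG", 0.09],
  ["HG3", "CG", 0.09],
  ["HD2", "CD", 0.09],
  ["HD3", "CD", 0.09],
  ["HE2", "CE", 0.05],
  ["HE3", "CE", 0.05],
  ["HZ1", "NZ", 0.33],
  ["HZ2", "NZ", 0.33],
  ["HZ3", "NZ", 0.33],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD"], ["CB", "CG", "CD", "CE"], ["CG", "CD", "CE", "NZ"]]
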