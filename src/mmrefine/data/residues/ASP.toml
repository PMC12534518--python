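# Default protonation: charged carboxylate (no HD2).  Variant "protonated"
# adds HD2 on OD2 and neutralizes the group.
name = "ASP"
formal = { OD2 = -1 }
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.28],
  ["CG",  "C", "sp2",   0.62],
  ["OD1", "O", "sp2",  -0.76],
  ["OD2", "O", "sp2",  -0.76],
]
bonds = [
  ["N",  "CA",  1.458],
  ["CA", "C",   1.525],
  ["C",  "O",   1.231],
  ["CA", "CB",  1.530],
  ["CB", "CG",  1.516],
  ["CG", "OD1", 1.249],
  ["CG", "OD2", 1.249],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
]
planes = [["CB", "CG", "OD1", "OD2"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "OD1"]]
angle_overrides = [
  ["CG", "CB",  "OD1", 118.3],
  ["CG", "CB",  "OD2", 118.3],
  ["CG", "OD1", "OD2", 123.4],
]

[variants.protonated]
add_hydrogens = [["HD2", "OD2", 0.44]]
charges = { CB = -0.21, CG = 0.75, OD1 = -0.55, OD2 = -0.61 }
formal = { OD2 = 0 }
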