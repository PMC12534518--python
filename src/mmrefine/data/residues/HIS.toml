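# Default protonation: neutral, proton on ND1 (the delta tautomer).
# Variant "epsilon" moves the proton to NE2; variant "charged" has both.
name = "HIS"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CA",  "C", "sp3",   0.07],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
  ["CB",  "C", "sp3",  -0.09],
  ["CG",  "C", "sp2",  -0.05],
  ["ND1", "N", "sp2",  -0.36],
  ["CD2", "C", "sp2",   0.22],
  ["CE1", "C", "sp2",   0.25],
  ["NE2", "N", "sp2",  -0.70],
]
bonds = [
  ["N",   "CA",  1.458],
  ["CA",  "C",   1.525],
  ["C",   "O",   1.231],
  ["CA",  "CB",  1.530],
  ["CB",  "CG",  1.500],
  ["CG",  "ND1", 1.378],
  ["CG",  "CD2", 1.354],
  ["ND1", "CE1", 1.321],
  ["CD2", "NE2", 1.374],
  ["CE1", "NE2", 1.321],
]
hydrogens = [
  ["H",   "N",   0.31],
  ["HA",  "CA",  0.09],
  ["HB2", "CB",  0.09],
  ["HB3", "CB",  0.09],
  ["HD1", "ND1", 0.32],
  ["HD2", "CD2", 0.10],
  ["HE1", "CE1", 0.13],
]
planes = [["CB", "CG", "ND1", "CD2", "CE1", "NE2", "HD1", "HD2", "HE1"]]
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "ND1"]]
angle_overrides = [
  ["CG",  "ND1", "CD2", 108.0],
  ["CG",  "CB",  "ND1", 122.7],
  ["CG",  "CB",  "CD2", 129.3],
  ["ND1", "CG",  "CE1", 108.0],
  ["CD2", "CG",  "NE2", 108.0],
  ["CE1", "ND1", "NE2", 108.0],
  ["NE2", "CE1", "CD2", 108.0],
]

[variants.epsilon]
remove = ["HD1"]
add_hydrogens = [["HE2", "NE2", 0.32]]
charges = { ND1 = -0.70, NE2 = -0.36 }

[variants.charged]
add_hydrogens = [["HE2", "NE2", 0.44]]
charges = { CB = -0.05, CG = 0.19, ND1 = -0.51, HD1 = 0.44, CD2 = 0.19, HD2 = 0.13, CE1 = 0.32, HE1 = 0.18, NE2 = -0.51 }
formal = { NE2 = 1 }
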