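name = "PRO"
heavy = [
  ["N",  "N", "sp3",  -0.29],
  ["CA", "C", "sp3",   0.02],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
  ["CB", "C", "sp3",  -0.18],
  ["CG", "C", "sp3",  -0.18],
  ["CD", "C", "sp3",   0.00],
]
bonds = [
  ["N",  "CA", 1.466],
  ["CA", "C",  1.525],
  ["C",  "O",  1.231],
  ["CA", "CB", 1.530],
  ["CB", "CG", 1.492],
  ["CG", "CD", 1.503],
  ["CD", "N",  1.473],
]
hydrogens = [
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
  ["HG2", "CG", 0.09],
  ["HG3", "CG", 0.09],
  ["HD2", "CD", 0.09],
  ["HD3", "CD", 0.09],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "CG"], ["CA", "CB", "CG", "CD"]]
angle_overrides = [
  ["N",  "CA", "CD", 112.0],
  ["CA", "N",  "CB", 103.2],
  ["CB", "CA", "CG", 104.5],
  ["CG", "CB", "CD", 106.1],
  ["CD", "CG", "N",  103.2],
]
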