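name = "ALA"
heavy = [
  ["N",  "N", "sp2",  -0.47],
  ["CA", "C", "sp3",   0.07],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
  ["CB", "C", "sp3",  -0.27],
]
bonds = [
  ["N",  "CA", 1.458],
  ["CA", "C",  1.525],
  ["C",  "O",  1.231],
  ["CA", "CB", 1.521],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB1", "CB", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = []
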