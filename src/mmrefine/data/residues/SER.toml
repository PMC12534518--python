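name = "SER"
heavy = [
  ["N",  "N", "sp2",  -0.47],
  ["CA", "C", "sp3",   0.07],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
  ["CB", "C", "sp3",   0.05],
  ["OG", "O", "sp3",  -0.66],
]
bonds = [
  ["N",  "CA", 1.458],
  ["CA", "C",  1.525],
  ["C",  "O",  1.231],
  ["CA", "CB", 1.530],
  ["CB", "OG", 1.417],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA",  "CA", 0.09],
  ["HB2", "CB", 0.09],
  ["HB3", "CB", 0.09],
  ["HG",  "OG", 0.43],
]
planes = []
chirality = [["CA", "N", "C", "CB"]]
chi = [["N", "CA", "CB", "OG"]]
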