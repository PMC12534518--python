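# N-methyl C-terminal cap: links through its N to the previous residue's C.
name = "NME"
heavy = [
  ["N",   "N", "sp2",  -0.47],
  ["CH3", "C", "sp3",  -0.11],
]
bonds = [
  ["N", "CH3", 1.455],
]
hydrogens = [
  ["H",  "N",   0.31],
  ["H1", "CH3", 0.09],
  ["H2", "CH3", 0.09],
  ["H3", "CH3", 0.09],
]
planes = []
chirality = []
chi = []
angle_overrides = [
  ["N", "-C", "CH3", 121.7],
]
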