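# Acetyl N-terminal cap: links through its carbonyl C to the next residue's N.
name = "ACE"
heavy = [
  ["CH3", "C", "sp3",  -0.27],
  ["C",   "C", "sp2",   0.51],
  ["O",   "O", "sp2",  -0.51],
]
bonds = [
  ["CH3", "C", 1.500],
  ["C",   "O", 1.231],
]
hydrogens = [
  ["H1", "CH3", 0.09],
  ["H2", "CH3", 0.09],
  ["H3", "CH3", 0.09],
]
planes = []
chirality = []
chi = []
angle_overrides = [
  ["C", "CH3", "O",  120.8],
  ["C", "CH3", "+N", 116.2],
  ["C", "O",   "+N", 123.0],
]
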