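# Residue template. Schema:
#   heavy     = [[name, element, geom class (sp3|sp2), partial charge e], ...]
#   bonds     = [[name_a, name_b, ideal length Angstrom], ...]  (heavy-heavy)
#   hydrogens = [[name, parent heavy atom, partial charge e], ...]
#   planes    = [[atom names of a planarity group], ...]
#   chirality = [[center, neighbor1, neighbor2, neighbor3], ...] (L sign +)
#   chi       = [[four atom names of a side-chain torsion], ...]
name = "GLY"
heavy = [
  ["N",  "N", "sp2",  -0.47],
  ["CA", "C", "sp3",  -0.02],
  ["C",  "C", "sp2",   0.51],
  ["O",  "O", "sp2",  -0.51],
]
bonds = [
  ["N",  "CA", 1.451],
  ["CA", "C",  1.516],
  ["C",  "O",  1.231],
]
hydrogens = [
  ["H",   "N",  0.31],
  ["HA2", "CA", 0.09],
  ["HA3", "CA", 0.09],
]
planes = []
chirality = []
chi = []
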