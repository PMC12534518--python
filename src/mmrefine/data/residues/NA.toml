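# Sodium ion (probe/counter-ion); no bonded structure.
name = "NA"
formal = { NA = 1 }
heavy = [
  ["NA", "NA", "sp3", 1.00],
]
bonds = []
hydrogens = []
planes = []
chirality = []
chi = []
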