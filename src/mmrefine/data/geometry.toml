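# Shared ideal-geometry rules used for both restraint generation and
# internal-coordinate model building.  Bond lengths to hydrogen are keyed by
# the parent element and geometry class; heavy-heavy lengths live in the
# per-residue files.  Angle ideals: residue-local overrides, then the global
# overrides below (matched by atom name; "-X"/"+X" mean an atom of the
# previous/next residue), then the per-class defaults.  Hydrogen-involving
# angle ideals are not tabulated: they are derived numerically from the
# canonical hydrogen-placement construction so that a model built at ideal
# internal coordinates scores exactly zero restraint energy.

# Global angle overrides: [center, neighbor_a, neighbor_b, degrees]
angle_overrides = [
  ["CA", "N",  "C",    111.2],
  ["CA", "N",  "CB",   110.4],
  ["CA", "C",  "CB",   110.5],
  ["C",  "CA", "O",    120.8],
  ["C",  "CA", "+N",   116.2],
  ["C",  "O",  "+N",   123.0],
  ["C",  "CA", "OXT",  117.0],
  ["C",  "O",  "OXT",  122.2],
  ["N",  "-C", "CA",   121.7],
  ["N",  "-C", "CD",   125.0],
]

[h_bond_lengths]
# parent element (+ optional geometry class) -> ideal X-H length, Angstrom
N = 1.00
O = 0.97
S = 1.33
C_sp3 = 1.09
C_sp2 = 1.08

[angle_defaults]
sp3 = 109.471
sp2 = 120.0
S = 98.0
O = 108.5
N_sp3 = 109.471

[peptide]
# Inter-residue peptide link geometry.
c_n_length = 1.329
detect_cutoff = 2.0   # C(i)-N(i+1) distance below which a link is assumed
omega_force = 3.0     # torsion weight, kcal/mol

[force_constants]
# Harmonic restraint weights; energies are k * deviation^2.
bond = 600.0        # kcal/mol/A^2
angle = 80.0        # kcal/mol/rad^2
torsion = 0.3       # kcal/mol, threefold terms on sp3-sp3 bonds
plane = 100.0       # kcal/mol/A^2
chirality = 100.0   # kcal/mol/A^6
nonbonded = 50.0    # kcal/mol/A^2, one-sided overlap term
tether = 10.0       # kcal/mol/A^2, regularization tether to start coords
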