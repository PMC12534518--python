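# Nonbonded parameters.
#
# vdw_radii: restraint-flavour van der Waals radii (Angstrom) used by the
# one-sided overlap repulsion restraint and the clash detector.  Pairs that
# can hydrogen bond are allowed to approach closer (see reductions below).
#
# pair_potential: per-element exp-6 parameters for the smooth physics
# surrogate backend.  Each element carries a well depth eps (kcal/mol) and a
# minimum-position rmin (Angstrom); pairs combine as eps_ij = sqrt(eps_i
# eps_j), rmin_ij = (rmin_i + rmin_j)/2 and the pair term is
#   A exp(-b r) - C6 / r^6,  A = eps_ij e^12, b = 12 / rmin_ij,
#   C6 = 2 eps_ij rmin_ij^6
# which has its minimum exactly at rmin_ij with depth eps_ij.

[vdw_radii]
H = 1.17
C = 1.70
N = 1.55
O = 1.52
S = 1.80
SE = 1.90
NA = 1.36
P = 1.80

[reductions]
# Allowed-approach reductions for hydrogen-bond-capable pairs (Angstrom).
polar_h_acceptor = 0.72   # H(on N/O) ... O/N acceptor
donor_acceptor = 0.60     # N/O donor heavy atom ... O/N acceptor

[pair_potential]
# element = [eps kcal/mol, rmin Angstrom]
H = [0.02, 2.40]
C = [0.10, 3.80]
N = [0.12, 3.60]
O = [0.14, 3.50]
S = [0.20, 4.00]
SE = [0.20, 4.10]
NA = [0.05, 3.00]
P = [0.20, 4.10]

[electrostatics]
coulomb_constant = 332.0637   # kcal/mol * Angstrom / e^2
dielectric_slope = 4.0        # distance-dependent dielectric eps(r) = 4 r

[hydrogen_bond]
# Directional 10-12 term on D-H...A triplets, D/A in {N, O}.
epsilon = 2.0   # kcal/mol well depth at ideal geometry
r0 = 1.90       # Angstrom, H...A distance at the minimum
angle_power = 4 # cos^p weighting of the D-H...A angle

[cutoff]
radius = 5.0    # Angstrom, pair interaction cutoff
switch_width = 1.0  # quintic taper over the last Angstrom before the cutoff
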