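# Methods

This document describes the algorithms and conventions implemented in
`mmrefine`.  All distances are in Angstrom, angles in degrees at API
boundaries (stored ideal angles are radians internally where noted), and
energies in arbitrary consistent units.

## Refinement target and macro-cycles

Refinement minimizes

```
T(x) = T_data(x) + w * T_restraints(x)
```

over Cartesian coordinates `x` with L-BFGS-B and analytic gradients.
Each macro-cycle:

1. rebuilds the symmetry environment around the current coordinates
   (when `use_supercell` is on);
2. re-determines the weight when `weight="auto"`:
   `w = ||grad T_data|| / ||grad T_restraints||`, evaluated at the
   cycle's starting coordinates, so the two terms enter with comparable
   gradient magnitudes.  A zero restraint gradient falls back to `w = 1`
   with a warning;
3. runs up to `max_iterations` minimizer iterations;
4. accepts the step only if the total target did not increase.  A
   diverging cycle is retried with `w` halved, up to six attempts; the
   damped weight carries into subsequent cycles;
5. stops when the maximum atomic shift falls below `shift_tolerance`
   (default 1e-3 A) or `max_cycles` (default 5) is reached.

A `SingularGeometryError` raised by the chemistry backend (degenerate
geometry such as collinear angle atoms) aborts the cycle with a note in
the trace rather than crashing the run.

The per-cycle trace records total/data/restraint target values, weight,
R factors or map correlation, maximum shift and rmsd from the starting
coordinates.

## Data targets

### Reciprocal space

Structure factors are computed by direct summation over atoms and
symmetry operators with 4-Gaussian atomic form factors, isotropic
Debye-Waller factors `exp(-B s^2)` (`s = 1/2d`) and occupancies.  The
data target is least-squares on amplitudes,

```
T = sum_work (|F_obs| - k |F_calc|)^2 / sum_work |F_obs|^2
```

with the scale `k` re-derived analytically at each evaluation
(`k = sum |F_obs||F_calc| / sum |F_calc|^2` over the working set).  The
gradient treats `k` as fixed at its optimum; by the envelope theorem the
omitted `dk/dx` term vanishes at the analytic optimum of `k`.  Free
reflections (deterministic, hash-based flags, order-independent in the
reflection list) are excluded from both the target and its gradient and
reported as `R_free`.

Reflection lists cover a unique hemisphere (no Friedel mates, no origin)
to the requested resolution.

### Real space

Maps are synthesized by FFT from the same direct-summation structure
factors on a grid with spacing at most `d_min / 4`, or directly as sums
of atomic Gaussians.  The real-space target is the negative sum of map
values interpolated at atom centers, normalized by atom count and map
sigma.  Interpolation is tricubic (Catmull-Rom) with an analytic spatial
gradient and periodic wrapping.  `cc_mask` correlates the experimental
map with a model-computed map over grid points within a mask around the
model's atoms, with the model map synthesized through the same route so
a model correlates perfectly with its own noise-free map.

## Chemistry backends

Both backends consume a `RestraintSet` built from residue templates
(bond/angle/torsion ideals, planes, chirality volumes, per-atom partial
charges, donor/acceptor flags, 1-2/1-3/1-4 exclusions).

* **RestraintBackend** — harmonic bonds and angles, periodic torsion
  potentials, plane and chirality terms, and a one-sided quadratic
  overlap penalty below contact distance.
* **SurrogateBackend** — everything above plus nonbonded pair terms:
  Coulomb `332.0637 q_i q_j / (4 r^2)` (distance-dependent dielectric),
  an exp-6 dispersion/repulsion term, and a directional 10-12
  hydrogen-bond well modulated by the D-H...A angle.  Nonbonded
  interactions use a k-d tree neighbor list, a quintic switching
  function between 4 and 5 A, 1-2/1-3 exclusion and 1-4 scaling (0.5).

Backends return `(energy, forces)` with `forces = -grad E`; a central
finite-difference oracle (`h = 1e-4`) is used throughout the tests.

## Crystal symmetry

Sohncke space-group operators are shipped as triplet tables (65 distinct
groups plus common alias symbols).  `expand_supercell` surrounds the
asymmetric unit with every symmetry/lattice image residue any of whose
atoms lies within the truncation radius; lattice translation bounds are
derived per operator from the fractional extents of the model, so the
expansion is correct wherever the model sits relative to the unit cell.
Whole residues are kept or dropped together.  Environment atoms are
images of ASU atoms: coordinates are regenerated from the ASU on every
evaluation and forces on images are rotated back and accumulated onto
their ASU parents (chain rule for a rigid symmetry generator), so the
minimized energy is invariant under re-choice of the asymmetric unit.

## Topology, finalisation and regularization

Residue templates provide connectivity, ideal internal coordinates,
protonation variants (e.g. neutral/charged histidine, protonated
aspartate/glutamate) and formal/partial charges; untemplated atoms keep
their formal charge.  Peptide bonds are detected by C-N distance;
chain breaks produce no link restraints.

Finalisation runs: completeness check (missing atoms classified as
blocking or trivially completable), trivial completion (e.g. OXT,
terminal atoms placed from ideal frames), hydrogen placement at
geometrically predicted positions (tetrahedral/planar frames, staggered
methyls), clash detection (nonbonded pairs below contact tolerance), and
a restraints-only regularization that runs only when clashes are found.
Blocking missing atoms abort with an error listing them.

## Validation

* Bond/angle rmsd against restraint ideals.
* Hydrogen bonds: donor-H...acceptor pairs with `d(H...A) < 2.7` and
  `angle(D-H...A) > 120 deg`, excluding covalently related pairs.
  Distance and angle populations are summarized by population-moment
  skewness and excess kurtosis; near-(0,0) values indicate sharply
  peaked, high-quality hydrogen bonding.
* Ramachandran classification by point-in-polygon tests against
  favored/allowed regions per residue class (general, glycine, proline,
  pre-proline).
* Model comparison: Kabsch superposition rmsd over backbone/CB atoms, or
  circular rmsd over matched phi/psi/omega/chi torsions.
* Dataset filtering: inclusive "between" bounds and strict "better
  than" thresholds on size, resolution, clashscore, bond outliers,
  data-fit (experiment-specific), and homolog statistics; each rejected
  row records the first failing criterion.

## Fixtures

Synthetic peptides are built from exact internal coordinates (natural
extension reference frame), with per-residue template backbone bond
lengths, ideal helix (-57, -47) or strand (-120, +120) torsions, full
protonation, and a staggered-rotamer sweep that selects the
lowest-overlap chi rotamer per side chain — a rigid 120-degree rotation
of the distal group leaves every bonded term exactly invariant, so
built fixtures score exactly zero bonded restraint energy.  The
carboxylate pair poses two carboxylates as an exact inversion pair
sharing a proton at the O...O midpoint, optionally with a +1 probe
placed near the second oxygen to break the symmetry.  Data generators
(`synth_data`) produce noise-free or seeded-noise reflections and maps
from a generating model; all generators are deterministic under a fixed
seed.
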