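# mmrefine

Gradient-driven macromolecular refinement with pluggable chemistry
backends.  `mmrefine` minimizes a combined target

```
T = T_data + w * T_restraints
```

over atomic coordinates, where `T_data` measures agreement with
experimental-style data (structure-factor amplitudes or a real-space
density map) and `T_restraints` is a chemical-plausibility energy
supplied by an exchangeable backend: classical stereochemical restraints,
or a physics-based surrogate that adds electrostatics,
dispersion/repulsion and directional hydrogen bonding on top of them.
The restraint weight `w` is re-determined each macro-cycle from the
gradient-norm ratio of the two terms, and refinement can run inside a
symmetry-expanded supercell so the chemistry term sees crystal-packing
contacts.

## Quick start

```python
from mmrefine import (FixtureSpec, RefinementConfig, build_peptide,
                      perturb, refine, synth_data)

truth = build_peptide(FixtureSpec(kind="helix", n_residues=10))
data = synth_data(truth, "reflections", resolution=2.0, noise=0.05, seed=0)
noisy = perturb(truth, sigma=0.3, seed=0)

refined, trace = refine(noisy, data,
                        RefinementConfig(backend="surrogate"))
print(trace.to_tsv())
```

The same engine refines against density maps (`mode="real"`, data from
`synth_data(..., "map", ...)` or `read_ccp4`) or with no data at all
(restraints-only regularization).

## Command line

```
mmrefine fixtures --kind helix --residues 10 --sigma 0.3 \
    --data reflections --prefix demo
mmrefine refine --model demo.pdb --data demo.tsv \
    --backend surrogate --out refined.pdb --trace trace.tsv
mmrefine validate --model refined.pdb
mmrefine finalise --model partial.pdb --out complete.pdb
mmrefine filter entries.tsv accepted.tsv
```

`mmrefine refine --config settings.toml` reads any of the
`RefinementConfig` fields from TOML; explicit command-line flags win.

## Package layout

| module | contents |
| --- | --- |
| `mmrefine.model` | atomic hierarchy (`AtomicModel`/`Chain`/`Residue`/`Atom`), unit cells, PDB/mmCIF I/O |
| `mmrefine.library` | residue templates: ideal internal coordinates, charges, protonation variants, Ramachandran regions |
| `mmrefine.topology` | chemical topology, restraint generation, completeness checks, hydrogen placement, clash detection, regularization |
| `mmrefine.energy` | restraint and surrogate backends (energy + analytic forces), neighbor lists, finite-difference oracle |
| `mmrefine.symmetry` | Sohncke space-group operators, supercell expansion, gradient folding |
| `mmrefine.scatter` | direct-summation structure factors, R factors, least-squares amplitude target, reflection I/O, free flags |
| `mmrefine.maps` | FFT map synthesis, tricubic interpolation with gradients, real-space target, `cc_mask`, CCP4 I/O |
| `mmrefine.refine` | the macro-cycle engine, weight determination, finalisation, hydrogen-position energy scans |
| `mmrefine.validate` | geometry RMSDs, H-bond detection and moment statistics, Ramachandran classification, model comparison, dataset filtering |
| `mmrefine.fixtures` | deterministic synthetic peptides, carboxylate pairs, perturbation and synthetic data generators |

See `docs/methods.md` for the algorithms and conventions in detail.

## Testing

```
pytest
```

The suite is deterministic (seeded generators throughout) and verifies
analytic gradients against finite differences, vectorized kernels against
literal reference implementations, and symmetry handling against
brute-force image enumeration.  `python scripts/acceptance.py --seed 1
--out report.json` produces a JSON summary of end-to-end metrics on the
seeded fixtures.
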