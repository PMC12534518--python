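import numpy as np
import pytest

from mmrefine import (FixtureSpec, RefinementConfig, RefinementError,
                      build_peptide, build_restraints, finalise,
                      hbond_energy_scan, perturb, refine, synth_data)
from mmrefine.energy import RestraintBackend
from mmrefine.refine import determine_weight
from mmrefine.fixtures import build_carboxylate_pair


@pytest.fixture(scope="module")
def dipeptide():
    return build_peptide(FixtureSpec(kind="dipeptide", n_residues=2,
                                     sequence=["ALA", "GLY"], seed=0))


class TestWeight:
    def test_gradient_norm_ratio(self):
        gd = np.array([[3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])   # norm 5
        gr = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 0.0]])   # norm 2
        assert determine_weight(gd, gr) == pytest.approx(2.5)

    def test_zero_restraint_gradient_warns_unit_weight(self):
        gd = np.ones((3, 3))
        gr = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            assert determine_weight(gd, gr) == 1.0


class TestConfigValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            RefinementConfig(mode="imaginary")

    def test_bad_backend(self):
        with pytest.raises(ValueError):
            RefinementConfig(backend="oracle")

    def test_nonpositive_weight(self):
        with pytest.raises(ValueError):
            RefinementConfig(weight=0.0)
        with pytest.raises(ValueError):
            RefinementConfig(weight=-1.0)

    def test_numeric_string_weight_coerced(self):
        cfg = RefinementConfig(weight="2.5")
        assert cfg.weight == 2.5

    def test_bad_shift_tolerance(self):
        with pytest.raises(ValueError):
            RefinementConfig(shift_tolerance=0.0)


class TestRestraintsOnly:
    def test_energy_decreases_and_input_unchanged(self, dipeptide):
        noisy = perturb(dipeptide, 0.15, 3)
        x_in = noisy.get_coords()
        refined, trace = refine(noisy, None,
                                RefinementConfig(max_cycles=3))
        rs = build_restraints(noisy)
        backend = RestraintBackend(rs)
        e_before = backend.energy_forces(x_in)[0]
        e_after = backend.energy_forces(refined.get_coords())[0]
        assert e_after < e_before
        assert np.array_equal(noisy.get_coords(), x_in)
        assert len(trace.cycles) >= 1
        assert trace.cycles[-1].t_restraints < trace.cycles[0].t_total

    def test_supercell_environment_runs(self, dipeptide):
        noisy = perturb(dipeptide, 0.1, 1)
        refined, trace = refine(noisy, None,
                                RefinementConfig(max_cycles=2,
                                                 use_supercell=True,
                                                 supercell_radius=6.0))
        assert trace.cycles[-1].t_restraints <= trace.cycles[0].t_total


class TestDataModes:
    def test_reciprocal_recovery(self, dipeptide):
        refl = synth_data(dipeptide, "reflections", resolution=2.0,
                          noise=0.0, seed=0)
        noisy = perturb(dipeptide, 0.2, 5)
        refined, trace = refine(noisy, refl,
                                RefinementConfig(backend="surrogate"))
        assert trace.cycles[0].r_work is not None
        assert trace.cycles[-1].r_work < 0.1
        rmsd = np.sqrt(np.mean(np.sum(
            (refined.get_coords() - dipeptide.get_coords()) ** 2, axis=1)))
        assert rmsd < 0.15

    def test_real_space_cc_improves(self, dipeptide):
        dmap = synth_data(dipeptide, "map", resolution=2.0, noise=0.0,
                          seed=0)
        noisy = perturb(dipeptide, 0.2, 6)
        from mmrefine import cc_mask
        cc_before = cc_mask(noisy, dmap)
        # a fixed unit weight keeps the geometry term competitive with the
        # density term on this small toy
        _refined, trace = refine(noisy, dmap,
                                 RefinementConfig(mode="real", weight=1.0))
        assert trace.cycles[-1].cc is not None
        assert trace.cycles[-1].cc > cc_before
        assert trace.cycles[-1].t_restraints < 5.0

    def test_mode_data_mismatch_rejected(self, dipeptide):
        refl = synth_data(dipeptide, "reflections", resolution=2.5,
                          noise=0.0, seed=0)
        with pytest.raises(RefinementError):
            refine(dipeptide, refl, RefinementConfig(mode="real"))
        dmap = synth_data(dipeptide, "map", resolution=2.5, noise=0.0,
                          seed=0)
        with pytest.raises(RefinementError):
            refine(dipeptide, dmap, RefinementConfig(mode="reciprocal"))

    def test_fixed_weight_respected(self, dipeptide):
        refl = synth_data(dipeptide, "reflections", resolution=2.5,
                          noise=0.0, seed=0)
        noisy = perturb(dipeptide, 0.05, 7)
        _m, trace = refine(noisy, refl,
                           RefinementConfig(weight=3.0, max_cycles=1))
        assert trace.cycles[0].weight == pytest.approx(3.0)


class TestTrace:
    def test_tsv_well_formed(self, dipeptide):
        noisy = perturb(dipeptide, 0.1, 8)
        _m, trace = refine(noisy, None, RefinementConfig(max_cycles=2))
        text = trace.to_tsv()
        lines = text.splitlines()
        header = lines[0].split("\t")
        assert header[0] == "cycle" and "r_work" in header
        assert len(lines) == 1 + len(trace.cycles)
        for line in lines[1:]:
            assert len(line.split("\t")) == len(header)
        rows = trace.to_rows()
        assert rows[0]["cycle"] == 1


class TestFinalise:
    def test_blocking_missing_atom_aborts(self, dipeptide):
        broken = dipeptide.copy()
        res = broken.chains[0].residues[0]
        res.atoms[:] = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(RefinementError, match="CA"):
            finalise(broken)

    def test_trivial_atoms_regrown(self, dipeptide):
        partial = dipeptide.copy()
        res = partial.chains[0].residues[-1]
        res.atoms[:] = [a for a in res.atoms
                        if a.name != "OXT" and a.element != "H"]
        fixed, _shift = finalise(partial)
        names = {a.name for a in fixed.chains[0].residues[-1].atoms}
        assert "OXT" in names
        assert any(n.startswith("H") for n in names)

    def test_clash_free_model_not_moved(self):
        # a single ideal residue has no clashes, so regularization is
        # skipped and the coordinates are returned untouched
        single = build_peptide(FixtureSpec(kind="helix", n_residues=1,
                                           sequence=["ALA"], seed=0))
        fixed, shift = finalise(single)
        assert shift == 0.0
        assert np.allclose(fixed.get_coords(), single.get_coords())


class TestHBondScan:
    def test_profile_minimum_zero_and_fractions_interior(self):
        m = build_carboxylate_pair(d_oo=2.5, symmetric=True)
        fr, prof = hbond_energy_scan(m, 3, 8, 4, n_steps=20,
                                     variants={("A", 1): "protonated"})
        assert prof.min() == pytest.approx(0.0, abs=0.0)
        assert len(fr) == len(prof) == 21
        assert fr[0] > 0.0 and fr[-1] < 1.0
        assert np.all(np.diff(fr) > 0)

    def test_element_validation(self):
        m = build_carboxylate_pair(d_oo=2.5, symmetric=True)
        with pytest.raises(RefinementError):
            hbond_energy_scan(m, 0, 8, 4, n_steps=4)   # atom 0 is carbon
        with pytest.raises(RefinementError):
            hbond_energy_scan(m, 3, 8, 0, n_steps=4)

    def test_inset_larger_than_half_separation_rejected(self):
        m = build_carboxylate_pair(d_oo=2.5, symmetric=True)
        with pytest.raises(RefinementError):
            hbond_energy_scan(m, 3, 8, 4, n_steps=4, inset=1.3)
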