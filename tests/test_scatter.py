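import numpy as np
import pytest

from mmrefine import (Atom, AtomicModel, Chain, DataError, FixtureSpec,
                      LSTarget, ReflectionSet, Residue, UnitCell,
                      build_peptide, calc_structure_factors, form_factor,
                      generate_hkl, make_free_flags, r_factor,
                      read_reflections, synth_data, write_reflections)


def toy_model(seed=0, n=5):
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "C", "S"][:n]
    atoms = [Atom(f"A{i}", el, rng.uniform(1, 9, 3),
                  occupancy=float(rng.uniform(0.5, 1.0)),
                  b_iso=float(rng.uniform(10, 40)))
             for i, el in enumerate(elements)]
    cell = UnitCell(10, 11, 12, 90, 90, 90)
    return AtomicModel([Chain("A", [Residue("UNK", 1, "", atoms)])],
                       cell, "P 1")


class TestFormFactors:
    @pytest.mark.parametrize("element,z", [
        ("H", 1), ("C", 6), ("N", 7), ("O", 8), ("S", 16), ("SE", 34)])
    def test_forward_scattering_is_electron_count(self, element, z):
        assert form_factor(element, 0.0) == pytest.approx(z, abs=0.05)

    def test_monotone_decay(self):
        s = np.linspace(0, 0.5, 20)
        f = np.array([form_factor("C", si) for si in s])
        assert np.all(np.diff(f) < 0)


class TestStructureFactors:
    def test_matches_slow_double_loop(self):
        """Vectorized direct summation vs a literal double loop over
        reflections and atoms on a 5-atom toy (< 1e-8)."""
        model = toy_model()
        hkl = generate_hkl(model.unit_cell, 2.5)
        fast = calc_structure_factors(model, hkl)
        cell = model.unit_cell
        slow = np.zeros(len(hkl), complex)
        m_frac = cell.fractionalization_matrix()
        d = cell.d_spacing(hkl)
        for hi, hrow in enumerate(hkl):
            s = 1.0 / (2.0 * d[hi])
            total = 0.0 + 0.0j
            for _ch, _res, atom in model.atoms():
                frac = m_frac @ atom.coords
                f = form_factor(atom.element, s)
                f *= atom.occupancy * np.exp(-atom.b_iso * s * s)
                total += f * np.exp(2j * np.pi * float(hrow @ frac))
            slow[hi] = total
        assert np.abs(fast - slow).max() < 1e-8

    def test_translation_phase_shift_theorem(self):
        model = toy_model(1)
        hkl = generate_hkl(model.unit_cell, 3.0)
        f0 = calc_structure_factors(model, hkl)
        shift = np.array([1.3, -0.7, 2.1])
        moved = model.copy()
        moved.set_coords(model.get_coords() + shift)
        f1 = calc_structure_factors(moved, hkl)
        frac_shift = model.unit_cell.fractionalization_matrix() @ shift
        phase = np.exp(2j * np.pi * hkl @ frac_shift)
        assert np.abs(f1 - f0 * phase).max() < 1e-8

    def test_symmetry_consistency(self):
        """F computed with explicit P 21 21 21 operators equals F of the
        same content expanded to P 1 by hand."""
        model = toy_model(2)
        model.space_group = "P 21 21 21"
        hkl = generate_hkl(model.unit_cell, 3.0)
        f_sym = calc_structure_factors(model, hkl)
        from mmrefine import symops_for
        cell = model.unit_cell
        m_orth = cell.orthogonalization_matrix()
        m_frac = cell.fractionalization_matrix()
        residues = []
        for k, op in enumerate(symops_for("P 21 21 21")):
            atoms = []
            for _c, _r, atom in model.atoms():
                frac = op.apply(m_frac @ atom.coords)
                atoms.append(Atom(atom.name, atom.element, m_orth @ frac,
                                  occupancy=atom.occupancy,
                                  b_iso=atom.b_iso))
            residues.append(Residue("UNK", k + 1, "", atoms))
        expanded = AtomicModel([Chain("A", residues)], cell, "P 1")
        f_p1 = calc_structure_factors(expanded, hkl)
        assert np.abs(f_sym - f_p1).max() < 1e-8


class TestHklGeneration:
    def test_unique_hemisphere(self):
        model = toy_model()
        hkl = generate_hkl(model.unit_cell, 2.0)
        seen = set(map(tuple, hkl))
        assert len(seen) == len(hkl)
        for h in seen:
            assert tuple(-x for x in h) not in seen   # no Friedel mates
        assert (0, 0, 0) not in seen

    def test_resolution_limit_respected(self):
        model = toy_model()
        hkl = generate_hkl(model.unit_cell, 2.0)
        d = model.unit_cell.d_spacing(hkl)
        assert d.min() >= 2.0 - 1e-9


class TestFreeFlags:
    def test_deterministic_and_fraction(self):
        model = toy_model()
        hkl = generate_hkl(model.unit_cell, 1.2)
        f1 = make_free_flags(hkl, seed=7, fraction=0.05)
        f2 = make_free_flags(hkl, seed=7, fraction=0.05)
        assert np.array_equal(f1, f2)
        assert 0.02 < f1.mean() < 0.08
        f3 = make_free_flags(hkl, seed=8, fraction=0.05)
        assert not np.array_equal(f1, f3)

    def test_order_independent(self):
        """Flags depend on the hkl index, not on array position."""
        model = toy_model()
        hkl = generate_hkl(model.unit_cell, 1.5)
        flags = make_free_flags(hkl, seed=3)
        perm = np.random.default_rng(0).permutation(len(hkl))
        flags_perm = make_free_flags(hkl[perm], seed=3)
        assert np.array_equal(flags[perm], flags_perm)


class TestRFactor:
    def test_perfect_fit_zero(self):
        f = np.array([3.0, 5.0, 2.0, 8.0])
        flags = np.array([False, False, True, False])
        r_work, r_free, scale = r_factor(2.0 * f, f.astype(complex), flags)
        assert r_work == pytest.approx(0.0, abs=1e-12)
        assert r_free == pytest.approx(0.0, abs=1e-12)
        assert scale == pytest.approx(2.0)

    def test_known_discrepancy(self):
        f_obs = np.array([1.0, 1.0, 2.4])
        f_calc = np.array([1.0 + 0j, 0.5 + 0j, 2.0 + 0j])
        flags = np.array([False, False, True])
        r_work, r_free, scale = r_factor(f_obs, f_calc, flags)
        assert r_free == pytest.approx(0.0, abs=1e-12)  # 2.4 = 1.2 * 2.0
        # scale k = sum(Fo*Fc)/sum(Fc^2) = 1.5/1.25 = 1.2
        assert scale == pytest.approx(1.2)
        # R = (|1-1.2| + |1-0.6|) / 2 = 0.3
        assert r_work == pytest.approx(0.3)


class TestLSTarget:
    def test_zero_at_generating_model(self):
        model = build_peptide(FixtureSpec(kind="dipeptide", n_residues=2,
                                          sequence=["ALA", "GLY"], seed=0))
        refl = synth_data(model, "reflections", resolution=2.0, noise=0.0,
                          seed=0)
        target = LSTarget(model, refl)
        t, grad = target.evaluate(model.get_coords())
        assert t == pytest.approx(0.0, abs=1e-15)
        assert np.abs(grad).max() == pytest.approx(0.0, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        model = build_peptide(FixtureSpec(kind="dipeptide", n_residues=2,
                                          sequence=["ALA", "GLY"], seed=0))
        refl = synth_data(model, "reflections", resolution=2.0, noise=0.05,
                          seed=1)
        target = LSTarget(model, refl)
        rng = np.random.default_rng(2)
        x = model.get_coords() + rng.normal(0, 0.1, (model.n_atoms, 3))
        _t, grad = target.evaluate(x)
        h = 1e-4
        for _ in range(10):
            i, k = rng.integers(model.n_atoms), rng.integers(3)
            xp, xm = x.copy(), x.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (target.evaluate(xp)[0] - target.evaluate(xm)[0]) / (2 * h)
            assert grad[i, k] == pytest.approx(
                fd, abs=1e-4 * max(1e-6, abs(fd)))


class TestReflectionIO:
    def test_tsv_roundtrip(self, tmp_path):
        model = toy_model()
        refl = synth_data(model, "reflections", resolution=2.5, noise=0.02,
                          seed=5)
        path = tmp_path / "r.tsv"
        write_reflections(refl, str(path))
        back = read_reflections(str(path))
        assert np.array_equal(back.hkl, refl.hkl)
        assert np.allclose(back.f_obs, refl.f_obs)
        assert np.array_equal(back.free_flag, refl.free_flag)
        assert back.cell.a == pytest.approx(refl.cell.a)
        assert back.space_group == refl.space_group

    def test_validation_rejects_bad_input(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        hkl = np.array([[1, 0, 0], [1, 0, 0]])        # duplicate
        with pytest.raises(DataError):
            ReflectionSet(hkl, np.array([1.0, 2.0]),
                          np.array([False, False]), cell, "P 1")
        with pytest.raises(DataError):
            ReflectionSet(np.array([[1, 0, 0]]), np.array([-1.0]),
                          np.array([False]), cell, "P 1")   # negative F
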