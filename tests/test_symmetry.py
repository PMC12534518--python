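import gemmi
import numpy as np
import pytest

from mmrefine import (Atom, AtomicModel, Chain, FixtureSpec, Residue,
                      SurrogateBackend, UnitCell, build_peptide,
                      build_restraints, expand_supercell, known_space_groups,
                      parse_triplet, symops_for)
from mmrefine.symmetry import SymmetryError


def op_set(ops):
    return {(op.rot, op.trans) for op in ops}


def gemmi_ops(symbol):
    out = set()
    for gop in gemmi.SpaceGroup(symbol).operations():
        rot = tuple(tuple(v // gop.DEN for v in row) for row in gop.rot)
        from fractions import Fraction
        trans = tuple(Fraction(t, gop.DEN) % 1 for t in gop.tran)
        out.add((rot, trans))
    return out


class TestTriplets:
    def test_parse_identity(self):
        op = parse_triplet("x,y,z")
        assert op.is_identity

    def test_parse_fractions_and_signs(self):
        op = parse_triplet("-y+1/2,x-y,z+2/3")
        assert op.rot == ((0, -1, 0), (1, -1, 0), (0, 0, 1))
        assert [float(t) for t in op.trans] == \
            pytest.approx([0.5, 0.0, 2.0 / 3.0])

    def test_triplet_roundtrip(self):
        for trip in ("x,y,z", "-x+1/2,-y,z+1/2", "y,x,-z",
                     "x-y,x,z+5/6"):
            op = parse_triplet(trip)
            assert parse_triplet(op.triplet()) == op

    def test_bad_triplet_rejected(self):
        with pytest.raises(Exception):
            parse_triplet("x,y")


class TestSpaceGroups:
    def test_sohncke_count(self):
        """65 distinct Sohncke groups (symbol list includes aliases)."""
        distinct = {frozenset(op_set(symops_for(s)))
                    for s in known_space_groups()}
        assert len(distinct) == 65

    @pytest.mark.parametrize("symbol", [
        "P 1", "P 21 21 21", "C 2", "P 61", "I 4", "R 32", "F 4 3 2",
        "P 65 2 2", "I 2 3"])
    def test_ops_match_gemmi(self, symbol):
        """Shipped operator table vs an independent crystallographic
        library, including centering translations."""
        assert op_set(symops_for(symbol)) == gemmi_ops(symbol)

    def test_group_closure(self):
        for symbol in ("P 21 21 21", "C 2", "R 32"):
            ops = symops_for(symbol)
            members = op_set(ops)
            for a in ops:
                for b in ops:
                    assert (a.compose(b).rot, a.compose(b).trans) in members

    def test_alias_lookup(self):
        assert op_set(symops_for("P212121")) == \
            op_set(symops_for("P 21 21 21"))

    def test_unknown_group_raises(self):
        with pytest.raises(SymmetryError):
            symops_for("P -1")   # non-Sohncke: not shipped


def single_atom_model():
    cell = UnitCell(10, 100, 100, 90, 90, 90)
    atom = Atom("NA", "NA", np.array([0.5, 0.0, 0.0]))   # frac 0.05,0,0
    return AtomicModel([Chain("A", [Residue("NA", 1, "", [atom])])],
                       cell, "P 1")


class TestExpansion:
    def test_p1_translation_counts(self):
        model = single_atom_model()
        sm5 = expand_supercell(model, 5.0)
        assert sm5.expanded_model.n_atoms - model.n_atoms == 0
        sm12 = expand_supercell(model, 12.0)
        assert sm12.expanded_model.n_atoms - model.n_atoms == 2

    def test_counts_match_brute_force_enumeration(self):
        """Whole-residue image retention vs direct enumeration of every
        op/translation image residue on a P 21 21 21 fixture."""
        cell = UnitCell(12, 13, 14, 90, 90, 90)
        rng = np.random.default_rng(3)
        residues = [Residue("GLY", k + 1, "", [
            Atom("N", "N", c) for c in rng.uniform(0, 8, (3, 3))])
            for k in range(4)]
        model = AtomicModel([Chain("A", residues)], cell, "P 21 21 21")
        radius = 6.0
        x = model.get_coords()
        m_orth = cell.orthogonalization_matrix()
        m_frac = cell.fractionalization_matrix()
        xf = x @ m_frac.T
        expected = 0
        for op in symops_for("P 21 21 21"):
            for sa in range(-4, 5):
                for sb in range(-4, 5):
                    for sc in range(-4, 5):
                        if op.is_identity and sa == sb == sc == 0:
                            continue
                        img = (op.apply(xf)
                               + np.array([sa, sb, sc])) @ m_orth.T
                        d = np.linalg.norm(
                            img[:, None, :] - x[None, :, :], axis=-1)
                        for res_start in range(0, 12, 3):
                            grp = slice(res_start, res_start + 3)
                            if d[grp].min() < radius:
                                expected += 3    # whole residue kept
        sm = expand_supercell(model, radius)
        assert sm.expanded_model.n_atoms - model.n_atoms == expected

    def test_requires_cell(self):
        model = single_atom_model()
        model.unit_cell = None
        with pytest.raises(SymmetryError):
            expand_supercell(model, 5.0)


@pytest.fixture(scope="module")
def crystal_helix():
    model = build_peptide(FixtureSpec(kind="helix", n_residues=3,
                                      sequence=["ALA", "SER", "GLY"],
                                      seed=0))
    model.unit_cell = UnitCell(11, 11, 11, 90, 90, 90)
    model.space_group = "P 21 21 21"
    return model


def supercell_energy(model, radius=5.0):
    sm = expand_supercell(model, radius)
    backend = SurrogateBackend(build_restraints(sm.expanded_model))
    return backend.energy_forces(sm.expand_coords(model.get_coords()))[0]


class TestSupercellPhysics:
    def test_energy_invariant_under_asu_rechoice(self, crystal_helix):
        """Replacing the ASU by any symmetry/lattice equivalent leaves the
        truncated supercell energy unchanged (< 1e-8)."""
        model = crystal_helix
        e0 = supercell_energy(model)
        cell = model.unit_cell
        m_orth = cell.orthogonalization_matrix()
        m_frac = cell.fractionalization_matrix()
        xf = model.get_coords() @ m_frac.T
        for op in symops_for(model.space_group):
            for extra in ((0, 0, 0), (1, 0, -1)):
                alt = model.copy()
                moved = op.apply(xf) + np.array(extra, float)
                alt.set_coords(moved @ m_orth.T)
                assert abs(supercell_energy(alt) - e0) < 1e-8

    def test_folded_gradient_matches_finite_differences(self, crystal_helix):
        """d(supercell energy)/d(ASU coords), with every image following
        its generator, checked against central differences."""
        model = crystal_helix
        sm = expand_supercell(model, 5.0)
        assert sm.expanded_model.n_atoms > model.n_atoms  # env present
        backend = SurrogateBackend(build_restraints(sm.expanded_model))

        def value_grad(x):
            e, f = backend.energy_forces(sm.expand_coords(x))
            return e, -sm.fold_gradients(f)

        x0 = model.get_coords()
        _e, grad = value_grad(x0)
        rng = np.random.default_rng(0)
        h = 1e-5
        for _ in range(12):          # spot-check random components
            i, k = rng.integers(len(x0)), rng.integers(3)
            xp, xm = x0.copy(), x0.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (value_grad(xp)[0] - value_grad(xm)[0]) / (2 * h)
            assert grad[i, k] == pytest.approx(fd, abs=1e-5 * max(
                1.0, abs(fd)))

    def test_environment_atoms_move_with_asu(self, crystal_helix):
        sm = expand_supercell(crystal_helix, 5.0)
        x = crystal_helix.get_coords()
        shifted = sm.expand_coords(x + 0.1)
        base = sm.expand_coords(x)
        # every expanded atom moves: images follow their generator rigidly
        assert np.linalg.norm(shifted - base, axis=1).min() > 0.0
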