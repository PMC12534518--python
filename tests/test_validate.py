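import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmrefine import (Atom, AtomicModel, Chain, FixtureSpec, Residue,
                      build_peptide, build_restraints, compare_models,
                      filter_entries, find_hbonds, geometry_rmsd, perturb,
                      rama_classify, skew_kurtosis)
from mmrefine.geomlib import axis_rotation, unit
from mmrefine.validate import ValidationError


@pytest.fixture(scope="module")
def helix():
    return build_peptide(FixtureSpec(kind="helix", n_residues=8,
                                     sequence=["ALA"] * 8, seed=0))


class TestGeometryRmsd:
    def test_ideal_fixture_zero(self, helix):
        rs = build_restraints(helix)
        rmsd_bond, rmsd_angle = geometry_rmsd(helix, rs)
        assert rmsd_bond == pytest.approx(0.0, abs=1e-6)
        assert rmsd_angle == pytest.approx(0.0, abs=1e-6)

    def test_single_stretched_bond_arithmetic(self, helix):
        """One bond stretched by +delta among n ideal bonds gives
        rmsd = delta / sqrt(n)."""
        m = helix.copy()
        rs = build_restraints(m)
        x = m.get_coords()
        i, j, d0, _k = rs.bonds[0]
        i, j = int(i), int(j)
        direction = unit(x[j] - x[i])
        # stretch bond 0 by exactly 0.1 A, moving only atom j if j is a
        # leaf would disturb others; instead verify on the measured values
        x2 = x.copy()
        x2[j] = x[i] + (d0 + 0.1) * direction
        m.set_coords(x2)
        rmsd_bond, _ = geometry_rmsd(m, rs)
        n = len(rs.bonds)
        # other bonds through atom j also move; measure directly instead
        d = np.array([np.linalg.norm(x2[int(a)] - x2[int(b)])
                      for a, b, _d, _kk in rs.bonds])
        expected = np.sqrt(np.mean((d - rs.bonds[:, 2]) ** 2))
        assert rmsd_bond == pytest.approx(expected, abs=1e-12)
        assert rmsd_bond >= 0.1 / np.sqrt(n) - 1e-9

    def test_invariant_under_rigid_motion(self, helix):
        rs = build_restraints(helix)
        m = helix.copy()
        rot = axis_rotation(unit(np.array([1.0, 1.0, 0.0])), 0.7)
        m.set_coords(helix.get_coords() @ rot.T + 4.0)
        assert geometry_rmsd(m, rs) == pytest.approx(
            geometry_rmsd(helix, rs), abs=1e-9)


def oh_o_toy(angle_deg_val=165.0, d_ha=1.9):
    """A minimal O-H donor (serine hydroxyl) aimed at a carbonyl O."""
    og = np.array([0.0, 0.0, 0.0])
    hg = np.array([0.96, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg_val)
    a = hg + d_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    c = a + 1.23 * np.array([np.cos(theta), np.sin(theta), 0.0])
    cb = og + np.array([-0.7, 1.2, 0.0])
    res1 = Residue("SER", 1, "", [Atom("CB", "C", cb), Atom("OG", "O", og),
                                  Atom("HG", "H", hg)])
    res2 = Residue("GLY", 2, "", [Atom("O", "O", a), Atom("C", "C", c)])
    return AtomicModel([Chain("A", [res1]), Chain("B", [res2])])


class TestFindHbonds:
    def test_toy_geometry_detected(self):
        import warnings
        model = oh_o_toy(165.0, 1.9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # fragments are incomplete
            hb = find_hbonds(model)
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(1.9, abs=1e-9)
        assert hb[0].angle == pytest.approx(165.0, abs=1e-6)

    def test_low_angle_rejected(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert find_hbonds(oh_o_toy(100.0, 1.9)) == []

    def test_long_distance_rejected(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert find_hbonds(oh_o_toy(165.0, 2.9)) == []

    def test_helix_backbone_count(self, helix):
        """An n-residue alpha-helix has n-4 backbone i -> i+4 H-bonds."""
        hb = find_hbonds(helix)
        backbone = [h for h in hb]
        assert len(backbone) == 8 - 4

    def test_invariant_under_rigid_motion(self, helix):
        m = helix.copy()
        rot = axis_rotation(unit(np.array([0.0, 1.0, 2.0])), 1.3)
        m.set_coords(helix.get_coords() @ rot.T - 7.0)
        hb0 = find_hbonds(helix)
        hb1 = find_hbonds(m)
        assert [(h.hydrogen, h.acceptor) for h in hb0] == \
            [(h.hydrogen, h.acceptor) for h in hb1]
        for a, b in zip(hb0, hb1):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)
            assert a.angle == pytest.approx(b.angle, abs=1e-7)

    def test_unprotonated_donor_warns(self, helix):
        m = helix.copy()
        res = m.chains[0].residues[3]
        res.atoms = [a for a in res.atoms if a.name != "H"]
        with pytest.warns(UserWarning, match="unprotonated"):
            find_hbonds(m)


class TestSkewKurtosis:
    def test_symmetric_sample_zero_skew(self):
        skew, _ = skew_kurtosis([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_moment_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            v = rng.normal(2.0, 3.0, 500)
            skew, kurt = skew_kurtosis(v)
            m = v - v.mean()
            m2, m3, m4 = (np.mean(m ** p) for p in (2, 3, 4))
            assert skew == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
            assert kurt == pytest.approx(m4 / m2 ** 2 - 3.0, abs=1e-12)

    def test_matches_scipy(self):
        v = np.random.default_rng(6).exponential(size=2000)
        skew, kurt = skew_kurtosis(v)
        assert skew == pytest.approx(stats.skew(v, bias=True), abs=1e-12)
        assert kurt == pytest.approx(stats.kurtosis(v, bias=True),
                                     abs=1e-12)

    def test_exponential_closed_form(self):
        """Exponential: skew 2, excess kurtosis 6.  A single n=1e5 draw
        has kurtosis sampling sd ~0.28, larger than the 0.1 tolerance,
        so the statistics are averaged over 30 seeded draws."""
        skews, kurts = [], []
        for seed in range(30):
            v = np.random.default_rng(seed).exponential(size=100000)
            s, k = skew_kurtosis(v)
            skews.append(s)
            kurts.append(k)
        assert np.mean(skews) == pytest.approx(2.0, abs=0.1)
        assert np.mean(kurts) == pytest.approx(6.0, abs=0.1)

    def test_normal_closed_form(self):
        v = np.random.default_rng(8).normal(size=100000)
        skew, kurt = skew_kurtosis(v)
        assert skew == pytest.approx(0.0, abs=0.05)
        assert kurt == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            skew_kurtosis([2.0, 2.0, 2.0])


class TestRamaClassify:
    def test_ideal_helix_all_favored(self, helix):
        classes, fractions = rama_classify(helix)
        assert fractions["favored"] == pytest.approx(1.0)
        assert len(classes) == 8 - 2    # termini unclassified

    def test_left_handed_outlier(self):
        """phi=+60, psi=-60 for a non-Gly residue is an outlier."""
        from mmrefine.validate import _point_in_regions
        from mmrefine.library import rama_regions
        table = rama_regions()["general"]
        assert not _point_in_regions(60.0, -60.0, table["favored"])
        assert not _point_in_regions(60.0, -60.0, table["allowed"])

    def test_strand_classified(self):
        m = build_peptide(FixtureSpec(kind="strand", n_residues=5,
                                      sequence=["ALA"] * 5, seed=0))
        _classes, fractions = rama_classify(m)
        assert fractions["outlier"] == pytest.approx(0.0)


class TestCompareModels:
    def test_self_zero(self, helix):
        assert compare_models(helix, helix, "cartesian") == \
            pytest.approx(0.0, abs=1e-9)
        assert compare_models(helix, helix, "torsion") == \
            pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, helix):
        m = helix.copy()
        rot = axis_rotation(unit(np.array([2.0, -1.0, 0.5])), 0.9)
        m.set_coords(helix.get_coords() @ rot.T + np.array([1.0, 2.0, 3.0]))
        assert compare_models(helix, m, "cartesian") == \
            pytest.approx(0.0, abs=1e-9)
        assert compare_models(helix, m, "torsion") == \
            pytest.approx(0.0, abs=1e-9)

    def test_single_chi_rotation_arithmetic(self):
        """Rotating one chi by 10 degrees: torsion rmsd = 10/sqrt(n) over
        the n matched angles."""
        m1 = build_peptide(FixtureSpec(kind="helix", n_residues=3,
                                       sequence=["GLY", "SER", "GLY"],
                                       seed=0))
        m2 = m1.copy()
        res = m2.chains[0].residues[1]
        ca, cb = res.atom("CA"), res.atom("CB")
        rot = axis_rotation(unit(cb.coords - ca.coords), np.radians(10.0))
        for atom in res.atoms:
            if atom.name in ("OG", "HG", "HB2", "HB3"):
                atom.coords = rot @ (atom.coords - cb.coords) + cb.coords
        # matched angles: phi/psi/omega sets unchanged, one chi differs
        from mmrefine.topology import Topology
        rmsd = compare_models(m1, m2, "torsion")
        # count matched torsions to form the expected value
        n_angles = 0
        from mmrefine.validate import _matched_instances, _torsion_quads
        for ia, _ib in _matched_instances(m1, m2, None):
            n_angles += len(_torsion_quads(ia))
        assert rmsd == pytest.approx(10.0 / np.sqrt(n_angles), abs=1e-6)

    def test_no_match_raises(self, helix):
        other = build_peptide(FixtureSpec(kind="helix", n_residues=3,
                                          sequence=["GLY"] * 3, seed=0))
        with pytest.raises(ValidationError):
            compare_models(helix, other, "cartesian")


def metadata_table():
    base = dict(n_atoms=5000, resolution=3.0, clashscore=20,
                bond_outlier_rmsd_multiple=2, experiment="xray",
                cc_mask=np.nan, r_work=0.25, homolog_resolution=1.8,
                homolog_rmsd=0.5, homolog_identity=98.0)
    rows, expected = [], []
    rows.append(dict(base)); expected.append((True, ""))
    rows.append(dict(base, n_atoms=500)); expected.append((False, "size"))
    rows.append(dict(base, n_atoms=10000)); expected.append((True, ""))
    rows.append(dict(base, resolution=4.0)); expected.append((True, ""))
    rows.append(dict(base, resolution=4.1))
    expected.append((False, "resolution"))
    rows.append(dict(base, clashscore=50))
    expected.append((False, "clashscore"))
    rows.append(dict(base, bond_outlier_rmsd_multiple=5))
    expected.append((False, "bond outliers"))
    rows.append(dict(base, r_work=0.35)); expected.append((False, "data fit"))
    rows.append(dict(base, experiment="cryoem", cc_mask=0.55, r_work=np.nan))
    expected.append((False, "data fit"))
    rows.append(dict(base, homolog_identity=90.0))
    expected.append((False, "homolog identity"))
    return pd.DataFrame(rows), expected


class TestFilterEntries:
    def test_ten_row_table_hand_checked(self):
        table, expected = metadata_table()
        assert len(table) == 10
        out = filter_entries(table)
        for (ok, reason), (_, row) in zip(expected, out.iterrows()):
            assert row["accepted"] == ok, row
            assert row["reason"] == reason, row

    def test_missing_column_rejected(self):
        table, _ = metadata_table()
        with pytest.raises(ValidationError):
            filter_entries(table.drop(columns=["clashscore"]))
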