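"""Synthetic model and data generators.

Everything in the test suite and the documentation runs from models and
data built here: ideal internal-coordinate peptides (helix / strand /
dipeptide), a posed carboxylate pair for hydrogen-position scans, seeded
Gaussian coordinate perturbation, and synthetic reflection/map data derived
from a generating model.  All generators are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geomlib import nerf, unit
from .library import library
from .model import Atom, AtomicModel, Chain, Residue, UnitCell
from .scatter import (DataError, ReflectionSet, calc_structure_factors,
                      generate_hkl, make_free_flags)
from .topology import add_hydrogens, build_restraints, detect_clashes

# Ideal backbone internal coordinates used by the builder (identical to the
# restraint ideals, so built models score zero bonded restraint energy).
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7,
    "ca_c_o": 120.8, "ca_c_oxt": 117.0, "c_oxt": 1.249,
}

_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic test case."""

    kind: str = "helix"                  # helix | strand | dipeptide
    n_residues: int = 10
    sequence: list[str] | None = None    # default poly-ALA
    seed: int = 0
    sigma: float = 0.0                   # perturbation, Angstrom
    data_kind: str = "reflections"       # reflections | map
    resolution: float = 2.0
    noise: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in ("helix", "strand", "dipeptide"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def build_peptide(spec: FixtureSpec) -> AtomicModel:
    """Ideal internal-coordinate peptide, fully protonated, in a P 1 cell.

    Helix torsions phi=-57, psi=-47; strand phi=-120, psi=+120; dipeptide
    is a 2-residue helix-torsion fragment.  The cell is a padded box
    (>= 10 A margin on every side).
    """
    kind = "helix" if spec.kind == "dipeptide" else spec.kind
    n_res = 2 if spec.kind == "dipeptide" else spec.n_residues
    sequence = spec.sequence or ["ALA"] * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length does not match n_residues")
    lib = library()
    for name in sequence:
        if name not in lib:
            raise ValueError(f"unknown residue {name!r}")
    phi, psi = _PHI_PSI[kind]

    residues = []
    prev = None   # (N, CA, C) of previous residue
    for i, name in enumerate(sequence):
        # backbone bond lengths are per-residue library values (glycine
        # differs slightly from the other residues)
        tpl_bonds = {tuple(sorted(p)): v for p, v in lib[name].bonds.items()}
        n_ca = tpl_bonds[("CA", "N")]
        ca_c = tpl_bonds[("C", "CA")]
        if prev is None:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([n_ca, 0.0, 0.0])
            ang = np.radians(180.0 - _BB["n_ca_c"])
            c = ca + ca_c * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            pn, pca, pc = prev
            n = nerf(pn, pca, pc, _BB["c_n"], _BB["ca_c_n"], psi)
            ca = nerf(pca, pc, n, n_ca, _BB["c_n_ca"], 180.0)
            c = nerf(pc, n, ca, ca_c, _BB["n_ca_c"], phi)
        # carbonyl O in the peptide plane, anti to the next N
        o_tors = psi + 180.0
        o = nerf(n, ca, c, _BB["c_o"], _BB["ca_c_o"], o_tors)
        res = Residue(name=name, number=i + 1, atoms=[
            Atom("N", "N", n), Atom("CA", "C", ca),
            Atom("C", "C", c), Atom("O", "O", o),
        ])
        if i == len(sequence) - 1:
            oxt = nerf(n, ca, c, _BB["c_oxt"], _BB["ca_c_oxt"], psi)
            res.add_atom(Atom("OXT", "O", oxt))
        residues.append(res)
        prev = (n, ca, c)

    model = AtomicModel(chains=[Chain(name="A", residues=residues)])
    _build_side_chains(model)
    add_hydrogens(model)
    _optimize_rotamers(model)
    _box_model(model, padding=10.0)
    return model


def _optimize_rotamers(model: AtomicModel) -> None:
    """Pick the lowest-overlap staggered rotamer for each side-chain chi.

    A 120-degree rotation of the distal group about a chi bond is a rigid
    motion of that group, so every bonded restraint term (including the
    threefold torsion potentials) is exactly invariant; only nonbonded
    contacts change.  Ideal-geometry fixtures therefore stay exactly
    ideal while avoiding accidental side-chain/backbone clashes.
    """
    from . import topology as topo_mod
    from .energy import restraint_energy
    from .geomlib import axis_rotation, unit

    topo = topo_mod.Topology(model)
    rs = topo_mod.build_restraints(model, topology=topo)
    x = model.get_coords()
    for inst in topo.instances:
        for quad in inst.template.chi:
            if not all(n in inst.index_of for n in quad):
                continue
            b, c = inst.index_of[quad[1]], inst.index_of[quad[2]]
            distal: list[int] = []
            seen, stack = {b, c}, [c]
            while stack:
                u = stack.pop()
                for v in topo.neighbors[u]:
                    if v not in seen:
                        seen.add(v)
                        distal.append(v)
                        stack.append(v)
            if not distal:
                continue
            idxs = np.array(sorted(distal))
            best_e, best_x = None, None
            for offset in (0.0, 120.0, -120.0):
                xi = x.copy()
                if offset:
                    rot = axis_rotation(unit(x[c] - x[b]),
                                        np.radians(offset))
                    xi[idxs] = (xi[idxs] - x[c]) @ rot.T + x[c]
                e, _ = restraint_energy(rs, xi)
                if best_e is None or e < best_e - 1e-9:
                    best_e, best_x = e, xi
            x = best_x
    model.set_coords(x)


def _build_side_chains(model: AtomicModel) -> None:
    """Place missing heavy side-chain atoms at ideal template geometry.

    Atoms are added iteratively outward from the backbone using the same
    rigid ideal-frame machinery as hydrogen placement, with side-chain
    torsions anti (trans) by construction.
    """
    from . import topology as topo_mod

    for chain in model.chains:
        for res in chain.residues:
            pending = True
            while pending:
                pending = False
                topo = topo_mod.Topology(model)
                inst = next(
                    i for i in topo.instances
                    if i.residue is res and i.chain is chain)
                itpl = inst.template
                by_center: dict[str, list[str]] = {}
                for name, atom in itpl.atoms.items():
                    if atom.geom == "h" or res.has_atom(name):
                        continue
                    if name in ("O", "OXT"):
                        continue
                    parent = next(
                        (nb for nb in itpl.heavy_neighbors(name)
                         if res.has_atom(nb)), None)
                    if parent is not None:
                        by_center.setdefault(parent, []).append(name)
                if not by_center:
                    break
                center = sorted(by_center)[0]
                targets = sorted(by_center[center])
                known = {}
                for nb in itpl._heavy_context_neighbors(center):
                    if nb == "-C" and inst.prev is not None:
                        known[nb] = inst.prev.residue.atom("C").coords
                    elif nb == "+N" and inst.next is not None:
                        known[nb] = inst.next.residue.atom("N").coords
                    elif res.has_atom(nb):
                        known[nb] = res.atom(nb).coords
                stagger = None
                geo_names = [k for k in known
                             if k in itpl.center_geometry(center)]
                if len(geo_names) == 1:
                    anchor_name = geo_names[0]
                    for nb in itpl.heavy_neighbors(anchor_name):
                        if nb != center and res.has_atom(nb):
                            stagger = res.atom(nb).coords
                            break
                    if stagger is None and anchor_name == "CA":
                        stagger = res.atom("N").coords
                new_pos = topo_mod._complete_center(
                    itpl, center, res.atom(center).coords, known,
                    targets, stagger)
                for name in targets:
                    atom = itpl.atoms[name]
                    res.add_atom(Atom(name=name, element=atom.element,
                                      coords=new_pos[name],
                                      formal_charge=atom.formal_charge))
                pending = True


def _box_model(model: AtomicModel, padding: float = 10.0) -> None:
    """Translate into the positive octant and set a padded P 1 cell."""
    coords = model.get_coords()
    lo = coords.min(axis=0)
    model.set_coords(coords - lo + padding)
    extent = coords.max(axis=0) - lo + 2.0 * padding
    model.unit_cell = UnitCell(*np.ceil(extent), 90.0, 90.0, 90.0)
    model.space_group = "P 1"


def build_carboxylate_pair(d_oo: float,
                           symmetric: bool = False,
                           bias_charge: float | None = None) -> AtomicModel:
    """Two capped carboxylate side chains facing across an O...O contact.

    A Glu-like and an Asp-like fragment are placed so the facing
    carboxylate oxygens sit ``d_oo`` apart, sharing a single proton at the
    midpoint of the O...O vector (assign the ``protonated`` variant to
    residue 1 when building restraints so the proton is covalently
    anchored).  With ``symmetric`` both fragments are identical charged
    Asp-like carboxylates posed as an exact inversion pair, and the proton
    is a bare shared H+ (formal charge +1, no covalent anchor), so the
    whole system — geometry and charges — is centro-symmetric.
    ``bias_charge`` adds a fixed sodium-like +1 probe near the second
    oxygen (for biased-scan tests).
    """
    if not 2.3 < d_oo < 3.2:
        raise ValueError("d_OO outside supported range (2.3, 3.2)")

    def carboxylate_coords():
        """Carboxylate fragment in a local frame, donor O on the +x axis.

        Returns positions for (C_attached, C_carboxyl, O_anti, O_donor)
        with the carboxyl carbon at the origin and the donor oxygen
        pointing along +x (toward the partner fragment).
        """
        half = np.radians(123.4)
        o_donor = 1.249 * np.array([1.0, 0.0, 0.0])
        o_anti = 1.249 * np.array([np.cos(half), np.sin(half), 0.0])
        bisector = unit(unit(o_donor) + unit(o_anti))
        c_att = -1.516 * bisector
        return c_att, np.zeros(3), o_anti, o_donor

    name_a = "ASP" if symmetric else "GLU"
    atom_names = {"ASP": ("CB", "CG", "OD1", "OD2"),
                  "GLU": ("CG", "CD", "OE1", "OE2")}
    local = carboxylate_coords()
    res_a = Residue(name=name_a, number=1, atoms=[
        Atom(n, "C" if n[0] == "C" else "O", p.copy())
        for n, p in zip(atom_names[name_a], local)])

    # fragment B is the inversion of the local fragment through the proton
    # midpoint, which lies d_oo/2 beyond the donor oxygen along +x — the
    # pose is therefore exactly centro-symmetric by construction
    o2_a = res_a.atoms[3].coords
    mid = o2_a + np.array([d_oo / 2.0, 0.0, 0.0])
    res_b = Residue(name="ASP", number=2, atoms=[
        Atom(n, "C" if n[0] == "C" else "O", 2.0 * mid - p)
        for n, p in zip(atom_names["ASP"], local)])

    # the shared proton: covalent to O2 of fragment A (protonated
    # variant) in the asymmetric pose, a bare H+ in the symmetric one
    res_a.add_atom(Atom("HD2" if symmetric else "HE2", "H", mid.copy(),
                        formal_charge=1 if symmetric else 0))

    residues = [res_a, res_b]
    if bias_charge is not None:
        o2_b = res_b.atoms[3].coords
        probe = Residue(name="NA", number=3, atoms=[
            Atom("NA", "NA", o2_b + np.array([0.0, 2.5, 0.0]),
                 formal_charge=1)])
        residues.append(probe)
    model = AtomicModel(chains=[Chain(name="A", residues=residues)])
    _box_model(model, padding=10.0)
    return model


def perturb(model: AtomicModel, sigma: float, seed: int) -> AtomicModel:
    """Seeded i.i.d. Gaussian coordinate noise; returns a new model."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = model.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        coords = out.get_coords()
        out.set_coords(coords + rng.normal(0.0, sigma, coords.shape))
    return out


def synth_data(model: AtomicModel, kind: str, resolution: float,
               noise: float, seed: int):
    """Synthetic data from a generating model.

    ``kind='reflections'``: all unique-hemisphere hkl to ``resolution``,
    F_obs = |F_calc| * (1 + eps), eps ~ N(0, noise), deterministic seeded
    free flags (5%).  ``kind='map'``: Fourier synthesis on a grid of
    spacing resolution/4, plus N(0, noise * sigma_map) voxel noise.
    """
    if resolution < 0.5:
        raise DataError("resolution finer than 0.5 A is outside the "
                        "validity of the shipped form factors")
    if model.unit_cell is None:
        raise DataError("synthetic data require a cell/box")
    if kind == "reflections":
        hkl = generate_hkl(model.unit_cell, resolution)
        f_calc = calc_structure_factors(model, hkl)
        amp = np.abs(f_calc)
        rng = np.random.default_rng(seed)
        f_obs = amp * (1.0 + rng.normal(0.0, noise, len(amp))) \
            if noise > 0 else amp.copy()
        f_obs = np.abs(f_obs)
        return ReflectionSet(hkl=hkl, f_obs=f_obs,
                             free_flag=make_free_flags(hkl, seed),
                             cell=model.unit_cell,
                             space_group=model.space_group or "P 1")
    if kind == "map":
        from .maps import map_from_model_fourier

        dmap = map_from_model_fourier(model, resolution)
        if noise > 0:
            rng = np.random.default_rng(seed)
            dmap.values = dmap.values + rng.normal(
                0.0, noise * dmap.values.std(), dmap.values.shape)
        return dmap
    raise ValueError(f"unknown data kind {kind!r}")


def clash_check(model: AtomicModel) -> int:
    """Convenience: number of hard clashes in a fixture."""
    rs = build_restraints(model)
    return len(detect_clashes(model, rs))
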