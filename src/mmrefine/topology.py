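"""Restraint generation and model finalisation.

Turns an :class:`~mmrefine.model.AtomicModel` plus the embedded residue
library into a :class:`RestraintSet`: typed lists of bond / angle / torsion /
planarity / chirality terms with ideal values and weights, the nonbonded
exclusion structure, per-atom van der Waals radii, partial charges and
donor/acceptor annotations.  Also provides the preparation steps that
precede refinement: completeness checking, hydrogen placement at
geometrically predicted positions, clash detection, and restraint-only
regularization that moves atoms as little as necessary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import library as lib
from .geomlib import (align_rotation as _align_rotation,
                      axis_rotation as _axis_rotation,
                      dihedral_deg, kabsch_rotation, unit)
from .model import Atom, AtomicModel, Chain, Residue

logger = logging.getLogger(__name__)

PEPTIDE_CUTOFF = 2.0  # A, C(i)-N(i+1) distance implying a peptide link

# Charge adjustments for charged termini (Charmm-style patch values).
_NTER_CHARGES = {"N": -0.30, "CA": 0.21, "HA": 0.10, "HA2": 0.10,
                 "HA3": 0.10, "H1": 0.33, "H2": 0.33, "H3": 0.33}
_CTER_CHARGES = {"C": 0.34, "O": -0.67, "OXT": -0.67}


class TopologyError(ValueError):
    pass


@dataclass
class RestraintSet:
    """Typed restraint lists indexing into a model's flat atom order."""

    n_atoms: int
    bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 4)))       # i, j, d0, k
    angles: np.ndarray = field(
        default_factory=lambda: np.empty((0, 5)))       # i, center, j, th0, k
    torsions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 7)))       # i,j,k,l, n, phi0, k
    planes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    chirality: np.ndarray = field(
        default_factory=lambda: np.empty((0, 6)))       # c,n1,n2,n3, v0, k

    excluded: set[tuple[int, int]] = field(default_factory=set)  # 1-2, 1-3
    pair14: set[tuple[int, int]] = field(default_factory=set)
    vdw_radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    charges: np.ndarray = field(default_factory=lambda: np.empty(0))
    elements: list[str] = field(default_factory=list)
    is_polar_h: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    is_donor: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    is_acceptor: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    donors: list[tuple[int, int]] = field(default_factory=list)  # (D, H)
    neighbors: list[set[int]] = field(default_factory=list)
    nonbonded_k: float = 50.0

    def allowed_distance(self, i: int, j: int) -> float:
        """vdW-sum allowed approach for a pair, with H-bond reductions."""
        red = lib.nonbonded_params()["reductions"]
        d = self.vdw_radii[i] + self.vdw_radii[j]
        hb_pair = ((self.is_polar_h[i] and self.is_acceptor[j])
                   or (self.is_polar_h[j] and self.is_acceptor[i]))
        da_pair = ((self.is_donor[i] and self.is_acceptor[j])
                   or (self.is_donor[j] and self.is_acceptor[i]))
        if hb_pair:
            d -= red["polar_h_acceptor"]
        elif da_pair:
            d -= red["donor_acceptor"]
        return d

    def dump(self) -> str:
        """Deterministic text dump (debugging / regression tests)."""
        out = []
        for i, j, d0, k in self.bonds:
            out.append(f"bond {int(i)} {int(j)} {d0:.4f} {k:.1f}")
        for i, c, j, t0, k in self.angles:
            out.append(f"angle {int(i)} {int(c)} {int(j)} "
                       f"{np.degrees(t0):.3f} {k:.1f}")
        for i, j, kk, l, n, p0, k in self.torsions:
            out.append(f"torsion {int(i)} {int(j)} {int(kk)} {int(l)} "
                       f"{int(n)} {np.degrees(p0):.1f} {k:.2f}")
        for idxs, k in self.planes:
            out.append("plane " + " ".join(str(int(x)) for x in idxs)
                       + f" {k:.1f}")
        for c, a, b, d, v0, k in self.chirality:
            out.append(f"chir {int(c)} {int(a)} {int(b)} {int(d)} "
                       f"{v0:.4f} {k:.1f}")
        return "\n".join(out) + "\n"


@dataclass
class ResidueInstance:
    chain: Chain
    residue: Residue
    template: lib.ResidueTemplate | None
    index_of: dict[str, int]          # template atom name -> flat model index
    prev: "ResidueInstance | None" = None
    next: "ResidueInstance | None" = None

    @property
    def is_nterm(self) -> bool:
        return self.prev is None

    @property
    def is_cterm(self) -> bool:
        return self.next is None


def _copy_template(tpl: lib.ResidueTemplate) -> lib.ResidueTemplate:
    out = lib.ResidueTemplate(
        tpl.name,
        {k: lib.TemplateAtom(v.name, v.element, v.geom, v.charge, v.parent,
                             v.formal_charge) for k, v in tpl.atoms.items()},
        dict(tpl.bonds), [list(p) for p in tpl.planes],
        list(tpl.chirality), [list(c) for c in tpl.chi],
        dict(tpl.angle_overrides), dict(tpl.variants))
    out.has_prev = getattr(tpl, "has_prev", True)
    return out


def _instance_template(name: str, variant: str | None,
                       nterm: bool, cterm: bool) -> lib.ResidueTemplate:
    tpl = lib.get_template(name)
    tpl = tpl.with_variant(variant) if variant else _copy_template(tpl)
    tpl.has_prev = not nterm
    if nterm and name == "PRO":
        for hname in ("H2", "H3"):
            tpl.atoms[hname] = lib.TemplateAtom(hname, "H", "h", 0.33, "N")
        tpl.atoms["N"].formal_charge = 1
    elif nterm and name != "ACE" and "N" in tpl.atoms:
        tpl.atoms.pop("H", None)
        for hname in ("H1", "H2", "H3"):
            tpl.atoms[hname] = lib.TemplateAtom(hname, "H", "h", 0.33, "N")
        for aname, q in _NTER_CHARGES.items():
            if aname in tpl.atoms:
                tpl.atoms[aname].charge = q
        tpl.atoms["N"].formal_charge = 1
        tpl.atoms["N"].geom = "sp3"
    if cterm and "O" in tpl.atoms and name != "NME":
        tpl.atoms["OXT"] = lib.TemplateAtom("OXT", "O", "sp2", -0.67,
                                            formal_charge=-1)
        tpl.bonds[frozenset(("C", "OXT"))] = 1.249
        for aname, q in _CTER_CHARGES.items():
            if aname in tpl.atoms:
                tpl.atoms[aname].charge = q
        tpl.planes.append(["CA", "C", "O", "OXT"])
    return tpl


class Topology:
    """Model-library correspondence plus the derived bonded graph."""

    def __init__(self, model: AtomicModel,
                 variants: dict[tuple[str, int], str] | None = None) -> None:
        self.model = model
        self.variants = variants or {}
        self.flat_index: dict[int, int] = {}
        self.atom_list: list[tuple[Chain, Residue, Atom]] = []
        for idx, (c, r, a) in enumerate(model.atoms()):
            self.atom_list.append((c, r, a))
            self.flat_index[id(a)] = idx
        self.n_atoms = len(self.atom_list)
        self.instances = self._build_instances()
        self.bond_list: list[tuple[int, int, float]] = []
        self.neighbors: list[set[int]] = [set() for _ in range(self.n_atoms)]
        self._build_bonds()

    # -- residue instances ----------------------------------------------

    def _build_instances(self) -> list[ResidueInstance]:
        instances: list[ResidueInstance] = []
        for chain in self.model.chains:
            prev_inst: ResidueInstance | None = None
            for res in chain.residues:
                lib.get_template(res.name)  # raise early on unknown residue
                linked = False
                if prev_inst is not None:
                    c_atom = prev_inst.residue.atom("C")
                    n_atom = res.atom("N")
                    if c_atom is not None and n_atom is not None:
                        d = np.linalg.norm(c_atom.coords - n_atom.coords)
                        if d < PEPTIDE_CUTOFF:
                            linked = True
                        else:
                            logger.info(
                                "chain %s: gap between %s and %s "
                                "(C-N %.2f A)", chain.name,
                                prev_inst.residue.label, res.label, d)
                inst = ResidueInstance(chain, res, None, {})
                if linked:
                    inst.prev = prev_inst
                    prev_inst.next = inst
                instances.append(inst)
                prev_inst = inst
        cache: dict[tuple, lib.ResidueTemplate] = {}
        for inst in instances:
            res = inst.residue
            variant = self.variants.get((inst.chain.name, res.number))
            key = (res.name, variant, inst.is_nterm, inst.is_cterm)
            if key not in cache:
                cache[key] = _instance_template(res.name, variant,
                                                inst.is_nterm, inst.is_cterm)
            inst.template = cache[key]
            for atom in res.atoms:
                if atom.name in inst.template.atoms:
                    inst.index_of[atom.name] = self.flat_index[id(atom)]
                else:
                    warnings.warn(
                        f"atom {atom.name} in {res.label} is not part of "
                        f"the {res.name} template (ignored in restraints)")
        return instances

    # -- bonded graph ----------------------------------------------------

    def _add_bond(self, i: int, j: int, d0: float) -> None:
        if j in self.neighbors[i]:
            return
        self.bond_list.append((min(i, j), max(i, j), d0))
        self.neighbors[i].add(j)
        self.neighbors[j].add(i)

    def _build_bonds(self) -> None:
        for inst in self.instances:
            tpl = inst.template
            for pair, d0 in tpl.bonds.items():
                a, b = tuple(pair)
                if a in inst.index_of and b in inst.index_of:
                    self._add_bond(inst.index_of[a], inst.index_of[b], d0)
            for hname in tpl.hydrogen_names:
                if hname in inst.index_of:
                    parent = tpl.atoms[hname].parent
                    if parent in inst.index_of:
                        self._add_bond(inst.index_of[hname],
                                       inst.index_of[parent],
                                       tpl.bond_length(hname, parent))
            if inst.prev is not None:
                c = inst.prev.index_of.get("C")
                n = inst.index_of.get("N")
                if c is not None and n is not None:
                    self._add_bond(
                        c, n, lib.geometry_rules()["peptide"]["c_n_length"])
        self.bond_list.sort()

    def element_of(self, idx: int) -> str:
        return self.atom_list[idx][2].element

    def total_charge(self) -> int:
        q = 0
        for inst in self.instances:
            for name in inst.index_of:
                q += inst.template.atoms[name].formal_charge
        return q

    def find_disulfides(self) -> list[tuple[int, int]]:
        """SG-SG contacts < 2.5 A (reported, not restrained)."""
        sgs = [idx for inst in self.instances
               for name, idx in inst.index_of.items()
               if name == "SG" and inst.residue.name == "CYS"]
        out = []
        for a in range(len(sgs)):
            for b in range(a + 1, len(sgs)):
                i, j = sgs[a], sgs[b]
                d = np.linalg.norm(self.atom_list[i][2].coords
                                   - self.atom_list[j][2].coords)
                if d < 2.5:
                    out.append((i, j))
        return out


def _local_name(inst: ResidueInstance, idx: int,
                owner_of: dict[int, tuple[ResidueInstance, str]]) -> str:
    owner, name = owner_of[idx]
    if owner is inst:
        return name
    if owner is inst.prev:
        return "-C"
    if owner is inst.next:
        return "+N"
    raise TopologyError("angle spans non-adjacent residues")


def build_restraints(model: AtomicModel,
                     variants: dict[tuple[str, int], str] | None = None,
                     topology: Topology | None = None) -> RestraintSet:
    """Generate the full restraint set for a model.

    Includes inter-residue peptide bond/angle/planarity terms.  Unknown
    residues raise; chain breaks are logged and produce no spurious link.
    """
    topo = topology if topology is not None else Topology(model, variants)
    fc = lib.geometry_rules()["force_constants"]
    nb = lib.nonbonded_params()
    rs = RestraintSet(n_atoms=topo.n_atoms, nonbonded_k=fc["nonbonded"])

    owner_of: dict[int, tuple[ResidueInstance, str]] = {}
    for inst in topo.instances:
        for name, idx in inst.index_of.items():
            owner_of[idx] = (inst, name)

    bonds = [(i, j, d0, fc["bond"]) for i, j, d0 in topo.bond_list]
    rs.bonds = np.array(sorted(bonds), dtype=float).reshape(-1, 4)
    rs.neighbors = topo.neighbors

    # angles: every pair of bonded neighbors around every center
    angles = []
    for inst in topo.instances:
        tpl = inst.template
        for cname, cidx in sorted(inst.index_of.items()):
            nbrs = sorted(topo.neighbors[cidx])
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    i, j = nbrs[x], nbrs[y]
                    ni = _local_name(inst, i, owner_of)
                    nj = _local_name(inst, j, owner_of)
                    theta0 = tpl.ideal_angle(cname, ni, nj)
                    angles.append((i, cidx, j, np.radians(theta0),
                                   fc["angle"]))
    rs.angles = np.array(sorted(angles), dtype=float).reshape(-1, 5)

    # torsions: peptide omega plus one threefold term per sp3-sp3 bond
    torsions = []
    pep = lib.geometry_rules()["peptide"]
    elements = {idx: topo.element_of(idx) for idx in range(topo.n_atoms)}
    for inst in topo.instances:
        if inst.prev is not None:
            p = inst.prev
            if ("CA" in p.index_of and "C" in p.index_of
                    and "N" in inst.index_of and "CA" in inst.index_of):
                torsions.append((p.index_of["CA"], p.index_of["C"],
                                 inst.index_of["N"], inst.index_of["CA"],
                                 1, 0.0, pep["omega_force"]))
    for i, j, _ in topo.bond_list:
        oi, ni = owner_of[i]
        oj, nj = owner_of[j]
        gi = oi.template.atoms[ni].geom
        gj = oj.template.atoms[nj].geom
        if gi == "sp3" and gj == "sp3":
            others_i = [n for n in topo.neighbors[i] if n != j]
            others_j = [n for n in topo.neighbors[j] if n != i]
            if others_i and others_j:
                a = max(others_i, key=lambda n: (lib.element_weight(
                    elements[n]), -n))
                d = max(others_j, key=lambda n: (lib.element_weight(
                    elements[n]), -n))
                torsions.append((a, i, j, d, 3, 0.0, fc["torsion"]))
    rs.torsions = np.array(sorted(torsions), dtype=float).reshape(-1, 7)

    # planes: intra-residue groups, peptide planes, C-terminal carboxylate
    for inst in topo.instances:
        for group in inst.template.planes:
            idxs = [inst.index_of[n] for n in group if n in inst.index_of]
            if len(idxs) >= 4:
                rs.planes.append((np.array(sorted(idxs)), fc["plane"]))
        if inst.next is not None:
            names_next = ["N", "CA"] + (
                ["CD"] if inst.next.residue.name == "PRO" else ["H"])
            idxs = [inst.index_of[n] for n in ("CA", "C", "O")
                    if n in inst.index_of]
            idxs += [inst.next.index_of[n] for n in names_next
                     if n in inst.next.index_of]
            if len(idxs) >= 4:
                rs.planes.append((np.array(sorted(idxs)), fc["plane"]))

    chir = []
    for inst in topo.instances:
        tpl = inst.template
        for center, n1, n2, n3 in tpl.chirality:
            if all(n in inst.index_of for n in (center, n1, n2, n3)):
                v0 = tpl.chirality_volume(center, (n1, n2, n3))
                chir.append((inst.index_of[center], inst.index_of[n1],
                             inst.index_of[n2], inst.index_of[n3],
                             v0, fc["chirality"]))
    rs.chirality = np.array(sorted(chir), dtype=float).reshape(-1, 6)

    # nonbonded bookkeeping
    rs.elements = [elements[i] for i in range(topo.n_atoms)]
    radii = nb["vdw_radii"]
    rs.vdw_radii = np.array([radii[e] for e in rs.elements])
    # untemplated atoms keep their formal charge (e.g. free ions/protons)
    charges = np.array([float(a.formal_charge)
                        for _, _, a in model.atoms()])
    for inst in topo.instances:
        for name, idx in inst.index_of.items():
            charges[idx] = inst.template.atoms[name].charge
    rs.charges = charges

    polar_h = np.zeros(topo.n_atoms, bool)
    donor = np.zeros(topo.n_atoms, bool)
    acceptor = np.zeros(topo.n_atoms, bool)
    for i in range(topo.n_atoms):
        e = rs.elements[i]
        if e == "H":
            parents = sorted(topo.neighbors[i])
            if parents and rs.elements[parents[0]] in ("N", "O"):
                polar_h[i] = True
                donor[parents[0]] = True
                rs.donors.append((parents[0], i))
        elif e == "O":
            acceptor[i] = True
        elif e == "N":
            heavy_nbrs = [j for j in topo.neighbors[i]
                          if rs.elements[j] != "H"]
            h_nbrs = [j for j in topo.neighbors[i] if rs.elements[j] == "H"]
            if not h_nbrs and len(heavy_nbrs) <= 2:
                acceptor[i] = True
    rs.is_polar_h, rs.is_donor, rs.is_acceptor = polar_h, donor, acceptor
    rs.donors.sort()

    excluded: set[tuple[int, int]] = set()
    for i, j, _ in topo.bond_list:
        excluded.add((min(i, j), max(i, j)))
    for c in range(topo.n_atoms):
        nbrs = sorted(topo.neighbors[c])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                excluded.add((nbrs[x], nbrs[y]))
    pair14: set[tuple[int, int]] = set()
    for i, j, _ in topo.bond_list:
        for a in topo.neighbors[i]:
            if a == j:
                continue
            for d in topo.neighbors[j]:
                if d == i or d == a:
                    continue
                pair14.add((min(a, d), max(a, d)))
    rs.excluded = excluded
    rs.pair14 = pair14 - excluded
    return rs


# ---------------------------------------------------------------------------
# completeness / hydrogen placement / clashes / regularization
# ---------------------------------------------------------------------------

@dataclass
class MissingAtom:
    chain: str
    residue: str
    atom: str
    blocking: bool


def check_completeness(model: AtomicModel,
                       variants: dict[tuple[str, int], str] | None = None,
                       ) -> list[MissingAtom]:
    """Report missing atoms, classifying each as trivially-addable
    (hydrogens, terminal O/OXT) or blocking (other heavy atoms)."""
    topo = Topology(model, variants)
    report = []
    for inst in topo.instances:
        tpl = inst.template
        for name, atom in sorted(tpl.atoms.items()):
            if name in inst.index_of:
                continue
            trivial = atom.geom == "h" or name in ("OXT", "O")
            report.append(MissingAtom(inst.chain.name, inst.residue.label,
                                      name, blocking=not trivial))
    return report


def _complete_center(tpl: lib.ResidueTemplate, center: str,
                     center_pos: np.ndarray,
                     known: dict[str, np.ndarray],
                     targets: list[str],
                     stagger_ref: np.ndarray | None = None,
                     ) -> dict[str, np.ndarray]:
    """Place missing neighbors of a center from its canonical ideal frame.

    ``known`` maps template-local neighbor names (including -C/+N) to actual
    positions.  With two or more known neighbors the ideal frame is aligned
    by least squares; with a single known neighbor the free spin about that
    axis is fixed by anti-periplanar staggering against ``stagger_ref``.
    """
    geo = tpl.center_geometry(center)
    known_names = [n for n in known if n in geo]
    out = {}
    if len(known_names) >= 2:
        ideal = np.array([geo[n] for n in known_names])
        actual = np.array([unit(known[n] - center_pos)
                           for n in known_names])
        rot = kabsch_rotation(ideal, actual)
        for t in targets:
            out[t] = center_pos + tpl.bond_length(center, t) * (rot @ geo[t])
    elif len(known_names) == 1:
        k0 = known_names[0]
        anchor = known[k0]
        if stagger_ref is None:
            raise TopologyError(f"cannot orient atoms on {center}: "
                                "no stagger reference")
        # Rigidly rotate the whole ideal frame: align the known-neighbor
        # direction, then fix the free spin about that axis so the first
        # target sits anti-periplanar to the stagger reference.  Rigid
        # placement keeps every frame angle (including target-target
        # angles) exactly at its ideal value.
        u = unit(anchor - center_pos)
        r1 = _align_rotation(geo[k0], u)
        t0 = targets[0]
        probe = center_pos + r1 @ geo[t0]
        tors = dihedral_deg(stagger_ref, anchor, center_pos, probe)
        # the torsion axis anchor->center is -u, so a spin of +g about u
        # lowers the measured torsion by g
        r = _axis_rotation(u, np.radians(tors - 180.0)) @ r1
        for t in targets:
            out[t] = center_pos + tpl.bond_length(center, t) * (r @ geo[t])
    else:
        raise TopologyError(f"no known neighbors around {center}")
    return out


def add_hydrogens(model: AtomicModel,
                  variants: dict[tuple[str, int], str] | None = None,
                  ) -> int:
    """Add every library hydrogen missing from the model, in place.

    Positions come from ideal internal coordinates: bond length by parent
    element, tetrahedral/trigonal angles, rotatable hydrogens staggered
    (anti) relative to the heaviest 1-4 neighbor.  Returns the number of
    atoms added; running twice adds zero.
    """
    topo = Topology(model, variants)
    return _add_missing(topo, hydrogens_only=True)


def complete_trivial(model: AtomicModel,
                     variants: dict[tuple[str, int], str] | None = None,
                     ) -> int:
    """Add trivially-addable heavy atoms (terminal O/OXT), in place."""
    topo = Topology(model, variants)
    return _add_missing(topo, hydrogens_only=False, heavy_only=True)


def _add_missing(topo: Topology, hydrogens_only: bool,
                 heavy_only: bool = False) -> int:
    added = 0
    for inst in topo.instances:
        tpl = inst.template
        res = inst.residue

        def pos_of(name: str) -> np.ndarray | None:
            if name == "-C":
                if inst.prev is None:
                    return None
                a = inst.prev.residue.atom("C")
            elif name == "+N":
                if inst.next is None:
                    return None
                a = inst.next.residue.atom("N")
            else:
                a = res.atom(name)
            return None if a is None else a.coords

        by_center: dict[str, list[str]] = {}
        for name, atom in tpl.atoms.items():
            if res.has_atom(name):
                continue
            if atom.geom == "h":
                if heavy_only:
                    continue
                by_center.setdefault(atom.parent, []).append(name)
            else:
                if hydrogens_only or name not in ("O", "OXT"):
                    continue
                by_center.setdefault("C", []).append(name)

        for center, missing in sorted(by_center.items()):
            cpos = pos_of(center)
            if cpos is None:
                raise TopologyError(
                    f"missing heavy anchor {center} in {res.label}")
            known: dict[str, np.ndarray] = {}
            for n in tpl._heavy_context_neighbors(center):
                p = pos_of(n)
                if p is not None:
                    known[n] = p
            for hn in tpl.hydrogens_on(center):
                if res.has_atom(hn) and hn not in missing:
                    known[hn] = pos_of(hn)
            stagger = None
            if len([n for n in known if n in tpl.center_geometry(center)]) == 1:
                kname = [n for n in known
                         if n in tpl.center_geometry(center)][0]
                cand = {}
                if kname in tpl.atoms:
                    for nb in (tpl.heavy_neighbors(kname)
                               + tpl.hydrogens_on(kname)
                               + (["-C"] if kname == "N" and tpl.has_prev
                                  else [])):
                        if nb == center:
                            continue
                        p = pos_of(nb)
                        if p is not None:
                            el = (tpl.atoms[nb].element if nb in tpl.atoms
                                  else "C")
                            cand[nb] = (el, p)
                if cand:
                    best = sorted(cand, key=lambda n: (
                        -lib.element_weight(cand[n][0]), n))[0]
                    stagger = cand[best][1]
            new_pos = _complete_center(tpl, center, cpos, known,
                                       sorted(missing), stagger)
            for name in sorted(missing):
                atom = tpl.atoms[name]
                res.add_atom(Atom(name=name, element=atom.element,
                                  coords=new_pos[name],
                                  formal_charge=atom.formal_charge))
                added += 1
    return added


@dataclass
class Clash:
    i: int
    j: int
    distance: float
    allowed: float
    label_i: str
    label_j: str


def detect_clashes(model: AtomicModel, restraints: RestraintSet,
                   overlap_threshold: float = 0.4) -> list[Clash]:
    """Nonbonded pairs approaching closer than vdW-sum minus the threshold.

    Bonded (1-2), 1-3 and 1-4 pairs are excluded (their geometry is
    governed by bond/angle/torsion restraints); hydrogen-bond-capable
    pairs use reduced allowed distances.  The boundary is a strict
    inequality.
    """
    coords = model.get_coords()
    labels = model.atom_labels()
    tree = cKDTree(coords)
    max_d = 2.0 * restraints.vdw_radii.max()
    clashes = []
    for i, j in sorted(tree.query_pairs(max_d)):
        key = (min(i, j), max(i, j))
        if key in restraints.excluded or key in restraints.pair14:
            continue
        allowed = restraints.allowed_distance(i, j) - overlap_threshold
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < allowed:
            clashes.append(Clash(i, j, d, allowed, labels[i], labels[j]))
    return clashes


def regularize(model: AtomicModel, restraints: RestraintSet,
               max_cycles: int = 5) -> float:
    """Restraint-only geometry minimization with tethers to the start.

    Minimizes the restraint energy plus harmonic tethers to the starting
    coordinates so atoms move as little as necessary; the tether is relaxed
    stepwise until the clash list is empty or the cycle cap is reached.
    Returns the maximum atomic shift (A).
    """
    from scipy.optimize import minimize

    from .energy import RestraintBackend

    start = model.get_coords()
    backend = RestraintBackend(restraints)
    tether_k = lib.geometry_rules()["force_constants"]["tether"]
    coords = start.copy()
    for cycle in range(max_cycles):
        k_t = tether_k / (2.0 ** cycle)

        def fun(x):
            xyz = x.reshape(-1, 3)
            e, f = backend.energy_forces(xyz)
            dt = xyz - start
            e_t = k_t * float(np.sum(dt * dt))
            g = -f + 2.0 * k_t * dt
            return e + e_t, g.ravel()

        res = minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 300, "gtol": 1e-3})
        coords = res.x.reshape(-1, 3)
        model.set_coords(coords)
        if not detect_clashes(model, restraints):
            break
    else:
        warnings.warn("regularization did not remove all clashes within "
                      "the cycle cap; returning best model")
    return float(np.linalg.norm(coords - start, axis=1).max())
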