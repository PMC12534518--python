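"""Crystal symmetry: operators, supercell expansion, gradient fold-back.

Crystallographic refinement evaluates the chemical energy on the model
*plus* its symmetry environment: the asymmetric unit (ASU) is expanded into
a supercell of symmetry and lattice images, truncated to whole residues
within a prescribed distance of the main copy.  Environment atoms are frozen
images — their coordinates are regenerated from the ASU each step, and the
forces acting on them are folded back onto the generating ASU atoms through
the transpose of the orthogonal-frame rotation.

Space-group operators for the 65 Sohncke groups ship as a plain-text table
(``data/spacegroups.txt``, symbol -> x,y,z triplet list) and are parsed
here without external dependencies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, AtomicModel, Chain, Residue


class SymmetryError(ValueError):
    pass


@dataclass(frozen=True)
class SymOp:
    """Symmetry operator in the fractional frame: x' = R x + t."""

    rot: tuple[tuple[int, ...], ...]       # 3x3 integer entries
    trans: tuple[Fraction, ...]            # translation, components mod 1

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, float)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.trans])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.rot_array.T + self.trans_array

    def compose(self, other: "SymOp") -> "SymOp":
        """self ∘ other: apply ``other`` first."""
        r1, r2 = np.array(self.rot, int), np.array(other.rot, int)
        rot = r1 @ r2
        trans = [
            (sum(Fraction(int(r1[i][k])) * other.trans[k] for k in range(3))
             + self.trans[i]) % 1
            for i in range(3)
        ]
        return SymOp(tuple(tuple(int(v) for v in row) for row in rot),
                     tuple(trans))

    @property
    def is_identity(self) -> bool:
        return (np.array_equal(np.array(self.rot), np.eye(3, dtype=int))
                and all(t == 0 for t in self.trans))

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, axis in enumerate(("x", "y", "z")):
                r = self.rot[i][j]
                if r:
                    sign = "-" if r < 0 else ("+" if s else "")
                    mag = "" if abs(r) == 1 else str(abs(r))
                    s += f"{sign}{mag}{axis}"
            t = self.trans[i] % 1
            if t:
                s += ("+" if s else "") + str(t)
            parts.append(s or "0")
        return ",".join(parts)


_TERM = re.compile(r"([+-]?)(\d+(?:/\d+)?|[xyz])(?:/(\d+))?")


def parse_triplet(triplet: str) -> SymOp:
    """Parse an x,y,z-notation operator string, e.g. ``-y,x-y,z+1/3``."""
    comps = triplet.replace(" ", "").lower().split(",")
    if len(comps) != 3:
        raise SymmetryError(f"malformed triplet {triplet!r}")
    rot = [[0, 0, 0] for _ in range(3)]
    trans = [Fraction(0)] * 3
    axes = {"x": 0, "y": 1, "z": 2}
    for i, comp in enumerate(comps):
        pos = 0
        for m in _TERM.finditer(comp):
            if m.start() != pos:
                raise SymmetryError(f"malformed triplet {triplet!r}")
            pos = m.end()
            sign = -1 if m.group(1) == "-" else 1
            body, denom = m.group(2), m.group(3)
            if body in axes:
                if denom is not None:
                    raise SymmetryError(f"malformed triplet {triplet!r}")
                rot[i][axes[body]] += sign
            else:
                frac = Fraction(body)
                if denom is not None:
                    frac /= int(denom)
                trans[i] += sign * frac
        if pos != len(comp):
            raise SymmetryError(f"malformed triplet {triplet!r}")
        trans[i] %= 1
    return SymOp(tuple(tuple(row) for row in rot), tuple(trans))


def _normalize_symbol(symbol: str) -> str:
    return symbol.replace(" ", "").upper()


@lru_cache(maxsize=1)
def _spacegroup_table() -> dict[str, tuple[str, ...]]:
    text = (resources.files("mmrefine") / "data" / "spacegroups.txt"
            ).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols, _, ops = line.partition(":")
        triplets = tuple(t.strip() for t in ops.split(";"))
        for symbol in symbols.split("|"):
            table[_normalize_symbol(symbol)] = triplets
    return table


def known_space_groups() -> list[str]:
    return sorted(_spacegroup_table())


def symops_for(space_group: str) -> list[SymOp]:
    """All operators of a Sohncke space group (closure included)."""
    key = _normalize_symbol(space_group)
    table = _spacegroup_table()
    if key not in table:
        raise SymmetryError(
            f"unknown or unsupported space group {space_group!r} "
            "(the 65 Sohncke groups are supported)")
    return [parse_triplet(t) for t in table[key]]


# --------------------------------------------------------------------------
# Supercell expansion


@dataclass
class SuperModel:
    """ASU plus truncated symmetry environment.

    Atoms ``0..n_asu-1`` are the main copy in model order; the remainder are
    frozen environment images.  ``asu_index`` maps every atom back to the
    ASU atom it images; ``generators`` holds one (SymOp, lattice shift)
    per atom.  ``rot_orth`` caches the orthogonal-frame rotation of each
    atom's generator, used both to regenerate environment coordinates and
    to fold forces back onto the ASU.
    """

    model: AtomicModel
    n_asu: int
    asu_index: np.ndarray                    # (n_total,)
    generators: list[tuple[SymOp, tuple[int, int, int]]]
    rot_orth: np.ndarray                     # (n_total, 3, 3)
    shift_orth: np.ndarray = field(default=None)  # (n_total, 3)
    radius: float = 0.0
    expanded_model: AtomicModel | None = None

    @property
    def n_total(self) -> int:
        return len(self.asu_index)

    @property
    def n_environment(self) -> int:
        return self.n_total - self.n_asu

    @property
    def is_environment(self) -> np.ndarray:
        flags = np.ones(self.n_total, bool)
        flags[:self.n_asu] = False
        return flags

    def expand_coords(self, asu_coords: np.ndarray) -> np.ndarray:
        """Regenerate all supercell coordinates from ASU coordinates."""
        x = np.asarray(asu_coords, float).reshape(-1, 3)
        if x.shape[0] != self.n_asu:
            raise ValueError("ASU coordinate count mismatch")
        src = x[self.asu_index]
        return np.einsum("nij,nj->ni", self.rot_orth, src) + self.shift_orth

    def fold_gradients(self, expanded_forces: np.ndarray) -> np.ndarray:
        """Fold supercell forces onto ASU atoms (images follow the ASU)."""
        f = np.asarray(expanded_forces, float)
        if f.shape != (self.n_total, 3):
            raise ValueError(
                f"expected forces of shape {(self.n_total, 3)}, "
                f"got {f.shape}")
        rotated = np.einsum("nji,nj->ni", self.rot_orth, f)
        out = np.zeros((self.n_asu, 3))
        np.add.at(out, self.asu_index, rotated)
        return out

    def elements(self) -> list[str]:
        base = self.model.elements()
        return [base[i] for i in self.asu_index]


def expand_supercell(model: AtomicModel, radius: float = 10.0) -> SuperModel:
    """Expand the model into its truncated symmetry environment.

    Generates every symmetry/lattice image over translations -1..+1 per
    axis (extended when the radius exceeds a cell edge) and keeps whole
    residues any of whose atoms lie within ``radius`` of the main copy.
    """
    if radius <= 0:
        raise SymmetryError("radius must be positive")
    if model.unit_cell is None:
        raise SymmetryError(
            "no unit cell: supercell expansion requires crystal symmetry "
            "(for cryo-EM data refine without expansion)")
    ops = symops_for(model.space_group or "P 1")
    cell = model.unit_cell
    m_orth = cell.orthogonalization_matrix()
    m_frac = cell.fractionalization_matrix()
    x_asu = model.get_coords()
    n_asu = len(x_asu)
    f_asu = x_asu @ m_frac.T

    # per-residue atom index groups, for whole-residue retention
    groups = []
    group_res = []
    start = 0
    for chain in model.chains:
        for res in chain.residues:
            n = len(res.atoms)
            groups.append(np.arange(start, start + n))
            group_res.append(res)
            start += n

    margin = [radius / edge for edge in (cell.a, cell.b, cell.c)]
    tree = cKDTree(x_asu)

    asu_index = list(range(n_asu))
    identity = parse_triplet("x,y,z")
    generators: list[tuple[SymOp, tuple[int, int, int]]] = \
        [(identity, (0, 0, 0))] * n_asu
    rots = [np.eye(3)] * n_asu
    shifts = [np.zeros(3)] * n_asu

    env_residues: list[Residue] = []
    for op in ops:
        r_orth = m_orth @ op.rot_array @ m_frac
        f_img_base = op.apply(f_asu)
        # lattice shift range that can bring any image atom within the
        # radius of any main-copy atom, regardless of where either sits
        # relative to the [0, 1) cell
        lo = [int(np.floor(f_asu[:, k].min() - f_img_base[:, k].max()
                           - margin[k])) for k in range(3)]
        hi = [int(np.ceil(f_asu[:, k].max() - f_img_base[:, k].min()
                          + margin[k])) for k in range(3)]
        for sa in range(lo[0], hi[0] + 1):
            for sb in range(lo[1], hi[1] + 1):
                for sc in range(lo[2], hi[2] + 1):
                    shift = (sa, sb, sc)
                    if op.is_identity and shift == (0, 0, 0):
                        continue
                    x_img = (f_img_base + np.array(shift, float)) @ m_orth.T
                    d, _ = tree.query(x_img, k=1)
                    for grp, res in zip(groups, group_res):
                        if np.min(d[grp]) < radius:
                            t_orth = (m_orth
                                      @ (op.trans_array
                                         + np.array(shift, float)))
                            for i in grp:
                                asu_index.append(i)
                                generators.append((op, shift))
                                rots.append(r_orth)
                                shifts.append(t_orth)
                            env_residues.append(Residue(
                                name=res.name,
                                number=len(env_residues) + 1,
                                atoms=[Atom(a.name, a.element,
                                            x_img[i],
                                            occupancy=a.occupancy,
                                            b_iso=a.b_iso,
                                            formal_charge=a.formal_charge)
                                       for a, i in zip(res.atoms, grp)]))

    expanded = AtomicModel(
        chains=([Chain(c.name, [_copy_residue(r) for r in c.residues])
                 for c in model.chains]
                + ([Chain("Z", env_residues)] if env_residues else [])),
        unit_cell=model.unit_cell, space_group=model.space_group)

    sm = SuperModel(model=model, n_asu=n_asu,
                    asu_index=np.array(asu_index, int),
                    generators=generators,
                    rot_orth=np.array(rots),
                    shift_orth=np.array(shifts),
                    radius=float(radius),
                    expanded_model=expanded)
    expanded.set_coords(sm.expand_coords(x_asu))
    return sm


def _copy_residue(res: Residue) -> Residue:
    return Residue(name=res.name, number=res.number,
                   insertion_code=res.insertion_code,
                   atoms=[Atom(a.name, a.element, a.coords.copy(),
                               occupancy=a.occupancy, b_iso=a.b_iso,
                               formal_charge=a.formal_charge)
                          for a in res.atoms])


def write_supermodel_pdb(sm: SuperModel, path) -> None:
    """Write the expanded supercell as PDB for inspection (env as chain Z)."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(sm.model.unit_cell.a, sm.model.unit_cell.b,
                             sm.model.unit_cell.c, sm.model.unit_cell.alpha,
                             sm.model.unit_cell.beta, sm.model.unit_cell.gamma)
    st.spacegroup_hm = sm.model.space_group or "P 1"
    md = gemmi.Model("1")
    coords = sm.expand_coords(sm.model.get_coords())
    labels = sm.model.atom_labels()
    elements = sm.model.elements()
    main = gemmi.Chain("A")
    env = gemmi.Chain("Z")
    res_main = gemmi.Residue()
    res_main.name = "ASU"
    res_main.seqid = gemmi.SeqId(1, " ")
    res_env = gemmi.Residue()
    res_env.name = "ENV"
    res_env.seqid = gemmi.SeqId(1, " ")
    for k in range(sm.n_total):
        i = sm.asu_index[k]
        at = gemmi.Atom()
        at.name = labels[i].split("/")[-1][:4]
        at.element = gemmi.Element(elements[i].capitalize())
        at.pos = gemmi.Position(*coords[k])
        (res_main if k < sm.n_asu else res_env).add_atom(at)
    main.add_residue(res_main)
    env.add_residue(res_env)
    md.add_chain(main)
    md.add_chain(env)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
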