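"""Atomic model data structures and PDB/mmCIF input/output.

The model is a plain chain -> residue -> atom hierarchy with coordinates kept
in the orthogonal (Cartesian, Angstrom) frame.  Fractional coordinates exist
only transiently, produced on demand from the unit cell.  Hydrogens are
ordinary atoms distinguished only by their element.

File parsing and writing go through :mod:`gemmi`; the hierarchy here is a
light, numerics-friendly wrapper (flat numpy coordinate access, stable atom
ordering) around what a structure file contains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

KNOWN_ELEMENTS = {
    "H", "D", "C", "N", "O", "S", "SE", "P", "F", "CL", "BR", "I", "NA",
    "MG", "K", "CA", "ZN", "FE", "MN", "CU",
}


class ModelError(ValueError):
    """Raised for malformed or unsupported model input."""


@dataclass
class Atom:
    """A single atom: name, element, Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom, orthogonal frame
    occupancy: float = 1.0
    b_iso: float = 20.0
    formal_charge: int = 0
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        el = self.element.upper()
        if el not in KNOWN_ELEMENTS:
            raise ModelError(f"unknown element symbol {self.element!r}")
        self.element = el
        if not np.all(np.isfinite(self.coords)):
            raise ModelError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    def add_atom(self, atom: Atom) -> None:
        if self.has_atom(atom.name):
            raise ModelError(
                f"duplicate atom name {atom.name!r} in residue "
                f"{self.name} {self.number}{self.insertion_code}"
            )
        self.atoms.append(atom)

    @property
    def label(self) -> str:
        return f"{self.name} {self.number}{self.insertion_code}"


@dataclass
class Chain:
    name: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class UnitCell:
    """Unit cell (a, b, c in Angstrom; angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for length in (self.a, self.b, self.c):
            if length <= 0:
                raise ModelError(f"degenerate cell length {length}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ModelError(f"degenerate cell angle {ang}")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self.to_gemmi().volume

    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M mapping fractional to orthogonal coordinates."""
        m = self.to_gemmi().orth.mat
        return np.array(m.tolist(), dtype=float)

    def fractionalization_matrix(self) -> np.ndarray:
        m = self.to_gemmi().frac.mat
        return np.array(m.tolist(), dtype=float)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) for an (n, 3) array of Miller indices."""
        cell = self.to_gemmi()
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        return np.array([cell.calculate_d(tuple(int(i) for i in row))
                         for row in hkl])


def orthogonalize(cell: UnitCell, frac_coords: np.ndarray) -> np.ndarray:
    """Fractional -> orthogonal (Angstrom) coordinates."""
    m = cell.orthogonalization_matrix()
    return np.asarray(frac_coords, dtype=float) @ m.T


def fractionalize(cell: UnitCell, coords: np.ndarray) -> np.ndarray:
    """Orthogonal (Angstrom) -> fractional coordinates."""
    m = cell.fractionalization_matrix()
    return np.asarray(coords, dtype=float) @ m.T


class AtomicModel:
    """Hierarchical atomic model with optional crystallographic frame."""

    def __init__(
        self,
        chains: Sequence[Chain] | None = None,
        unit_cell: UnitCell | None = None,
        space_group: str | None = None,
    ) -> None:
        self.chains: list[Chain] = list(chains) if chains else []
        self.unit_cell = unit_cell
        self.space_group = space_group

    # -- iteration -------------------------------------------------------

    def residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def total_charge(self) -> int:
        return sum(a.formal_charge for _, _, a in self.atoms())

    # -- flat numeric views ---------------------------------------------

    def get_coords(self) -> np.ndarray:
        """(n_atoms, 3) array in hierarchy traversal order."""
        return np.array([a.coords for _, _, a in self.atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ModelError(f"coordinate array shape {coords.shape} does not "
                             f"match atom count {self.n_atoms}")
        for i, (_, _, atom) in enumerate(self.atoms()):
            atom.coords = coords[i].copy()

    def elements(self) -> list[str]:
        return [a.element for _, _, a in self.atoms()]

    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for _, _, a in self.atoms()])

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for _, _, a in self.atoms()])

    def atom_labels(self) -> list[str]:
        return [f"{c.name}/{r.label}/{a.name}" for c, r, a in self.atoms()]

    # -- editing ---------------------------------------------------------

    def copy(self) -> "AtomicModel":
        import copy as _copy
        return _copy.deepcopy(self)

    def select(self, predicate: "Selection") -> "AtomicModel":
        """New model containing only atoms matching the selection."""
        chains = []
        for chain in self.chains:
            new_res = []
            for res in chain.residues:
                kept = [a for a in res.atoms if predicate(chain, res, a)]
                if kept:
                    new_res.append(Residue(res.name, res.number,
                                           res.insertion_code,
                                           [Atom(a.name, a.element,
                                                 a.coords.copy(), a.occupancy,
                                                 a.b_iso, a.formal_charge,
                                                 a.serial) for a in kept]))
            if new_res:
                chains.append(Chain(chain.name, new_res))
        return AtomicModel(chains, self.unit_cell, self.space_group)


@dataclass
class Selection:
    """Predicate over (chain, residue, atom); idempotent by construction."""

    chain_name: str | None = None
    residue_name: str | None = None
    residue_number: int | None = None
    atom_name: str | None = None
    element: str | None = None
    custom: Callable | None = None

    def __call__(self, chain: Chain, residue: Residue, atom: Atom) -> bool:
        if self.chain_name is not None and chain.name != self.chain_name:
            return False
        if self.residue_name is not None and residue.name != self.residue_name:
            return False
        if (self.residue_number is not None
                and residue.number != self.residue_number):
            return False
        if self.atom_name is not None and atom.name != self.atom_name:
            return False
        if self.element is not None and atom.element != self.element.upper():
            return False
        if self.custom is not None and not self.custom(chain, residue, atom):
            return False
        return True


NOT_PROTEIN = {"HOH", "WAT", "DOD", "SO4", "PO4", "GOL", "EDO", "CL", "NA",
               "MG", "ZN", "CA", "K"}


def read_model(path: str | Path, fmt: str | None = None,
               drop_non_protein: bool = True) -> AtomicModel:
    """Read an atomic model from a PDB or mmCIF file.

    Alternate-location records are rejected (static disorder is out of
    scope).  Multi-model files are truncated to the first model with a
    warning.  Waters and common non-protein het groups are dropped with a
    warning when ``drop_non_protein`` is set.
    """
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ModelError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelError(f"no models in {path}")
    if len(st) > 1:
        logger.warning("%s holds %d models; reading the first only",
                       path, len(st))

    cell = None
    sg = None
    if st.cell and st.cell.a > 1.001:  # gemmi uses a=1 dummy cell for no cell
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
        sg = st.spacegroup_hm or None

    chains = []
    dropped: set[str] = set()
    for gchain in st[0]:
        residues = []
        for gres in gchain:
            if drop_non_protein and gres.name in NOT_PROTEIN:
                dropped.add(gres.name)
                continue
            res = Residue(gres.name, gres.seqid.num,
                          (gres.seqid.icode or " ").strip())
            for gatom in gres:
                if gatom.altloc not in ("", "\0"):
                    raise ModelError(
                        f"alternate conformations are not supported "
                        f"(altloc {gatom.altloc!r} on {gres.name} "
                        f"{gres.seqid.num} {gatom.name})")
                res.add_atom(Atom(
                    name=gatom.name,
                    element=gatom.element.name.upper(),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=gatom.occ,
                    b_iso=gatom.b_iso,
                    formal_charge=int(gatom.charge),
                    serial=gatom.serial,
                ))
            residues.append(res)
        if residues:
            chains.append(Chain(gchain.name, residues))
    if dropped:
        warnings.warn(f"ignored non-protein residues: {sorted(dropped)}")
    return AtomicModel(chains, cell, sg)


def _to_gemmi(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "model"
    if model.unit_cell is not None:
        st.cell = model.unit_cell.to_gemmi()
        if model.space_group:
            st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    serial = 0
    for chain in model.chains:
        gc = gemmi.Chain(chain.name)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for atom in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                ga.charge = atom.formal_charge
                ga.serial = serial
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path: str | Path,
                fmt: str | None = None) -> None:
    """Write a model as PDB or mmCIF (deterministic for a given model)."""
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
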