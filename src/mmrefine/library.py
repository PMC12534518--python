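"""Embedded residue chemical library.

Templates for the 20 standard amino acids plus the ACE/NME chain caps are
shipped as TOML data files (one per residue; see the schema comment in
``data/residues/GLY.toml``).  This module loads them and augments the raw
tables with derived quantities:

* ideal bond angles for every atom triple around a center, combining
  per-residue overrides, global overrides and per-class defaults;
* hydrogen-involving angle ideals derived from the canonical hydrogen
  placement construction (so that a model built at ideal internal
  coordinates has exactly zero bond/angle restraint energy);
* signed-volume targets for chirality centers, evaluated numerically from
  the ideal local geometry.

Pseudo atom names ``-C`` and ``+N`` denote the peptide-bond partners in the
previous and next residue.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable

import numpy as np

_ELEMENT_WEIGHT = {"H": 1, "C": 12, "N": 14, "O": 16, "NA": 23, "P": 31,
                   "S": 32, "SE": 79}


def _data_path(*parts: str):
    path = resources.files("mmrefine").joinpath("data")
    for part in parts:
        path = path.joinpath(part)
    return path


@lru_cache(maxsize=1)
def geometry_rules() -> dict:
    with _data_path("geometry.toml").open("rb") as fh:
        return tomllib.load(fh)


@lru_cache(maxsize=1)
def nonbonded_params() -> dict:
    with _data_path("nonbonded.toml").open("rb") as fh:
        return tomllib.load(fh)


@lru_cache(maxsize=1)
def rama_regions() -> dict:
    with _data_path("rama_regions.json").open("r") as fh:
        return json.load(fh)


class UnknownResidueError(KeyError):
    pass


@dataclass
class TemplateAtom:
    name: str
    element: str
    geom: str               # "sp3" | "sp2"; hydrogens carry "h"
    charge: float
    parent: str | None = None  # for hydrogens: the bonded heavy atom
    formal_charge: int = 0


@dataclass
class ResidueTemplate:
    name: str
    atoms: dict[str, TemplateAtom]
    bonds: dict[frozenset, float]          # heavy-heavy ideal lengths
    planes: list[list[str]]
    chirality: list[tuple[str, str, str, str]]
    chi: list[list[str]]
    angle_overrides: dict[frozenset, float] = field(default_factory=dict)
    variants: dict[str, dict] = field(default_factory=dict)
    # whether this residue is peptide-linked to a previous one (False at the
    # N-terminus); affects the bonded context of the backbone nitrogen
    has_prev: bool = True

    # -- rosters ---------------------------------------------------------

    @property
    def heavy_names(self) -> list[str]:
        return [a.name for a in self.atoms.values() if a.geom != "h"]

    @property
    def hydrogen_names(self) -> list[str]:
        return [a.name for a in self.atoms.values() if a.geom == "h"]

    def hydrogens_on(self, heavy: str) -> list[str]:
        return [a.name for a in self.atoms.values()
                if a.geom == "h" and a.parent == heavy]

    def heavy_neighbors(self, name: str) -> list[str]:
        out = []
        for pair in self.bonds:
            if name in pair:
                (other,) = pair - {name}
                out.append(other)
        return sorted(out)

    def bond_length(self, a: str, b: str) -> float:
        rules = geometry_rules()
        key = frozenset((a, b))
        if key in self.bonds:
            return self.bonds[key]
        atom_a, atom_b = self.atoms.get(a), self.atoms.get(b)
        # X-H lengths keyed by parent element / class
        for h, x in ((atom_a, atom_b), (atom_b, atom_a)):
            if h is not None and h.geom == "h" and x is not None:
                tab = rules["h_bond_lengths"]
                if x.element == "C":
                    return tab[f"C_{x.geom}"]
                return tab[x.element]
        if "-C" in (a, b) or "+N" in (a, b):
            return rules["peptide"]["c_n_length"]
        raise KeyError(f"no ideal length for bond {a}-{b} in {self.name}")

    # -- angle ideals ----------------------------------------------------

    def _element_of(self, name: str) -> str:
        if name == "-C":
            return "C"
        if name == "+N":
            return "N"
        return self.atoms[name].element

    def _tabulated_angle(self, center: str, a: str, b: str) -> float | None:
        key = frozenset((center + "|c", a, b))
        if key in self.angle_overrides:
            return self.angle_overrides[key]
        glob = _global_angle_overrides()
        if key in glob:
            return glob[key]
        return None

    def _default_angle(self, center: str) -> float:
        rules = geometry_rules()["angle_defaults"]
        atom = self.atoms[center]
        if atom.element == "S":
            return rules["S"]
        if atom.element == "O":
            return rules["O"]
        if atom.element == "N" and atom.geom == "sp3":
            return rules["N_sp3"]
        return rules[atom.geom]

    def ideal_angle(self, center: str, a: str, b: str) -> float:
        """Ideal angle a-center-b in degrees."""
        tab = self._tabulated_angle(center, a, b)
        if tab is not None:
            return tab
        is_h = [self.atoms[n].geom == "h" for n in (a, b)
                if n in self.atoms]
        if any(is_h):
            geo = self.center_geometry(center)
            ua, ub = geo[a], geo[b]
            return math.degrees(
                math.acos(float(np.clip(np.dot(ua, ub), -1.0, 1.0))))
        return self._default_angle(center)

    def _heavy_context_neighbors(self, center: str) -> list[str]:
        """Heavy neighbors including peptide pseudo-atoms where relevant."""
        nbrs = self.heavy_neighbors(center)
        if center == "N" and self.name != "ACE" and self.has_prev:
            nbrs = ["-C"] + nbrs
        if center == "C" and "OXT" not in self.atoms:
            nbrs = nbrs + ["+N"]
        return nbrs

    @lru_cache(maxsize=None)
    def center_geometry(self, center: str) -> dict[str, np.ndarray]:
        """Canonical ideal unit vectors for all neighbors of ``center``.

        Heavy directions realize the tabulated heavy-heavy angle ideals;
        hydrogen directions come from the same completion construction used
        when hydrogens are placed on a real model, which is what makes the
        derived hydrogen angle ideals self-consistent.
        """
        heavies = self._heavy_context_neighbors(center)
        hyds = self.hydrogens_on(center)
        geo: dict[str, np.ndarray] = {}

        def ang(a, b):
            tab = self._tabulated_angle(center, a, b)
            return math.radians(tab if tab is not None
                                else self._default_angle(center))

        nh = len(heavies)
        if nh >= 3:
            u = _vectors_from_angles(ang(heavies[0], heavies[1]),
                                     ang(heavies[0], heavies[2]),
                                     ang(heavies[1], heavies[2]))
            for name, vec in zip(heavies[:3], u):
                geo[name] = vec
            if hyds:
                h = -sum(u)
                geo[hyds[0]] = h / np.linalg.norm(h)
        elif nh == 2:
            th = ang(heavies[0], heavies[1])
            u1 = np.array([1.0, 0.0, 0.0])
            u2 = np.array([math.cos(th), math.sin(th), 0.0])
            geo[heavies[0]], geo[heavies[1]] = u1, u2
            if len(hyds) == 1:
                h = -(u1 + u2)
                geo[hyds[0]] = h / np.linalg.norm(h)
            elif len(hyds) == 2:
                bis = -(u1 + u2)
                bis /= np.linalg.norm(bis)
                perp = np.array([0.0, 0.0, 1.0])
                alpha = math.radians(109.471 / 2.0)
                geo[hyds[0]] = math.cos(alpha) * bis + math.sin(alpha) * perp
                geo[hyds[1]] = math.cos(alpha) * bis - math.sin(alpha) * perp
        elif nh == 1:
            u1 = np.array([1.0, 0.0, 0.0])
            geo[heavies[0]] = u1
            sp2 = self.atoms[center].geom == "sp2"
            if len(hyds) == 1:
                th = math.radians(self._default_angle(center))
                geo[hyds[0]] = np.array([math.cos(th), math.sin(th), 0.0])
            elif len(hyds) == 2 and sp2:
                for name, sign in zip(hyds, (1.0, -1.0)):
                    th = math.radians(120.0)
                    geo[name] = np.array([math.cos(th),
                                          sign * math.sin(th), 0.0])
            else:  # 2 or 3 hydrogens, tetrahedral
                th = math.radians(109.471)
                for k, name in enumerate(hyds):
                    phi = 2.0 * math.pi * k / 3.0
                    geo[name] = np.array([
                        math.cos(th),
                        math.sin(th) * math.cos(phi),
                        math.sin(th) * math.sin(phi)])
        return geo

    def chirality_volume(self, center: str,
                         neighbors: tuple[str, str, str]) -> float:
        """Signed-volume target (A^3) for a chirality center.

        Evaluated from the ideal local geometry; the positive sign follows
        the construction in :meth:`center_geometry`, which matches the
        L-configuration for CA with neighbor order (N, C, CB).
        """
        geo = self.center_geometry(center)
        vecs = []
        for n in neighbors:
            d = self.bond_length(center, n)
            vecs.append(d * geo[n])
        return float(np.dot(vecs[0], np.cross(vecs[1], vecs[2])))

    # -- variants --------------------------------------------------------

    def with_variant(self, variant: str) -> "ResidueTemplate":
        if variant not in self.variants:
            raise KeyError(f"{self.name} has no variant {variant!r}")
        spec = self.variants[variant]
        atoms = {k: TemplateAtom(v.name, v.element, v.geom, v.charge,
                                 v.parent, v.formal_charge)
                 for k, v in self.atoms.items()}
        for name in spec.get("remove", []):
            atoms.pop(name, None)
        for name, parent, charge in spec.get("add_hydrogens", []):
            atoms[name] = TemplateAtom(name, "H", "h", charge, parent)
        for name, q in spec.get("charges", {}).items():
            if name in atoms:
                atoms[name].charge = q
        for name, f in spec.get("formal", {}).items():
            if name in atoms:
                atoms[name].formal_charge = int(f)
        out = ResidueTemplate(self.name, atoms, dict(self.bonds),
                              [list(p) for p in self.planes],
                              list(self.chirality),
                              [list(c) for c in self.chi],
                              dict(self.angle_overrides),
                              dict(self.variants),
                              has_prev=self.has_prev)
        return out

    def __hash__(self):  # needed for lru_cache on methods
        return id(self)

    def __eq__(self, other):
        return self is other


def _vectors_from_angles(t12: float, t13: float, t23: float) -> list[np.ndarray]:
    """Three unit vectors with prescribed pairwise angles (radians).

    The third vector takes the +z branch; together with neighbor ordering
    this fixes the handedness convention for chirality targets.
    """
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([math.cos(t12), math.sin(t12), 0.0])
    x3 = math.cos(t13)
    y3 = (math.cos(t23) - math.cos(t12) * x3) / math.sin(t12)
    z2 = 1.0 - x3 * x3 - y3 * y3
    if z2 < 0:
        raise ValueError("inconsistent angle triple")
    u3 = np.array([x3, y3, math.sqrt(z2)])
    return [u1, u2, u3]


@lru_cache(maxsize=1)
def _global_angle_overrides() -> dict[frozenset, float]:
    out = {}
    for center, a, b, deg in geometry_rules()["angle_overrides"]:
        out[frozenset((center + "|c", a, b))] = float(deg)
    return out


def _load_template(path) -> ResidueTemplate:
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    atoms: dict[str, TemplateAtom] = {}
    formal = raw.get("formal", {})
    for name, element, geom, charge in raw["heavy"]:
        atoms[name] = TemplateAtom(name, element.upper(), geom, float(charge),
                                   formal_charge=int(formal.get(name, 0)))
    for name, parent, charge in raw["hydrogens"]:
        atoms[name] = TemplateAtom(name, "H", "h", float(charge), parent)
    bonds = {}
    for a, b, length in raw["bonds"]:
        length = float(length)
        if not 0.8 < length < 2.5:
            raise ValueError(f"{raw['name']}: bond {a}-{b} length {length} "
                             "outside (0.8, 2.5) A")
        key = frozenset((a, b))
        if key in bonds:
            raise ValueError(f"{raw['name']}: duplicate bond {a}-{b}")
        bonds[key] = length
    overrides = {}
    for center, a, b, deg in raw.get("angle_overrides", []):
        overrides[frozenset((center + "|c", a, b))] = float(deg)
    variants = {}
    for vname, vspec in raw.get("variants", {}).items():
        variants[vname] = {
            "remove": vspec.get("remove", []),
            "add_hydrogens": [(n, p, float(q))
                              for n, p, q in vspec.get("add_hydrogens", [])],
            "charges": vspec.get("charges", {}),
            "formal": vspec.get("formal", {}),
        }
    tpl = ResidueTemplate(
        name=raw["name"],
        atoms=atoms,
        bonds=bonds,
        planes=[list(p) for p in raw.get("planes", [])],
        chirality=[tuple(c) for c in raw.get("chirality", [])],
        chi=[list(c) for c in raw.get("chi", [])],
        angle_overrides=overrides,
        variants=variants,
    )
    for center, n1, n2, n3 in tpl.chirality:
        if abs(tpl.chirality_volume(center, (n1, n2, n3))) < 1e-6:
            raise ValueError(f"{tpl.name}: zero chirality target at {center}")
    return tpl


@lru_cache(maxsize=1)
def library() -> dict[str, ResidueTemplate]:
    """Name -> template for every shipped residue."""
    out = {}
    for entry in sorted(_data_path("residues").iterdir(),
                        key=lambda p: p.name):
        if entry.name.endswith(".toml"):
            tpl = _load_template(entry)
            out[tpl.name] = tpl
    return out


def get_template(name: str) -> ResidueTemplate:
    try:
        return library()[name]
    except KeyError:
        raise UnknownResidueError(f"residue {name!r} is not in the embedded "
                                  "chemical library") from None


def element_weight(element: str) -> int:
    return _ELEMENT_WEIGHT.get(element.upper(), 0)


def heaviest(names: Iterable[str], elements: dict[str, str]) -> str:
    """Pick the heaviest atom (by element, ties by name) from ``names``."""
    return sorted(names,
                  key=lambda n: (-element_weight(elements[n]), n))[0]
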