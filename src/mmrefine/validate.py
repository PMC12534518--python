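"""Geometry and model-comparison metrics.

Bond/angle RMSDs against library ideals, clash counting, hydrogen-bond
detection with skew/kurtosis summary statistics, a simplified polygonal
Ramachandran classifier, Cartesian and torsion-space model comparison,
and the dataset selection filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

from . import library as lib
from .geomlib import angle_deg, dihedral_deg, kabsch_rotation, wrap_deg
from .model import AtomicModel
from .topology import RestraintSet, Topology, build_restraints, detect_clashes


class ValidationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Geometry deviations


def geometry_rmsd(model: AtomicModel, restraints: RestraintSet
                  ) -> tuple[float | None, float | None]:
    """(rmsd_bond A, rmsd_angle deg) of observed vs ideal restraint values.

    An empty restraint class is reported as None (absent), not zero.
    """
    x = model.get_coords()
    rmsd_bond = rmsd_angle = None
    if len(restraints.bonds):
        i = restraints.bonds[:, 0].astype(int)
        j = restraints.bonds[:, 1].astype(int)
        d = np.linalg.norm(x[i] - x[j], axis=1)
        rmsd_bond = float(np.sqrt(np.mean((d - restraints.bonds[:, 2]) ** 2)))
    if len(restraints.angles):
        devs = []
        for i, c, j, th0, _k in restraints.angles:
            th = angle_deg(x[int(i)], x[int(c)], x[int(j)])
            devs.append(th - np.degrees(th0))   # th0 stored in radians
        rmsd_angle = float(np.sqrt(np.mean(np.square(devs))))
    return rmsd_bond, rmsd_angle


# --------------------------------------------------------------------------
# Hydrogen bonds


@dataclass
class HBondRecord:
    donor: int          # flat atom index of D
    hydrogen: int       # flat atom index of H
    acceptor: int       # flat atom index of A
    distance: float     # d(H...A), A
    angle: float        # D-H...A, degrees


def find_hbonds(model: AtomicModel, restraints: RestraintSet | None = None,
                variants: dict | None = None,
                max_distance: float = 2.7, min_angle: float = 120.0
                ) -> list[HBondRecord]:
    """All (D-H, A) pairs with D, A in {N, O}, d(H...A) below the cutoff
    and D-H...A angle above the cutoff.  Covalently related H/A pairs
    (1-2 and 1-3) are excluded, as is A == D.  Polar donors that carry
    no hydrogen in the model trigger a warning listing them.
    """
    if restraints is None:
        restraints = build_restraints(model, variants)
    rs = restraints
    x = model.get_coords()
    labels = model.atom_labels()

    # warn about expected-but-absent donor protons
    topo = Topology(model, variants)
    bare: list[str] = []
    for inst in topo.instances:
        for hname, tat in inst.template.atoms.items():
            if tat.geom != "h" or tat.parent is None:
                continue
            parent = inst.template.atoms.get(tat.parent)
            if parent is None or parent.element not in ("N", "O"):
                continue
            if tat.parent in inst.index_of and hname not in inst.index_of:
                bare.append(labels[inst.index_of[tat.parent]])
    if bare:
        warnings.warn("unprotonated polar donors: " + ", ".join(sorted(set(bare))))

    acceptors = np.flatnonzero(rs.is_acceptor
                               | (np.array(rs.elements) == "O"))
    records = []
    for d_idx, h_idx in rs.donors:
        dist = np.linalg.norm(x[acceptors] - x[h_idx], axis=1)
        for a_idx, r in zip(acceptors, dist):
            if a_idx == d_idx or r >= max_distance:
                continue
            pair = (min(h_idx, int(a_idx)), max(h_idx, int(a_idx)))
            if pair in rs.excluded:
                continue
            theta = angle_deg(x[d_idx], x[h_idx], x[a_idx])
            if theta > min_angle:
                records.append(HBondRecord(d_idx, h_idx, int(a_idx),
                                           float(r), float(theta)))
    records.sort(key=lambda h: (h.hydrogen, h.acceptor))
    return records


def skew_kurtosis(values) -> tuple[float, float]:
    """Population-moment skewness m3/m2^1.5 and excess kurtosis m4/m2^2 - 3."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValidationError("need at least 3 values")
    m = v - v.mean()
    m2 = np.mean(m ** 2)
    if m2 == 0.0:
        raise ValidationError("zero variance: skew/kurtosis undefined")
    skew = float(np.mean(m ** 3) / m2 ** 1.5)
    kurt = float(np.mean(m ** 4) / m2 ** 2 - 3.0)
    return skew, kurt


# --------------------------------------------------------------------------
# Ramachandran


def _residue_class(name: str, next_name: str | None) -> str:
    if name == "GLY":
        return "gly"
    if name == "PRO":
        return "pro"
    if next_name == "PRO":
        return "prepro"
    return "general"


def _point_in_regions(phi: float, psi: float, polygons) -> bool:
    pt = (wrap_deg(phi), wrap_deg(psi))
    for poly in polygons:
        if _MplPath(np.asarray(poly, float)).contains_point(pt,
                                                            radius=1e-9):
            return True
    return False


def rama_classify(model: AtomicModel, variants: dict | None = None):
    """Per-residue Ramachandran class from shipped polygonal regions.

    Returns ``(classes, fractions)``: ``classes`` maps (chain, resnum) to
    'favored' | 'allowed' | 'outlier'; chain termini (no phi or no psi)
    are unclassified and excluded from the fractions.  This is a coarse
    polygon classifier, not a Ramachandran Z-score.
    """
    regions = lib.rama_regions()
    topo = Topology(model, variants)
    x = model.get_coords()
    classes: dict[tuple[str, int], str] = {}
    for inst in topo.instances:
        if inst.prev is None or inst.next is None:
            continue
        need = all(n in inst.index_of for n in ("N", "CA", "C"))
        if not (need and "C" in inst.prev.index_of
                and "N" in inst.next.index_of):
            continue
        phi = dihedral_deg(x[inst.prev.index_of["C"]],
                           x[inst.index_of["N"]],
                           x[inst.index_of["CA"]],
                           x[inst.index_of["C"]])
        psi = dihedral_deg(x[inst.index_of["N"]],
                           x[inst.index_of["CA"]],
                           x[inst.index_of["C"]],
                           x[inst.next.index_of["N"]])
        rclass = _residue_class(inst.residue.name, inst.next.residue.name)
        table = regions[rclass]
        if _point_in_regions(phi, psi, table["favored"]):
            verdict = "favored"
        elif _point_in_regions(phi, psi, table["allowed"]):
            verdict = "allowed"
        else:
            verdict = "outlier"
        classes[(inst.chain.name, inst.residue.number)] = verdict
    n = len(classes)
    fractions = {k: (sum(v == k for v in classes.values()) / n if n else 0.0)
                 for k in ("favored", "allowed", "outlier")}
    return classes, fractions


# --------------------------------------------------------------------------
# Model comparison

_SUPERPOSE_NAMES = ("N", "CA", "C", "O", "CB", "CG")


def _matched_instances(model_a: AtomicModel, model_b: AtomicModel,
                       variants: dict | None):
    ta, tb = Topology(model_a, variants), Topology(model_b, variants)
    by_key = {(i.chain.name, i.residue.number, i.residue.name): i
              for i in tb.instances}
    pairs = []
    for ia in ta.instances:
        ib = by_key.get((ia.chain.name, ia.residue.number, ia.residue.name))
        if ib is not None:
            pairs.append((ia, ib))
    return pairs


def compare_models(model_a: AtomicModel, model_b: AtomicModel,
                   mode: str = "cartesian",
                   variants: dict | None = None) -> float:
    """RMSD between models matched by chain name + residue number + name.

    cartesian: least-squares superposition (Kabsch) on backbone + CB + CG
    atoms present in both, RMSD over that set (A).  torsion: RMS of
    circular differences over matching phi/psi/omega/chi angles (deg).
    """
    if mode not in ("cartesian", "torsion"):
        raise ValidationError(f"unknown mode {mode!r}")
    pairs = _matched_instances(model_a, model_b, variants)
    xa_all, xb_all = model_a.get_coords(), model_b.get_coords()

    if mode == "cartesian":
        pa, pb = [], []
        for ia, ib in pairs:
            for name in _SUPERPOSE_NAMES:
                if name in ia.index_of and name in ib.index_of:
                    pa.append(xa_all[ia.index_of[name]])
                    pb.append(xb_all[ib.index_of[name]])
        if not pa:
            raise ValidationError("no matched atoms between models")
        pa, pb = np.array(pa), np.array(pb)
        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        rot = kabsch_rotation(pb - cb, pa - ca)
        moved = (pb - cb) @ rot.T + ca
        return float(np.sqrt(np.mean(np.sum((moved - pa) ** 2, axis=1))))

    diffs = []
    for ia, ib in pairs:
        for quad in _torsion_quads(ia):
            try:
                ta = dihedral_deg(*(xa_all[i.index_of[n]]
                                    for i, n in quad))
                tb = dihedral_deg(*(xb_all[_twin(i, ia, ib).index_of[n]]
                                    for i, n in quad))
            except (KeyError, ValueError, AttributeError):
                continue
            diffs.append(wrap_deg(ta - tb))
    if not diffs:
        raise ValidationError("no matched torsion angles between models")
    return float(np.sqrt(np.mean(np.square(diffs))))


def _twin(inst, ia, ib):
    """Map an instance of model A's chain (ia or its neighbors) onto B."""
    if inst is ia:
        return ib
    if inst is ia.prev:
        return ib.prev
    return ib.next


def _torsion_quads(ia):
    """(instance, atom-name) quads for phi, psi, omega and each chi of ia."""
    quads = []
    if ia.prev is not None:
        quads.append([(ia.prev, "C"), (ia, "N"), (ia, "CA"), (ia, "C")])
        quads.append([(ia.prev, "CA"), (ia.prev, "C"), (ia, "N"),
                      (ia, "CA")])
    if ia.next is not None:
        quads.append([(ia, "N"), (ia, "CA"), (ia, "C"), (ia.next, "N")])
    for chi in ia.template.chi:
        quads.append([(ia, n) for n in chi])
    out = []
    for quad in quads:
        if all((inst is not None) and (n in inst.index_of)
               for inst, n in quad):
            out.append(quad)
    return out


# --------------------------------------------------------------------------
# Geometry report


@dataclass
class GeometryReport:
    rmsd_bond: float | None
    rmsd_angle: float | None
    clashes_per_1000: float
    rama_fractions: dict = field(default_factory=dict)
    hbond_count: int = 0
    hbond_distance_moments: tuple[float, float] | None = None
    hbond_angle_moments: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "rmsd_bond": self.rmsd_bond,
            "rmsd_angle": self.rmsd_angle,
            "clashes_per_1000": self.clashes_per_1000,
            "rama_fractions": self.rama_fractions,
            "hbond_count": self.hbond_count,
            "hbond_distance_skew_kurtosis": self.hbond_distance_moments,
            "hbond_angle_skew_kurtosis": self.hbond_angle_moments,
        }

    def to_table(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = []
        for k, v in d.items():
            if isinstance(v, float):
                v = f"{v:.4f}"
            lines.append(f"{k:<{width}}  {v}")
        return "\n".join(lines) + "\n"


def geometry_report(model: AtomicModel, variants: dict | None = None
                    ) -> GeometryReport:
    rs = build_restraints(model, variants)
    rmsd_bond, rmsd_angle = geometry_rmsd(model, rs)
    n_atoms = model.n_atoms
    clashes = detect_clashes(model, rs)
    hbonds = find_hbonds(model, restraints=rs, variants=variants)
    dist_m = ang_m = None
    if len(hbonds) >= 3:
        try:
            dist_m = skew_kurtosis([h.distance for h in hbonds])
            ang_m = skew_kurtosis([h.angle for h in hbonds])
        except ValidationError:
            pass
    _, fractions = rama_classify(model, variants)
    return GeometryReport(
        rmsd_bond=rmsd_bond, rmsd_angle=rmsd_angle,
        clashes_per_1000=1000.0 * len(clashes) / max(1, n_atoms),
        rama_fractions=fractions, hbond_count=len(hbonds),
        hbond_distance_moments=dist_m, hbond_angle_moments=ang_m)


# --------------------------------------------------------------------------
# Dataset selection filter

_FILTER_COLUMNS = ("n_atoms", "resolution", "clashscore",
                   "bond_outlier_rmsd_multiple", "experiment",
                   "cc_mask", "r_work", "homolog_resolution",
                   "homolog_rmsd", "homolog_identity")


def filter_entries(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the dataset selection criteria; adds 'accepted' and 'reason'.

    'between' thresholds are inclusive at both ends; 'better than' is a
    strict inequality.  'reason' holds the first failing criterion, in
    the order size, resolution, clashscore, bond outliers, data fit,
    homolog resolution, homolog rmsd, homolog identity.
    """
    missing = [c for c in _FILTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing columns: {', '.join(missing)}")
    accepted, reasons = [], []
    for _, row in table.iterrows():
        reason = ""
        if not 1000 <= row["n_atoms"] <= 10000:
            reason = "size"
        elif not 2.5 <= row["resolution"] <= 4.0:
            reason = "resolution"
        elif not row["clashscore"] < 50:
            reason = "clashscore"
        elif not row["bond_outlier_rmsd_multiple"] <= 4:
            reason = "bond outliers"
        elif row["experiment"] == "cryoem" and not row["cc_mask"] > 0.6:
            reason = "data fit"
        elif row["experiment"] == "xray" and not row["r_work"] < 0.3:
            reason = "data fit"
        elif not row["homolog_resolution"] < 2.0:
            reason = "homolog resolution"
        elif not row["homolog_rmsd"] < 1.0:
            reason = "homolog rmsd"
        elif not row["homolog_identity"] > 95.0:
            reason = "homolog identity"
        accepted.append(reason == "")
        reasons.append(reason)
    out = table.copy()
    out["accepted"] = accepted
    out["reason"] = reasons
    return out
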