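"""Restraint and surrogate energy backends.

Every backend follows the same contract: given Cartesian coordinates in
Angstrom it returns a total energy in kcal/mol together with analytic forces
(−∇E) in kcal/mol/A.  Two providers are shipped:

* :class:`RestraintBackend` — the classic stereochemical restraint score
  (bonds, angles, torsions, planarity, chirality, one-sided nonbonded
  overlap).
* :class:`SurrogateBackend` — a smooth physics surrogate layering screened
  Coulomb electrostatics, an exponential-repulsion / r^-6-dispersion pair
  term and a directional hydrogen-bond term on top of the bonded restraints,
  exposing the same interface a trained interatomic potential plugin would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .library import nonbonded_params
from .topology import RestraintSet


class SingularGeometryError(ValueError):
    """Raised when coincident atoms make an angle/torsion undefined."""


class UnparameterizedElementError(KeyError):
    """Raised when the pair-potential table has no entry for an element."""


# --------------------------------------------------------------------------
# Neighbor list


@dataclass
class NeighborList:
    """Symmetric i<j pair list of atoms closer than ``cutoff``."""

    pairs: np.ndarray        # (n, 2) int, i < j
    cutoff: float

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}


def build_neighbor_list(coords: np.ndarray, cutoff: float = 5.0
                        ) -> NeighborList:
    """All atom pairs with d < cutoff (k-d tree; O(N log N))."""
    coords = np.asarray(coords, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if cutoff <= 0.0 or len(coords) < 2:
        return NeighborList(np.empty((0, 2), int), cutoff)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # query_pairs uses d <= cutoff; the contract is strict inequality.
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
    return NeighborList(pairs[order].astype(int), cutoff)


# --------------------------------------------------------------------------
# Classic restraint terms (all analytic gradients)


def _bond_terms(rs: RestraintSet, x: np.ndarray, grad: np.ndarray) -> float:
    if not len(rs.bonds):
        return 0.0
    i = rs.bonds[:, 0].astype(int)
    j = rs.bonds[:, 1].astype(int)
    d0, k = rs.bonds[:, 2], rs.bonds[:, 3]
    dv = x[i] - x[j]
    d = np.linalg.norm(dv, axis=1)
    if np.any(d < 1e-6):
        raise SingularGeometryError("coincident bonded atoms")
    dev = d - d0
    g = (2.0 * k * dev / d)[:, None] * dv
    np.add.at(grad, i, g)
    np.add.at(grad, j, -g)
    return float(np.sum(k * dev ** 2))


def _angle_terms(rs: RestraintSet, x: np.ndarray, grad: np.ndarray) -> float:
    if not len(rs.angles):
        return 0.0
    i = rs.angles[:, 0].astype(int)
    c = rs.angles[:, 1].astype(int)
    j = rs.angles[:, 2].astype(int)
    th0, k = rs.angles[:, 3], rs.angles[:, 4]
    u = x[i] - x[c]
    v = x[j] - x[c]
    lu = np.linalg.norm(u, axis=1)
    lv = np.linalg.norm(v, axis=1)
    if np.any(lu < 1e-6) or np.any(lv < 1e-6):
        raise SingularGeometryError("coincident atoms in angle restraint")
    uh = u / lu[:, None]
    vh = v / lv[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
    dev = theta - th0
    dE = 2.0 * k * dev                       # dE/dtheta
    # dtheta/d(atom): from theta = arccos(uh . vh)
    gi = (-dE / (lu * sin_t))[:, None] * (vh - cos_t[:, None] * uh)
    gj = (-dE / (lv * sin_t))[:, None] * (uh - cos_t[:, None] * vh)
    np.add.at(grad, i, gi)
    np.add.at(grad, j, gj)
    np.add.at(grad, c, -(gi + gj))
    return float(np.sum(k * dev ** 2))


def _torsion_terms(rs: RestraintSet, x: np.ndarray,
                   grad: np.ndarray) -> float:
    if not len(rs.torsions):
        return 0.0
    ia = rs.torsions[:, 0].astype(int)
    ib = rs.torsions[:, 1].astype(int)
    ic = rs.torsions[:, 2].astype(int)
    id_ = rs.torsions[:, 3].astype(int)
    n = rs.torsions[:, 4]
    phi0, k = rs.torsions[:, 5], rs.torsions[:, 6]
    b1 = x[ib] - x[ia]
    b2 = x[ic] - x[ib]
    b3 = x[id_] - x[ic]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    l2 = np.linalg.norm(b2, axis=1)
    ln1 = np.einsum("ij,ij->i", n1, n1)
    ln2 = np.einsum("ij,ij->i", n2, n2)
    if np.any(l2 < 1e-6) or np.any(ln1 < 1e-12) or np.any(ln2 < 1e-12):
        raise SingularGeometryError("degenerate torsion geometry")
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / l2
    xx = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, xx)
    energy = float(np.sum(k * (1.0 + np.cos(n * phi - phi0))))
    dE = -k * n * np.sin(n * phi - phi0)     # dE/dphi
    # standard analytic dihedral derivatives
    dphi_da = (-l2 / ln1)[:, None] * n1
    dphi_dd = (l2 / ln2)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / l2 ** 2
    c32 = np.einsum("ij,ij->i", b3, b2) / l2 ** 2
    dphi_db = (-1.0 - c12)[:, None] * dphi_da + c32[:, None] * dphi_dd
    dphi_dc = c12[:, None] * dphi_da + (-1.0 - c32)[:, None] * dphi_dd
    np.add.at(grad, ia, dE[:, None] * dphi_da)
    np.add.at(grad, ib, dE[:, None] * dphi_db)
    np.add.at(grad, ic, dE[:, None] * dphi_dc)
    np.add.at(grad, id_, dE[:, None] * dphi_dd)
    return energy


def _plane_terms(rs: RestraintSet, x: np.ndarray, grad: np.ndarray) -> float:
    """Planarity as k * (sum of squared deviations from the best plane).

    The deviation sum equals the smallest eigenvalue of the point-set
    scatter matrix; by first-order perturbation theory its gradient is
    2 (n . (x_i - centroid)) n with n the associated unit eigenvector.
    """
    energy = 0.0
    for idxs, k in rs.planes:
        pts = x[idxs]
        cen = pts.mean(axis=0)
        q = pts - cen
        s = q.T @ q
        w, vec = np.linalg.eigh(s)
        lam, nrm = w[0], vec[:, 0]
        energy += k * lam
        dev = q @ nrm
        grad[idxs] += (2.0 * k) * dev[:, None] * nrm[None, :]
    return float(energy)


def _chirality_terms(rs: RestraintSet, x: np.ndarray,
                     grad: np.ndarray) -> float:
    if not len(rs.chirality):
        return 0.0
    c = rs.chirality[:, 0].astype(int)
    a1 = rs.chirality[:, 1].astype(int)
    a2 = rs.chirality[:, 2].astype(int)
    a3 = rs.chirality[:, 3].astype(int)
    v0, k = rs.chirality[:, 4], rs.chirality[:, 5]
    u1 = x[a1] - x[c]
    u2 = x[a2] - x[c]
    u3 = x[a3] - x[c]
    cr23 = np.cross(u2, u3)
    vol = np.einsum("ij,ij->i", u1, cr23)
    dev = vol - v0
    dE = (2.0 * k * dev)[:, None]
    g1 = dE * cr23
    g2 = dE * np.cross(u3, u1)
    g3 = dE * np.cross(u1, u2)
    np.add.at(grad, a1, g1)
    np.add.at(grad, a2, g2)
    np.add.at(grad, a3, g3)
    np.add.at(grad, c, -(g1 + g2 + g3))
    return float(np.sum(k * dev ** 2))


def _overlap_terms(rs: RestraintSet, x: np.ndarray,
                   grad: np.ndarray) -> float:
    """One-sided nonbonded overlap penalty k * max(0, allowed - d)^2."""
    n = len(x)
    if n < 2:
        return 0.0
    max_allowed = float(2.0 * rs.vdw_radii.max()) if len(rs.vdw_radii) else 4.0
    nl = build_neighbor_list(x, max_allowed)
    energy = 0.0
    k = rs.nonbonded_k
    for i, j in nl.pairs:
        key = (int(i), int(j))
        if key in rs.excluded or key in rs.pair14:
            continue
        dv = x[i] - x[j]
        d = float(np.linalg.norm(dv))
        allowed = rs.allowed_distance(int(i), int(j))
        if d >= allowed or d < 1e-6:
            continue
        dev = allowed - d
        energy += k * dev ** 2
        g = (-2.0 * k * dev / d) * dv
        grad[i] += g
        grad[j] -= g
    return float(energy)


def restraint_energy(rs: RestraintSet, coords: np.ndarray,
                     include_nonbonded: bool = True):
    """Total restraint energy and analytic forces.

    Returns ``(energy, forces)`` with forces = −∇E, shape (n_atoms, 3).
    """
    e, f, _ = restraint_energy_breakdown(rs, coords, include_nonbonded)
    return e, f


def restraint_energy_breakdown(rs: RestraintSet, coords: np.ndarray,
                               include_nonbonded: bool = True):
    x = np.asarray(coords, float).reshape(-1, 3)
    if x.shape[0] != rs.n_atoms:
        raise ValueError(f"expected {rs.n_atoms} atoms, got {x.shape[0]}")
    grad = np.zeros_like(x)
    terms = {
        "bond": _bond_terms(rs, x, grad),
        "angle": _angle_terms(rs, x, grad),
        "torsion": _torsion_terms(rs, x, grad),
        "plane": _plane_terms(rs, x, grad),
        "chirality": _chirality_terms(rs, x, grad),
    }
    if include_nonbonded:
        terms["nonbonded"] = _overlap_terms(rs, x, grad)
    energy = float(sum(terms.values()))
    return energy, -grad, terms


# --------------------------------------------------------------------------
# Backends


class RestraintBackend:
    """Classic stereochemical restraint score as an energy backend."""

    needs_restraint_set = True
    supports_charge = False

    def __init__(self, restraints: RestraintSet,
                 include_nonbonded: bool = True):
        self.restraints = restraints
        self.include_nonbonded = include_nonbonded

    def energy_forces(self, coords: np.ndarray):
        return restraint_energy(self.restraints, coords,
                                self.include_nonbonded)

    def breakdown(self, coords: np.ndarray) -> dict[str, float]:
        _, _, terms = restraint_energy_breakdown(
            self.restraints, coords, self.include_nonbonded)
        return terms

    def report(self, coords: np.ndarray) -> str:
        terms = self.breakdown(coords)
        lines = [f"{name:<12s} {val:14.6f}" for name, val in terms.items()]
        lines.append(f"{'total':<12s} {sum(terms.values()):14.6f}")
        return "\n".join(lines)


def _quintic_switch(r: np.ndarray, r_on: float, r_off: float):
    """C2-smooth taper: 1 below r_on, 0 above r_off.  Returns (S, dS/dr)."""
    r = np.asarray(r, float)
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t ** 3 * (10.0 - 15.0 * t + 6.0 * t ** 2)
    ds = -30.0 * t ** 2 * (1.0 - t) ** 2 / (r_off - r_on)
    return s, ds


class SurrogateBackend:
    """Smooth physics surrogate: bonded restraints + pair terms.

    On top of the full classic restraint score this adds, for every
    nonbonded pair within the cutoff:

    * screened Coulomb electrostatics with a distance-dependent dielectric
      eps(r) = slope * r (an implicit-solvent stand-in),
    * an exponential-repulsion / r^-6-dispersion (Buckingham-style) term
      parameterized per element so each homo-pair has its minimum exactly at
      the tabulated (eps, rmin),
    * a directional 10-12 hydrogen-bond term on D-H...A triplets (O/N donors
      and acceptors) weighted by the fourth power of the D-H/H...A alignment.

    1-2 and 1-3 pairs are excluded, 1-4 pairs are scaled by 0.5, and all pair
    terms are tapered to zero by a quintic switch over the last Angstrom
    before the cutoff, so the energy is C2-continuous everywhere.
    """

    needs_restraint_set = True
    supports_charge = True

    def __init__(self, restraints: RestraintSet,
                 include_charges: bool = True,
                 include_hbond: bool = True,
                 scale14: float = 0.5):
        self.restraints = restraints
        self.include_charges = include_charges
        self.include_hbond = include_hbond
        self.scale14 = scale14
        nb = nonbonded_params()
        pp = nb["pair_potential"]
        for e in set(restraints.elements):
            if e not in pp:
                raise UnparameterizedElementError(
                    f"no pair-potential parameters for element {e!r}")
        self._eps = np.array([pp[e][0] for e in restraints.elements])
        self._rmin = np.array([pp[e][1] for e in restraints.elements])
        self._coulomb = nb["electrostatics"]["coulomb_constant"]
        self._dielectric_slope = nb["electrostatics"]["dielectric_slope"]
        hb = nb["hydrogen_bond"]
        self._hb_eps = hb["epsilon"]
        self._hb_r0 = hb["r0"]
        self._hb_pow = int(hb["angle_power"])
        self._cutoff = nb["cutoff"]["radius"]
        self._switch_on = self._cutoff - nb["cutoff"]["switch_width"]
        self.total_charge = float(np.round(restraints.charges.sum()))
        if include_hbond and not restraints.donors:
            n_polar = int(np.sum([e in ("N", "O")
                                  for e in restraints.elements]))
            if n_polar:
                warnings.warn("no polar hydrogens present; "
                              "hydrogen-bond term skipped")

    # -- pair terms -------------------------------------------------------

    def _pair_terms(self, x: np.ndarray, grad: np.ndarray):
        rs = self.restraints
        nl = build_neighbor_list(x, self._cutoff)
        energy = 0.0
        for i, j in nl.pairs:
            key = (int(i), int(j))
            if key in rs.excluded:
                continue
            scale = self.scale14 if key in rs.pair14 else 1.0
            dv = x[i] - x[j]
            r = float(np.linalg.norm(dv))
            if r < 1e-6:
                raise SingularGeometryError("coincident nonbonded atoms")
            s, ds = _quintic_switch(r, self._switch_on, self._cutoff)
            s, ds = float(s), float(ds)
            # Buckingham-style exp-6, combined so the homo-pair minimum sits
            # exactly at (rmin_i, depth eps_i): A=eps*e^12, B=12/rmin,
            # C6=2*eps*rmin^6.
            eps = np.sqrt(self._eps[i] * self._eps[j])
            rmin = 0.5 * (self._rmin[i] + self._rmin[j])
            b = 12.0 / rmin
            u_rep = eps * np.exp(12.0 - b * r)
            u_disp = -2.0 * eps * (rmin / r) ** 6
            u = u_rep + u_disp
            du = -b * u_rep - 6.0 * u_disp / r
            if self.include_charges:
                qq = rs.charges[i] * rs.charges[j]
                u_c = self._coulomb * qq / (self._dielectric_slope * r * r)
                u += u_c
                du += -2.0 * u_c / r
            energy += scale * u * s
            de = scale * (du * s + u * ds)
            g = (de / r) * dv
            grad[i] += g
            grad[j] -= g
        return float(energy)

    def _hbond_terms(self, x: np.ndarray, grad: np.ndarray):
        rs = self.restraints
        if not rs.donors:
            return 0.0
        acc = np.flatnonzero(rs.is_acceptor)
        if not len(acc):
            return 0.0
        tree = cKDTree(x[acc])
        energy = 0.0
        for d_idx, h_idx in rs.donors:
            for a_pos in tree.query_ball_point(x[h_idx], self._cutoff):
                a_idx = int(acc[a_pos])
                if a_idx == d_idx:
                    continue
                key = (min(h_idx, a_idx), max(h_idx, a_idx))
                if key in rs.excluded or key in rs.pair14:
                    continue
                rv = x[a_idx] - x[h_idx]
                r = float(np.linalg.norm(rv))
                if r < 1e-6 or r >= self._cutoff:
                    continue
                uv = x[h_idx] - x[d_idx]
                lu = float(np.linalg.norm(uv))
                if lu < 1e-6:
                    raise SingularGeometryError("coincident donor/hydrogen")
                uh = uv / lu
                vh = rv / r
                align = float(np.dot(uh, vh))
                if align <= 0.0:
                    continue
                w = align ** self._hb_pow
                t = self._hb_r0 / r
                u_rad = self._hb_eps * (5.0 * t ** 12 - 6.0 * t ** 10)
                du_rad = (60.0 * self._hb_eps / r) * (t ** 10 - t ** 12)
                s, ds = _quintic_switch(r, self._switch_on, self._cutoff)
                s, ds = float(s), float(ds)
                energy += u_rad * w * s
                # radial part (acts along H...A)
                g_rad = (du_rad * s + u_rad * ds) * w
                grad[a_idx] += g_rad * vh
                grad[h_idx] -= g_rad * vh
                # angular part
                dw = self._hb_pow * align ** (self._hb_pow - 1)
                pref = u_rad * s * dw
                da_dD = -(vh - align * uh) / lu
                da_dA = (uh - align * vh) / r
                grad[d_idx] += pref * da_dD
                grad[a_idx] += pref * da_dA
                grad[h_idx] += pref * (-da_dD - da_dA)
        return float(energy)

    def energy_forces(self, coords: np.ndarray):
        e, f, _ = self.energy_forces_breakdown(coords)
        return e, f

    def energy_forces_breakdown(self, coords: np.ndarray):
        x = np.asarray(coords, float).reshape(-1, 3)
        e_b, f_b, terms = restraint_energy_breakdown(self.restraints, x)
        grad = np.zeros_like(x)
        terms = dict(terms)
        terms["pair"] = self._pair_terms(x, grad)
        if self.include_hbond:
            terms["hbond"] = self._hbond_terms(x, grad)
        energy = e_b + terms["pair"] + terms.get("hbond", 0.0)
        return float(energy), f_b - grad, terms

    def breakdown(self, coords: np.ndarray) -> dict[str, float]:
        return self.energy_forces_breakdown(coords)[2]

    def report(self, coords: np.ndarray) -> str:
        terms = self.breakdown(coords)
        lines = [f"{name:<12s} {val:14.6f}" for name, val in terms.items()]
        lines.append(f"{'total':<12s} {sum(terms.values()):14.6f}")
        return "\n".join(lines)


def finite_difference_forces(backend, coords: np.ndarray,
                             h: float = 1e-4) -> np.ndarray:
    """Central finite-difference forces; the test oracle for any backend."""
    x = np.array(coords, float).reshape(-1, 3)
    f = np.zeros_like(x)
    for i in range(x.shape[0]):
        for k in range(3):
            xp = x.copy()
            xp[i, k] += h
            ep, _ = backend.energy_forces(xp)
            xm = x.copy()
            xm[i, k] -= h
            em, _ = backend.energy_forces(xm)
            f[i, k] = -(ep - em) / (2.0 * h)
    return f
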