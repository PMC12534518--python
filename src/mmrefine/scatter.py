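"""Reciprocal-space data targets: structure factors, R factors, LS target.

Structure factors use the standard 4-Gaussian atomic scattering model with
direct summation over symmetry-equivalent positions.  The refinement target
is amplitude least squares on the working set,

    T = sum_work (F_obs - k*|F_calc|)^2 / sum_work F_obs^2 ,

with the linear scale k = sum(F_obs*|F_c|)/sum(|F_c|^2) recomputed at every
evaluation and analytic coordinate gradients.  (At the least-squares scale
the chain-rule term through k vanishes identically, since the residual is
orthogonal to |F_c| — used and unit-tested.)  Free-set reflections never
contribute to the target or its gradient.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AtomicModel, UnitCell
from .symmetry import symops_for

# 4-Gaussian scattering-factor coefficients (a1..a4, b1..b4, c),
# International Tables for Crystallography Vol. C, table 6.1.1.4.
FORM_FACTORS: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "SE": ((17.0006, 5.81960, 3.97310, 4.35430),
           (2.40980, 0.027200, 15.2372, 43.8163), 2.84090),
}


class DataError(ValueError):
    pass


def form_factor(element: str, s) -> np.ndarray | float:
    """Atomic scattering factor f(s), s = sin(theta)/lambda in 1/A."""
    key = element.upper()
    if key not in FORM_FACTORS:
        raise DataError(f"no form factors for element {element!r}")
    a, b, c = FORM_FACTORS[key]
    s2 = np.square(np.asarray(s, float))
    f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
    return float(f) if np.isscalar(s) else f


# --------------------------------------------------------------------------
# Reflection data


@dataclass
class ReflectionSet:
    """Observed amplitudes indexed by Miller indices, with free-set flags."""

    hkl: np.ndarray                  # (n, 3) int
    f_obs: np.ndarray                # (n,) amplitudes
    free_flag: np.ndarray            # (n,) bool
    cell: UnitCell
    space_group: str = "P 1"
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.f_obs = np.asarray(self.f_obs, float)
        self.free_flag = np.asarray(self.free_flag, bool)
        n = len(self.hkl)
        if len(self.f_obs) != n or len(self.free_flag) != n:
            raise DataError("reflection array length mismatch")
        if len(np.unique(self.hkl, axis=0)) != n:
            raise DataError("duplicate Miller indices")
        if np.any(self.f_obs < 0):
            raise DataError("negative F_obs")
        frac = self.free_flag.mean() if n else 0.0
        if not 0.0 < frac < 0.5:
            raise DataError(
                f"free fraction {frac:.3f} outside (0, 0.5)")

    def __len__(self) -> int:
        return len(self.hkl)

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d_spacings().min())


def make_free_flags(hkl: np.ndarray, seed: int,
                    fraction: float = 0.05) -> np.ndarray:
    """Deterministic free-set flags by seeded hash of the Miller indices."""
    if not 0.0 < fraction < 0.5:
        raise DataError("free fraction must be in (0, 0.5)")
    hkl = np.asarray(hkl, int).reshape(-1, 3)
    flags = np.zeros(len(hkl), bool)
    for i, (h, k, l) in enumerate(hkl):
        digest = hashlib.md5(f"{h},{k},{l},{seed}".encode()).digest()
        val = int.from_bytes(digest[:8], "big") / 2 ** 64
        flags[i] = val < fraction
    if not flags.any():           # tiny sets: force one free reflection
        flags[0] = True
    if flags.all():
        flags[0] = False
    return flags


def generate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """Unique-hemisphere Miller indices with d >= d_min (Friedel collapsed).

    The hemisphere convention is h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0.
    """
    if d_min <= 0:
        raise DataError("d_min must be positive")
    hmax = int(np.ceil(cell.a / d_min))
    kmax = int(np.ceil(cell.b / d_min))
    lmax = int(np.ceil(cell.c / d_min))
    cand = []
    for h in range(0, hmax + 1):
        kr = range(-kmax, kmax + 1) if h > 0 else range(0, kmax + 1)
        for k in kr:
            if h == 0 and k == 0:
                lr = range(1, lmax + 1)
            elif h == 0:
                lr = range(-lmax, lmax + 1) if k > 0 else range(0)
            else:
                lr = range(-lmax, lmax + 1)
            for l in lr:
                cand.append((h, k, l))
    cand = np.array(sorted(cand), int).reshape(-1, 3)
    if not len(cand):
        return cand
    keep = cell.d_spacing(cand) >= d_min
    return cand[keep]


# --------------------------------------------------------------------------
# Structure factors


def _model_scatter_arrays(model: AtomicModel):
    elements = model.elements()
    for e in elements:
        if e.upper() not in FORM_FACTORS:
            raise DataError(f"no form factors for element {e!r}")
    return (np.array([e.upper() for e in elements]),
            model.occupancies(), model.b_factors())


def calc_structure_factors(model: AtomicModel,
                           hkl: np.ndarray) -> np.ndarray:
    """Complex F(hkl) by direct summation over symmetry copies."""
    f, _ = _structure_factors_core(model, np.asarray(hkl, int),
                                   want_gradient_context=False)
    return f


def _structure_factors_core(model: AtomicModel, hkl: np.ndarray,
                            want_gradient_context: bool):
    if model.unit_cell is None:
        raise DataError("structure factors require a unit cell")
    elements, occ, bfac = _model_scatter_arrays(model)
    cell = model.unit_cell
    ops = symops_for(model.space_group or "P 1")
    m_frac = cell.fractionalization_matrix()
    frac = model.get_coords() @ m_frac.T

    d = cell.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d * d)                      # (sin(theta)/lambda)^2
    # per-atom hkl-dependent weights: occ * f(s) * exp(-B s^2)
    f_elem = {e: form_factor(e, np.sqrt(s2)) for e in set(elements)}
    w = np.empty((len(hkl), len(elements)))
    for j, e in enumerate(elements):
        w[:, j] = occ[j] * f_elem[e] * np.exp(-bfac[j] * s2)

    f_total = np.zeros(len(hkl), complex)
    ctx = []
    hkl_f = hkl.astype(float)
    for op in ops:
        xf = frac @ op.rot_array.T + op.trans_array
        phase = np.exp(2j * np.pi * (hkl_f @ xf.T))      # (n_hkl, n_atoms)
        f_total += np.sum(w * phase, axis=1)
        if want_gradient_context:
            # d(phase angle)/dx = M_frac^T R^T h  per hkl
            v = hkl_f @ op.rot_array @ m_frac               # (n_hkl, 3)
            ctx.append((phase, v))
    return f_total, (w, ctx)


def r_factor(f_obs: np.ndarray, f_calc: np.ndarray,
             free_flag: np.ndarray):
    """(R_work, R_free, scale) with the LS scale fit on the working set."""
    f_obs = np.asarray(f_obs, float)
    amp = np.abs(np.asarray(f_calc))
    free = np.asarray(free_flag, bool)
    work = ~free
    if not work.any() or not free.any():
        raise DataError("empty work or free partition")
    denom = float(np.sum(amp[work] ** 2))
    if denom == 0.0:
        raise DataError("all-zero calculated amplitudes")
    scale = float(np.sum(f_obs[work] * amp[work]) / denom)

    def _r(sel):
        return float(np.sum(np.abs(f_obs[sel] - scale * amp[sel]))
                     / np.sum(f_obs[sel]))

    return _r(work), _r(free), scale


class LSTarget:
    """Amplitude least-squares data target (DataTarget contract).

    ``evaluate(coords)`` returns (T, dT/dcoords).  Only working-set
    reflections enter T and the gradient; ``r_factors`` reports
    (R_work, R_free, scale) for monitoring.
    """

    mode = "reciprocal"

    def __init__(self, model: AtomicModel, reflections: ReflectionSet):
        if reflections.free_flag.all():
            raise DataError("all reflections flagged free")
        self.model = model.copy()
        self.reflections = reflections
        self._work = ~reflections.free_flag
        self._fo_work = reflections.f_obs[self._work]
        self._denom = float(np.sum(self._fo_work ** 2))
        if self._denom == 0.0:
            raise DataError("zero F_obs normalization")
        self._hkl_work = reflections.hkl[self._work]

    def evaluate(self, coords: np.ndarray):
        x = np.asarray(coords, float).reshape(-1, 3)
        self.model.set_coords(x)
        f_c, (w, ctx) = _structure_factors_core(
            self.model, self._hkl_work, want_gradient_context=True)
        amp = np.abs(f_c)
        amp_safe = np.maximum(amp, 1e-12)
        s2 = float(np.sum(amp ** 2))
        if s2 == 0.0:
            raise DataError("all-zero calculated amplitudes")
        k = float(np.sum(self._fo_work * amp) / s2)
        resid = self._fo_work - k * amp
        t = float(np.sum(resid ** 2) / self._denom)
        # dT/d|F| = -2 k resid / denom  (k-chain term vanishes at LS scale)
        dt_damp = -2.0 * k * resid / self._denom
        c = dt_damp * np.conj(f_c) / amp_safe            # (n_hkl,) complex
        grad = np.zeros_like(x)
        for phase, v in ctx:
            p = c[:, None] * w * phase                   # (n_hkl, n_atoms)
            grad += -2.0 * np.pi * np.imag(
                np.einsum("ha,hc->ac", p, v))
        return t, grad

    def r_factors(self, coords: np.ndarray):
        x = np.asarray(coords, float).reshape(-1, 3)
        self.model.set_coords(x)
        f_c = calc_structure_factors(self.model, self.reflections.hkl)
        return r_factor(self.reflections.f_obs, f_c,
                        self.reflections.free_flag)


# --------------------------------------------------------------------------
# Reflection I/O (TSV with documented header; MTZ read via gemmi)

_COLUMNS = ["h", "k", "l", "f_obs", "sigma", "free"]


def write_reflections(refl: ReflectionSet, path) -> None:
    df = pd.DataFrame({
        "h": refl.hkl[:, 0], "k": refl.hkl[:, 1], "l": refl.hkl[:, 2],
        "f_obs": refl.f_obs,
        "sigma": (refl.sigma if refl.sigma is not None
                  else np.zeros(len(refl))),
        "free": refl.free_flag.astype(int),
    })
    with open(path, "w") as fh:
        cell = refl.cell
        fh.write(f"# cell {cell.a:g} {cell.b:g} {cell.c:g} "
                 f"{cell.alpha:g} {cell.beta:g} {cell.gamma:g}\n")
        fh.write(f"# space_group {refl.space_group}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_reflections(path) -> ReflectionSet:
    path = str(path)
    if path.lower().endswith(".mtz"):
        return _read_mtz(path)
    cell_vals, sg = None, "P 1"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] == "cell":
                cell_vals = [float(v) for v in parts[1:7]]
            elif parts and parts[0] == "space_group":
                sg = " ".join(parts[1:])
    if cell_vals is None:
        raise DataError(f"{path}: missing '# cell a b c al be ga' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return ReflectionSet(
        hkl=df[["h", "k", "l"]].to_numpy(int),
        f_obs=df["f_obs"].to_numpy(float),
        free_flag=(df["free"].to_numpy(int).astype(bool)
                   if "free" in df.columns
                   else make_free_flags(df[["h", "k", "l"]].to_numpy(int), 0)),
        sigma=(df["sigma"].to_numpy(float) if "sigma" in df.columns
               else None),
        cell=UnitCell(*cell_vals),
        space_group=sg)


def _read_mtz(path: str) -> ReflectionSet:
    import gemmi

    mtz = gemmi.read_mtz_file(path)
    hkl = np.array([[int(r[0]), int(r[1]), int(r[2])] for r in mtz.array],
                   int)
    f_col = next((c for c in mtz.columns if c.type == "F"), None)
    if f_col is None:
        raise DataError(f"{path}: no amplitude column")
    flag_col = next((c for c in mtz.columns if c.type == "I"
                     and "free" in c.label.lower()), None)
    f_obs = np.array(f_col)
    if flag_col is not None:
        flags = np.array(flag_col).astype(int) == 0
    else:
        flags = make_free_flags(hkl, 0)
    c = mtz.cell
    return ReflectionSet(hkl=hkl, f_obs=f_obs, free_flag=flags,
                         cell=UnitCell(c.a, c.b, c.c,
                                       c.alpha, c.beta, c.gamma),
                         space_group=mtz.spacegroup.hm)
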