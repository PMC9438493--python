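"""Unit cells, space-group symmetry, grids, reflection/map containers and I/O.

Densities are represented on a regular grid covering one full unit cell
(P1-expanded); crystallographic symmetry is imposed by averaging over the
space-group operators in real space.  Structure factors follow the convention

    G(h) = sum_x rho(x) exp(+2 pi i h.x),

evaluated by FFT on the cell grid; the overall scale (cell volume factor) is
left out because every amplitude comparison in the package is performed after
least-squares scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
import scipy.fft


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        # metric tensor must be positive definite (triangle-like condition)
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("degenerate cell: metric tensor not positive definite")

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (3x3), in A^2."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array([
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ])

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (standard PDB convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ])

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization_matrix()))

    def s(self, h, k=None, l=None) -> np.ndarray | float:
        """Scattering-vector magnitude s = 1/d (A^-1) for Miller indices."""
        if k is None:
            hkl = np.asarray(h, dtype=float)
        else:
            hkl = np.stack(np.broadcast_arrays(
                np.asarray(h, float), np.asarray(k, float), np.asarray(l, float)), axis=-1)
        gstar = self.reciprocal_metric_tensor()
        s2 = np.einsum("...i,ij,...j->...", hkl, gstar, hkl)
        out = np.sqrt(np.maximum(s2, 0.0))
        return float(out) if out.ndim == 0 else out

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def scattering_magnitude(h: int, k: int, l: int, cell: UnitCell) -> float:
    """s = 1/resolution in A^-1 for reflection (h, k, l)."""
    return float(cell.s(h, k, l))


# --------------------------------------------------------------------------
# Space groups
# --------------------------------------------------------------------------

def _frac_vec(*xs) -> np.ndarray:
    return np.array([float(Fraction(x)) for x in xs])


@dataclass(frozen=True)
class SymOp:
    """One symmetry operator x -> R x + t in fractional coordinates."""

    rot: tuple  # 3x3 integer rotation, stored as nested tuples (hashable)
    trans: tuple  # fractional translation

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)

    @staticmethod
    def from_arrays(R, t) -> "SymOp":
        t = np.mod(np.asarray(t, float), 1.0)
        t = np.round(t * 24) / 24  # snap to crystallographic fractions
        t = np.mod(t, 1.0)
        return SymOp(tuple(map(tuple, np.asarray(R, int))), tuple(t))

    def compose(self, other: "SymOp") -> "SymOp":
        # (R1,t1) o (R2,t2): x -> R1(R2 x + t2) + t1
        return SymOp.from_arrays(self.R @ other.R, self.R @ other.t + self.t)

    @staticmethod
    def from_triplet(triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        R = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        return SymOp.from_arrays(np.round(R).astype(int), t)


class SpaceGroupSpec:
    """Space-group description: operators, origin ambiguity, chirality.

    ``operators`` must form a group (closure is validated).  Allowed origin
    shifts are derived from the operators: a shift t is permissible iff
    (R - I) t = 0 (mod 1) for every rotation part R.  Directions along which
    (R - I) annihilates a lattice axis for all operators are continuous
    (polar) origin directions.
    """

    def __init__(self, name: str, operators, *, chiral: bool = False,
                 enantiomorph_partner: str | None = None):
        self.name = name
        self.operators: list[SymOp] = list(operators)
        self.chiral = bool(chiral)
        self.enantiomorph_partner = enantiomorph_partner
        # density inversion changes the group for chiral (enantiomorphic) groups
        self.inversion_ambiguous = not self.chiral
        if chiral and enantiomorph_partner is None:
            raise ValueError("chiral group needs an enantiomorph partner name")
        self._validate_group()
        self.continuous_origin_axes, self.allowed_origin_shifts = self._origin_shifts()

    # -- group structure ---------------------------------------------------

    def _validate_group(self):
        ops = {(op.rot, op.trans) for op in self.operators}
        ident = SymOp.from_arrays(np.eye(3, dtype=int), np.zeros(3))
        if (ident.rot, ident.trans) not in ops:
            raise ValueError("identity operator missing")
        for a in self.operators:
            for b in self.operators:
                c = a.compose(b)
                if (c.rot, c.trans) not in ops:
                    raise ValueError(
                        f"operators of {self.name} not closed under composition")

    def __len__(self):
        return len(self.operators)

    # -- origin ambiguity --------------------------------------------------

    def _origin_shifts(self):
        rots = [op.R for op in self.operators]
        continuous = []
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = 1.0
            continuous.append(all(np.allclose((R - np.eye(3)) @ e, 0) for R in rots))
        # discrete solutions on a 1/12 grid along non-continuous axes
        grids = [np.arange(12) / 12.0 if not cont else np.array([0.0])
                 for cont in continuous]
        shifts = []
        for x in grids[0]:
            for y in grids[1]:
                for z in grids[2]:
                    t = np.array([x, y, z])
                    ok = all(
                        np.allclose(np.mod((R - np.eye(3)) @ t + 0.5, 1.0) - 0.5, 0,
                                    atol=1e-9)
                        for R in rots)
                    if ok:
                        shifts.append(t)
        return tuple(continuous), shifts

    # -- action on reflections --------------------------------------------

    def reflection_orbit(self, hkl: np.ndarray):
        """Equivalent indices h' with G(h') = G(h) * exp(2 pi i h'.t).

        Returns (h_equiv, phase_turns) where phase_turns is h'.t (in cycles),
        one row per operator.  Friedel mates are not included.
        """
        hkl = np.asarray(hkl, int)
        out_h, out_p = [], []
        for op in self.operators:
            Rinv = np.round(np.linalg.inv(op.R)).astype(int)
            h2 = Rinv.T @ hkl
            # G(h2) = G(h) exp(2 pi i h2 . t_of_inverse_op)?  Derivation:
            # rho(x) = rho(R x + t)  =>  G(R^-T h) = G(h) exp(2 pi i (R^-T h).t)
            out_h.append(h2)
            out_p.append(float(h2 @ op.t))
        return np.array(out_h), np.array(out_p)

    def epsilon_and_absent(self, hkl) -> tuple[int, bool]:
        """Symmetry enhancement factor and systematic-absence flag."""
        hkl = np.asarray(hkl, int)
        h_eq, turns = self.reflection_orbit(hkl)
        sel = np.all(h_eq == hkl, axis=1)
        phase_sum = np.exp(2j * np.pi * turns[sel]).sum()
        n_stab = int(sel.sum())
        absent = bool(abs(phase_sum) < 1e-6)
        return n_stab, absent

    def centric_flag_and_phase(self, hkl) -> tuple[bool, float]:
        """(centric?, allowed phase in degrees modulo 180) for a reflection."""
        hkl = np.asarray(hkl, int)
        h_eq, turns = self.reflection_orbit(hkl)
        sel = np.all(h_eq == -hkl, axis=1)
        if not sel.any():
            return False, float("nan")
        # G(-h) = G(h) e^{2 pi i (-h).t}; with Friedel G(-h) = G(h)*:
        # 2 phi = -2 pi (-h).t  =>  phi = 180 * (h.t) (mod 180) in degrees
        turn = turns[np.nonzero(sel)[0][0]]
        return True, float(np.mod(-180.0 * turn, 180.0))

    # -- serialization ------------------------------------------------------

    @staticmethod
    def from_operator_file(path, name: str | None = None, *, chiral=False,
                           enantiomorph_partner=None) -> "SpaceGroupSpec":
        """Read operators from a text file, one x,y,z-style triplet per line."""
        ops = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                ops.append(SymOp.from_triplet(line))
        return SpaceGroupSpec(name or Path(path).stem, ops, chiral=chiral,
                              enantiomorph_partner=enantiomorph_partner)


def _group_from_triplets(name, triplets, **kw) -> SpaceGroupSpec:
    return SpaceGroupSpec(name, [SymOp.from_triplet(s) for s in triplets], **kw)


@lru_cache(maxsize=None)
def get_spacegroup(name: str) -> SpaceGroupSpec:
    """Built-in space-group table (operators from the standard settings)."""
    key = name.replace(" ", "").replace("(", "").replace(")", "")
    table = {
        "P1": lambda: _group_from_triplets("P1", ["x,y,z"]),
        "P21": lambda: _group_from_triplets(
            "P21", ["x,y,z", "-x,y+1/2,-z"]),
        "P212121": lambda: _group_from_triplets(
            "P212121",
            ["x,y,z", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2", "-x+1/2,-y,z+1/2"]),
        "I222": lambda: _group_from_triplets(
            "I222",
            ["x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z",
             "x+1/2,y+1/2,z+1/2", "-x+1/2,-y+1/2,z+1/2",
             "-x+1/2,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z+1/2"]),
        "P61": lambda: _group_from_triplets(
            "P61",
            ["x,y,z", "-y,x-y,z+1/3", "-x+y,-x,z+2/3",
             "-x,-y,z+1/2", "y,-x+y,z+5/6", "x-y,x,z+1/6"],
            chiral=True, enantiomorph_partner="P65"),
        "P65": lambda: _group_from_triplets(
            "P65",
            ["x,y,z", "-y,x-y,z+2/3", "-x+y,-x,z+1/3",
             "-x,-y,z+1/2", "y,-x+y,z+1/6", "x-y,x,z+5/6"],
            chiral=True, enantiomorph_partner="P61"),
    }
    if key not in table:
        raise KeyError(
            f"space group {name!r} is not in the built-in table "
            f"({sorted(table)}); load arbitrary groups with "
            "SpaceGroupSpec.from_operator_file")
    return table[key]()


# --------------------------------------------------------------------------
# Grids and maps
# --------------------------------------------------------------------------

def _good_fft_size(n: int, multiple: int) -> int:
    """Smallest 5-smooth integer >= n that is a multiple of ``multiple``."""
    m = multiple * math.ceil(n / multiple)
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += multiple


@dataclass(frozen=True)
class GridSpec:
    nu: int
    nv: int
    nw: int

    def __post_init__(self):
        if min(self.nu, self.nv, self.nw) < 2:
            raise ValueError("grid counts must be >= 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nu, self.nv, self.nw)

    @property
    def size(self) -> int:
        return self.nu * self.nv * self.nw

    @staticmethod
    def from_spacing(cell: UnitCell, spacing: float,
                     spacegroup: SpaceGroupSpec | None = None) -> "GridSpec":
        """Grid with target spacing (A), FFT-friendly and symmetry-compatible."""
        targets = [max(2, math.ceil(L / spacing)) for L in (cell.a, cell.b, cell.c)]
        multiples = [1, 1, 1]
        tied = [{i} for i in range(3)]
        if spacegroup is not None:
            for op in spacegroup.operators:
                for axis in range(3):
                    den = Fraction(op.t[axis]).limit_denominator(24).denominator
                    multiples[axis] = _lcm(multiples[axis], den)
                R = op.R
                for i in range(3):
                    for j in range(3):
                        if i != j and R[i, j] != 0:
                            tied[i] |= tied[j]
        # propagate axis ties (rotations mixing axes need equal counts)
        for _ in range(3):
            for i in range(3):
                for j in list(tied[i]):
                    tied[i] |= tied[j]
        counts = [0, 0, 0]
        for i in range(3):
            group = sorted(tied[i])
            t = max(targets[j] for j in group)
            m = 1
            for j in group:
                m = _lcm(m, multiples[j])
            counts[i] = _good_fft_size(t, m)
        return GridSpec(*counts)


def _lcm(a: int, b: int) -> int:
    return a * b // math.gcd(a, b)


class DensityMap:
    """Real-valued density on a grid over one full unit cell.

    Fractional coordinate (0,0,0) sits at grid index (0,0,0); values are
    stored C-ordered with axes (u, v, w).
    """

    def __init__(self, values: np.ndarray, cell: UnitCell,
                 spacegroup: SpaceGroupSpec | None = None):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError("density values must be a 3-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("density contains non-finite values")
        self.values = values
        self.cell = cell
        self.spacegroup = spacegroup or get_spacegroup("P1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(*self.values.shape)

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell, self.spacegroup)

    def with_values(self, values: np.ndarray) -> "DensityMap":
        return DensityMap(values, self.cell, self.spacegroup)

    def symmetrized(self) -> "DensityMap":
        perms = symmetry_permutations(self.grid.shape, self.spacegroup)
        if len(perms) == 1:
            return self.copy()
        flat = self.values.ravel()
        acc = np.zeros_like(flat)
        for p in perms:
            acc += flat[p]
        return self.with_values((acc / len(perms)).reshape(self.values.shape))


@lru_cache(maxsize=32)
def _symmetry_permutations_cached(shape: tuple, ops_key: tuple):
    n = np.array(shape)
    idx = np.indices(shape).reshape(3, -1)  # fractional index columns
    perms = []
    for rot, trans in ops_key:
        R = np.array(rot, int)
        t = np.array(trans, float)
        tn = t * n
        tn_int = np.round(tn).astype(int)
        if not np.allclose(tn, tn_int, atol=1e-6):
            raise ValueError(
                "grid incompatible with symmetry translations; choose counts "
                "divisible by the translation denominators")
        j = (R @ idx + tn_int[:, None]) % n[:, None]
        perms.append(np.ravel_multi_index(j, shape))
    return perms


def symmetry_permutations(shape, spacegroup: SpaceGroupSpec):
    """Flat-index permutation arrays realizing each operator on the grid."""
    ops_key = tuple((op.rot, op.trans) for op in spacegroup.operators)
    return _symmetry_permutations_cached(tuple(shape), ops_key)


# --------------------------------------------------------------------------
# Fourier transforms between maps and structure factors
# --------------------------------------------------------------------------

def map_to_structure_factors(map_: DensityMap) -> np.ndarray:
    """Complex coefficients G(h) on the FFT grid (h indexed modulo counts)."""
    v = map_.values
    return scipy.fft.ifftn(v) * v.size


def structure_factors_to_map(coeffs: np.ndarray, cell: UnitCell,
                             spacegroup: SpaceGroupSpec | None = None) -> DensityMap:
    v = np.real(scipy.fft.fftn(coeffs)) / coeffs.size
    return DensityMap(np.ascontiguousarray(v), cell, spacegroup)


def grid_miller_indices(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed Miller indices (h,k,l) for every FFT grid point."""
    hs = [np.fft.fftfreq(n, d=1.0 / n).astype(int) for n in shape]
    return np.meshgrid(*hs, indexing="ij")


# --------------------------------------------------------------------------
# Reflection data
# --------------------------------------------------------------------------

class ReflectionData:
    """Symmetry-unique reflection list with amplitudes and classification.

    One record per symmetry-unique reflection (one Friedel hemisphere);
    ``missing`` marks records whose amplitude must not be imposed (either the
    file had no amplitude, or the reflection lies below the low-resolution
    cutoff).
    """

    def __init__(self, hkl: np.ndarray, f_obs: np.ndarray, sigma: np.ndarray,
                 missing: np.ndarray, cell: UnitCell, spacegroup: SpaceGroupSpec,
                 low_res_cutoff: float | None = None):
        self.hkl = np.asarray(hkl, int).reshape(-1, 3)
        self.f_obs = np.asarray(f_obs, float)
        self.sigma = np.asarray(sigma, float)
        self.missing = np.asarray(missing, bool)
        self.cell = cell
        self.spacegroup = spacegroup
        self.low_res_cutoff = low_res_cutoff
        if np.any(self.f_obs[~self.missing] < 0):
            raise ValueError("negative amplitude in reflection data")
        if len({tuple(x) for x in map(tuple, self.hkl)}) != len(self.hkl):
            raise ValueError("duplicate reflections in unique set")
        self.s = cell.s(self.hkl)
        cen, eps = [], []
        for row in self.hkl:
            e, absent = spacegroup.epsilon_and_absent(row)
            if absent:
                raise ValueError(f"systematically absent reflection {tuple(row)}")
            c, _ = spacegroup.centric_flag_and_phase(row)
            cen.append(c)
            eps.append(e)
        self.centric = np.array(cen, bool)
        self.epsilon = np.array(eps, int)

    def __len__(self):
        return len(self.hkl)

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    @property
    def d_min(self) -> float:
        return float(1.0 / self.s.max())

    def centric_allowed_phase(self) -> np.ndarray:
        """Allowed phase (degrees, modulo 180) for centric records, NaN else."""
        out = np.full(len(self), np.nan)
        for i, row in enumerate(self.hkl):
            c, phi = self.spacegroup.centric_flag_and_phase(row)
            if c:
                out[i] = phi
        return out


def canonical_representatives(hkl: np.ndarray, spacegroup: SpaceGroupSpec):
    """Canonical unique representative for each reflection.

    The representative is the lexicographically largest member of the orbit
    under the space group and Friedel symmetry.  Returns (reps (N,3), the
    phase-turn carrying G(rep) = G(h) e^{2 pi i turn}, and a Friedel flag
    meaning the representative is related to h through conjugation).
    """
    hkl = np.asarray(hkl, int).reshape(-1, 3)
    reps = np.empty_like(hkl)
    turns = np.empty(len(hkl))
    friedel = np.empty(len(hkl), bool)
    for i, h in enumerate(hkl):
        h_eq, t_eq = spacegroup.reflection_orbit(h)
        candidates = []  # (tuple, turn, conj)
        for he, te in zip(h_eq, t_eq):
            candidates.append((tuple(he), te, False))
            # Friedel mate: G(-h') = conj(G(h')) => conj then phase
            candidates.append((tuple(-he), -te, True))
        best = max(candidates, key=lambda c: c[0])
        reps[i] = best[0]
        turns[i] = best[1]
        friedel[i] = best[2]
    return reps, turns, friedel


def generate_unique_reflections(cell: UnitCell, spacegroup: SpaceGroupSpec,
                                d_min: float,
                                low_res_cutoff: float | None = None) -> np.ndarray:
    """All symmetry-unique, non-absent Miller indices with d >= d_min."""
    s_max = 1.0 / d_min
    hmax = [int(math.floor(L * s_max)) + 1 for L in (cell.a, cell.b, cell.c)]
    h, k, l = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = cell.s(hkl)
    hkl = hkl[s <= s_max + 1e-12]
    reps, _, _ = canonical_representatives(hkl, spacegroup)
    uniq = np.unique(reps, axis=0)
    keep = []
    for row in uniq:
        _, absent = spacegroup.epsilon_and_absent(row)
        if not absent:
            keep.append(row)
    return np.array(keep, int).reshape(-1, 3)


def read_reflections(path, cell: UnitCell, spacegroup: SpaceGroupSpec,
                     low_res_cutoff: float = 25.0) -> ReflectionData:
    """Read the text HKL dialect: 'h k l F [sigF]', '#' comments.

    Reflections are reduced to the canonical unique set; duplicates after
    reduction raise an error naming the indices.  Records with resolution
    lower than ``low_res_cutoff`` (A) are retained but flagged missing.
    """
    rows = []
    warned_extra = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"line {ln}: expected 'h k l F [sigF]'")
        if len(parts) > 5 and not warned_extra:
            warnings.warn("extra columns in HKL file ignored")
            warned_extra = True
        h, k, l = (int(x) for x in parts[:3])
        f = float(parts[3])
        sig = float(parts[4]) if len(parts) >= 5 else np.nan
        if f < 0:
            raise ValueError(f"line {ln}: negative amplitude for ({h},{k},{l})")
        rows.append((h, k, l, f, sig))
    if not rows:
        raise ValueError(f"no reflections found in {path}")
    hkl = np.array([r[:3] for r in rows], int)
    f = np.array([r[3] for r in rows])
    sig = np.array([r[4] for r in rows])
    reps, _, _ = canonical_representatives(hkl, spacegroup)
    uniq, first, counts = np.unique(reps, axis=0, return_index=True,
                                    return_counts=True)
    if np.any(counts > 1):
        bad = uniq[counts > 1][0]
        raise ValueError(
            f"duplicate observations reduce to the same unique reflection "
            f"{tuple(int(x) for x in bad)}")
    order = np.argsort(first)
    uniq, first = uniq[order], first[order]
    s = cell.s(uniq)
    missing = s < (1.0 / low_res_cutoff)
    return ReflectionData(uniq, f[first], sig[first], missing, cell, spacegroup,
                          low_res_cutoff=low_res_cutoff)


def write_reflections(refl: ReflectionData, path, phases: np.ndarray | None = None,
                      weights: np.ndarray | None = None, header: str = ""):
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    for i in range(len(refl)):
        h, k, l = refl.hkl[i]
        row = f"{h:5d} {k:5d} {l:5d} {refl.f_obs[i]:14.6g}"
        if phases is not None:
            row += f" {phases[i]:10.4f}"
        if weights is not None:
            row += f" {weights[i]:8.5f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Phase sets and envelopes
# --------------------------------------------------------------------------

class PhaseSet:
    """Per-reflection phases (degrees, [0, 360)) with apodization weights."""

    def __init__(self, refl: ReflectionData, phase_deg: np.ndarray,
                 weight: np.ndarray | None = None):
        self.refl = refl
        self.phase_deg = np.mod(np.asarray(phase_deg, float), 360.0)
        if weight is None:
            weight = np.ones(len(refl))
        self.weight = np.asarray(weight, float)
        if len(self.phase_deg) != len(refl) or len(self.weight) != len(refl):
            raise ValueError("phase/weight length mismatch with reflection set")

    def __len__(self):
        return len(self.refl)

    def copy(self) -> "PhaseSet":
        return PhaseSet(self.refl, self.phase_deg.copy(), self.weight.copy())


class BinaryEnvelope:
    """Boolean protein/solvent partition (True = protein)."""

    def __init__(self, mask: np.ndarray, solvent_fraction: float,
                 cell: UnitCell | None = None,
                 spacegroup: SpaceGroupSpec | None = None):
        self.mask = np.asarray(mask, bool)
        if not 0.0 < solvent_fraction < 1.0:
            raise ValueError("solvent fraction must lie in (0, 1)")
        self.solvent_fraction = float(solvent_fraction)
        self.cell = cell
        self.spacegroup = spacegroup

    @property
    def realized_solvent_fraction(self) -> float:
        return 1.0 - self.mask.mean()

    @property
    def protein_count(self) -> int:
        return int(self.mask.sum())

    def resampled(self, shape, target_fraction: float | None = None) -> "BinaryEnvelope":
        """Trilinear resample of the mask onto a new grid, re-thresholded."""
        frac = self.solvent_fraction if target_fraction is None else target_fraction
        src = self.mask.astype(float)
        out_shape = tuple(shape)
        coords = np.meshgrid(*[
            np.arange(n_new) * (n_old / n_new)
            for n_new, n_old in zip(out_shape, src.shape)], indexing="ij")
        from scipy.ndimage import map_coordinates
        dense = map_coordinates(src, np.array([c.ravel() for c in coords]),
                                order=1, mode="grid-wrap").reshape(out_shape)
        n_protein = int(round((1.0 - frac) * dense.size))
        order = np.argsort(-dense.ravel(), kind="stable")
        mask = np.zeros(dense.size, bool)
        mask[order[:n_protein]] = True
        return BinaryEnvelope(mask.reshape(out_shape), frac, self.cell,
                              self.spacegroup)


# --------------------------------------------------------------------------
# CCP4/MRC map I/O (gemmi)
# --------------------------------------------------------------------------

def write_map(map_: DensityMap, path):
    """Write a CCP4/MRC map, mode 2, full cell, cell in the header."""
    g = gemmi.FloatGrid(*map_.grid.shape)
    g.set_unit_cell(map_.cell.to_gemmi())
    g.spacegroup = gemmi.SpaceGroup("P1")  # values cover the full cell
    arr = np.array(g, copy=False)
    arr[...] = map_.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header(2)
    m.write_ccp4_map(str(path))


def read_map(path, spacegroup: SpaceGroupSpec | None = None) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    c = m.grid.unit_cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    values = np.array(m.grid, copy=True).astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("map file does not cover the full unit cell")
    return DensityMap(values, cell, spacegroup)


def write_envelope(env: BinaryEnvelope, path):
    cell = env.cell or UnitCell(1, 1, 1)
    write_map(DensityMap(env.mask.astype(float), cell, env.spacegroup), path)
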