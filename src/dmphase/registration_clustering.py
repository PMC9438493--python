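"""Origin/inversion registration, pairwise distances, DB-SCAN clustering and
consensus envelope / phase-set construction.

Randomly initiated runs select the crystallographic origin (and, in groups
without enantiomorphic character, the hand) arbitrarily, so envelopes and
phase sets must be brought onto a common origin before comparison.  The
allowed origin shifts come from the space-group description; registration
scores every allowed shift (via FFT cross-correlation when an origin
direction is continuous) and the inversion alternative when the group
permits it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft
from scipy import ndimage
from sklearn.cluster import DBSCAN as _SKDBSCAN

from .crystal_core import (
    BinaryEnvelope,
    DensityMap,
    PhaseSet,
    SpaceGroupSpec,
    _good_fft_size,
    symmetry_permutations,
)

_EXACT_SCORE_BUDGET = 1_000_000  # candidate x reflection products before
                                 # falling back to FFT preselection


def wrap_abs_deg(delta) -> np.ndarray:
    """Wrapped absolute phase difference in degrees, in [0, 180]."""
    return np.abs((np.asarray(delta, float) + 180.0) % 360.0 - 180.0)


# --------------------------------------------------------------------------
# Allowed origin shifts on a grid
# --------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _allowed_shift_mask_cached(shape: tuple, key: tuple) -> np.ndarray:
    continuous, shifts = key
    n = np.array(shape)
    mask = np.zeros(shape, bool)
    for d in shifts:
        idx = np.asarray(d) * n
        ridx = np.round(idx).astype(int)
        if not np.allclose(idx, ridx, atol=1e-6):
            continue  # shift not representable on this grid
        axes = []
        for ax in range(3):
            axes.append(np.arange(n[ax]) if continuous[ax]
                        else np.array([ridx[ax] % n[ax]]))
        mask[np.ix_(*axes)] = True
    if not mask.any():
        raise ValueError("no allowed origin shift is representable on this grid")
    return mask


def allowed_shift_mask(shape, spacegroup: SpaceGroupSpec) -> np.ndarray:
    key = (tuple(spacegroup.continuous_origin_axes),
           tuple(tuple(s) for s in spacegroup.allowed_origin_shifts))
    return _allowed_shift_mask_cached(tuple(shape), key)


def cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """C(t) = sum_x a(x + t) b(x) over the periodic grid, via FFT."""
    return np.real(scipy.fft.ifftn(scipy.fft.fftn(a) * np.conj(scipy.fft.fftn(b))))


def invert_grid(arr: np.ndarray) -> np.ndarray:
    """arr(-x) on the periodic grid."""
    return np.roll(arr[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))


def apply_shift(arr: np.ndarray, shift_idx) -> np.ndarray:
    """Shift by +t (grid units): out(x) = arr(x - t)."""
    return np.roll(arr, tuple(int(s) for s in shift_idx), axis=(0, 1, 2))


# --------------------------------------------------------------------------
# Registration result
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Registration:
    """Origin shift (fractional) and inversion flag aligning b onto a."""

    shift: tuple
    inverted: bool
    score: float

    def shift_idx(self, shape) -> np.ndarray:
        return np.round(np.asarray(self.shift) * np.asarray(shape)).astype(int)


# --------------------------------------------------------------------------
# Envelope registration and correlation
# --------------------------------------------------------------------------

def envelope_cc(e1: BinaryEnvelope, e2: BinaryEnvelope) -> float:
    """Matthews/phi correlation between two binary envelopes (no shift)."""
    a, b = e1.mask, e2.mask
    if a.shape != b.shape:
        raise ValueError("envelopes on different grids")
    n = a.size
    m11 = float(np.sum(a & b))
    sa, sb = float(a.sum()), float(b.sum())
    return _phi_from_counts(m11, sa, sb, n)


def _phi_from_counts(m11, sa, sb, n):
    denom = sa * (n - sa) * sb * (n - sb)
    if denom <= 0:
        raise ValueError("single-class envelope: correlation undefined")
    return float((n * m11 - sa * sb) / np.sqrt(denom))


def _envelope_cc_all_shifts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.size
    sa, sb = float(a.sum()), float(b.sum())
    denom = sa * (n - sa) * sb * (n - sb)
    if denom <= 0:
        raise ValueError("single-class envelope: correlation undefined")
    m11 = cross_correlation(a.astype(float), b.astype(float))
    return (n * m11 - sa * sb) / np.sqrt(denom)


def _best_envelope_registration(e1, e2, spacegroup):
    allowed = allowed_shift_mask(e1.mask.shape, spacegroup)
    options = [False] + ([True] if spacegroup.inversion_ambiguous else [])
    best = None
    shape = np.array(e1.mask.shape)
    for inv in options:
        b = invert_grid(e2.mask) if inv else e2.mask
        cc = _envelope_cc_all_shifts(e1.mask, b)
        cc_masked = np.where(allowed, cc, -np.inf)
        flat = int(np.argmax(cc_masked))
        t = np.array(np.unravel_index(flat, e1.mask.shape))
        score = float(cc_masked.ravel()[flat])
        if best is None or score > best.score + 1e-12:
            best = Registration(tuple(t / shape), inv, score)
    return best


# --------------------------------------------------------------------------
# Phase-set registration
# --------------------------------------------------------------------------

def _default_registration_grid(refl) -> tuple:
    shape = []
    hmax = np.max(np.abs(refl.hkl), axis=0)
    for ax in range(3):
        mult = 1
        for op in refl.spacegroup.operators:
            from fractions import Fraction
            mult = np.lcm(mult, Fraction(op.t[ax]).limit_denominator(24).denominator)
        for d in refl.spacegroup.allowed_origin_shifts:
            mult = np.lcm(mult, Fraction(d[ax]).limit_denominator(24).denominator)
        # oversample so continuous origin shifts are finely sampled
        shape.append(_good_fft_size(int(4 * hmax[ax] + 4), int(mult)))
    return tuple(shape)


def _common_reflections(p1: PhaseSet, p2: PhaseSet):
    if p1.refl is p2.refl:
        idx = np.arange(len(p1))
        return idx, idx
    lookup = {tuple(h): i for i, h in enumerate(map(tuple, p2.refl.hkl))}
    i1, i2 = [], []
    for i, h in enumerate(map(tuple, p1.refl.hkl)):
        j = lookup.get(h)
        if j is not None:
            i1.append(i)
            i2.append(j)
    if not i1:
        raise ValueError("phase sets share no reflections")
    return np.array(i1), np.array(i2)


def _synthesize_for_registration(p: PhaseSet, shape) -> np.ndarray:
    refl = p.refl
    n = np.array(shape)
    G = np.zeros(shape, complex)
    idx = tuple(refl.hkl.T % n[:, None])
    amps = np.where(refl.observed, refl.f_obs, 0.0) * p.weight
    G[idx] = amps * np.exp(1j * np.deg2rad(p.phase_deg))
    v = np.real(scipy.fft.fftn(G)) / G.size
    perms = symmetry_permutations(shape, refl.spacegroup)
    if len(perms) > 1:
        flat = v.ravel()
        acc = np.zeros_like(flat)
        for perm in perms:
            acc += flat[perm]
        v = (acc / len(perms)).reshape(shape)
    return v


def _phase_score_exact(dphi0, hkl, taus_frac, weights):
    """Weighted mean |wrapped(dphi0 - 360 h.tau)| for each candidate tau."""
    shift_deg = 360.0 * (hkl @ taus_frac.T)           # (n_refl, n_cand)
    d = wrap_abs_deg(dphi0[:, None] - shift_deg)
    wsum = weights.sum()
    return (weights[:, None] * d).sum(axis=0) / wsum


def _best_phase_registration(p1, p2, spacegroup, grid_shape=None, weights=None):
    i1, i2 = _common_reflections(p1, p2)
    hkl = p1.refl.hkl[i1]
    obs = p1.refl.observed[i1] & p2.refl.observed[i2]
    hkl = hkl[obs]
    ph1 = p1.phase_deg[i1][obs]
    ph2 = p2.phase_deg[i2][obs]
    if weights is None:
        w = np.ones(len(hkl))
    else:
        w = np.asarray(weights, float)[i1][obs]
    if grid_shape is None:
        grid_shape = _default_registration_grid(p1.refl)
    shape = np.array(grid_shape)
    allowed = allowed_shift_mask(grid_shape, spacegroup)
    cand_idx = np.array(np.nonzero(allowed)).T          # (n_cand, 3)
    options = [False] + ([True] if spacegroup.inversion_ambiguous else [])
    preselect = len(cand_idx) * len(hkl) > _EXACT_SCORE_BUDGET
    if preselect:
        m1 = _synthesize_for_registration(p1, grid_shape)
    best = None
    for inv in options:
        ph2i = -ph2 if inv else ph2
        dphi0 = ph1 - ph2i
        if preselect:
            p2inv = PhaseSet(p2.refl, -p2.phase_deg, p2.weight) if inv else p2
            m2 = _synthesize_for_registration(p2inv, grid_shape)
            corr = np.where(allowed, cross_correlation(m1, m2), -np.inf)
            k = min(64, int(allowed.sum()))
            top = np.argpartition(-corr.ravel(), k - 1)[:k]
            top = top[np.argsort(top)]  # deterministic candidate order
            cands = np.array(np.unravel_index(top, grid_shape)).T
        else:
            cands = cand_idx
        taus = cands / shape
        scores = _phase_score_exact(dphi0, hkl, taus, w)
        j = int(np.argmin(scores))
        score = float(scores[j])
        if best is None or score < best[0] - 1e-12:
            best = (score, tuple(taus[j]), inv)
    return Registration(best[1], best[2], best[0])


def best_registration(a, b, spacegroup: SpaceGroupSpec,
                      mode: str = "envelope", grid_shape=None) -> Registration:
    """Best allowed origin shift (and inversion) aligning b onto a.

    Envelope mode maximizes the binary correlation coefficient; phase mode
    minimizes the mean absolute phase difference.  Ties are broken toward
    the lexicographically smallest shift and the non-inverted alternative.
    """
    if mode == "envelope":
        if a.mask.shape != b.mask.shape:
            raise ValueError("incompatible grids")
        return _best_envelope_registration(a, b, spacegroup)
    if mode == "phase":
        return _best_phase_registration(a, b, spacegroup, grid_shape)
    raise ValueError("mode must be 'envelope' or 'phase'")


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def envelope_distance(e1: BinaryEnvelope, e2: BinaryEnvelope,
                      spacegroup: SpaceGroupSpec) -> float:
    """d = sqrt(1 - CC^2) with CC from the best registration."""
    reg = _best_envelope_registration(e1, e2, spacegroup)
    cc = min(1.0, abs(reg.score))
    return float(np.sqrt(max(0.0, 1.0 - cc * cc)))


def phase_distance(p1: PhaseSet, p2: PhaseSet, spacegroup: SpaceGroupSpec,
                   grid_shape=None) -> float:
    """Mean absolute phase difference (degrees) after best registration."""
    reg = _best_phase_registration(p1, p2, spacegroup, grid_shape)
    return float(reg.score)


def weighted_mean_abs_phase_diff(p: PhaseSet, model: PhaseSet,
                                 spacegroup: SpaceGroupSpec | None = None,
                                 register: bool = True,
                                 grid_shape=None) -> float:
    """Apodization-weighted mean absolute phase difference (degrees)."""
    if register:
        if spacegroup is None:
            spacegroup = p.refl.spacegroup
        reg = _best_phase_registration(p, model, spacegroup, grid_shape,
                                       weights=p.weight)
        return float(reg.score)
    i1, i2 = _common_reflections(p, model)
    obs = p.refl.observed[i1] & model.refl.observed[i2]
    d = wrap_abs_deg(p.phase_deg[i1][obs] - model.phase_deg[i2][obs])
    w = p.weight[i1][obs]
    return float((w * d).sum() / w.sum())


def pairwise_envelope_distances(envelopes, spacegroup):
    n = len(envelopes)
    d = np.zeros((n, n))
    regs = {}
    for i in range(n):
        for j in range(i + 1, n):
            reg = _best_envelope_registration(envelopes[i], envelopes[j],
                                              spacegroup)
            cc = min(1.0, abs(reg.score))
            d[i, j] = d[j, i] = np.sqrt(max(0.0, 1.0 - cc * cc))
            regs[(i, j)] = reg
    return d, regs


def pairwise_phase_distances(phase_sets, spacegroup, grid_shape=None):
    n = len(phase_sets)
    d = np.zeros((n, n))
    regs = {}
    for i in range(n):
        for j in range(i + 1, n):
            reg = _best_phase_registration(phase_sets[i], phase_sets[j],
                                           spacegroup, grid_shape)
            d[i, j] = d[j, i] = reg.score
            regs[(i, j)] = reg
    return d, regs


# --------------------------------------------------------------------------
# DB-SCAN
# --------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Density-based clustering result on a precomputed distance matrix."""

    labels: np.ndarray
    min_points: int
    eps: float

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]

    def clusters(self) -> list[np.ndarray]:
        return [self.members(k) for k in range(self.n_clusters)]


def dbscan(distances: np.ndarray, min_points: int, eps: float) -> ClusterSet:
    """DB-SCAN on a precomputed, symmetric, zero-diagonal distance matrix.

    Core points are order-independent; border points are assigned to the
    first cluster that reaches them (scikit-learn's rule), which is
    deterministic for a fixed input order.
    """
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(~np.isfinite(d)):
        raise ValueError("NaN/inf distances")
    model = _SKDBSCAN(eps=eps, min_samples=min_points, metric="precomputed")
    labels = model.fit_predict(d)
    return ClusterSet(labels, min_points, eps)


def choose_eps_envelopes(distances: np.ndarray, percentile: float = 4.0) -> float:
    """Clustering radius for envelopes: percentile of the unique distances."""
    d = np.asarray(distances, float)
    iu = np.triu_indices(d.shape[0], k=1)
    return float(np.percentile(d[iu], percentile))


# --------------------------------------------------------------------------
# Consensus construction
# --------------------------------------------------------------------------

def _periodic_label(mask: np.ndarray):
    """Connected components of a boolean grid with periodic wrap-around."""
    labels, n = ndimage.label(mask)
    if n <= 1:
        return labels, n
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for ax in range(3):
        lo = np.take(labels, 0, axis=ax).ravel()
        hi = np.take(labels, -1, axis=ax).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(int(a), int(b))
    remap = np.array([find(i) for i in range(n + 1)])
    labels = remap[labels]
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(uniq, start=1):
        out[labels == old] = new
    return out, len(uniq)


def edit_connectivity(mask: np.ndarray,
                      min_component_fraction: float = 0.01) -> np.ndarray:
    """Erase small protein islands and fill small solvent voids."""
    mask = mask.copy()
    threshold = max(1, int(round(min_component_fraction * mask.sum())))
    labels, n = _periodic_label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        for comp, size in enumerate(sizes, start=1):
            if size < threshold:
                mask[labels == comp] = False
    labels, n = _periodic_label(~mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for comp, size in enumerate(sizes, start=1):
            if comp != keep and size < threshold:
                mask[labels == comp] = True
    return mask


def consensus_envelope(members, spacegroup: SpaceGroupSpec,
                       target_fraction: float | None = None,
                       min_component_fraction: float = 0.01,
                       connectivity_edit: bool = True) -> BinaryEnvelope:
    """Per-voxel majority vote over registered cluster members.

    Members are brought onto the origin (and hand) of the first member;
    exact vote ties go to protein.  Small disconnected protein islands are
    erased and small enclosed solvent voids filled afterwards.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members for a consensus")
    ref = members[0]
    shape = ref.mask.shape
    votes = ref.mask.astype(int).copy()
    for m in members[1:]:
        if m.mask.shape != shape:
            raise ValueError("members on different grids")
        reg = _best_envelope_registration(ref, m, spacegroup)
        b = invert_grid(m.mask) if reg.inverted else m.mask
        votes += apply_shift(b, reg.shift_idx(shape)).astype(int)
    mask = votes * 2 >= len(members)  # ties -> protein
    if connectivity_edit:
        mask = edit_connectivity(mask, min_component_fraction)
    frac = target_fraction if target_fraction is not None else ref.solvent_fraction
    return BinaryEnvelope(mask, frac, ref.cell, ref.spacegroup)


def consensus_phases(members, spacegroup: SpaceGroupSpec, grid_shape=None,
                     resultant_tolerance: float = 1e-9):
    """Circular-mean phases over registered cluster members.

    Returns (consensus PhaseSet, sample circular variance, defined mask).
    The circular variance is 1 minus the mean resultant length, averaged
    over reflections; reflections with a vanishing resultant have no
    defined mean phase and are flagged out in the mask.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members for a consensus")
    ref = members[0]
    hkl = ref.refl.hkl
    z = np.exp(1j * np.deg2rad(ref.phase_deg)).astype(complex)
    for m in members[1:]:
        reg = _best_phase_registration(ref, m, spacegroup, grid_shape)
        ph = -m.phase_deg if reg.inverted else m.phase_deg
        ph = ph + 360.0 * (hkl @ np.asarray(reg.shift))
        z += np.exp(1j * np.deg2rad(ph))
    z /= len(members)
    resultant = np.abs(z)
    defined = resultant > resultant_tolerance
    phases = np.where(defined, np.mod(np.angle(z, deg=True), 360.0), 0.0)
    obs = ref.refl.observed
    circ_var = float(1.0 - resultant[obs & defined].mean()) if (obs & defined).any() else 1.0
    return PhaseSet(ref.refl, phases, ref.weight.copy()), circ_var, defined


class GroundTruthComparator:
    """Per-iteration agreement metrics against a known solution.

    ``ground_truth`` carries 'phases' (PhaseSet), 'envelope' (BinaryEnvelope)
    and optionally 'density' (DensityMap, used to preselect origin shifts
    through the phased translation function).
    """

    def __init__(self, projector, ground_truth: dict):
        self.projector = projector
        self.sg = projector.refl.spacegroup
        self.truth_phases = ground_truth.get("phases")
        self.truth_env = ground_truth.get("envelope")
        self.shape = projector.shape

    def evaluate(self, est_values: np.ndarray, envelope, apod) -> dict:
        out = {}
        if self.truth_phases is not None:
            ph = self.projector.phases(est_values)
            p = PhaseSet(self.projector.refl, ph, self.projector.weights(apod))
            out["phase_error_deg"] = weighted_mean_abs_phase_diff(
                p, self.truth_phases, self.sg, grid_shape=self.shape)
        if self.truth_env is not None and envelope is not None:
            if self.truth_env.mask.shape == envelope.mask.shape:
                reg = _best_envelope_registration(self.truth_env, envelope,
                                                  self.sg)
                out["envelope_cc"] = reg.score
        return out
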