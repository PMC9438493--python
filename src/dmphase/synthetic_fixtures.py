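"""Ground-truth toy crystals and simulated diffraction data.

A toy crystal is a compact, connected cluster of Gaussian pseudo-atoms in a
small unit cell, constructed so that the statistical structure the phasing
method relies on is present: Wilson-behaved intensities with an overall B
factor, a generic unimodal protein density histogram, and a featureless
solvent region occupying a stated volume fraction.  The ground-truth map,
envelope and phases are retained so every stage of the pipeline can be
scored against the known answer.

All densities follow the package's mean-zero convention: F(000) is removed
from the true map, mirroring its treatment as missing data during phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .crystal_core import (
    BinaryEnvelope,
    symmetry_permutations,
    DensityMap,
    GridSpec,
    PhaseSet,
    ReflectionData,
    SpaceGroupSpec,
    UnitCell,
    generate_unique_reflections,
    get_spacegroup,
)
from .fourier_space import Apodization
from .real_space import ReferenceHistogram

BOND_STEP = 3.8  # A, consecutive pseudo-atom spacing (Calpha-like)
ATOM_VOLUME = 10.0  # A^3 of protein volume per pseudo-atom


@dataclass
class ToyCrystal:
    """Synthetic crystal with full ground truth."""

    cell: UnitCell
    spacegroup: SpaceGroupSpec
    atoms_frac: np.ndarray          # asymmetric-unit pseudo-atom positions
    atom_weight: float
    b_factor: float
    resolution: float
    density: DensityMap             # true (mean-zero) density
    envelope: BinaryEnvelope        # true envelope at the stated fraction
    phases: PhaseSet                # true phases on the unique set
    refl: ReflectionData            # amplitudes (optionally noisy)
    solvent_fraction: float
    noise_frac: float
    seed: int | None

    @property
    def realized_solvent_fraction(self) -> float:
        return self.envelope.realized_solvent_fraction

    def ground_truth(self) -> dict:
        return {"phases": self.phases, "envelope": self.envelope,
                "density": self.density}


def _random_globule(rng, n_atoms: int, cell, protein_volume: float,
                    center_frac=(0.3, 0.3, 0.3),
                    periphery_fraction: float = 0.25,
                    periphery_weight: float = 0.35,
                    periphery_extent: float = 1.35):
    """Connected random-walk cluster confined to a ball, with a
    low-occupancy periphery (fractional coordinates and atom weights).

    The periphery emulates disordered loops and termini: a quarter of the
    atoms carry reduced weight and may wander beyond the core radius, so
    the protein region's density histogram has the low-density shoulder
    real molecular envelopes contain.
    """
    M = cell.orthogonalization_matrix()
    radius = 0.95 * (3.0 * protein_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    if 2.0 * radius >= min(cell.a, cell.b, cell.c):
        raise ValueError("requested protein fraction not achievable: the "
                         "molecule would span the whole cell")
    center = M @ np.asarray(center_frac, float)
    n_core = max(1, int(round((1.0 - periphery_fraction) * n_atoms)))
    pts = np.empty((n_atoms, 3))
    weights = np.ones(n_atoms)
    pts[0] = center
    for i in range(1, n_atoms):
        rmax = radius if i < n_core else periphery_extent * radius
        if i >= n_core:
            weights[i] = periphery_weight
        for _ in range(200):
            step = rng.normal(size=3)
            step *= BOND_STEP / np.linalg.norm(step)
            cand = pts[i - 1] + step
            if np.linalg.norm(cand - center) <= rmax:
                pts[i] = cand
                break
        else:  # walk cornered: branch from a previously placed atom
            pts[i] = pts[rng.integers(0, i)]
    return np.linalg.solve(M, pts.T).T, weights


def _deposit_atoms(shape, frac_positions: np.ndarray, weights) -> np.ndarray:
    """Trilinear (cloud-in-cell) deposit of point weights on a periodic grid."""
    n = np.array(shape)
    grid = np.zeros(shape)
    pos = np.mod(frac_positions, 1.0) * n
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    w = np.broadcast_to(np.asarray(weights, float), (len(pos),))
    for du in (0, 1):
        for dv in (0, 1):
            for dw in (0, 1):
                idx = (i0 + [du, dv, dw]) % n
                coef = (np.where(du, frac[:, 0], 1 - frac[:, 0]) *
                        np.where(dv, frac[:, 1], 1 - frac[:, 1]) *
                        np.where(dw, frac[:, 2], 1 - frac[:, 2]))
                np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), w * coef)
    return grid


def generate_toy_crystal(cell: UnitCell | None = None,
                         spacegroup: SpaceGroupSpec | str = "P1",
                         n_atoms: int | None = None,
                         solvent_fraction: float = 0.80,
                         b_factor: float = 20.0,
                         resolution: float = 3.0,
                         noise_frac: float = 0.02,
                         seed: int | None = 0,
                         low_res_cutoff: float = 25.0,
                         grid_spacing_factor: float = 0.4,
                         envelope_smoothing_radius: float = 4.0) -> ToyCrystal:
    """Build a seeded toy crystal with known density, envelope and phases.

    Pseudo-atoms form a connected random-walk cluster confined to a ball
    whose volume matches the requested protein fraction, are smeared with
    the overall B factor, and band-limited at the stated resolution.
    Amplitudes receive multiplicative Gaussian noise of relative size
    ``noise_frac`` (floored at zero), with sigmas emitted consistently.
    """
    if cell is None:
        cell = UnitCell(24.0, 24.0, 24.0)
    if isinstance(spacegroup, str):
        spacegroup = get_spacegroup(spacegroup)
    rng = np.random.default_rng(seed)
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent fraction must lie in (0, 1)")
    v_protein = (1.0 - solvent_fraction) * cell.volume
    v_asu = v_protein / len(spacegroup.operators)
    if n_atoms is None:
        n_atoms = max(0, int(round(v_asu / ATOM_VOLUME)))
    grid = GridSpec.from_spacing(cell, grid_spacing_factor * resolution,
                                 spacegroup)
    shape = grid.shape
    n = np.array(shape)

    if n_atoms > 0:
        frac, atom_w = _random_globule(rng, n_atoms, cell, v_asu)
        # symmetry-expand the asymmetric unit
        all_frac = np.concatenate([
            (op.R @ frac.T).T + op.t for op in spacegroup.operators])
        all_w = np.tile(atom_w, len(spacegroup.operators))
        deposit = _deposit_atoms(shape, all_frac, all_w)
    else:
        deposit = np.zeros(shape)

    G = scipy.fft.ifftn(deposit) * deposit.size
    # deconvolve the trilinear deposit's transfer function so the
    # amplitude falloff is the pure Debye-Waller Gaussian
    cic = 1.0
    for ax, m in enumerate(shape):
        f = np.fft.fftfreq(m)
        w = np.sinc(f) ** 2
        sh = [1, 1, 1]
        sh[ax] = m
        cic = cic * w.reshape(sh)
    G /= cic
    hs = [np.fft.fftfreq(m, d=1.0 / m).astype(int) for m in shape]
    hg, kg, lg = np.meshgrid(*hs, indexing="ij")
    s = cell.s(np.stack([hg, kg, lg], axis=-1))
    s_max = 1.0 / resolution
    G *= np.exp(-b_factor * s * s / 4.0)
    G[s > s_max] = 0.0
    G.flat[0] = 0.0  # mean-zero convention
    density = DensityMap(np.ascontiguousarray(
        np.real(scipy.fft.fftn(G)) / G.size), cell, spacegroup).symmetrized()
    G = scipy.fft.ifftn(density.values) * density.values.size

    # true envelope: molecular boundary, i.e. the smoothed density
    # thresholded at the requested fraction (a per-voxel ranking of the raw
    # density would make the boundary speckle-sharp, unlike a real molecule)
    if n_atoms > 0:
        from .real_space import TriweightKernel
        smooth = TriweightKernel(envelope_smoothing_radius, shape,
                                 cell).convolve(density.values)
        n_protein = int(round((1.0 - solvent_fraction) * grid.size))
        order = np.argsort(-smooth.ravel(), kind="stable")
        mask = np.zeros(grid.size, bool)
        mask[order[:n_protein]] = True
        perms = symmetry_permutations(shape, spacegroup)
        if len(perms) > 1:  # threshold must not split a symmetry orbit
            votes = np.zeros(grid.size)
            for perm in perms:
                votes += mask.astype(float)[perm]
            mask = votes / len(perms) >= 0.5
        envelope = BinaryEnvelope(mask.reshape(shape), solvent_fraction,
                                  cell, spacegroup)
        # make the solvent genuinely featureless: alternate exact solvent
        # flattening (fixed envelope) with band-limiting until the map is a
        # joint fixed point, so the stored amplitudes really do correspond
        # to a flat-solvent, band-limited density
        v = density.values
        solvent = ~envelope.mask
        band = s <= s_max
        band.flat[0] = False
        for _ in range(100):
            v = v.copy()
            v[solvent] = v[solvent].mean()
            Gv = scipy.fft.ifftn(v) * v.size
            Gv[~band] = 0.0
            v_new = np.real(scipy.fft.fftn(Gv)) / Gv.size
            if np.max(np.abs(v_new - v)) < 1e-10 * np.ptp(v_new):
                v = v_new
                break
            v = v_new
        density = DensityMap(np.ascontiguousarray(v), cell,
                             spacegroup).symmetrized()
        G = scipy.fft.ifftn(density.values) * density.values.size
    else:
        envelope = BinaryEnvelope(np.zeros(shape, bool), solvent_fraction,
                                  cell, spacegroup)

    hkl = generate_unique_reflections(cell, spacegroup, resolution)
    idx = tuple(hkl.T % n[:, None])
    coeffs = G[idx]
    amp_true = np.abs(coeffs)
    phase_true = np.mod(np.angle(coeffs, deg=True), 360.0)
    if noise_frac > 0:
        noisy = amp_true * np.maximum(0.0, 1.0 + noise_frac * rng.standard_normal(len(amp_true)))
    else:
        noisy = amp_true.copy()
    sigma = noise_frac * amp_true
    missing = cell.s(hkl) < (1.0 / low_res_cutoff)
    refl = ReflectionData(hkl, noisy, sigma, missing, cell, spacegroup,
                          low_res_cutoff=low_res_cutoff)
    phases = PhaseSet(refl, phase_true)
    return ToyCrystal(cell, spacegroup, frac if n_atoms else np.empty((0, 3)),
                      1.0, b_factor, resolution, density, envelope, phases,
                      refl, solvent_fraction, noise_frac, seed)


# --------------------------------------------------------------------------
# Reference histograms from synthetic reference structures
# --------------------------------------------------------------------------

def reference_histogram_from_toy(toy: ToyCrystal,
                                 apod: Apodization | None = None,
                                 low_res_cutoff: float | None = None,
                                 region: np.ndarray | None = None) -> ReferenceHistogram:
    """Histogram of the toy density over its protein region, with the
    reference transform treated equivalently to the working data: the same
    apodization and the same low-resolution cutoff (sub-cutoff terms and
    F000 removed) are applied before the histogram is taken."""
    if region is None:
        region = toy.envelope.mask
    if not region.any():
        raise ValueError("toy crystal has an empty protein region")
    apod = apod or Apodization(None)
    if low_res_cutoff is None:
        low_res_cutoff = toy.refl.low_res_cutoff
    v = toy.density.values
    G = scipy.fft.ifftn(v) * v.size
    shape = v.shape
    hs = [np.fft.fftfreq(m, d=1.0 / m).astype(int) for m in shape]
    hg, kg, lg = np.meshgrid(*hs, indexing="ij")
    s = toy.cell.s(np.stack([hg, kg, lg], axis=-1))
    G = G * apod.weight(s)
    if low_res_cutoff:
        G[s < 1.0 / low_res_cutoff] = 0.0
    G.flat[0] = 0.0
    smoothed = np.real(scipy.fft.fftn(G)) / G.size
    return ReferenceHistogram(smoothed[region], provenance={
        "b_factor": toy.b_factor, "resolution": toy.resolution,
        "sigma": apod.sigma, "low_res_cutoff": low_res_cutoff})


class SyntheticReferenceProvider:
    """Reference-histogram source built from a synthetic reference structure.

    Emulates selecting a reference structure matched in overall B factor and
    resolution: a fresh pseudo-atom structure is generated at the estimated
    B, and its protein-region histogram is recomputed under whatever
    apodization is in force (cached per sigma and grid).
    """

    def __init__(self, cell: UnitCell, spacegroup, solvent_fraction: float,
                 b_factor: float, resolution: float, seed: int = 7_654_321,
                 grid_spacing_factor: float = 0.4, calibrate: bool = True,
                 fraction_margin: float = 0.0):
        import warnings
        from .fourier_space import estimate_overall_B

        # The reference molecule is made slightly smaller than the stated
        # protein fraction implies (solvent-rich by ``fraction_margin``)
        # and its histogram is taken over the full stated fraction, so the
        # reference distribution carries the low-density boundary shoulder
        # a region selected at an uncertain (possibly underestimated)
        # solvent fraction will contain.
        self.region_fraction = solvent_fraction
        f_gen = min(solvent_fraction + fraction_margin, 0.93)

        def make(b_gen):
            return generate_toy_crystal(
                cell, spacegroup, solvent_fraction=f_gen,
                b_factor=b_gen, resolution=resolution, noise_frac=0.0,
                seed=seed, grid_spacing_factor=grid_spacing_factor)

        def fitted(toy):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return estimate_overall_B(toy.refl)[0]

        # match the reference by its *fitted* overall B, not the generator
        # parameter: the construction itself contributes to the apparent
        # falloff, so the generator B is calibrated by bisection
        target = max(b_factor, 0.0)
        if not calibrate:
            self.toy = make(target)
        else:
            lo, hi = 0.0, max(2.0 * target, 40.0)
            toy_lo = make(lo)
            if fitted(toy_lo) >= target:
                self.toy = toy_lo
            else:
                toy_hi = make(hi)
                while fitted(toy_hi) < target and hi < 8 * max(target, 40.0):
                    hi *= 2.0
                    toy_hi = make(hi)
                best = toy_hi
                for _ in range(6):
                    mid = 0.5 * (lo + hi)
                    toy_mid = make(mid)
                    f_mid = fitted(toy_mid)
                    if abs(f_mid - target) <= 0.05 * max(target, 1.0):
                        best = toy_mid
                        break
                    if f_mid < target:
                        lo = mid
                    else:
                        hi, best = mid, toy_mid
                self.toy = best
        self._cache: dict = {}

    def _region(self) -> np.ndarray:
        if not hasattr(self, "_region_mask"):
            from .real_space import TriweightKernel
            v = self.toy.density.values
            smooth = TriweightKernel(4.0, v.shape, self.toy.cell).convolve(v)
            n_protein = int(round((1.0 - self.region_fraction) * v.size))
            order = np.argsort(-smooth.ravel(), kind="stable")
            mask = np.zeros(v.size, bool)
            mask[order[:n_protein]] = True
            self._region_mask = mask.reshape(v.shape)
        return self._region_mask

    def __call__(self, sigma: float | None) -> ReferenceHistogram:
        if sigma not in self._cache:
            self._cache[sigma] = reference_histogram_from_toy(
                self.toy, Apodization(sigma), region=self._region())
        return self._cache[sigma]


# --------------------------------------------------------------------------
# Simulated Wilson amplitudes
# --------------------------------------------------------------------------

@dataclass
class SimulatedAmplitudes:
    """Wilson-distributed amplitude sample (duck-typed like ReflectionData
    for the estimators: exposes s, f_obs, epsilon, centric, observed)."""

    s: np.ndarray
    f_obs: np.ndarray
    epsilon: np.ndarray
    centric: np.ndarray
    sigma_true: float
    b_true: float

    @property
    def observed(self) -> np.ndarray:
        return np.ones(len(self.s), bool)

    @property
    def missing(self) -> np.ndarray:
        return ~self.observed

    def __len__(self):
        return len(self.s)


def simulate_wilson_amplitudes(n: int, Sigma: float, B: float,
                               centric_fraction: float = 0.0,
                               seed: int | None = 0,
                               s_range=(0.05, 0.5)) -> SimulatedAmplitudes:
    """Draw n amplitudes from Wilson statistics with an exponential B falloff.

    Acentric amplitudes are Rayleigh (intensity exponential with mean
    Sigma e^{-B s^2/2}), centric amplitudes half-normal with the same mean
    square; s is drawn uniformly in reciprocal-space volume.
    """
    rng = np.random.default_rng(seed)
    lo, hi = s_range
    s = (rng.uniform(lo ** 3, hi ** 3, n)) ** (1.0 / 3.0)
    mean_sq = Sigma * np.exp(-B * s * s / 2.0)
    cen = rng.uniform(size=n) < centric_fraction
    f = np.where(cen,
                 np.abs(rng.normal(0.0, np.sqrt(mean_sq))),
                 np.sqrt(rng.exponential(mean_sq)))
    return SimulatedAmplitudes(s, f, np.ones(n), cen, Sigma, B)
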