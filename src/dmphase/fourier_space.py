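"""Fourier-space machinery: apodization, the magnitude projection P_B,
the Wilson guard for unmeasured modes, amplitude agreement metrics, and
overall B-factor estimation.

The magnitude projection replaces the amplitude of every constrained Fourier
coefficient with the (apodized, scaled) observed amplitude while keeping the
calculated phase, which is the Euclidean-closest point on the amplitude
constraint set.  Unmeasured in-band modes evolve freely, subject to a cap
based on Wilson intensity statistics; modes beyond the resolution of the data
are constrained to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.optimize import brentq
from scipy.special import erfc, erfcinv

from .crystal_core import (
    DensityMap,
    ReflectionData,
    canonical_representatives,
    grid_miller_indices,
)

GUARD_TAIL_PROBABILITY = 5e-6


# --------------------------------------------------------------------------
# Apodization
# --------------------------------------------------------------------------

# half width at 1/100 of maximum height of a Gaussian, in units of sigma
WIDTH_1_100 = math.sqrt(2.0 * math.log(100.0))  # = 3.0349


@dataclass(frozen=True)
class Apodization:
    """Gaussian down-weighting of amplitudes, w(s) = exp(-s^2 / 2 sigma^2).

    ``sigma`` is the standard deviation in A^-1; ``sigma=None`` means no
    apodization (w = 1 everywhere).
    """

    sigma: float | None

    def __post_init__(self):
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("apodization sigma must be positive (or None)")

    def weight(self, s) -> np.ndarray | float:
        s = np.asarray(s, float)
        if self.sigma is None:
            out = np.ones_like(s)
        else:
            out = np.exp(-(s * s) / (2.0 * self.sigma ** 2))
        return float(out) if out.ndim == 0 else out

    @property
    def width_1_100(self) -> float | None:
        """Half width at 1/100 of maximum height (A^-1), = 3.03 sigma."""
        return None if self.sigma is None else WIDTH_1_100 * self.sigma

    @property
    def resolution_1_100(self) -> float | None:
        """Resolution (A) corresponding to the 1/100-height half width."""
        w = self.width_1_100
        return None if w is None else 1.0 / w

    def area(self, s_max: float) -> float:
        """Integral of w(s) over [0, s_max]."""
        if self.sigma is None:
            return s_max
        sig = self.sigma
        return sig * math.sqrt(math.pi / 2.0) * math.erf(s_max / (sig * math.sqrt(2)))

    def describe(self) -> str:
        if self.sigma is None:
            return "no apodization"
        return (f"sigma = {self.sigma:.4g} A^-1 "
                f"(1/100 height at {self.resolution_1_100:.3g} A)")


def apodization_weight(s: float, sigma: float) -> float:
    """Gaussian apodization weight at scattering magnitude s (A^-1)."""
    return float(Apodization(sigma).weight(s))


@dataclass(frozen=True)
class ApodizationSchedule:
    """Sequence of apodizations with strictly increasing sigma.

    Constructed so that the area under successive weight curves (integrated
    over the measured s-range) increases by equal increments, reaching the
    unapodized limit at the final step.
    """

    steps: tuple
    iterations_per_step: int = 1
    s_max: float = 0.0

    def __len__(self):
        return len(self.steps)

    def areas(self) -> np.ndarray:
        return np.array([a.area(self.s_max) for a in self.steps])


def build_schedule(sigma0: float, n_steps: int, s_max: float,
                   iterations_per_step: int = 1,
                   rtol: float = 1e-6) -> ApodizationSchedule:
    """Equal-area-increment schedule from sigma0 to the unapodized limit."""
    if not sigma0 > 0:
        raise ValueError("sigma0 must be positive")
    if n_steps < 2:
        raise ValueError("a schedule needs at least 2 steps")
    if not s_max > 0:
        raise ValueError("s_max must be positive")
    a0 = Apodization(sigma0).area(s_max)
    if a0 >= s_max * (1.0 - 1e-4):
        raise ValueError("sigma0 already gives the unapodized area")
    targets = np.linspace(a0, s_max, n_steps)
    steps = [Apodization(sigma0)]
    hi = sigma0
    for a_t in targets[1:-1]:
        # area(sigma) is monotone increasing in sigma
        while Apodization(hi).area(s_max) < a_t:
            hi *= 2.0
        sig = brentq(lambda x: Apodization(x).area(s_max) - a_t,
                     sigma0, hi, rtol=rtol)
        steps.append(Apodization(sig))
    steps.append(Apodization(None))
    return ApodizationSchedule(tuple(steps), iterations_per_step, s_max)


# --------------------------------------------------------------------------
# Wilson shell statistics and guard
# --------------------------------------------------------------------------

@dataclass
class ShellStatistics:
    """Equal-count resolution shells with Wilson normalization statistics."""

    edges: np.ndarray          # shell boundaries in s, length n_shells + 1
    mean_i_over_eps: np.ndarray
    mean_f: np.ndarray
    counts: np.ndarray
    centric_fraction: np.ndarray

    @staticmethod
    def from_amplitudes(s: np.ndarray, f: np.ndarray, epsilon: np.ndarray,
                        centric: np.ndarray, n_shells: int = 20,
                        min_per_shell: int = 50) -> "ShellStatistics":
        s = np.asarray(s, float)
        n = len(s)
        if n == 0:
            raise ValueError("no reflections for shell statistics")
        n_shells = max(1, min(n_shells, n // max(min_per_shell, 1) or 1))
        qs = np.linspace(0, 1, n_shells + 1)
        edges = np.quantile(s, qs)
        edges[0], edges[-1] = 0.0, edges[-1] + 1e-12
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_shells - 1)
        i_over_eps = (f * f) / epsilon
        mean_i = np.zeros(n_shells)
        mean_f = np.zeros(n_shells)
        counts = np.zeros(n_shells, int)
        cfrac = np.zeros(n_shells)
        for j in range(n_shells):
            sel = idx == j
            counts[j] = sel.sum()
            if counts[j]:
                mean_i[j] = i_over_eps[sel].mean()
                mean_f[j] = f[sel].mean()
                cfrac[j] = centric[sel].mean()
        return ShellStatistics(edges, mean_i, mean_f, counts, cfrac)

    @property
    def n_shells(self) -> int:
        return len(self.counts)

    def shell_index(self, s) -> np.ndarray:
        return np.clip(np.searchsorted(self.edges, np.asarray(s, float),
                                       side="right") - 1, 0, self.n_shells - 1)


def wilson_guard(f_calc, sigma_shell, centric, epsilon,
                 tail_probability: float = GUARD_TAIL_PROBABILITY):
    """Cap improbably large amplitudes under the Wilson distribution.

    ``sigma_shell`` is the shell mean intensity <I/eps> (Sigma).  Acentric
    amplitudes follow a Rayleigh distribution with mean square eps*Sigma,
    centric amplitudes a half-normal with the same mean square.  Amplitudes
    whose upper-tail probability is strictly below ``tail_probability`` are
    reset to the class expectation <F>; others pass through unchanged.
    """
    f = np.asarray(f_calc, float)
    sig = np.asarray(sigma_shell, float)
    if np.any(sig <= 0):
        raise ValueError("nonpositive shell mean intensity")
    cen = np.asarray(centric, bool)
    eps = np.asarray(epsilon, float)
    ms = eps * sig  # mean-square amplitude
    # upper-tail probabilities
    tail = np.where(cen,
                    erfc(np.sqrt(np.maximum(f * f, 0.0) / (2.0 * ms))),
                    np.exp(-(f * f) / ms))
    expected = np.where(cen,
                        np.sqrt(2.0 * ms / np.pi),
                        np.sqrt(np.pi * ms) / 2.0)
    out = np.where(tail < tail_probability, expected, f)
    if out.ndim == 0:
        return float(out)
    return out


def wilson_guard_threshold(sigma_shell, centric, epsilon,
                           tail_probability: float = GUARD_TAIL_PROBABILITY):
    """Amplitude at which the guard triggers, for the given class."""
    ms = np.asarray(epsilon, float) * np.asarray(sigma_shell, float)
    acent = np.sqrt(-ms * np.log(tail_probability))
    cent = np.sqrt(2.0 * ms) * erfcinv(tail_probability)
    return np.where(np.asarray(centric, bool), cent, acent)


# --------------------------------------------------------------------------
# Amplitude agreement
# --------------------------------------------------------------------------

def amplitude_agreement(f_obs, f_calc, weights=None):
    """(CC, R) between observed (apodized) and calculated amplitudes.

    CC is the Pearson correlation; R = sum |k f_calc - w f_obs| / sum(w f_obs)
    with k the least-squares scale from calculated onto observed.
    """
    f_obs = np.asarray(f_obs, float)
    f_calc = np.asarray(f_calc, float)
    w = np.ones_like(f_obs) if weights is None else np.asarray(weights, float)
    g = w * f_obs
    if len(g) < 2:
        raise ValueError("need at least 2 observed reflections")
    if np.std(g) == 0 or np.std(f_calc) == 0:
        cc = float("nan")
    else:
        cc = float(np.corrcoef(g, f_calc)[0, 1])
    denom = float(np.sum(f_calc * f_calc))
    k = float(np.sum(f_calc * g) / denom) if denom > 0 else 0.0
    r = float(np.sum(np.abs(k * f_calc - g)) / np.sum(g)) if np.sum(g) > 0 else float("nan")
    return cc, r


# --------------------------------------------------------------------------
# The magnitude projection P_B
# --------------------------------------------------------------------------

class FourierProjector:
    """Projection onto the measured-amplitude constraint set for a fixed
    reflection list and grid.

    Precomputes the mapping between the FFT coefficient grid and the
    symmetry-unique reflection list, the resolution shells used by the
    Wilson guard, and the apodization weights per sigma.
    """

    def __init__(self, refl: ReflectionData, grid_shape, *, guard: bool = True,
                 n_shells: int = 20, min_per_shell: int = 50):
        self.refl = refl
        self.shape = tuple(grid_shape)
        self.guard = guard
        self.n_shells = n_shells
        self.min_per_shell = min_per_shell
        self._weights_cache: dict = {}
        self._precompute()

    # -- geometry ----------------------------------------------------------

    def _precompute(self):
        refl, shape = self.refl, self.shape
        n = np.array(shape)
        if np.any(np.max(np.abs(refl.hkl), axis=0) * 2 >= n):
            raise ValueError("grid too coarse to index every reflection uniquely")
        # representative flat index per unique reflection
        self.rep_idx = np.ravel_multi_index((refl.hkl.T % n[:, None]), shape)
        # uid over the full grid via orbit expansion (Friedel included);
        # the expansion arrays also let a map be synthesized exactly from
        # coefficients on the unique set
        uid = np.full(shape, -1, np.int64).ravel()
        sg = refl.spacegroup
        exp_src, exp_dst, exp_phase, exp_conj = [], [], [], []
        for i, h in enumerate(refl.hkl):
            h_eq, turns = sg.reflection_orbit(h)
            for he, turn in zip(h_eq, turns):
                for hh, tt, cj in ((he, turn, False), (-he, -turn, True)):
                    flat = int(np.ravel_multi_index(tuple(hh % n), shape))
                    uid[flat] = i
                    exp_src.append(i)
                    exp_dst.append(flat)
                    exp_phase.append(np.exp(2j * np.pi * tt))
                    exp_conj.append(cj)
        self.uid_grid = uid
        self._exp_src = np.array(exp_src)
        self._exp_dst = np.array(exp_dst)
        self._exp_phase = np.array(exp_phase)
        self._exp_conj = np.array(exp_conj, bool)
        hg, kg, lg = grid_miller_indices(shape)
        s_grid = refl.cell.s(np.stack([hg, kg, lg], axis=-1)).ravel()
        self.s_grid = s_grid
        self.s_max = float(refl.s.max()) * (1.0 + 1e-9)
        in_band = s_grid <= self.s_max
        in_band[0] = True  # F000 handled explicitly
        self.obs_uid = np.where((uid >= 0) & refl.observed[np.clip(uid, 0, None)],
                                uid, -1)
        self.obs_mode = in_band & (self.obs_uid >= 0)
        self.free_mode = in_band & ~self.obs_mode  # guarded modes, incl. F000
        self.zero_mode = ~in_band
        # classification of guarded modes: map to unique reps once
        free_pos = np.nonzero(self.free_mode)[0]
        hkl_free = np.stack([hg.ravel()[free_pos], kg.ravel()[free_pos],
                             lg.ravel()[free_pos]], axis=1)
        eps = np.ones(len(free_pos))
        cen = np.zeros(len(free_pos), bool)
        nonzero = np.any(hkl_free != 0, axis=1)
        if nonzero.any():
            reps, _, _ = canonical_representatives(hkl_free[nonzero], sg)
            uniq, inv = np.unique(reps, axis=0, return_inverse=True)
            ue = np.ones(len(uniq))
            uc = np.zeros(len(uniq), bool)
            for j, row in enumerate(uniq):
                e, _ = sg.epsilon_and_absent(row)
                c, _ = sg.centric_flag_and_phase(row)
                ue[j], uc[j] = e, c
            eps[nonzero] = ue[inv]
            cen[nonzero] = uc[inv]
        cen[~nonzero] = True  # F000 is phase restricted
        self.free_pos = free_pos
        self.free_eps = eps
        self.free_cen = cen
        # shells defined by the observed reflections
        obs = refl.observed
        if obs.sum() == 0:
            raise ValueError("all reflections are missing")
        self._shell_src = (refl.s[obs], refl.epsilon[obs], refl.centric[obs])
        edges = ShellStatistics.from_amplitudes(
            refl.s[obs], refl.f_obs[obs], refl.epsilon[obs], refl.centric[obs],
            self.n_shells, self.min_per_shell).edges
        self._edges = edges
        nsh = len(edges) - 1
        self.shell_of_obs = np.clip(
            np.searchsorted(edges, refl.s[obs], side="right") - 1, 0, nsh - 1)
        self.shell_of_free = np.clip(
            np.searchsorted(edges, s_grid[free_pos], side="right") - 1, 0, nsh - 1)
        self.n_shell_bins = nsh
        self._obs_pos = np.nonzero(self.obs_mode)[0]
        self._obs_uid_at_pos = self.obs_uid[self._obs_pos]
        self._obs_sel = obs

    def weights(self, apod: Apodization) -> np.ndarray:
        """Apodization weights per unique reflection (cached per sigma)."""
        key = apod.sigma
        if key not in self._weights_cache:
            self._weights_cache[key] = apod.weight(self.refl.s)
        return self._weights_cache[key]

    # -- projection --------------------------------------------------------

    def project_values(self, values: np.ndarray, apod: Apodization):
        """Apply P_B to a value grid; returns (new_values, info dict)."""
        N = values.size
        G = scipy.fft.ifftn(values) * N
        Gf = G.ravel()
        absG = np.abs(Gf)
        refl = self.refl
        obs = self._obs_sel
        w = self.weights(apod)[obs]
        g = w * refl.f_obs[obs]
        f_calc = absG[self.rep_idx[obs]]
        denom = float(np.sum(g * g))
        if denom <= 0:
            raise ValueError("apodized observed amplitudes vanish")
        scale = float(np.sum(f_calc * g) / denom)  # observed -> calculated
        if scale <= 0:
            scale = 1.0
        target_u = np.zeros(len(refl))
        target_u[obs] = scale * g
        amp = np.zeros(N)
        amp[self._obs_pos] = target_u[self._obs_uid_at_pos]
        # guarded (missing / unconstrained) modes
        if len(self.free_pos):
            a = absG[self.free_pos]
            if self.guard:
                sig_shell = np.zeros(self.n_shell_bins)
                i_scaled = (scale * g) ** 2 / refl.epsilon[obs]
                np.add.at(sig_shell, self.shell_of_obs, i_scaled)
                cnt = np.bincount(self.shell_of_obs, minlength=self.n_shell_bins)
                sig_shell = sig_shell / np.maximum(cnt, 1)
                sig_shell[sig_shell <= 0] = sig_shell[sig_shell > 0].min()
                a = wilson_guard(a, sig_shell[self.shell_of_free],
                                 self.free_cen, self.free_eps)
            amp[self.free_pos] = a
        phase = np.where(absG > 1e-300, Gf / np.where(absG > 0, absG, 1.0), 1.0)
        G_new = (amp * phase).reshape(self.shape)
        out = np.real(scipy.fft.fftn(G_new)) / N
        if obs.sum() >= 2:
            cc, r = amplitude_agreement(refl.f_obs[obs], f_calc, w)
        else:
            cc, r = float("nan"), float("nan")
        return np.ascontiguousarray(out), {
            "cc": cc, "r": r, "scale": scale, "f_calc": f_calc}

    def project(self, map_: DensityMap, apod: Apodization) -> DensityMap:
        values, _ = self.project_values(map_.values, apod)
        return map_.with_values(values)

    def phases(self, values: np.ndarray) -> np.ndarray:
        """Phases (degrees in [0,360)) of a value grid at the unique set."""
        G = scipy.fft.ifftn(values) * values.size
        ph = np.angle(G.ravel()[self.rep_idx], deg=True)
        return np.mod(ph, 360.0)

    def synthesize(self, phases_deg: np.ndarray,
                   amplitudes: np.ndarray | None = None) -> DensityMap:
        """Map from phases (degrees) and amplitudes on the unique set,
        expanded over the full symmetry orbit (Friedel mates included)."""
        refl = self.refl
        if amplitudes is None:
            amplitudes = np.where(refl.observed, refl.f_obs, 0.0)
        z = amplitudes * np.exp(1j * np.deg2rad(phases_deg))
        zz = z[self._exp_src]
        zz[self._exp_conj] = np.conj(zz[self._exp_conj])
        src = zz * self._exp_phase
        G = np.zeros(int(np.prod(self.shape)), complex)
        G[self._exp_dst] = src
        v = np.real(scipy.fft.fftn(G.reshape(self.shape))) / G.size
        return DensityMap(np.ascontiguousarray(v), refl.cell, refl.spacegroup)


def project_fourier(map_: DensityMap, refl: ReflectionData,
                    apod: Apodization | None = None,
                    guard: bool = True) -> DensityMap:
    """One-shot magnitude projection (see :class:`FourierProjector`)."""
    proj = FourierProjector(refl, map_.grid.shape, guard=guard)
    return proj.project(map_, apod or Apodization(None))


# --------------------------------------------------------------------------
# Overall B factor
# --------------------------------------------------------------------------

def estimate_overall_B(refl, n_shells: int = 20, min_per_shell: int = 50,
                       d_max_fit: float = 4.5):
    """Overall isotropic B (A^2) from the slope of the Wilson plot.

    Fits ln<I/eps> per resolution shell against s^2/2 by weighted least
    squares (weights = shell counts); the slope is -B.  The fit uses only
    the atomic-scattering regime (d < ``d_max_fit``, default 4.5 A) because
    solvent contrast inflates the low-resolution intensities far above the
    Wilson trend; if fewer than 5 shells remain there, the range is widened.
    Returns (B, standard error).  A poor fit triggers a warning rather than
    failing silently.
    """
    obs = getattr(refl, "observed", None)
    if obs is None:
        obs = ~refl.missing
    s = refl.s[obs]
    f = refl.f_obs[obs]
    high = s >= 1.0 / d_max_fit
    if high.sum() >= 5 * min_per_shell:
        obs = obs.copy()
        obs[obs] = high
        s, f = s[high], f[high]
    eps = refl.epsilon[obs] if hasattr(refl, "epsilon") else np.ones_like(f)
    cen = refl.centric[obs] if hasattr(refl, "centric") else np.zeros_like(f, bool)
    stats = ShellStatistics.from_amplitudes(s, f, eps, cen, n_shells, min_per_shell)
    if stats.n_shells < 5:
        raise ValueError("need at least 5 resolution shells to estimate B")
    good = stats.mean_i_over_eps > 0
    x = ((stats.edges[:-1] ** 2 + stats.edges[1:] ** 2) / 2.0 / 2.0)[good]
    y = np.log(stats.mean_i_over_eps[good])
    w = stats.counts[good].astype(float)
    W = np.diag(w)
    A = np.stack([x, np.ones_like(x)], axis=1)
    cov = np.linalg.inv(A.T @ W @ A)
    beta = cov @ (A.T @ W @ y)
    resid = y - A @ beta
    dof = max(len(x) - 2, 1)
    sigma2 = float((resid * w * resid).sum() / w.sum() * len(x) / dof)
    stderr = math.sqrt(abs(cov[0, 0]) * sigma2)
    B = -float(beta[0])
    ss_tot = float(((y - np.average(y, weights=w)) ** 2 * w).sum())
    if ss_tot > 0:
        r2 = 1.0 - float((resid ** 2 * w).sum()) / ss_tot
        if r2 < 0.5:
            warnings.warn(f"Wilson plot fit is poor (R^2 = {r2:.2f}); "
                          "B estimate may be unreliable")
    return B, stderr
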