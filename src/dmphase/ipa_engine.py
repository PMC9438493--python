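"""Error Reduction and Difference Map update rules, and single-run execution.

The Difference Map update is

    x_{n+1} = x_n + beta * (P_A(f_B(x_n)) - P_B(f_A(x_n)))

with relaxed maps f_A(x) = (1 + gamma_A) P_A(x) - gamma_A x and
f_B(x) = (1 + gamma_B) P_B(x) - gamma_B x; the defaults gamma_A = -1/beta,
gamma_B = +1/beta are Elser's recommended choice.  The two arguments of the
update are the solution estimates: est_A = P_A(f_B(x)) satisfies the
real-space constraint exactly, est_B = P_B(f_A(x)) the Fourier-space
constraint; their RMS deviation (delta_DM) measures convergence.  Changing
the sign of beta (with the tied gamma defaults) swaps the roles of the two
projections.

Error Reduction is plain alternating projection, x <- P_A(P_B(x)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .crystal_core import BinaryEnvelope, DensityMap, PhaseSet, ReflectionData
from .fourier_space import Apodization, FourierProjector
from .real_space import (
    ReferenceHistogram,
    TriweightKernel,
    envelope_from_variance,
    local_variance_map,
    project_real,
    solvent_variance,
    wasserstein_1_samples,
)


# --------------------------------------------------------------------------
# Update rules (array-level, projection callables)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DMParameters:
    """Difference Map parameters; gamma defaults are tied to beta."""

    beta: float
    gamma_A: float | None = None
    gamma_B: float | None = None

    def __post_init__(self):
        if not -1.0 < self.beta < 1.0 or self.beta == 0.0:
            raise ValueError("beta must lie in (-1, 0) or (0, 1)")

    @property
    def gA(self) -> float:
        return -1.0 / self.beta if self.gamma_A is None else self.gamma_A

    @property
    def gB(self) -> float:
        return 1.0 / self.beta if self.gamma_B is None else self.gamma_B


def er_step(x: np.ndarray, P_A: Callable, P_B: Callable) -> np.ndarray:
    """One Error Reduction cycle: Fourier projection, then real projection."""
    return P_A(P_B(x))


def dm_step(x: np.ndarray, P_A: Callable, P_B: Callable, params: DMParameters):
    """One Difference Map update; returns (x_next, est_A, est_B)."""
    pa_x = P_A(x)
    pb_x = P_B(x)
    f_A = (1.0 + params.gA) * pa_x - params.gA * x
    f_B = (1.0 + params.gB) * pb_x - params.gB * x
    est_A = P_A(f_B)
    est_B = P_B(f_A)
    x_next = x + params.beta * (est_A - est_B)
    return x_next, est_A, est_B


def delta_dm(est_A: np.ndarray, est_B: np.ndarray) -> float:
    """RMS deviation between the two solution estimates."""
    d = np.asarray(est_A, float) - np.asarray(est_B, float)
    return float(np.sqrt(np.mean(d * d)))


def negate_beta_semantics(params: DMParameters) -> DMParameters:
    """Flip the sign of beta (with tied gamma defaults this reverses the
    order in which the two projections act)."""
    return DMParameters(-params.beta, params.gamma_A, params.gamma_B)


# --------------------------------------------------------------------------
# Iteration plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IterationSpec:
    """Parameters in force at a single iteration of a stage."""

    algorithm: str          # "DM" | "ER"
    beta: float | None      # None for ER
    sigma: float | None     # apodization sigma (None = unapodized)
    r0: float               # triweight filter radius (A)
    update_envelope: bool


@dataclass(frozen=True)
class BetaSchedule:
    """Ordered blocks of (beta value, block length in iterations)."""

    blocks: tuple

    def __post_init__(self):
        for beta, length in self.blocks:
            DMParameters(beta)
            if length < 1:
                raise ValueError("block lengths must be >= 1")

    @staticmethod
    def alternating(beta_pair, period: int, total: int) -> "BetaSchedule":
        b1, b2 = beta_pair
        blocks = []
        i, which = 0, 0
        while i < total:
            n = min(period, total - i)
            blocks.append((b1 if which == 0 else b2, n))
            which ^= 1
            i += n
        return BetaSchedule(tuple(blocks))

    def values(self) -> np.ndarray:
        return np.concatenate([[b] * n for b, n in self.blocks])

    @property
    def total(self) -> int:
        return sum(n for _, n in self.blocks)


# --------------------------------------------------------------------------
# Random starts
# --------------------------------------------------------------------------

def random_phases(refl: ReflectionData, rng: np.random.Generator) -> np.ndarray:
    """Random initial phases: uniform for acentric reflections, uniform over
    the two allowed values for centric ones (degrees)."""
    ph = rng.uniform(0.0, 360.0, size=len(refl))
    cen = refl.centric
    if cen.any():
        allowed = refl.centric_allowed_phase()
        flip = rng.integers(0, 2, size=len(refl)) * 180.0
        ph[cen] = np.mod(allowed[cen] + flip[cen], 360.0)
    return ph


def random_start(projector: FourierProjector,
                 rng: np.random.Generator) -> DensityMap:
    """Density synthesized from observed amplitudes with random phases."""
    refl = projector.refl
    ph = random_phases(refl, rng)
    amps = np.where(refl.observed, refl.f_obs, 0.0)
    return projector.synthesize(ph, amps)


# --------------------------------------------------------------------------
# Single-run execution
# --------------------------------------------------------------------------

@dataclass
class StageResult:
    trajectory: pd.DataFrame
    est_A: DensityMap
    est_B: DensityMap
    envelope: BinaryEnvelope
    phase_set: PhaseSet
    seed: int | None = None

    def write_trajectory(self, path):
        header = f"# seed: {self.seed}\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.trajectory.to_csv(fh, sep="\t", index=False,
                                   float_format="%.6g")


def run_stage(projector: FourierProjector,
              plan: Sequence[IterationSpec],
              solvent_fraction: float,
              reference_provider: Callable[[float | None], ReferenceHistogram],
              *,
              x0: DensityMap | None = None,
              initial_envelope: BinaryEnvelope | None = None,
              seed: int | None = None,
              ground_truth: dict | None = None,
              gt_every: int = 1,
              preserve_variance: str = "mapped",
              protein_transform: str = "moment") -> StageResult:
    """Execute one envelope- or phase-determination run.

    ``reference_provider`` maps an apodization sigma to the matching
    reference histogram.  ``ground_truth`` may carry ``phases`` (a PhaseSet)
    and/or ``envelope`` (a BinaryEnvelope); agreement metrics against them
    are evaluated every ``gt_every`` iterations (carried forward between
    evaluations so every trajectory row is finite).
    """
    refl = projector.refl
    cell, sg = refl.cell, refl.spacegroup
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = random_start(projector, rng)
    x = x0.values.copy()
    shape = x.shape

    comparator = None
    if ground_truth:
        from .registration_clustering import GroundTruthComparator
        comparator = GroundTruthComparator(projector, ground_truth)

    kernels: dict[float, TriweightKernel] = {}
    refs: dict[float | None, ReferenceHistogram] = {}

    def kernel_for(r0: float) -> TriweightKernel:
        if r0 not in kernels:
            if len(kernels) > 4:
                kernels.clear()
            kernels[r0] = TriweightKernel(r0, shape, cell)
        return kernels[r0]

    def ref_for(sigma) -> ReferenceHistogram:
        if sigma not in refs:
            refs[sigma] = reference_provider(sigma)
        return refs[sigma]

    def make_map(values) -> DensityMap:
        return DensityMap(values, cell, sg)

    def update_envelope(values, r0) -> BinaryEnvelope:
        var = local_variance_map(make_map(values), r0, kernel_for(r0))
        return envelope_from_variance(var, solvent_fraction)

    if plan:
        first_r0 = plan[0].r0
    else:
        first_r0 = 8.0
    env = initial_envelope or update_envelope(x, first_r0)
    records = []
    est_A_vals, est_B_vals = x, x
    last_gt: dict = {}

    for it, spec in enumerate(plan):
        apod = Apodization(spec.sigma)
        ref = ref_for(spec.sigma)
        pb_info = {}

        def P_B(vals):
            out, info = projector.project_values(vals, apod)
            pb_info.update(info)
            return out

        def P_A(vals):
            return project_real(make_map(vals), env, ref, preserve_variance,
                                protein_transform).values

        if spec.algorithm == "DM":
            params = DMParameters(spec.beta)
            x, est_A_vals, est_B_vals = dm_step(x, P_A, P_B, params)
        elif spec.algorithm == "ER":
            est_B_vals = P_B(x)
            est_A_vals = P_A(est_B_vals)
            x = est_A_vals
        else:
            raise ValueError(f"unknown algorithm {spec.algorithm!r}")
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite density at iteration {it}; run aborted")

        est_B_map = make_map(est_B_vals)
        rec = {
            "iteration": it + 1,
            "algorithm": spec.algorithm,
            "beta": spec.beta if spec.beta is not None else np.nan,
            "sigma": spec.sigma if spec.sigma is not None else 0.0,
            "r0": spec.r0,
            "delta_dm": delta_dm(est_A_vals, est_B_vals),
            "solvent_variance": solvent_variance(est_B_map, env),
            "wasserstein": wasserstein_1_samples(
                est_B_vals[env.mask], ref.values),
            "amplitude_cc": pb_info.get("cc", np.nan),
            "r_factor": pb_info.get("r", np.nan),
        }
        if comparator is not None:
            if it % gt_every == 0 or it == len(plan) - 1:
                last_gt = comparator.evaluate(est_B_vals, env, apod)
            rec.update(last_gt)
        records.append(rec)

        if spec.update_envelope:
            env = update_envelope(est_B_vals, spec.r0)

    final_apod = Apodization(plan[-1].sigma) if plan else Apodization(None)
    phases = projector.phases(est_B_vals)
    phase_set = PhaseSet(refl, phases, projector.weights(final_apod).copy())
    return StageResult(pd.DataFrame.from_records(records),
                       make_map(est_A_vals), make_map(est_B_vals),
                       env, phase_set, seed=seed)
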