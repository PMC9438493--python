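"""Stage parameterizations and the two-stage phasing pipeline.

Envelope determination runs the Difference Map at low effective resolution
(heavy fixed apodization) many times from random phases, clusters the
resulting binary envelopes and averages each cluster into a consensus
envelope.  Phase determination restarts from random phases with the best
consensus envelope imposed, gradually removing the apodization over an
equal-area schedule, and finishes with alternating DM/ER polishing blocks.
The emergence of two or more mutually consistent final phase sets (mean
absolute phase difference below the clustering radius) is the success
diagnostic; no conventional agreement metric is needed.

Runs never communicate: each is an independent task with a seed derived
deterministically from the master seed, so results do not depend on the
worker count.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from joblib import Parallel, delayed

from .crystal_core import (
    BinaryEnvelope,
    DensityMap,
    GridSpec,
    PhaseSet,
    ReflectionData,
)
from .fourier_space import (
    FourierProjector,
    build_schedule,
    estimate_overall_B,
)
from .ipa_engine import IterationSpec, StageResult, run_stage
from . import registration_clustering as rc

LOW_RES_CUTOFF = 25.0           # A; lower-resolution terms treated as missing
GRID_SPACING_FACTOR = 0.4       # grid spacing = 2/5 of the effective limit
ENVELOPE_EFFECTIVE_RESOLUTION = 3.6  # A, envelope-stage effective limit


# --------------------------------------------------------------------------
# Stage configuration
# --------------------------------------------------------------------------

@dataclass
class StageConfig:
    """Declarative parameterization of one envelope- or phase-determination
    stage; :meth:`iteration_plan` expands it into per-iteration settings."""

    kind: str                       # "envelope" | "phase"
    n_runs: int
    low_res_cutoff: float = LOW_RES_CUTOFF
    grid_spacing_factor: float = GRID_SPACING_FACTOR
    effective_resolution: float | None = None  # None: use the data limit
    envelope_hold: int = 0          # iterations with the envelope held fixed
    protein_transform: str = "moment"   # "moment" | "histogram"
    gt_every: int = 10
    # envelope stage fields
    n_dm: int = 0
    n_er: int = 0
    beta_pair: tuple = (0.72, 0.78)
    beta_period: int = 1
    sigma: float | None = None      # fixed apodization
    r0_start: float = 10.8
    r0_end: float = 8.0
    r0_shrink_iters: int = 1000
    # phase stage fields
    schedule_steps: int = 0
    iters_per_step: int = 0
    sigma0: float = 0.16
    r0: float = 8.0
    final_cycles: int = 0
    final_dm_pos: int = 0
    final_beta_pos: float = 0.75
    final_dm_neg: int = 0
    final_beta_neg: float = -0.55
    final_er: int = 0

    @property
    def total_iterations(self) -> int:
        if self.kind == "envelope":
            return self.n_dm + self.n_er
        return (self.schedule_steps * self.iters_per_step +
                self.final_cycles * (self.final_dm_pos + self.final_dm_neg +
                                     self.final_er))

    def grid_for(self, refl: ReflectionData) -> GridSpec:
        d_eff = self.effective_resolution or refl.d_min
        return GridSpec.from_spacing(refl.cell,
                                     self.grid_spacing_factor * d_eff,
                                     refl.spacegroup)

    def iteration_plan(self, s_max: float) -> list[IterationSpec]:
        specs: list[IterationSpec] = []
        if self.kind == "envelope":
            b1, b2 = self.beta_pair
            for i in range(self.n_dm):
                if self.r0_shrink_iters > 1 and i < self.r0_shrink_iters:
                    frac = i / (self.r0_shrink_iters - 1)
                    r0 = self.r0_start + frac * (self.r0_end - self.r0_start)
                else:
                    r0 = self.r0_end
                beta = (b1, b2)[(i // self.beta_period) % 2]
                specs.append(IterationSpec("DM", beta, self.sigma, r0,
                                           i >= self.envelope_hold))
            for i in range(self.n_er):
                specs.append(IterationSpec("ER", None, self.sigma,
                                           self.r0_end, True))
        elif self.kind == "phase":
            schedule = build_schedule(self.sigma0, self.schedule_steps, s_max)
            b1, b2 = self.beta_pair
            it = 0
            for apod in schedule.steps:
                for _ in range(self.iters_per_step):
                    beta = (b1, b2)[(it // self.beta_period) % 2]
                    specs.append(IterationSpec("DM", beta, apod.sigma, self.r0,
                                               it >= self.envelope_hold))
                    it += 1
            for _ in range(self.final_cycles):
                for _ in range(self.final_dm_pos):
                    specs.append(IterationSpec("DM", self.final_beta_pos, None,
                                               self.r0, True))
                for _ in range(self.final_dm_neg):
                    specs.append(IterationSpec("DM", self.final_beta_neg, None,
                                               self.r0, True))
                for _ in range(self.final_er):
                    specs.append(IterationSpec("ER", None, None, self.r0, True))
        else:
            raise ValueError("kind must be 'envelope' or 'phase'")
        assert len(specs) == self.total_iterations
        return specs


def default_envelope_config() -> StageConfig:
    """Benchmark envelope-determination stage: 50 runs of 1475 DM + 25 ER
    iterations, beta alternating 0.72/0.78 each iteration, fixed apodization
    sigma = 0.091 A^-1, triweight radius shrinking 10.8 -> 8.0 A over the
    first 1000 iterations."""
    return StageConfig(
        kind="envelope", n_runs=50, n_dm=1475, n_er=25,
        beta_pair=(0.72, 0.78), beta_period=1, sigma=0.091,
        r0_start=10.8, r0_end=8.0, r0_shrink_iters=1000,
        low_res_cutoff=25.0,
        effective_resolution=ENVELOPE_EFFECTIVE_RESOLUTION)


def default_phase_config(data_resolution: float) -> StageConfig:
    """Benchmark phase-determination stage: 20 runs of 8100 iterations —
    7200 DM iterations over a 30-step equal-area apodization schedule from
    sigma = 0.16 A^-1 (beta alternating 0.675/0.800 every 60 iterations),
    then four cycles of 100 DM at beta=0.75, 100 DM at beta=-0.55 and
    25 ER iterations, unapodized.  The envelope is held for 10 iterations."""
    return StageConfig(
        kind="phase", n_runs=20,
        schedule_steps=30, iters_per_step=240, sigma0=0.16,
        beta_pair=(0.675, 0.800), beta_period=60,
        final_cycles=4, final_dm_pos=100, final_beta_pos=0.75,
        final_dm_neg=100, final_beta_neg=-0.55, final_er=25,
        r0=8.0, envelope_hold=10, low_res_cutoff=25.0,
        effective_resolution=data_resolution)


TOY_LENGTH_SCALE = 0.5  # toy molecules are about half the linear size of a
                        # typical protein, so the filter radii scale with them


def toy_envelope_config(n_runs: int = 10, total: int = 300,
                        length_scale: float = TOY_LENGTH_SCALE) -> StageConfig:
    """Envelope stage scaled down for small synthetic crystals: same block
    structure, proportionally shortened, with the triweight filter radii
    scaled to the toy molecule's linear size."""
    n_er = max(10, total // 12)
    n_dm = total - n_er
    cfg = default_envelope_config()
    cfg.n_runs = n_runs
    cfg.n_dm = n_dm
    cfg.n_er = n_er
    cfg.r0_shrink_iters = (2 * total) // 3
    cfg.r0_start = round(10.8 * length_scale, 2)
    cfg.r0_end = round(8.0 * length_scale, 2)
    cfg.gt_every = 25
    return cfg


def toy_phase_config(data_resolution: float, n_runs: int = 5,
                     schedule_steps: int = 30, iters_per_step: int = 30,
                     length_scale: float = TOY_LENGTH_SCALE) -> StageConfig:
    """Phase stage scaled down for small synthetic crystals: 1200
    iterations — a 30-step apodization schedule of 30 iterations each, then
    four 75-iteration polish cycles — with the triweight filter radius
    scaled to the toy molecule's linear size."""
    cfg = default_phase_config(data_resolution)
    cfg.n_runs = n_runs
    cfg.schedule_steps = schedule_steps
    cfg.iters_per_step = iters_per_step
    cfg.beta_period = max(1, iters_per_step // 4)
    cfg.final_cycles = 4
    cfg.final_dm_pos = 25
    cfg.final_dm_neg = 25
    cfg.final_er = 25
    cfg.r0 = round(8.0 * length_scale, 2)
    cfg.gt_every = 25
    return cfg


# --------------------------------------------------------------------------
# Candidate-envelope ranking
# --------------------------------------------------------------------------

def rank_candidate_envelopes(candidates, target_fraction: float):
    """Order consensus envelopes by volume-fraction conformity and
    protein-region connectivity (fewer disconnected islands first)."""
    def key(item):
        i, env = item
        realized = env.realized_solvent_fraction
        labels, n_comp = rc._periodic_label(env.mask)
        if n_comp > 0:
            sizes = np.bincount(labels.ravel())[1:]
            island_frac = 1.0 - sizes.max() / sizes.sum()
        else:
            island_frac = 1.0
        return (abs(realized - target_fraction), n_comp, island_frac, i)

    order = sorted(enumerate(candidates), key=key)
    return [env for _, env in order]


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class StageSummary:
    results: list
    distances: np.ndarray | None = None
    clusters: object = None
    consensus: list = field(default_factory=list)


@dataclass
class PipelineResult:
    success: bool
    envelope_stage: StageSummary
    phase_stage: StageSummary
    consensus_phases: PhaseSet | None = None
    circular_variance: float | None = None
    best_envelope: BinaryEnvelope | None = None
    b_factor: float | None = None
    wall_time_s: float = 0.0

    def summary(self) -> str:
        lines = [f"success: {self.success}"]
        if self.b_factor is not None:
            lines.append(f"estimated overall B: {self.b_factor:.1f} A^2")
        if self.envelope_stage.clusters is not None:
            lines.append(
                f"envelope clusters: {self.envelope_stage.clusters.n_clusters} "
                f"from {len(self.envelope_stage.results)} runs")
        if self.phase_stage.clusters is not None:
            cl = self.phase_stage.clusters
            lines.append(
                f"phase clusters: {cl.n_clusters} from "
                f"{len(self.phase_stage.results)} runs")
            for k in range(cl.n_clusters):
                lines.append(f"  cluster {k}: size {len(cl.members(k))}")
        if self.circular_variance is not None:
            lines.append(f"sample circular variance: {self.circular_variance:.2f}")
        return "\n".join(lines)


def _run_seed(master_seed: int, stage: str, index: int) -> int:
    ss = np.random.SeedSequence([master_seed, {"env": 1, "phase": 2}[stage],
                                 index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _execute_stage(refl, solvent_fraction, config: StageConfig,
                   reference_provider, seeds, *, initial_envelope=None,
                   ground_truth=None, n_workers=1, guard=True):
    grid = config.grid_for(refl)
    projector = FourierProjector(refl, grid.shape, guard=guard)
    plan = config.iteration_plan(s_max=float(refl.s.max()))
    init_env = initial_envelope
    if init_env is not None and init_env.mask.shape != grid.shape:
        init_env = init_env.resampled(grid.shape, solvent_fraction)

    def one(seed):
        return run_stage(projector, plan, solvent_fraction, reference_provider,
                         initial_envelope=init_env, seed=seed,
                         ground_truth=ground_truth, gt_every=config.gt_every,
                         protein_transform=config.protein_transform)

    if n_workers > 1:
        results = Parallel(n_jobs=n_workers)(delayed(one)(s) for s in seeds)
    else:
        results = [one(s) for s in seeds]
    return projector, results


def run_two_stage(refl: ReflectionData, solvent_fraction: float, *,
                  envelope_config: StageConfig | None = None,
                  phase_config: StageConfig | None = None,
                  reference_provider=None,
                  seed: int = 0, n_workers: int = 1,
                  ground_truth: dict | None = None,
                  phase_cluster_eps: float = 40.0,
                  skip_envelope_stage: bool = False,
                  initial_envelope: BinaryEnvelope | None = None,
                  guard: bool = True) -> PipelineResult:
    """Full two-stage ab initio phasing with clustering at both stages.

    Success is declared iff a cluster of at least two mutually consistent
    final phase sets forms at the clustering radius (40 degrees mean
    absolute phase difference by default).
    """
    import warnings
    if not 0.5 < solvent_fraction < 0.95:
        raise ValueError("solvent fraction outside the supported range "
                         "(0.5, 0.95)")
    if not 0.70 < solvent_fraction < 0.85:
        warnings.warn("solvent fraction outside (0.70, 0.85): direct phasing "
                      "succeeds rarely in this regime")
    t0 = time.perf_counter()
    envelope_config = envelope_config or default_envelope_config()
    phase_config = phase_config or default_phase_config(refl.d_min)

    b_factor = None
    if reference_provider is None:
        from .synthetic_fixtures import SyntheticReferenceProvider
        b_factor, _ = estimate_overall_B(refl)
        reference_provider = SyntheticReferenceProvider(
            refl.cell, refl.spacegroup, solvent_fraction,
            max(b_factor, 0.0), refl.d_min)

    env_summary = StageSummary(results=[])
    best_env = initial_envelope
    if not skip_envelope_stage:
        seeds = [_run_seed(seed, "env", i) for i in range(envelope_config.n_runs)]
        _, env_results = _execute_stage(
            refl, solvent_fraction, envelope_config, reference_provider,
            seeds, ground_truth=ground_truth, n_workers=n_workers, guard=guard)
        envelopes = [r.envelope for r in env_results]
        dists, _ = rc.pairwise_envelope_distances(envelopes, refl.spacegroup)
        eps = rc.choose_eps_envelopes(dists)
        min_pts = max(2, int(round(0.1 * envelope_config.n_runs)))
        clusters = rc.dbscan(dists, min_pts, eps)
        consensus = []
        for members_idx in clusters.clusters():
            members = [envelopes[i] for i in members_idx]
            consensus.append(rc.consensus_envelope(
                members, refl.spacegroup, target_fraction=solvent_fraction))
        env_summary = StageSummary(env_results, dists, clusters, consensus)
        if consensus:
            best_env = rank_candidate_envelopes(consensus, solvent_fraction)[0]
        else:
            warnings.warn("no envelope cluster formed; starting phase "
                          "determination from the best single envelope")
            # fall back: envelope of the run with best amplitude agreement
            ccs = [r.trajectory["amplitude_cc"].iloc[-1] for r in env_results]
            best_env = envelopes[int(np.argmax(ccs))]

    if phase_config.n_runs == 0:
        return PipelineResult(False, env_summary, StageSummary(results=[]),
                              None, None, best_env, b_factor,
                              time.perf_counter() - t0)

    seeds = [_run_seed(seed, "phase", i) for i in range(phase_config.n_runs)]
    projector, phase_results = _execute_stage(
        refl, solvent_fraction, phase_config, reference_provider, seeds,
        initial_envelope=best_env, ground_truth=ground_truth,
        n_workers=n_workers, guard=guard)
    phase_sets = [r.phase_set for r in phase_results]
    pd_matrix, _ = rc.pairwise_phase_distances(phase_sets, refl.spacegroup,
                                               projector.shape)
    phase_clusters = rc.dbscan(pd_matrix, 2, phase_cluster_eps)
    phase_summary = StageSummary(phase_results, pd_matrix, phase_clusters, [])
    consensus_ps, circ_var = None, None
    success = phase_clusters.n_clusters > 0
    if success:
        sizes = [len(phase_clusters.members(k))
                 for k in range(phase_clusters.n_clusters)]
        kbest = int(np.argmax(sizes))
        members = [phase_sets[i] for i in phase_clusters.members(kbest)]
        consensus_ps, circ_var, _ = rc.consensus_phases(
            members, refl.spacegroup, projector.shape)
        phase_summary.consensus = [consensus_ps]
    return PipelineResult(success, env_summary, phase_summary, consensus_ps,
                          circ_var, best_env, b_factor,
                          time.perf_counter() - t0)


# --------------------------------------------------------------------------
# Parameter files
# --------------------------------------------------------------------------

def load_parameter_file(path) -> dict:
    """Single structured parameter file controlling the whole procedure.

    Top-level keys: 'envelope' and 'phase' (StageConfig field overrides),
    'solvent_fraction', 'seed', 'n_workers', 'phase_cluster_eps'."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return data


def configs_from_parameters(params: dict, data_resolution: float):
    env = default_envelope_config()
    ph = default_phase_config(data_resolution)
    for cfg, key in ((env, "envelope"), (ph, "phase")):
        for k, v in (params.get(key) or {}).items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown {key} parameter {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
    return env, ph
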