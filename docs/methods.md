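# Methods

This note records the models, conventions, parameter choices and known
limitations of `dmphase`, at the level of detail a user would need to judge
what a result does and does not demonstrate.

## Constraint sets and projections

The electron density is represented on a regular grid over one full unit
cell (P1-expanded). Crystallographic symmetry is imposed by averaging over
the space-group operators after every inverse Fourier transform; reflection
bookkeeping works on one Friedel hemisphere of symmetry-unique indices, with
centric flags, allowed centric phases, symmetry-enhancement factors ε and
systematic absences derived from the operator table. Structure factors use
the convention G(**h**) = Σ_x ρ(x) e^{+2πi h·x}; absolute scale is
irrelevant because every amplitude comparison happens after a single
least-squares scale fit.

**Fourier projection P_B.** The current density is transformed; observed
amplitudes are replaced by `scale · w(s) · F_obs` (phase kept), where
w(s) = exp(−s²/2σ²) is the Gaussian apodization in force and `scale` is the
least-squares fit of the calculated amplitudes onto the apodized
observations, recomputed at every projection. Grid modes beyond the
resolution of the data set are constrained to zero, so the reconstruction
is band-limited. Unobserved in-band modes — reflections below the 25 Å
low-resolution cutoff, reflections absent from the input file, and
F(000) — keep their calculated value unless it is improbably large under
Wilson statistics (upper-tail probability strictly below 5×10⁻⁶, acentric
amplitudes Rayleigh and centric half-normal with mean square εΣ), in which
case it is reset to the class expectation ⟨F⟩ at that resolution. Σ comes
from equal-count resolution shells of the scaled observations (20 shells
with at least 50 reflections where possible). Because F(000) is never
imposed, all densities are effectively mean-free; every reference
distribution in the package follows the same convention.

**Real-space projection P_A.** The solvent region is set to its mean. For
the protein region two transforms are provided. The default (`moment`)
shifts the region mean to the reference mean while preserving the variance
— this is the Euclidean projection onto the mean constraint, it is
idempotent, and it is the literal reading of the published description of
the operation ("shifting the overall mean to its expected value, while
preserving the variance"); full rank-based histogram specification
(`histogram`) maps the sorted region values through the reference quantile
function, with tied input values mapped to the mean reference quantile of
their rank span so genuinely flat blocks stay flat. The full specification
is deliberately not the engine default: when the stated solvent fraction
underestimates the true one — the common and, per the protocol's design,
benign direction of error — the working protein region contains genuinely
flat solvent, and rank specification spreads that flat block across the
reference quantiles, which empirically destroys convergence on our
synthetic crystals, whereas the mean-shift transform reproduces the
method's documented robustness to underestimation. Both modes are exercised
by the test suite; the choice is a `protein_transform` configuration field.

**Reference distributions.** The expected protein distribution depends on
resolution, overall B factor and apodization, so reference histograms are
recomputed under whatever apodization (and the same low-resolution cutoff)
is in force. References come from synthetic reference structures generated
at a B factor calibrated so that the reference's *fitted* Wilson B matches
the data's fitted Wilson B (bisection over the generator parameter), which
mirrors matched-reference selection without any external structure. The
overall B itself is estimated from a weighted Wilson-plot fit of ln⟨I/ε⟩
against s²/2 restricted to d < 4.5 Å, because solvent contrast inflates the
low-resolution shells far above the Wilson trend.

## Envelope determination

The molecular envelope is the top (1 − solvent fraction) of the local
density variance, computed with a periodic triweight kernel
T(r) = (1 − (r/r₀)²)³ by the one-pass identity K∗ρ² − (K∗ρ)², and
re-thresholded at every iteration from the Fourier-side solution estimate.
Ties at the threshold are broken by grid index, and the mask is
symmetrized by per-orbit majority vote, so envelopes are deterministic and
symmetry-consistent.

## The iterative engine

Difference Map update, solution estimates, δ_DM, and the β-sign/projection
-order equivalence are implemented exactly as in the README formula, with
relaxation constants γ_A = −1/β, γ_B = 1/β (exposed as configuration; the
published display of the update could not be transcribed verbatim, so the
standard recommended constants are used and verified behaviourally: the
alternative assignment stagnates like ER on our fixtures). Runs are
seed-reproducible; per-run seeds derive deterministically from a master
seed, independently of the worker count, and runs never communicate.

## Protocols

The benchmark parameterizations are reproduced field by field:

| parameter | envelope stage | phase stage |
|---|---|---|
| runs | 50 | 20 |
| iterations | 1475 DM + 25 ER | 7200 DM + 4×(100 DM β=0.75, 100 DM β=−0.55, 25 ER) |
| β | 0.72/0.78 alternating each iteration | 0.675/0.800 alternating every 60 |
| apodization | fixed σ = 0.091 Å⁻¹ (1% height at 3.6 Å) | 30-step equal-area schedule from σ₀ = 0.16 Å⁻¹ to none |
| filter radius r₀ | 10.8 → 8.0 Å linearly over the first 1000 iterations | 8.0 Å |
| low-res cutoff | 25 Å | 25 Å |
| envelope | updated every iteration | held 10 iterations, then updated |
| grid spacing | 2/5 × 3.6 Å effective limit | 2/5 × data resolution |

Envelope clustering uses DB-SCAN (scikit-learn, precomputed distances,
d = √(1−CC²) after registration over allowed origin shifts and the
inversion alternative) with minPoints = 10% of the run count and ε at the
4th percentile of the pairwise distances; consensus envelopes are per-voxel
majority votes (ties → protein) followed by a connectivity edit that erases
protein islands and fills solvent voids smaller than 1% of the protein
volume (periodic connectivity). Candidate envelopes are ranked by
volume-fraction conformity, then connectivity. Phase-set clustering uses
minPoints = 2 and ε = 40° mean absolute phase difference; a cluster of two
or more mutually consistent phase sets declares success. Consensus phases
are per-reflection circular means after registration, with the sample
circular variance (1 − mean resultant length) as the consistency measure;
reflections with vanishing resultant are flagged undefined.

Registration evaluates envelope correlations over all grid translations by
FFT cross-correlation restricted to the allowed origin set (continuous
polar directions search every grid translation), plus the inversion
alternative in non-enantiomorphic groups; phase sets are scored by the
exact registered mean absolute difference, with a phased-translation-
function preselection when the candidate set is large. Continuous origin
shifts are searched on a grid; sub-grid refinement is not attempted, so
evaluation against an external truth should use the map's own grid as the
registration frame.

## The synthetic-crystal generator

A toy crystal is a connected random-walk globule of unit-weight Gaussian
pseudo-atoms (3.8 Å steps, ~10 Å³ of protein volume per atom, a quarter of
the atoms forming a reduced-weight disordered periphery), symmetry-expanded,
deposited on the grid (with the trilinear transfer function deconvolved),
smeared by exp(−Bs²/4), band-limited at the stated resolution, and
mean-subtracted. The true envelope is the thresholded smoothed density — a
molecular boundary rather than a per-voxel density ranking. The map is then
driven to a joint fixed point of band-limiting and exact solvent flattening
(fixed envelope), so the stored amplitudes correspond to a genuinely
featureless solvent, which is the statistical structure the method assumes.
Amplitudes carry multiplicative Gaussian noise (2% by default) with
consistent sigmas; ground-truth map, envelope and phases are retained.

Defaults — 24 Å cubic P1 cell, solvent fraction 0.80, B = 20 Å², 3 Å data,
2% noise — were chosen once as a realistic miniature of the method's target
regime. Two scale-driven choices deserve emphasis. First, the default cell
is small enough that no reflection falls below the 25 Å cutoff: in a small
cell a compact molecule concentrates a large share of its power in the
handful of sub-cutoff modes, and the Wilson guard necessarily caps them,
which distorts the constraint geometry in a way real crystals (where those
modes hold on the order of a percent of the power) do not experience.
Second, the scaled protocols shrink the triweight radii by the ratio of the
toy molecule's linear size to a typical protein's (factor 0.5: 5.4 → 4.0 Å
and 4.0 Å), since the benchmark radii are absolute lengths tuned to
full-size molecules. The scaled study conditions are 10 envelope runs × 300
iterations and 5 phase runs × 1200 iterations (30 schedule steps of 30
iterations plus four 75-iteration polish cycles).

What the toys do not emulate: atomic form factors and chemistry (single
Gaussians only), realistic measurement-error models, bulk-solvent
scattering, anisotropy, non-crystallographic symmetry, and the truncated
low-resolution data regime of real cells. Passing the end-to-end tests
therefore demonstrates the correctness and the qualitative behavior of the
algorithm (success at high solvent fraction, failure at 0.60, asymmetric
response to solvent-fraction mis-specification, the two-stage advantage
direction), not its quantitative success rates on deposited data.

## Numerical choices and determinism

Population variance throughout (grid points are the whole population).
Grids are 5-smooth and compatible with the operator translation
denominators; axes mixed by a rotation share a count. Degenerate inputs are
rejected loudly: constant variance maps, empty regions, all-missing data,
non-finite densities mid-run (the run aborts with a diagnostic). Wasserstein
distances are evaluated exactly for empirical distributions (step CDFs) and
trapezoidally for supplied CDFs. DB-SCAN border points follow
scikit-learn's first-reached rule; vote ties go to protein; registration
ties go to the lexicographically smallest shift and the non-inverted
alternative. Repeated runs with the same seed are bitwise identical in
their trajectories.

## Known limitations

* The built-in space-group table covers P1, P2₁, P2₁2₁2₁, I222 and the
  P6₁/P6₅ enantiomorph pair; other groups must be supplied as operator
  files, and hand determination for achiral groups is left to the user.
* End-to-end phasing has been validated on P1 toys; in other groups the
  component operations (symmetry bookkeeping, registration, clustering)
  are tested individually.
* Sub-grid origin refinement is not implemented, so reported phase
  differences include a small registration-quantization term when the
  compared sets do not share a grid.
* The guard's Σ extrapolates the lowest shell to all deeper-resolution
  modes; in very small cells this under-predicts sub-cutoff amplitudes
  (see the generator discussion above).
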