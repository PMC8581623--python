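# Methods

This note records the models, estimators, conventions and numerical
choices behind `oligokin`, and what the synthetic validation does and
does not demonstrate.

## Coordinate conventions

Lengths are nm, times ns, rates ns⁻¹. The membrane plane is xy and all
analyses are two-dimensional; the minimum-image convention is applied in
xy only (z is not periodic in a membrane system). "Clockwise" angles are
defined viewed from +z, i.e. from the extracellular side.

## Oligomer detection

The contact criterion is a fixed cutoff on the minimum bead–bead
distance between two proteins, default 0.75 nm. The cutoff is motivated
by the shape of the pairwise minimum-distance density: a bound-state
peak near 0.55 nm separated from the unbound background by a trough
near 0.7 nm (`distance_density` reproduces this diagnostic so the cutoff
can be re-derived per system). Partitions are single-linkage groupings
at that fixed threshold — equivalently, connected components of the
thresholded contact graph — which is what hierarchical clustering
reduces to when cut at a fixed distance; we implement it as connected
components because that form is directly testable against a brute-force
graph oracle.

Event counting operates on smoothed minimum-distance traces (centered
moving average, default window 31 frames, exposed as a parameter; the
window suppresses single-frame flicker at typical coarse-grained output
strides). Partition assignment uses unsmoothed frame distances; flicker
handling is instead applied at the duration level, where contact breaks
shorter than 100 ns are merged (`fill_flickers`), reflecting that rapid
contact flickering does not constitute a real dissociation. Whether
counting should use smoothed or raw distances is genuinely open; the
package keeps the two paths separate and documented.

## Configuration clustering

Coordinate RMSD between oligomers depends on member indexing, so every
structure is reordered against a pool reference: all order! member
permutations are tried (order ≤ 5, at most 120) and the permutation with
the lowest RMSD after optimal in-plane rigid superposition wins, ties
going to the lexicographically smallest permutation. Superposition
allows rotation and translation only — no reflection, which would flip
the clockwise angle convention. The reference is the pool's
first-occurring structure: a reproducible stand-in for an arbitrary
choice. Oligomers of order ≥ 6 are counted and labeled but not
clustered.

KMeans runs on the flattened reordered coordinates with a fixed seed;
when the cluster count is not given it is chosen by a silhouette scan
over k ∈ [2, 15]. Labels `A.b` are assigned by descending cluster size.

Geometric descriptors:

- **θ₁, θ₂** (dimers): for each protomer, the clockwise angle from its
  reference axis (geometric center → orientation bead; the in-plane
  analogue of an H8-parallel axis) to the direction of the partner's
  geometric center, in [0, 360). The partner-center direction stands in
  for "the interface direction"; a contact-centroid variant would be a
  reasonable alternative and the convention is documented rather than
  asserted as canonical.
- **ϕ** (trimers): the angle at the vertex protomer (the one in contact
  with both others) subtended by the other two centers; for cyclic
  trimers, where no unique vertex exists, the smallest of the three
  vertex angles.
- **D₁ ≥ D₂** (tetramers/pentamers): spans (max − min projection) of the
  protomer centers on the principal axes of their in-plane covariance;
  isotropic (equal-eigenvalue) cases fall back to the x axis. Centers
  are put in lexicographic order first so the result is bitwise
  independent of protein labeling.

Periodic unwrapping of an oligomer anchors at the member with the
lexicographically smallest center and attaches the remaining members
greedily by minimum-image proximity — again labeling-independent, so
relabeling proteins leaves every downstream quantity bit-identical.

## Residence-time kinetics

Durations of a species' continuous appearances (flicker-merged) are
summarized by the empirical survival function σ(Δt) = fraction of
appearances with duration ≥ Δt, normalized so σ(0) = 1, evaluated on a
log-spaced grid (200 points reaching from two decades below the
shortest duration to 5% beyond the longest). A time-correlation
estimator that sums an indicator over all start times ν with a
1/(T − t) factor double-counts within long appearances; the
duration-based survival has the identical decay shape and is the
standard construction, so the normalization absorbs that factor.

The fit is unweighted nonlinear least squares of
A·e^(−k₁Δt) + B·e^(−k₂Δt) with A + B = 1, A, B ≥ 0 and k₁ ≥ k₂ > 0
enforced by parameter transforms (logistic for A, log for k₂, softplus
offset for k₁/k₂; all transform arguments clipped so residuals stay
finite). Initialization: k₂ from a log-linear fit to the final 30% of
the positive part of the curve, k₁ = 10·k₂, A = 0.5, plus five jittered
restarts; the lowest residual wins. k_off = k₂ and residence time =
1/k_off. If the fitted slow component carries less than 1% amplitude the
decay is treated as single-exponential and refitted as such: a
sub-percent "slow phase" is indistinguishable from a handful of extreme
dwells and would otherwise dominate k_off spuriously. A survival curve
with no decay in the observation window raises an error (k_off is then
only bounded above by 1/T). Durations truncated by the trajectory end
are included as-is (no censoring correction).

Bootstrap uncertainty resamples durations with replacement and refits
(warm-started, one restart, a fixed jitter seed shared across resamples
so identical resamples give identical fits), reporting the SD and the
2.5/97.5 percentiles of k_off; a warning is raised if more than 20% of
resample fits fail. Per-order summaries are arithmetic means of the
member configurations' residence times with a 1000-sample bootstrap
interval over configurations.

## Lipid binding sites

Residue–lipid contacts use a dual-cutoff hysteresis: a contact opens
when the head-group distance drops below 0.55 nm and closes only when
it exceeds 1.0 nm. Residue residence times reuse the survival machinery
(with a fallback to the mean contact duration, flagged, when fewer than
10 events exist or the fitted residence time exceeds the observation
time — beyond which it is unidentifiable). The interaction graph has
residues as nodes and, as edge weights, the fraction of trajectory time
two residues spent simultaneously in contact with the same lipid
molecule (the natural per-frame normalization of an otherwise unstated
"frequency"); residues with occupancy below 10⁻⁴ are dropped as noise.
Binding sites are Louvain communities (resolution 1.0, seeded,
implemented with networkx's Louvain) of that graph. Site-level contacts
apply the same dual cutoff to the minimum distance from a lipid to any
site residue, so a lipid hopping among member residues counts as one
continuous site contact; the mean bound-lipid count is total site-bound
lipid time divided by trajectory time.

The in-plane g(r) is computed against the minimum distance to a
reference bead set; shell areas are estimated by seeded uniform Monte
Carlo sampling of the periodic box (2 × 10⁵ points by default), which
handles the multi-bead reference "surface" and periodic wrap-around
exactly in expectation and makes a uniform lipid distribution read
g(r) = 1 at every r.

## Markov state models

States are whole-membrane compositions `A^a-B^b-C^c` (orders ascending),
deliberately ignoring specific oligomer geometries — tracking structures
as well would multiply the state space and prevent convergence.
Transitions are counted with a sliding window at lag τ; replicate
trajectories are summed, never bridged. The default estimator is the
non-reversible row-normalized maximum-likelihood matrix on the largest
strongly connected state set (excluded states are reported, never
silently dropped); a reversible, detailed-balance-constrained MLE via
the classic fixed-point iteration (tolerance 10⁻¹⁰) is available, since
established MSM toolchains default to reversible estimation. Implied
timescales are k = −τ/ln(μ) per non-unit eigenvalue (modulus for complex
pairs, undefined for non-positive ones) and should be flat in τ where
the process is Markovian; the scan is always available so the lag can be
chosen by convergence. Mean first passage times solve
m_i = τ + Σ_{k≠j} P_ik m_k with m_j = 0; state lifetimes are the
first-exit times τ/(1 − P_ii) — one reading of "mean first passage to
the other states"; the full mfpt matrix is exposed so a per-target
reading is also recoverable. Reaction-rate networks use rate = 1/mfpt,
with a 50 s⁻¹ display threshold conventional for such network figures
(the full matrix is always available).

## The synthetic generator

The Brownian simulator is a stand-in for undeposited coarse-grained
trajectories, built so that ground truth is exact rather than inferred:

- Rigid near-circular bodies (12 perimeter beads at 1.1 nm plus a
  center bead) diffuse in a periodic 45 × 45 nm box with D = 0.05
  nm²/ns (coarse-grained-scale lateral diffusion; rotational diffusion
  uses the same numerical value, since only relative geometry matters
  for the metrics tested).
- Binding occurs when the centers of two bodies in different oligomers
  come within the 3.0 nm capture radius; the joining oligomer is
  snapped to the 2.7 nm contact distance and the pair moves as a rigid
  unit. Bonds break independently with rate k_off (default 0.01 ns⁻¹,
  i.e. 100 ns mean dwell), upon which the separating oligomers are
  displaced to just beyond the capture radius. Higher orders arise by
  chaining pairwise bonds.
- The geometry is chosen so that bound pairs sit at bead–bead minimum
  distances of ~0.50–0.58 nm and unbound pairs never drop below
  0.8 nm: the 0.75 nm detection cutoff then separates the two regimes
  with no ambiguity, mirroring the 0.55 nm peak / 0.7 nm trough
  structure of real contact-distance densities. Detected partitions
  therefore equal ground-truth partitions exactly, which is what makes
  the detector testable end to end.

The default kinetic regime is dilute and dissociation-dominated, so
association is the rate-limiting second-order step. Under it the 16:9
ratio of total association events at equal box area measures ≈ 2.6–3.0
across seeds against the ideal (16/9)² ≈ 3.16: the denser 16-copy
system holds a larger fraction of its copies inside oligomers, and this
bound-fraction saturation depresses the ratio by roughly 10–15%. The
scaling is second-order with a quantified saturation correction, not an
exact power law.

Features of real systems the stand-in does **not** emulate: excluded
volume (snapped oligomers can transiently interpenetrate), internal
flexibility and interface specificity (bound geometry is frozen at the
capture orientation), force-field energetics, explicit lipids (lipid
analyses use planted contact series instead), and hydrodynamics
(oligomer diffusion does not slow with size). Passing tests therefore
demonstrate that the *analysis machinery* recovers known kinetics,
partitions, geometries and Markov models from data with the assumed
statistical structure — not that any particular receptor behaves this
way.

The lipid-series generator plants one site-bound pseudo-lipid per bound
epoch (fresh lipid id each epoch, so analyses keyed on (residue, lipid)
contact intervals see realistic turnover); bound epochs are exponential
with the site k_off, gaps exponential with mean 20 ns, bound distances
uniform in (0.35, 0.50) nm and everything else far (3 nm). Dwells are
discretized to whole frames (ceiling), which biases mean dwells upward
by about half a frame interval — at the default 10 ns dwell and 1 ns
frames, a ~5% effect visible in recovered site k_off.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the Brownian
simulator at 10⁵ frames (100 µs) per seed with 5 seeds per copy number
for the event-scaling measurement, 10³–5×10³ dwell samples for k_off
recovery, 10⁵-step chains for MSM round trips and 6×10⁴-frame contact
series (~2000 bound epochs) for binding-site recovery — sizes at which
the statistical estimators are well within their asymptotic regimes
while the whole suite completes in minutes on one CPU.

## Known limitations

- Eq.-style start-time survival estimators and the duration-based
  survival used here coincide in decay shape but not in absolute
  normalization; only the decay is used.
- The biexponential's amplitude constraint (A + B = 1) assumes σ(0) = 1
  exactly; fitting an unconstrained amplitude would absorb short-dwell
  censoring but is not provided.
- Louvain resolution is fixed at 1.0; strongly overlapping binding
  sites would require a resolution scan.
- MSM uncertainty (Bayesian or bootstrap) is out of scope; only point
  estimates with round-trip validation are provided.
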