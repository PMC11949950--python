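# Methods

This note documents the models implemented in `elanull`, the default
parameters and why they were chosen, the numerical conventions that make
every result reproducible, and the limits of what the synthetic tests can
show about real recordings.

## Pairwise maximum-entropy model and energy landscape

The core object is the maximum-entropy distribution over ±1 patterns
matching the first and second empirical moments of binarized data —
identical in form to an Ising model with fields h and couplings J
(symmetric, zero diagonal). Binarization thresholds each channel at its
temporal mean, values exactly at the threshold mapping to −1; the result
is invariant to per-channel positive-gain affine rescaling.

Fitting is plain gradient ascent on the exact log-likelihood with model
moments computed by full 2^N enumeration (N ≤ 20 enforced; the intended
regime is N ≲ 12). The step size starts at 0.2 and is halved whenever a
step decreases the log-likelihood (the step is retried from the last
accepted point); convergence is declared when the largest absolute
moment discrepancy falls below `tol` (default 1e-6, reachable in a few
hundred iterations for N=7, T=8000 data). Boundary moments — a channel
always +1, two channels perfectly correlated — have no finite maximum-
likelihood parameters; the fit then raises a convergence error naming the
worst-matched moment rather than returning a silently diverged model.

The landscape enumerates all 2^N energies. Local minima use strict
inequality against all N single-flip neighbours. Basins follow steepest
descent: repeatedly move to the lowest-energy strictly-lower neighbour,
ties broken by the smallest state index. Exact energy ties that strand the
descent (possible only for measure-zero parameter sets such as the all-zero
model) raise an error instead of silently assigning a basin. The
disconnectivity tree activates states in ascending energy order and merges
single-flip-adjacent components with union-find; when two components each
holding a minimum first join, the activating state's energy is the saddle
between every cross pair — exactly the minimax path energy, hence the
barrier matrix is an ultrametric. State coding is LSB-first: pattern σ maps
to index Σᵢ 2ⁱ(σᵢ+1)/2, and outputs also render states as ±1 strings to
avoid ambiguity.

## Null models

* **Static**: i.i.d. draws from N(mean(x), cov(x)). The mean is the
  sample mean — the reference methodology specifies only the covariance,
  but binarization thresholds are per-dataset so the choice is harmless;
  it is fixed here for determinism. Rank-deficient covariances (T < N+1)
  are eigenvalue-clipped with a warning.
* **ARR** (autoregressive randomization): A₁ = C₁C₀⁻¹ from mean-centred
  lag-0/lag-1 sample covariances; innovation covariance is the symmetrized
  Lyapunov residual C₀ − A₁C₀A₁ᵀ with negative eigenvalues clipped at 0;
  ill-conditioned C₀ gets a ridge of 1e-8·trace(C₀)/N with a warning.
  Generation starts from a randomly selected real sample and iterates the
  fitted recursion with no burn-in, so the surrogate length is exactly
  `length_factor × T`.
* **PR** (phase randomization): each strictly positive DFT frequency is
  rotated by a phase uniform on [0, 2π), *shared across channels*; DC and
  (for even T) Nyquist are untouched so the output stays real without sign
  flips. This preserves every auto- and cross-spectrum exactly, hence all
  circular lagged covariances to machine precision. Output length equals
  input length by construction.
* **Dichotomized Gaussian** (binary static null): thresholds
  zᵢ = Φ⁻¹(1−pᵢ); each pairwise latent correlation is found by bisection on
  (−1, 1) so that the bivariate-normal upper-orthant probability beyond
  (zᵢ, zⱼ) equals the joint probability implied by the target binary
  moments (residual tolerance 1e-10; exact ±1 for targets on the Fréchet
  bounds, which are checked and reported per pair when violated). The
  assembled latent matrix is repaired to the nearest unit-diagonal PSD
  matrix by eigenvalue clipping and rescaling, then rows are sampled
  i.i.d. and thresholded.

Rationale for the four nulls: static tests whether a feature needs more
than covariance; ARR adds lag-1 structure; PR adds the entire linear
temporal structure; the dichotomized Gaussian asks the same
covariance-only question *after* the binarization nonlinearity. The
pipeline's central finding on linear test data — landscapes reproduced by
all nulls, transition matrices only by ARR/PR — falls directly out of
which statistics each null preserves.

## Dynamics and comparisons

Each binary volume is labelled by the basin containing it; consecutive
labels give a count matrix, row-normalized into transition probabilities.
Basins never visited as a source keep flagged all-zero rows, which are
excluded pairwise from elementwise correlations (the reference methodology
does not address empty rows; pairwise exclusion is this package's choice).
Off-diagonal comparisons require more than three basins, implemented
literally as B ≥ 4 and exposed as a configuration knob; fewer basins raise
a recordable ineligibility signal rather than a hard error. Surrogate
dynamics can be compared two ways: labelled by the surrogate's own basins
(only meaningful when the minima sets coincide — both a strict
basin-identity and a minima-only mode are provided, since either reading
of "identical landscapes" is defensible) or projected through the real
data's basins, which is always applicable.

Population summaries are mean ± sd (n−1 denominator) per (null, metric)
cell; paired and two-sample t-tests use scipy, with the two-sample test
pooled-variance by default (Welch by flag). No multiple-testing
correction is applied; raw p values are recorded.

## Synthetic-data generators (the study conditions)

* **HCP-like VAR(1)** (`hcp_like_var_model`): diagonal lag-1 coefficients
  uniform in [0.5, 0.8] (channel autocorrelations typical of fast-TR
  fMRI), small random off-diagonal couplings (sd 0.1/√N), spectral radius
  rescaled below 0.95, innovation covariance WWᵀ/N + 0.2I, and the whole
  model rescaled so stationary variances are 1 — covariance tolerances in
  tests are then scale-free. Standard sample: N=7 channels, T=8000
  volumes, dt=0.72 s. The initial state is drawn from the exact Lyapunov
  stationary distribution, eliminating burn-in transients
  deterministically.
* **Two-regime switching** (`two_regime_model`): a 2-state Markov chain
  (stay probability 0.95 each, off-diagonal mass split uniformly — the
  simplest fully specified chain) emitting i.i.d. Gaussians with means
  ±(separation/2)·u along a random unit direction u (default separation 4
  in units of the within-regime sd) and random unit-variance correlated
  covariances. This is a genuinely non-Gaussian, nonlinear process whose
  linear surrogates are unimodal by construction.
* **Exact Ising sampler**: inverse-CDF over all 2^N enumerated Boltzmann
  probabilities — i.i.d. rows, no Monte-Carlo chain, so goodness-of-fit
  and parameter-recovery tests have clean statistics.

What these generators emulate: realistic second-order structure
(covariance, autocorrelation) and, for the switching model, multi-state
organization. What they do not emulate: hemodynamics, measurement noise
spectra, heavy tails, spatial maps, or the smooth low-dimensional
trajectory geometry of real fMRI. Consequently, passing tests show the
pipeline's *internal* consistency and its behaviour under known linear and
piecewise-Gaussian ground truth — not that real recordings behave the
same way.

## Mapper topological analysis

Filter: Euclidean distances between volumes → symmetrized k-nearest-
neighbour graph (k default 12) → all-pairs shortest-path geodesics →
classical (eigendecomposition) MDS to 2 dimensions. Classical MDS is used
instead of stochastic stress minimization so the embedding is
deterministic; axes are ordered by eigenvalue and sign-fixed so each
axis's largest-magnitude coordinate is positive. Disconnected kNN graphs
are bridged by the single shortest inter-component Euclidean edge,
repeated until connected and logged per bridge. Cover: 14×14 axis-aligned
bins over the bounding box (resolution 14 following the published
protocol), each enlarged so adjacent bins share half their width; a
volume belongs to every bin containing it (≤ 4 bins). Partial clustering:
single-linkage on original-space distances within each bin, cut at the
first empty bin of the 10-bin linkage-distance histogram (the standard
Mapper heuristic; the reference protocol leaves this unspecified). Shape
graph: clusters from different bins sharing any volume are linked; the
summary statistic is the proportion of nodes with degree > 20, compared
across conditions with one-way ANOVA.

### Known limitation: the high-degree contrast on mixture data

With this cover geometry a volume lies in at most 4 bins, so without
cluster fragmentation a node's degree is bounded near 8; degree-above-20
nodes arise only where single-linkage fragments sparse high-dimensional
bins into many small clusters. For the i.i.d. Gaussian-mixture switching
generator this fragmentation is a sampling-density effect that is
statistically similar for the mixture and for its moment-matched linear
surrogates: across wide sweeps of separation, dwell time, length, k,
overlap and histogram granularity, the per-seed direction
"real > mean(ARR, PR)" occurs at roughly chance rates (and suppressing
fragmentation with a coarser histogram yields zero high-degree nodes in
all conditions). The corresponding end-to-end test is retained at the
stated conditions and currently fails; the high-degree phenomenon
reported for real recordings evidently depends on geometric features —
smooth trajectories, low intrinsic dimension, non-Gaussian tails — that
an i.i.d.-within-regime mixture deliberately lacks. The shuffle-invariance
and construction-level properties of the Mapper implementation are fully
tested and pass.

## Determinism policy

Every stochastic routine takes an integer seed and uses an isolated
`numpy.random.Generator`. The experiment driver derives one 31-bit seed
per (stage, sample) cell via `SeedSequence(master, spawn_key=(stage_code,
sample))`, so adding samples or stages never perturbs existing draws and a
saved manifest reproduces every number bit-exactly. Two further
conventions make results exactly independent of input row order:
binarization thresholds are computed with correctly-rounded `math.fsum`
column sums (all subsequent PMEM statistics are exact integer sums), and
the Mapper filter internally processes volumes in canonical lexicographic
order before mapping the embedding back. The energy landscape and the
Mapper degree multiset are therefore bit-identical under temporal
shuffling — the formal statement that neither analysis uses temporal
information.

## Problem sizes

Default study conditions — 20 pseudo-real samples of N=7, T=8000 for the
surrogate comparison (dichotomized-Gaussian surrogates generated at 100×
length to suppress sampling error, mirroring standard practice); 10 seeds
of N=7, T=1000 switching data for the Mapper contrast; T=1e5 for
Monte-Carlo moment checks — were chosen so the full pipeline and test
suite complete in about half a minute on a single CPU while keeping all
Monte-Carlo tolerances comfortably away from their noise floors.
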