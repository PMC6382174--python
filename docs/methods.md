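# Methods

## The Gaussian transition model

Everything is estimated from an m × n real-valued time series (rows =
time points, columns = channels).  At lag τ the aligned pairs
(x_{t−τ}, x_t), t = τ+1…m give m − τ samples; each channel is demeaned
over its own window and sample covariances use the (pairs − 1)
denominator.  The full model is the linear regression X_t = A X_{t−τ} + E
with A from the normal equation A = Σ_cross Σ_past⁻¹ and residual
covariance Σ_E = Σ_present − A Σ_crossᵀ — the conditional covariance of
the present given the past.  We deliberately use Σ_present (not Σ_past)
in the residual formula: the two agree under stationarity, and the
Σ_present form is the one that is correct without it.  A condition number
of Σ_past above 1e12 raises an error; no ridge term is ever added
silently.  All entropies and information quantities are in bits.

## Integrated information Φᴳ

Φᴳ across a bipartition is the minimized KL divergence between the full
model and a disconnected model whose regression matrix A′ is
block-diagonal with respect to the partition.  For fixed A′ the optimal
disconnected residual covariance is Σ_E′ = Σ_E + (A−A′) Σ_past (A−A′)ᵀ
(the residual covariance of the misspecified regression), so the search
runs only over the within-block entries of A′ with objective
½ log₂(|Σ_E′|/|Σ_E|).  This profiling avoids a coupled fixed-point
iteration over (A′, Σ_E′); note the disconnected residual covariance is
*not* constrained to be block-diagonal — only the cross-part regression
terms are removed.

Two optimizers stand behind `phi_g`, chosen by problem size:

* **≤ 400 free parameters** (every system an exhaustive search visits): a
  damped Newton method with the analytic Hessian
  H[(i,j),(k,l)] = G_ik (S − S Dᵀ G D S)_lj − B_il B_kj, where G = M⁻¹,
  B = G D S, D = A − A′, M = Σ_E + D S Dᵀ, S = Σ_past.  Levenberg damping
  handles indefiniteness, an Armijo backtracking line search guarantees
  monotone descent, and convergence is quadratic (typically 4–8
  iterations).
* **larger systems**: L-BFGS-B over the free entries with the analytic
  gradient −(M⁻¹ D S) restricted to the blocks.

Both declare convergence when the gradient max-norm falls below `tol`
(default 1e-8) or the per-iteration objective decrease falls below `ftol`
(default 1e-12); a stalled line search is treated as the latter.  The two
paths agree to ~1e-14 bits on shared problems and are cross-checked in
the tests against an independent multi-resolution grid search.
Initialization is the block-diagonal part of A (always feasible, usually
near-optimal); one restart from zeros is attempted on failure, the
reported Φ never exceeds the objective at the initialization point, and
values in (−1e-6, 0) from floating point are clipped to zero (anything
more negative raises).

The normalization K is the smaller of the two groups' Gaussian entropies
of the past covariance, ½ log₂((2πe)^k |Σ_block|).  Partitions with
K ≤ 1e-6 bits are flagged invalid rather than divided by; MIB searches
skip and count them.  Normalized Φ is a dimensionless ratio but is
labelled "bits (normalized)" in reports, matching common usage.
Time-lag selection (`select_time_lag`) scans a user-given lag grid, finds
the MIB at each lag, and returns the Φ-maximizing lag (ties toward the
smallest), flagging the scan when every Φ is below 0.01 bits.

## The MIB search

`brute_force_mib` enumerates all 2ⁿ⁻¹ − 1 canonical bipartitions (channel
0 pinned to group 1) and minimizes Φ/K; ties break by smaller Φ, then
lexicographically.  It refuses n > 18.

`spectral_mib` is the scalable approximation.  From the Pearson
correlation matrix C it builds 11 source matrices — power adjacency
transforms w = ((r+1)/2)^β at 10 β values log-spaced on [1, 10], plus C
itself with negative entries floored at 0 (the Laplacian needs
non-negative weights; the power transform does not) — thresholds each at
the 199 percentiles {0, 0.005, …, 0.99} of its off-diagonal weights
(strictly-below-cutoff weights are zeroed; the 0th percentile leaves the
matrix untouched), and spectrally bipartitions each of the 2189 cells.
Degenerate cells (all-zero graphs) are counted as skipped.  Candidates
are deduplicated before Φ evaluation — the minimum is unchanged and the
unique count is typically 20–130.

`spectral_bipartition` clusters the eigenvectors of the two smallest
eigenvalues of the combinatorial Laplacian L = D − W with a deterministic
2-means (seeded random first center, farthest-point second center), also
scores all sweep cuts along the Fiedler ordering (the classical
splitting-point selection for the normalized-cut objective), keeps the
candidate with the smallest Ncut value and polishes it with greedy
single-node moves.  The combinatorial Laplacian was chosen over the
symmetric-normalized variant after a head-to-head comparison on the
small-network validation (16/20 vs 14/20 exact MIB matches, with an order
of magnitude smaller mean Φ/K gap); the whole pipeline is bit-reproducible
given a seed.  Rand indices between partitions are the standard
pair-agreement fraction.

## Synthetic networks

**Brain-like connectomes.**  Nodes are assigned uniformly to ⌈ln n⌉
modules ("log" read as the natural log).  Within a module of size s,
edges appear with probability 4.5/s (4/s when s < 4); across modules with
probability 3.3/(s̄M) (3.75/(s̄M) when s̄ < 4), with s̄ the mean of the
two module sizes and M the module count.  A Hebbian redistribution then
prunes the poorly connected and rewards the hubs: with q the
38th-percentile degree, f the maximum degree and Z = max((n + ln n)/7, f),
a 3-parameter logistic S is least-squares fitted to a profile over
x = [q−1, …, f+5] that is 1 on a short head plateau (at most ⌊f/4⌋
entries, confined to degrees strictly below q), Z on a tail plateau
covering degrees f…f+5, and linear in between; every node's degree is
then pulled toward round(S(degree)) (floor 1) by random edge
additions/deletions in seeded random order.  The head/tail confinement
and the Z floor at f are this package's repair of the profile: applied
verbatim, the published plateau lengths squash almost every node's target
degree to ~1 and no draw is connected.  Connectivity is enforced by
regeneration (fresh sub-seed, 100-attempt cap).  The outputs are
connected, modular (>50 % of edges within modules) and right-skewed in
degree — but sparser (mean degree ≈ 4) than the originals they emulate
appear to be, which is the main caveat on the small-network validation
below.

**Cut networks.**  A brain-like network is severed into two halves
(whole modules assigned to halves as evenly as possible, assignment order
shuffled by the seed), every cross-half edge deleted, and the draw
regenerated until both halves are internally connected.  The cut is
returned as ground truth: with enough data its Φ converges to zero.

**Watts–Strogatz graphs** use the standard connected generator (ring
lattice of even degree k, each edge rewired with probability p,
regenerated until connected), via networkx.

## Dynamics

**Stochastic Rössler oscillators** (per node: a = 0.2, b = 0.2, c = 9,
intrinsic frequency w ~ Normal(10, 0.1)):

```
ẋᵢ = −wᵢyᵢ − zᵢ − σ Σₕ gᵢₕ xₕ      (g = Laplacian coefficients)
ẏᵢ =  wᵢxᵢ + a yᵢ + d ηᵢ
żᵢ =  b + (xᵢ − c) zᵢ
```

Euler-integrated at dt = 0.001 with noise amplitude d = 750 injected into
the y equation as d·η·dt per step (plain Euler; the Euler–Maruyama √dt
scaling is available behind a flag but diverges at this d — per-step
noise of sd 23.7 overwhelms the attractor).  Initial states are uniform
in [−1,1]³, the first 5,000 steps are discarded, and the y component is
recorded every `record_every` steps (default 50; the validation
experiments use 100, i.e. a 0.1-time-unit sampling interval).  The
sampling interval was set by the same rule used for lag selection: it is
the lag at which Φ across the MIB peaks for this oscillator family.
Recording every integration step would leave 25,000 samples spanning only
25 time units — so strongly autocorrelated that every Φ difference
between partitions drowns in estimation noise.  Divergence (any state
above 1e6 or non-finite) raises an error naming the step; runs are
bit-reproducible by seed.

The coupling σ comes from the master stability function for x-coupled
oscillators of this family: the synchronization interval requires
σλ ∈ (0.186, 4.614) for every nonzero Laplacian eigenvalue, giving
σ_lower = 0.186/λ₂ (Fiedler value) and σ_upper = 4.614/λ_max; experiments
use the midpoint.  For cut (disconnected) networks the bounds are
computed per connected component and the intervals intersected.  The
structure sweep instead fixes σ = 0.25 for all networks so that Φ
differences reflect topology, not coupling.

**VAR(1)** dynamics use A = 0.2·I + coupling·(W/degree), rescaled to
spectral radius 0.9 if above it, with unit Gaussian innovations and a
1,000-step burn-in.

## Validation experiments and problem sizes

All three experiments derive per-network seeds from a master seed through
a `SeedSequence`, so reports are bit-reproducible.  Aggregates are always
recomputable from the per-network records they summarize.

* **Small-network validation** (desk scale: 10 brain-like 14-node
  networks, 25,000 samples, full 2189-cell grid): counts networks where
  the spectral candidate set attains the exhaustive minimum of Φ/K
  exactly (difference ≤ 1e-9; both searches use the same estimator, so a
  true match is exact).  Across seed batches the match rate runs
  ~70–90 %, with mean Φ/K excess ~2e-4 and mean Rand index ~0.93 on the
  non-matches' account.
* **Cut-network validation** (10 severed 50-node networks, 50,000
  samples, 4-β/0.02-step grid, optimizer tol 1e-5): mean |Φ/K difference|
  between the spectral partition and the planted cut, and the fraction
  with Rand > 0.8.  At these sizes the spectral search recovers the
  planted cut essentially always.
* **Structure sweep** (19 rewiring probabilities — 10 log-spaced in
  [0.001, 0.1], 9 linear in (0.1, 1] — 5 networks each, 50 nodes, mean
  degree 6, σ = 0.25, 25,000 samples, coarse 4-source/0.05-step grid,
  optimizer tol 1e-5): Spearman correlations of non-normalized Φ across
  the spectral MIB with binary-hop global efficiency and with Newman
  modularity Q.  The looser optimizer tolerance changes Φ by < 1e-6 bits
  — far below what Spearman ranks can feel.  Efficiency counts
  unreachable pairs as zero contribution; modularity detection uses
  igraph's leading-eigenvector bisection with Q evaluated independently
  through networkx.

`paper_scale_config` exposes the full-size protocols (50 networks per
size of 14 and 16 nodes; 40 cut networks per size from 50 to 300 at
100,000 samples; 50 networks per p at 100 nodes with the full grid).

## What the synthetic data do and do not show

The generators emulate modular connectivity, right-skewed degrees,
near-Gaussian weakly coupled oscillations and planted informational
boundaries.  They do not emulate measurement noise, volume conduction or
common reference artifacts, non-stationarity, or non-Gaussian dynamics —
so passing validations demonstrate the estimator and search behave as
designed on in-model data, not that the MIB of a real recording is
correct.  Known limitations: the Φ estimate carries a finite-sample
upward bias that grows with channel count and sample autocorrelation
(visible as small positive Φ across truly severed cuts); near-minimal
Φ/K plateaus can make the exact data-estimated MIB ambiguous at realistic
sample sizes; and the brain-like generator is sparser than the networks
it is modelled on, which lowers the exact-match rate of the small-network
validation relative to its published counterpart.
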