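# Methods

## The model

`guildspec` simulates and analyzes an environment-mediated
consumer-resource model (ECRM): N microbial species with abundances
x_i(t) compete for M resources with concentrations R_α(t),

    dx_i/dt = x_i ( Σ_α r_iα γ_iα R_α − d_x )
    dR_α/dt = K_α(t) − ( d_R + Σ_i r_iα x_i ) R_α

where r_iα is the uptake rate of resource α by species i, γ_iα the
yield, d_x the species death rate and d_R the resource depletion rate.
Growth is multiplicative (resources act through exponential growth), so
species abundances are structurally positive; we integrate them in log
space. The gain matrix G_iα = r_iα γ_iα summarizes per-resource growth
contributions, and the resource-utilization overlap GG⊤ is the
ground truth the inference half of the package tries to recover: large
off-diagonal entries mark species pairs competing for the same
resources.

**Guild structure.** The binary adjacency g_iα (r_iα = r g_iα) is
organized in blocks: the species are split into k guilds and the shared
resources into k matching blocks; g_iα ~ Bernoulli(p_in) inside a
species' preferred block and Bernoulli(p_out) outside. With two guilds a
single bias q sets p_in = 0.5 + q, p_out = 0.5 − q: q = 0.5 means
disjoint guilds, q = 0 no structure at all. Every species additionally
owns one private resource (consumed by nobody else) that prevents
extinction; private resources use the same uptake rate and yield
distribution as shared ones (the model defines no separate parameters
for them). Yields are Gaussian(1, 1/6), redrawn until non-negative.
Species are ordered block-contiguously by guild, but the stored label
vector is authoritative, not the order.

For larger systems the block probabilities scale as
p_in = (0.5 + q)(N/6)^(−1/2), p_out = (0.5 − q)(N/6)^(−1) with M ∝ N and
k ∝ √N, which keeps the expected overlap-graph degree bounded as N
grows; closed forms for the no-overlap probability of same-/
different-guild pairs and for the expected degree are provided and are
checked against Monte-Carlo sampling in the tests. In these formulas M
counts **shared** resources only (M_shared = M − N): private resources
cannot create overlap between distinct species. Heterogeneous variants
use geometric series for guild sizes (ratio q_N) and per-guild resource
counts (ratio q_M), rounded up and corrected so sizes sum exactly
(deficits go to the largest guild, excesses are removed from the
smallest guild that still has more than two members).

**Environmental drive.** The supply K_α(t) is either sinusoidal,
K_α0 + A_α sin(ω_α t − φ_α), or an Ornstein-Uhlenbeck process
K_α0 + Q_α with dQ_α/dt = −ω_α Q_α + A_α ω_α η_α(t), whose stationary
variance is A_α²ω_α/2 and autocorrelation e^(−ω_α τ). The OU update uses
the exact discretization on the integrator grid and is held piecewise
constant within each step; each resource has an independent noise
stream. For mixed-timescale sinusoidal drives the ω_α are sampled
log-uniformly over a configured range with uniform phases. Note that
matching "power" between the two drive families holds exactly at ω = 1
(sinusoid mean-square A²/2 vs OU variance A²ω/2) and drifts apart for
other ω; we implement the OU variance literally.

## Default parameters

| parameter | symbol | default | rationale |
| --- | --- | --- | --- |
| uptake rate (nonzero entries) | r | 0.1 | model definition |
| yield distribution | γ | N(1, 1/6), ≥ 0 | model definition |
| species death rate | d_x | 0.3 | turnover time 1/d_x = 3.33 |
| resource depletion rate | d_R | 0.5 | model definition |
| base supply | K_α0 | 1.0 | sets the concentration scale |
| drive amplitude | A_α | 0.5·K_α0 | visible fluctuations, supply rarely negative |
| integrator step | — | 0.01 | resolves ω up to ~10 with RK4 |
| burn-in | — | 10/d_x | discards the transient |
| initial state | x_i(0), R_α(0) | 1, K_α0/d_R | near supply balance |

The base supply and amplitude are not dictated by the model and are
config-exposed; all results in this repository use the defaults above.
Under the OU drive the supply occasionally dips negative (about 0.2% of
the time at A = 0.5); the integrator floors resource concentrations at
exactly zero when the dynamics would cross it, counts the events on the
returned trajectory, and warns — it never clips silently. Fixed-step
RK4 with the log-abundance formulation keeps species positive by
construction; step-halving changes trajectories by less than 1e−7
relative over the tested horizons.

**Randomness.** Every stochastic component draws from a named substream
of a single root seed (adjacency, yields, drive noise, shuffles), so
adding one more drive realization never changes the sampled network,
and all outputs are bit-for-bit reproducible given (seed, config).
Ensemble drivers derive per-realization child seeds from the root.

## Pairwise metrics

Abundance series are log-transformed and z-scored per species
(population standard deviation, so the equal-time correlation has an
exact unit diagonal). Zero or constant abundances are an error by
contract: the metrics are defined on gap-free, zero-free series. Four
pairwise measures:

* **C(0)** — equal-time correlation (1/T) Σ_t s_i s_j;
* **|C(0)|** — its absolute value;
* **𝒫** (total CPSD magnitude) — Σ_k |P_ij(f_k)| Δf;
* **𝒯𝒞** (total coherence) — Σ_k Coh_ij(f_k) Δf, with
  Coh_ij = |P_ij|²/(P_ii P_jj) ∈ [0, 1].

Spectra come from Welch averaging: Hamming window, 50% overlap,
per-segment mean removal, one-sided density scaling, segment length
round(1/(Δf·Δt)) samples. The frequency grid runs from 0 (DC included)
to the Nyquist frequency f_max = 1/(2Δt) in steps of Δf = f_max/15 by
default — a resolution at which the totals are stable under doubling or
halving of Δf (rank correlation of pair scores > 0.9 on simulated
data). The totals are rectangular sums over all 16 bins, so the
coherence diagonal equals (kmax+1)Δf = (16/15) f_max; only rankings
enter the downstream detection tasks, so this constant is
inconsequential. Coherence requires at least two Welch segments (a
single segment yields coherence ≡ 1 and is rejected), and series
shorter than two segment lengths raise an insufficient-data error. The
signed rectangular sum of Re P_ij recovers C_ij(0) (Parseval), which
the tests verify within 5% on stationary signals; per-segment mean
removal costs about 1/nperseg of total power.

The lagged cross-correlation C_ij(τ) divides by the number of
overlapping samples (T − |τ|) rather than T, avoiding the triangular
taper when it is inspected directly.

## Detection and scoring

A metric matrix becomes an undirected link graph by strict thresholding
of off-diagonal values. Guilds are the connected components of that
graph (full single-linkage transitive closure); a one-iteration variant
instead classifies a pair as same-guild when linked directly or through
one shared neighbor — that relation is deliberately non-transitive and
is used for pair classification only. Performance measures:

* **Spearman** rank correlation between metric and overlap
  off-diagonals (i < j);
* **link ROC/AUC** — detecting strictly positive overlap entries
  (tolerance 1e−12), swept over all distinct score values;
* **guild ROC/AUC** — same/different-cluster classification of pairs
  after threshold-and-cluster, swept over 200 evenly spaced thresholds
  plus ±∞ endpoints (each threshold requires a clustering pass, so the
  sweep is discretized; cluster growth is monotone in the threshold);
* **local detectability** — per-guild within-link TPR and
  outside-link FPR.

Ensembles report per-realization AUCs and their mean; pooled pair-level
scoring across realizations is also available for the link task. At
small N with dense overlap (q = 0.4, N = 6) a draw can link every pair,
leaving no negative class: the link AUC is then recorded as NaN rather
than fabricated.

## Empirical pipeline

Relative-abundance tables (taxa × day-replicate columns) are averaged
per day, restricted to taxa present on every day, and log-z-scored
exactly like simulated abundances — relative values change the scores
(the column-sum constraint couples taxa) but not the machinery. Day
labels must be consecutive and equally spaced; gaps are an error, never
imputed. Phylogenetic distance is Jukes-Cantor,
d = −(3/4) ln(1 − 4p/3), with p the mismatch fraction over pairwise
comparable sites (sites with gaps or ambiguity codes in either sequence
are excluded per pair; U reads as T); p ≥ 3/4 is reported as an error.
Pairwise metrics are binned in equal-width distance bins (default 8,
config-exposed) and compared against an index-shuffle null: random
joint permutations of the metric matrix rows/columns, which preserve
the multiset of metric values while destroying any relation to
phylogeny. The first-bin p value is the strict upper-tail proportion of
shuffles whose first non-empty bin mean exceeds the observed one
(no add-one correction, matching the plain proportion definition); the
estimator is validated against exhaustive enumeration of all
permutations at N = 6. For network export, `cluster_to_k` finds the
threshold whose single-linkage partition has a requested number of
clusters by binary search over the sorted unique metric values
(cluster count is non-increasing as the threshold drops); when ties
make the exact count unreachable the nearest achievable count is
returned with a warning.

## Problem sizes used in tests and the acceptance script

Simulated experiments run at desk scale: the workhorse community is
N = 6, M = 30, k = 2; ensemble checks use 10–20 realizations with
acquisition times t_f between 5 000 and 20 000 time units at sampling
interval 1 (the sampling-interval sweep subsamples one t_f = 20 000
trajectory per realization at Δt ∈ {0.25, …, 8}). These sizes make the
suite run in minutes while leaving the ensemble means' Monte-Carlo
error well below the effect sizes being asserted — with the exception
of the interval-optimum statistic discussed under limitations, whose
fragility is intrinsic to the saturated regime rather than to the
ensemble size (it persists at 50 realizations).

## Known limitations and observed behavior

* Under the default drive parameterization the guild-detection task at
  N = 6, q = 0.4 is easy for the spectral metrics: the total-coherence
  guild AUC saturates at 1.0 for every tested sampling interval once
  t_f ≳ 1 000, and the total-CPSD AUC sits within ~0.01 of 1.0 across
  the grid, so "the interval that maximizes the AUC" is decided by ties
  (broken to the smallest tied interval) or by one or two
  below-ceiling realizations and varies between ensembles. Interval
  optima are intrinsically fragile in this saturated regime; the AUC
  surface itself (exported by the sweep drivers) is the robust object,
  and a clear interior optimum only emerges when the data volume or
  signal amplitude is reduced.
* No demographic noise, migration, extinction/invasion, or spatial
  structure; no missing time points, uneven sampling, or zero handling
  (Lomb-Scargle-style estimators are out of scope).
* The simulator is the data generator for all tests: passing tests
  demonstrate recovery of the generator's own ground truth under its
  stated dynamics, not performance on real communities, where
  compositionality, measurement noise and unmodeled interactions
  intervene. The empirical pipeline therefore reports associations
  against a phylogenetic proxy with a permutation null rather than
  claiming recovered guilds are true metabolic guilds.
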