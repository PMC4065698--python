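# Methods

## Model and assumptions

`hsmmseg` fits a hidden semi-Markov model to a position-indexed signal.  The
hidden layer is a semi-Markov chain: an embedded first-order Markov chain over
*distinct* states (transition matrix `A` with zero diagonal) plus an explicit
occupancy (sojourn) distribution `d_j(u)` attached to every state, defined on
discrete durations `u ∈ {1..M}` and truncated-renormalized there.  The
observation layer attaches a per-state emission density: normal or Student-t
(univariate or multivariate) for continuous signals, Poisson or negative
binomial for counts.  With a geometric sojourn `d_j(u) = p^{u-1}(1-p)` the
model reduces exactly to an ordinary HMM whose self-transition probability is
`p`; this reduction is used as an independent oracle in the tests.

The likelihood treats the first sojourn as complete and the last as
right-censored: the final run of a sequence contributes the survivor function
`D_j(u) = Σ_{v≥u} d_j(v)` instead of the pmf, because the sequence ends while
the state is still occupied.  No left-censoring is modeled.

Model assumptions worth keeping in mind: segment lengths are conditionally
independent given the state sequence; emissions are conditionally independent
across positions given the states; sample columns within a multivariate group
are jointly Gaussian (or t) with a shared segmentation.

## Inference

The forward recursion runs over *run endpoints*: `F_t(j)` is the probability
of the data up to `t` jointly with a sojourn of state `j` ending exactly at
`t`, and `G_t(j)` aggregates transitions into a run starting at `t+1`.
Emission products over candidate runs are window differences of cumulative
per-state log-densities, so each forward cell costs one pass over the
duration support.  All recursions are evaluated in log space with streaming
log-sum-exp (the numerically safest variant of per-step scaling) and compiled
with numba.  Per-state duration supports are clipped to the last duration
with positive truncated mass, so the effective cost is
`O(J · T · min(T, M_eff))` time and `O(J · T)` memory, with `M_eff` the actual
sojourn support rather than the nominal bound.

The smoothed posterior `γ_tj = P(S_t = j | x)` is accumulated segment-wise:
each candidate run `[s, e]` of state `j` has posterior probability
`G_{s-1}(j) · (emission window) · d_j(e-s+1) · B_e(j) / L` (survivor instead
of `d·B` when `e = T`), added to a difference array in O(1) and cumulated —
this yields `γ`, the expected duration weights `η_j(u)` (complete runs and
the censored final run separately) and the expected embedded transition
counts in a single pass.  Viterbi replaces sums by maxima and backtracks
stored duration/predecessor choices; all ties break toward the lower state
index (and shorter duration) for determinism.

Positions with vanishing emission density in every state abort with the
offending position index rather than silently flushing to zero.

## EM estimation

EM alternates the E-step above with block updates:

- **Emissions** — weighted maximum likelihood (normal, multivariate normal,
  Poisson) or weighted moments (negative binomial; t with fixed df).
- **Transitions** — expected embedded transition counts, row-normalized;
  `π` re-estimation is off by default (one sequence gives a single
  observation of the initial state) but available.
- **Sojourns** — *parametric* M-step: method-of-moments point estimates on
  the expected duration weights of complete runs.  The censored final run is
  excluded (its length is only a lower bound) unless no complete run carries
  appreciable mass.

The moment updates (sojourn families; nbinom/t emissions) need not maximize
their block of the expected complete-data log-likelihood exactly, so each is
accepted per state only if its block objective — for sojourns
`Σ_u η_j(u) log d_j(u) + Σ_u η^c_j(u) log D_j(u)` — does not decrease;
otherwise the previous parameters are kept.  This generalized-EM guard makes
the log-likelihood trace provably non-decreasing (up to floating point)
without changing the estimator when the moment fit behaves, which is
essentially always away from degenerate weights.

Defaults: `max_iter = 100`, convergence when the relative log-likelihood
change drops below `1e-4`.  Degenerate cases: states with total posterior
weight below `1e-8` keep their previous emission parameters; weighted
variances are floored at `1e-2·mean²` before gamma/nbinom moment inversion;
standard deviations and covariance diagonals are floored at `1e-3` to prevent
collapse onto single points (covariances additionally jittered until Cholesky
succeeds).  Fixed t/mvt degrees of freedom default to 5; df re-estimation is
out of scope.

## Initialization and priors

- **Emission locations** — `quantile` mode (default) places state `j` at the
  pooled empirical quantile `(2j-1)/(2J)` with pooled dispersion shared
  across states; `cluster` mode runs k-means (deterministic seed) and uses
  cluster centroids and within-cluster dispersions — preferable when the
  value distribution is asymmetric (e.g. methylation differences, p-values).
  After either init, states are relabeled so locations ascend; all
  "state 1 = lowest, state J = highest" semantics downstream rely on this.
- **Sojourn prior** — flat by default: the uniform vector for the
  nonparametric family, otherwise parameters moment-matched to the discrete
  uniform on `{1..M}` (the natural parametric embedding of "flat").
  Alternatively learned from annotation intervals: widths are moment-fitted
  per label class and classes are rank-mapped by mean width (shortest class →
  state 1); unlabeled intervals are first partitioned into `J` classes by
  k-means on log-widths; states without intervals fall back to flat with a
  warning.
- **Duration bound** — `M = max_k` if given, else the largest number of
  consecutive features spanning at most `max_bp`, else `min(T, 1000)`
  (`max_k`/`max_bp` are mutually exclusive).  The default cap bounds the
  `O(JTM)` worst-case work on long sequences.
- **Duration units** — durations are feature counts.  When priors are
  learned from base-pair annotation on irregularly spaced features, the
  fitted parameters are rescaled by the median inter-feature spacing
  (exact parameter transforms per family).  Without positional information
  the model operates on feature ranks, which is the same thing.

## Batch segmentation

`segment_profile` loops over sequence names, then over sample groups.
Groups are modeled jointly only for multivariate emissions; for univariate
families the columns are fitted iteratively, columns after the first
inheriting the sojourn distribution fitted on the first as their starting
prior.  `auto_group` clusters sample columns by average-linkage hierarchical
clustering of correlation distances, cutting at the cluster count (2 to
min(N−1, 8)) with the best mean silhouette and falling back to one group
below 0.2 — the cut rule is this package's choice, as is treating
zero-variance (constant) columns as mutually identical.

Decoded tracks become segments as maximal constant-state runs; a run is
additionally split where consecutive features are farther apart than
`max_gap` (CpG-site workflows use 100 bp).  Segment means are arithmetic
means of the observed values per sample.  Internally all coordinates are
1-based closed; BED/bedGraph conversion happens at the I/O boundary, and
wide bedGraph intervals are stored as (start, value, length-weight) rows
which the engine expands before inference — so a run-compressed count track
yields bit-identical likelihoods to its expanded form, while emission
densities are still evaluated only once per run row.

## Simulation benchmark

The `cnv` scenario draws segment lengths from Poisson(20)/Poisson(270)/
Poisson(10) for states 1–3 (zero draws redrawn) and intensities from
N(r,1)/N(2r,1)/N(3r,1), r ∈ {1,2,3}; the `counts` scenario uses
Poisson(285)/Poisson(5)/Poisson(10) lengths and Poisson(1)/Poisson(r)/
Poisson(r²) counts, r ∈ {1.5, 1.75, 2}.  A sequence joins 14 segments with
uniformly drawn states, adjacent segments forced to differ and all three
states required; inter-feature spacing is 1.  A *formation* fixes the
segment layout; iterations redraw only the observations on it.  Replication
defaults are 10 formations × 10 iterations per r level, chosen to keep a
full two-scenario run within minutes on one CPU while leaving the pooled
AUCs stable to roughly ±0.01; larger runs are a parameter away.

Scoring pools position-level (true state, estimated segment mean) pairs
across replicates.  The ROC sweep moves the threshold over the sorted unique
estimated values (strictest to loosest, endpoints pinned at (0,0)/(1,1));
sweeping every raw simulated value instead would add operating points on the
same polyline, so the AUC is unchanged.  The trapezoidal AUC equals the
Mann–Whitney statistic with ties counted half, which the tests verify
against a direct rank computation.  Segment counts per replicate are
summarized by MAE, RMSE (on the printed-table formulas), median and mean.

What the generators do *not* emulate: outliers and heavy-tailed noise, wavy
baselines / GC trends, correlated noise between neighboring probes,
mappability artifacts, and replicate-to-replicate scaling differences.
Passing benchmarks therefore demonstrate correct inference and competitive
power under the stated generative conditions, not robustness to every
real-data pathology (the t emission family exists precisely for the
heavier-tailed cases).

The methylation fixture plants three DMRs (two hyper, one hypo, effect
±0.35 over noise sd 0.05, p-values ≤0.01 inside vs ≥0.05 outside) on
irregular CpG-like spacing; it is a synthetic stand-in constructed for
workflow testing, not an excerpt of any published data set.

## Known limitations

- The sojourn M-step is moment-based; for heavily multimodal duration
  posteriors the guard may freeze a state's sojourn parameters at their
  prior.
- Multivariate groups assume a shared segmentation across member columns;
  discordant columns should be split into groups (or auto-grouped) first.
- No left-censoring: profiles that begin mid-segment slightly misweight the
  first run's duration evidence.
- Count emissions expect integer input; fractional coverage values must be
  rounded or modeled with the continuous families.
- Per-sequence processing is a simple loop; no parallel scheduling is
  provided or promised.
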