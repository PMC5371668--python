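# Methods

`glvnet` reconstructs signed, directed interaction networks among
bacterial genera from a single time series of community composition, and
scores the outcome of probiotic feeding trials against the inferred
network. This note records the models, the estimator, the synthetic data
the test suite relies on, and the design decisions that were genuinely
open.

## The community model

Community dynamics follow the generalized Lotka-Volterra (gLV) system

    dx_i/dt = x_i (b_i + Σ_j a_ij x_j)

where `x_i` is the abundance of taxon *i*, `b_i` its intrinsic growth
rate (1/day), and `a_ij` the per-unit effect of taxon *j* on taxon *i*
(1/day per abundance unit). Diagonal entries are strictly negative
(self-limitation). A directed edge *j → i* in every export corresponds
to the coefficient `a_ij`.

Dividing by `x_i` makes the log-derivative linear in the community
state:

    d(ln x_i)/dt = b_i + Σ_j a_ij x_j

which is the basis of the estimator.

### Compositional caveat

Sequencing data are compositional: only relative abundances are
observed. The pipeline therefore runs the regression on proportions,
as the tools it emulates do. This is a documented approximation, not an
oversight: renormalization adds a shared "closure" term
(−d ln T/dt, with T the total abundance) to every taxon's response and
rescales predictors by T(t). Our experiments show this distortion is
large enough that *quantitative* coefficient recovery from normalized
data is not achievable even without noise; what survives is the
strong-edge *ranking and sign* structure that the consensus procedure
consumes. Accordingly:

* the inference path (`glvnet fit`, `glvnet consensus`) accepts
  normalized profiles and reports signed, support-filtered edges —
  never calibrated coefficient values;
* quantitative recovery checks in the test suite run on
  absolute-abundance trajectories (`TimeSeriesProfile(normalized=False)`,
  `simulate_glv(renormalize=False)`), where the estimator is consistent.

## Estimation: gradient matching with ridge regularization

For consecutive samples `t_k, t_{k+1}` the response of taxon *i* is the
finite-difference log growth rate

    y_i(k) = (ln x_i(t_{k+1}) − ln x_i(t_k)) / Δt_k

and the shared design row is `[1, x_1, …, x_n]` evaluated either at the
interval start (explicit-Euler convention, the default) or at the
interval mean (`predictor="midpoint"`, second-order accurate and
preferred for densely sampled data). Each taxon is fit by ridge
regression with the intercept (growth rate) unpenalized; the penalty λ
defaults to leave-one-interval-out cross-validation pooled across taxa.

Numerical choices:

* **Zeros.** Counts of zero are replaced by a pseudo-abundance (half the
  smallest nonzero relative abundance in the profile) before logs.
  Dropping rows is also supported but discards rare genera.
* **Uneven sampling.** Each response is divided by its own Δt; intervals
  wider than 5 days are excluded by default so that one long fasting gap
  cannot dominate ten short intervals (`gap_threshold=None` keeps all).
* **Degenerate fits.** A rank-deficient design at λ=0 raises rather than
  pseudo-inverting; non-negative fitted self-limitation terms are
  clamped to a tiny negative value (with a warning) so every fit is a
  valid gLV model. During bootstrap replication this clamping is routine
  and silenced.
* **Replicate hosts.** `pool_regression_systems` stacks the intervals of
  several profiles of one community; a pooled design is far better
  conditioned than any single smooth trajectory, which matters because a
  lone relaxation trajectory may leave whole directions of the
  coefficient space unexcited.

## Consensus networks and interaction types

A single fit is fragile, so the network is a consensus over `R = 100`
replicates. Each replicate bootstrap-resamples the regression intervals,
refits, ranks all off-diagonal coefficients by absolute value (one
global ranking), and keeps the top 25%. A directed edge enters the
consensus network only if it survives in at least half the replicates
(`support ≥ 0.5`, inclusive) with a stable majority sign; exact sign
ties are dropped. All three thresholds are parameters.

What varies across replicates is a declared design choice: the original
tool's internal randomization is not published, so this package
bootstraps intervals (optionally jittering λ by ±25%). It is a
work-alike, not a bit-level clone.

Unordered pairs with at least one retained edge are classified by their
directed sign pattern: (+,+) mutual, (−,−) competitive, (+, absent)
commensal, (−, absent) amensal. Opposite-sign pairs (+,−) are
exploitative; they are reported as a fifth class and excluded from the
four-type tally, which matches the arithmetic of the published study
network (the four type counts sum exactly to the total).

## Motif screening

Motif analysis drops signs and asks whether 3-node topologies —
particularly the fan-in, two edges converging on one node (triad class
021U) — occur more often than in randomized networks with identical in-
and out-degrees. The null is the classic pairwise directed edge swap
(u→v, x→y becomes u→y, x→v), 100 attempted swaps per edge per sample;
this move preserves every node's degrees exactly. (The path-based
three-edge swap shipped elsewhere fails on bipartite-like graphs, so
the pairwise swap is implemented here.) Graphs admitting no legal swap
fall back to rejection-sampled configuration-model draws that also keep
degrees exact. z-scores use the null mean and standard deviation; a
degenerate null (sd = 0) is reported as undefined rather than inflated.

One caution for interpretation: degree-preserving rewiring conserves
Σ_v C(d_in(v), 2), the number of co-pointing pairs, so fan-in
enrichment can only arise from how often co-pointing parents are
themselves connected. The planted-enrichment generator used in tests is
built around exactly this fact.

## Diversity

Richness, Shannon entropy (natural log), Gini-Simpson (1 − Σp²) and
inverse Simpson (1/Σp²) per sample; Bray-Curtis dissimilarity between
samples; rarefaction by multivariate-hypergeometric subsampling.
Natural-log Shannon and the Gini-Simpson reading are forced by internal
consistency: only under those conventions do the Hill-number ordering
exp(H) ≥ 1/Σp² and the identity inverse = 1/(1 − Simpson) hold,
and both are enforced as property tests. Between-time-point comparisons
use the two-sample Student t-test (pooled variance) by default, Welch on
request, with no multiple-testing correction — matching the practice of
the emulated analysis; the caveat belongs to any report built on it.

## Trial validation

Fold change of a taxon is the ratio of its mean relative abundance in a
treatment group to the control group. Relevance is strict: FC > 2 is an
increase, FC < 0.5 a decrease, anything else (including the boundaries)
no-difference. Taxa with all-zero counts in either group are excluded
and listed. A two-sided Wilcoxon rank-sum test (exact null for the small
group sizes of feeding trials, mid-ranks on ties) is attached to every
fold change but does not gate the classification by default — the
source analysis states thresholds, not a significance requirement, so
the flag is reported rather than enforced.

Consistency of a pair {P, Q} with P administered is judged by the
retained directed edge P → Q: positive predicts an increase of Q,
negative a decrease. Matching relevant class → consistent; opposite
relevant class → conflict; otherwise no-difference. Pairs whose only
retained edge points *at* P carry no prediction for Q and are skipped.
In multi-strain groups each partner is evaluated against each
administered genus separately, and co-administered genera are not used
as read-outs for one another. This operational rule is an
interpretation: the emulated study never defines "responded
consistently" formally, and this is the minimal reading of its
relevance thresholds combined with its three-way summary tables.

qPCR expression changes use the ΔΔCt convention: with
ΔCt = Ct(target) − Ct(housekeeping) per animal,
log2FC = −(mean ΔCt_treatment − mean ΔCt_control), paired t-test when
the design is paired.

## Synthetic data: what it emulates and what it does not

The generator provides every input the pipeline needs:

* **Interaction matrices** with an exact requested mixture of pair types
  (assignment by largest-remainder apportionment, not independent
  draws), magnitudes uniform on a configurable range, negative
  diagonals.
* **Trajectories** by adaptive ODE integration, sampled on arbitrary
  grids including the emulated study schedule (12 points over 15 days:
  day 1, then 6-h and 12-h spacing after day 11). Noise is
  multiplicative log-normal, either observation noise (sampled values
  only) or process noise (state kicks that propagate — environmental
  stochasticity that keeps a community near equilibrium persistently
  excited). An extinction floor of 1e-8 relative abundance precedes
  renormalization.
* **Counts** as multinomial draws at a configurable depth. The default
  depth is 5,000 reads/sample — a deliberate scale-down of the
  ~130k reads/sample of the emulated study, preserving multinomial
  noise structure at desk-scale run times.
* **Trials**: the administered genus is raised `boost`-fold (default 15,
  within the ~10–26× colonization range the emulated trials show), the
  rest of the community responds through one interaction step around the
  baseline treated as equilibrium over the trial duration (default 14
  days), per-animal log-normal variation (sd 0.3) and multinomial
  counts follow; the control group is drawn from the unperturbed
  baseline. Holding the administered genus at its dosed level makes the
  no-coupling limit exact (only the dosed genus changes) and reflects
  that colonization, not free dynamics, sets its level.
* **Planted communities** for recovery tests: a weak-background matrix
  with a few strong pairs (≥ 5× background), an interior equilibrium
  imposed via b = −A x*, and self-limitation strengthened until that
  equilibrium is stable.
* **Fan-in-enriched graphs**: hubs in a directed cycle feed each target
  from a non-adjacent hub pair, so rewiring can only lower the fan-in
  count.

What passing tests on these data do **not** show: recovery of real gut
networks from compositional 12-point series. The recovery suites run at
sampling densities and noise regimes chosen to make the estimator
identifiable (hundreds of points for consensus recovery, absolute
abundances for coefficient recovery); the emulated study's 12
compositional time points carry far less information, which is precisely
why its pipeline leans on consensus filtering and external trial
validation rather than coefficient estimates.

### Problem sizes used by the bundled checks

The recovery checks use a 5-taxon community observed noise-free on three
pooled 4-day trajectories at 0.01-day spacing (coefficient recovery),
and a 10-taxon community with 5 planted pairs observed every half day
for 400 days under 10% process noise, 50 consensus replicates
(planted-edge recovery). The motif checks use 100 random graphs of ≤ 9
nodes against exhaustive triple enumeration and a 60-target planted
fan-in graph with 100 randomizations. These sizes were chosen as the
smallest at which each property is comfortably identifiable.

## Known limitations

* Coefficients fitted to compositional data are distorted by closure;
  only sign/rank structure is interpretable (see above).
* Gradient matching amplifies observation noise by 1/Δt; densifying the
  grid does not help once smoothing-induced autocorrelation shrinks the
  effective sample size. Process-noise-excited or replicate designs are
  the reliable regimes.
* The consensus procedure's agreement with the original tool is
  architectural, not numerical: published pair counts are reproduced as
  arithmetic on published tallies, not re-derived from raw reads.
* The fold-change consistency rule is an interpretation of an informally
  described procedure and is marked as such wherever it is exposed.
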