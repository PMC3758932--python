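# Methods

This note records the statistical conventions, the synthetic-data model, the
numerical choices, and the known limitations of the pcrnet pipeline.

## Data model and missingness

A participant record is a frequency vector over the 40-item instrument
(ordinal 0–7) plus a sparse directed PCR map.  The adaptive questioning rule
is an invariant, not a convention: the causal question about the ordered pair
(i, j) exists iff both i and j were endorsed at least "Once in the past
month" (frequency ≥ 1), so a participant endorsing k symptoms has exactly
k·(k−1) PCR slots.  Slots outside that set are *missing by design* and are
derived, never stored or serialized; within the set, an unanswered question
is *missing by intention*.  All downstream statistics are available-case: no
imputation anywhere, and models delete listwise within themselves, so
degrees of freedom vary across models.

Subset frequency scores (ANX items 1–4, REEXP items 5–9, DEP items 12, 13,
18, 24, 27–30, 32, 33) default to the **mean** of available items, which is
robust to a skipped item; `mode="sum"` is available.  The *frequency sum
score* used as the symptom-burden measure in the loop analysis is the plain
sum over all 40 items; the item set is an argument for sensitivity analyses
(e.g. excluding the two impairment items).

## Cause/effect scoring

C_i is the mean of present outgoing PCR ratings of symptom i, E_i the mean of
incoming ones; both live on the 0–10 rating scale.  The cause-vs-effect
contrast is a paired t test on per-participant (C−E) over participants with
both defined.  Zero variance of the paired difference is reported as an
undefined-result marker unless the difference is identically zero (then
t = 0, p = 1).

**Effect size convention.**  d = |t| / √(df+1), i.e. the mean paired
difference in units of its standard deviation (with df = n−1 this is
|t|/√n).  This convention reproduces the three reference conversions the
acceptance script recomputes (t = 4.95, df = 112 → 0.47; t = 6.74,
df = 195 → 0.48; t = 3.78, df = 137 → 0.32).  One published tabulation we
checked prints 0.61 where this formula gives 0.60; no alternative simple
convention reproduces that row without breaking the other three, so the
package standardizes on t/√(df+1) and flags the discrepancy here.

Family-wise error over the 40 contrasts is controlled with Holm–Bonferroni
(step-down), delegated to `statsmodels.stats.multitest`; the result also
reports the plain Bonferroni threshold α/m (0.00125 for α = 0.05, m = 40)
and the largest p-value actually rejected (the "obtained threshold").  d is
tabulated only for contrasts that survive the correction.

## Regression designs

All three designs mean-center the continuous predictors before forming
product terms, so first-order coefficients are slopes at the moderator mean
and probes at mean ± 1 SD are directly interpretable.

* **Moderation**: OLS of y on (1, x_c, w_c, x_c·w_c).  The interaction is
  tested by ΔR² with F = ΔR² / ((1−R²_full)/(n−4)).  Simple slopes at probe
  w₀ are b₁ + b₃(w₀−w̄) with delta-method SEs from the coefficient
  covariance.  The *simple-slope contrast d* is defined as
  b₃·(x₀−x̄)·(w_hi−w_lo)/σ̂_resid — the interaction-attributable
  difference-in-differences at predictor value x₀, in residual-SD units.
  The moderator main-effect term b₂(w_hi−w_lo) is deliberately excluded: the
  quantity is meant to isolate what the *moderation* contributes, so it is
  zero when b₃ = 0 and linear in b₃.
* **Mediation**: a from m ~ x; b and c′ from y ~ x + m; c from y ~ x
  (c = c′ + a·b holds exactly in OLS on complete data and is tested).
  Inference on a·b uses a nonparametric case-resampling bootstrap
  (default 10,000 resamples) with percentile CIs; BCa is not implemented.
  The indirect/direct ratio uses the same resamples.  Degenerate resamples
  (zero predictor variance or a singular two-regressor system) are redrawn
  and counted.  Proportion mediated is reported both as a·b/c and as
  a·b/(a·b+c′), since the two definitions diverge in inconsistent-mediation
  cases.
* **Moderated mediation**: w moderates x→m and v moderates m→y.
  Conditional indirect effects (a₁+a₃w₀)(b₁+b₃v₀) are evaluated on a probe
  grid — the 25th/50th/75th percentiles of each moderator by default, the
  median included deliberately so "at the median or higher" statements can be
  probed — with every cell's CI computed from one shared set of resamples.
  A moderator with zero variance is dropped (with a flag) instead of raising
  a singularity error, which makes the model degrade exactly to simple
  mediation; this realizes the intended equivalence between the two fits.
  A secondary, clearly-labeled variant augments the y-model with w·v and
  m·(w·v) terms and reports the m·(w·v) coefficient; the standard
  second-stage equations contain m·v rather than moderator-product terms,
  and reported "PCR × PCR interaction" coefficients do not map uniquely onto
  them, so both parameterizations are exposed and neither is asserted as
  canonical.

CI level defaults to 95%; passing `level=0.9833` gives the
Bonferroni-corrected 95% CI appropriate when three model families are tested
(α = 0.05/3 = 0.017).

The bootstrap inner loops are closed-form normal-equation solves vectorized
over resamples (einsum / batched `linalg.solve`), not per-resample model
objects; the headline fits use statsmodels and agree with the bootstrap
point estimates by construction.

## Networks and centrality

The group network's edge (i, j) is the available-case mean of present
PCR(i, j) over participants who endorsed both symptoms (`min_n` exposes a
minimum-contributor filter; default 1).  Display conventions: edges above 3
are drawn, above 4.5 drawn dark.  Centralities follow the weighted-network
definitions: out/indegree are weight sums; betweenness uses shortest paths
under edge costs w⁻ᵅ with α = 1 by default (α exposed because published
analyses rarely print it), fractional credit across co-minimal paths,
unreachable pairs contributing nothing, zero-weight edges uncrossable, and
no normalization (raw pair counts) unless requested.  networkx supplies the
shortest-path machinery; tests verify it against an exhaustive
all-simple-paths oracle on small graphs.

The permutation null keeps the node set fixed and permutes the multiset of
observed edge weights — over the existing edge positions by default
(`shuffle_weights`; the observed quantity is the scores, so the default
permutes scores, not structure), or over all 40·39 ordered pairs
(`rewire_pairs`) since the published description is ambiguous about whether
topology was preserved.  Permutation is without replacement.  Per node and
measure the report gives the 2.5/50/97.5 empirical percentiles of 1,000
permuted networks and an extremity flag iff the observed value falls outside
the central 95% interval.  The pipeline runs the null on the full rated
network rather than the display-thresholded one: thresholding first leaves a
handful of near-equal weights whose permutation distribution is nearly
degenerate and the null loses all power.

Layout is Fruchterman–Reingold (networkx `spring_layout`), deterministic per
seed; a single node is placed at the origin.

## Feedback loops

Each participant's network keeps endorsed symptoms as nodes and present PCR
ratings strictly above 4.5 as edges ("above" read literally as >; the
operator is configurable).  Feedback loops are simple directed cycles of
length 2–4 (self-loops cannot exist since PCR is only asked for distinct
symptoms).  Enumeration is a bounded-depth DFS anchored at each node in
increasing id order and restricted to larger ids, which emits every cycle
exactly once already in canonical rotation (smallest id first, direction
preserved); with the length bound at 4 this is exact and fast even on a
complete 40-node digraph (≈ 5.7·10⁵ cycles), so Johnson-style machinery is
unnecessary.  Tests verify equivalence against `networkx.simple_cycles`
(length-bounded) and against brute-force enumeration over node subsets.

Population totals are reported both as (participant, loop) incidences and as
distinct canonical loop types pooled across participants, since a printed
"unique feedback loops" total is ambiguous between the two readings.

Per-symptom involvement counts (participant, cycle) incidences containing
the symptom; the frequency correction divides by the number of endorsing
participants by default (alternatives: divide by the symptom's total
frequency, or none) — the published figure's correction is not specified, so
the simplest per-capita normalization is the default.

The burden association is Spearman's rho between per-participant loop count
and the 40-item frequency sum.  Partial Spearman is computed as the Pearson
partial correlation on mid-rank-transformed variables (residualizing both
rank vectors on the ranked controls), p from the t approximation with
df = n−2−k; this matches `pingouin.partial_corr(method="spearman")`, which
tests use as a cross-check.  Controls: the number of endorsed symptoms, then
additionally the number of PCR entries — present ratings by default, with
supra-threshold edge count as the alternative reading.

## Synthetic-data generator

The generator emulates the structure of a PCR survey, not any particular
dataset.  Ground truth is a 40×40 non-negative weight matrix W (zero
diagonal) with planted directed cycles; defaults (chosen once, before the
recovery experiments were run): two 2-cycles, two 3-cycles and one 4-cycle
over reexperiencing / worry / depressed-mood / guilt-shame items with weight
4.0, sparse background weights U(0.5, 2.0) at density 8%, per-item base
endorsement rate 0.30, rating-noise SD 1.0 on the 0–10 scale, and PCR
fidelity 1.5 (expected rating per unit of true weight) — so planted-loop
edges rate ≈ 6 (above the 4.5 loop cutoff) and background edges ≤ 3 (below
it).

Mechanism, deterministic given the seed:

1. **Activation.**  Each participant's latent activation on [0, 1] starts at
   clip(base + ε) with ε ~ N(0, noise/10) and iterates
   a ← clip(base + 0.05·W·a + ε) three times.  The iterated-linear pass is
   the minimal mechanism by which feedback loops amplify the activation of
   their member symptoms, which is exactly the coherence property the loop
   analysis is meant to detect.  `base` places the endorsement threshold so
   that P(endorse) ≈ the configured base rate absent coupling
   (base = 1/8 + (noise/10)·Φ⁻¹(rate); rate 0 maps to never-endorse).
2. **Frequencies.**  Eight equally spaced thresholds on [0, 1] map activation
   to the ordinal 0–7 scale (zero-inflated: activation below 1/8 scores 0).
   Equal spacing is an arbitrary but documented choice; nothing downstream
   depends on it.
3. **PCR ratings.**  For each eligible ordered pair,
   clip(round(fidelity·W_ij + N(0, noise)), 0, 10).  With noise → 0 and full
   endorsement the mean rating recovers fidelity·W exactly (tested).
4. **Missingness.**  By-intention skips are injected at 2% (frequencies,
   first, so a skipped frequency converts its pairs to by-design) and 0.8%
   (PCR ratings).

What the generator does **not** emulate: per-participant heterogeneity in
causal structure (W is population-constant, so between-person variation in
PCR is pure rating noise), demographic structure, item wording effects, and
any dependence of the x→y frequency association on the participant's own
PCR rating.  The last point matters for interpretation: moderation recovery
is tested on explicit linear-Gaussian truths with planted interactions, not
on the survey generator, because the generator's frequencies are driven by a
shared W and therefore contain no true PCR-moderation signal.  Passing tests
show the estimators recover planted structure under their assumed models —
they cannot certify that real survey data satisfies those assumptions.

## Problem sizes and determinism

Default analysis sizes: simulated populations of 300 participants for the
narrative drivers, 500 for recovery experiments (20 seeds for the
loop-burden check, 200 replicates at n = 500 for bootstrap-CI calibration),
10,000 bootstrap resamples in the drivers and 1,000 in tests, 1,000
permutations for centrality nulls.  Every stochastic component takes an
explicit seed; the pipeline fans one global seed into per-stage seeds via
seed·1000003 + stage-offset (mod 2³¹).  Pipeline JSON/CSV outputs are
byte-identical across reruns of the same config and seed; wall-clock
runtimes are logged and written only to the Markdown summary.

## Known limitations

- Percentile bootstrap only (no BCa); coverage is validated empirically at
  n = 500 under Gaussian truths, and can undercover for small n or strongly
  skewed indirect-effect distributions.
- The partial-Spearman p-value uses the t approximation, which is asymptotic
  and approximate under heavy ties (mid-ranks are used).
- The permutation null conditions on the observed weight multiset; it tests
  exchangeability of scores across edges, not sampling variability of the
  means themselves.
- Betweenness ties are resolved with fractional credit across co-minimal
  paths; costs compare with an absolute 1e-12-scale tolerance inside
  networkx's Dijkstra, which is adequate for ratings-scale weights.
- `cause_effect_table` rounds to 2 decimals for presentation; full precision
  is retained in `d_EC_raw` and in the programmatic results.
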