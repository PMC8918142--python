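# Methods

## The screening problem

Given n subjects with right-censored survival outcomes (observed time
V = min(T, C), event indicator δ = 1{T ≤ C}) and p ≫ n covariates,
marginal feature screening computes a per-feature association score and
keeps the top-ranked features.  The package's accuracy currency is the
minimum model size (MMS): the smallest k such that the top-k set contains
every truly associated feature.  Screening is a dimension-reduction step,
not a final model: its job is to make the truth reachable by a downstream
sparse fit at moderate k.

## Generative model of the simulator

Survival times follow the linear transformation model

    H(T) = −x′β + ε,    H(t) = log(0.5 (e^{2t} − 1)).

H is strictly increasing from (0, ∞) onto ℝ with the analytic inverse
H⁻¹(u) = ½ log(1 + 2eᵘ) (evaluated in a split form to avoid overflow at
either extreme).  Two error families are supported:

* **extreme-value** (CDF 1 − exp(−eᵘ), i.e. the log of a unit
  exponential): H(T) = −x′β + ε is then a proportional-hazards model, and
  with η = 0 the survivor function is S(t) = exp(−0.5(e^{2t} − 1)), median
  ½ log(1 + 2 log 2) ≈ 0.43493;
* **logistic**: proportional odds, S(t) = 1/(1 + 0.5(e^{2t} − 1)), median
  ½ log 3 ≈ 0.54931.

These closed forms are asserted by the test suite against large Monte-Carlo
draws (n = 200,000, tolerance ±0.005 on the median; survivor deciles within
3/√n).

### Study designs

* **Design 1** — AR(1) correlation corr(x_j, x_k) = 0.5^{|j−k|}, p = 2,000,
  n = 500, and the sparse coefficient vector
  β = (−1, −0.9, 0.5, 0.8, 0.6, 0₅, 0.3, 0.7, −0.8, −0.5, −1, 0₅, −2, 1,
  0, −0.5, −2, 0₁₉₇₅) with 14 nonzero entries — 14 true predictors whose
  effect sizes range from weak (0.3) to strong (2).
* **Design 2** — the same coefficients, but features 1, 2, 4, 5 act through
  nonlinear links g₁(x) = β₁|x|, g₂(x) = β₂|x|, g₄(x) = β₄x²,
  g₅(x) = β₅1{x > 0}; all other features stay linear.
* **Design 3** — network-structured correlation (hub, band, cluster or
  scale-free) with a ±1.5 coefficient vector carrying 15 nonzero entries
  (the design-1 zero at position 23 becomes 1.5; the truth set is reported
  from the vector as defined).

### Network covariance construction

AR(1) is analytic.  The four graph structures build a 0/1 adjacency A
(band: |j − k| ≤ bandwidth; hub: groups of `group_size` features with the
first linked to the rest; cluster: independent within-group edges at
probability 0.3; scale-free: Barabási–Albert preferential attachment with
m = 1), then form the precision matrix

    Ω = v·A + (|λ_min(v·A)| + 0.1 + u)·I,   v = 0.3, u = 0.1,

whose inverse is rescaled to unit diagonal.  This is the standard
graphical-model simulator convention; the diagonal boost guarantees
positive definiteness by construction, and the resulting precision's
off-diagonal sparsity pattern equals A (asserted in tests).  The smallest
eigenvalue is computed by Lanczos iteration with a fixed start vector so
covariance generation is deterministic given the seed.

### Contamination

With probability 0.1 each covariate **entry** is independently replaced by
a Student-t(2) draw (no finite variance).  Entry-level granularity is the
package's choice — it matches the heavy-tailed marginal contamination used
in the robust-screening literature; a per-subject mode (whole rows
replaced) is available via `ContaminationSpec(per_subject=True)`.
Contamination models measurement corruption, so by default the latent
survival times are computed from the clean covariates and only the table
handed to screeners is contaminated; `contaminate_before_eta=True` flips
this.

### Censoring calibration

Censoring times are uniform U(0, b) with a ≡ 0.  Given a target rate r,
`calibrate_censoring` freezes a Monte-Carlo sample of 200,000 survival
times T and bisects on b: the censoring proportion P(T > C) =
E[min(T, b)]/b is continuous and strictly decreasing in b, so the bisection
converges to |rate − r| ≤ 0.005.  Calibration and the large validation
cohorts sample the linear predictor η = x′β directly from the support block
of the covariance (exact in distribution, since features with β_j = 0 and a
linear link contribute nothing to η) instead of materialising 100,000 ×
2,000 covariate tables.  Validated targets 0.3/0.5/0.7 reproduce within
±0.01 on independent 100,000-subject cohorts.

### Random-number discipline

A single master seed is expanded through `numpy.random.SeedSequence`
spawning into independent child streams (network build, covariate draw,
contamination, survival, censoring; one child per replication in the
benchmark), so every replication is individually reproducible.  Integer
outputs are bitwise reproducible; floating-point covariate tables are
reproducible to ~1e-10 (threaded BLAS reduction order).

## Screening utilities: conventions that matter

* **Censoring Kaplan–Meier** Ĝ(t) = P(C > t) treats censorings as events
  with risk sets {V_k ≥ t} — at tied times deaths precede censorings.  IPCW
  weights query the left limit Ĝ(t−).
* **IPCW tau**: pair (i, k) carries weight Δ_ik/Ĝ(min(V_i,V_k)−)² where
  Δ_ik indicates the pair's earlier subject is an event; tied observed
  times contribute zero.  Ĝ is floored at 0.05 (weight cap 400) so a few
  late-follow-up pairs cannot dominate; the number of floored pairs is
  reported in the ranking diagnostics.  With no censoring the statistic is
  exactly the classical Kendall tau-a (asserted to 1e−12).
* **PL** reports ℓ(β̂) − ℓ(0) ≥ 0 (Breslow ties, Newton–Raphson with
  step-halving); subtracting the shared ℓ(0) leaves the ranking unchanged
  and makes the utility non-negative.
* **SIS** correlates with log V by default (survival times are positively
  skewed); raw-time mode via `log_time=False`.  The estimator deliberately
  ignores censoring — it is the ad hoc baseline.
* **CINDEX** uses |C − ½| so hazardous and protective features rank
  symmetrically.
* **RCDCS** replaces the covariate by its ECDF (rank/n, average ranks on
  ties) and the outcome by the Kaplan–Meier CDF of T at each observed time,
  then takes their distance correlation — hence invariance to monotone
  covariate transforms.
* **CRCDCS**: for each grid quantile q ∈ {0.25, 0.5, 0.75}, the survival
  status ψ = 1{V > t_q} at the KM quantile t_q (leftmost time with CDF ≥ q)
  is compared with the covariate ECDF by weighted distance correlation;
  a subject is usable when its status at t_q is determined (event, or
  censored after t_q) and carries weight 1/Ĝ(min(V, t_q)−) — the
  redistribute-to-the-right correction.  Grid points beyond the KM plateau
  are dropped with a warning.  The exact composite construction is not
  settled in the literature this follows; this default reduces to the plain
  distance correlation of (rank(x), 1{V > median}) when there is no
  censoring (asserted).

## Network adjustment (NPN-MB / MB)

1. **Nonparanormal transform**: per column, ranks/(n+1) Winsorized at
   δ_n = 1/(4 n^{1/4} √(π log n)) then probit-transformed.  Rank-preserving,
   so tau-based utilities are unchanged; its role is to make the graph
   estimation step resistant to the heavy-tailed contamination (the test
   suite checks that graph recovery under t(2) contamination is at least as
   good on transformed data as on raw data).
2. **Neighborhood selection**: nodewise lasso of each standardized column
   on the rest at penalty λ = √(log p / n), edges by the OR rule (either
   direction nonzero; AND available).  The Gram matrix is precomputed once
   and shared across the p regressions.  At this λ false-positive edges are
   rare but not zero — tests assert a ≤ 5% cross-block false-positive rate
   with ≥ 80% chain recovery on two independent AR(1) blocks.  λ = 0 with
   p > n is refused (unidentifiable dense neighborhoods).
3. **Smoothing**: u = (1 − α)|τ̂| + α·W u with W the row-stochastic walk
   matrix (isolated nodes get self-loops so every row is total mass 1);
   α = 0.5, one iteration by default, both configurable and recorded in the
   ranking diagnostics.  One iteration keeps the output a convex
   combination bounded by [min τ̂, max τ̂].  The PageRank-style adjustment
   in the literature this emulates is not printed in closed form anywhere
   accessible; this convex one-step propagation is the simplest
   construction consistent with it and is exposed as a tunable rather than
   a fixed constant.

For desk-scale runs `pre_cap=K` restricts graph estimation to the top-K
tau-ranked features; utilities outside the cap pass through unsmoothed.

## Evaluation machinery

MMS is reported as the full replication sample (medians and violins are
downstream summaries).  Overlap-coefficient curves |top-k ∩ truth| /
min(k, |truth|) are monotone non-decreasing only for k ≥ |truth| — below
that the denominator grows with k.  The benchmark's held-out c-index curves
split each cohort 1:1, refit a ridge-stabilized Cox model (penalizer 1e−4)
on the top-k train features, and score Harrell's C on the held-out half;
within-sample mode is deliberately not offered to avoid optimistic curves.
Deviance is D = −2(logL(β̂) − logL(0)) with both terms the Breslow log
partial likelihood on the **test** set; D = 0 for the null model exactly,
negative when the fitted model beats the null.

## Application pipeline

`evaluate_splits` runs: random train/test split (default 0.8, matching a
294:74 split at n = 368) → marginal-Cox prefilter to the top 2,000 features
by Wald p-value → screening → hard threshold to the top d → pluggable
sparse-Cox fit → test-set deviance / c-index / NOSF (coefficients above
1e−8 in magnitude).  Defaults:

* the prefilter runs **inside each training fold** (no test information
  reaches feature selection, asserted by a spy test); the
  `whole_data_prefilter=True` variant prefilters once on the whole data, the
  common published practice, for comparability;
* when `top_d` is a grid (default 10–300 step 10), the value maximising
  the **median held-out c-index** wins — "best overall prediction
  performance" made concrete;
* the shipped fitter is a ridge-penalized Cox fit (lifelines); an MCP or
  other sparse solver plugs in as any callable `(X, V, delta) → coef`.
  NOSF for the ridge fitter counts all retained coefficients (ridge does
  not zero them), so NOSF ≈ top_d there; a genuinely sparse plug-in fitter
  yields informative NOSF.

## Problem sizes used by the shipped checks

The package's replication checks run at a reduced scale chosen to keep a
full test cycle comfortable on a laptop: n = 400, p = 500, 20 replications,
30% censoring for the directional claim that NPN-MB's median MMS does not
exceed plain IPCW-tau's (design 1 AR(1); design 3 band and hub).  The
full-scale study (n = 500, p = 2,000, 200 replications, three censoring
levels) is supported through the same `BenchmarkConfig` / `benchmark
--full` surface.  Monte-Carlo constants use n = 100,000–200,000 draws where
they are cheap (medians, censoring rates, contamination fraction).

## What the simulator does and does not emulate

It reproduces correlated Gaussian expression-like features with
network-structured dependence, sparse linear/nonlinear effects, calibrated
uniform censoring and heavy-tailed contamination.  It does not emulate
RNA-Seq count skew or library-size effects, batch structure, informative
(outcome-dependent) censoring, competing risks, or time-varying effects —
passing tests therefore demonstrate correctness of the estimators and the
claimed orderings under the stated generative model, not performance on any
particular real cohort.

## Known limitations

* The CRCDCS composite and the PageRank-style smoothing are package
  defaults for constructions the source literature leaves under-specified;
  both are parameterised and logged rather than hard-coded.
* Neighborhood selection at p = 2,000 is the pipeline bottleneck (p lasso
  fits); use `pre_cap` or the `--full` benchmark deliberately.
* `utility_pl` reports a best-iterate value with a warning on the rare
  non-converged marginal fit (e.g. complete separation in a binary-ish
  covariate).
* Harrell's C and the IPCW tau are O(n²) in memory (pair matrices); fine
  for cohort sizes in the hundreds to a few thousand, not for biobank-scale
  n.
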