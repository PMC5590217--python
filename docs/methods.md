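# Methods

## Setting and model

Data are horizontally partitioned: each node holds every covariate for
a disjoint subset of matched case-control strata, and may release only
aggregates.  A stratum comprises one case and M matched controls
(1:M design; M constant within a dataset).  The analysis model is
conditional logistic regression: with design row x for a subject and
parameter vector θ, the stratum's likelihood contribution is the
softmax of θᵀx over the M+1 members.  Conditioning removes the
stratum intercepts, so matching factors never need to be shared or even
coded.

Virtual pooling replaces g whole strata by one *pooled stratum*: the
elementwise sum of the g case design rows, and, for each control
position j = 1..M, the sum of the g position-j control rows.  The
pooled strata satisfy a conditional logistic model of the same form
with the *same* θ, so the fitting machinery is unchanged and estimates
keep their individual-level interpretation.  Two rules make this work
for rich models:

* every derived column — log/square transforms, products with an
  effect modifier — is computed per subject *before* summation (a
  pooled interaction column is a sum of products; a product of sums
  would estimate nothing useful);
* pools never mix outcome roles: case rows are summed with case rows,
  position-j controls with position-j controls.

Controls within a stratum are exchangeable given matching, so the
assignment of controls to positions before position-wise summation is
arbitrary.  By default each stratum's control order is shuffled once
with a seeded generator before aggregation, removing any accidental
ordering artifact from data entry while staying reproducible; pools of
size 1 keep the stored order, which makes g=1 pooling an exact
(bit-level) identity.  Setting `shuffle_controls=False` preserves input
order throughout.

## Pool planning

Within each node, strata are randomly permuted (seeded) and sliced into
consecutive pools:

* **single_g_exclude** — pools of one size g; the n mod g leftover
  strata (the permutation tail, i.e. a random subset) are excluded from
  analysis.  A node smaller than g is fully excluded, with a warning.
* **mixed_g** — two sizes g and g_alt; each node's count n is
  decomposed as a·g + b·g_alt maximizing covered strata, ties broken
  toward more size-g pools (more pooled strata retain more
  information).  The decomposition is found by enumeration over a.
* **cross_node** — pools may span nodes.  This exists only as a
  comparison against unstratified pooling; it would require secure
  multi-party summation in practice, which this package deliberately
  does not provide, so such plans are flagged `non_private`.

Pool size trades privacy for power: aggregates over more subjects
reveal less but carry less information (fewer pooled strata).  Privacy
rules of the hosting network (e.g. "no statistic over fewer than 5
subjects") put a floor under g; the simulation study quantifies the
efficiency cost of raising it.

## Estimation

Maximum likelihood from θ = 0 by Newton–Raphson with analytic gradient
and Hessian.  Per stratum the gradient is (case row − softmax-weighted
mean row) and the Hessian is minus the softmax-weighted covariance of
the rows, hence negative semidefinite: the likelihood is concave and
Newton with step-halving (halve until the log-likelihood does not
decrease) converges in a handful of iterations for p ≲ 10.

Numerical choices:

* within-stratum log-sum-exp with max subtraction everywhere —
  mandatory because pooled rows are g-fold larger in scale;
* convergence when the gradient ∞-norm drops below 1e-8 or the
  relative log-likelihood change below 1e-12; at most 100 iterations;
* covariance = inverse of the negative Hessian at θ̂ (observed
  information); this is the "model-based" SE reported everywhere;
* **identifiability**: at θ = 0 the information is the pooled
  within-stratum covariance of the design rows; a relative minimum
  eigenvalue below 1e-10 (e.g. all rows equal within each stratum, or a
  column constant within strata) raises a non-identifiability error;
* **separation**: under (quasi-)separation the score decays
  exponentially along the divergent direction, so a gradient-based
  stopping rule halts at a finite θ̂ that is not an MLE.  A norm
  threshold alone cannot catch this scale-dependently, so the fit is
  additionally declared non-converged when the minimum eigenvalue of
  the observed information at θ̂ collapses below 1e-6 of its value at
  the origin (a scale-free signature of information loss), or when
  ‖θ̂‖∞ exceeds 1e3.  Non-convergence is reported, never papered over
  with clipped estimates.

Wald confidence intervals use normal quantiles; nested models are
compared by likelihood-ratio test (χ² upper tail) or AIC
(−2·loglik + 2p).

## Synthetic-data generator

`simulation.simulate_dataset` emulates the reference study design: a
matched case-control study nested in a multi-site cohort, 1020 matched
sets with M = 10 controls per case over 5 nodes holding
120/180/180/240/300 sets.  Disease status follows

    logit Pr(D=1) = α_i + ν_k + β·U + γ·X + δ·Z1 + ω·Z2 + ϑ·U·Z2

with defaults β=0.3, γ=0.2, δ=0.15, ω=0.09, ϑ=0.05.  Covariates:
U log-normal (log U standard normal — the simplest member of the
family; its scale is not otherwise pinned down), X binary with
prevalence 0.4 independent of U, Z1 standard normal with correlation
0.35 with log U (bivariate-normal construction), Z2 standard normal
independent of the rest.  Stratum intercepts α_i ~ Normal(−3, 2²)
(SD 2, not variance 2); node intercepts ν_k are standard-normal draws
sorted descending and assigned to nodes by ascending size, so the
smallest node has the highest baseline prevalence.

Matched-set assembly is by rejection sampling: under a stratum's α_i,
subjects are drawn from the covariate model and their outcomes
realized until one case and M controls have accrued; the first case
and first M controls in draw order form the set.  An α_i so low that
no case appears within the draw cap (200 000 subjects) is resampled;
exceeding a resample cap raises an error with diagnostics.  This
emulates risk-set sampling where matching factors are absorbed into
α_i.  Alternatives (simulating a full cohort and then sampling
matched sets from it) could shift the small pooling biases slightly;
the generator conditions on achieving exactly 1:M per stratum.

What the generator does *not* emulate: real matching on observed
factors (no explicit matching variables exist — α_i stands in for
them), measurement error, missing data, node-level covariate
heterogeneity beyond the baseline intercept, and informative cluster
sizes.  Passing tests therefore demonstrate correctness of the pooled
estimator under a correctly specified conditional model, not
robustness to those real-data features.

## The Monte Carlo study

`run_study` simulates `n_reps` datasets; per replicate it fits the
unpooled model (terms U, X, Z1, Z2, U·Z2) and, for each pool size g in
{4, 6, 10}, the pooled model after within-node single-size planning
(under the reference node sizes these give exactly 255, 170 and 102
pools, none excluded).  Reported per analysis and parameter: mean
estimate, EmpSE (SD of estimates across replicates), ModelSE (mean of
model-based SEs) and coverage of the 95 % Wald interval.
Non-converged replicates are dropped from that analysis's cells and
counted — never re-drawn, which would bias the comparison by hiding
separation-prone configurations.

Seeding: a root `SeedSequence(base_seed)` spawns one child per
replicate, which spawns one stream for data generation and one per
pool size for pool planning; runs are bit-reproducible given
`base_seed`.

Problem sizes: the test suite and the acceptance script run the study
at 200 replicates (the full 500-replicate run is a config change:
`n_reps: 500`), which stabilizes means to ~EmpSE/14 and keeps a full
run in the minutes range on a single CPU.  Expected behaviour, and
what the tests assert: near-unbiased estimates up to g = 6, a visible
bias away from the null at g = 10 (fewer, coarser pooled strata),
EmpSE increasing monotonically with g, and coverage near nominal for
g ≤ 6.

## Disclosure audit

Aggregation hides individual values except in one degenerate case: a
0/1-coded covariate whose pool aggregate equals 0 or g reveals every
member's value for that covariate.  `privacy_audit` flags exactly
those (pool, role, position, term) cells and tallies them per node —
at g = 2 with all-binary microdata this happens often, which is why
small pools of purely binary covariates should be avoided or handled
with other disclosure-limitation techniques.

## Limitations and non-goals

* Only 1:M matched (and, structurally, unmatched) case-control designs
  with a logit link; no N:M with N > 1 (no pooled formula is
  established for it here), no survival or other link functions — no
  aggregation-based method exists for those.
* No secure multi-party computation: within-node pooling is the privacy
  mechanism; `cross_node` planning exists only for comparison and is
  flagged non-private.
* No robust/sandwich variances, no Firth correction; separation is
  reported, not repaired.
* Missing covariate values are rejected, not imputed: pooling sums
  would silently absorb imputations, and complete-record analysis keeps
  the aggregate semantics exact.
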