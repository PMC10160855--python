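# Methods

## Model

Let `C` be the number of causes in an age stratum (7 for children 1–59
months, 5 for neonates, in the fixed canonical orders of the packaged
tables). Each death carries simplex-valued data:

- `x` — the reference-standard (MITS) encoding: 1 at a cause named as both
  underlying and immediate (or when no distinct immediate cause exists),
  0.5 at each of two distinct causes, 0 elsewhere;
- `y_a` — the score vector emitted by CCVA algorithm `a`;
- `p` — the population CSMF of the survey population (the estimand);
- `q_a` — the raw CSMF, the per-cause mean of `y_a` over survey records.

The misclassification matrix `M_a` of algorithm `a` is row-stochastic with
`M_a[i, j]` the average score given to cause `j` among deaths of reference
cause `i`. Two identities drive everything:

1. `E[y | x] = M'x` for paired records (a 0.5/0.5 reference is read as a
   50:50 mixture of the two causes), and
2. `q = M'p` for the survey population (law of total probability).

Because the data are compositional rather than categorical, a multinomial
likelihood is unavailable; the KL cross-entropy loss replaces it:

```
loss(p, {M_a}) = Σ_a w_a [ Σ_paired −Σ_j y_ij log((M_a'x_i)_j)
                         + Σ_survey −Σ_j y_kj log((M_a'p)_j) ]
```

(y-entropy constants dropped; for one-hot data this is exactly the
multinomial negative log-likelihood, so the single-cause analysis is the
degenerate case). Inference uses the generalized posterior
`∝ exp(−loss) × prior`. Summing the per-algorithm losses with `w_a = 1`
gives the ensemble calibration; the weights are exposed for a priori
preference of one algorithm.

## Estimation choices

**Misclassification fit** (`fit_multicause_M`): multiplicative EM updates
`M ← row-normalize(M ∘ X'(Y / XM))`, which stay on the simplex and never
increase the loss (asserted per iteration in tests). Convergence at an
absolute loss decrease below 1e-8, cap 10,000 iterations. Initialization is
the uniform matrix plus a 0.1 diagonal bump (deterministic, breaks label
symmetry toward the plausible optimum). Fitted entries are floored at
1e-10 and rows renormalized so a structurally zero column (an algorithm
that never names a cause) cannot produce infinite downstream log terms.
Causes with zero total reference mass raise an error naming the cause: the
calibration equation is meaningless for causes never observed in the
paired data.

**Fixed-M solve** (`solve_fixed_M`): exact linear solve of `q = M'p` when
`M'` has condition number below 1e10 and the unconstrained solution is
feasible; otherwise simplex-constrained least squares (SLSQP). A
numerically singular `M` raises with the advice to run the full sampler,
which is the honest treatment of that uncertainty.

**Sampler** (`sample_posterior`): random-walk Metropolis within Gibbs; one
block for `p` and one per row of each `M_a`, all on additive-log-ratio
coordinates (the ALR Jacobian `Π_j v_j` makes a uniform Dirichlet prior
contribute `Σ_j log v_j` in the unconstrained space, so every retained draw
is exactly on the simplex up to renormalization at 1e-12). Proposal scales
start at 0.3 and adapt in batches of 50 during burn-in toward ~25%
acceptance, frozen afterwards so the chains are valid Markov chains.
Defaults: 4 chains, 5,000 iterations, 2,500 burn-in, uniform Dirichlet
priors on `p` and each `M` row, loss unscaled inside the exponent (a
tempering knob exists for research use but is fixed at 1). `M` chains
start at the pseudo-ML fit and `p` at the fixed-M solve of the mean raw
CSMF — deterministic starts, fast burn-in. Chain seeds derive from one
root seed by `SeedSequence` spawning; fixed seed ⇒ byte-identical draws.
Split-R̂ and effective sample size (via arviz) are attached to the result;
R̂ > 1.05 is a recorded warning, not a failure. Paired records are
aggregated by distinct `x` pattern (at most C(C+1)/2 patterns) so a loss
evaluation is O(patterns × C), which is what makes replicate studies cheap.

**WAIC** (`waic`, `waic_uncalibrated`): the pointwise unit is one death
record; its generalized log-density is the negative of its loss
contribution, summed over algorithms for the ensemble. `lppd` uses a
stabilized log-mean-exp; `p_waic` is the per-record variance of the
log-density over draws; `waic = −2(lppd − p_waic)`. The uncalibrated
comparator fixes `M` at the identity: its survey posterior is then
conjugate (Dirichlet with the aggregate scores added), and paired records
are scored against their own epsilon-floored `x`. Scoring the paired
records too is what puts the two models on the same observation set: the
survey fit alone is nearly identical between them, and the misfit of the
identity model lives in the paired data. Note that under a truth with no
misclassification the calibrated model still pays a small premium — the
flat prior shrinks `M` rows off the one-hot boundary, and the extra
parameters inflate `p_waic` — so the honest null statement is a negligible
*per-observation* WAIC gap, not exact equality.

**CSMF accuracy**: `CSMFA = 1 − Σ_j |p̂_j − p_j| / (2(1 − min_j p_j))`,
1 at perfect agreement, 0 at the worst case (all mass on the rarest
cause).

## Preprocessing rules

- Cause grouping (fine → canonical labels) sums scores within groups and
  is applied before everything else, preserving total mass.
- Site exclusion drops flagged records and logs the count (the neonate
  stratum of the reference tables excludes one site's 274 deaths,
  614 → 340).
- Inconclusive rank-algorithm records: survey-side, the element-wise mean
  of all conclusive score vectors; paired-side, the single-cause
  misclassification row (mean conclusive `y` per *underlying* cause) of
  the record's underlying cause. Imputation is single-pass; imputed
  records then enter the multi-cause estimator once. Imputation flags are
  retained, and single-cause comparisons use non-imputed records only.
- Plurality-rule ties break to the lowest cause index (deterministic,
  order-stable).
- Records missing an immediate cause are single-cause: the only coherent
  reading of the {1, 0.5, 0} encoding.
- Compositions whose sum is off by ≤ 1e-6 (CSV rounding) are renormalized;
  larger deviations are rejected as corrupt.

## Synthetic-data generator

`gen_paired` / `gen_survey` emulate the assumed data-generating process:
underlying cause from the calibration-population CSMF, immediate cause
from a row-stochastic transition kernel, latent class `z` drawn from `x`,
probabilistic-algorithm output `y ~ Dirichlet(concentration × M_true[z])`
(mean-preserving; zero-mean components stay exactly zero), rank-algorithm
output with the top weight (default 0.75) on a first draw from `M_true[z]`
and the remainder on an independent second draw (a collision yields a
single-cause output — this keeps `E[y | z] = M_true[z]` exactly, which the
consistency checks require), inconclusiveness as an independent
per-record Bernoulli for the rank algorithm, and a site flag for
exclusion.

Stratum presets encode the study conditions: children — 7 causes, 426
paired and 1,841 survey deaths; neonates — 5 causes, 614 paired (site
exclusion probability 274/614) and 818 survey deaths; inconclusive
fraction 0.175 in both (the reported loss of ~15–20% of survey records to
inconclusive EAVA output); calibration-population CSMFs and transition
kernels from the packaged contingency-table profiles; survey CSMFs set to
round values near the published calibrated estimates. The Dirichlet
concentration defaults to 20 — individual-level score dispersion is not
identified by any published quantity, so it is a free realism knob, chosen
once.

What the generator does *not* emulate: questionnaire symptoms or the
internals of the VA algorithms, cause-dependent inconclusiveness (an
optional extension point), within-site correlation, or temporal drift.
Passing recovery tests therefore demonstrate correctness of the estimator
under the model's own assumptions, not robustness to their violation.

## Evaluation conditions

The replicate recovery study runs at C = 3, 500 paired / 2,000 survey
deaths, diagonally dominant truth (diagonal 0.7), concentration 25, with 2
chains × 1,200 iterations (600 burn-in) per replicate — chain lengths
chosen so that 100 replicates complete in about a minute while the
credible intervals remain conservative (observed coverage ≈ 98–100%
against the nominal 95%; the generalized posterior is wider than a
likelihood-based one when the compositional noise carries less information
than a multinomial draw). Posterior means recover the true CSMF with mean
absolute error ≈ 0.02 per cause. The WAIC comparison uses a strongly
non-identity truth at the same sizes.

## Known limitations

- The calibration is population-level only; no individual death is
  reassigned a cause.
- Identifiability degrades as `M` approaches singularity; the posterior
  then widens sharply (reported through the credible intervals) and the
  fixed-M solver refuses outright.
- The generalized-Bayes loss is used at learning rate 1 without
  loss-scale calibration; coverage is conservative rather than exact.
- The packaged tables carry aggregate scores only, so the published
  calibrated CSMFs themselves are not recomputable from shipped data; the
  fixtures support arithmetic and structural checks, and the full pipeline
  is exercised on synthetic data.
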