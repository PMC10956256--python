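# Methods

## Model

All base learners share the whole-genome linear model

    y = X α + Z β + e,    e ~ N(0, σ²ₑ I)

with `y` the phenotypes of the training individuals, `Z` the additive marker
codes (0/1/2 for biallelic SNPs, 0/1 for dominant presence/absence markers),
`β` the marker effects and `X` an intercept plus optional fixed covariates.
Genetic values are `g = Z β` (equivalently `g ~ N(0, σ²_g G)` for GBLUP).
Binary disease status, where used, is treated as a 0/1 continuous response
under the same model.

### GBLUP

The genomic relationship matrix is VanRaden method 1: columns centered by
twice the allele frequency (taken as half the mean code) and the
cross-product scaled by `2 Σ pₖ(1−pₖ)`.  For dominant 0/1 markers this
scaling is only a global constant, which REML absorbs into `σ²_g`.  Variance
components come from the restricted likelihood profiled over
`λ = σ²ₑ/σ²_g` on the eigenbasis of the training-block kinship (a 41-point
log₁₀ grid scan on [−5, 5] followed by bounded Brent refinement, tolerance
1e−6 in log₁₀λ).  If the smallest eigenvalue of the training block is below
1e−8, a 1e−6 ridge is added (the unjittered cross-block is still used for
prediction).  Held-out individuals are predicted by the conditional mean
`g_test = K_test,train (K_train + λI)⁻¹ (y − Xβ̂)`.

### Bayesian alphabet

BayesA, BayesB and BayesCπ are fit by single-site Gibbs sampling over
markers (a numba-compiled kernel; all chain randomness is seeded, so runs
are exactly reproducible).  The three variants differ only in the prior on
`βₖ`:

* **BayesA** — every marker in the model, `σ²ₖ ~ scaled-inv-χ²(ν, S)`;
* **BayesB** — spike-and-slab, inclusion probability π fixed (default 0.1),
  per-marker slab variances; inclusion is sampled from the marginal
  likelihood ratio with `βₖ` integrated out;
* **BayesCπ** — spike-and-slab with one common slab variance and
  `π ~ Uniform(0,1)`, updated from its Beta full conditional (clamped to
  [1e−6, 1−1e−6] to keep the inclusion odds finite).

Hyperpriors are not fixed by the method's description and are our defaults:
ν = 5 for both marker and residual variances, and scales chosen so the
prior-expected genetic/residual variance split is `r² = 0.5` of the
phenotypic variance, with the marker share divided by `Σₖ Var(zₖ)` times
the expected inclusion fraction.  Chains default to 5000 iterations with
1000 burn-in (the benchmark uses 2000/500; posterior-mean effects are stable
at that length for the panel sizes involved).  Genetic values are
`Z β̄` with `β̄` the posterior mean; masked individuals use the same rule.

## Ensemble weight training

The ensemble prediction is the *unnormalized* weighted sum
`ĝ = Σⱼ Wⱼ pⱼ` over base-method predictions.  The fitness of a weight
vector is the Pearson correlation between `ĝ` and a target vector; because
correlation is scale-invariant there is no sum-to-one constraint, and a
zero-variance ensemble output maps to a −∞ sentinel that loses every
selection comparison (a run whose initial particles are all degenerate
aborts).

One optimizer restart runs, with `m = 20` particles over weight vectors in
`[0, 1]ⁿ`:

1. **Initialization** — weights uniform in `[W_min, W_max] = [0, 1]`,
   velocities uniform in `[V_min, V_max] = [−0.01, 0.01]`; incumbent =
   best-fitness particle.
2. **Mutation** — drift candidate `Pᵢ = Wᵢ + Vᵢ` and differential candidate
   `Hᵢ = Wₖ + F (Wₚ − W_q)` with `F = 0.5` and `k, p, q` drawn without
   replacement from the other particles, resampled per particle per
   iteration; both candidates clamped to the weight box.
3. **Crossover** — one uniform draw per particle: `Uᵢ = Hᵢ` if
   `rand ≤ CR = 0.3`, else the particle's previous weights (a per-dimension
   variant is available behind a flag).
4. **Greedy selection** — `Uᵢ` vs `Pᵢ`, then the survivor vs the previous
   weights, ties favoring the newer candidate; particle fitness is therefore
   non-decreasing, and so is the incumbent trajectory.
5. **Velocity update** — `Vᵢ ← ε Vᵢ + c₁ r₁ (Wᵢ(t) − Wᵢ(t−1)) +
   c₂ r₂ (W_best(t−1) − Wᵢ(t−1))` with `ε = 1`, `c₁ = c₂ = 2`, clamped to
   the velocity box.  Without clamping, `c₁ = c₂ = 2` would immediately
   dwarf the stated velocity bounds, so run-long clamping is the coherent
   reading of those bounds.

The restart stops after `Max_iterations = 25` (an optional
early-stop — incumbent gain < 1e−8 over 5 iterations — is off by default,
since the fixed budget is the reproducible baseline).  Training runs 100
restarts, restart *r* seeded `base_seed + r`, and averages the returned
incumbents component-wise; the averaged weights make the final prediction.
The mutation loop is vectorized over particles; the order of RNG draws
within an iteration is an internal choice and only the per-restart stream is
contractual.

### Targets: phenotype vs reference mode

With observed phenotypes on the fitted cohort, the target is `y` directly
(*phenotype mode*).  For an unphenotyped target cohort (*reference mode*),
the base method whose fitted genetic values best correlate with the
*training* phenotypes supplies its predictions on the target cohort as
*reference genetic values*, and the weights are trained on the target
cohort's predictions against them.  Reference mode has a degenerate global
optimum — all mass on the reference method gives fitness 1 — and is
implemented as described, without repairing the objective: the bounded
25-iteration search plus 100-restart averaging is precisely what keeps the
other methods' weights non-zero, and measured on the benchmark the ensemble
consistently edges out its own reference method.

## Evaluation protocol

Monte Carlo cross-validation: independent random 9:1 partitions (real-data
protocol) or a shuffle into five near-even parts with one held out
(simulation protocol, test sizes n/5 ± 1).  Predictive ability is the
Pearson correlation between predictions and held-out phenotypes (for
simulations, ability against the true genetic values is reported
alongside).  Because all methods share each replicate's split and base-learner
fits, methods are compared by a paired-sample t-test on per-replicate
abilities: `t = d̄/(s_d/√R)`, df `R − 1`, two-sided by default (one-sided
available).  Under a simulated null the empirical size is 4–5% at α = 0.05.

## Trait simulator

The generator emulates a wheat inbred panel: 599 individuals × 1279
dominant 0/1 markers, per-marker presence frequencies uniform on
(0.1, 0.9) — a post-QC-like spectrum chosen once; a Hardy–Weinberg 0/1/2
mode exists for SNP panels.  QTL positions are uniform without replacement;
effect magnitudes are Gamma(shape 0.4, scale 1.66) (mean |effect| 0.664)
with equiprobable random signs (all-positive behind a flag).  The residual
variance is `Var(g)·(1−h²)/h²` against the *empirical* variance of the
genetic values, so each replicate hits its target heritability in
expectation; `h² = 1` yields exactly noise-free phenotypes.  A fixed-seed
fixture (`wheat_fixture_genotypes`) provides a deterministic 599 × 1279
panel for tests; it is synthetic and clearly so.

**What the generator does not emulate:** linkage disequilibrium, allele-
frequency spectra estimated from real data, population/pedigree structure,
and epistasis.  The independence of markers matters for one result in
particular.  Reference-mode selection ranks methods by *training-set* fit,
and on an independent-marker panel the most flexible learners (BayesA, and
GBLUP when REML shrinks little) reach training correlations near 0.96 while
the best *test* predictor (BayesCπ under a 5-QTL architecture) fits the
training set near 0.71.  The reference is then often a method ~0.05 below
the best on test, and the ensemble — which reliably improves on its
reference by a few thousandths — cannot cover that spread.  On panels with
LD the test-ability spread between base methods collapses to ~0.01–0.02
(verified with a block-correlated panel), which the ensemble's gain can
cover; this is the regime in which stacking beats every base method.
Passing benchmark results on the fixture therefore demonstrate the
mechanism (monotone optimization, oracle-level optima, gain over the
reference, the GBLUP deficit shrinking from oligogenic to polygenic
architectures) but understate what the method achieves on real, LD-rich
panels; the fixture benchmark's "ensemble above every base method" ordering
is not expected to hold and is reported honestly.

## Numerical choices and degenerate inputs

* Pearson fitness on a zero-variance vector → −∞ sentinel, never silently 0;
  `predictive_ability` on constant input raises.
* Argmax ties (incumbent, reference selection) break by lowest index; "≥"
  comparisons let new candidates win selection ties.
* Genotype loaders mean-impute missing codes per marker (configurable to
  hard-fail); codes outside [0, 2] and duplicate ids are rejected with the
  offending row/id named.
* A kinship over only monomorphic markers is rejected (checked by column
  variance, since a marker fixed at code 1 still has allele frequency 0.5).
* A QTL set whose genetic values are constant is redrawn up to 10 times.
* Benchmark problem sizes: 20 replicates per simulation scenario with
  2000/500 chains — chosen as the package's standard scaled-down protocol;
  per-replicate chain and optimizer seeds are derived from the base seed
  (offset 7919·replicate) so every replicate is independently reproducible.

## Known limitations

* The Bayesian samplers use our documented default hyperpriors, not any
  particular external implementation's; no claim of bit-compatibility with
  other software.
* No MCMC convergence diagnostics beyond the chain settings recorded in the
  fit; chains short enough to be fast can understate posterior uncertainty
  (posterior means, which the ensemble consumes, are much more stable).
* Reference mode inherits the degenerate-optimum caveat above by design.
* The CLI covers single-trait analyses; multi-trait models, LD-aware
  simulation and nested cross-validation are out of scope.
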