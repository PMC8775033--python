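# Methods

This note records the statistical model behind `propbayes`, the numerical
design of each property engine, the synthetic study systems, and the
choices made where the design was genuinely open. Every number quoted here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## 1. The inference model

Let `q = (q_1, …, q_k)` be the unknown distribution of a discrete system
and `F(q)` a scalar property of it (entropy, mutual information, a marginal
probability). Given a count vector `n` with `n = Σ n_i` samples, the
estimator is the posterior mean of `F` under a prior that is deliberately
agnostic about everything except `F` itself: the one-parameter
maximum-entropy family

```
p(q | β) ∝ exp[β F(q)],
```

the unique family that is constant on each level surface of `F` and has no
structure beyond a constrained mean property. β plays the role of an
inverse temperature: β → +∞ concentrates the prior on the maximal-`F`
surface, β → −∞ on the minimal one, β = 0 is the flat prior on the simplex.

All member-level quantities come from the log-partition function of the
tilted posterior, exactly as in equilibrium statistical mechanics:

* `⟨F|n,β⟩ = ∂β log Z(n,β)` (posterior property mean),
* `⟨ΔF²|n,β⟩ = ∂²β log Z(n,β)` (posterior property variance),
* `log p(n|β) = log Z(n,β) − log Z₀(β)` (evidence, up to β-independent
  constants — multinomial coefficients and discretization constants are
  deliberately dropped since they cancel in every comparison across β).

`Z₀(β)` is always obtained by evaluating the same `log Z` implementation on
an empty counts object, never through a second formula, so the prior and
posterior routes cannot drift apart numerically.

**Hyperparameter selection.** The default estimator is the MAP member: the
root β₀ of the discrepancy `D(β) = ⟨F|n,β⟩ − ⟨F|β⟩`, i.e. the β at which
prior and posterior property estimates coincide. This is the stationary
point of the evidence under a flat hyperprior (empirical Bayes). The flat
hyperprior is a modeling choice: when the data contain coincidences the
evidence is sharply peaked and the hyperprior's shape is immaterial; when
they do not, no choice of hyperprior would help. Evidence-weighted
averaging over a β grid (`averaged_estimate`) is available as an opt-in
alternative; it integrates uniformly in β (the Jacobian between the mean-
value and exponential parametrizations is not tracked — a documented
simplification) and agrees with the MAP estimate within one posterior
standard deviation whenever the evidence peak dominates.

**Existence of the fixed point.** `D(β) → 0` at both β extremes (prior and
posterior both saturate at the property bounds), so a root is an interior
crossing, and for some datasets — notably very small `k`, or conflicting
coincidence evidence — `D` stays one-signed and no interior MAP exists.
The solver then reports a non-convergence error with `D` at both bracket
ends rather than inventing a boundary estimate. Zero counts, or data whose
evidence is exactly flat in β (coincidence-free data in the MI model),
yield a *degenerate* solution pinned at β₀ = 0.

**Solver policy.** Root finding operates on the scaled coordinate
γ = β/kx for the two bivariate models (whose natural per-state tilt is
β/kx) and on raw β for entropy. The initial bracket is γ ∈ [−50, 50],
scanned on 9 points, doubled up to 8 times if no sign change is found;
the bracketed root is refined by Brent's method. Evaluations that fail at
extreme β (partition-function underflow) are treated as carrying no sign
information during the scan. Derivatives default to analytic routes where
available (all three models register one for the mean); the generic path
is central differences with step `1e-3·max(1,|β|)`, Richardson-extrapolated
once, with the variance from a 5-point second-difference stencil. The
finite-difference path is retained as a cross-check: analytic and numeric
means agree to ≤1e-6 (marginal, MI) and ≤1e-4 (entropy) on all fixtures.

Internal units are nats throughout; the CLI converts to bits on request.

## 2. The three property engines

### Marginal probability (closed form)

System: `kx` equiprobable hidden states, binary outcome; target
`q₁ = mean_x q₁|x`. Prior, likelihood and posterior factorize per state and
each factor's normalizer is a confluent hypergeometric function, so

```
log Z(n,β) = Σ_x log M(n1x+1, nx+2, γ),    γ = β/kx,
```

with the `kx − (sampled)` unsampled states contributing `M(1,2,γ)` factors.
`log M(a,b,z)` is evaluated through `scipy.special.hyp1f1`, with the Kummer
transformation `M(a,b,z) = e^z M(b−a,b,−z)` applied for `z < 0` so the
underlying series has positive terms (no cancellation); the supported range
`|z| ≤ 500` is guarded, beyond which the per-state mean saturates within
1e-12 of its bound and the evaluator clamps with a warning. Accuracy is
verified against mpmath at 1e-10 relative and against the Kummer contiguous
relations.

The model's notable exact property, reproduced to machine precision by the
solver: on coincidence-free data (all `nx ≤ 1`) the MAP estimate equals the
plug-in frequency `n₁/n`.

### Mutual information (per-state quadrature)

System as above with symmetric outcome marginal (`q_y = 1/2`, hard-coded;
non-uniform marginals are out of scope). The property decomposes as
`I = mean_x Ix(q₁|x)` with `Ix(q) = ln 2 + q ln q + (1−q) ln(1−q)`, so the
partition function factorizes into one-dimensional integrals

```
Z(n1, n0, γ) = ∫₀¹ q^n1 (1−q)^n0 e^{γ Ix(q)} dq.
```

Each factor is evaluated with a fixed 200-node Gauss–Legendre rule on
(0, 1) in the log domain (log-sum-exp over nodes). The integrands are
smooth and bounded, so a fixed rule keeps the solver deterministic and
fast; agreement with adaptive quadrature is ≤1e-8 on the log scale over
the count and γ ranges the solver visits. The rule's symmetry about 1/2
makes the singleton identity `Z(1,0,γ) = Z(0,0,γ)/2` hold at machine
precision — which is the structural reason only coincidence states
(`nx ≥ 2`) carry β-dependent evidence: every singleton contributes the
exact constant −ln 2 to the log evidence, and the evidence is flat in β iff
`k2 = 0`. States are processed in multiplicity groups (distinct `(n1, n0)`
pairs), which is exactly equivalent to the per-state product.

### Entropy (grid convolutions)

Target `H(q) = −Σ q_x ln q_x` over `k` accessible states. The tilted
posterior factor per state is `w_c(q) = q^c e^{−β q ln q}` and the simplex
constraint makes `Z(n,β)` the k-fold convolution of these factors evaluated
at total mass 1. The engine:

* tabulates factors on a uniform grid on [0, 1] (default G = 4096 points),
  with the endpoint limits `w_0(0) = 1`, `w_c(0) = 0` for `c ≥ 1`,
  `w_c(1) = 1` taken exactly (`x·ln x → 0` handled by `xlogy`);
* convolves pairs with the trapezoid rule **in the time domain**
  (`np.convolve`), truncating every intermediate to [0, 1] — valid because
  all factors are supported on [0, 1], so mass beyond 1 can never reach the
  value at 1. Direct convolution was chosen over FFT deliberately: at
  β < 0 the density at the endpoint sits orders of magnitude below its
  maximum and FFT round-off noise would swamp it, while direct convolution
  of non-negative arrays is exact to relative rounding;
* raises the `m_c` identical factors of each multiplicity class to
  convolution powers by repeated squaring (O(log k) convolutions per
  distinct count value) and carries a separate log-scale per array to avoid
  under/overflow;
* applies one factor of the grid spacing per pairwise convolution, so
  differences `log Z(n,β) − log Z(0,β)` are grid-consistent.

The posterior mean uses a leave-one-out identity: `E[−q ln q | count c]` is
a ratio of two convolution evaluations, the numerator with one factor
replaced by `(−q ln q)·w_c(q)`. Summed over classes this is the analytic
route; the finite-difference route through `log Z` agrees to ≤1e-4.

Correctness gates, all in the test suite: at β = 0 the engine must match
the flat-Dirichlet closed forms — the posterior mean entropy
`ψ(n+k+1) − Σ (n_i+1)/(n+k)·ψ(n_i+2)` and the Beta-function identity for
`log Z(n,0) − log Z(0,0)` — to 1e-3 at G = 2048 over a (k ≤ 30, n ≤ 12)
fixture grid; at β = ±2 it must agree with an importance-sampling oracle
(proposal Dirichlet(n+1), weights `e^{βH}`, 2×10⁵ draws) within 3 standard
errors; and results at G and 2G must differ by ≤1e-4 nats. Convergence is
O(Δ²), which sets the G = 4096 default.

`k` is a required parameter of the entropy model: the number of accessible
states genuinely changes the estimate, no principled marginalization over
`k` is attempted, and if `k` is omitted the observed support is used with a
prominent warning.

## 3. Synthetic study systems

The generators define the study conditions; their defaults are the
conditions under which the recovery claims are tested.

**Bivariate system** (`make_bivariate_system`): `kx = 100` equiprobable
states, conditionals `q₁|x` i.i.d. Beta(0.5, 0.5), `n = 60` samples
(x uniform, then `y ~ Bernoulli(q₁|x)`). The arcsine-shaped Beta pushes
conditionals toward the deterministic endpoints, giving a population mean
information `E[Ix] ≈ 0.307` nats and, at `n = 60`, an expected `k2 ≈ 12`
coincidence states — deep in the undersampled regime where the plug-in
estimator is uninformative (on singleton-only data it returns the empirical
outcome entropy, ≈ ln 2, regardless of the truth). Over 100 replicates the
MAP estimator's mean absolute bias is roughly forty times smaller than the
plug-in's (≈0.006 vs ≈0.29 nats, seed-dependent); per-replicate scatter
(RMSE) remains comparable, as expected — the gain is in bias, not variance.

**Evidence-width sweep** (`evidence_width_vs_k2`): the width of the
evidence peak is measured as the Laplace width `(−∂²_γ log p(n|γ))^{−1/2}`
at the MAP, using the identity that the per-state evidence curvature is
`Var_post[Ix] − Var_prior[Ix]`. The sweep scales `kx` and `n` together
(`n = 0.6·kx`, `kx` from 100 to 1600), which grows `k2` while keeping each
coincidence state's information content fixed. Widths are heavy-tailed
across replicates — a dataset whose coincidences look like `q = 1/2` pushes
γ₀ onto the flat left shoulder of the evidence — so the regression uses the
median width per level against the mean `k2`. The fitted log-log slope is
−0.54 ± 0.03 across seeds, consistent with the theoretical −1/2. Levels
below `kx = 100` are excluded because there the fixed point frequently
fails to exist and the dropout would bias the level medians.

**Power-law system** (`make_powerlaw_system`): ranked probabilities
`q_r ∝ r^{−3/2}` over `k = 30` states (true entropy 2.1244 nats), sampled
`n = 6` at a time. The entropy benchmark enumerates all 11 multiplicity
sets of `n = 6`, discards the coincidence-free set `(1,1,1,1,1,1)` (no
evidence, degenerate MAP) and the fully concentrated set `(6,)`, weights
the remaining 9 by their probability under the source — by default a
Monte-Carlo frequency over 10⁶ multinomial draws; an exact
dynamic-programming computation over count-to-state assignments is
available and agrees within Monte-Carlo error — and compares each method's
weighted mean to the truth. Measured weighted absolute errors: MAP ≈ 0.04
nats, versus ≈ 0.97 (plug-in), ≈ 0.74 (Miller–Madow), ≈ 0.84 (flat-Bayes,
which at `k = 30` is dominated by the prior mean `ψ(31) − ψ(2) ≈ 2.995`).

**What the generators do not emulate.** Real data rarely have exactly
equiprobable hidden states, an exactly symmetric outcome marginal, or a
known `k`; conditionals need not be Beta, and samples need not be i.i.d.
Passing these benchmarks therefore demonstrates correct inference *under
the model's assumptions* and calibrated machinery — not robustness to
misspecification, which is untested here.

## 4. Numerical choices and degenerate inputs

* Variance estimates are clipped at zero; raw values below −1e-8 (convexity
  violation beyond tolerance) raise a warning.
* Posterior variance of the property, not of the estimator, is reported as
  `std`; for sharply peaked evidence it understates total uncertainty by
  the between-member spread, which `averaged_estimate` includes.
* Flat discrepancy over the whole scanned bracket (max |D| ≤ 1e-8) is
  declared degenerate rather than picking an arbitrary root.
* Empty data give the degenerate β₀ = 0 member for all three models.
* `k = 1` entropy is the closed case `H = 0`.
* Ties among equal-likelihood multiplicity sets need no special handling:
  the benchmark weights, it does not rank.

## 5. Problem sizes

Default experiment sizes — 100 MI replicates, 16 width replicates per
level over five levels, 9 entropy solves at G = 4096, 10⁶ weighting draws —
were chosen so the full recovery suite recomputes in a few minutes on one
CPU while leaving the Monte-Carlo error of every stochastic comparison an
order of magnitude below the effect being measured.

## 6. Known limitations

* The entropy engine's partition function can underflow at the [0, 1]
  endpoint for extreme |β| (roughly |β| ≳ 300 at `k = 30`); the solver
  treats such points as uninformative during bracketing and errors cleanly
  if the root itself lies beyond reach.
* The MI quadrature loses accuracy for |γ| well beyond the solver's
  default search range (integrand width ~1/γ vs 200 nodes); within
  |γ| ≤ 500 it is verified to 1e-8.
* No marginalization over `k` (entropy) and no non-uniform `x` marginals or
  multi-valued outcomes (MI/marginal) — these are explicit non-goals.
* The MAP fixed point need not exist for tiny systems (see §1); this is a
  property of the method, not a solver deficiency.
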