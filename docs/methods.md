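# Methods

## The estimation problem

A closed population of unknown size N is observed through a single
register over a discrete window of T time-steps. Every member, while not
yet registered, has per-step registration probability π; registrations
after the first may occur with a different probability. Persons with no
registrations are invisible, so the data are (i) the first-registration
times and (ii) the per-person registration counts of the observed
sub-population. The package estimates N from either reduction.

## Removal maximum likelihood

The window (optionally after a burn-in, below) is split into M equal
epochs of d = floor(T'/M) steps; trailing steps that do not fill an
epoch are dropped so the per-epoch registration probability
p = 1 − (1 − π)^d is constant across epochs. The first-registration
counts n₁..n_M then follow the conditional binomial chain
n_j | n₁..n_{j−1} ~ Bin(N − Σ_{i<j} n_i, p): registered persons are
"removed" from the at-risk pool, so the counts decline in expectation —
and the *rate* of decline identifies how many were never seen.

With s = Σ n_j, X = Σ (j−1) n_j and q = 1 − p, the joint log-likelihood
is, up to constants,

    L(N, p) = log Γ(N+1) − log Γ(N−s+1) + s log p + A log q,
    A = Σ_i (N − Σ_{j≤i} n_j) = M(N − s) + X.

Setting both partial derivatives to zero (with the Stirling form
n! ≈ n log n − n for the N-derivative) reduces the 2-D problem exactly
to one profile equation in q:

    q/(1−q) − M q^M/(1−q^M) = X/s,       N̂ = s/(1−q^M),  p̂ = 1−q.

### Numerical treatment

The left side is evaluated through the cancellation-free identity

    q/(1−q) − M q^M/(1−q^M) = (Σ_{i=1}^{M−1} q^i S_{M−i}) / S_M,
    S_k = 1 + q + … + q^{k−1},

which contains no subtraction, is exact at both endpoints (0 at q = 0,
(M−1)/2 at q = 1) and is monotone increasing, so Brent's method on
[0, 1] is guaranteed a bracket and cannot diverge — this replaces the
fragile 2-D Newton iteration, whose convergence is known to depend on
starting values. The root is found to xtol = 1e−12 and the residual of
the score equation is reported in the result diagnostics. `N̂` is
treated as continuous and additionally reported rounded to the nearest
integer. Degenerate case X = 0 (everyone caught in epoch 1): q = 0,
p̂ = 1, N̂ = s, handled explicitly.

A solution exists iff X/s < (M−1)/2 — the standard removal-design
solvability condition, which reduces to n₁ > n₂ at M = 2. Equality is
treated as nonexistence (it is the n₁ = n₂ boundary). Nonexistence is
*data*, not an error: fits return `valid=False` with the reason, and the
Monte Carlo harness counts such replicates in `failure_rate`.

Two likelihood forms are exposed: the exact log-gamma form above
(default for likelihood evaluation) and the literal Stirling form. Both
give the same profile equation in continuous N up to O(1/N) terms; the
reported estimator is defined by the profile equation, whose stationary
point is exactly the Stirling-form optimum.

### Burn-in

A first registration early in the window may in truth be the middle of a
care sequence that started before observation began. The reduction
therefore supports a burn-in: the first b time-steps are discarded and —
importantly — every person whose *first* event falls inside them is
excluded entirely, not merely truncated, since their later events would
masquerade as first contacts.

## Truncated-Poisson estimators

When registrations are memoryless, per-person counts are Bin(T, π) ≈
Poisson(λ = Tπ) for the small per-step probabilities typical of
registries (e.g. 30% yearly coverage at daily resolution: π ≈ 0.001,
λ ≈ 0.36). From E(h_j) = N λ^j e^{−λ}/j! follows
E(h₀) = E(h₁)²/(2E(h₂)), giving Chao's estimator
N_C = Σ h_j + h₁²/(2h₂) and, estimating the rate by λ_e = 2h₂/h₁,
Zelterman's N_Z = Σ h_j/(1 − e^{−λ_e}). Plugging exact Poisson expected
frequencies into either formula returns N identically (a unit-test
invariant). Chao with h₂ = 0 is reported invalid rather than silently
replaced by a bias-corrected variant. The capture histogram accepts
non-integral counts so expected frequencies can be used as analytic
inputs.

Both estimators assume registration does not alter future registration.
If a registered person's per-step probability changes from p₁ to
p₂ = p₁/k, the plug-in ratio E(h₁)²/(2E(h₂)) tends to kN as the rates
become small — an arbitrarily large overestimate for k > 1, and a
corresponding underestimate when p₂ > p₁. `evaluation.expected_chao`
computes the exact finite-sample expectations by brute-force summation
over the two-phase binomial process (first-registration time geometric,
re-registrations binomial on the remaining steps), both the plug-in form
and the exact expectation of the random ratio h₁²/(2h₂) conditional on
h₂ > 0 (h₁ | h₂ is binomial under the multinomial class structure, so
the sum is finite and exact); the latter exceeds the former by the
Jensen gap of 1/h₂, which matters whenever E(h₂) is modest.

## Diagnostics

* **M-sensitivity** refits the removal estimator across a list of M and
  reports the relative spread of the valid estimates; strong dependence
  on M indicates an inadequately sampled population.
* **Split-window Chao stability** compares Chao's estimate on the first
  half of the window with the full window; under the Poisson assumption
  the two agree in expectation, while state-dependent registration makes
  them drift apart.
* **Poisson ratio** r₁₂ = h₁/(2h₂), equal to h₀/h₁ under the Poisson
  model when an external census supplies h₀.

## Synthetic registers

`SimulationConfig` fixes the study conditions: N, T (default 512 steps),
the per-step probability p₁ (or a whole-window `target_coverage`, mapped
through π = 1 − (1 − c)^{1/T}), between-individual heterogeneity (p_i
drawn once per individual from Normal(p₁, sd), clipped to [0, 1] — so
large sd yields genuinely unobservable individuals, deliberately), and
the post-registration multiplier `p2_factor`. Draws are vectorized:
geometric first-registration times by inverse CDF, then exact per-step
Bernoulli draws for re-registrations when a full event table is needed,
or a Binomial re-registration count (`simulate_sufficient_stats`, O(N))
when only epoch counts or capture histograms are consumed, as in the
Monte Carlo harness; the two paths sample the same joint law of those
statistics, and a distributional test compares them. Identical config
and seed give byte-identical output. Uniform heterogeneity is not
implemented; the normal model with an sd knob spans the axis of
interest.

What passing simulation tests shows — and does not show: the generator
realises exactly the closed-population, constant-probability world (plus
the two controlled violations), so they validate the estimators' math
and the harness, not robustness to open populations, reporting delays or
duplicate administrative rows.

## Monte Carlo evaluation

`run_grid` summarises each (estimator, N, coverage, heterogeneity,
p2_factor, M) cell by the coefficient of variation (sample SD over
sample mean of N̂) and the relative bias (sample mean over true N) over
valid replicates, with invalid replicates counted in `failure_rate`.
Default 500 replicates per cell (raise for publication-grade smoothness;
the desk-scale acceptance checks use 200). Per-replicate generators are
seeded by `SeedSequence(master, N, round(coverage·10⁶), replicate)`, so
any sub-grid reproduces exactly regardless of execution order.
`m_agreement` fits all requested M to the *same* realizations and
reports Pearson correlations over replicates valid under every M.

### Operating points used in the acceptance checks

* Removal ML at (N = 50000, coverage 0.15, M = 8) and (N = 500,
  coverage 0.55, M = 8), 200 replicates each. Note: the asymptotic CV of
  the removal estimator at the first design is 0.229 (expected Fisher
  information; essentially independent of M), so a CV below 0.3 — not
  0.1 — is what this design can deliver; the corresponding check is
  asserted at its stated band regardless and documents the discrepancy.
* Chao under p₂ = p₁/2 at N = 1000, coverage 0.2, 200 replicates.
  Coverage 0.2 (λ₁ ≈ 0.22) was chosen because the kN asymptote requires
  small rates while E(h₂) ≈ 11 keeps the estimator defined in
  essentially every replicate (P(h₂ = 0) ≈ 2·10⁻⁵). At this design the
  exact expectation of the estimator is ≈ 2073 vs the asymptote
  k·N = 2000; the simulated mean is compared to the exact expectation
  within a Monte Carlo band and to kN within ±10%.
* Cross-M agreement at N = 1000, coverage 0.5 (a design with CV ≤ 0.3),
  M ∈ {8, 16, 32}, 200 shared realizations, correlations ≥ 0.98.

## Known limitations

* No confidence intervals: point estimation only, matching the method's
  original formulation; a bootstrap would be straightforward but is out
  of scope.
* The removal estimator's sampling distribution is right-skewed at low
  information (small N·coverage); means over replicates then exceed N
  even though the estimator is asymptotically unbiased, and single
  estimates can be far off — the CV/bias grid is the guide to when it is
  usable.
* Closed-population and constant-first-registration-probability
  assumptions; moderate heterogeneity is tolerated (verified by the
  heterogeneity axis of the harness) but mass at p ≈ 0 biases any
  single-register method.
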