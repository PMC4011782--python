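# hiddenpop

Estimating the size of partly *hidden* populations — problem drug users,
undiagnosed patients, any group whose members cannot simply be counted —
from a **single register** of timestamped events (health-care contacts,
arrests, prescription fills).

Each member of a closed population of unknown size *N* has, per discrete
time-step, a probability *π* of being registered; registrations carry a
person identifier and a time-point, so the register records *when each
person was seen and how often*, but never the people with zero
registrations. `hiddenpop` implements two complementary ways of
estimating that hidden zero class:

* **Removal maximum likelihood.** Divide the window of length *T* into
  *M* equal epochs and count the previously unregistered persons first
  appearing in each epoch, n₁,…,n_M. With per-epoch registration
  probability p = 1 − (1 − π)^d these counts form a conditional binomial
  chain n_j | n₁..n_{j−1} ~ Bin(N − Σ_{i<j} n_i, p) — the classical
  capture-and-remove design. Writing s = Σ n_j and X = Σ (j−1) n_j, the
  ML estimate solves the profile score equation in q = 1 − p,
  q/(1−q) − M q^M/(1−q^M) = X/s, and N̂ = s/(1−q^M). A solution exists
  iff X/s < (M−1)/2 (for M = 2: n₁ > n₂, with the closed form
  N̂ = n₁²/(n₁−n₂)). Because only *first* registrations enter, this
  estimator is immune to the probability of being seen *again* changing
  after first contact — the typical situation in health-care data.
* **Zero-truncated Poisson estimators (Chao, Zelterman).** If per-person
  counts are Poisson(λ), then E(h₀) = E(h₁)²/(2E(h₂)), giving
  N_C = Σ h_j + h₁²/(2h₂) and N_Z = Σ h_j/(1 − e^(−2h₂/h₁)) from the
  capture-frequency histogram h_j. These are more efficient when the
  Poisson assumption holds and badly biased when it does not: with the
  re-registration probability reduced to p₁/k, E(h₁)²/(2E(h₂)) → kN.

The package also provides the matching diagnostics (sensitivity of the ML
estimate to M, the split-window stability of Chao's estimate, the
h₁/(2h₂) Poisson-ratio check), a synthetic-register simulator
(heterogeneous registration probabilities, post-registration probability
switching) and a Monte Carlo harness mapping the bias and coefficient of
variation of every estimator over population size and sampled fraction.

## Worked example

The removal estimator on the raster-illustration register (N = 50
persons, 60 time-steps, π = 0.025, M = 3 epochs of 20 days, observed
first-registration counts 19, 10, 8):

```python
>>> from hiddenpop import EpochCounts, RemovalModel
>>> print(RemovalModel(EpochCounts((19, 10, 8), d=20)).fit().summary())
Removal maximum-likelihood population size
============================================
  epochs M                   3
  counts n_j       (19, 10, 8)
  observed s_M              37
Population size estimate (removal-ml)
--------------------------------------------
  N_hat                49.3570
  N_hat (rounded)           49
  nuisance            0.369737
  valid                   True
  q_hat           0.630262964197069
  score_residual  1.9473311851925246e-13
  iterations      7
```

37 distinct persons were observed; the fitted per-epoch registration
probability is p̂ = 0.37 and the population estimate is 49 — one short
of the true 50.

The truncated-Poisson estimators on a real care register of fatal
opiate-overdose cases (262 persons ever in substance-misuse inpatient
care during the five years before death, 75 of them exactly once and 55
exactly twice; the true census is 486):

```python
>>> from hiddenpop import CaptureHistogram, chao, zelterman, poisson_ratio_diagnostic
>>> hist = CaptureHistogram({1: 75, 2: 55}, observed_total=262)
>>> chao(hist).N_hat_rounded
313
>>> round(zelterman(hist).N_hat, 1)
340.6
>>> round(poisson_ratio_diagnostic(hist).r12, 2)
0.68
```

Both truncated-Poisson estimates fall far short of the census — being in
care once strongly raises the chance of further care, violating the
Poisson assumption, as the small one-vs-twice ratio 0.68 already hints.
The removal estimator applied to the same register's first-care dates
does far better (the original analysis reports 462 at M = 2).

Simulation and evaluation from the shell:

```bash
hiddenpop simulate --N 50 --T 60 --p 0.025 --seed 1 --out events.csv
hiddenpop estimate events.csv --method all --M 3 --T 60
hiddenpop evaluate --N 1000 --coverage 0.3 --coverage 0.5 --replicates 200 \
    --estimator ml --seed 0 --out grid.csv
```

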