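# survemvs

Spike-and-slab Bayesian variable selection for high-dimensional Weibull
survival regression, fitted to the posterior mode by an EM algorithm.

## Who this is for

Prognostic-marker discovery in omics cohorts: you observe right-censored
survival outcomes `(T_i, δ_i)` for `n` subjects together with a
high-dimensional marker matrix `X` (genotypes, expression, methylation;
`p ≫ n`) and optionally a handful of clinical covariates `Z`. The goal is to
select the few markers genuinely associated with survival, estimate their
effects, and score predictive accuracy — without the hours-long MCMC runs
that full Bayesian variable selection normally requires.

## The model

Survival times follow a Weibull regression with shape `α` and scale

    λ_i = exp(−(Z_i u + X_i β)),
    f(T|λ,α) = α T^{α−1} λ exp(−λ T^α),   S(T|λ,α) = exp(−λ T^α),

so the censored-data log-likelihood is
`log L = Σ_i [δ_i log f(T_i) + (1−δ_i) log S(T_i)]`. Each marker effect β_j
carries a two-component normal mixture prior indexed by a latent inclusion
indicator γ_j ∈ {0,1}:

    β_j | σ², γ_j ~ N(0, σ²[(1−γ_j) υ0 + γ_j υ1]),   0 < υ0 < υ1,
    γ_j | θ ~ Bernoulli(θ),  θ ~ Beta(a,b),  σ² ~ IG(ν/2, νη/2),

with flat priors on `u` and `α`. Treating γ as missing data, an EM
algorithm maximises the expected log-posterior: the E-step yields posterior
inclusion probabilities `p*_j` and adaptive ridge weights
`d*_j = (1−p*_j)/υ0 + p*_j/υ1`; the M-step updates β by trust-region cyclic
coordinate descent on `−log L + ‖D*^{1/2}β‖²/(2σ²)`, updates `u` and `α` by
safeguarded one-dimensional Newton steps, and updates σ² and θ in closed
form. A marker is selected when its final `p*_j ≥ 0.5`. The spike/slab
variances `(υ0, υ1)` are tuned over a small grid by the extended BIC,

    EBIC_τ = −2 log L + p_m log n + 2τ log C(p, p_m),   τ ∈ {0, 0.5, 1},

where `p_m` is the number of selected markers. See `docs/methods.md` for
the full account, defaults and limitations.

## Worked example

```python
import numpy as np
import survemvs as sv

rng = np.random.default_rng(1)
n, p = 300, 30
X = rng.standard_normal((n, p))
beta_true = np.zeros(p); beta_true[[0, 1, 2]] = [0.8, -0.6, 0.5]
lam = np.exp(-X @ beta_true)
t = rng.exponential(1 / lam)
c = rng.uniform(0, 3.0, n)
data = sv.SurvivalDataset(np.minimum(t, c), (t <= c).astype(float), X)

res = sv.fit(data, sv.PriorSpec(v0=0.05, v1=10.0))
```

Running `python examples/01_fit_single_prior.py` (the same code) prints:

```
converged: True after 11 EM iterations
log-likelihood at the posterior mode: -110.675
selected markers (p* >= 0.5): ['m0', 'm1', 'm2']
  m0: beta_hat = +0.789 (truth +0.8), p* = 1.000
  m1: beta_hat = -0.654 (truth -0.6), p* = 1.000
  m2: beta_hat = +0.402 (truth +0.5), p* = 1.000
shape alpha_hat = 1.007 (truth 1.0)
```

All three planted effects are recovered with posterior inclusion
probability 1 and estimates close to truth; the 27 noise markers are left
out. `examples/02_tune_ebic.py` runs the full 24-point `(υ0, υ1)` grid on a
benchmark scenario (n=500, p=1000, block-correlated markers, 40% censoring)
and reports the EBIC winner with its selection accuracy and test-set
Harrell's c; `examples/03_simulate_scenarios.py` and
`examples/04_replication_study.py` demonstrate the synthetic-data generator
and the replication-study driver.

## Command line

A thin CLI wraps the library for file-based workflows:

```bash
survemvs fit      --survival cohort.csv --markers expr.csv --v0 0.01 --v1 10
survemvs tune     --survival cohort.csv --markers expr.csv --tau 0.5
survemvs simulate --scenario 1 --seed 7 --out-dir sim/
survemvs study    --scenario 1 --reps 50 --seed 7
survemvs evaluate --effects out/best_effects_full.csv \
                  --survival test.csv --markers test_markers.csv
```

Inputs are delimited text (CSV/TSV) with a header; outputs are CSV tables
(effects with `p*` and selection flags, the grid table, metric reports) plus
a plain-text log recording seed, settings and the convergence trace.

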