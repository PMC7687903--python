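# thinpred

**Predictability limits of partially observed count time series.**

Surveillance systems rarely see every event: hospitals under-report new
infections, social platforms expose a fixed fraction of posts, activity
feeds are rate-limited. `thinpred` models this partial observation as
independent event-level sampling — each event is seen with probability
*p* — so the observed series is a binomial thinning of the ground truth:

```
Y_t ~ Binomial(X_t, p),    E[Y_t] = p E[X_t].
```

The package quantifies, in closed form and by simulation, how much
predictability this observation process destroys, and shows that the loss
is irrecoverable — even an external signal highly correlated with the
ground truth does not restore it. It is aimed at epidemiologists and
computational social scientists who forecast from sampled event streams
and need to know how much of their model's skill the sampling has already
taken off the table.

## The model

For a stationary ground truth X with mean E[X], variance Var(X) and lagged
covariances Cov(X_i, X_{i+k}), thinning at rate p gives

```
Var(Y)            = p² Var(X) + p(1−p) E[X]
Cov(Y_i, Y_{i+k}) = p² Cov(X_i, X_{i+k})
ρ_Y(k)            = p² Cov(X_i, X_{i+k}) / (p² Var(X) + p(1−p) E[X])
Cov(Y, S)         = p Cov(X, S)                      (external signal S)
```

The `p(1−p) E[X]` term is binomial observation noise. It drives three
results the package verifies end to end:

1. **Autocorrelation decays monotonically** as p falls — `|ρ_Y(k)|` is
   strictly increasing in p whenever E[X] > 0.
2. **External-signal covariance decays linearly** in p, but the *Pearson
   correlation* ρ_{Y,S} survives sampling when Var(X) ≫ E[X] (the two
   linear factors cancel: σ_Y ≈ p σ_X) and collapses for Poisson-like
   signals where Var(X) ≈ E[X].
3. **Forecast skill collapses**: an AR(1) predictor fitted to heavily
   thinned data is no more accurate than a Poisson model that assumes
   independent events.

Alongside the closed forms, two model-free predictability measures are
implemented: **weighted permutation entropy** (Shannon entropy of ordinal
patterns, normalized by log₂ d!, with the standard grid search over
2 ≤ d ≤ 5, 1 ≤ τ ≤ 7) and **plug-in mutual information**, plus lagged
Pearson autocorrelation with automatic most-significant-lag selection.

## Worked example

Simulate a Poisson INAR(1) ground truth (α = 0.6, λ = 4: stationary mean
10, lag-1 autocorrelation 0.6), then measure what thinning does to it:

```bash
$ thinpred simulate inar --alpha 0.6 --lam 4 --length 1200 --seed 1 --out X.csv
$ thinpred acf --input X.csv --lag auto --max-lag 20
acf,lag,length
0.608058,1,1200
$ thinpred pe --input X.csv --grid-search
pe,d,tau,weighted,normalization,length
0.886812,5,1,True,possible_permutations,1200
$ thinpred sweep --input X.csv --metric acf --rates 0.25,0.5,1.0 --reps 30 --seed 7 --out sweep.csv
$ cat sweep.csv
p,median,q25,q75,metric
0.25,0.2635644829637178,0.22517173209917216,0.3043241132346999,acf
0.5,0.5234353117760797,0.4854496040280304,0.5405961795969084,acf
1.0,1.0,1.0,1.0,acf
```

Reading the output: the ground truth has lag-1 autocorrelation 0.608
(close to the design value α = 0.6) and normalized weighted permutation
entropy 0.887 at the grid-searched parameters (d=5, τ=1). The sweep
reports the *relative* autocorrelation — the thinned series' value divided
by the ground truth's — whose closed form for this process is simply p:
observing 25% of events keeps only ~26% of the autocorrelation (median
0.264, IQR [0.225, 0.304]), 50% keeps ~52%, and full observation is
exactly 1. A forecaster limited to a 10% sample of this process is working
with a signal whose memory is a tenth of the original, and no model choice
can win it back.

The same pattern holds for the library API:

```python
from thinpred import (INARParams, SamplingConfig, generate_inar,
                      binomial_sample, autocorrelation)

x = generate_inar(INARParams(alpha=0.6, lam=4.0, length=10_000, seed=1))
y = binomial_sample(x, SamplingConfig(rate=0.1, seed=2))
autocorrelation(x, 1), autocorrelation(y, 1)   # ~0.60 vs ~0.06  (= p·α)
```

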