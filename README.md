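# commstruct

Community-structure statistics for pooled abundance surveys of
ground-dwelling arthropods (and any other taxon-by-count community table):
species-abundance-distribution (SAD) model fitting with maximum-likelihood
and MCMC estimation and AIC model selection, Shannon–Wiener diversity with
Hutcheson's t-test, and trophic-guild chi-square analysis, together with a
synthetic community generator so every stage can be exercised without field
data.

It is aimed at community ecologists working with pitfall-trap or similar
pooled count data, and the methods (rank-abundance models, Shannon/evenness
comparisons, guild contingency tests) are the same ones used for microbial
and metagenomic diversity tables.

## The statistics

A community sample is a vector of ranked counts `n_1 ≥ n_2 ≥ … ≥ n_S`
with `N = Σ n_i` individuals over `S` species (or families, or orders).
Four classical SAD models are fitted, in increasing order of the evenness
they predict:

* **Dominance pre-emption (geometric series)** — each species takes a
  fraction `k` of the remaining niche:
  `p_i = k(1−k)^(i−1) / (1−(1−k)^S)`; 1 free parameter.
* **Fisher's log series** — `P(n) = −x^n / (n·ln(1−x))`, `n ≥ 1`;
  1 free parameter, with Fisher's `α = −S/ln(1−x)` derived.
* **Poisson-lognormal** — Poisson counts on lognormal mean abundances
  `exp(z)`, `z ~ N(μ, σ²)`, zero-truncated; 2 free parameters.
* **MacArthur's broken stick** — `p_i = (1/S) Σ_{j=i}^{S} 1/j`;
  0 free parameters.

The log series and Poisson-lognormal are count distributions fitted over
species counts; pre-emption and broken stick predict deterministic rank
proportions and are scored with the multinomial likelihood of the ranked
counts, which gives every model a log-likelihood and hence an AIC
(`2k − 2·logL`). Models within ΔAIC < 2 of the best are flagged as
statistically equivalent. Posterior sampling (uniform priors on `x`, `k`;
Normal/Half-Normal on `μ`, `σ`) is available for the parametric models and
reproduces the ML answers.

Diversity uses the Shannon–Wiener index in natural log, `H = −Σ p_i ln p_i`,
evenness `J = H/ln S`, and Hutcheson's t-test:
`t = (H_a − H_b) / √(Var H_a + Var H_b)` with
`Var H = (Σ p (ln p)² − (Σ p ln p)²)/N + (S−1)/(2N²)` and Welch-type
degrees of freedom. Guild structure (herbivore / predator / scavenger) is
tested with Pearson chi-square against equal expectations, three pairwise
tests at the Bonferroni level `α' = α/3`.

## Worked example

Generate the synthetic fixture suite and fit the log-series fixture
(S=150, N=25,000):

```
$ commstruct simulate --seed 11 --out demo
$ commstruct fit --input demo/logseries.csv --level species
...
SAD model: logseries (mle)
  S = 150, N = 25000
  logL = -736.3439   AIC = 1474.6878   free params = 1
  x = 0.999152 (se 0.000199)
  fishers_alpha = 21.207 (derived)
...
      model          aic    delta_aic  equivalent
  logseries  1474.687824     0.000000        True
  lognormal  1486.765768    12.077944       False
 preemption  4934.072864  3459.385039       False
brokenstick 24388.502950 22913.815125       False
best model: logseries
```

The ranking table reads: the log series has the lowest AIC; the
Poisson-lognormal is 12.1 AIC units behind (not equivalent at the ΔAIC < 2
rule), and the two rank-profile models are far worse — the generated
community indeed has log-series structure. `x` near 1 reflects the large
mean count per species (N/S ≈ 167); Fisher's α ≈ 21 is the derived
diversity parameter.

```
$ commstruct diversity --input demo/logseries.csv
level=species: H = 3.4554 nats, Var(H) = 7.154e-05, S = 150, N = 25000, J = 0.6896
```

H is the Shannon index in nats with its Hutcheson sampling variance;
J = H/ln S says the community sits at ~69% of maximal evenness.

`commstruct guilds --input demo/logseries.csv` prints the guild abundance
and family-richness chi-square batteries with `α' = 0.0167` decisions, and
`commstruct run --config cfg.yaml` executes the whole pipeline (all levels,
with/without exclusion filters such as `family=Formicidae`, Hutcheson
comparisons between label-defined groups, guild tests) into a JSON bundle,
CSV tables and a plain-text report.

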