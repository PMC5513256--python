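# richsplit

**Sample-splitting species richness estimation under constrained sampling.**

Ecologists routinely need the species richness `S` of a community from a
single, resource-limited sample — a net haul of zooplankton, a kick sample of
invertebrates, a plot count.  The number of species actually observed,
`s_obs`, underestimates `S` because rare species are missed, and the
nonparametric estimators that correct for this come in two families:
*abundance-based* (Chao1, abundance jackknife, ACE), which use the counts in
one sample, and *incidence-based* (Chao2, incidence jackknife, ICE), which
use presence/absence across two or more samples.

`richsplit` implements a simple way to get the benefits of the incidence
family from a single sample: **randomly split the n counted individuals into
two equally sized sub-samples, form a species discovery matrix, apply an
incidence estimator, and average over many random splits**.  With `f_k` the
number of species seen exactly `k` times and `q_k` the number present in
exactly `k` of the `m = 2` halves, the key estimators are

    Chao1_bc = s_obs + ((n-1)/n) f1(f1-1) / (2(f2+1))        (unsplit sample)
    Chao2_bc = s_obs + ((m-1)/m) q1(q1-1) / (2(q2+1))        (split halves)
    Jk1a     = s_obs + f1 (n-1)/n
    Jk1i/2i  = s_obs + q1/2                                   (identical at m=2)

Whether splitting helps depends on the community's evenness (the coefficient
of variation, CV, of per-species abundance) and on the sampling ratio
`n/s_obs`.  The package therefore also ships the simulation machinery to map
that decision boundary: assemblage generators for lognormal, log-series,
geometric and negative-binomial species-abundance distributions;
inverse-CDF sampling of individuals; mean-squared-error (MSE) sweeps over
thousands of random assemblages; extraction of the critical ratio `(n/s)_C`
above which splitting wins; power-law fits `(n/s)_C = a · CV^b`; and the
resulting recommendation rule:

* `CV > 0.65` → consider the split incidence jackknife (vs. Jk1a unsplit);
* `CV < 0.65` → consider split Chao2 (vs. Chao1 unsplit);
* split exactly when `n/s_obs` exceeds the predicted `(n/s)_C`.

See `docs/methods.md` for the full model description, conventions and
numerical choices.

## Worked example

Estimate richness from one sample by repeated random splitting:

```python
import richsplit as rs

counts = {"cope1": 41, "cope2": 33, "clad1": 18, "rot1": 11, "rot2": 7,
          "cope3": 4, "clad2": 2, "rot3": 2, "cirr1": 1, "poly1": 1}
sample = rs.AbundanceSample(counts)

res = rs.SplitRichness(sample, estimator="chao2_bc", k=2).fit(n_splits=300, seed=1)
print(res.summary())
```

```
Split-based richness estimation
===============================================
estimator                              chao2_bc
splits (k)                                    2
random partitions                           300
sample size n                               120
observed richness s_obs                      10
aggregate (mean)                        10.2466
split variance                           0.0348
split std. dev.                          0.1866
estimator fallbacks                           0
===============================================
```

The sample holds n = 120 individuals in 10 species; averaging bias-corrected
Chao2 over 300 random 2-way splits estimates about 10.25 species — the two
singletons hint that roughly a quarter of a species-equivalent was missed —
with a split-to-split standard deviation of ~0.19 species.  For comparison,
`rs.chao1_bc(sample).estimate` on the unsplit sample gives 10.33.

The decision rule, given fitted threshold models (see below):

```python
cv_hat = rs.estimate_cv_from_sample(sample)   # 1.13 -> jackknife branch
rec = rs.recommend(n=sample.n, s_obs=sample.s_obs, N_hat=5e4, cv_hat=cv_hat,
                   chao_model=chao_model, jk_model=jk_model)
print(rec.describe())
```

A command-line interface mirrors the library:
`richsplit estimate --method split ...`, `richsplit simulate --config ...`,
`richsplit thresholds --results ...`, `richsplit recommend ...`.

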