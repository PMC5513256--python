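# Methods

`richsplit` estimates species richness from a single abundance sample by
randomly splitting it into equally sized sub-samples and applying
incidence-based nonparametric estimators, and provides the Monte Carlo
machinery to decide *when* that helps.  This note records the models,
conventions and numerical choices the package is built on.

## Theoretical assemblages

An assemblage (the statistical population) is described by its true richness
`S`, the mean abundance per species (so total abundance `N = S * mean`), and
the coefficient of variation (CV) of per-species abundance.  Four
species-abundance distribution (SAD) families are supported.

Each family is turned into a *ranked* abundance vector `b_1 >= ... >= b_S`
by evaluating its abundance-by-rank function — the inverse of the cumulative
species distribution — at `S` rank quantiles, then normalising to obtain the
probability `Pr(s_i) = b_i / N` that a randomly caught individual belongs to
the species of rank `i`.  Catchability is proportional to abundance and
otherwise independent of species identity.

* **Lognormal** (the primary family): `ln b ~ Normal(mu, sigma)` with the
  moment mapping `sigma^2 = ln(1 + CV^2)`, `mu = ln(mean) - sigma^2/2`.  The
  ranked weight at quantile `p` is `exp(-sigma * sqrt(2) * erfinv(2p - 1))`
  (the location parameter cancels in the normalisation).
* **Geometric series**: abundance decays by a constant factor per rank,
  `b_i ∝ x^(i-1)`.  `x` is calibrated by root-finding (`brentq`) so that the
  length-`S` ranked vector has exactly the requested CV; the attainable range
  at richness `S` is `(0, sqrt(S-1))` and requests outside it raise an
  infeasibility error naming the range.
* **Log series**: the SAD places `alpha x^n / n` species at abundance `n`.
  Its continuous relaxation has species density `∝ x^t / t` on `t >= 1`,
  whose tail integral is the exponential integral `E1(-t ln x)`; ranked
  abundances solve `E1(-w ln x) = p * E1(-ln x)` by bracketed root-finding.
  `x` is again calibrated to the target CV.
* **Negative binomial**: moment mapping `r = mean^2/(var - mean)`,
  `p = mean/var` with `var = (CV * mean)^2` (requires `var > mean`).  Ranked
  abundances use the gamma continuous relaxation matching the NB mean and
  variance (shape `1/CV^2`, scale `mean * CV^2`), which avoids the
  zero-abundance ties a discrete quantile function would produce at small
  ranks.

### Rank quantile conventions

Where the quantiles `p_i` are placed is not cosmetic; it decides whether the
rarest species in the assemblage is realistically samplable, and that in turn
drives the entire estimator-comparison phenomenology.

* `midpoint` (library default): `p_i = (i - 1/2)/S`.  Strictly inside
  (0, 1), symmetric between the common and rare halves (mirrored ranks have
  reciprocal weights), no singularity of the inverse CDF.  Every species has
  a non-negligible catch probability.
* `endpoint` (simulation default): `p_i = i/S`, with the final quantile
  clipped to `1 - eps` (float machine epsilon) because the inverse normal
  CDF diverges at 1.  The rarest species then sits at the *numerical
  detectability floor*: for a lognormal assemblage its weight is
  `exp(-8.1 * sigma)` relative to the median species, so it is essentially
  never caught at survey-scale effort (a few percent of `N`) but can still
  be found when a small population is sampled near-exhaustively.

The distinction matters because the headline comparison — split-sample
incidence estimators versus single-sample abundance estimators — hinges on
species that remain hidden at realistic effort.  With every species
detectable (midpoint), all estimators converge quickly and the
larger-correction estimators (incidence jackknife, split Chao2) are left
with a slowly decaying *positive* bias (per species roughly `e^(-lambda/2)`
for the 2-split jackknife versus `lambda e^(-lambda)` for the abundance
jackknife, `lambda` the expected catches of that species), so splitting
never wins at high sampling ratios.  With a barely detectable rarest
species (endpoint), every estimator carries a persistent deficit that the
split estimators' stronger corrections partially compensate, and splitting
wins *above* a critical sample-size-to-richness ratio — the regime the
threshold curves describe.  The simulation sweeps therefore default to the
endpoint convention, while the library-level constructors default to the
cleaner midpoint convention; both are exposed as a parameter.

## Sampling

Individuals are drawn **with replacement**: uniform variates are mapped
through the cumulative catch-probability vector by binary search (half-open
classes `[cum_{i-1}, cum_i)`).  With-replacement sampling matches the
assumption under which the nonparametric estimators are derived.  A single
seeded `numpy` Generator drives each experiment, with per-assemblage child
streams spawned from a `SeedSequence`, so results are reproducible and
independent of execution order.

## Estimators

With `f_k` the number of species seen exactly `k` times (`n` individuals,
`s_obs` species) and `q_k` the number of species present in exactly `k` of
`m` sub-samples:

| id | form |
|----|------|
| `chao1_bc` | `s_obs + ((n-1)/n) * f1(f1-1) / (2(f2+1))` |
| `chao2_bc` | `s_obs + ((m-1)/m) * q1(q1-1) / (2(q2+1))` |
| `jk1a` | `s_obs + f1 (n-1)/n` |
| `jk2a` | `s_obs + f1 (2n-3)/n - f2 (n-2)^2 / (n(n-1))` |
| `jk1i` | `s_obs + q1 (m-1)/m` |
| `jk2i` | `s_obs + q1 (2m-3)/m - q2 (m-2)^2 / (m(m-1))` |
| `ace` | `S_abund + S_rare/C + (f1/C) gamma^2`, `C = 1 - f1/N_rare` |
| `ice` | incidence analogue with `m_infreq/(m_infreq - 1)` in `gamma^2` |

Notes and choices:

* The bias-corrected Chao forms are defined for every configuration of
  singletons and doubletons.  The `(n-1)/n` small-sample factor in
  `chao1_bc` can be disabled (`small_sample_correction=False`) for
  comparison with implementations that omit it.
* At `m = 2` the two incidence jackknife orders coincide exactly (the
  order-2 term carries `(m-2)^2`).  At `m > 2` they diverge, and the
  multi-split comparisons use the order-2 form: its stronger correction is
  what makes 3- and 4-way splitting counterproductive relative to 2-way,
  whereas the order-1 form degrades gracefully with more splits.
* The raw order-2 jackknife can fall below `s_obs` when doubletons dominate;
  since an estimate below the observed richness is impossible, order-2
  estimates are floored at `s_obs`.
* ACE/ICE use the standard rare/infrequent cutoff of 10 (exposed as a
  parameter).  When coverage is undefined (all rare species singletons) they
  fall back to the corresponding bias-corrected Chao estimator with a logged
  warning; fallbacks are counted and reported, so sweeps never silently lose
  replicates.  For ICE at `m > 2` the number of sub-samples containing an
  infrequent species is approximated by `min(m, N_infreq)` (exact at
  `m = 2`, the recommended design).

## The splitting method

One abundance sample of `n` individuals is partitioned at random into `k`
groups whose sizes differ by at most one (`k = 2` recommended); each group's
species set forms one column of an incidence matrix, to which an
incidence-based estimator is applied.  Because a single partition is noisy,
the partition is redrawn `n_splits` times (300 by default) and the estimates
aggregated — by the mean by default; the median is available for sensitivity
analysis.

Dealing a uniform random permutation into fixed group sizes is
distributionally identical to sequential multivariate hypergeometric draws
of per-species group counts, which is how partitions are generated (the
`count`/`marginals` sampler is chosen by whichever of individuals or species
is smaller).  For `k = 2` the per-split incidence statistics
`(s_obs, q1, q2)` are computed vectorised across all partitions.

## Accuracy accounting

Estimator accuracy against the known `S` is `MSE = Var + bias^2` over
repeated samples, with the population (1/N) variance convention throughout.
For split-based estimates the variance has two components: the variance of
the aggregated estimate across draws, **plus** the mean across draws of the
per-draw variance over random partitions (the law-of-total-variance
decomposition of treating one random partition as the estimator).  The
second term is an accuracy penalty the splitting method must overcome.

The pairwise comparison statistic is the proportionate MSE difference
`(MSE_incidence - MSE_abundance) / min(...)`, negative when splitting wins.
Assemblages where either MSE is exactly zero are excluded (the statistic is
undefined), and so are assemblages where **both** MSEs fall below one squared
species: there each estimator is within a fraction of a species of the
truth, and the sign of their difference reflects sub-species rounding — the
"trivial" near-saturation regime in which the unsplit Chao1 converges
exactly while split Chao2 keeps a negligible positive bias.  Left in, these
trivially positive points occupy the highest `n/s` bins and would mask every
genuine crossing.  One squared species is the natural quantum of richness
error; the cutoff is exposed as a parameter (`converged_mse`).

## Scenario sweeps

The main lognormal sweep draws, per CV grid point (0.15, 0.25, ..., 1.15):
`N ~ Uniform[1e3, 1e5]`; `S ~ Uniform{2 .. min(500, round(N/200))}` so that
richness scales with population size (500 attainable only at the largest
populations); `n ~ Uniform[300, 5000]` redrawn until `n < N`.  This design
implies a mean sampling fraction `n/N` of about 11%.  Full study scale is
6000 assemblages per CV, 1000 draws per assemblage, 300 splits per draw;
`ScenarioConfig.scaled()` shrinks replicate counts proportionally for
desk-scale runs.  The small-population sweep uses `N ~ Uniform[100, 1000]`,
`S ~ Uniform{2..20}` and `n` a uniform 1–100% fraction of `N`, for all four
SAD families.  Sweeps checkpoint per assemblage to CSV and resume after
interruption.

## Threshold extraction and the recommendation rule

For an estimator pair (split Chao2 vs Chao1; split incidence jackknife vs
abundance jackknife), assemblages in one CV cell are placed into ten
equal-count bins of `n/s` (sample size over mean observed richness).  The
**mid-criterion** critical ratio `(n/s)_C` is the centre of the smallest bin
from which the fraction of negative proportionate differences exceeds 0.5 in
that bin and every larger bin; the **edge-criterion** uses 0.95
("almost all negative" made operational).  Cells that never satisfy the
criterion yield an explicit no-crossing sentinel rather than an exception.

The CV at which the best split estimator changes is located by comparing,
per CV cell and restricted to assemblages above the fitted mid-criterion of
both pairs, the mean MSE of split Chao2 against the split incidence
jackknife; the switch point is the midpoint between the last grid point
Chao2 wins and the first the jackknife wins (the centre of the contested
region when the winner sequence is noisy).

Across the CV grid the critical ratios are fitted with a power law
`(n/s)_C = a * CV^b` by nonlinear least squares initialised from a log-log
regression; across `N` with an ordinary cubic fit in a scaled domain (the
raw Vandermonde at `N ~ 1e5` is numerically rank-deficient).

The recommendation rule for a real sample `(n, s_obs)` with plug-in
estimates `N_hat` and `cv_hat` (population standard deviation over mean of
the observed counts): if `cv_hat > 0.65` the candidate pair is the split
incidence jackknife versus the abundance jackknife, otherwise split Chao2
versus Chao1; splitting (with `k = 2`) is recommended exactly when
`n/s_obs` exceeds the predicted `(n/s)_C`.  A `cv_hat` of exactly 0.65 is
assigned to the Chao branch with a logged note.

## What the generator emulates — and what it does not

The synthetic assemblages emulate communities whose ranked abundances follow
smooth parametric SADs with equal catchability per individual, sampled
independently with replacement.  Real survey data violate several of these
assumptions: catchability varies by species (gear selectivity, body size),
individuals are spatially and temporally aggregated (so presence/absence
across real replicate samples is over-dispersed relative to random
partitions), abundances drift between samples, and taxonomic resolution is
imperfect.  Passing tests therefore demonstrate the statistical behaviour of
the estimators under the stated sampling model, not robustness to these
field realities.  The recommendation rule additionally relies on `cv_hat`,
a biased (sample-based) plug-in for the assemblage CV; it tracks the true
CV monotonically but compresses it at low effort.

## Problem sizes and numerics

* Scaled-down sweeps used by the test suite and the acceptance script: 200
  assemblages per CV, 200 draws, 50 splits (a few minutes on one CPU);
  qualitative-trend checks use smaller dedicated configs.  These sizes give
  threshold fits stable to within the tolerance bands asserted in the tests.
* Probability vectors must sum to 1 within 1e-12 and be non-increasing;
  series CV calibration solves to ~1e-12; power-law fits recover noiseless
  synthetic coefficients to 1e-6 or better.
* Degenerate inputs are errors, not silent results: empty samples, `m < 2`,
  infeasible (family, S, CV) combinations, `n < k` splits, fewer than 3
  points for a power-law fit, fewer than 4 distinct points for a cubic.

## Known limitations

* The series-family CV calibration is defined on the midpoint ranked vector;
  under the endpoint convention the realised CV differs slightly from the
  nominal value.
* ICE is restricted to 2-way splits inside sweeps (its general-`m`
  infrequent-sample correction needs the full `q_k` spectrum).
* `cv_hat` and `N_hat` plug-ins are deliberately simple; no bias correction
  is attempted.
* Thresholds are fitted for the two headline estimator pairs only; the
  coverage estimators inherit the same qualitative behaviour but get no
  dedicated curves.
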