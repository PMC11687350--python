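# Methods

`polydem` estimates environment-dependent total fitness for two near-isogenic
plant genotypes and asks which combinations of soil drought and herbivore
damage allow a defence polymorphism to persist. This note documents the model,
the estimation choices, the synthetic data generator used for validation, and
the numerical decisions, in the order the pipeline applies them.

## State space and life cycle

The population state is a seed bank plus a continuous distribution over
log height `z` crossed with a binary *bolting* state `q` (0 = vegetative
rosette, 1 = elongated flowering stalk; bolting is a prerequisite for
reproduction). Discretised on `m` size bins, the annual projection kernel is
a non-negative matrix of order `2m + 1`: index 0 is the seed bank, indices
`1..m` are non-bolting size bins, `m+1..2m` bolting size bins.

One census-to-census transition at environment `E = (M, H)` (soil moisture as
% volumetric water content; herbivory as % leaf area removed) is composed of:

* seed bank: persist with `sigma_sb * (1 - gamma)`, or germinate and survive
  the first summer with `gamma * sigma_j`, entering the non-bolting
  continuum at a Normal(`mu_R`, `s_R^2`) log size;
* plants `(z, q)`: survive with `s(z, E)`; switch to bolting state `q'` with
  probability `b_q(z, E)` (for `q' = 1`); grow to a Normal size with mean
  `g_qq'(z, E)` and variance `v_qq'(z, E)`;
* bolting plants additionally reproduce: with probability `r(z, E)` they set
  `f(z, E)` seeds (negative predictions truncated to 0), and each seed either
  recruits next year (`gamma * sigma_j`, entering as a non-bolting recruit)
  or enters the seed bank (`(1 - gamma) * sigma_sb`).

Total fitness is `lambda`, the dominant eigenvalue of this kernel: the
asymptotic per-year growth rate of a genotype's lineage; `lambda = 1` is
demographic replacement.

**Timing convention.** Reproduction is scored at the census at which the
plant is bolting, using the plant's size at that census. Concretely, the
regressions for `r` and `f` are fitted on survivors that are bolting at
t+1, with size at t+1 as the size predictor, so the kernel's fecundity
terms `r(z, E) * f(z, E)` on the bolting columns are evaluated at the
plant's current size. Fecundity is not multiplied by parent survival:
seeds set at one census are in the ground regardless of whether the parent
survives the following year. The individual-based simulator applies exactly
the same ordering (reproduce, disperse seed fates, then survive / switch
state / grow), which is why it can serve as an independent Monte-Carlo
oracle for `lambda`.

## Vital-rate regressions

Thirteen rates are regressions fitted per genotype to the census table
(one row per individual x year transition):

| key | response | family | rows |
|---|---|---|---|
| `s` | survival to t+1 | binomial-logit | all plants |
| `b0`, `b1` | bolting at t+1 | binomial-logit | survivors by state at t |
| `g00..g11` | size at t+1 | gaussian | survivors by state pair |
| `v00..v11` | squared growth residual | gaussian | survivors by state pair |
| `r` | reproduced at t+1 | binomial-logit | survivors bolting at t+1 |
| `f` | seed count | gaussian | reproducers |

Three recruitment rates (`gamma` germination, `sigma_sb` seed-bank survival,
`sigma_j` germinant survival) and the recruit-size distribution
(`mu_R`, `s_R`) are constants supplied via configuration, not refitted —
in field applications they come from independent data. Seed counts can be
obtained from fruit lengths through an ordinary least-squares calibration
(`fit_seed_calibration`), with predictions floored at 0.

Candidate predictors are size `z`, moisture `M`, herbivory `H` and all
two- and three-way products, used uncentred and unscaled so coefficients are
directly interpretable against configured driver values. Predictors enter
as continuous values; although field manipulations are categorical, the
realised block/plant-level driver values carry the information.

**Model selection.** All subsets of the 7-term global model that respect
marginality (an interaction enters only with all its lower-order
constituents; 19 candidates) are fitted and ranked by AICc,
`-2 ln L + 2k + 2k(k+1)/(n-k-1)`, with `k` counting the residual variance
for gaussian fits. Candidates within 2 AICc units of the minimum are treated
as equally supported and the most parsimonious of them is selected (ties:
lower AICc, then lexicographic term order). The 2-unit window matters: with
19 candidates, strict minimisation admits a spurious extra term in roughly a
third of fits (a 1-parameter extension wins whenever its chi-square deviance
improvement exceeds ~2, probability ~0.16 each), whereas the parsimony
preference requires an improvement of >2 units and recovers the generating
term set in well over 80% of simulated replicates — the rate the test suite
verifies. `parsimony_window=0` restores strict minimisation.

**Growth variance.** The `v` rates regress the squared residuals of the
paired mean-growth fit on the same candidate terms. Squared residuals are
heteroskedastic by construction (their variance scales with `v^2`), so these
fits report heteroskedasticity-robust (HC1) coefficient covariances;
homoskedastic covariances would understate parameter uncertainty and
mis-calibrate the bootstrap. Predicted variances are floored at
`1e-6` (log-size^2) everywhere they are consumed.

## Discretisation and eigenanalysis

* Mesh: `m = 100` equal bins (default) over the observed log-size range
  padded by 3x the largest fitted growth SD. Growth and recruit-size
  densities are integrated over bins by normal-CDF differences, and the tail
  mass outside the mesh is added to the boundary bins, so each survival/
  growth column sums exactly to the survival probability (no eviction loss).
  With this padding and resolution, `lambda` changes by <0.5% under mesh
  doubling (tested).
* Dominant eigenvalue: shifted power iteration (shift `0.1 * max(K)` breaks
  the cycling that periodic kernels such as strict biennials induce; for
  non-negative matrices the shift only translates the Perron root).
  Convergence is declared when the unshifted residual
  `max|Kv - lambda v| <= 1e-10 * lambda`; after 20 000 iterations without
  convergence a dense eigendecomposition is used instead. The solver is
  validated against dense decompositions to 1e-10 relative error.

## Environment grid

25 moisture cells x 25 herbivory cells (625 environments). Moisture cells
are centres of equal-width bins on `[0, 1.25 * max observed]`. Herbivory
bin edges are `{0}` followed by a geometric sequence from a configurable
floor (default 0.5%) to 100%, reflecting the zero-heavy, right-skewed damage
distribution; cell values are geometric midpoints. The zero-edge cell takes
the geometric continuation `floor / sqrt(ratio)` rather than an arithmetic
midpoint so that cell spacing is strictly increasing throughout — an
arithmetic first midpoint would make the first gap wider than the second.

## Uncertainty propagation

Parameter uncertainty is propagated by parametric bootstrap: each replicate
draws one coefficient vector per vital rate from Normal(beta_hat, Sigma_hat),
independently across vital rates (separate regressions share no estimated
covariance) and across replicates; recruitment constants are held fixed.
The full `lambda` surface is recomputed per replicate; per-cell 2.5/50/97.5
percentiles summarise the ensemble. Draws that imply negative growth
variances are floored like any other prediction rather than redrawn, keeping
the number of replicates fixed. The library default is `B = 1000`
replicates; the bundled demo and the acceptance script use `B = 200` with
`m = 50` size bins, sizes at which the reported fractions are stable to
within a percentage point or two.

## Inference on the polymorphism

* **Driver contributions.** The contribution of driver D to `lambda` through
  vital rate k is `c = mean over grid cells of
  (lambda_full - lambda_pinned) / lambda_full`, where the pinned model set
  evaluates D at a reference value (the observed mean) in rate k only.
  Pairs where selection did not retain D are exact structural zeros.
  Averaging is uniform over cells; evaluating on a single-cell grid gives
  the single-reference-environment variant. Contributions use point
  estimates, not bootstrap draws.
* **Fitness differences.** Bootstrap replicates are paired by index across
  genotypes; the difference `lambda_MM - lambda_BB` is significant in a cell
  when its 95% percentile interval excludes 0.
* **Criteria.** A genotype *persists* in a cell when the upper bound of its
  95% bootstrap interval reaches 1. Criterion I: both genotypes persist.
  Criterion II: the fitness difference is not significant. Criterion III:
  both — a putatively polymorphic environment. Ambient (field) driver
  means are mapped to their nearest grid cell and reported with the distance
  (in cells, per axis) to the nearest non-polymorphic cell.

## Synthetic data generator

The generator is the package's testbed: it produces census tables with the
exact statistical structure the regressions assume, from known truth
coefficients, so estimation can be validated end to end.

* **Environment.** Block x year soil moisture is uniform on a configurable
  range (default 4-20% VWC, the scale of a subalpine rainout-shelter
  experiment); block-mean herbivory has a scaled-beta marginal (mean 8%).
  A gaussian copula induces a configurable Pearson correlation between the
  two (default -0.4, drought exacerbating herbivory) without changing the
  marginals. Plant-level herbivory is zero-inflated (25% exact zeros) around
  the block mean with beta dispersion.
* **Census.** Per genotype, a fixed cohort (default 800 plants, the scale of
  the motivating field experiment) is followed for 4 annual transitions;
  dead plants are replaced by fresh recruits the next year, as in a
  maintained common-garden planting. Transitions draw from the truth vital
  rates at each row's (size, moisture, herbivory); seed counts are rounded
  gaussians floored at 0.
* **Truth parameters.** The bundled truth makes genotype BB the more
  drought-sensitive (strong positive moisture slopes on survival, bolting
  and seed set: its `lambda` falls below 1 when VWC drops below ~8%) and MM
  the more herbivory-sensitive (larger negative herbivory slopes, with small
  compensatory positive herbivory effects on vegetative growth and repeat
  bolting), on a shared size-structured life cycle. Magnitudes were chosen
  once so that `lambda` spans roughly 0.5-1.5 across the grid and ambient
  conditions sit inside, but near the dry edge of, polymorphic space.
* **IBM oracle.** `simulate_lineage_ibm` tracks individuals (size, bolting
  state) and a seed-bank count at a constant environment with the kernel's
  timing; seed numbers are Poisson so expectations match `r * f`. It raises
  an explicit extinction signal rather than returning a growth rate from an
  extinct lineage.

What the generator does **not** emulate: random block/year effects (the
regressions assume exchangeable rows, as do the fitted models), overdispersed
or zero-inflated seed counts, observation error in size, temporal
autocorrelation in drivers, density dependence, and within-season phenology.
Passing tests therefore show that the estimation machinery is correct and
calibrated *under the stated model*, not that the model is adequate for any
particular field system.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own trade-off between resolution and turnaround:
parameter recovery, 25 replicates of 5000 transitions; model selection, 100
replicates at n = 5000; bootstrap coverage, 100 replicates of 2000
transitions with B = 200 at 5 central grid cells and m = 50; IBM checks,
n0 = 10 000 individuals over 30 years with a 10-year burn-in. The acceptance
script runs the full pipeline at the demo scale (1600 plants x 4 years,
B = 200, m = 50).

## Known limitations

* Size is modelled on natural-log height; the transform is a package
  convention (it stabilises growth variance), not a field fact.
* Recruitment constants are shared between genotypes by default; the
  containers accept genotype-specific values.
* No random effects for block or year, no overdispersion in seed number,
  no temporal environmental stochasticity in `lambda` (a single constant
  environment per kernel), no density dependence, and no allele-frequency
  dynamics: the polymorphism criteria are demographic, not population-
  genetic.
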