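# Methods

## Model and estimators

All inference concerns the per-gene, per-donor linear model
`Y = Xβ + ε`, `ε ~ N(0, σ²I)`, with design columns (intercept, binary
group, `x2 = −log` mean cell-type probability). Three estimators share
one plug-in residual variance `σ̂² = RSS/(n−p)` from the full OLS fit,
computed once and never re-estimated inside iterations. Treating σ² as
known keeps the conjugate updates closed-form and makes the three methods
directly comparable on the same variance scale; it is also why p-values
use the normal rather than a t reference (the 1.96-interval convention is
deliberate and is kept even at small n, see "Calibration" below).

**Conjugate parameterization.** The normal prior is specified per
coefficient as `N(μⱼ, τⱼ²)` with the posterior precision
`diag(1/τ²) + XᵀX/σ²`. An equivalent textbook form absorbs σ² into the
prior covariance, writing the posterior as
`(Σ⁻¹ + XᵀX)⁻¹(Σ⁻¹μ + XᵀY)` with covariance `(Σ⁻¹ + XᵀX)⁻¹σ²`; the two
conventions coincide when that Σ is read in σ²-scaled units. The
σ²-explicit form is used because it makes the flat-prior limit recover
OLS exactly, which is a tested invariant and matches the observed
behavior that a non-informative hybrid and a frequentist fit report the
same point estimate.

**Hybrid alternation.** The partition mask splits β into a Bayesian
block B and frequentist block F. Starting from full OLS, the algorithm
alternates (1) conditional conjugate posterior mean of β_B on the
residual `Y − X_F β_F`, (2) conditional OLS of β_F on `Y − X_B β_B`,
until the max absolute coefficient change falls below `tol` (default
1e-8, `max_iter` 100; both exposed). With a flat prior this is exactly
backfitting and converges to OLS; in general the fixed point solves a
2×2 block linear system, which the tests solve directly as an oracle.
Non-convergence returns `converged=False` with a warning rather than
raising, since a partial answer with its iteration record is more useful
than none. Degenerate partitions route cleanly: all-frequentist → OLS,
all-Bayesian → conjugate fit (with a notice), both tagged `hybrid`.

**Hybrid standard errors.** At the fixed point, β_B's SE is its
conditional posterior SD given β_F, and β_F's is conditional OLS given
β_B. Conditioning removes cross-coefficient uncertainty, so the hybrid's
SE for the group coefficient is never larger than the all-Bayesian
marginal SD — the source of its narrower intervals and higher selection
counts. This is a design choice: a marginal (Fisher-information)
construction would be possible but would erase precisely the advantage
the alternation buys.

## Priors from bulk DE summaries

Per gene the prior for the group coefficient is centered at the bulk
cohort's covariate-adjusted group difference, with variance equal to the
**square root** of that difference's sampling variance. The sqrt rule is
dimensionally inconsistent on purpose: bulk sampling variances are far
smaller than the effects, and using them directly would pin the
posterior to the bulk estimate; the sqrt inflates sub-unit variances
(0.0092 → 0.096) toward a moderate dispersion while deflating variances
above one. It is implemented exactly as stated with a `literal` switch
for the untransformed alternative. Intercept and `x2` always keep the
non-informative N(0, 100); genes absent from the bulk table fall back to
N(0, 100) rather than being dropped, so the screened gene universe (and
hence the enrichment background) is unaffected by bulk coverage.

## Pseudo-bulk construction and QC

The weighted average uses the normalized form `Σwc/Σw`, making Y
invariant to rescaling the probabilities; a donor with zero total weight
is an error, not a silent NaN. `x2` averages probabilities **then** takes
−log (the alternative order is a config flag). The gene filter keeps
means strictly greater than 0.1; the cell filter drops cells strictly
below the 2nd percentile (linear-interpolation percentile) of
detected-gene counts or above 10% mitochondrial fraction, both computed
on the pre-filter distribution; mitochondrial genes are identified by
the configurable name prefix `MT-`, case-insensitively. Gene filtering
runs before cell filtering by default (configurable), and the filter log
records in/removed/out counts for every step. The hard-assignment
aggregator (unweighted mean over cells with probability ≥ 0.5, no `x2`
column) is retained as the classical baseline.

## Screening and enrichment

Group-coefficient p-values are BH-adjusted (statsmodels) across all
successfully fitted genes; fit failures are reported as NA and excluded
from the BH universe. Selection requires adjusted p < 0.01 **and**
|β̂₁| ≥ 0.585 (≥, not >; both thresholds are parameters). Enrichment
uses the inclusive upper tail `P(X ≥ r)` of
Hypergeometric(N, n, R), accumulated from log-gamma pmf terms with
logsumexp so tails below 1e-30 do not underflow, and the moment
standardization `z = (r − Rn/N)/sqrt(R(n/N)(1−n/N)(N−R)/(N−1))`. Gene
sets are intersected with the background before sizing; q-values are BH
over all tested sets, with results thresholded at q < 0.05 by default
(raw-p thresholding available via `p_max`). The background universe is
the caller's choice; the pipeline uses the set of tested genes.

## Synthetic cohorts

The generator emulates a two-group cohort of the shape this pipeline
targets: 10 control and 12 case donors by default, 200 cells per donor,
300 genes (5% mitochondrial), 10% of non-mito genes differentially
expressed with additive effect 1.0 in target-type cells of case donors.
Cell-type truth is Bernoulli(0.5); classifier probabilities come from
Beta(20, 1) for target and Beta(1, 20) for non-target cells — a
well-separated classifier, so the probability weights attenuate the
injected effect only by the factor `E[w·1(target)]/E[w] ≈ 0.95`.
Expression is continuous and nonnegative (normal around a per-gene
baseline in [3, 6], sd 0.5 per cell plus a per-gene, per-donor random
intercept of sd 0.25, clipped at zero where clipping is negligible by
construction), with a 3% random zero mask standing in for droplet
sparsity. Mitochondrial rows are rescaled per cell so the mito fraction
follows Beta(2, 40). The bulk prior table carries each gene's true
effect plus N(0, 0.1) noise with sampling variance 0.1²; one gene set is
enriched for true DE genes (60% of its members) among random decoys.
One seed drives named independent substreams (cells, expression, mito,
bulk, gene sets), so outputs are bitwise reproducible and extending one
stage never shifts another's draws.

What the generator does **not** model: discrete counts (the inference
operates on a normal model of pseudo-bulk averages, so continuous
expression is the matched choice), library-size variation, batch
effects, classifier miscalibration, or mechanistic dropout. Passing
tests therefore demonstrate correctness of the estimation and selection
machinery under the model's own assumptions, not robustness to the full
messiness of real droplet data.

## Calibration and simulation scale

Bias/coverage calibration uses 200 donor-level replicates at n = 20
donors, group effect 1.0, residual sd 0.5: OLS is unbiased and the
1.96-normal interval's empirical coverage sits near
`P(|t₁₇| < 1.96) ≈ 0.93` — inside the accepted [0.90, 0.99] band and a
direct consequence of the fixed-1.96 convention at small n.

The method-comparison experiment (100 replicates, 150 genes, 10+10
donors, 80 cells/donor, frac_de 0.2) is deliberately run where selection
is p-value-limited rather than effect-cut-limited: effect 1.1 keeps the
estimate clear of the 0.585 cut while donor-level sd 0.8 puts the
frequentist z near the selection boundary, and prior noise 0.1 (prior
variance 0.1 via the sqrt rule) makes the informative prior strong and
well-specified. In that regime the average selected-gene counts order
strictly as hybrid-informative ≥ bayes-informative ≥
hybrid-non-informative ≥ frequentist. When instead the effect cut binds,
the two informative methods tie (their point estimates coincide); the
ordering is a statement about uncertainty, not about point estimation.

Problem sizes throughout the suite (desk-scale cohorts of 40–200 genes
and 30–200 cells per donor) were chosen so every property is resolved
with comfortable statistical margin while the whole suite stays fast to
iterate on.

## Known limitations

* σ² is plugged in, not propagated; intervals ignore its sampling error
  (visible as coverage ≈ 0.93 rather than 0.95 at n = 20).
* The hybrid's conditional SEs understate marginal uncertainty by
  construction; they are the method's definition of reported precision,
  not an estimate of the frequentist sampling SD.
* The sqrt-of-variance prior rule is heuristic and scale-dependent;
  effects measured in different units would need the `literal` switch or
  rescaling.
* Enrichment q-values depend on the number of sets tested, so they are
  only comparable within one collection.
* The dense in-memory count matrix targets desk-scale data (≤ ~10⁷
  entries); atlas-scale inputs should be down-sampled or aggregated
  upstream.
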