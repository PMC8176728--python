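# Methods

This note documents the models, numerical choices and known limitations of
`snoclass`, in the spirit of the methods documentation of packages like
statsmodels or scanpy. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Abundance classes from the coefficient of variation

Tissue specificity is summarised per gene as
`CV = 100 · sd / mean` of the per-tissue mean abundances (replicates are
averaged first, so seven tissues contribute seven observations). Two
choices here were genuinely open:

- **ddof.** The standard deviation uses `ddof=1` (sample sd). With seven
  tissues the difference to `ddof=0` is a uniform factor of
  √(7/6) ≈ 1.08 on every CV, which shifts the threshold and all CVs
  together and therefore barely affects the classification. Configurable
  via `AnalysisConfig.ddof`.
- **Observation unit.** The CV runs on tissue means rather than on all 21
  samples; per-sample CVs would fold replicate noise into the tissue
  signal. The correlation stage, in contrast, defaults to all samples
  (more observations, n = 21); `correlation_level="tissue-means"` is
  available.

### The KDE-tangent threshold

The CV distribution of a mixed cohort is bimodal. The UE/TE boundary is
found on a Gaussian KDE (Scott's bandwidth rule, 1024-point uniform grid
over `[0, 1.05 · max]`, all configurable): take the numerical derivative
(central differences), restrict to grid points strictly right of the
global mode, find the point of most negative derivative (ties broken
towards smaller x), and intersect the tangent there with the x-axis:
`threshold = x0 − f(x0)/f'(x0)`.

Restricting the search to the right flank prevents the construction from
latching onto the left flank's inflection on noisy curves; the bimodal CV
curve of interest descends rightward from its dominant peak. For an exact
Gaussian density the construction has a closed form: the derivative is
minimised at `x0 = μ + σ` and the tangent crosses zero at `μ + 2σ` (the
error is second-order in the grid spacing because d(threshold)/dx0
vanishes at the optimum, which is why a 4096-point grid reproduces
μ + 2σ to much better than 0.1%). This is also the sense in which the
canonical threshold of CV = 125 corresponds to a dominant CV mode near 65
with effective spread ≈ 30.

Boundary rule: a CV exactly equal to the threshold is UE ("above" is read
strictly). Degenerate inputs raise errors rather than guessing: fewer than
10 CVs, zero variance, a density whose global mode sits at the right grid
edge, or no descending flank right of the mode.

### Tissue enrichment

TE genes get the argmax tissue of their mean-abundance profile. The joint
rule — assign both tissues when the top two are exactly the configured
pair (default breast/ovary) and the maximum is within `joint_fold`
(default 2×) of the runner-up — is implemented generally rather than as a
fixed gene list, so it applies to any dataset with an analogous pair of
related tissues. Exact argmax ties outside the pair retain all tied
tissues with a logged warning.

## Host-gene correlation

Pearson's r with its two-sided p-value (scipy) across the chosen
observation unit; Benjamini–Hochberg adjustment (statsmodels) over the
family of all pairs tested in the run. Pairs with a missing gene, fewer
than three observations or zero variance are excluded *before* the FDR
family is formed, with logged counts. Correlation classes use cut-offs
±0.25 with an inclusive middle band; significance is q < 0.05 on the
adjusted values.

The per-tissue snoRNA/host ratio is `log2((sno + 1)/(host + 1))` TPM; the
pseudocount of 1 TPM (configurable) keeps the ratio finite at zero
abundance and is of the order of the expression-filter threshold.

## Association battery

2×2 tables use scipy's Fisher exact test with the sample odds ratio
`ad/bc` (infinite when `bc = 0` and `ad > 0`, undefined when both products
vanish). For 2×k tables (k ≤ 4) no established Python routine provides an
exact conditional test, so the package enumerates all tables with the
observed margins, computes multivariate hypergeometric probabilities via
log-gamma, and sums those at most as probable as the observed table
(probability-ordering two-sided rule, 1e-7 relative tolerance as in
standard implementations). Enumeration is refused beyond a few million
candidate tables; collapse categories in that case. The Mann-Whitney U
test uses the exact null when both groups have ≤ 20 observations with no
ties, and the tie-corrected normal approximation otherwise; two groups of
entirely identical values yield p = 1 with a warning.

Battery p-values are reported raw, uncorrected across the battery, with
the conventional stars (* < 0.05, ** < 0.01, *** < 0.001). Degenerate
strata (empty class, all-unknown annotation) produce explicit
`skipped: …` records instead of disappearing, so the battery's shape is
stable. Unknown annotation values are dropped pairwise per test, never
imputed.

## Synthetic cohorts

`simulate_cohort` emulates the data structure of a seven-tissue,
three-replicate profiling experiment with 475 snoRNAs (390 UE / 85 TE by
default):

- **Baseline abundance** is log-normal (location 3.3, scale 1.1 in natural
  log TPM; median ≈ 27 TPM), reflecting the heavy-tailed TPM
  distributions of real cohorts and keeping > 99% of genes above the
  1-TPM expression filter.
- **Tissue structure.** Every gene receives i.i.d. log-normal per-tissue
  jitter with population CV 0.65, so UE genes' planted tissue CV is 65.
  Note that the *sample* CV of seven tissue means is biased low for
  right-skewed data, so the realised CV mode sits near 55–60 rather than
  exactly 65; the bimodal split is unaffected. TE genes additionally get
  one enrichment tissue (or, for a 5% minority, the configured joint pair
  with folds within 2× of each other) multiplied by a fold drawn uniformly
  from 5–50, which puts the TE CV mode above 200. Replicates are drawn
  around tissue means with 15% log-normal noise.
- **Hosts.** Each intron-embedded snoRNA (91% of genes by default) gets
  its own host gene whose log-abundance is built from the snoRNA's
  standardised log profile at a planted Pearson correlation ρ
  (default design: 60% of pairs at ρ = 0.7, 25% at 0, 15% at −0.6).
  Because ρ is planted on the log scale, recovery checks correlate
  `log2(TPM + 1)`; the pipeline's default linear-scale Pearson r is
  systematically attenuated for negative ρ on log-normal data (≈ −0.5
  observed for ρ = −0.6), which is a property of linear correlation on
  skewed data, not an estimation error.
- **Annotations.** Binary flags (box C/D, orphan target, protein-coding
  host, NMD substrate, DI promoter) are drawn per class from an
  odds-ratio design (`FlagDesign(p_ue, odds_ratio)`); defaults are shaped
  after the real snoRNome (H/ACA and DI promoters enriched in UE, orphans
  and non-coding hosts in TE). Conservation scores are Beta-distributed
  with class-dependent means. `SimulationParams.null()` removes every
  planted association (all ORs 1, all ρ 0, equal conservation) for
  calibration studies.

What the generator does **not** emulate: shared hosts (each snoRNA gets
its own host gene), multi-snoRNA host families, correlated flags (e.g.
real NMD susceptibility is itself associated with promoter type),
compositional coupling between genes induced by TPM normalisation, and
host-function effects on correlation sign. Passing recovery tests
therefore demonstrate that the estimators recover the planted marginal
structure, not that real tissues satisfy these independence assumptions.

## Null calibration of the battery

Under `SimulationParams.null()` the battery's Mann-Whitney series are
continuous and their p-values are checked for uniformity across seeds
(two-sided Kolmogorov–Smirnov). The exact Fisher tests, however, have
discrete and *conservative* null p-values by construction — on small
strata (e.g. ~20 protein-coding TE hosts) P(p ≤ α) can sit well below α —
so demanding strict uniformity from them would reject correct behaviour.
Their calibration is therefore checked as validity: a one-sided KS test
must find no excess of small p-values. Both checks run at the 0.01 level
per series in `tests/test_acceptance.py`.

## Problem sizes and determinism

The test suite simulates 20 default cohorts for recovery checks and 100
null cohorts for calibration, enumerates all ~25k canonical 2×2 tables
with margins ≤ 30 against the hypergeometric oracle, and verifies 1000
random Benjamini–Hochberg vectors — chosen so the whole suite completes in
about a minute on one core. Every stochastic component takes an explicit
integer seed (numpy `default_rng`); identical seeds give bit-identical
cohorts, and the pipeline itself contains no hidden randomness, so reruns
on identical inputs are byte-identical up to the output directory path
embedded in the report.

## Known limitations

- The tangent threshold assumes a dominant left mode with a descending
  right flank; heavily overlapping modes or a TE-dominated cohort move the
  threshold off the antimode, and a cohort with no high-CV component makes
  it meaningless (the construction still returns mode + 2σ-like values).
- The KDE bandwidth, grid and ddof all displace the threshold slightly;
  exact reproduction of a threshold obtained with other tooling may
  require matching that tooling's defaults (`kde_bandwidth`,
  `kde_grid_points`, `ddof`, and `cv_threshold` as a hard override).
- The exact 2×k test is exponential in k and margins; it is deliberately
  capped and is not a substitute for chi-square approximations on large
  tables.
- Correlation is Pearson-only (no Spearman/partial), and the battery
  applies no multiple-testing correction across its ~20 tests.
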