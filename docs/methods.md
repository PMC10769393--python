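# Methods

`nanoconcord` implements a cross-species concordance analysis for targeted
expression panels: how well do the transcriptome-wide effects of genetic
perturbations in mouse models of late-onset Alzheimer's disease (LOAD)
track the expression changes seen in human postmortem brain? The pipeline
has five computational stages — normalization, per-gene effect estimation,
mouse-human correlation, enrichment, and directional-coherence analysis —
plus a synthetic-data generator that makes every stage testable against
planted ground truth without any access-controlled human or animal data.

## Normalization

Panel counts are probe-based counts per gene per sample (lane). Three steps:

1. **Housekeeping scaling.** Each sample's counts are divided by the
   geometric mean of the designated housekeeping genes in that sample.
   After scaling, the housekeeping geometric mean is exactly 1 in every
   sample; the operation is invariant to per-sample scale factors and
   idempotent. A zero housekeeping count is an error, not a silent
   pseudocount — a housekeeping gene that drops out indicates a failed lane.
2. **Log transform.** `log_base(value + pseudocount)`, default base 2 with
   pseudocount 1. The base is cosmetic for every headline output: Pearson
   correlations and rank orders are invariant to a positive scale factor on
   log expression. This is asserted in the tests to ~1e-12 on the
   correlations (exact invariance is a mathematical statement; a change of
   floating-point scale perturbs the last bits of every intermediate).
3. **Batch correction.** The parametric empirical-Bayes location/scale
   model of Johnson et al. (ComBat): per gene, standardize by the
   covariate-adjusted grand mean and pooled variance, estimate per-batch
   additive (gamma) and multiplicative (delta-squared) effects, shrink gamma
   toward a normal prior and delta-squared toward an inverse-gamma prior
   with moment-matched hyperparameters (joint posterior solved by fixed-point
   iteration, relative tolerance 1e-6), adjust, and restore the scale.
   Strain and sex are protected covariates by default; `covariates=None`
   gives the conservative covariate-free correction. A single batch is the
   identity (logged). A batch fully confounded with a covariate raises a
   singular-design error. The `shrink=False` mode removes the exact
   per-batch location/scale estimates — the large-sample limit of the EB
   adjustment — and is the mode in which the grand mean of every gene is
   preserved to 1e-8 and a planted additive shift is removed to numerical
   precision; with shrinkage the preservation is approximate by design,
   since shrunk batch effects need not average exactly to zero. The
   implementation is cross-checked against scanpy's ComBat in the tests.

## Effect estimation

One joint per-gene ordinary-least-squares model per age cohort:

    log(expr) = beta_0 + beta_male * male + sum_s beta_s * x_s + eps

The strain encoding is **nested**: the baseline strain (B6J) is the
all-zero reference; the transgenic amyloidosis model (5xFAD) and the
sensitized comparator background (LOAD1, humanized APOE4 + Trem2*R47H) set
only their own indicator; each variant strain — a LOAD GWAS variant carried
on the LOAD1 background — sets the LOAD1 indicator *and* its own. Under
this encoding a variant's beta is its effect relative to LOAD1, which is
the contrast of interest, while LOAD1 and 5xFAD are measured relative to
B6J, all inside a single model. A `flat` encoding (each strain its own sole
indicator relative to baseline) is available for comparison but not used by
default. A heterozygous knockout is an ordinary 0/1 indicator; no dosage
column. Cohorts with a single sex drop the `male` column rather than carry
a constant regressor.

Inference is standard OLS: unbiased residual variance on `n - p` degrees of
freedom, two-sided t-tests. No shrinkage, no moderation, no gene-level
multiple-testing correction — downstream stages consume the coefficient
vectors, not gene p-values. Genes whose residual variance is at rounding
level relative to the data (threshold `(1e3 * eps)^2 *` mean square) are
flagged with `p = NA`. A rank-deficient design raises an error; there is no
silent pseudo-inverse fallback.

## Concordance

The headline statistic. For each mouse factor and each human contrast, the
Pearson correlation between the factor's per-gene coefficients and the human
log2 fold changes over the homologous genes, with the two-sided p-value of
`t = r * sqrt((n-2)/(1-r^2))` on `n - 2` degrees of freedom:

- **factor x module** — gene universe is the module's members mapped 1:1
  onto the panel (modules carry consensus-cluster labels A-E);
- **factor x subtype** — universe is every homologous panel gene, one cell
  per disease subtype and cohort (2 ROSMAP, 3 Mayo, 2 MSBB);
- **factor x factor** — similarity of effect vectors across strains, each
  unordered pair computed once and mirrored so the matrix is exactly
  symmetric.

Cells with fewer than `n_min = 5` complete pairs (the t approximation is
meaningless below that; never fewer than 3) or a constant
vector are NA with the attained n and a reason. Genes with NA on either side
are dropped per cell. Flags use the display rule *unadjusted* `p < alpha`
(strict inequality, default 0.05) with the sign of r; a BH-adjusted variant
exists but is off by default to match the display convention of the
dot-matrix figures.

Homolog mapping is case-sensitive with a declared cardinality policy:
default `1:1` drops any pair ambiguous after restriction to the panel (with
a logged count); `all` keeps every pair.

## Enrichment

Two engines, both BH-FDR corrected across evaluated terms:

- **Preranked GSEA.** Genes ranked by a factor's coefficients (ties broken
  by gene identifier, recorded). Running sum: hits advance by
  `|score|^w / sum_hits |score|^w` (weight `w = 1`, the classic default),
  misses retreat by `1/(N - N_hits)`; ES is the extreme deviation, signed.
  The null permutes gene-set *membership* (the only null available from a
  coefficient vector alone; sample permutation would require the raw data),
  default 10,000 seeded draws, with permutations cached per set size.
  Nominal p is the same-sign tail fraction with a +1 continuity correction;
  NES divides ES by the mean magnitude of same-sign permuted scores.
  Terms outside `[min_size, max_size] = [10, 500]` are skipped; a term
  equal to the whole universe is an error (the miss denominator vanishes).
  The vectorized ES is held to exact agreement with a brute-force loop
  oracle, and the sampled p to exhaustive enumeration on small universes.
- **Over-representation.** Upper-tail hypergeometric `P(X >= k)` for a
  query of size n overlapping a K-member term in an N-gene universe,
  computed from the exact distribution.

BH adjustment is the step-up `q_i = min_{j>=i} p_(j) * m / j`, capped at 1,
order-preserving, with NA p-values excluded from m (they yield NA q). It is
cross-checked against statsmodels.

## Directional coherence

For a (factor, module) pair — in practice the significant-positive cells of
the concordance matrix — the coherent set is the module-panel homolog pairs
whose mouse beta and human log2FC agree in sign *strictly*; exact zeros
carry no direction and are excluded. The coherent genes are tested by ORA
against the universe of panel genes mappable to that module's contrast (not
the whole genome: the panel is AD-enriched by construction, and a genome
universe would manufacture significance from panel composition). Terms
significant at BH-adjusted p < 0.05 in both the factor's GSEA and at least
one module's coherent-gene ORA are annotated to those modules and their
consensus clusters. Both runs must use the same term library; a mismatch is
an error.

## Synthetic data

The generator emulates the study design: a baseline strain, the comparator
background, a transgenic model, and eleven variant strains; both sexes; six
animals per strain/sex/age (the study's stated group size); ages 4 and 12
months; a ~760-gene panel with 10 housekeeping genes; four lanes.

Counts are negative binomial with log-mean = gene baseline + male effect +
strain effects + lane shift, and variance `m + dispersion * m^2`
(`dispersion = 0.1`; zero dispersion degenerates to Poisson). Gene baselines
are log-normal (`log-mean 5, log-sd 1`, i.e. median ~150 counts).
Housekeeping genes get a raised, tightened baseline (high stable
expressors), both realistic and necessary: the normalizer treats a zero
housekeeping count as an error. Per factor, exactly
`round(frac_affected * n_free_genes)` non-housekeeping genes carry a
N(0, effect_sd) effect (`frac_affected = 0.3`, `effect_sd = 0.5` natural
log — roughly 1.3-2-fold changes for a typical affected gene, a realistic
effect scale for brain expression in these models). Housekeeping genes carry
no strain or sex effect by construction. Variant-strain samples receive the
comparator effect plus their own, mirroring the nested design. Lane batches
get additive per-gene log-scale shifts (sd 0.2) and a multiplicative
dispersion scale (sd 0.05) — exactly the location/scale structure the
correction stage assumes, so its removal is verifiable. Lane assignment is
random and balanced, independent of strain/sex/age.

Human references are planted: each module (or subtype contrast) has one
driver factor and a target correlation rho; its log2FC over the member
genes is `rho * standardize(beta_true[driver]) + sqrt(1-rho^2) * noise`, so
the *population* correlation with the planted mouse effect equals rho by
construction. Non-driver factors have independent effects, hence zero
population concordance. Default planting cycles rho through 0.6 / 0 / 0.3
round-robin over factors, giving every bundle clearly positive, null, and
intermediate cells. The homolog map is 1:1 (uppercase aliases);
many-to-many handling is exercised through hand-written fixtures only.
Same seed, same outputs, bit-identical.

What the generator does **not** emulate: probe-level QC flags and
instrument artifacts, count outliers beyond NB dispersion, litter/cage
structure, correlated gene-gene expression networks (genes are independent
given the design), many-to-many orthology, and human cohort heterogeneity.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the declared model, not that real postmortem
concordances of any particular magnitude will be detected.

## Validation studies and problem sizes

`nanoconcord.benchmarks` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs the validation battery at sizes chosen to
complete in a few minutes on one core:

- OLS vs normal-equations oracle: 100 random 0/1 designs, up to 8 factors
  and 60 samples; max relative error ~1e-12.
- CI calibration: one full simulated cohort (300 genes, 5 strains, 6 per
  sex/group), 95% CI coverage of planted effects across ~1,500
  factor-gene cells. The benchmark rescales normalized ratios by the
  reference housekeeping geometric mean before the log so the +1
  pseudocount stays negligible at count scale — the standard reference-lane
  convention — and uses the natural log to keep the planted effect scale.
- Concordance recovery: 200 replicates per rho in {0, 0.3, 0.6}, module
  size 100, concordance computed on the exact planted effect vectors (this
  isolates the correlation machinery; estimation noise is covered by the
  CI and end-to-end studies). Null flag rate measured over all 3,000
  null factor-module cells.
- GSEA: 1,000 random instances of up to 12 genes against the loop oracle
  (exact agreement); sampled permutation p against exhaustive enumeration
  of all memberships for an 8-gene universe.
- ORA: exact agreement with enumeration over all draws for N <= 12.
- Batch correction: two batches of 40 with a planted 1.5-unit shift,
  exact (unshrunk) regime: shift removal to machine precision, per-gene
  post-correction batch F-test flag rate at alpha 0.05.
- End-to-end: 20 full simulated studies (250 genes, 5 strains, 2 lanes,
  age 12), three rho = 0.6 modules and three null modules of 100 genes;
  sensitivity of the flag matrix on planted pairs and the null flag rate.
  With n = 6 per sex/group the estimated-coefficient attenuation puts
  per-cell power near 99%, so the all-pairs sensitivity is 1.0 for most
  seeds but a single borderline cell can miss for some.

## Known limitations

- The EB shrinkage variant of the batch correction is parametric only.
- Preranked GSEA's membership-permutation null is known to be
  anti-conservative relative to sample permutation on correlated gene sets;
  with independent simulated genes it is calibrated (verified), but real
  co-expression would inflate it — inherent to any preranked analysis.
- The concordance p-values are per-cell and unadjusted by default,
  matching the display rule; treat the factor x module grid accordingly.
- No mixed effects, no sex-by-strain interactions, no meta-analytic
  combination across brain regions.
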