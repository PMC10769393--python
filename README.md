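# nanoconcord

Mouse-to-human transcriptomic concordance for targeted expression panels.

New mouse models carrying late-onset Alzheimer's disease (LOAD) risk
variants need a quantitative answer to one question: do the expression
changes they drive look like human disease? `nanoconcord` implements the
panel-based analysis that answers it. Starting from a gene x sample count
matrix (a NanoString-style AD panel measured across strains, sexes, ages
and lanes), it:

1. **normalizes** — divides each lane by its housekeeping geometric mean,
   log-transforms, and removes lane batch effects with the parametric
   empirical-Bayes (ComBat) location/scale model;
2. **estimates effects** — one joint per-gene OLS model per age,
   `log(expr) = β₀ + β_male + Σ_s β_s`, with variant strains nested on the
   LOAD1 (APOE4/Trem2*R47H) background so each variant β is its
   background-relative effect;
3. **correlates** — Pearson r (with the t-based p of `r√((n−2)/(1−r²))`)
   between each factor's β vector and human log2 fold changes: per
   co-expression module (consensus clusters A-E), per disease subtype and
   cohort, and between factors;
4. **characterizes drivers** — preranked GSEA on β-ranked panel genes with
   a seeded membership-permutation null, hypergeometric over-representation
   of directionally coherent genes (sign(β) = sign(log2FC)), both BH-FDR
   corrected, and annotation of shared terms back to modules.

A first-class synthetic-data module simulates the whole study — negative
binomial counts with planted strain/sex/batch effects, plus human module
and subtype contrasts with *planted* mouse-human correlations — so every
stage is validated against known truth with no access-controlled data.

## Worked example

The numbered scripts under `analysis/` run a full simulated study. After
`python analysis/01_simulate.py` (full-scale bundle: 760 genes, 14 strains,
336 samples per age pair, planted module concordances cycling
ρ = 0.6/0/0.3):

```
$ python analysis/02_normalize.py
expression written to results/expression/expression.tsv (760 genes x 336 samples)
  mean lane-variance fraction: 0.1487 before -> 0.0040 after correction
  RMS adjustment applied: 0.0793 (log2 units)

$ python analysis/03_fit_effects.py
age 4 months: 168 samples, 14 factors; corr(estimated, planted beta) median 0.737 (range 0.689-0.837)
age 12 months: 168 samples, 14 factors; corr(estimated, planted beta) median 0.732 (range 0.682-0.841)

$ python analysis/04_concordance.py
age 12 months: 9 factor-module cells flagged positive; 4/4 planted rho=0.6 pairs recovered; 5/136 other cells flagged (3.7%)
age 4 months: 10 factor-module cells flagged positive; 4/4 planted rho=0.6 pairs recovered; 6/136 other cells flagged (4.4%)
```

Reading: batch correction removes essentially all lane-associated variance
(14.9% → 0.4%); per-gene effect estimates correlate ~0.73 with the planted
truth at n = 6 animals/sex/group (the attenuation expected at that sample
size); and in the flagged factor x module matrix every pair planted at
ρ = 0.6 is recovered as significant-positive while null cells are flagged
at roughly the nominal 5% rate. `05_enrichment.py` and `06_coherence.py`
continue with ranked-list enrichment and the coherent-driver analysis;
`results/concordance/*.png` holds the dot-matrix views (circle size/color
∝ r, frame = significant at p < 0.05).

The same stages are scriptable on real data through the library or the CLI:

```sh
nanoconcord normalize --counts counts.tsv --annot annot.tsv \
    --housekeeping hk.txt --out expr.tsv
nanoconcord fit --expr expr.tsv --annot annot.tsv --roles roles.yaml \
    --age 12 --out effects_12mo.tsv
nanoconcord concord --effects effects_12mo.tsv --contrasts contrasts.tsv \
    --modules modules.gmt --clusters clusters.tsv --homologs homologs.tsv \
    --out concordance.tsv
nanoconcord run --config pipeline.yaml   # everything, with a manifest
```

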