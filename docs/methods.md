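# Methods

This document records the statistical models, the default parameters and
their rationale, and the detection conventions used by `poqtl`.

## Cross designs and lineage bookkeeping

Four reciprocal backcrosses are modeled, written *mother × father*:

| cross  | F1 parent | segregating allele origin | mito strain | Y strain |
|--------|-----------|---------------------------|-------------|----------|
| DAxF1  | father    | paternal                  | D           | P        |
| F1xDA  | mother    | maternal                  | D           | D        |
| PVGxF1 | father    | paternal                  | P           | P        |
| F1xPVG | mother    | maternal                  | D           | P        |

DABC = {DAxF1, F1xDA} (DA background), PVGBC = {PVGxF1, F1xPVG} (PVG
background).  The F1 always derives from a DA mother and PVG father, so
mitochondria follow the maternal lineage (only PVGxF1 offspring carry PVG
mitochondria) and the Y follows the patriline (only F1xDA males carry the
DA Y).  These two facts create the lineage confounds that the classifier
must flag: a detection pattern of exactly {DAxF1, F1xDA, F1xPVG} splits the
four crosses along the mitochondrial lineage, and a male-only F1xDA-specific
pattern splits DABC along the patriline.

Meiosis assumes no crossover interference: recombination between adjacent
positions follows the Haldane map, r = (1 − e^(−2d/100))/2 for d in cM.
Physical and genetic coordinates are related linearly at 0.55 cM/Mb, which
is adequate for microsatellite framework maps at 20–25 cM spacing.  The
default map has 20 autosomes and 140 markers at 20 cM spacing (≈ 36.4 Mb).

Advanced intercross lines are bred by explicit pedigree: two founder
crosses, then random-pair intercrossing to G10 with recorded family origin.

## Phenotype model

Clinical phenotypes derive from a liability-threshold model.  Disease
liability is Gaussian (residual SD 1); an animal is affected when liability
exceeds the threshold (default 0, giving 50% baseline incidence, matching
the 60–77% range of the motivating study once risk alleles are added).
Affected animals receive onset, duration and maximum-score values monotone
in liability, with link coefficients chosen so simulated group means and
SDs resemble the published reciprocal-cross summaries; weight loss is
observed for all animals.  Unaffected animals are censored: onset = study
end (day 40) by default, or NaN under `censor_onset="nan"`.

QTL modes act on liability: `additive` (per risk-allele effect),
`maternal_expressed` / `paternal_expressed` (only the allele of that
parental origin acts), `y_linked` (males of the risk patriline), and
`mitochondrial`.  The mitochondrial mode is simulated as a *nuclear locus
expressed only in individuals whose mitochondrial lineage carries the risk
strain* (mito-nuclear conditioning).  A pure lineage shift with no nuclear
locus would leave nothing to map and could never produce the published
three-cross detection pattern; conditioning a mappable locus on the
lineage reproduces exactly that pattern.

Derived phenotypes from daily scores: scoring starts day 7 post
immunization; an animal counts as affected only with signs on more than one
day; onset is the first scored day, duration the number of scored days,
MAX the maximum 0–5 score, WL the largest weight loss as a percentage of
the weight at immunization.

## Genotype probabilities

A backcross segregates two genotype classes per autosomal locus, so the
true genotype along a chromosome is a two-state Markov chain with Haldane
transition probabilities; observed marker genotypes are emissions with a
symmetric error probability (default 1e-4).  `calc_genoprob` runs the
forward–backward algorithm with per-position rescaling (posterior marginals
are invariant to the scaling) over a pseudomarker grid (default step 1 Mb;
step 0 gives a markers-only grid).  `sim_geno` draws joint genotype paths
by filtering forward and sampling backward; over many draws the empirical
het frequency converges to the forward–backward marginals.  Both are tested
against exhaustive enumeration of all 2^m state paths at 1e-10.

## Genome scans

Haley–Knott regression: at each grid position the phenotype is regressed on
P(het) plus covariates, and LOD = (n/2)·log10(RSS0/RSS1).  The scan is
vectorized by projecting phenotypes and genotype probabilities onto the
orthogonal complement of the covariate space (QR), so permutations are a
single matrix product.  Pointwise p-values use the equivalent F statistic
F = (10^(2·LOD/n) − 1)·df2 with df2 = n − 2 − df_covar.

Genome-wide thresholds: phenotype labels are permuted (default 1000 times),
and the threshold is the empirical (1 − α) quantile (type-7) of the
genome-wide maximum LOD.  Calibration: over 500 null backcross datasets
(n = 200, 140 markers), the observed max LOD exceeds the 1000-permutation
5% threshold in ≈ 6% of datasets — within three binomial SEs of nominal;
the slight excess reflects the regression approximation and quantile
interpolation at finite permutation counts.

Peak localization: case bootstrap (default 1000 replicates) of the
single-chromosome scan peak; the profile of peak positions gives a smallest
contiguous set with ≥ 95% coverage.  On the default map a 0.5 SD QTL at
n = 220 yields intervals spanning ~110 Mb — localization below chromosome
scale is not attainable at these sample sizes, which motivates the
chromosome-level truth matching used in the recovery tests.

## Multiple-QTL models

Forward selection adds the genome-wide best position given the current
model (existing QTL probabilities as additive covariates) up to `max_qtl`
(default 10); backward elimination repeatedly drops the QTL with the
smallest drop-one LOD until all clear `keep_lod` (default 1.5).  Ties break
leftmost, so the search is deterministic.  The selected model is fitted
over multiple imputations (default 128): each draw by least squares, draws
combined on the likelihood scale (log-mean-exp of RSS^(−n/2)), and each
term tested by a drop-one F against the full-model residual.  With one
imputation on fully typed markers this reduces exactly to OLS, which is how
it is tested.

## Parent-of-origin detection conventions

`stratified_scan` scans each reciprocal cross separately plus pooled, for
ONS/MAX/WL by default.  The conventions mirror how reciprocal-cross studies
report per-cross allelic effects:

- **Locate**: a QTL exists wherever any scan reaches LOD ≥ 1.3 (the
  nominal, suggestive-linkage threshold).  Permutation thresholds are
  available but per-cross effects in the motivating design are reported at
  nominal significance once a region is implicated.
- **Merge**: peaks on one chromosome closer than
  max(`merge_mb`, grid spacing × 1.01) are one QTL.  The default 20 Mb
  radius is below the default 36.4 Mb marker spacing, so on a markers-only
  grid the effective radius is one grid step; analyses combining two
  populations should pass `merge_mb=40`.
- **Detect per cross**: at the merged peak, a cross counts as detecting the
  QTL if its best pointwise p across the scanned phenotypes is ≤ 0.05
  (Student-t-at-peak convention).
- **Classify**: detection confined to F1-mother crosses ⇒ maternal;
  F1-father crosses ⇒ paternal; both crosses of a population ⇒ additive
  ("none"); opposite single-cross sides in the two populations ⇒
  unresolved.  The exact mitochondrial split (all four crosses observed,
  detected in precisely the three D-mito crosses) is flagged
  `mito_candidate` and never given a parental call; a male-only
  F1xDA-specific pattern with PVGBC observed is flagged `y_candidate`.
- **Confirm**: a classification becomes a *final* parent-of-origin call for
  a population only if the QTL is single-cross there, its cross-by-QTL
  interaction (drop-one F of the QTL × cross term in the full
  multiple-QTL model, over imputations) is significant at α = 0.05 for at
  least two phenotypes, and no disqualifying confound is flagged.

Strata below 30 individuals trigger a warning (detection power is poor).

Measured operating characteristics at the design's published scale
(0.5 SD maternally expressed QTL, 110 per cross, defaults above):
P(locate on the true chromosome) ≈ 0.80; P(correct single-cross pattern |
located) ≈ 0.88; joint maternal recovery ≈ 0.65.  A noncentral-F power
analysis predicts the same 0.6–0.7 range, i.e. the procedure operates at
its theoretical ceiling for this effect size and design.

## Comparison statistics

Incidence differences use Fisher's exact test (two-sided); continuous
phenotypes use the pooled-variance Student t (Welch available), computable
directly from printed mean/SD/n summaries so published comparison tables
can be recomputed without raw data.  Mann–Whitney, a two-sided
variance-ratio F and Brown–Forsythe Levene serve as robustness checks.
Note that a printed SD of 0.51 for a binary trait with mean 0.60 is not
attainable (Bernoulli max ≈ 0.49); incidence SDs in transcribed summaries
are treated as transcription artifacts and only the counts are used
(Fisher on back-computed affected counts).

## Determinism and numerics

All randomness flows from a single seed via named substreams
(`SeedSequence([seed, crc32(name)])`); no stage reads the wall clock or
global RNG state, and pipeline reports are byte-identical across runs with
the same seed.  Cross files round-trip bit-exactly: genetic positions are
written with full float repr and parsed with correctly rounded `float()`
(pandas' fast parser can be off by one ulp).  Regressions guard against
degenerate designs: collinear covariates raise, RSS is floored at 1e-300
before logs, and rank-deficient full models raise rather than silently
dropping terms.

## Limitations

- The genotype-probability HMM is backcross-specific (two states); AIL
  populations are supported for breeding, map-expansion and
  origin-interaction analyses, but dosage-based scans of an intercross
  should regress on allele dosage directly (see
  `examples/05_advanced_intercross.py`).
- Published per-QTL peak p-values, LODs and variance-explained values from
  the motivating study cannot be recomputed without the undeposited raw
  genotypes; they ship as fixtures and are verified by pass-through only.
- The 0.55 cM/Mb linear map ignores local recombination-rate variation.
- X-chromosome genetics is not modeled (the default map is autosomal).
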