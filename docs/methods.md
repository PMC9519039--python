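# Methods

This note records the models, parameter choices and numerical conventions
behind `granulecall`, including the points where the underlying procedure
is ambiguous and a concrete reading had to be fixed.

## Coordinate and file conventions

All interval logic is 0-based, half-open. GTF (1-based inclusive) and
BED (0-based half-open) are converted at the readers/writers in
`granulecall.io` and nowhere else. Result tables are written as TSV,
sorted by their stable keys (feature/protein id, then contig, start,
strand), with missing values as `NA`; writing the same records in any row
order produces a byte-identical file. Transcription end sites are taken
from GTF `transcript` records: the end coordinate on `+`, the start
coordinate on `-`, deduplicated; strandless transcripts are skipped with
a warning.

## RNA granule-component calling

**Normalization.** Median-of-ratios size factors: features with a zero in
any sample are excluded; each remaining feature contributes
count / geometric-mean, and the per-sample factor is the median of those
ratios. Only ratios of factors matter downstream, so no rescaling is
applied. If no feature is all-nonzero the estimator refuses (no
pseudo-reference fallback).

**Differential enrichment.** The engine is intentionally plain:
log2FC = log2((mean normalized a + 0.5)/(mean normalized b + 0.5)), p
from a two-sided Welch test on log2(normalized + 0.5), base mean = mean
normalized count over all samples, Benjamini–Hochberg adjustment. It is a
stand-in for a full negative-binomial DE model; `classify_rna_components`
accepts any table with columns `feature_id, log2fc, base_mean, p_value,
p_adjusted`, so results from a dedicated DE package can be substituted
without touching the classification layer, which is the substantive part.

**Classification.** Base-mean gate: strictly > 10, applied to the mean of
the four tables' base means. Criterion (i) uses the *signed* difference
wt − mut > 0.5: the direction of interest is enrichment lost in the
mutant; an absolute difference would also call mutant-gained features.
Criterion (ii) reads "significant only in wild type" as: wild type
positive-and-significant AND mutant not positive-and-significant — a
mutant fold change that is significant but *negative* does not block the
call. The p in criterion (ii) is the raw p-value (the procedure
contrasts it explicitly with the adjusted p used for ordinary DE gene
lists). Both criteria are strict inequalities except where "at least"
forces inclusiveness (see proteins). A feature is called only when a
criterion holds in both granule fractions independently.

**Known behavior at the default dispersion.** With negative-binomial
dispersion 0.1 and 3 replicates, the fold-change estimator has
sd ≈ 0.26 per group mean, so the criterion-(i) statistic has null
sd ≈ 0.53 and P(>0.5 | null) ≈ 0.17 per fraction (≈ 0.06 jointly, the
two fractions sharing lysate samples). On the default simulation (2,000
genes, 100 planted) this yields sensitivity ≈ 1.0 but precision ≈ 0.45:
criterion (i) carries no significance requirement, so its specificity is
entirely at the mercy of the fold-change sampling noise. Shrunken or
moderated fold-change estimates (as a full DE package provides) would
restore precision; with the plain estimator the calls should be read as
a high-sensitivity candidate list at this noise level.

## Protein processing and calling

**Imputation.** Per condition (genotype × fraction): exactly one missing
replicate → copy the protein's value from the nearest replicate column;
two or more missing → basement value in every missing cell. "Nearest" is
the donor column minimizing the root-mean-square difference to the
incomplete column over co-observed proteins (RMS rather than raw
Euclidean so pairs with different co-observation counts are comparable;
with equal counts the two orderings coincide). Ties break to the lower
replicate id. Observed cells are never altered by any imputation step.

**Basement value 8** is interpreted on the log2-iBAQ scale: a raw
intensity of 8 would be indistinguishable from zero after log transform,
whereas 8 on the log2 scale sits plausibly below the observed dynamic
range, which is what a detection-floor placeholder is for.

**Reliability filters.** (i) A protein is dropped if any wild-type
replicate was missing in both its granule and its lysate column before
imputation — that replicate pair carries no information about
enrichment. (ii) A protein is dropped if, in either genotype, a replicate
pair containing a nearest-neighbour-imputed value has a granule-minus-
lysate sign opposite to *every* fully observed replicate pair; requiring
disagreement with all observed pairs is the conservative generalization
beyond the 3-replicate design (where one imputed implies two observed).

**Normalization.** "Mean normalization" is column centering: each sample
column minus its mean on the log2 scale. Row scaling and common-mean
rescaling were the alternatives; column centering is what a
center-transform in standard preprocessing toolkits does and is
shift-invariant per sample. Note one consequence: planted or real granule
signal present in many proteins shifts the granule column's mean and is
partly absorbed by centering (see "Synthetic data" below).

**Classification.** Genotype fold change = mean over replicate pairs of
(granule − lysate), paired by replicate id. Route 1: mutant expression
observed and wt − mut ≥ 4.8 ("at least" read as inclusive). Route 2:
every mutant cell missing before imputation and wt fold change > 0.

**Global proteome test.** Pooled-variance two-sided t per protein on the
imputed, mean-normalized lysate columns; significant ⇔ p < 0.05 and
|log2FC| > 0.5. Degenerate rows (zero variance in both groups) get p = 1
for equal means and p = 0 with a logged warning otherwise.

**RAP-MS.** Keep proteins with ≥ 2 valid values in either group;
log2-transform (a stand-in for variance-stabilizing normalization — the
interface takes `log_transform=False` for pre-transformed input, so an
exact vsn replication can be injected); impute each sample's missing
cells from Normal(μ_s − 1.8 σ_s, (0.5 σ_s)²) with μ_s, σ_s the sample's
observed mean and sd — the downshift/width convention is per sample, in
units of that sample's sd; pooled two-sided t (an ordinary test in place
of moderated statistics); Benjamini–Yekutieli adjustment (valid under
arbitrary dependence); enriched ⇔ adjusted p ≤ 0.05, |log2FC| > 0.5 and
positive toward the cross-linked group. With complete data the result is
seed-independent because no draw occurs.

## Poly(A)-site calling

"More than 70 % A in a 10-bp window" is evaluated as an integer count:
the minimum count is the smallest integer strictly exceeding
a_fraction × window (8 for the defaults; 7/10 = 70 % does not qualify).
The comparison is done on integers to avoid float-boundary artifacts.
"Upstream" is 5′ of the site on the read strand and excludes the site
position: reference [p−10, p) on `+`; on `-` the window is reference
[p+1, p+11) with read-strand A equal to reference T. Windows truncated
by a contig edge never blacklist (insufficient context, logged). `N`
never counts as A. TES protection is symmetric ±250 bp and
strand-matched. Coverage filtering: blacklist first, unconditionally;
then a site is kept if it has ≥ 5 reads in *at least one* sample — the
every-sample reading would discard genotype-specific sites and defeat a
wild-type-vs-mutant comparison. Clustering is single-linkage with an
inclusive 15-bp gap to the most recent member, so chains longer than
15 bp are expected behavior, not a bug. Coverage is conserved: summed
cluster coverage equals summed retained-site coverage.

## Synthetic data

The generators are first-class, tested code; their defaults *are* the
study conditions of the recovery analyses.

**Fraction counts.** 2,000 genes × (2 genotypes × 3 fractions × 3
replicates). Baseline means log-uniform on [20, 2000] (so everything
clears the base-mean gate and spans typical bulk RNA-seq depth); counts
negative binomial with variance μ + 0.1 μ² (dispersion 0.1, the upper
end of what well-replicated bulk experiments show at moderate counts);
100 planted components get ×2² mean in wild-type granule fractions only.
What this does not emulate: library-size imbalance beyond size-factor
noise, gene-length effects, count correlation between fractions of the
same animal. Passing recovery tests therefore demonstrate the logic of
the calling rules at a stated noise level, not performance on any real
library.

**iBAQ intensities.** 1,000 proteins; per-protein baseline
Normal(14, 2²) on the log2 scale (placing the basement value 8 three
between-protein sds below the center, i.e. under the detection floor, as
in real iBAQ tables); replicate noise sd 0.5; 100 planted proteins gain
+6 log2 in wild-type granules. Dropout is missing-not-at-random:
P(missing) = expit(2 · (midpoint − intensity)), the midpoint solved
numerically (Gauss–Hermite + Brent) so the expected missing fraction of
a baseline-distributed cell equals the configured rate (default 10 %).
A quantitative consequence of the design: 100/1000 planted proteins at
+6 raise the wild-type granule column mean by ≈ 0.6, and column
centering absorbs that much of the planted difference (realized
≈ 5.4 vs 4.8 threshold). Together with imputation variance this puts
planted-recovery sensitivity near 0.79 at the defaults — the recovery
analysis reports what the full pipeline, centering included, actually
delivers under these conditions.

**3′-end reads.** One 150-kb random contig (uniform base composition);
250 sites on an even grid with jitter, shuffled labels: 50 true sites,
each with an emitted same-strand TES within 100 bp (well inside the
250-bp protection), and 200 decoys whose upstream window sits inside a
planted 30-bp homo-A tract (T-tract on the reference for `-` sites) and
which lie > 250 bp from every TES — the generator verifies these
guarantees rather than trusting construction. The 150-kb default gives
≈ 600 bp spacing, the minimum that can keep decoys clear of all TES
windows. Per-sample coverage Poisson(20) across 6 samples. Not emulated:
microheterogeneity of cleavage (multi-base site clouds), partial A
stretches, chained sites — so cluster widths here are degenerate
(single-base) by design.

**Determinism.** Each generator consumes a single
`numpy.random.Generator` seeded from the config (or an explicit seed
argument), so all outputs are bit-reproducible functions of
(config, seed).

## Problem sizes

The recovery and calibration analyses run at the full stated conditions
(2,000 genes / 1,000 proteins / 250 sites; 1,000 randomized inputs for
each classifier cross-check; a 50-kb genome for the exhaustive blacklist
scan). The complete test suite and the acceptance script each finish in
well under a minute on a single CPU.

## Known limitations

- The DE engine is a Welch-on-log stand-in; its p-values are slightly
  conservative at n = 3 (empirical null size ≈ 0.035 at α = 0.05).
- Criterion (i)'s precision depends directly on fold-change estimator
  noise (see above); with dispersion ≥ ~0.1 and 3 replicates it admits
  many background genes.
- Nearest-neighbour imputation copies a donor value verbatim; it does not
  model within-condition correlation structure.
- The blacklist stores one boolean per (position, strand); for genomes
  far larger than the simulated contigs an interval representation would
  be preferable.
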