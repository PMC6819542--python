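# Methods

This note documents the models and procedures implemented in `pavomics`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## ePAV calling

Expression presence/absence is called per tissue from FPKM values T:
*present* if T > 0, *absent* if T = 0, *no call* in the open band
0 < T < 0.10 · max(T) where the maximum is taken per gene over the inbreds
with data in that tissue (tissues may cover different inbred subsets; the
band threshold is therefore per gene **and** per tissue). The across-tissue
consensus keeps a present call if any tissue is present; an inbred-gene
pair whose available tissue calls contain only absent and no-call states
becomes absent if at least one tissue says absent. A pair that is no-call
in every tissue stays no-call rather than absent: treating pure
no-call tuples as absent would contradict the rule that identical tissue
calls are kept, and no-call carries no evidence of absence. A gene is an
ePAV at threshold t if its consensus row has ≥ t present and ≥ t absent
calls (no-calls count toward neither side); t = 2 is the default and
EPAVSet(t+1) ⊆ EPAVSet(t) by construction.

Because the band threshold is relative, rescaling a gene's FPKM row leaves
its calls unchanged; this is a tested invariant.

### Windowed calls and length resampling

Both operations recompute expression from per-gene read-coverage profiles.
Coverage is stored as binned counts (bin = 1 bp for genes up to 100 bp,
proportionally wider above that cap), so restricting to a position subset
is exact at bin resolution. The 10 bp window variant recomputes an
FPKM-like value from coverage in ± 5 bp around a genic SNP (clipped at gene
bounds, partial bin overlap prorated) and feeds it through the unchanged
calling rule. The robustness resampling selects a random contiguous block
covering 20% of each gene's length (a scattered-positions strategy is
available behind a flag), recomputes expression, and reruns calling,
merging and designation; 50 replicates is the conventional default, and a
gene counts as "detected" in a replicate if it has positive expression in
at least two samples across all tissues and inbreds.

## gPAV inference from segregating missing data

The deletion signature on a SNP array: a progeny of a cross between a
deletion carrier and a non-carrier inherits 0, 1 or 2 null copies of the
locus. Cluster-based array callers no-call both null homozygotes and
hemizygotes (their intensities fall outside the diploid clusters), so at a
SNP inside a gene deleted in one parent the expected missing proportion is
the carrier frequency of the null haplotype — 17/32 ≈ 0.53 for F5 progeny
under single-seed descent (P(het) = 2⁻⁴, carriers = 1 − (1 − 2⁻⁴)/2). The
generator and a brute-force gamete-dropping oracle in the test suite agree
on this value.

Per population, Q90 is the 90th percentile (linear interpolation between
order statistics; convention exposed as an option) of the major-allele
frequency over fully-observed SNPs. Only SNPs segregating in that
population enter: monomorphic SNPs sit at frequency 1.0 by definition and
carry no information about random deviation from the expected 0.5 ratio.
Heterozygous calls contribute half a count to each allele.

Categories use the ordering consistent with Q90 ≥ 0.5 — A: m ∈ [0, 1−Q90),
B: m ∈ [1−Q90, Q90], C: m ∈ (Q90, 1] — preserving the interpretation
A = both parents present, B = exactly one absent, C = both absent. (The
bounds in the printed order A: [0, Q90) … are empty or overlapping for
Q90 > 0.5; that literal form is available behind a `strict_literal` flag.)

A parent is **absent** at a SNP if all its populations are B or C *and at
least one is C*; **present** if all are A or B *and at least one is A*.
All-B patterns satisfy both of the quoted conditions simultaneously and are
therefore left undetermined by default. An optional resolution pass
(`resolve_all_b=True`) assigns absent to an all-B parent whose every
crossing partner carries a present call at the SNP — category B means
exactly one parent of the cross is absent, so present partners pin the
absence — which recovers sole deletion carriers in sparse crossing designs.

gPAV-SNPs have at least one present and one absent parent; genic PAV-SNPs
additionally lie inside a CDS and more than 30 bp from every insertion
(a SNP exactly 31 bp away is kept).

Scoring the ePAV caller against this channel:

- power 1 − β* = % of genic PAV-SNPs whose gene is an ePAV;
- α* = % of ePAV genes that contain a genic SNP but no genic PAV-SNP.
  The denominator is the ePAV genes containing a genic SNP — the evaluable
  subset; dividing by all ePAV (available via `literal_denominator=True`)
  mixes genes for which the SNP channel is silent into the rate;
- o = % agreement between consensus ePAV calls and parental SNP calls over
  (gene, inbred) pairs at genic PAV-SNPs, skipping pairs where either side
  is no-call/undetermined (agreement is undefined there).

The dispensable-genome extrapolation is
`round(n_epav · fraction) / power`, rounded.

## Variant QC

The cascade runs in a fixed order: variants with mapping quality < 55 are
removed; calls with depth < 5 become NA; variants with > 10% heterozygous
calls (among non-NA calls — missingness must not dilute the fraction) are
discarded and residual het calls become NA; more than two observed alleles
removes the variant; inbreds whose every tissue record is NA count as
missing and variants with > 20% missing inbreds are removed; conflicting
cross-tissue calls resolve to the higher-depth call with ties going to NA
(no basis to prefer either); finally remaining NAs are imputed with the
variant's mean coded dosage. Every input variant is attributed to exactly
one outcome in the QC log, and re-running the cascade on a reconstruction
of its own output changes nothing.

LD between an ePAV (coded present = 1, absent = 0, no-calls mean-imputed)
and a variant is the squared Pearson correlation — symmetric and invariant
to allele relabeling. The LD profile takes, per ePAV gene, the maximum r²
over variants within 100 kb of the gene's boundaries (linked) and outside
(unlinked), plus the same for the variant closest to the gene, and bins the
maxima into the five classes [1.0, 0.8], (0.8, 0.6], …, (0.2, 0]. Genes
with no variant in a scope are excluded from that scope's denominator and
counted. Note that r²max is an extreme statistic: comparing linked against
unlinked distributions requires size-matched variant sets, which is how the
package's null test is constructed.

## Structure statistics

PCA scores come from the SVD of the column-standardized feature matrix;
concordance between layers is the squared correlation of paired component
scores (sign-invariant) with the two-sided correlation p-value. Mantel
tests delegate to scikit-bio's implementation (Pearson correlation of
off-diagonal distances, row/column permutations, (b+1)/(m+1) p-value — so
permutation p-values are never exactly zero). The ePAV-uniformity test bins
gene midpoints into sliding windows (default width 20 Mb, step = width/2;
both are options since "sliding" fixes neither) and summarises each
chromosome by the range of window-wise ePAV proportions — a statistic
sensitive to local enrichment; a chi-square alternative is provided, and
neither is claimed to be canonical. The null distribution permutes ePAV
labels over all genes. Gene-length comparison uses Welch's t-test because
the two groups' variances are clearly unequal for length data.

## Prediction

Feature matrices W (inbred × feature) are column-centered and standardized;
zero-variance columns are dropped and counted. The VanRaden additive
relationship matrix is G = WW′/m, so the diagonal mean is ≈ 1 and
duplicated features cancel. Kernels combine as Σ wᵢGᵢ with w on the unit
simplex; the 0.1-step grid over three predictors has C(12,2) = 66 points.

GBLUP fits y = 1μ + g + e with g ~ N(0, σ²g G), e ~ N(0, σ²e I). The
variance ratio λ = σ²e/σ²g is estimated by REML, profiling the restricted
likelihood over log λ with a single eigendecomposition of the
intercept-projected training kernel per fit — exact, dependency-light and
stable at n = 23. Validation predictions are the conditional mean
μ̂ + G_vt (G_tt + λI)⁻¹ (y − 1μ̂) with μ̂ from GLS; a singular system
falls back to a 1e-8 ridge on the diagonal. The implementation is tested
to 1e-8 against a brute-force mixed-model-equation solve (the MME oracle
requires a full-rank G; centered VanRaden kernels have the ones vector in
their null space, so oracle comparisons blend in a small identity
component on both sides).

Cross-validation splits the panel into five disjoint subsets of sizes
differing by at most one (5/5/5/4/4 for 23 inbreds), repeated 200 times
(1000 runs); accuracy is the raw Pearson correlation r(ĝ, y) on the
validation entry means — not divided by h, consistent with reporting
negative medians on small folds. The fold plan is derived from the seed
and *shared* across all weight settings of a grid search, making the
66-way comparison paired; whether to share plans was an open choice, and
pairing was chosen for variance reduction, not claimed as original.

The read-downsampling experiment thins every coverage bin of the chosen
tissue and every variant depth binomially with the target fraction,
recomputes expression, ePAV calls (depth-dependent) and the variant matrix
through the full QC, and re-evaluates single-kernel and best-combination
accuracies. Thinning with fraction 1.0 reproduces the full pipeline
bit-exactly (feature preprocessing makes a contiguous array copy precisely
so that results cannot depend on DataFrame memory layout). Default grid
step within the experiment is 0.5 and CV replicates 20, keeping the
30-replicate × 4-fraction experiment tractable; both are parameters.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 23 founder
inbreds, three tissues with the third profiled in only ~6 inbreds, gene
lengths log-normal (median ≈ 3 kb), expression levels log-normal with
per-inbred noise, read counts multinomial over genes (weight ∝ level ×
length) at a configurable library size, and coverage multinomial over
bins within each gene — so FPKM = count/(gene_kb · mapped_millions)
holds exactly and Σ FPKM·len_kb = 10⁶ per sample. Deletions (frac_gpav)
and silencing (frac_silenced) are disjoint gene classes; carriers per gene
are 1 + Binomial(n − 2, sharing) because the share of private vs common
PAV is not pinned down by the design and is left as a parameter. Silencing
is all-tissue with probability 0.67 (matching the observation that about
two-thirds of dispensable genes behave consistently across tissues) and
otherwise hits a random tissue subset. Selfing is single-seed descent
without selection; F5 = F1 selfed four times. Crosses follow a
double-chain round robin (i×i+1, then i×i+2) truncated to the requested 45
populations of 35–146 progeny. Sequence variants are exonic, biallelic,
and copy the previous variant's allele per inbred with probability
exp(−d/ld_block_bp), giving distance-decaying LD; deliberately bad records
(low MQ, shallow depth, het flags, a third allele) exercise every QC
branch. Genetic values mix a variant-driven and an expression-driven
standardized component (weight `causal_mix`); entry means add Gaussian
noise scaled so var(g)/var(y) = h², with h² = 0.72 as the default inside
the observed 0.69–0.76 range.

What the generator does **not** emulate: read-level sequencing artifacts
(mapping bias, positional coverage trends, GC effects), recombination
linkage between array SNPs (each SNP segregates marginally correctly but
independently), population structure among the founders, partial-gene
deletions (deletions silence whole genes, which is why detection power on
synthetic deletions sits at its ceiling), genotype × environment
interaction, and the field-trial adjustment that produces entry means.
Passing tests therefore demonstrate correctness of the procedures under
the stated model, not performance on real data.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of every
experiment: panels of 120–300 genes, 150–600 array SNPs, 150–300 sequence
variants, 45 populations of 60 progeny, cross-validation with 10–200
replicates and permutation tests with 99 permutations over a few hundred
null simulations. These sizes were chosen so the full pipeline, including
the 66-point grid search, completes in minutes on a single CPU while
leaving the Monte-Carlo checks enough resolution for their stated
tolerances.

## Known limitations

- The Q90 category boundaries sit close to the expected missing proportion
  of a one-parent deletion (0.53 for F5), so binomial noise in small
  populations occasionally misclassifies a population; parental calls are
  correspondingly left undetermined or (rarely, ~0.5%) wrong. This is a
  property of the method, not of the implementation.
- α* depends directly on the silenced fraction in the generator; its
  synthetic value is not comparable to any particular empirical estimate.
- Mean imputation of variant and ePAV matrices shrinks LD estimates for
  high-missingness variants.
- REML on 23 inbreds estimates λ with large sampling variance; accuracy
  medians are nevertheless stable because prediction is insensitive to
  moderate mis-estimation of λ.
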