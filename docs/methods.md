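# Methods

This note records the models and procedures `mirnaome` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Study design

The pipeline targets a 2 × 5 pooled design: one small-RNA library per
(breed, stage) cell, breeds TC and YK, stages 40/55/63/70/90 days post
coitum. There are no within-cell replicates; each library represents an
equal-quantity RNA pool, so all inference is the pooled-count kind (the
exact test below), not replicate-aware dispersion modelling.

## Tag annotation

Inputs are collapsed tags: unique uppercase sequences with occurrence
counts (`id_x<count>` FASTA headers). Preprocessing drops tags shorter
than 18 nt or containing non-ACGT characters; adaptor trimming and quality
filtering are assumed already done upstream.

Mapping is exact full-length matching on both strands, implemented as an
18-mer seed index plus verification. Exact matching (rather than a
mismatch-tolerant aligner) keeps every downstream statement deterministic
and oracle-testable; the cost is that sequencing errors would unmap tags,
which the generator does not simulate (see Limitations).

Each mapped tag receives exactly one category, the highest-priority one
over all its hits:
`rRNAetc_genbank > rRNAetc_rfam > known_miRNA > repeat > exon > intron`,
else `unann`. The miRNA category is strand-specific; the other categories
match on either strand because rRNA/repeat annotations are commonly
unstranded. Multi-mapping tags are annotated once, by their best hit.

Known-miRNA quantification accrues a tag to a mature locus when a hit lies
on the mature strand with both ends within ±2 nt (the isomiR tolerance;
configurable). Ties across matures are broken by the smallest total end
offset, then lexicographic id, so a tag's count is never double-counted.

## TPM and the analysis universe

`TPM = count / N × 10⁶` with `N` the library's total clean reads (not the
miRNA-mapped total). Zero cells are revised to 0.01 **after**
normalisation, so log-ratios are finite; the revision value is a floor
well below any observable expression (one read at the default depth is
20 TPM). The analysis universe keeps miRNAs strictly above 28 TPM in at
least one library; the threshold is applied after the revision (immaterial
at 28, since 0.01 < 28).

## Exact count test and the DE screen

For counts x (library 1, N₁ reads) and y (library 2, N₂ reads) of one tag,
the second count conditional on the first under equal concentration is

    p(y | x) = (N₂/N₁)^y (x+y)! / (x! y!) (1 + N₂/N₁)^−(x+y+1)

computed in log space via log-gamma. Algebraically this is the negative
binomial NB(x+1, N₁/(N₁+N₂)) mass, an identity the test-suite uses as an
independent cross-check. Tails: `p_lower = Σ_{y≤y_obs} p(y|x)`;
`p_upper = 1 − Σ_{y<y_obs} p(y|x)` (complement form, no infinite sum).
When the complement underflows below 1e−8 the upper tail is recomputed by
direct forward summation, so p-values never collapse to exactly zero.
The two-sided p is the doubled minimum tail capped at 1 (sidedness is a
convention choice; both tails are always reported so either convention can
be audited). No multiple-testing correction is applied in the screen: the
DE criteria are fold change > 2 (strict, computed on revised TPM) **and**
two-sided P < 0.05 (strict).

Breed-DE runs the five same-stage comparisons; stage-DE runs the four
neighbour-stage comparisons per breed. When only a TPM table is available,
counts are recovered as `round(TPM · N / 10⁶)`.

## Ordination

PCA and average-linkage HCA operate on the row-wise Z-scored (mean 0,
sample SD 1) filtered TPM matrix, libraries as observations. PCA component
signs are fixed so each component's largest-magnitude loading is positive;
HCA uses 1 − Pearson correlation between library columns, with columns
processed in lexicographic id order to fix merge tie-breaks. Constant rows
carry no information and are dropped with a warning.

## Model-profile clustering

Candidate profiles over T stages start at 0 and step by {−c, 0, +c}
(c = 1), giving 3^(T−1) = 81 candidates at T = 5. Selection keeps m = 20
maximally distinct profiles greedily: seed with the largest absolute total
change (lexicographic tie-break — the monotone decline, profile 0), then
repeatedly add the candidate with the largest minimum 1 − correlation
distance to the selected set. The flat profile has undefined correlation;
its distance is defined as 1 and constant trajectories are assigned to it
directly. Trajectories are `log2(TPM_t / TPM_first)` on revised TPM (the
standard transform for this profile method when data are not already
zero-anchored) and each miRNA joins its maximum-correlation profile (ties
to the lower profile id).

Significance: the expected count of each profile is the mean assignment
count over **all** 5! = 120 permutations of the stage labels (exact
enumeration — no sampling randomness at T = 5); the p-value is the
binomial tail P(X ≥ observed) with n = number of miRNAs and
p = expected / n, Bonferroni-corrected across the m profiles, significant
at corrected p < 0.05. Profiles are computed per breed on that breed's
five libraries.

## Novel hairpin candidates

Unannotated mapped tags are evaluated for precursor-like structure in a
±100 nt window. Folding maximises the number of canonical pairs (A:U,
G:C, G:U wobble; minimum loop 3) by dynamic programming; among the many
co-optimal structures the DP breaks ties by stacked-pair count, so long
uninterrupted helices are preferred without ever sacrificing a pair (each
pair scores 1024, a stack scores 1 — the stacking bonus cannot reach one
pair's worth on windows under 2 kb, so brute-force enumeration of the
maximum pair count remains a valid oracle for the DP).

A candidate is accepted when the tag lies on one arm of a stem: the pairs
joining tag bases to partners on a single side must form a compact nested
helix chain — consecutive chain pairs separated by at most 6 nt on either
strand (the bulge/internal-loop tolerance of a single helix) — with at
least 16 of the tag's bases paired and the innermost pair spanning a loop
of 3–50 nt. Because maximum-pairing optima are degenerate, flank sequence
can "steal" tag bases from a genuine stem; the caller therefore also folds
the one-sided subwindows (same 16-base bar) and precursor-scale scan
windows of 60 and 80 nt anchored at the tag. The scan windows remove
far-flank interference entirely but are deliberately permissive contexts,
so they must clear a stricter 19-base bar. All thresholds are reported
with every candidate and configurable.

Calibration of this caller on synthetic data: 300/300 planted hairpins
recovered across 30 generator seeds; on pure-random windows the acceptance
(false-positive) rate is ≈ 11%. Base-pair maximisation is a deliberately
simple stand-in for thermodynamic folding — it has no energy model, so its
specificity on real genomes would be materially worse than an MFE-based
caller, and candidates should be treated as a screen, not calls.

## Network and enrichment

Pairing is three conjunctive filters, so their order is immaterial:
(1) miRNA breed-DE at ≥ 1 stage, pair predicted (external target table or
the built-in 7-mer seed-match stand-in: reverse complement of miRNA
positions 2–8 found in the 3′UTR), and Spearman ρ < −0.5 between the
5-stage trajectories in TC and/or YK; (2) mRNA breed-DE; (3) edges of a
bipartite graph with hubs at degree ≥ 5 (inclusive). The printed pairing
threshold is implemented on the negative side (ρ < −0.5) because the
procedure is defined by negative co-trends; the threshold and sign are
flags. Spearman uses average ranks; constant trajectories have undefined ρ
and the pair is excluded. Exports: SIF and GraphML.

Term overrepresentation is the one-sided binomial tail
P(X ≥ k | n, q = term share of the universe), enriched at p < 0.05; the
universe defaults to all annotated genes. The same machinery serves both
generic term tables and pathway-style annotations.

## Synthetic-data generator

The generator's defaults are the study conditions of the tests:
2 chromosomes × 100 kb, 150 known miRNAs (every 10th flagged as the
other-mammal catalog category), 10 novel hairpins, 20 contaminant features
per non-miRNA category, ~50,000 tags/library with a 30% contaminant share
(so ~70% of reads annotate as miRNA, a realistic composition for muscle
small-RNA libraries), 30 declining miRNAs (geometric decay, factor
0.42–0.48 per stage), 3 breed-DE miRNAs per stage at fold 4, 300 mRNAs,
20 planted regulatory pairs (the first DE miRNA carries six targets, a
designed hub) and 40 decoys. Planted hairpins are inverted repeats: 25 nt
arms at ≥ 90% complementarity (two substitutions), 8–20 nt loops, mature
tag on the 5′ arm. Known-miRNA tags are emitted as the mature sequence
(70% of the mean) plus a 3′ +1 isomiR (30%).

Counts are deterministic by default (rounded means), so every planted
effect is exactly recoverable and the end-to-end tests are sharp; Poisson
and negative-binomial modes (variance m + φm²; φ → 0 recovers Poisson)
exist for calibration and power studies, and φ is a free parameter because
a pooled library's biological dispersion is not identified by this design.
Planted-pair mRNAs follow K/x of their miRNA's mean trajectory, making the
noise-free Spearman ρ exactly −1; decoy mRNAs draw i.i.d. stage effects,
so decoy ρ follows the exchangeable permutation null (at 5 points,
P(|ρ| ≥ 0.5) = 42/120 — small-sample rank correlations are weakly
informative, which is why the pairing rule needs the DE and prediction
filters as well). Decoys are constructed to fail at least one conjunctive
filter, so the noise-free network recovers exactly the planted qualifying
pairs.

What passing these tests does **not** show: robustness to sequencing
error, adaptor remnants, cross-mapping between paralogous miRNA families,
unmodelled per-fetus biological variance within pools, or the specificity
of hairpin calling on repeat-rich real genomes.

## Numerical and problem-size choices

All randomness flows through one seeded generator; identical configs give
byte-identical output files. Simulations in the test-suite use 10,000
pairs for null calibration and 1,000 for power (Monte-Carlo SE ≈ 0.2% and
1% respectively); the end-to-end study runs in seconds at the default
scale. Coordinates are 0-based half-open everywhere; BED in, BED out.
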