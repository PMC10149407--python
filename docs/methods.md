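# Methods

This note documents the models, estimators and numerical choices behind
`chapvar`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where several reasonable options existed.

## Study design and terminology

The pipeline targets a *strains × {treated, untreated} × replicates* bulk
RNA-seq design in which "treated" means growth under a chaperone (Hsp90)
inhibitor. A gene is *buffered* when inhibiting the chaperone reveals
between-strain expression divergence, and *potentiated* when divergence
visible under normal growth shrinks on inhibition. A TF's *regulon* is the
set of genes carrying a conserved predicted binding site for it.

## Differential expression

Counts are raw integers (fractional estimated counts are rejected rather
than rounded). Gene filtering removes genes whose count is below
`min_count = 5` in **every** sample — a gene observed well in even one
sample is kept. The literal alternative (drop a gene when *any* sample is
below threshold) is exposed as `filter_mode="min"` but discards most of a
realistic matrix. Genes with missing values are always removed.

Normalization is median-of-ratios: each sample's size factor is the median,
over genes expressed in all samples, of its count over the gene's geometric
mean. Scaling one column by *c* scales its factor by *c* relative to the
others; because the geometric means absorb a small common factor, the
invariance of fold changes is exact only up to the pseudocount's response to
that common rescaling (tested with tolerance 0.1 on log2 FC, dominated by
near-zero-count genes).

The test is a deliberately simple negative-binomial Wald test, not a DESeq2
re-implementation (no dispersion shrinkage, independent filtering or outlier
replacement; numerical equality with DESeq2 is not promised):

* per-condition normalized means with pseudocount ½;
  log2 FC = log2(m̄_trt + ½) − log2(m̄_unt + ½);
* NB variance model var = μ + αμ². The default dispersion estimate is a
  **bias-corrected pooled regression of moments**: α̂ = Σ(v − m̄) / Σ(m̄² − v/n)
  over all genes and both conditions, floored at 0.01. The naive median of
  gene-wise moment estimates is biased low at n = 3 replicates (≈ 0.038 when
  the truth is 0.05), which inflates the type-I rate to ≈ 0.077; the
  corrected pooled estimator recovers α ≈ 0.050 and holds the empirical
  level at ≈ 0.051–0.054. Gene-wise estimation remains available
  (`dispersion_mode="genewise"`) for data with strong dispersion
  heterogeneity;
* delta-method variance of the log2 FC, standard-normal reference,
  Benjamini–Hochberg adjustment across genes. DE call: adj. p < `alpha`
  **and** FC > `fc_cutoff` or < 1/`fc_cutoff` (defaults 0.05 and 2; 1.5 and
  2.5 are the conventional sensitivity settings and `sweep_fc_cutoffs`
  automates the comparison).

Gene-level BH and TF-level Bonferroni are deliberately distinct: the gene
screen tolerates a false-discovery *rate*, while the TF cascade controls
family-wise error, and the two families are never mixed.

### Pair classification

FC ratios are linear (same pseudocount as the log2 FC), so
`ratio_cutoff = 2` means FC_A/FC_B > 2 or < 0.5. By default only genes DE in
at least one strain of the pair are eligible (`require_de_for_pairs`),
since pair-specific genes are meant to refine the DE sets; the flag exists
because the definition is also coherent over all analysed genes. Buffered
vs potentiated compares D⁺ = |log2(m̄_A,trt + ½) − log2(m̄_B,trt + ½)| with
the analogous untreated D⁻; exact equality is reported as `tie`.

## Binding-site prediction and conservation

Promoters are the `promoter_len = 500` bases immediately 5′ of the
translation start on the coding strand (reverse-complemented for −-strand
genes); shorter upstream regions are returned truncated and flagged. A PWM
is a 4 × L matrix of per-position log-likelihoods with a per-TF score
cutoff. A window's score is the sum of the log-likelihoods of its bases;
calls use **strict** inequality (score > cutoff), windows containing N are
skipped, and both strands are scanned (the reverse strand by scoring the
reverse-complemented matrix at the same coding-strand coordinates).
Reported offsets are 1-based distances from the translation start to the
hit base nearest it — the convention in which a site is "273 bp upstream".
The batch scanner one-hot encodes all windows and scores every PWM/strand
with one matrix product; each float32 screen is confirmed in float64 before
a hit is emitted so cutoff ties behave exactly like the scalar path (an
exhaustive-enumeration oracle checks equality in the tests).

Cross-strain comparison aligns orthologous promoters with a center-star
multiple alignment built from pairwise Needleman–Wunsch (match +1, mismatch
−1, gap −2; biopython's `PairwiseAligner` computes the pairwise steps): the
center is the strain minimizing the summed pairwise distance, and pairwise
alignments merge under "once a gap, always a gap". Hits of one TF whose
alignment **columns** (gaps counted — the only reading consistent with
measuring the window on an alignment) differ by ≤ `conservation_window = 20`
are grouped greedily left to right, one hit per strain per group, nearest
column first with ties to the higher score; every hit belongs to exactly
one group. A group with a hit in every strain is *conserved* (identical
site sequence in coding orientation) or *conserved with variation*; any
missing strain makes it *non-conserved*. Target sets include conserved and
(by default) conserved-with-variation sites — `include_variant_motifs=False`
restricts to strictly conserved ones — intersected with the genes that
survive count filtering. How overlapping same-TF hits should be de-duplicated
is underdetermined; the greedy grouping makes the choice explicit and
deterministic.

## TF-inference cascade

* **Exclusion:** a TF with fewer than `min_targets = 3` targets in *any*
  strain is excluded from testing.
* **Screen:** Kruskal–Wallis on the per-strain lists of target log2 FCs,
  Bonferroni across tested TFs; candidates pass at adj. p < 0.05. Log2 FC
  (not linear FC) is used for symmetry of up- and down-regulation; the
  rank tests are invariant to that monotone choice within a strain.
* **Localization:** two-sided Wilcoxon rank-sum per strain pair for every
  candidate, Bonferroni over **all** (candidate, pair) tests performed (a
  per-TF family is a config alternative).
* **Enrichment:** per candidate and pair, a one-sided pooled two-proportion
  z test of "fraction of targets that are pair-specific > fraction among all
  analysed genes", with continuity correction on by default (mirroring R's
  `prop.test`), Bonferroni over (candidate, pair); enrichment in at least
  one pair makes the TF high-confidence. Targets here are genes targeted in
  both strains of the pair; the universe is all genes surviving the filter.
* **Labels:** per (TF, pair), 0 when the TF's KW adj. p ≥ 0.05, 1 when KW
  passes but the pair's Wilcoxon adj. p does not, 2 when both pass. Label
  rows are clustered with complete linkage on Euclidean distances; the
  agglomeration is implemented in-package with a deterministic
  smallest-index tie-break (scipy's linkage is the test oracle).
* **Client enrichment:** hypergeometric upper tail for the overlap between
  candidates and a supplied chaperone-client TF list. The default is the
  strict tail P(X > k) — the convention of R's upper-tail `phyper`, under
  which the published 7/21-vs-23/187 contingency gives p = 0.0011; the
  inclusive tail P(X ≥ k) (= 0.0063 for the same counts) is available via
  `include_observed=True`. `hypergeometric_ge` itself is always the
  inclusive tail.
* **GO:** per-term hypergeometric over-representation, Bonferroni over terms
  present in the universe, significant at adj. p < 0.05.

Shared targets of paralogous TFs are *not* de-duplicated: each TF is tested
on its own target set, so paralogs with overlapping regulons can both be
nominated and attribution between them is beyond the method's resolution.

Exact Wilcoxon p-values are computed by enumeration when the combined sample
size is ≤ 12 with no ties (cheap: ≤ 924 arrangements) and by the
tie-corrected, continuity-corrected normal approximation otherwise; fully
tied data returns p = 1 for both rank tests rather than dividing by a zero
tie-correction factor.

## Distance trees

TN93 distances separate the two transition classes (A↔G, C↔T) from
transversions with base frequencies averaged over each pair at the sites
both sequences resolve (pairwise deletion of gaps/N). Saturation (a
non-positive logarithm argument) raises an error naming the pair instead of
returning infinity. Expression distances are Euclidean on replicate-mean
TPM vectors divided by 1000 (TPM: length-normalized rates scaled to sum 10⁶
per sample). Trees are built with BIONJ — neighbor joining with a variance
matrix (initialized to the distances) and reduction weight
λ = ½ + Σ_k(V_jk − V_ik)/(2(r−2)V_ij), clamped to [0, 1] — which is exact on
additive matrices. Negative branch lengths are clamped to zero with the
deficit moved to the sibling branch, preserving leaf-to-leaf path lengths.
Matrices are compared by Spearman correlation of strictly-lower-triangle
entries paired by label.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the emulated design: 5 strains × 2 conditions × 3
biological replicates, 2000 genes, 20 TFs × 30 targets, 5 planted responsive
(TF, strain) pairs at log2 effect 1.5. Parameters chosen once as realistic
for diverged yeast isolates: `snp_rate` 0.005/bp (isolates differing by
~50–85k SNPs over a ~12 Mb genome), `motif_len` 12 (yeast TFBS run ~5–15 bp),
motif variant and loss rates 0.02 each (so ~96% of planted sites stay
strictly conserved), count means log-normal (log-mean ln 100, log-sd 1.2),
shared NB dispersion α = 0.05, library-size factors log-normal (sd 0.15).

Strains are related by a random strain tree (mean root-to-leaf depth 1).
Background substitutions and per-gene baseline log2-expression offsets
(Brownian, sd 0.25 per unit branch length) both accumulate along its
branches, giving genetic and untreated-expression distances a shared
phylogenetic signal — on default runs their Spearman correlation is ≈ 0.85,
and it drops sharply for the treated condition where planted strain-specific
effects dominate. Treatment effects are planted multiplicatively on treated
means only. Regulons are disjoint gene sets so ground-truth attribution is
unambiguous (the inference code itself never assumes this). PWMs are sharp
consensus matrices (85% vs 5% base probabilities against a uniform
background) whose cutoff admits the consensus and any single substitution
and rejects two or more; variant events apply one substitution, loss events
re-draw the site until it scores below cutoff on both strands.

Idealizations a user should keep in mind when transferring conclusions to
real data: planted motif footprints are shielded from background SNPs, so
conservation classes are exact by construction rather than probabilistic;
there are no indels (promoter alignments of real strains gap); dispersion is
shared across genes; regulons neither overlap nor interact; promoters are
i.i.d. uniform sequence rather than yeast-like in composition. Passing
recovery tests therefore demonstrates the cascade's correctness and error
control under its own model, not performance on real genomes.

One integer seed drives everything; the generator uses documented derived
streams (`[seed, 0]` genomes, `[seed, 1]` counts, `[seed, 2]` GO map,
`[seed, 3]` distance fixtures) so each stage is independently reproducible
bit for bit.

## Calibration experiments

`recovery_experiment` (default 20 fresh full-pipeline simulations of the
default design) pools true/false positives of the high-confidence list
against the planted TFs; precision and recall are ≥ 0.8 by design target
and 1.0 in practice at the default effect size. `null_calibration`
(default 200 seeds) simulates the genome/motif stage once with no planted
effects and redraws only the count matrix per seed — count noise is the
stochastic layer that produces false positives, so conditioning on one
genome measures the cascade's family-wise error where it matters while
keeping the experiment tractable; it also reports the raw DE type-I
fraction pooled over genes, strains and seeds (≈ 0.052). Problem sizes for
these drivers (20 and 200 seeds, default design) are the package's standard
calibration settings.

## Degenerate inputs and tie-breaks

Empty promoters are excluded from alignments and reported absent (their
strain then forces non-conserved groups); promoters shorter than a motif
yield an empty scan with a warning; all-zero count columns are rejected by
the size-factor step (no gene positive everywhere); `adjust` validates
p ∈ [0, 1]; distance matrices validate symmetry, zero diagonal and
finiteness on construction. All order-dependent steps (center choice in the
star alignment, hit grouping, agglomeration) break ties deterministically —
lexicographic or smallest-index — so reruns are bit-identical.
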