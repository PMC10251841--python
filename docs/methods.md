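# Methods

This note documents the models, parameter choices and numerical decisions
behind `chondroatac`, and what the synthetic-data tests do and do not show
about real data.

## Coordinate conventions

All intervals are 0-based, half-open (`[start, end)`), the BED convention,
everywhere internally and in every file format. A SNP at position `p` is
inside a peak iff `start <= p < end`; abutting intervals do not overlap.

## Replicate-consensus peaks

A per-replicate peak is retained when at least `min_replicates − 1` *other*
replicates each contain a peak whose overlap strictly exceeds
`threshold` (default 0.5) of **both** peak lengths. The reciprocal reading is
deliberate: it is the stricter, symmetric interpretation of "more than 50%
overlap in the two replicates". One boundary case is resolved in favour of
usability: an interval that is completely covered passes its side of the test
at any threshold, since otherwise even identical peaks would fail at
threshold 1.0; for thresholds below 1 this clause changes nothing.

Retained peaks overlapping by ≥1 bp are linked transitively (across and
within replicates) and each component is emitted as one consensus peak
spanning the outer bounds, so consensus intervals are pairwise disjoint.
Each replicate set is pre-merged first so "a peak" is well defined.
The construction is validated against an independent all-pairs brute-force
oracle with fixpoint union on random instances, and is invariant to
replicate order and within-replicate input order.

## Tn5 correction and the peak caller

Read 5′ ends are corrected +4 bp on the plus strand and −5 bp on the minus
strand. From a fragment record `(chrom, start, end)` the two insertion
events are `start + 4` and `(end − 1) − 5`; negative results are clamped
to zero with a warning.

The caller is a transparent shift/extend model: each corrected cut site
becomes a window `[pos + shift, pos + shift + extsize)` (defaults −100 and
200, i.e. a 200 bp window centred on the cut), clipped at chromosome
bounds. Per-base pileup is tested against a single genome-wide Poisson rate
λ = total pileup mass / genome length; there is no local background or
model building. The p-value at a position with pileup k is the Poisson
upper tail P(X ≥ k) = sf(k−1; λ). BH correction runs over covered
(pileup > 0) positions only, to avoid inflating the test count with empty
genome. Significant positions (q < 0.05) separated by gaps under 30 bp are
merged; merged regions shorter than `extsize` are discarded; the summit is
the leftmost pileup maximum. The 30 bp merge gap and the minimum-length rule
are conventional defaults, stated here because production callers do not
document their internal equivalents. Pileup mass is conserved exactly
(Σ pileup = Σ clipped window lengths), which the tests assert.

With a single global λ the caller over-extends peak flanks by up to ~100 bp
(the window half-width); on the planted-recovery construction (10×-enriched
3 kb region among 50,000 cuts on 100 kb) this still leaves bp-level recall
and precision above 0.9 in every tested seed.

## Fragment-ladder periodicity

The length histogram, restricted to the observed length range, is
mean-centred and autocorrelated over lags 100–300 bp; the argmax lag is the
period. Restricting to the observed range matters: zero padding outside the
range correlates with itself and manufactures spurious strength. The
distribution is flagged aperiodic when the best normalised autocorrelation
falls below 0.2 — a flat length distribution tops out near 0.10 by chance
(maximum over ~200 lags of noise with σ ≈ N_bins^−1/2) while a true
200/400/600 ladder exceeds 0.3, so 0.2 separates the two regimes with
margin. In the pipeline QC the period is computed on fragments ≥ 100 bp:
the sub-100 bp nucleosome-free mode is not part of the nucleosome ladder,
and its ~140 bp spacing to the mono-nucleosome mode otherwise dominates the
autocorrelation.

## TSS enrichment

Cut counts are accumulated strand-orientedly in ±2000 bp of each TSS; the
score is the mean per-base density in the central ±100 bp divided by the
mean density in the two outermost 100 bp tails. Zero tail density yields an
infinite score with a warning rather than an error, since it is a legitimate
(if degenerate) outcome on tiny inputs.

## Annotation priority

Feature tracks per gene: promoter = TSS ± 3000 bp (strand-aware; TSS is the
leftmost coordinate of + genes and the rightmost of − genes); 5′/3′ UTRs are
exonic sequence outside the CDS, swapped by strand; exon means coding exon
bodies (full exons for non-coding genes); intron is the gene span minus
exons; downstream extends 3000 bp past the 3′ end. A peak is assigned the
highest-priority category it overlaps by ≥1 bp, in the order promoter >
5′UTR > 3′UTR > exon > intron > downstream, defaulting to distal intergenic.
Downstream and distal intergenic are placed after intron, matching the
promoter-first annotator convention; ≥1 bp overlap (rather than a midpoint
rule) is used because a peak genuinely spanning several elements should be
claimed by the highest-priority one it touches. The nearest gene minimises
|peak midpoint − TSS| with lexicographic gene-id tie-break; signed distance
is negative upstream in gene orientation. Assignment is validated against a
per-base oracle that applies the priority to every covered base.

Summaries always report all seven categories and sum to 100% within 0.01.

## Over-representation (ORA)

For a universe of N genes, a term with K members and a query of n genes with
k hits, p = P(X ≥ k) under the hypergeometric distribution, BH-adjusted
across terms, significance flagged at adjusted p ≤ 0.01. The test is generic
over user-supplied term maps; no ontology snapshot ships with the package
because term-level results are database-version-dependent.

## GWAS-SNP permutation enrichment

The observed statistic is the in-peak proportion of the candidate SNPs
(presence/absence). The null re-draws `|candidates|` SNPs from the full
panel without replacement `n_perm` times (default 10,000); fold is
observed / null mean and the one-tailed empirical p uses the add-one
correction p = (1 + #{null ≥ obs}) / (1 + n_perm), so p ∈ (0, 1]. Draws are
size-matched to the candidate count in every permutation — a mixture of
random sample sizes would make the fold's null ill-defined.

Implementation note: for the presence/absence statistic, the in-peak count
of a uniform without-replacement draw of k SNPs from a panel with m in-peak
members is exactly hypergeometric(m, N−m, k), so null counts are sampled
from that distribution directly; this is distributionally identical to
materialising each index sample and keeps a 10,000-permutation run at
microseconds. With-replacement sampling (binomial null) and an
effect-weighted statistic (mean |effect| of in-peak SNPs, explicit index
draws) are available behind flags; the effect-weighted variant makes no
equivalence claim to any published pipeline. Candidates are part of the
panel, so their in-peak excess slightly inflates the null mean; the bias is
proportional to the candidate share of the panel (~1% at the default
construction) and shrinks as the panel grows. Inputs must share one
coordinate system; no liftover is provided.

## Motif scanning and footprints

PWMs are position probability matrices (rows sum to 1, length ≥ 4) with a
pseudocount applied before log2-odds scoring against a uniform background
(configurable). Both strands are scanned; N-containing windows are skipped;
minus-strand hits are reported at their forward window start. Motif
enrichment counts sequences with ≥1 hit in targets vs backgrounds and
applies a one-tailed hypergeometric test per motif with BH across motifs.

Footprint profiles sum cut counts in ±100 bp of each motif centre,
reversing minus-strand sites before aggregation, giving a 201-long profile.
The centre region is the motif span; the flanks are the outermost 20 bp on
each side (so the "200 bp genome range" is split into a protected core and
unprotected shoulders). `depth_score = mean(flank) / max(mean(centre), 1)`;
the floor avoids division by zero at fully protected sites. Classification:
`indeterminate` below 50 sites; `active` requires depth ≥ 1.5 **and** that
the global minimum of the 5 bp moving-average profile (computed on valid
positions only — `same`-mode smoothing would bias the edges low) falls
inside the motif span; otherwise `inactive`. The smoothness clause is what
distinguishes a genuine protected core from a "disordered" curve whose
depth comes from incidental flank pileup. This transparent depth-plus-shape
criterion deliberately replaces HMM-based footprinters; Tn5 sequence-bias
correction is out of scope, so absolute depths on real data will differ
from the synthetic calibration.

Expression cross-check: a TF is expressed when its gene's mean TPM strictly
exceeds 2; active+expressed and inactive+silent are concordant; TFs missing
from the TF→gene map are flagged unmapped, never dropped.

## Expression

TPM per sample: rate_g = count_g / (length_g / 1000), TPM_g = rate_g / Σrate
× 10⁶, so each column sums to one million (asserted to 10⁻³). An all-zero
sample stays zero and is flagged. Expressed genes have mean TPM strictly
greater than the threshold (default 2; a gene at exactly 2 is excluded).
Replicate correlation is Pearson on log2(TPM+1) — the conventional QC scale;
raw-scale correlation is a flag away. When gene lengths are absent the sum
of exon lengths from the gene model is used.

## Synthetic-data generators

The generators emulate the structure of a three-replicate ATAC + RNA study
at desk scale and always return ground truth alongside observables. All
randomness flows through numpy generators seeded as `[seed, stream]` with a
fixed stream constant per generator, so outputs are byte-identical under a
fixed config regardless of call order.

Defaults (the study design the tests run under):

* genome: 3 chromosomes × 1 Mb, 100 genes (lognormal lengths around 8 kb,
  1–5 exons, 90% coding), placed by random gap allocation, which succeeds
  at any feasible packing density;
* 200 true peaks, mean length 572 bp (normal, σ = 20% of the mean);
  45.61% of them centred inside TSS ± 3 kb promoter windows and the rest
  placed clear of all promoter windows, so the promoter fraction is
  controlled exactly;
* replicate dropout 0.1 with independent ±10%-of-length boundary jitter on
  each end — jitter keeps same-peak replicates above 50% reciprocal overlap
  with high probability, exercising the consensus rule near its threshold;
* fragment mixture (0.45, 0.35, 0.15, 0.05) over the sub-100/200/400/600 bp
  ladder components, 50,000 fragments per replicate, in-peak cut density
  10× background (exactly, by placing the left cut in peak vs non-peak bp
  with the corresponding odds), plus a 10% fragment fraction concentrated
  at TSSs (normal, σ 200 bp);
* SNPs: 10,000 background (uniform, U(0,1) p-values) plus 500 candidates at
  2.32× in-peak density (U(0, 0.01) p-values); the fold caps at an in-peak
  proportion of 1 with a warning;
* footprints: 500 motif sites inside peaks with *non-overlapping* ±100 bp
  windows (overlapping windows would leak one site's flank cuts into
  another's centre and dilute the constructed depletion), Poisson 1
  cut/bp/site, bound fraction 0.8, centre rate × 0.5 at bound sites;
* counts: negative binomial with dispersion (shape) 0.5 around per-gene
  means shared across 3 replicates; 30% of genes get target TPM in
  (0.05, 1) and the rest a lognormal target, with targets normalised to sum
  to 10⁶ so realised TPM tracks the construction. The dispersion is
  calibrated so mean pairwise log-TPM replicate correlation sits near the
  0.8 typical of good replicates.

What the generators do **not** emulate: sequence composition (no Tn5
sequence bias, no real motif backgrounds — motif-enrichment sequences are
i.i.d. random DNA with planted consensus sites), linkage disequilibrium
between SNPs, chromatin-state correlation between neighbouring peaks, and
library-level artefacts (duplicates, mitochondrial reads). Passing tests
therefore demonstrate correctness of the statistical machinery under its
stated model, not robustness to those real-data complications.

## Pipeline and determinism

`run_pipeline` executes simulate → QC → per-replicate peak calling →
consensus → annotation → ORA → GWAS enrichment → motif/footprint →
expression, writing every intermediate as a plain-text file and a JSON
report containing only seed-determined quantities (timings go to the
logger), so identical seed + config reproduces the report byte for byte.
Stage failures abort with the stage name; partial outputs are retained.
The demo footprint stage simulates the CCAAT-box TF as bound and the
AP-1-like TF as unbound, and maps them to an expressed and a silent gene
respectively, so the expression cross-check is concordant by construction.

## Problem sizes

The shipped configurations are desk-scale by design: 3 Mb genomes, tens of
thousands of cuts and SNPs, hundreds of peaks. The recovery constructions
(fold-3 GWAS enrichment with a 2,020,000-SNP panel; 10× planted peak at
50,000 cuts; 500-site footprints) were chosen so that sampling error is
several times smaller than the tested tolerance bands. All sizes scale up
linearly through `SimulationConfig`.
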