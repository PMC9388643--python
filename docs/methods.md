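# Methods

This note documents the models and procedures implemented in
`strictlnc`, the defaults that matter, what the synthetic data does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Coordinates and models

All interval arithmetic is 0-based half-open; GTF's 1-based closed
convention is converted at the file boundary only. Strand is `+`, `-`
or `.` (unknown orientation — transcripts assembled purely from
unstranded single-end libraries). Bookended exons are merged on read;
exons that overlap within one transcript are rejected, which keeps the
invariant set (sorted, disjoint, single chrom/strand) checkable
everywhere downstream.

## The strict identification cascade

Ten steps run for *every* transcript — the cascade never short-circuits,
so the trail is a complete per-filter audit log and per-step removal
counts can be reported; survival is unaffected because the final status
only asks whether an unrescued fail exists anywhere.

| step | rule (fail condition) | default |
|---|---|---|
| 1 | chrom not allowed, or length < min | 200 nt, all chroms allowed |
| 2 | blastp hit, e-value ≤ cutoff (inclusive) | 1e−6 |
| 3 | blastx hit on plus subject strand, e-value ≤ cutoff | 1e−6 |
| 4 | protein-domain hit, e-value ≤ cutoff | 1e−6 |
| 5 | signal-peptide D-score ≥ cutoff | 0.45 |
| 6 | longest ATG-initiated ORF > limit (strict) | 100 aa |
| 7 | nr best hit (lowest e-value, ties by identity) with identity ≥ 70% and an *informative* description; an uninformative description **rescues** | keywords: hypothetical protein, similar to, putative protein, unknown, predicted protein, unnamed protein product |
| 8 | tRNA/rRNA family hit, or plus-strand blastn hit against known ncRNAs at the same cutoff | — |
| 9 | any intron > limit (strict) | 6000 bp |
| 10 | curation denylist (allowlist force-retains) | empty |

Semantics worth stating explicitly:

* **Rescue scope.** A step-7 rescue clears fails at the protein-homology
  steps (2, 3, 4 and 7 itself): the rescue expresses the judgment that
  similarity to an uncharacterized protein is not evidence of coding
  potential, and that judgment applies to whichever database produced
  the similarity. It never clears length, signal-peptide, ORF-size,
  ncRNA-family or intron-size fails, which are intrinsic properties of
  the transcript rather than homology calls.
* **ORF semantics.** The longest ATG-initiated ORF over the three
  forward frames, requiring an in-frame stop by default; ties go to the
  5′-most start; N-containing codons are neither start nor stop and
  translate to X. blastp-style evidence is assumed to derive from the
  longest ORF only (a flag exists to change nothing else about the
  pipeline if callers score all ORFs externally).
* **Signal peptide.** D ≥ 0.45 predicts a signal peptide and removes the
  transcript (the standard direction for that score).
* **Manual curation** is replaced by machine-readable allow/deny lists
  recorded in the trail as a tenth step, preserving the mechanism
  without an unreproducible by-hand pass.

Coding-potential scores in [0, 1] are binned four ways:
≤ 0.1 high-confidence non-coding; ≤ 0.5 non-coding; < 0.9 coding;
≥ 0.9 high-confidence coding (the overlapping published definitions
refined into mutually exclusive bins).

## Positional biotypes

Overlap is measured between *exon base sets* (not genomic spans), per
reference gene, pooling all of the gene's isoforms; the fraction
threshold (default 0.1 of the lncRNA's exonic length) is inclusive.
`intronic` requires the whole transcript span inside a single intron of
at least one isoform with zero exon contact with that gene, on either
strand; `lincRNA` requires zero overlap with any gene base (exon or
intron, any strand). Labels accumulate over genes, so a transcript
flanked by a sense and an antisense gene is legitimately
NAT + sense-exonic. Two documented edge cases can leave the label set
empty: unknown-strand transcripts overlapping exons (the default policy
assigns no strand-dependent label; policy `both` assigns the pair), and
stranded transcripts overlapping a gene only sub-threshold. Gene-level
labels are the union over isoforms; the distinct-gene count equals the
per-label sum minus the per-gene excess (|labels| − 1).

Annotation-set comparison uses reciprocal 100% same-strand overlap —
identical spans at the default granularity, identical exon chains
optionally — with gene-level sharing meaning any isoform pair matches.

## Expression, confidence, specificity

TPM is the standard length-normalized rate scaled to 10⁶ per sample.
HC/LC confidence: HC iff TPM ≥ 3 in at least one sample (inclusive).
Stage bins are closed integer day ranges (3–5, 6–25, 26–29, 30–47,
48–51); ages outside every bin stay unbinned rather than clamped.

Tau uses group means of log₂(TPM+1) (the index's source convention; a
raw-TPM option exists and is echoed in output metadata). Genes silent in
every group get no Tau. The specificity cutoff is the *median Tau of the
supplied mRNA set*, recomputed per dataset — the published cutoff value
is cohort-dependent and hard-coding it would silently mis-calibrate
other data. The comparison is strict (τ > cutoff).

## Co-expression network

Counts are variance-stabilized with median-of-ratios size factors
followed by log₂(count/s + 1). This is a deliberate, simpler substitute
for a regularized variance-stabilizing transform; downstream
correlations are rank-robust to the difference, and the choice is
recorded in the config echo.

Biweight midcorrelation uses tuning constant 9 with weights
(1 − u²)²·1{|u| < 1}, u = (x − med)/(9·MAD), falling back to
Pearson-style weighting per vector when the MAD is zero; results are
clipped to [−1, 1]. Signed adjacency ((1 + cor)/2)^β with β = 12 by
default; `scale_free_fit` reports the signed R² of the log–log degree
fit over a β grid so users can re-derive β on their own data.
Topological overlap is the standard (ℓ + a)/(min(k) + 1 − a) form,
verified against brute force.

Module detection: average-linkage clustering of 1 − TOM with a static
height cut at 99% of the tallest merge, honoring a minimum module size
of 50; smaller clusters go to module 0 (the unassigned convention);
modules are *not* merged by eigengene similarity and are labeled by
decreasing size. A static cut was chosen over a full dynamic hybrid
cut because the desk-scale problems this package targets produce
well-separated dendrograms where the two agree; the cut height and
minimum size are configurable.

Eigengenes are the first right-singular vector of the per-gene z-scored
module matrix, sign-oriented to correlate positively with the module's
mean standardized profile; per-gene module membership (kME) is the
correlation of each member with its eigengene.

## Enrichment and guilt-by-association

One-sided upper-tail hypergeometric test per GO(BP) term present in the
module, over an annotated background (the analyzed coding genes by
default; a genome-wide file can be supplied instead). Classic Fisher
testing — no graph-decorrelation variants. BH correction is applied
within each module's term family (per-module testing matches per-module
reporting; a global family is available), significance at q < 0.01
strict. With discrete hypergeometric p-values BH is conservative: null
simulations show empirical FDR at or below the nominal 1%. lncRNAs
inherit their module's significant terms; module-0 lncRNAs inherit
nothing.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a large multi-tissue RNA-seq cohort. Scale
defaults were chosen once as a desk-scale study: 2 chromosomes × 800 kb,
400 coding genes, 34 planted lncRNAs across all biotypes (plus 4
rescuable), 12 contaminants cycling through the failure modes, 4
tRNA/rRNA mimics, boundary decoys at 199 nt / 6001-bp intron / 101-aa
ORF / e-value 1e−6 / D = 0.45 / identity 70; 6 tissues × 10 samples
spanning all five stage bins; 3 planted modules of 60 coding genes + 6
lncRNAs each.

* Counts are negative-binomial (dispersion 0.02) over log-normal
  expected expression — standard bulk noise, no GC/length bias, no batch
  structure, no isoform-level ambiguity.
* Module genes share a latent profile (a small tissue-level component,
  σ = 0.3, plus per-sample jitter) whose scale is set analytically from
  the target within-module correlation (default 0.8) and the gene-level
  noise (σ = 0.5): σ_f = σ_noise·√(r/(1−r)). Observed count-scale
  correlations land slightly below the target because counting noise
  adds variance — the Monte-Carlo check allows ±0.1.
* Tissue-specific genes have expected expression exactly zero outside
  their tissue, so their Tau is exactly 1. Half of the coding genes are
  planted specific, mirroring the near-half specific fraction seen in
  real cohorts; this also places the mRNA-median Tau cutoff in the gap
  between broadly expressed and specific genes, which is why specificity
  recovery on synthetic data is essentially perfect — real data, with a
  continuum of specificity, will sit closer to the cutoff.
* On/off tissue-specific genes are strongly mutually correlated by
  construction; per tissue they form blocks below the minimum module
  size (hence module 0), but they can attach to a planted module whose
  profile peaks in their tissue. This is a genuine co-expression signal,
  not a detection error; it is why whole-run module ARI is ~0.8 rather
  than 1 while the planted lncRNAs still land in their modules.
* Candidate sequences are extracted from the generated genome, so
  overlap-derived candidates (NAT/sense-exonic) genuinely contain coding
  fragments; free regions are re-drawn until the ORF filter passes,
  giving clean lncRNAs that pass for the right reason.
* Unknown orientation is applied to intronic candidates (default
  probability 0.15), emulating orientation-less single-end assemblies
  without breaking the planted-label agreement guarantee.
* GO coherence is planted as one term per module carried by 85% of the
  module's coding genes (2% background leakage).

Passing tests on this data therefore demonstrate correctness of the
*decision rules* at and around every threshold, and recoverability of
planted structure under standard noise — not robustness to alignment
artifacts, annotation errors or batch effects in real cohorts.

## Numerical choices

Percentages are rounded half-up at the printed precision. TPM columns
conserve 10⁶ to ~1e−9 relative. ORF ties break to the 5′-most start.
bicor results are clipped to [−1, 1] against floating-point spill.
Degenerate cases return missing values rather than guesses: Tau for
all-zero genes, bicor for doubly-degenerate vectors, scale-free R² for
equal-connectivity graphs. Everything stochastic flows from a single
seed through per-stage substreams, so stages can be re-run individually
while full runs stay byte-deterministic.
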