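# Methods

## Coordinate conventions

All internal intervals are 0-based half-open; GTF input (1-based inclusive)
is converted on read, and branch points (BPs) are 0-based single positions.
On the minus strand the 5′ splice site of an intron is `span.end − 1` and the
3′ splice site is `span.start`; window offsets and profile positions are
always transcript-oriented (negative = upstream), so minus-strand sequences
are reverse-complemented and reported 5′→3′ of the transcript.

## Intron universe

Isoform structure is deliberately discarded: per gene, the introns of all
transcripts are union-merged, and every position covered by an exon is
subtracted from the merged span into `kept_blocks`. The subtraction scope is
configurable (`mask_scope`): the default `gene` masks only the gene's own
exons (alternative isoforms); `strand` masks exons of every gene on the same
chromosome and strand, for annotations with overlapping genes. Intron
identifiers are ordinal along the direction of transcription
(`<gene>_intronN`), making rebuilds deterministic. Host-candidate introns
have a collapsed span of 100–10 000 bp; the length filter applies to the
span, not to the kept-block total, because masking is a measurement
correction, not a biological change of intron size. Sub-100 bp and very long
introns are still built (annotation artifacts such as 1-bp introns exist in
real gene sets) and removed downstream.

Host assignment returns the *shortest* intron fully containing the query
interval on the same strand; ties break on smaller start coordinate, then
lexicographic identifier, so results are independent of input order. A
separate flag records 5′ concordance (query 5′ end within 10 bp of the
intron's 5′SS), which defines the high-confidence subset without discarding
the rest.

## Junction clustering and classification

Junction calls carry a donor (5′SS) and an acceptor — the 3′-most
circularized base, which is the BP for a stable lariat and the 3′SS for an
intronic circle. Filters: mitochondrial calls, non-protein-coding host
genes, and circle lengths outside 30–10 000 bp are removed; calls with no
containing intron are removed and counted. Collapsing groups calls by
*exact* (host intron, donor) — the donor is splice-site anchored and
reliable, whereas the acceptor jitters with reverse-transcriptase errors —
and the representative end is the member with the most junction-spanning
reads. Tie-breaks, in order: more samples, smaller distance to the annotated
3′SS, leftmost. Clusters must be expressed (nonzero reads) in at least two
distinct samples.

Classification: a cluster is an intronic circle iff
`|representative_end − 3′SS| ≤ tol_3ss`, else a stable lariat. The default
`tol_3ss = 0` treats the max-read representative as defining; 1–2 is
appropriate for noisy callers, and recall of planted circles is monotone in
the tolerance (tested). A representative end outside the host intron span is
a caller inconsistency; such clusters are excluded with a report rather than
classified.

Cross-caller agreement matches clusters on (chrom, strand, donor,
representative end) within a coordinate tolerance and reports the fraction
supported by at least two callers.

## Branch points, tails, and sequence context

When both exist, the external BP map (experimentally mapped/statistically
inferred positions with support counts) and the caller-derived BP (the
representative end of a stable lariat) are kept side by side, not merged;
feature analyses default to the map. Multiple map BPs in one intron resolve
by max support, then proximity to the 3′SS, then leftmost. The 3′ tail is
the number of intronic bases strictly 3′ of the BP; tails ≤ 1 bp (or a BP
outside the span) are flagged as discarded — they are artifacts of truncated
intron annotations.

Sequence windows: 5′SS→+20, −20→3′SS, and BP ± 10 are the default anchors.
BP windows drop introns with a tail < 10 bp and mask in-window positions
within 10 nt of the 3′SS, so splice-site signal cannot leak into BP
summaries; positions outside the intron span or the chromosome are masked
('N'). Information content per offset is the Kullback–Leibler divergence
from a uniform background in bits, with `0·log 0 := 0`; a background with a
zero entry is rejected rather than smoothed. Motif scanning is exact
degenerate IUPAC matching on the given strand over 101-nt BP-centred
windows; all (possibly overlapping) occurrences are reported, matching the
default semantics of occurrence scanners, and hit offsets are relative to
the BP (negative = upstream).

## Tracks and profiles

Depth and conservation tracks are sparse per-position maps with different
missing-value semantics: an absent depth position is 0, an absent phyloP
position is *missing* and excluded from numerator and denominator — phyloP
is signed, so zero-filling would bias means toward neutrality. Depth from
aligned blocks excludes a read from an intron when one of its splice gaps
spans the whole intron (a linearly spliced read across the intron is
evidence for the mRNA, not the intron); remaining reads add +1 over covered
kept-block positions, and per-sample tracks are averaged position-wise (each
sample contributes its own mean first, so deep samples do not dominate).
Whole-intron means trim 10 bp at both span ends. BP-anchored profiles
additionally exclude positions within the 10-bp end trims and introns with
tails < 10 bp. Group contrasts use
`log2((mean_A + 1e-6)/(mean_B + 1e-6))` per offset; the "adjacent to the
BP" exceedance statistic is the fraction of offsets in ±50 (excluding 0,
the BP itself) with log FC strictly above 1. The ±50 window is a package
choice — it matches the 101-nt scanning window.

## Expression and enrichment

Counting is stranded with loose overlap: a read counts toward a feature if
any aligned base overlaps it on the same strand, and may count toward
multiple features — pre-mRNA reads partially overlapping an intron are
intentionally included, and no fractional assignment is attempted.
RPM = reads × 1e6 / library size (library size is the metadata's total
mapped reads, not a junction-read total); FPKM = reads × 1e9 / (length ×
library size). Relative intron expression is the intron/parent-gene FPKM
ratio with a 1e-6 pseudocount on both sides, making (0, 0) → 1 (no
evidence either way) and flagging retained introns at ratios > 1.

RNase-R enrichment includes a circular junction only when it has at least
`min_reads = 2` junction reads in both the treated and the control sample;
linear junctions are included only when their circular counterpart is, and a
"linear counterpart" is defined as the intron-skipping junction (splice gap
exactly matching the intron span) for determinism. Enrichment is a
treated/control RPM ratio strictly greater than 1 (a zero-control junction
is enriched at ratio +∞), and the junction-type × enrichment association is
a two-sided conditional Fisher exact test (sum of hypergeometric tables with
point probability ≤ observed) with the sample odds ratio ad/bc.

## Cohort statistics

Wilcoxon rank-sum p-values use exact enumeration for pooled n ≤ 12 without
ties and the tie-corrected, continuity-corrected normal approximation
otherwise; constant pooled values give p = 1. Differential expression tests
features whose total raw junction reads are *strictly above* 10 and that are
detected (nonzero) in at least 10 samples — the conjunction is the stricter
reading of the filter, and both thresholds are configurable.
Benjamini–Hochberg correction is applied within each class-pair family (not
globally), with q < 0.1 significant, and effect sizes are pseudocounted
log2 fold changes of class means. Survival analysis dichotomizes at the
median (strictly-greater = high group, so a median of 0 splits zero vs
nonzero expression), fits Kaplan–Meier curves per group, and compares them
with the two-group log-rank test; events are progressions and censored
patients contribute risk-set time only. Tissue summaries use the mean RPM
over a tissue's samples, a ≥ 2-read detection rule, the top ⌈0.1 n⌉
features' contribution to the tissue total, and the intronic-circle fraction
of detected features; fraction summaries report per cell line × fraction
totals, detected sets, nuclear∩cytoplasmic overlaps, and detected-feature
length quartiles (linear interpolation).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the analyses assume, fixed
up front:

| parameter | default | rationale |
|---|---|---|
| genes / introns per gene | 60 / Poisson(4) | desk-scale universe (~200 candidate introns) |
| intron length | log-normal, median 900 bp, σ = 0.5 | host introns are short (sub-kilobase medians) |
| host fractions | 22% lariat, 18% circle | 55/45 lariat/circle class split among hosts |
| 3′ tail | log-normal, median 33 bp | observed stable-lariat tail median |
| RT jitter | p(representative) = 0.8, geometric decay 0.5, ≤ 8 nt upstream | roughly a third of clusters show multiple 3′-end annotations |
| BP map | 85% coverage, 55% exact, geometric ± noise | median caller-map distance 0 with a dispersed tail |
| motif | `AYAUUAUUAAU`, 9.4% of lariat hosts, 6.2× lower in controls, lag N(−24, 8) | observed prevalence, enrichment, and upstream placement |
| conservation | background N(0.05, 0.3), +1.0 in BP ± 50 of lariat hosts | BP-region elevation ≥ 2× background |
| risk classes | 96 / 232 / 129 samples, library size log-normal median 2e7 | cohort class sizes |
| class effect | 2-fold in 10% of hosts (class 1 up) | planted differential expression |
| RNase-R ratios | log-normal: circular ×2.2, linear ×1/1.8, σ = 0.8 | ~80% circular and ~25% linear junctions enriched, odds ratio ≈ 12–15 |
| survival | baseline hazard 0.02/month, hazard ratio 2 for the low-expression group, ~30% censoring | expression–prognosis coupling |

Sequences are i.i.d. uniform nucleotides apart from planted GT…AG splice
dinucleotides, BP nucleotides (48% adenine in lariat hosts vs 66%
elsewhere), and planted motifs, so sequence-context code sees realistic
anchors but *no* genuine splicing grammar: polypyrimidine tracts, BP
consensus motifs, GC structure, repeats, and mappability artifacts are all
absent. Depth tracks derive from the count model rather than from simulated
reads, and junction counts are Poisson given the per-host rate (library-size
scaled) rather than arising from alignment. Passing recovery tests therefore
demonstrates that the *analysis logic* is correct under the stated noise
model — not that the pipeline is robust to alignment artifacts, caller
biases, or real sequence composition. Identical seeds give byte-identical
bundles; every draw comes from one `numpy` generator.

## Numerical and degenerate-input choices

Frequencies in positional profiles are normalized per offset over unmasked,
non-'N' sequences; offsets with no coverage report NaN bits and n = 0.
Spearman correlation is undefined (NaN) under zero rank variance. Fisher
tests with a zero margin return p = 1 and an undefined odds ratio. Log-rank
requires two nonempty groups; a degenerate cutoff raises with a suggestion
to choose another. The Wilcoxon normal approximation differs from full
enumeration by up to ~0.016 at pooled n = 12, which is why the exact branch
is used there. BH q-values are clipped at 1 and mapped back to input order.

## Known limitations

Only GTF (not GFF3) annotation is parsed; trans-spliced and single-exon
fusion transcripts are out of scope. Donor grouping is exact-position — a
caller with jittered 5′ ends would need pre-rounding. bigWig tracks must be
converted to bedGraph text (or read via pyBigWig upstream); track handling
is in-memory and sized for desk-scale analyses, not whole-genome
conservation maps. Cox regression and multivariable survival adjustment are
deliberately absent; risk-class labels are consumed, never derived.
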