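# Methods

This note records the models and conventions behind `seatlas`, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and interval arithmetic

All internal coordinates are 0-based, half-open (BED convention);
GFF3 (1-based, closed) is converted at the I/O boundary. Two
intervals merge when their gap (`start_next − end_prev`) is at most
`max_gap`; overlap or touching counts as gap ≤ 0. The clustering rule
"less than 50 bp apart" is therefore `max_gap = 49`. Distances across
chromosomes are a typed `None` sentinel, never a large number, so a
closest-feature search can never silently cross chromosomes.

A gene's TSS is its strand-aware 5′ boundary coordinate (`start` for
`+`, `end` for `−`); the promoter window is the half-open 500-bp
window immediately upstream, excluding the TSS base itself — a stated
convention, since "overlaps the upstream window" does not say whether
the boundary base counts. Promoter classification requires ≥ 1 bp of
window overlap (configurable minimum).

## Peak calling

The caller is the core of kernel-density DNase-seq peak callers made
explicit: read 5′ positions are binned on a `grid_step` (10 bp) grid
and smoothed with a unit-mass Gaussian kernel of sd `bandwidth`
(60 bp, truncated at ±4 sd), giving a density in reads/bp whose
integral equals the read count to within 1 %. Maximal runs of grid
points with density ≥ threshold become peaks (runs shorter than
`min_peak_length` = 50 bp are dropped); the summit is the run
argmax and the score its density.

The segmentation threshold defaults to 2.5× the chromosome-mean read
density. This factor is a boundary-accuracy choice: steep thresholds
bias peak edges inward (with a flat cut-density plateau the edge sits
where the smoothed density crosses the threshold, ~Φ⁻¹ of the
fold-change in kernel-sd units), and an inward bias of ~25 bp per
side is enough to widen sub-50-bp gaps between constituent ACRs past
the clustering limit. False positives from the permissive threshold
are controlled downstream by the empirical FDR stage, not by the
threshold itself.

Empirical FDR: for each of `n_null_reps` replicates the same number
of reads is placed uniformly over the chromosome (no mappability
mask — none is modeled) and peaks are called identically. For a score
threshold *s*, FDR(*s*) = mean null count of peaks scoring ≥ *s*
divided by the observed count scoring ≥ *s*, regularized to be
non-increasing in *s* by a running minimum from the high-score end;
the retained set is observed peaks at the smallest *s* with
FDR(*s*) < `fdr_target` (0.001). If no threshold qualifies the result
is an empty set with a warning record, not an error. The FDR is a
global score-threshold construction, not a per-peak quantity. The
default `n_null_reps` is 100 — at the problem sizes this package
targets the threshold estimate is stable well below that;
`FULL_SCALE_NULL_REPS = 10_000` documents the publication-scale setting.

## ACR atlas and SE definition

The union atlas merges all samples' peaks with overlap-merge
(`max_gap = 0`); each union ACR records every sample contributing
≥ 1 bp. DNase sensitivity combines both normalizations in one number
(reads in ACR / ACR bp / million mapped reads) so that region size
and library size are both accounted for.

Nonpromoter ACRs chain at gaps ≤ 49 bp into clusters; singletons are
singleton clusters. The SE definition is size-based only (no
coactivator/H3K27ac ranking): by default the top 2.5 % of cluster
lengths, with `k = ceil(top_fraction · n_clusters)`, ties broken by
genomic coordinate then chromosome name so tiny inputs are
deterministic and never empty. A fixed length cutoff
(`length_threshold`, e.g. the 1.5 kb the quantile resolves to at
genome scale) is available as a switch; the quantile is the primary
rule, the bp threshold the derived, reported one.

Cognate gene: the gene with minimal body distance to the SE span
(0 if overlapping); ties by smaller |SE midpoint − TSS|, then
lexicographic gene id. Position class: an SE is genic when ≥ 50 % of
its length overlaps a single gene body (a stated convention — the
boundary between "within a gene" and "intergenic" has no canonical
rule); genic SEs fully inside one intron or one exon get that
subclass, otherwise multi-feature. Intergenic SEs are 5′-of-a-flank
when either flanking gene points away from them (left flank on `−` or
right flank on `+`), and 3′-of-both between convergent flanks.
Report percentages are rounded to the nearest integer alongside the
unrounded values.

## Genomic context

Gene density uses 15-kb windows stepped by 5 kb (full windows only):
`density = window · n_genes / (window − subtracted)`, where
`subtracted` is the bp of a caller-supplied region set (default: the
SEs) inside the window — large regulatory blocks would otherwise
depress the apparent gene density of their own neighborhoods. The
subtracted set is an explicit parameter because "what to subtract" is
genuinely ambiguous; windows fully covered by it are flagged
undefined (NaN), and a gene counts by ≥ 1 bp body overlap.

TAD membership defaults to full containment ("located within"), with
a fractional-overlap rule as a sensitivity switch. The enrichment
null places, for each observed region size, an interval uniformly at
random over all gene-disjoint positions (exact enumeration of valid
starts, no rejection loop), and the p-value is the add-one empirical
form p = (1 + #{null ≥ observed}) / (1 + n): never zero, uniform
under the null (property-tested by KS), monotone in the observed
fraction.

Chromatin loops are consumed, not called: rows with FDR < 1e−10 link
an SE to a gene when one anchor overlaps the SE and the other the
gene body or its promoter window. Expression comparisons use a
one-sided Mann–Whitney test (cognate genes stochastically greater);
for combined n ≤ 12 the p-value is computed by exhaustive enumeration
of group assignments on the U statistic with 0.5 tie credit (the
textbook exact tables do not handle ties), otherwise by the normal
approximation with tie correction. All-tied input returns p = 1.

## TF occupancy

Coverage uses the union of a TF's peaks (an area statement — no
double counting), and the bound call is strict: covered fraction
must exceed 0.5. Odds ratios are `(a/b)/(c/d)` per TF with the
class under test in the "a/b" slot; the Haldane–Anscombe +0.5 is
applied to all four cells only when some cell is zero, and flagged.
The per-TF log-OR scan sorts descending with ties on TF id. Note the
log-OR estimator carries the usual small-sample bias of order
1/(class size); with very small classes (tens of regions) permutation
nulls center near, but not exactly at, zero.

## Conservation

For each intergenic SE the nearest gene on each side forms its
spanning pair (genic SEs and chromosome-end SEs are skipped with a
reason). In a target species the pair is `syntenic_adjacent` when
both genes have synteny partners and the partners are consecutive in
the target annotation (any intervening gene makes it
`syntenic_nonadjacent`; a missing partner, `absent`).

The sequence search is iterated masked local alignment standing in
for a seed-and-extend tool at desk scale: Smith–Waterman (Gotoh
affine gaps, both strands, `N` never matches) via Biopython's C
aligner; after each hit the query span is masked with a
non-alignable symbol and the next-best hit extracted until the best
score falls below what a minimal acceptable hit could score. Hits
need ≥ 70 % identity and ≥ 30 bp of query by default. Scoring is
match +1, mismatch −1, gap open −5, gap extend −2. The stiff gap
costs are deliberate: with mild costs (−2/−1) the optimizer buys
spurious matches through paired micro-gaps in highly diverged
sequence, inflating the identity estimate by ~3 points at 40 %
divergence; with −5/−2 planted divergences of 5/20/40 % are recovered
within a fraction of a point (verified in the acceptance suite).

Identity is matches over aligned columns (gap columns included);
aligned fraction is the union of accepted query spans over SE length.
Both are invariant under joint reverse-complement. Note the 70 %
per-hit identity filter means uniformly diverged sequence beyond
~30 % divergence yields no hit at all — measuring divergence itself
is done with the filter off.

Motif retention asks only whether a query motif id occurs anywhere in
the orthologous sequence, not at the aligned position — presence, not
positional conservation; zero query motifs gives an undefined (not
0 %) rate. Synteny maintenance compares the share of SE-spanning
pairs adjacent in ≥ `min_species` species against resamples (without
replacement, capped and flagged if the pool is small) from the
adjacent-gene pairs that span no SE, with the add-one p.

## Insertion genotyping

Three junction references of length 2 × flank (default 200 bp):
upstream flank + element 5′ end, element 3′ end + downstream flank,
and the two genomic flanks concatenated (element absent). "Spanning"
is operationalized as: both mates place fully inside the reference
(exact or ≤ 2 mismatches, either orientation) strictly on opposite
sides of the joint midpoint; a mate crossing the midpoint counts for
neither side. Calls follow the rule table exactly — present needs
≥ 4 pairs on both insertion joints and zero on the cross joint,
absent the mirror image, everything else (including heterozygous-like
mixed evidence) ambiguous. Elements shorter than the flank are
rejected rather than padded.

## Synthetic data: what it emulates, and what it does not

Default scale: 2 chromosomes × 1 Mb, 300 genes (log-normal lengths,
1–5 exons, ≥ 1.2-kb intergenic spacing), 6 samples, 20 planted
intergenic SEs (3–8 constituents of ~400 bp at 10–49-bp gaps,
redrawn until the span is ≥ 1.6 kb), 400 background nonpromoter ACRs
(≤ 1.2 kb, spaced ≥ 60 bp so they can never chain into SE-sized
clusters), promoter peaks at 90 % of genes (~590 bp), 80 reads per
supported peak drawn uniformly across the open interval over a
0.002 reads/bp uniform background, each ACR supported by each sample
with probability 0.7. This keeps the full pipeline around half a
minute on one CPU while matching the intended regime: ~40 % promoter
ACRs, nonpromoter ACRs averaging ~400 bp, SEs of 1.6–4 kb.

TADs cover 25 % of the genome; each planted SE is covered by a TAD
with probability coverage × multiplier (default 2.0 → 0.5), and
background TADs avoiding SEs top up the genome-wide coverage. Loops
join each planted SE to its cognate promoter at FDR ≪ 1e−10 with
above-cutoff decoys. Two of ten TFs bind 80 % of constituents vs
10 % elsewhere (the rest 20 % everywhere). Motifs are literal 8-mers
written into the SE sequence, so retention is decidable by exact
string search. Ortholog panels copy each SE between its syntenic
partners mutated at per-species substitution rates (5–38 %, indels at
5 % of the substitution rate); adjacency breaks by gene insertion at
0.2 per SE pair and 0.35 per background pair per species, so
SE-spanning pairs maintain synteny in ≥ 4 of 5 species about 70 % of
the time versus ~45 % for the rest. Insertion libraries sample mate
pairs from opposite sides of the appropriate joints at 10 pairs per
junction plus a little unmappable noise.

Deliberately not emulated: real nucleotide composition and repeats,
DNase cut bias and mappability structure, tissue-specific differential
accessibility, heterogeneous (core-vs-turnover) conservation inside an
element, rearrangements beyond single gene insertions/losses, and
heterozygous insertion genotypes. Consequently, passing tests show
the statistics and procedures are implemented correctly and recover
planted truth under clean conditions — not that the biological
conclusions would survive the messiness of real data. Two effects of
the clean design worth knowing: the read-level caller merges sub-50-bp
constituent gaps (smoothing at 60-bp bandwidth cannot resolve them),
so called SEs are typically single long ACRs — constituent-level
analyses are best run from the per-sample peak files, which the
pipeline accepts directly; and uniform within-element divergence
means distant species fall off the 70 %-identity cliff together
rather than retaining alignable cores.

## Determinism and degenerate inputs

Every stochastic step flows from one seeded `numpy` generator (the
pipeline derives fixed per-sample and per-stage sub-seeds), reports
are serialized with sorted keys and no timestamps, and emitted
datasets are byte-stable per seed. Degenerate inputs fail loudly and
early: empty read tracks, unstranded genes, inverted intervals,
negative gaps or counts, empty cluster sets, elements shorter than
the junction flank. Quantities that would otherwise be silently
misleading are flagged instead of coerced — undefined gene density in
fully subtracted windows, undefined motif-retention with no query
motifs, cross-chromosome distances, FDR searches that reach no
qualifying threshold.
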