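# Methods

`dinucmap` analyses libraries of mapped mono- and dinucleosomal DNA
fragment intervals produced by MNase digestion of chromatin. This note
describes the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make every output
bit-reproducible.

## Fragments, piles and midpoints

A fragment is a 0-based, half-open interval on a contig, tagged `mono`
or `di`. Class length ranges are fixed and inclusive: mono fragments
must fall in [80, 230] nt, di fragments in [200, 400] nt; everything
else is dropped by `filter_by_length` (with a kept/dropped report).

**Duplicates are evidence.** The number of fragments mapping to the
identical (contig, start, end) is the *pile* count of that interval.
This inverts standard ChIP-seq practice — PCR-duplicate removal would
delete exactly the signal used here, because a nucleosome is called
well-positioned when many independent fragment pairs map to the same
interval. The default analyses use the pile ≥ 5 subset. Piling on
identical intervals (rather than identical midpoints) keeps the length
of a pile well defined, which the size-by-pile analysis needs;
`count_piles(on="midpoint")` implements the alternative reading (the
reported length of a midpoint-pile is its modal member length, smallest
on ties).

**Midpoint convention.** `fragment_midpoint` returns
`floor((start + end) / 2)`: for even-length fragments the right-of-center
base. Any fixed convention works; this one is a single integer,
identical for both classes, and documented so profiles reproduce
bit-exact. A mono midpoint estimates the nucleosome dyad; a di midpoint
falls in the linker between the two cores the fragment spans — that is
the observation the linker analyses are built on.

## Length distributions by pile level

`length_histogram_by_pile` extracts, for each threshold L, the fragment
lengths of all intervals piled ≥ L times, at fragment multiplicity (an
interval piled k times contributes k copies). Because the subsets are
nested and of very different sizes, every subset is subsampled without
replacement to the size of the smallest one (seed-controlled) before
normalizing to frequencies — distributions at different pile levels are
then directly comparable.

`find_modes` lays the histogram densely over its observed support,
smooths with a centered moving average (window 3, truncated and
renormalized at the edges), and reports strict local maxima (plateaus
report their leftmost bin; a single-bin histogram is its own mode; a
histogram that is one flat plateau has no mode and warns). Maxima are
ranked by smoothed height and kept greedily subject to a pairwise
distance ≥ 5 nt, so the two mononucleosomal modes 18 nt apart survive
while shot noise does not. Smoothing exists only inside mode finding;
emitted frequency tables are never smoothed.

`compare_mw` is a two-sided Mann–Whitney U (delegating to
`scipy.stats.mannwhitneyu`): exact enumeration when both samples are
tie-free and ≤ 20, the tie-corrected normal approximation otherwise; a
fully degenerate pooled sample returns p = 1.

`linker_difference_from_di_modes` encodes the arithmetic that a
dinucleosomal fragment is two mononucleosomal DNAs plus their shared
linker: with equal mono lengths, the between-dataset linker difference
equals the difference of the di modal lengths.

## Anchored composite profiles and the NDR test

`build_profile` accumulates piled midpoints into transcript-oriented
offsets around a per-gene anchor — the called TSS, or the 3′-most CDS
base (`orf3`, translational termination, not transcript end). For
+ strand genes offset = midpoint − anchor; for − strand genes the sign
flips. Each distinct piled interval counts **once**; piles gate
inclusion via `min_pile` but do not weight (a `weight="pile"` option
exists for sensitivity analysis). Genes lacking the anchor are skipped
and counted. Windows crossing contig edges are kept; out-of-contig
offsets simply receive no counts (a documented asymmetry at edges).
W defaults to ±1000 nt.

`ndr_depletion_chisq` compares two groups' dinucleosome TSS profiles in
an upstream window (default [−200, −1] nt) with a Pearson χ² (df 1, no
continuity correction unless requested) on the 2×2 table
[group × (counts in window, counts in the rest of ±W)]. Using the rest
of the profile as the control column is a design choice surfaced in the
output metadata; any control window can be substituted. Display
smoothing never feeds the test.

## Expression layer

RPKM = reads × 10⁹ / (total mapped reads × mature transcript length),
counted over exons; a read overlapping several genes counts for each
(simplest consistent rule), but once per gene. Groups are assigned on
ascending RPKM rank — rank 1 is the *lowest* expression — with ties
broken by gene id for determinism. Two schemes: `thirds` (tertiles of
all N genes; the default, scale-free) and `rank-windows` (three windows
of g genes at the bottom, middle — centered on ⌈N/2⌉ — and top of the
ranking, the rest ungrouped; g defaults to min(1000, ⌊N/3⌋)).

The TSS of a gene is the position most intensely mapped by 5′-end
(oligo-cap) reads within the 1 kb window upstream of the translation
start, TRS base included, strand-matched; ties break toward the TRS.
Genes with no read in the window get no TSS and are excluded from
TSS-anchored analyses (with a count in the run report).

## Dinucleotide preference statistics

Both statistics are computed for all 16 dinucleotides and normalized to
an all-genome-positions background, scaled so no enrichment = 100:
value(o) = 100 × (observed rate at o) / (background rate at o);
offsets with zero background are masked. The alternative reading of
"normalized to 100" (rescaling each profile's own mean) was rejected
because the chosen one makes the all-positions identity exact: feeding
every eligible position as the midpoint set returns exactly 100
everywhere unmasked — a built-in self-test.

*Closest distance*: per midpoint, the signed distance (downstream
positive) to the nearest occurrence within a cap of W = 500 nt; a
two-sided exact tie contributes 0.5 to each side (any consistent rule
cancels in the ratio; halving avoids directional bias). Occurrence
position is the start index of the 2-mer; overlapping occurrences all
count; ambiguity codes match nothing. Positions within W of a contig
edge are excluded from both observed and background sets so the ratio
stays unbiased. The scan is vectorized with a sorted-occurrence binary
search and matches a position-by-position naive oracle exactly (tested
on genomes up to 1 kb).

*Frequency*: the fraction of midpoints whose 2-mer at offset o equals
the dinucleotide (W = 150 nt display window), against the genome-wide
scalar fraction. With a scalar background the all-positions identity
holds only up to O(W/L) edge effects — the closest-distance statistic is
the one with the exact identity.

## The synthetic chromatin generator

The generator exists so every analysis stage is testable with no
sequencing download; its defaults are the package's study conditions.

* **Genome**: i.i.d. uniform A/C/G/T, 2 contigs × 100 kb — a neutral
  canvas for bias planting.
* **Genes**: 30, placed non-overlapping with ≥ 2 kb flanks (sizing error
  if they do not fit), 1–3 exons (60 nt introns), UTR 50–200 nt, CDS
  800–1600 nt, random strand; truth expression groups are near-equal
  thirds.
* **Arrays**: 147 nt cores tiled with linkers ~ N(20, 2) nt (fungal-like
  short linkers; nucleosome repeat length ≈ 167 nt). With a fixed
  linker, the dyad count per contig is floor((L + linker) / (core +
  linker)) — verified against hand tiling.
* **NDR**: the cores whose footprint overlaps the configured upstream
  window of each TSS are deleted (widths 80/140/200 nt for
  low/medium/high expression); the linker spanning the carved gap
  inherits the group's dinucleosome suppression probability
  (0.2/0.6/0.95). Dinucleosomes with midpoints within 200 nt downstream
  of an ORF 3′ end are suppressed with probability 0.8.
* **Fragments**: mono fragments are centred on dyads with lengths from
  the 0.5/0.5 mixture of N(132, 2) and N(150, 2) (both modes inside
  [80, 230]); di fragments are centred on linker midpoints with lengths
  ~ N(300, 2). Positioning jitter is applied as **independent integer
  displacements of the two fragment ends** (round N(0, jitter_sd),
  default sd 1). This is a deliberate design choice: MNase trimming and
  positioning uncertainty act on fragment ends, so tighter positioning
  simultaneously raises pile counts and sharpens lengths — which is
  exactly the joint convergence the size-by-pile analysis measures. A
  center-jitter-with-independent-length design was rejected because it
  decouples the two: pile selection then *widens* with tighter
  positioning (lower jitter inflates per-interval counts, making the
  pile ≥ 5 threshold less selective), inverting the convergence
  property. Fragment counts (400k each) give ~330 fragments per
  dyad/linker, enough for a rich pile ≥ 5 subset at the default jitter.
  Fragments clipped at contig ends are discarded.
* **Linker sequence bias**: linker bases are resampled i.i.d. with
  p(C) = p(G) = √f/4 (f = enrichment factor, default 2, valid in
  (0, 4]). This puts each of CC/CG/GC/GG at exactly f/16 expected
  frequency inside linkers — f times the uniform core background — and
  depresses AT/TA to ((1 − √f/2)/2)². A first-order Markov chain tuned
  on dinucleotide weights was rejected: its stationary-distribution
  feedback realizes ≈ 1.7× for a nominal 2×, i.e. it misses the
  enrichment contract the factor is supposed to set.
* **Expression**: per-group target RPKM is log-uniform on 0.5–14.6 /
  41.3–63.9 / 199–2400 (separated decades typical of low/medium/high
  fungal RNA-seq tertiles), converted to exon counts at 2M total mapped
  reads; 5′-end reads put a 0.6 point mass on the truth TSS, the rest
  displaced by round N(0, 5) and clipped into the upstream window, with
  depth ∝ RPKM — so TSS calling recovers truth exactly and 5′ totals
  correlate with RPKM by construction.

All randomness derives from the single `SimConfig.seed` through tagged
sub-streams, so the same config is byte-identical across runs, and each
stage (genome, genes, chromatin, bias, fragments, expression) is
individually reproducible.

**What the generator does not emulate**: real base composition and
isochore structure; MNase sequence preference at cut sites (cut-site
bias is planted only as linker composition, not as a digestion model);
the MNase concentration series (one digestion condition); read-level
errors, mappability and alignment (fragments are emitted as mapped
intervals); overlapping/nested genes, alternative splicing, antisense
transcription; biological coupling between expression and chromatin
beyond the parameterized NDR/ORF-end suppression. Passing tests
therefore show the *analyses* are correct and sensitive at realistic
signal strengths; they do not show that real chromatin has these effect
sizes.

## Problem sizes and test conditions

The test suite runs the full machinery at reduced scale chosen as the
package's own desk-scale conditions: 2 × 100 kb genomes with 30 genes
and 400k fragments per class for recovery checks; 200k fragment draws
for mode recovery (modes within ±2 nt); 20 seeded replicates of a
2 × 60 kb, 18-gene simulation for the expression-ordering of the
promoter χ² (majority vote ≥ 15/20); and the jitter-monotonicity run
uses a single length mode with zero trimming noise (jitter sd 4/2/1) so
positioning noise is the only variance source being compared. The
baseline-100 identity is checked on a 100 kb genome with all ~99k
eligible positions as midpoints.

## Known limitations

* BEDPE reading assumes both mates on one contig and collapses to the
  outer span; mapping-quality filtering is assumed done upstream.
* The frequency-statistic background is a genome-wide scalar, so its
  baseline identity is exact only up to O(W/L) edge terms.
* `count_reads_in_exons` double-counts a read for each gene it overlaps
  (documented rule); no transcript assembly or splicing-aware counting.
* Gene placement in the simulator is evenly spaced, not clustered;
  promoter windows never overlap neighbouring genes, which real compact
  fungal genomes do exhibit.
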