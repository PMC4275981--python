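# Methods

## Motif model and scanner

A G4 motif is defined structurally, not thermodynamically: at least
`min_islands` (default 4) maximal runs of at least `min_g_run` (default 3)
guanines, consecutive runs separated by 1 to `max_loop` (default 25)
bases. The scanner finds maximal G-runs (regex `G{3,}`), then greedily
chains runs whose gaps lie in `[1, max_loop]`. Every maximal chain with
enough islands is exactly one motif spanning first-island start to
last-island end; chains with more than four islands are **not** decomposed
into sub-patterns. A gap longer than `max_loop` splits the chain, and each
side qualifies independently. Loops have length ≥ 1 by construction
(maximal runs cannot abut); loops may contain G-runs shorter than
`min_g_run`, and N is legal loop content but never island content (N never
counts as G or C anywhere).

Minus-strand motifs are found by chaining maximal C-runs on the reference
with identical gap rules, reported in reference coordinates with strand
`-`. This is equivalent to scanning the reverse complement (a tested
symmetry property). Both strands are counted as separate motifs even when
their intervals overlap: intra-strand G4 formation is strand-specific, and
strand identity is needed downstream (transcribed-strand bias, rDNA-style
analyses). For all overlap tests the motif's location is the full chain
interval, not the island positions.

Tests verify the scanner against an independent oracle that enumerates
regex matches of the query pattern at every start position (lazy loops,
greedy islands, via lookahead) and merges overlapping matches into maximal
intervals.

## Coordinates and I/O

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
is converted at the boundary by subtracting 1 from starts; BED and
narrowPeak pass through unchanged; narrowPeak column 8 (−log10 P) becomes
the peak significance. Non-ACGTN FASTA characters are mapped to N with a
logged count rather than dropped. Chromosome-name mismatches between a
genome and a track are hard errors: a silent misjoin would corrupt every
downstream count.

## Matched-control null

Each of `n_sets` (default 1,000) control sets contains one region per
observed motif with the same chromosome, the same length, and the same G+C
**count** ("same GC content" is interpreted as an identical count; with
equal lengths, count and fraction coincide, and integer counts avoid float
tolerance questions). Regions are drawn by rejection sampling of uniform
starts with an O(1) prefix-sum GC lookup; after `max_attempts` (default
50,000) failures the tolerance widens by ±1 count at a time, each widening
logged and the tolerance actually used recorded per region. Control
regions may overlap one another or the real motifs — no exclusion rule is
stated for the procedure being modelled, and none is added. Set *i* uses a
child generator spawned from `(seed, i)`, so collections are bit-for-bit
reproducible.

Note a real consequence of GC matching on motif-rich genomes: because G4
motifs are locally much more GC-dense than a ~36–44% GC background, a
nontrivial share of GC-eligible positions sits on or near motifs, so the
matched null is tighter (higher expected overlap with motif-co-located
features) than a uniform null. This is the point of the control — it asks
"is the association stronger than expected for *this* base composition?" —
but it reduces contrast against composition-correlated features, and it is
why planted-signal tests use effect sizes well above 1×.

## Association and empirical significance

Two intervals are associated at window 0 iff they strictly overlap; at
window w > 0 iff they overlap or the gap (bases strictly between them) is
≤ w. Defaults: 0 for annotation tracks, 300 bp for helicase (Pfh1) and
polymerase (Cdc20) peak sets — the chromatin shearing size — and 5,000 bp
for γ-H2A, which spreads kilobases around a break; 0/500 are exposed as
robustness settings. A query element is counted once regardless of how
many subjects it touches.

The empirical P-value defaults to the add-one estimator
`(b + 1)/(n_sets + 1)` with ties counted as extreme; it is never exactly
zero and is provably super-uniform under exchangeability (tested). The
literal `b/n_sets` mode reproduces historical reports in which zero
exceedances print as "P < 1/n". The reported direction is enriched iff
observed > null mean, with the one-sided P for that direction.

q-values follow Storey's procedure: π0(λ) = mean(p > λ)/(1 − λ) on
λ ∈ {0, 0.05, …, 0.90}, smoothed by a cubic polynomial evaluated at
λ = 0.90, clamped to (0, 1]; q-values are the π0-scaled step-up values.
With fewer than 20 tests, or a failed/degenerate fit, π0 falls back to 1,
which reduces exactly to Benjamini–Hochberg (tested against an independent
BH implementation).

Transcribed-strand bias: a stranded motif overlapping a stranded gene lies
on the transcribed (template) strand iff its strand differs from the
gene's annotated (sense) strand — such a motif is absent from the mRNA. A
motif overlapping several genes is resolved to the largest overlap, ties
to the first gene in sorted order (logged). The test is the exact
two-sided binomial (minimum-likelihood convention) at p = 0.5.

## Contingency statistics and classification

Class definitions over the five association columns (helicase/WT,
polymerase/WT, polymerase/depleted, damage/WT, damage/depleted), with
instability(c) = polymerase(c) OR damage(c):

* Class I = helicase-bound in WT;
* Class II = instability(depleted) AND NOT instability(WT);
* Class III = instability(WT) AND instability(depleted).

Class II ∩ Class III = ∅ identically; Class I may intersect either.

Fisher's exact test defaults to the two-sided minimum-likelihood rule and
also exposes one-sided alternatives, because published tables mix
conventions: the helicase-vs-polymerase tables are extreme enough that
one- and two-sided P coincide, while the pausing-vs-damage tables
(P = 0.23 and 8.7E-6) are reproduced exactly by the one-sided test and not
by the two-sided one (0.33 and 1.1E-5). The package reports whichever the
caller requests and uses one-sided for those two tables in its acceptance
computations.

For the paired peak-significance comparison, each motif takes the most
significant overlapping peak (maximum −log10 P) within the window in each
condition, P = 1 when no peak overlaps; the two-sided Wilcoxon signed-rank
test (zeros dropped) compares conditions. Equal sequencing depth between
conditions is an upstream assumption that the operation documents but
cannot enforce; when all paired differences are zero the test is
degenerate and P = 1 is returned with a warning.

## Conservation

A motif of species A is conserved in species B iff the aligned portion of
B corresponding to the motif interval strictly overlaps any motif scanned
in B — overlap of locations, not sequence identity, and one-directional
(A→B); asymmetric counts are expected for asymmetric alignments. Alignment
input is a pairwise MAF subset ('+'-strand blocks with two rows) or, for
fixtures, an ungapped six-column block TSV. Gapped blocks are mapped
column-by-column; only columns with both rows ungapped contribute.

## Synthetic data generator

The generator emulates the study conditions: by default three chromosomes
totalling 12.6 Mb at 36% GC (i.i.d. bases with the GC mass split evenly
between G and C), 446 planted motifs, and five MACS-like peak sets whose
fractions of peaked motifs (~20% helicase, ~11/17% polymerase WT/depleted,
~17/40% damage WT/depleted) and truncated-normal peak lengths
(e.g. 1838 ± 983 bp) mirror the modelled experiments. Planted motifs use
a fixed template with 1 bp loops (`GGGTGGGTGGGTGGG`, complemented for the
minus strand) flanked by one neutral base so detection is unambiguous;
spurious background motifs are expected at realistic GC and are identified
by differencing pre- and post-plant scans. `plant_spacing` optionally
enforces a minimum distance between planted sites; truth-recovery tests
use it so that zero-background peak sets recover the planted association
masks exactly (without spacing, a peak on one motif can legitimately fall
within the window of a close neighbour).

What the generator does **not** emulate: chromatin context, replication
timing, GC isochores, repeat structure, read-level noise, or peak-caller
artefacts. Passing recovery tests therefore demonstrates correctness of
the interval/statistics machinery under the stated composition model, not
biological completeness. Likewise, expected motif densities in "random
sequence of the same GC" depend strongly on the composition model
(i.i.d. vs. shuffling vs. region-matched), so simulated expected densities
are reported with Monte-Carlo standard errors and are not treated as
universal constants.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down problem sizes chosen to
exercise every code path with comfortable statistical power: 2 kb × 200
sequences for scanner/oracle equivalence; a 5 Mb two-chromosome genome for
the matched-control contract (10 sets); 400 kb genomes with 100 planted
motifs, 5% promoter coverage, 3× co-location and n_sets = 200 for
planted-signal recovery (50 replicates each for signal and null); and
2,000 replicates at n_sets = 100 for the super-uniformity check. The
44% GC used in recovery replicates keeps GC-matched rejection sampling
fast and the eligible-position pool dominated by background rather than by
the planted motifs themselves (see the null note above). All randomness
flows through `numpy.random.Generator` seeded from a single integer;
per-set child seeding makes control collections order-independent.

## Known limitations

* No G4 stability scoring (G4Hunter-style), inter-strand or RNA
  quadruplexes, or thermodynamic folding — the motif definition is purely
  pattern-based.
* The MAF reader handles '+'-strand pairwise blocks only.
* The Storey smoother is a cubic polynomial fit, not a spline with
  df-selection; for very small or highly non-uniform P-value families the
  BH fallback is the safer default and is applied automatically below 20
  tests.
* Peak calling, read mapping, and telomeric/rDNA copy-number inference are
  out of scope; peaks enter as interval files with significances.
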