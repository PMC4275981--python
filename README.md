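# g4atlas

Genome-wide G-quadruplex (G4) motif discovery and association analysis for
small eukaryotic genomes, with matched-control resampling nulls, ChIP-seq
peak association, helicase-dependence classification, cross-species
conservation, and a fully synthetic test bed.

## The problem

G-quadruplexes are four-stranded DNA secondary structures built from
stacked guanine quartets. Sequences able to form them in vitro — **G4
motifs** — impede replication forks unless they are unwound, in fission
yeast by the Pif1-family helicase Pfh1. Mapping where G4 motifs sit
relative to promoters, nucleosome-depleted regions, meiotic DSB hotspots,
ORFs and helicase/polymerase/damage ChIP-seq peaks, and testing whether
those associations exceed chance, requires a null that controls for the
motifs' unusual base composition. `g4atlas` implements that entire
computational pipeline.

## The core method

1. **Motif scanning.** A G4 motif is a maximal chain of G-islands matching

   (G≥3 N1–25)3 G≥3

   i.e. four or more maximal runs of ≥3 guanines separated by loops of
   1–25 bases. Chains of more than four islands count as a *single* motif
   spanning the whole chain. The minus strand is found by chaining C-runs
   on the reference with identical rules.

2. **Matched-control null.** For the observed motif set, N (default 1,000)
   control sets are drawn; each control region matches its motif's
   chromosome, length, and G+C count exactly (rejection sampling, with
   logged ±1 tolerance relaxation only if a match is unreachable). The
   empirical P-value of an observed motif–feature association count x
   against null counts x₁…x_N is the add-one estimator

   P = (#{i : xᵢ ≥ x} + 1) / (N + 1)

   (≤ for depletion; a paper-literal b/N mode is available). Multiple
   tests are corrected with Storey q-values (cubic-smoother π0 estimate,
   Benjamini–Hochberg fallback for small families).

3. **Peak association and classes.** Motifs are associated with ChIP-seq
   peak sets within factor-specific windows (300 bp for helicase and
   polymerase occupancy — the DNA shearing size — and 5 kb for the γ-H2A
   damage mark). Motifs are then classified: Class I (helicase-bound in
   wild type), Class II (fork pausing and/or damage only under helicase
   depletion), Class III (pausing/damage in both conditions; disjoint from
   Class II by construction). 2×2 contingency tables over these columns
   are tested with Fisher's exact test, and per-motif best peak P-values
   across conditions with the Wilcoxon signed-rank test.

4. **Conservation.** A motif is conserved in a second species if the
   aligned portion of that genome (pairwise MAF-subset or ungapped block
   TSV) overlaps a motif scanned there.

5. **Synthetic data.** `g4atlas.synthetic_data` generates i.i.d. genomes
   of chosen GC, plants motif templates with known strand and position,
   and builds feature tracks and MACS-like peak sets with controlled
   enrichment — every pipeline stage is testable offline against ground
   truth.

## Worked example

```python
import numpy as np
from g4atlas import scan_genome, build_control_sets, enrichment_test
from g4atlas.synthetic_data import (
    SimulationSpec, FeatureClassSpec, random_genome, plant_motifs,
    synth_features,
)

spec = SimulationSpec(
    chrom_lengths=(400_000,), gc_fraction=0.44, n_planted_motifs=100,
    seed=1,
    feature_classes=(
        FeatureClassSpec("promoters", 100, 200, 20, motif_colocation=0.15),
    ),
)
rng = np.random.default_rng(1)
genome = random_genome(spec, rng)
genome, truth = plant_motifs(genome, spec, rng)
promoters = synth_features(genome, spec, truth, rng)["promoters"]

motifs = scan_genome(genome)
controls = build_control_sets(motifs, genome, n_sets=200, seed=1)
result = enrichment_test(motifs, controls, promoters, window=0)
print(len(motifs), result.observed_overlap,
      round(result.expected_overlap, 1), result.direction,
      round(result.p_value, 4))
```

prints

```
123 22 7.4 enriched 0.005
```

123 motifs were scanned (100 planted plus background motifs expected at
44% GC); 22 of them touch a promoter versus 7.4 expected under the
chromosome/length/GC-matched null, so promoters are reported enriched with
empirical P = (0+1)/(200+1) ≈ 0.005 — the planted 3× co-location is
recovered.

The same pipeline is available from the shell:

```sh
g4atlas simulate --seed 1 --outdir sim/
g4atlas scan --fasta sim/genome.fa --out motifs.bed
g4atlas controls --fasta sim/genome.fa --motifs motifs.bed \
    --n-sets 200 --seed 1 --out controls.tsv
g4atlas enrich --motifs motifs.bed --controls controls.tsv \
    --features sim/feature_promoters.bed --out enrichment.tsv
```

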