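"""Chromosome/length/GC-matched resampling nulls.

The empirical null for every enrichment test is a collection of control
sets, each containing one random region per observed motif, matched to that
motif on three properties: same chromosome, same length, and same GC
content.  "Same GC content" means an identical G+C base *count* (lengths
being equal, count and fraction coincide and the count avoids float
tolerance questions).  N bases never count toward GC.

Regions are drawn by rejection sampling: uniform starts on the motif's
chromosome, rejected until the GC count matches.  If ``max_attempts`` draws
fail, the tolerance widens by +/-1 GC-count steps (each widening logged)
until a region is found, and the tolerance actually used is recorded
per-region in the collection.  Control regions may overlap each other or
the real motifs; no exclusion is applied.

Each control set is generated from a child seed spawned from (seed, set
index), so collections are bit-for-bit reproducible and sets could be drawn
in any order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from g4atlas.sequence_io import AnnotationTrack, GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

_BATCH = 4096


def gc_count(genome: GenomeSequence, interval: GenomicInterval) -> int:
    """Count of G plus C bases in the spanned reference sequence."""
    seq = genome.fetch(interval)
    return seq.count("G") + seq.count("C")


class GenomeGCIndex:
    """Per-chromosome prefix sums of the G/C indicator for O(1) GC counts."""

    def __init__(self, genome: GenomeSequence):
        self._prefix: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            prefix = np.zeros(len(seq) + 1, dtype=np.int64)
            np.cumsum(is_gc, out=prefix[1:])
            self._prefix[chrom] = prefix

    def count(self, chrom: str, start: int, end: int) -> int:
        p = self._prefix[chrom]
        return int(p[end] - p[start])

    def counts(self, chrom: str, starts: np.ndarray, length: int) -> np.ndarray:
        p = self._prefix[chrom]
        return p[starts + length] - p[starts]

    def chrom_length(self, chrom: str) -> int:
        return len(self._prefix[chrom]) - 1


def sample_matched_region(
    motif_interval: GenomicInterval,
    genome: GenomeSequence,
    rng: np.random.Generator,
    max_attempts: int = 50_000,
    match_gc: bool = True,
    gc_index: GenomeGCIndex | None = None,
    target_gc: int | None = None,
) -> tuple[GenomicInterval, int]:
    """Draw one random region matched to a motif.

    Returns ``(region, tolerance_used)``.  The region is on the motif's
    chromosome with the motif's length; when ``match_gc`` its GC count is
    within ``tolerance_used`` of the motif's (0 unless relaxation was
    needed and logged).  When ``match_gc`` is false the first uniform draw
    is returned.
    """
    if gc_index is None:
        gc_index = GenomeGCIndex(genome)
    chrom = motif_interval.chrom
    length = motif_interval.length
    chrom_len = gc_index.chrom_length(chrom)
    if chrom_len < length:
        raise ValueError(
            f"chromosome {chrom!r} ({chrom_len} bp) shorter than motif "
            f"({length} bp): matching unsatisfiable"
        )
    n_starts = chrom_len - length + 1

    if not match_gc:
        start = int(rng.integers(0, n_starts))
        return (
            GenomicInterval(chrom, start, start + length),
            0,
        )

    if target_gc is None:
        target_gc = gc_index.count(chrom, motif_interval.start, motif_interval.end)

    tolerance = 0
    while True:
        attempts = 0
        while attempts < max_attempts:
            batch = min(_BATCH, max_attempts - attempts)
            starts = rng.integers(0, n_starts, size=batch)
            gcs = gc_index.counts(chrom, starts, length)
            hits = np.nonzero(np.abs(gcs - target_gc) <= tolerance)[0]
            if hits.size:
                start = int(starts[hits[0]])
                return (
                    GenomicInterval(chrom, start, start + length),
                    tolerance,
                )
            attempts += batch
        tolerance += 1
        logger.info(
            "sample_matched_region: widening GC tolerance to +/-%d for "
            "%s:%d-%d (target GC %d)",
            tolerance,
            chrom,
            motif_interval.start,
            motif_interval.end,
            target_gc,
        )


@dataclass
class ControlSetCollection:
    """N control sets, each parallel to the observed motif list.

    ``sets[i][j]`` is the matched region for motif j in set i;
    ``gc_tolerance_used[i][j]`` the GC-count deviation that was required
    (0 in the common case).
    """

    n_sets: int
    sets: list[list[GenomicInterval]]
    gc_tolerance_used: list[list[int]]
    seed: int
    match_gc: bool

    def __post_init__(self) -> None:
        if len(self.sets) != self.n_sets:
            raise ValueError("sets length must equal n_sets")

    @property
    def n_motifs(self) -> int:
        return len(self.sets[0]) if self.sets else 0

    def set_track(self, i: int) -> AnnotationTrack:
        return AnnotationTrack(f"control_set_{i}", list(self.sets[i]))

    def max_tolerance(self) -> int:
        return max(
            (t for row in self.gc_tolerance_used for t in row), default=0
        )


def build_control_sets(
    motifs: AnnotationTrack,
    genome: GenomeSequence,
    n_sets: int = 1000,
    seed: int = 0,
    match_gc: bool = True,
    max_attempts: int = 50_000,
) -> ControlSetCollection:
    """Build the resampling null: ``n_sets`` sets of regions matched 1:1 to
    the motifs by chromosome, length and GC count.

    Deterministic given ``seed``; set i uses a child generator spawned from
    (seed, i).
    """
    if len(motifs) == 0:
        raise ValueError("motif track is empty")
    motifs.validate_against(genome)
    gc_index = GenomeGCIndex(genome)
    targets = [
        gc_index.count(iv.chrom, iv.start, iv.end) for iv in motifs.intervals
    ]
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sets)
    sets: list[list[GenomicInterval]] = []
    tolerances: list[list[int]] = []
    for i in range(n_sets):
        rng = np.random.default_rng(children[i])
        regions: list[GenomicInterval] = []
        tols: list[int] = []
        for iv, tgt in zip(motifs.intervals, targets):
            try:
                region, tol = sample_matched_region(
                    iv,
                    genome,
                    rng,
                    max_attempts=max_attempts,
                    match_gc=match_gc,
                    gc_index=gc_index,
                    target_gc=tgt,
                )
            except ValueError as exc:
                raise ValueError(
                    f"control sampling failed for motif {iv}: {exc}"
                ) from exc
            regions.append(region)
            tols.append(tol)
        sets.append(regions)
        tolerances.append(tols)
    return ControlSetCollection(
        n_sets=n_sets,
        sets=sets,
        gc_tolerance_used=tolerances,
        seed=seed,
        match_gc=match_gc,
    )
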