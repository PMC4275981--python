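"""Cross-species motif conservation through pairwise genome alignments.

A motif in species A is conserved in species B iff the aligned portion of
B's genome corresponding to the motif strictly overlaps any motif scanned
in B.  Conservation is one-directional (A toward B); counts need not be
symmetric unless the alignment is an identity.

Alignment input is a pairwise-block subset of MAF ('a' blocks with exactly
two '+'-strand 's' lines) or, for fixtures, an ungapped six-column TSV
(src_chrom src_start src_end tgt_chrom tgt_start tgt_end).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from g4atlas.sequence_io import AnnotationTrack, GenomicInterval


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block.

    ``src_text``/``tgt_text`` are equal-length gapped alignment rows
    ('-' for gaps); when both are None the block is colinear and ungapped,
    requiring equal source and target lengths.
    """

    src: GenomicInterval
    tgt: GenomicInterval
    src_text: Optional[str] = None
    tgt_text: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.src_text is None) != (self.tgt_text is None):
            raise ValueError("src_text and tgt_text must both be set or unset")
        if self.src_text is not None:
            if len(self.src_text) != len(self.tgt_text):
                raise ValueError("gapped rows must have equal length")
            if len(self.src_text) - self.src_text.count("-") != self.src.length:
                raise ValueError("src row gapless length != src interval")
            if len(self.tgt_text) - self.tgt_text.count("-") != self.tgt.length:
                raise ValueError("tgt row gapless length != tgt interval")
        else:
            if self.src.length != self.tgt.length:
                raise ValueError("ungapped block requires equal lengths")


@dataclass
class AlignmentBlockSet:
    """Pairwise alignment blocks between two species' genomes."""

    blocks: list[AlignmentBlock]
    src_species: str = "A"
    tgt_species: str = "B"

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.src.chrom, []).append((b.src.start, b.src.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"source intervals overlap on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )


def _block_map(block: AlignmentBlock, start: int, end: int) -> list[GenomicInterval]:
    """Target intervals aligned to source positions [start, end) of a block."""
    lo = max(start, block.src.start)
    hi = min(end, block.src.end)
    if lo >= hi:
        return []
    if block.src_text is None:
        off = block.tgt.start - block.src.start
        return [GenomicInterval(block.tgt.chrom, lo + off, hi + off)]
    # Walk alignment columns, collecting target positions where both rows
    # are non-gap and the source position falls in [lo, hi).
    out: list[GenomicInterval] = []
    spos = block.src.start
    tpos = block.tgt.start
    run_start = None
    for sc, tc in zip(block.src_text, block.tgt_text):
        s_gap = sc == "-"
        t_gap = tc == "-"
        hit = (not s_gap) and (not t_gap) and lo <= spos < hi
        if hit:
            if run_start is None:
                run_start = tpos
        else:
            if run_start is not None:
                out.append(GenomicInterval(block.tgt.chrom, run_start, tpos))
                run_start = None
        if not s_gap:
            spos += 1
        if not t_gap:
            tpos += 1
    if run_start is not None:
        out.append(GenomicInterval(block.tgt.chrom, run_start, tpos))
    return out


def map_interval(
    blocks: AlignmentBlockSet, interval: GenomicInterval
) -> list[GenomicInterval]:
    """Target-genome intervals covered by the alignment of ``interval``;
    empty if the interval is unaligned."""
    out: list[GenomicInterval] = []
    for block in blocks.blocks:
        if block.src.chrom != interval.chrom:
            continue
        out.extend(_block_map(block, interval.start, interval.end))
    return out


def conserved_motifs(
    motifs_a: AnnotationTrack,
    motifs_b: AnnotationTrack,
    blocks: AlignmentBlockSet,
) -> tuple[int, list[GenomicInterval]]:
    """Motifs of A whose aligned portion of B's genome contains a motif.

    Returns (count, list of conserved A-motif intervals).
    """
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in motifs_b.intervals:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    conserved: list[GenomicInterval] = []
    for m in motifs_a.intervals:
        mapped = map_interval(blocks, m)
        hit = any(
            t.overlaps(b)
            for t in mapped
            for b in b_by_chrom.get(t.chrom, ())
        )
        if hit:
            conserved.append(m)
    return len(conserved), conserved


def aligned_fraction(blocks: AlignmentBlockSet, genome_size: int) -> float:
    """Fraction of the source genome covered by alignment blocks."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    total = sum(b.src.length for b in blocks.blocks)
    return total / genome_size


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_maf(path, src_species: str = "A", tgt_species: str = "B") -> AlignmentBlockSet:
    """Read a pairwise subset of MAF: 'a' blocks with exactly two 's' lines,
    both on the '+' strand.  Sequence names may be 'species.chrom' or bare
    chromosome names."""
    blocks: list[AlignmentBlock] = []
    current: list[list[str]] = []

    def flush() -> None:
        if not current:
            return
        if len(current) != 2:
            raise ValueError(
                f"MAF block with {len(current)} 's' lines; need exactly 2"
            )
        rows = []
        for f in current:
            # s name start size strand srcSize text
            name, start, size, strand, _src_size, text = (
                f[1], int(f[2]), int(f[3]), f[4], f[5], f[6],
            )
            if strand != "+":
                raise ValueError("only '+'-strand MAF rows are supported")
            chrom = name.split(".", 1)[1] if "." in name else name
            rows.append((chrom, start, size, text))
        (sc, ss, ssz, stext), (tc, ts, tsz, ttext) = rows
        blocks.append(
            AlignmentBlock(
                src=GenomicInterval(sc, ss, ss + ssz),
                tgt=GenomicInterval(tc, ts, ts + tsz),
                src_text=stext,
                tgt_text=ttext,
            )
        )
        current.clear()

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("a"):
                flush()
            elif line.startswith("s"):
                current.append(line.split())
    flush()
    return AlignmentBlockSet(blocks, src_species, tgt_species)


def read_block_tsv(
    path, src_species: str = "A", tgt_species: str = "B"
) -> AlignmentBlockSet:
    """Read ungapped colinear blocks from a six-column TSV:
    src_chrom src_start src_end tgt_chrom tgt_start tgt_end."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            blocks.append(
                AlignmentBlock(
                    src=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    tgt=GenomicInterval(f[3], int(f[4]), int(f[5])),
                )
            )
    return AlignmentBlockSet(blocks, src_species, tgt_species)
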