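"""Intra-strand G-quadruplex motif scanning.

A G4 motif is four or more G-islands -- maximal runs of at least
``min_g_run`` consecutive guanines -- separated by loops of 1 to
``max_loop`` bases: the (G>=3 N1-25)3 G>=3 query pattern with defaults
min_g_run=3, max_loop=25, min_islands=4.  Chains of more than four islands
with all gaps within the loop bound are merged and counted as a single
motif spanning the whole chain; a gap longer than ``max_loop`` splits the
chain, and each side qualifies independently if it retains enough islands.

The minus strand is scanned by chaining maximal C-runs on the reference
sequence with identical gap rules (equivalent to scanning the
reverse-complement), reported in reference coordinates with strand '-'.
N never counts as G or C; it is legal loop content only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from g4atlas.sequence_io import AnnotationTrack, GenomeSequence, GenomicInterval

_G_RUN_RE_CACHE: dict[tuple[str, int], re.Pattern] = {}


@dataclass(frozen=True)
class ScanParams:
    """Scanner parameters; the defaults reproduce the standard query pattern
    (G>=3 N1-25)3 G>=3 on both strands."""

    min_g_run: int = 3
    max_loop: int = 25
    min_islands: int = 4
    strands: tuple[str, ...] = ("+", "-")

    def __post_init__(self) -> None:
        if self.min_g_run < 2:
            raise ValueError("min_g_run must be >= 2")
        if self.max_loop < 1:
            raise ValueError("max_loop must be >= 1")
        if self.min_islands < 2:
            raise ValueError("min_islands must be >= 2")
        if not set(self.strands) <= {"+", "-"}:
            raise ValueError("strands must be a subset of {+, -}")


@dataclass(frozen=True)
class G4Motif:
    """One maximal G-island chain.

    ``island_starts`` are reference-coordinate offsets of each island,
    ``island_lengths`` the run lengths, ``loop_lengths`` the gaps between
    consecutive islands.  The interval spans the first island start to the
    last island end exactly.  ``sequence`` holds the reference-strand bases
    spanned (the motif-forming strand is ``interval.strand``).
    """

    interval: GenomicInterval
    island_starts: tuple[int, ...]
    island_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    sequence: str = ""

    @property
    def n_islands(self) -> int:
        return len(self.island_starts)

    @property
    def signature(self) -> str:
        """Compact islands:loops description, e.g. ``3,3,3,3:1,1,1``."""
        return (
            ",".join(map(str, self.island_lengths))
            + ":"
            + ",".join(map(str, self.loop_lengths))
        )


def find_g_runs(seq: str, min_len: int, letter: str = "G") -> list[tuple[int, int]]:
    """All maximal runs of ``letter`` with length >= min_len, in order.

    Runs are maximal by construction (regex greediness), hence
    non-overlapping and separated by at least one non-``letter`` base.
    """
    key = (letter, min_len)
    pat = _G_RUN_RE_CACHE.get(key)
    if pat is None:
        pat = re.compile(f"{re.escape(letter)}{{{min_len},}}")
        _G_RUN_RE_CACHE[key] = pat
    return [(m.start(), m.end() - m.start()) for m in pat.finditer(seq)]


def _chain_runs(
    runs: list[tuple[int, int]], params: ScanParams
) -> list[list[tuple[int, int]]]:
    """Greedy maximal chaining of runs whose gaps lie in [1, max_loop]."""
    chains: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for run in runs:
        if not current:
            current = [run]
            continue
        prev_start, prev_len = current[-1]
        gap = run[0] - (prev_start + prev_len)
        if 1 <= gap <= params.max_loop:
            current.append(run)
        else:
            chains.append(current)
            current = [run]
    if current:
        chains.append(current)
    return [c for c in chains if len(c) >= params.min_islands]


def _chains_to_motifs(
    chains: list[list[tuple[int, int]]],
    chrom: str,
    strand: str,
    seq: str,
) -> list[G4Motif]:
    motifs = []
    for chain in chains:
        starts = tuple(s for s, _ in chain)
        lengths = tuple(l for _, l in chain)
        loops = tuple(
            chain[i + 1][0] - (chain[i][0] + chain[i][1])
            for i in range(len(chain) - 1)
        )
        start = chain[0][0]
        end = chain[-1][0] + chain[-1][1]
        motifs.append(
            G4Motif(
                interval=GenomicInterval(chrom, start, end, strand),
                island_starts=starts,
                island_lengths=lengths,
                loop_lengths=loops,
                sequence=seq[start:end],
            )
        )
    return motifs


def scan_plus_strand(
    seq: str, params: ScanParams = ScanParams(), chrom: str = "seq"
) -> list[G4Motif]:
    """Plus-strand motifs in one sequence: maximal G-run chains with every
    gap in [1, max_loop] and at least ``min_islands`` islands, each chain a
    single motif."""
    runs = find_g_runs(seq, params.min_g_run, "G")
    return _chains_to_motifs(_chain_runs(runs, params), chrom, "+", seq)


def scan_minus_strand(
    seq: str, params: ScanParams = ScanParams(), chrom: str = "seq"
) -> list[G4Motif]:
    """Minus-strand motifs: maximal C-run chains on the reference, same gap
    rules, reported in reference coordinates with strand '-'."""
    runs = find_g_runs(seq, params.min_g_run, "C")
    return _chains_to_motifs(_chain_runs(runs, params), chrom, "-", seq)


def scan_genome(
    genome: GenomeSequence, params: ScanParams = ScanParams()
) -> AnnotationTrack:
    """Scan every chromosome on the requested strands.

    Returns an :class:`AnnotationTrack` named ``g4_motifs`` sorted by
    (chrom, start), with per-interval attributes carrying the motif detail
    (``n_islands``, ``signature``, :class:`G4Motif` under ``motif``).
    """
    motifs: list[G4Motif] = []
    for chrom, seq in genome.items():
        if "+" in params.strands:
            motifs.extend(scan_plus_strand(seq, params, chrom))
        if "-" in params.strands:
            motifs.extend(scan_minus_strand(seq, params, chrom))
    motifs.sort(
        key=lambda m: (m.interval.chrom, m.interval.start, m.interval.strand)
    )
    return AnnotationTrack(
        "g4_motifs",
        [m.interval for m in motifs],
        [
            {
                "name": m.signature,
                "score": m.n_islands,
                "n_islands": m.n_islands,
                "motif": m,
            }
            for m in motifs
        ],
    )


def motif_density(n_motifs: int, total_bp: int) -> tuple[float, float]:
    """Motifs per bp and per kb."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    per_bp = n_motifs / total_bp
    return per_bp, per_bp * 1000.0


def count_in_region(motifs: AnnotationTrack, region: GenomicInterval) -> int:
    """Number of motifs strictly overlapping ``region`` (half-open)."""
    return sum(1 for iv in motifs.intervals if iv.overlaps(region))
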