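"""Genome and interval I/O plus the shared interval data model.

All coordinates are 0-based half-open throughout the package.  GFF3 input
(1-based inclusive) is converted at the boundary by subtracting 1 from the
start.  BED and narrowPeak are consumed as-is.  Non-ACGTN characters in
FASTA input are mapped to N (and counted in the log) rather than dropped, so
the scanner sees a consistent alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap on the same chromosome (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class GenomeSequence:
    """Named chromosomes of uppercase A/C/G/T/N sequence.

    Chromosome order is preserved from the source file.
    """

    def __init__(self, chroms: dict[str, str]):
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {bad}"
                )
        self._chroms = dict(chroms)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self._chroms.values())

    def sequence(self, chrom: str) -> str:
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._chroms[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Reference-strand bases spanned by ``interval``."""
        seq = self.sequence(interval.chrom)
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def items(self):
        return self._chroms.items()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeSequence({len(self._chroms)} chromosomes, "
            f"{self.total_size} bp)"
        )


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals with optional per-interval attributes.

    ``attributes``, when present, is a list parallel to ``intervals`` of
    key/value dicts (gene id, expression, essentiality, ...).
    """

    name: str
    intervals: list[GenomicInterval]
    attributes: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        if self.attributes is not None and len(self.attributes) != len(
            self.intervals
        ):
            raise ValueError("attributes must parallel intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "AnnotationTrack":
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
                self.intervals[i].strand,
            ),
        )
        return AnnotationTrack(
            self.name,
            [self.intervals[i] for i in order],
            [self.attributes[i] for i in order] if self.attributes else None,
        )

    def validate_against(self, genome: GenomeSequence) -> None:
        """Hard error if any interval names an unknown chromosome or exceeds
        its bounds; silent misjoins would corrupt every downstream count."""
        lengths = genome.lengths
        for iv in self.intervals:
            if iv.chrom not in lengths:
                raise ValueError(
                    f"track {self.name!r}: chromosome {iv.chrom!r} absent "
                    "from genome"
                )
            if iv.end > lengths[iv.chrom]:
                raise ValueError(
                    f"track {self.name!r}: interval {iv} exceeds chromosome "
                    f"length {lengths[iv.chrom]}"
                )


@dataclass
class PeakSet:
    """Scored intervals from one ChIP-seq experiment.

    ``scores`` are per-peak significances on the -log10 P scale (finite,
    non-negative), as emitted by a MACS-style caller.  ``source_cutoff`` is
    the upstream caller's P threshold, recorded for provenance only.
    """

    factor: str
    condition: str
    peaks: list[GenomicInterval]
    scores: list[float] = field(default_factory=list)
    source_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scores and len(self.scores) != len(self.peaks):
            raise ValueError("scores must parallel peaks")
        for s in self.scores:
            if not (s >= 0 and s == s and s != float("inf")):
                raise ValueError(
                    f"peak significance {s!r} not finite/non-negative"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def as_track(self) -> AnnotationTrack:
        attrs = (
            [{"significance": s} for s in self.scores] if self.scores else None
        )
        return AnnotationTrack(
            f"{self.factor}/{self.condition}", list(self.peaks), attrs
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Raised on malformed input files."""


def read_fasta(path) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; any character outside {A,C,G,T,N} becomes N and
    the substitution count is logged.  Duplicate headers and empty files are
    format errors.
    """
    chroms: dict[str, str] = {}
    n_subst = 0
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chroms:
            raise FormatError(f"duplicate FASTA header {name!r}")
        seq = str(record.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in VALID_BASES:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_subst += 1
        chroms[name] = "".join(cleaned)
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    if n_subst:
        logger.info(
            "read_fasta: mapped %d non-ACGTN characters to N", n_subst
        )
    return GenomeSequence(chroms)


def _parse_strand(token: str) -> str:
    return token if token in ("+", "-") else "."


def read_intervals(path, format: str, **kwargs):
    """Read an interval file into an :class:`AnnotationTrack` or
    :class:`PeakSet`.

    Parameters
    ----------
    format : {"BED", "GFF3", "narrowPeak"}
        BED start/end are used as-is (0-based half-open); GFF3 starts are
        shifted by -1 (1-based inclusive -> half-open); narrowPeak column 8
        (-log10 P) becomes the peak significance and a :class:`PeakSet` is
        returned (``factor``/``condition`` from keyword arguments).
    """
    fmt = format.lower()
    path = Path(path)
    name = kwargs.pop("name", path.stem)

    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            lines.append((lineno, line.split("\t")))

    if fmt == "bed":
        intervals, attrs = [], []
        for lineno, f in lines:
            try:
                start, end = int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED") from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end <= start ({start}, {end})"
                )
            strand = _parse_strand(f[5]) if len(f) > 5 else "."
            intervals.append(GenomicInterval(f[0], start, end, strand))
            attrs.append(
                {"name": f[3] if len(f) > 3 else ".",
                 "score": f[4] if len(f) > 4 else "."}
            )
        return AnnotationTrack(name, intervals, attrs)

    if fmt == "gff3":
        intervals, attrs = [], []
        for lineno, f in lines:
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: malformed GFF3")
            start = int(f[3]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(f[4])
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end <= start after conversion"
                )
            strand = _parse_strand(f[6])
            attr: dict = {"type": f[2]}
            if len(f) > 8 and f[8] not in (".", ""):
                for kv in f[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attr[k.strip()] = v.strip()
            intervals.append(GenomicInterval(f[0], start, end, strand))
            attrs.append(attr)
        return AnnotationTrack(name, intervals, attrs)

    if fmt == "narrowpeak":
        peaks, scores = [], []
        for lineno, f in lines:
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: malformed narrowPeak")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end <= start ({start}, {end})"
                )
            strand = _parse_strand(f[5]) if len(f) > 5 else "."
            peaks.append(GenomicInterval(f[0], start, end, strand))
            scores.append(float(f[7]))  # column 8: -log10 P
        return PeakSet(
            factor=kwargs.pop("factor", name),
            condition=kwargs.pop("condition", ""),
            peaks=peaks,
            scores=scores,
            source_cutoff=kwargs.pop("source_cutoff", None),
        )

    raise ValueError(f"unknown interval format {format!r}")


def write_intervals(track, path, format: str = "BED6") -> None:
    """Write a track (or PeakSet) to disk as BED6 or TSV.

    BED6 round-trips through :func:`read_intervals`: name and score columns
    come from the attributes when present, else ``.``/``0``.
    """
    fmt = format.lower()
    if isinstance(track, PeakSet):
        track = track.as_track()
    with open(path, "w") as fh:
        if fmt == "bed6":
            for i, iv in enumerate(track.intervals):
                attr = track.attributes[i] if track.attributes else {}
                name = str(attr.get("name", "."))
                score = str(attr.get("score", 0))
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t"
                    f"{iv.strand if iv.strand != '.' else '.'}\n"
                )
        elif fmt == "tsv":
            keys: list[str] = []
            if track.attributes:
                seen = set()
                for a in track.attributes:
                    for k in a:
                        if k not in seen:
                            seen.add(k)
                            keys.append(k)
            header = ["chrom", "start", "end", "strand"] + keys
            fh.write("\t".join(header) + "\n")
            for i, iv in enumerate(track.intervals):
                attr = track.attributes[i] if track.attributes else {}
                row = [iv.chrom, str(iv.start), str(iv.end), iv.strand]
                row += [str(attr.get(k, "")) for k in keys]
                fh.write("\t".join(row) + "\n")
        else:
            raise ValueError(f"unknown output format {format!r}")
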