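"""Synthetic genomes, annotations and peak sets with known ground truth.

The generator emulates the study conditions of a small yeast-like genome:
three chromosomes totalling ~12.6 Mb at 36% GC (i.i.d. bases with the GC
mass split evenly between G and C), a few hundred planted G4 motifs, MACS-
style peak sets whose lengths follow a truncated Normal(1838, 983) bp, and
stranded feature tracks with controlled motif co-location.  Every generator
is deterministic per seed and returns its truth set alongside the data, so
downstream recovery can be checked exactly.

Planted motifs use a fixed template with 1 bp loops (GGGTGGGTGGGTGGG, or
its complement for the minus strand) so scanner detection is unambiguous
against background; spurious background motifs are expected at realistic GC
and are identified by comparing the pre-plant and post-plant scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from g4atlas.g4scan import ScanParams, scan_genome
from g4atlas.sequence_io import (
    AnnotationTrack,
    GenomeSequence,
    GenomicInterval,
    PeakSet,
    revcomp,
)

DEFAULT_MOTIF_TEMPLATE = "GGGTGGGTGGGTGGG"


@dataclass(frozen=True)
class FeatureClassSpec:
    """One synthetic feature class (promoters, ORFs, NDRs, ...).

    ``motif_colocation`` is the fraction of features placed overlapping a
    randomly chosen true motif; the rest are uniform.  ``expressed`` classes
    get a log-normal ``expression`` attribute per feature.
    """

    name: str
    count: int
    length_mean: float = 500.0
    length_sd: float = 100.0
    stranded: bool = False
    motif_colocation: float = 0.0
    expressed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_colocation <= 1.0):
            raise ValueError("motif_colocation must lie in [0, 1]")


@dataclass(frozen=True)
class PeakSpec:
    """One synthetic (factor, condition) peak set.

    ``motif_fraction`` of true motifs receive an overlapping signal peak;
    background peaks are placed uniformly at ``background_per_mb``.  Peak
    lengths are Normal(length_mean, length_sd) truncated at 100 bp;
    significances (-log10 P) are uniform over the signal/background ranges,
    signal above background on average.
    """

    factor: str
    condition: str
    motif_fraction: float = 0.2
    background_per_mb: float = 5.0
    length_mean: float = 1838.0
    length_sd: float = 983.0
    sig_signal: tuple[float, float] = (8.0, 30.0)
    sig_background: tuple[float, float] = (5.0, 8.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_fraction <= 1.0):
            raise ValueError("motif_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Defaults emulate the study conditions: a 12.6 Mb three-chromosome
    genome at 36% GC with 446 planted motifs and ~20% of motifs bound by
    the helicase."""

    chrom_lengths: tuple[int, ...] = (5_600_000, 4_600_000, 2_400_000)
    gc_fraction: float = 0.36
    n_planted_motifs: int = 446
    motif_template: str = DEFAULT_MOTIF_TEMPLATE
    minus_strand_fraction: float = 0.5
    plant_spacing: int = 0  # minimum bp between planted sites
    feature_classes: tuple[FeatureClassSpec, ...] = ()
    peak_specs: tuple[PeakSpec, ...] = (
        PeakSpec("pfh1", "wt", motif_fraction=0.20),
        PeakSpec("cdc20", "wt", motif_fraction=0.11, length_mean=1526, length_sd=717),
        PeakSpec("cdc20", "depleted", motif_fraction=0.17, length_mean=1666, length_sd=860),
        PeakSpec("gh2a", "wt", motif_fraction=0.17, length_mean=1486, length_sd=742),
        PeakSpec("gh2a", "depleted", motif_fraction=0.40, length_mean=1974, length_sd=1071),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must lie in [0, 1)")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> GenomeSequence:
    """i.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {}
    for name, length in zip(spec.chrom_names(), spec.chrom_lengths):
        idx = rng.choice(4, size=length, p=probs)
        chroms[name] = _BASES[idx].tobytes().decode("ascii")
    return GenomeSequence(chroms)


def _draw_nonoverlapping_positions(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    site_len: int,
    spacing: int = 0,
    max_tries: int = 200,
) -> list[tuple[str, int]]:
    """Uniform non-overlapping (chrom, start) placements, genome-weighted,
    keeping at least ``spacing`` bp between sites."""
    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    out: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            limit = chrom_lengths[chrom] - site_len
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + site_len
            if all(
                end + spacing <= s or start >= e + spacing
                for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                out.append((chrom, start))
                break
        else:
            raise ValueError(
                f"could not place {n} non-overlapping sites of {site_len} bp"
            )
    return out


def plant_motifs(
    genome: GenomeSequence,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, AnnotationTrack]:
    """Overwrite the genome with motif-template instances at uniform
    non-overlapping positions; returns the new genome and the truth track.

    Minus-strand plantings write the template's reverse complement on the
    reference.  A post-plant scan is guaranteed to report a motif covering
    every planted interval (background motifs may merge with or add to
    them; compare against a pre-plant scan to identify those).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    template = spec.motif_template
    site_len = len(template)
    # 1 bp neutral padding so a planted site cannot extend an adjacent run
    pad_len = site_len + 2
    lengths = genome.lengths
    placements = _draw_nonoverlapping_positions(
        rng, lengths, spec.n_planted_motifs, pad_len, spec.plant_spacing
    )
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    intervals: list[GenomicInterval] = []
    for chrom, pad_start in placements:
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        insert = template if strand == "+" else revcomp(template)
        start = pad_start + 1
        seqs[chrom][pad_start : pad_start + 1] = b"A" if strand == "+" else b"T"
        seqs[chrom][start : start + site_len] = insert.encode("ascii")
        seqs[chrom][start + site_len : start + site_len + 1] = (
            b"A" if strand == "+" else b"T"
        )
        intervals.append(
            GenomicInterval(chrom, start, start + site_len, strand)
        )
    new_genome = GenomeSequence(
        {c: bytes(b).decode("ascii") for c, b in seqs.items()}
    )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return new_genome, AnnotationTrack("planted_motifs", intervals)


def synth_features(
    genome: GenomeSequence,
    spec: SimulationSpec,
    truth: AnnotationTrack,
    rng: np.random.Generator | None = None,
) -> dict[str, AnnotationTrack]:
    """Synthetic feature tracks with controlled motif co-location.

    For each class, ``count`` intervals are placed; a ``motif_colocation``
    fraction overlap randomly chosen truth motifs, the remainder are
    uniform.  Stranded classes get random strands; expressed classes get a
    log-normal ``expression`` attribute.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    lengths = genome.lengths
    names = list(lengths)
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    tracks: dict[str, AnnotationTrack] = {}
    for fclass in spec.feature_classes:
        intervals: list[GenomicInterval] = []
        attrs: list[dict] = []
        n_coloc = int(round(fclass.count * fclass.motif_colocation))
        if n_coloc > 0 and len(truth) == 0:
            raise ValueError("co-location requested but truth track empty")
        for i in range(fclass.count):
            flen = max(
                50, int(round(rng.normal(fclass.length_mean, fclass.length_sd)))
            )
            if i < n_coloc:
                m = truth.intervals[int(rng.integers(0, len(truth)))]
                flen = max(flen, m.length + 2)
                lo = max(0, m.end - flen + 1)
                hi = min(lengths[m.chrom] - flen, m.start)
                if hi < lo:
                    start = min(lo, lengths[m.chrom] - flen)
                else:
                    start = int(rng.integers(lo, hi + 1))
                chrom = m.chrom
            else:
                chrom = names[rng.choice(len(names), p=weights)]
                limit = lengths[chrom] - flen
                if limit <= 0:
                    raise ValueError(
                        f"feature of {flen} bp does not fit on {chrom}"
                    )
                start = int(rng.integers(0, limit + 1))
            strand = (
                ("+", "-")[int(rng.integers(0, 2))] if fclass.stranded else "."
            )
            intervals.append(
                GenomicInterval(chrom, start, start + flen, strand)
            )
            attr = {"name": f"{fclass.name}_{i}", "gene_id": f"{fclass.name}_{i}"}
            if fclass.expressed:
                attr["expression"] = float(rng.lognormal(3.0, 1.0))
            attrs.append(attr)
        tracks[fclass.name] = AnnotationTrack(fclass.name, intervals, attrs)
    return tracks


def synth_peaks(
    genome: GenomeSequence,
    truth: AnnotationTrack,
    pspec: PeakSpec,
    rng: np.random.Generator | None = None,
    peaked_indices: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[PeakSet, np.ndarray]:
    """Synthetic MACS-like peak set for one (factor, condition).

    A ``motif_fraction`` subset of truth motifs (or the explicit
    ``peaked_indices``) receives an overlapping signal peak; background
    peaks are uniform at ``background_per_mb``.  Returns the peak set and
    the boolean truth mask of peaked motifs.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    lengths = genome.lengths
    names = list(lengths)
    weights = np.array([lengths[c] for c in names], dtype=float)
    total_bp = weights.sum()
    weights /= weights.sum()
    n_motifs = len(truth)
    if peaked_indices is None:
        n_signal = int(round(pspec.motif_fraction * n_motifs))
        peaked_indices = rng.choice(n_motifs, size=n_signal, replace=False)
    mask = np.zeros(n_motifs, dtype=bool)
    mask[np.asarray(peaked_indices, dtype=int)] = True

    peaks: list[GenomicInterval] = []
    scores: list[float] = []

    def draw_len() -> int:
        return max(100, int(round(rng.normal(pspec.length_mean, pspec.length_sd))))

    for idx in np.sort(np.asarray(peaked_indices, dtype=int)):
        m = truth.intervals[idx]
        plen = draw_len()
        # centre the peak on the motif (guaranteed overlap at any window)
        centre = (m.start + m.end) // 2
        start = max(0, centre - plen // 2)
        end = min(lengths[m.chrom], start + plen)
        if end - start < 50:
            start, end = m.start, m.end
        peaks.append(GenomicInterval(m.chrom, start, end))
        scores.append(float(rng.uniform(*pspec.sig_signal)))

    n_background = rng.poisson(pspec.background_per_mb * total_bp / 1e6)
    for _ in range(n_background):
        chrom = names[rng.choice(len(names), p=weights)]
        plen = draw_len()
        limit = lengths[chrom] - plen
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit + 1))
        peaks.append(GenomicInterval(chrom, start, start + plen))
        scores.append(float(rng.uniform(*pspec.sig_background)))

    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    return (
        PeakSet(
            factor=pspec.factor,
            condition=pspec.condition,
            peaks=[peaks[i] for i in order],
            scores=[scores[i] for i in order],
            source_cutoff=1e-5,
        ),
        mask,
    )


def simulate(spec: SimulationSpec) -> dict:
    """Run the full generator: genome, planted motifs, features, peaks.

    Returns a dict with keys ``genome``, ``truth``, ``features`` (dict of
    tracks), ``peaks`` (dict of (factor, condition) -> PeakSet) and
    ``peak_truth`` (dict of matching boolean masks).
    """
    rng = np.random.default_rng(spec.seed)
    genome = random_genome(spec, rng)
    genome, truth = plant_motifs(genome, spec, rng)
    features = synth_features(genome, spec, truth, rng)
    peaks: dict[tuple[str, str], PeakSet] = {}
    peak_truth: dict[tuple[str, str], np.ndarray] = {}
    for pspec in spec.peak_specs:
        ps, mask = synth_peaks(genome, truth, pspec, rng)
        peaks[(pspec.factor, pspec.condition)] = ps
        peak_truth[(pspec.factor, pspec.condition)] = mask
    return {
        "genome": genome,
        "truth": truth,
        "features": features,
        "peaks": peaks,
        "peak_truth": peak_truth,
    }


def expected_density_by_simulation(
    gc: float,
    total_bp: int,
    params: ScanParams = ScanParams(),
    seed: int = 0,
    n_chunks: int = 10,
) -> tuple[float, float]:
    """Monte-Carlo expected motif density (per kb) in i.i.d. sequence of
    the given GC, with the standard error over replicate chunks."""
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks for a standard error")
    chunk = max(1, total_bp // n_chunks)
    rng = np.random.default_rng(seed)
    densities = []
    for _ in range(n_chunks):
        g = random_genome(
            SimulationSpec(chrom_lengths=(chunk,), gc_fraction=gc, seed=0),
            rng,
        )
        n = len(scan_genome(g, params))
        densities.append(n / chunk * 1000.0)
    arr = np.array(densities)
    se = float(arr.std(ddof=1) / np.sqrt(n_chunks))
    return float(arr.mean()), se
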