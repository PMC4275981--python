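import numpy as np
import pytest

from g4atlas.sequence_io import GenomeSequence, GenomicInterval, AnnotationTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome():
    """Tiny deterministic two-chromosome genome."""
    return GenomeSequence(
        {
            "chr1": "ACGTGGGTGGGTGGGTGGGACGTACGTNNACGT",
            "chr2": "CCCACCCACCCACCCTTTT",
        }
    )


@pytest.fixture
def random_genome_100kb(rng):
    """100 kb single-chromosome i.i.d. genome at 38% GC."""
    from g4atlas.synthetic_data import SimulationSpec, random_genome

    spec = SimulationSpec(chrom_lengths=(100_000,), gc_fraction=0.38, seed=11)
    return random_genome(spec, np.random.default_rng(11))


def random_track(rng, n, chrom_lengths, stranded=True, max_len=500):
    """Random interval track within the given chromosome bounds."""
    names = list(chrom_lengths)
    intervals = []
    for _ in range(n):
        chrom = names[rng.integers(0, len(names))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
        strand = ("+", "-")[rng.integers(0, 2)] if stranded else "."
        intervals.append(GenomicInterval(chrom, start, start + length, strand))
    return AnnotationTrack("random", intervals)
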