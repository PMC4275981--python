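"""Motif-feature association counting, empirical P-values against the
matched-control null, Storey q-values, and gene strand bias.

Association is interval-based: with window 0, two intervals are associated
iff they strictly overlap; with window w > 0 they are associated iff they
overlap or the gap between them (bases strictly in between) is <= w.  A
query element is counted at most once no matter how many subject elements
it touches.

The empirical P-value for an observed association count against the
control-set null defaults to the add-one estimator (b+1)/(n+1), where b is
the number of control sets at least as extreme as the observed count (ties
count as extreme on both sides); a "literal" b/n mode is provided for
comparison with historical reports in which zero exceedances print as
P < 1/n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from g4atlas.matched_controls import ControlSetCollection
from g4atlas.sequence_io import AnnotationTrack, GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interval association
# ---------------------------------------------------------------------------


def associated(
    a: GenomicInterval, b: GenomicInterval, window: int = 0
) -> bool:
    """True iff ``a`` and ``b`` are on the same chromosome and overlap, or
    (for window > 0) lie within ``window`` bases of each other.

    The gap between disjoint intervals is the number of bases strictly
    between them, so [0,10) and [10,20) have gap 0: associated at any
    window >= 1 but not at window 0.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if a.chrom != b.chrom:
        return False
    if a.start < b.end and b.start < a.end:
        return True
    if window == 0:
        return False
    gap = max(a.start - b.end, b.start - a.end)
    return gap <= window


class _SubjectIndex:
    """Per-chromosome start/end arrays for vectorised association checks."""

    def __init__(self, intervals: list[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.by_chrom = {
            chrom: (
                np.array([p[0] for p in pairs], dtype=np.int64),
                np.array([p[1] for p in pairs], dtype=np.int64),
            )
            for chrom, pairs in by_chrom.items()
        }

    def any_associated(self, iv: GenomicInterval, window: int) -> bool:
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        if window == 0:
            return bool(np.any((starts < iv.end) & (iv.start < ends)))
        return bool(
            np.any((starts <= iv.end + window) & (ends >= iv.start - window))
        )


def count_associated(
    query: AnnotationTrack | list[GenomicInterval],
    subject: AnnotationTrack | list[GenomicInterval],
    window: int = 0,
) -> int:
    """Number of query elements with at least one associated subject element
    (each query counted once)."""
    q = query.intervals if isinstance(query, AnnotationTrack) else query
    s = subject.intervals if isinstance(subject, AnnotationTrack) else subject
    index = _SubjectIndex(s)
    return sum(1 for iv in q if index.any_associated(iv, window))


def association_mask(
    query: AnnotationTrack | list[GenomicInterval],
    subject: AnnotationTrack | list[GenomicInterval],
    window: int = 0,
) -> np.ndarray:
    """Boolean vector: query element i has >= 1 associated subject."""
    q = query.intervals if isinstance(query, AnnotationTrack) else query
    s = subject.intervals if isinstance(subject, AnnotationTrack) else subject
    index = _SubjectIndex(s)
    return np.array([index.any_associated(iv, window) for iv in q], dtype=bool)


# ---------------------------------------------------------------------------
# Empirical P and the enrichment test
# ---------------------------------------------------------------------------


def empirical_p(
    observed: int,
    null_counts,
    direction: str = "enriched",
    mode: str = "add_one",
) -> float:
    """Empirical P-value of an observed count against resampled null counts.

    ``direction='enriched'`` counts null sets with count >= observed,
    ``'depleted'`` those with count <= observed (ties are extreme).  The
    default ``add_one`` estimator returns (b+1)/(n+1), never exactly zero;
    ``mode='literal'`` returns b/n.
    """
    nulls = np.asarray(null_counts)
    if nulls.size == 0:
        raise ValueError("null_counts is empty")
    if direction == "enriched":
        b = int(np.sum(nulls >= observed))
    elif direction == "depleted":
        b = int(np.sum(nulls <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = nulls.size
    if mode == "add_one":
        return (b + 1) / (n + 1)
    if mode == "literal":
        return b / n
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EnrichmentResult:
    """Observed vs. null association of a motif set with one feature class."""

    feature_name: str
    observed_overlap: int
    expected_overlap: float
    null_counts: np.ndarray
    direction: str
    p_value: float
    q_value: float | None = None
    window: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1) and self.p_value != 0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def enrichment_test(
    motifs: AnnotationTrack,
    control_sets: ControlSetCollection,
    feature_track: AnnotationTrack,
    window: int = 0,
    mode: str = "add_one",
) -> EnrichmentResult:
    """Compare the observed motif-feature association count to the
    control-set null.

    Direction is ``enriched`` iff observed > null mean; the reported P is
    the one-sided empirical P for that direction.
    """
    if control_sets.n_motifs != len(motifs):
        raise ValueError(
            f"control sets built for {control_sets.n_motifs} motifs, "
            f"got {len(motifs)}"
        )
    index = _SubjectIndex(feature_track.intervals)
    observed = sum(
        1 for iv in motifs.intervals if index.any_associated(iv, window)
    )
    nulls = np.array(
        [
            sum(1 for iv in s if index.any_associated(iv, window))
            for s in control_sets.sets
        ],
        dtype=np.int64,
    )
    expected = float(nulls.mean())
    direction = "enriched" if observed > expected else "depleted"
    p = empirical_p(observed, nulls, direction=direction, mode=mode)
    return EnrichmentResult(
        feature_name=feature_track.name,
        observed_overlap=observed,
        expected_overlap=expected,
        null_counts=nulls,
        direction=direction,
        p_value=p,
        window=window,
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def _bh(p: np.ndarray, pi0: float) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def estimate_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Storey pi0: the fraction of true nulls, estimated from the flatness
    of the P-value histogram above a grid of lambda thresholds, smoothed by
    a cubic fit and read off at the largest lambda.  Clamped to (0, 1]."""
    if lambdas is None:
        lambdas = np.arange(0.0, 0.95, 0.05)  # 0, 0.05, ..., 0.90
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    try:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    except Exception:
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def qvalues(
    p_values,
    pi0: float | None = None,
    min_tests_for_pi0: int = 20,
) -> np.ndarray:
    """Storey q-values.

    q_i = min over p_j >= p_i of (pi0 * n * p_j / rank_j).  pi0 is estimated
    with :func:`estimate_pi0` unless given; with fewer than
    ``min_tests_for_pi0`` tests (or a failed fit) pi0 falls back to 1 and
    the result equals Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = 1.0 if p.size < min_tests_for_pi0 else estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    return _bh(p, pi0)


# ---------------------------------------------------------------------------
# Strand bias and expression ranking
# ---------------------------------------------------------------------------


def strand_bias_in_genes(
    motifs: AnnotationTrack, gene_track: AnnotationTrack
) -> tuple[int, int, float]:
    """Transcribed-strand bias of motifs inside stranded genes.

    A motif overlapping a gene lies on the transcribed (template) strand iff
    its strand differs from the gene's strand (the motif is then absent from
    the mRNA).  A motif overlapping several genes is assigned to the gene
    with the largest overlap, ties to the first gene in sorted order
    (logged).  Returns (n_transcribed_strand, n_in_genes, two-sided exact
    binomial P at null probability 0.5).
    """
    genes = sorted(
        gene_track.intervals, key=lambda g: (g.chrom, g.start, g.end)
    )
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene interval {g} is unstranded")
    n_total = 0
    n_template = 0
    for m in motifs.intervals:
        if m.strand not in ("+", "-"):
            continue
        best = None
        best_ov = 0
        for g in genes:
            if g.chrom != m.chrom:
                continue
            ov = min(m.end, g.end) - max(m.start, g.start)
            if ov > 0 and ov > best_ov:
                best, best_ov = g, ov
            elif ov > 0 and ov == best_ov and best is not None:
                logger.debug(
                    "strand_bias_in_genes: tie for motif %s resolved to "
                    "first gene in sorted order",
                    m,
                )
        if best is None:
            continue
        n_total += 1
        if m.strand != best.strand:
            n_template += 1
    if n_total == 0:
        return 0, 0, 1.0
    p = stats.binomtest(n_template, n_total, 0.5).pvalue
    return n_template, n_total, float(p)


def select_top_expressed(gene_track: AnnotationTrack, n: int) -> AnnotationTrack:
    """The ``n`` genes with the highest ``expression`` attribute.

    Ties broken by gene id (``gene_id`` or ``name`` attribute), logged.  If
    ``n`` exceeds the track size the whole track is returned.
    """
    if gene_track.attributes is None:
        raise ValueError("gene track has no attributes")
    rows = []
    for iv, attr in zip(gene_track.intervals, gene_track.attributes):
        if "expression" not in attr:
            raise ValueError(f"gene {attr} lacks an expression attribute")
        gid = str(attr.get("gene_id", attr.get("name", "")))
        rows.append((float(attr["expression"]), gid, iv, attr))
    rows.sort(key=lambda r: (-r[0], r[1]))
    if len(rows) > n and rows[n - 1][0] == rows[n][0]:
        logger.info(
            "select_top_expressed: expression tie at the n=%d boundary "
            "broken by gene id",
            n,
        )
    top = rows[:n]
    return AnnotationTrack(
        f"{gene_track.name}_top{n}",
        [r[2] for r in top],
        [r[3] for r in top],
    )
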