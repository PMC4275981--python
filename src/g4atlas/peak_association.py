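"""Motif-peak association, helicase-dependence classification, and the
contingency statistics.

Motifs are associated with ChIP-seq peak sets within factor-specific
windows (300 bp for helicase and polymerase occupancy, matching the DNA
shearing size; 5 kb for the phospho-H2A damage mark, which spreads several
kb around a break).  Association columns for five (factor, condition)
experiments feed a three-way classification:

* Class I   -- motifs bound by the helicase in wild-type cells;
* Class II  -- motifs showing fork pausing and/or DNA damage only when the
  helicase is depleted;
* Class III -- motifs showing pausing/damage in both conditions.

Class II and Class III are disjoint by construction; Class I may intersect
either.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from g4atlas.feature_enrichment import associated
from g4atlas.sequence_io import AnnotationTrack, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = {"pfh1": 300, "cdc20": 300, "gh2a": 5000}


@dataclass
class AssociationVectors:
    """Motif-side and peak-side association masks for one peak set."""

    motif_mask: np.ndarray  # bool per motif: >=1 peak within window
    peak_mask: np.ndarray  # bool per peak: >=1 motif within window

    @property
    def n_motifs_associated(self) -> int:
        return int(self.motif_mask.sum())

    @property
    def n_peaks_associated(self) -> int:
        return int(self.peak_mask.sum())


def associate_motifs(
    motifs: AnnotationTrack, peaks: PeakSet, window: int
) -> AssociationVectors:
    """Associate motifs with a peak set at the given window.

    Several peaks may hit one motif and one peak may hit several motifs;
    both directions are reported.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    m_ivs = motifs.intervals
    p_ivs = peaks.peaks
    motif_mask = np.zeros(len(m_ivs), dtype=bool)
    peak_mask = np.zeros(len(p_ivs), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for j, p in enumerate(p_ivs):
        by_chrom.setdefault(p.chrom, []).append(j)
    for i, m in enumerate(m_ivs):
        for j in by_chrom.get(m.chrom, ()):
            if associated(m, p_ivs[j], window):
                motif_mask[i] = True
                peak_mask[j] = True
    return AssociationVectors(motif_mask, peak_mask)


@dataclass
class MotifAssociationMatrix:
    """Per-motif boolean association columns, one per (factor, condition).

    Canonical column names: ``pfh1_wt``, ``cdc20_wt``, ``cdc20_depleted``,
    ``gh2a_wt``, ``gh2a_depleted``.  ``windows`` records the bp window used
    for each column.
    """

    motif_ids: list[str]
    columns: dict[str, np.ndarray]
    windows: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.motif_ids)
        for name, col in self.columns.items():
            if len(col) != n:
                raise ValueError(
                    f"column {name!r} has length {len(col)}, expected {n}"
                )

    def column(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise KeyError(f"missing association column {name!r}")
        return np.asarray(self.columns[name], dtype=bool)


def build_association_matrix(
    motifs: AnnotationTrack,
    peak_sets: dict[str, PeakSet],
    windows: dict[str, int],
) -> MotifAssociationMatrix:
    """Run :func:`associate_motifs` for every named peak set."""
    ids = [
        f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        for iv in motifs.intervals
    ]
    columns = {
        name: associate_motifs(motifs, ps, windows[name]).motif_mask
        for name, ps in peak_sets.items()
    }
    return MotifAssociationMatrix(ids, columns, dict(windows))


@dataclass
class MotifClassLabels:
    """Boolean membership vectors for the three motif classes."""

    class_I: np.ndarray
    class_II: np.ndarray
    class_III: np.ndarray

    def sizes(self) -> tuple[int, int, int]:
        return (
            int(self.class_I.sum()),
            int(self.class_II.sum()),
            int(self.class_III.sum()),
        )


REQUIRED_COLUMNS = (
    "pfh1_wt",
    "cdc20_wt",
    "cdc20_depleted",
    "gh2a_wt",
    "gh2a_depleted",
)


def classify_motifs(assoc: MotifAssociationMatrix) -> MotifClassLabels:
    """Classify motifs by helicase dependence.

    instability(c) = cdc20(c) OR gh2a(c).  Class I = pfh1_wt; Class II =
    instability(depleted) AND NOT instability(wt); Class III =
    instability(wt) AND instability(depleted).  Class II and III are
    disjoint by construction.
    """
    cols = {name: assoc.column(name) for name in REQUIRED_COLUMNS}
    instability_wt = cols["cdc20_wt"] | cols["gh2a_wt"]
    instability_dep = cols["cdc20_depleted"] | cols["gh2a_depleted"]
    return MotifClassLabels(
        class_I=cols["pfh1_wt"].copy(),
        class_II=instability_dep & ~instability_wt,
        class_III=instability_wt & instability_dep,
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table: rows = stratum true/false, columns = outcome
    true/false.  a,b = stratum-true row; c,d = stratum-false row."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be > 0")

    def row_percentages(self) -> tuple[float, float]:
        """Percent outcome-positive in each row."""
        r1 = self.a + self.b
        r2 = self.c + self.d
        return (
            100.0 * self.a / r1 if r1 else float("nan"),
            100.0 * self.c / r2 if r2 else float("nan"),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> float:
    """Fisher's exact P on a 2x2 table.

    The default is two-sided by the minimum-likelihood rule: the sum of
    hypergeometric probabilities (margins fixed) of all tables whose point
    probability does not exceed the observed one.  ``alternative`` may also
    be ``greater``/``less`` for a one-sided test (some published tables are
    one-sided; for highly extreme tables the conventions coincide).
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("table has an all-zero margin")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def build_table(
    assoc: MotifAssociationMatrix, stratum_col: str, outcome_col: str
) -> ContingencyTable2x2:
    """Cross-tabulate two association columns over all motifs."""
    s = assoc.column(stratum_col)
    o = assoc.column(outcome_col)
    return ContingencyTable2x2(
        a=int(np.sum(s & o)),
        b=int(np.sum(s & ~o)),
        c=int(np.sum(~s & o)),
        d=int(np.sum(~s & ~o)),
    )


def contingency_from_counts(
    n_stratum: int, k_stratum: int, n_rest: int, k_rest: int
) -> ContingencyTable2x2:
    """Build a table from row totals and outcome-positive counts, the form
    in which published tables report them."""
    return ContingencyTable2x2(
        a=k_stratum, b=n_stratum - k_stratum, c=k_rest, d=n_rest - k_rest
    )


def paired_peak_significance_comparison(
    motifs: AnnotationTrack,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    window: int,
) -> tuple[float, float, float]:
    """Per-motif best peak P-values in two conditions, compared pairwise.

    For each motif, take the most significant overlapping peak's P (i.e.
    the maximum -log10 P, converted back) within the window in each peak
    set; motifs with no peak in a given condition get P = 1.  Returns
    (mean_pA, mean_pB, two-sided Wilcoxon signed-rank P over the paired
    vectors with zero-differences dropped).  Comparability assumes both
    peak sets derive from equal-depth sequencing upstream; this is
    documented, not enforced.
    """

    def best_p(peak_set: PeakSet) -> np.ndarray:
        if not peak_set.scores:
            raise ValueError(
                f"peak set {peak_set.factor}/{peak_set.condition} has no "
                "significance scores"
            )
        by_chrom: dict[str, list[int]] = {}
        for j, p in enumerate(peak_set.peaks):
            by_chrom.setdefault(p.chrom, []).append(j)
        out = np.ones(len(motifs), dtype=float)
        for i, m in enumerate(motifs.intervals):
            best = 0.0  # max -log10 P among associated peaks
            for j in by_chrom.get(m.chrom, ()):
                if associated(m, peak_set.peaks[j], window):
                    best = max(best, peak_set.scores[j])
            if best > 0:
                out[i] = 10.0 ** (-best)
        return out

    pa = best_p(peaks_a)
    pb = best_p(peaks_b)
    diffs = pa - pb
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn(
            "all paired differences are zero; signed-rank test degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(pa.mean()), float(pb.mean()), 1.0
    res = stats.wilcoxon(
        pa, pb, zero_method="wilcox", alternative="two-sided"
    )
    return float(pa.mean()), float(pb.mean()), float(res.pvalue)
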