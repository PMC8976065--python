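"""Replicate-consensus AR-binding-site (ARBS) calling and classification.

The chain implemented here mirrors how a control-locus-calibrated ChIP-seq
cistrome comparison is run in practice:

1. calibrate a genome-wide q-value threshold on a positive control locus
   (an androgen-responsive enhancer, e.g. the KLK3 enhancer) and a negative
   control locus (a housekeeping promoter, e.g. GAPDH);
2. apply the threshold to every sample's peak calls;
3. merge surviving peaks across replicates (single-linkage on >= 1 bp
   overlap) and keep clusters supported by a minimum number of replicates;
4. annotate consensus sites to genes via the gene body or a strand-aware
   upstream promoter window (20 kb by default);
5. classify genes as condition-exclusive or shared by binding-signal fold
   change, and summarise as Venn counts and cross-study overlap percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import CalibrationError, ConfigError, DataError
from .io import GeneModel, Peak

__all__ = [
    "Interval",
    "CalibrationSpec",
    "ConsensusARBS",
    "GeneBindingTable",
    "DifferentialPartition",
    "calibrate_q_threshold",
    "filter_peaks",
    "call_consensus_arbs",
    "annotate_arbs_to_genes",
    "classify_differential_genes",
    "venn_counts",
    "cross_study_overlap",
]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise DataError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class CalibrationSpec:
    """Control-locus design for q-value threshold calibration.

    ``positive_samples`` are samples in which the positive control locus must
    be called; ``negative_samples`` are samples in which it must not be.
    ``cap`` is the fallback threshold when the negatives impose no bound.
    """

    positive_locus: Interval
    negative_locus: Interval
    positive_samples: tuple[str, ...]
    negative_samples: tuple[str, ...]
    cap: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "positive_samples", tuple(self.positive_samples))
        object.__setattr__(self, "negative_samples", tuple(self.negative_samples))
        if not self.positive_samples or not self.negative_samples:
            raise ConfigError("positive and negative sample lists must be nonempty")
        if set(self.positive_samples) & set(self.negative_samples):
            raise ConfigError("positive and negative sample lists must be disjoint")
        if not 0 < self.cap <= 1:
            raise ConfigError(f"cap {self.cap} outside (0, 1]")


@dataclass(frozen=True)
class ConsensusARBS:
    """A merged cross-replicate binding site."""

    chrom: str
    start: int
    end: int
    support: int
    condition: str
    mean_signal: float

    def __post_init__(self):
        if self.support < 1:
            raise DataError("consensus support must be >= 1")
        if self.mean_signal < 0:
            raise DataError("mean_signal must be >= 0")


@dataclass
class GeneBindingTable:
    """Per-gene binding status and best signal for one condition.

    A gene is bound iff it appears in ``signals``; the stored value is the
    max mean_signal over annotating consensus sites.
    """

    condition: str
    universe: tuple[str, ...]
    signals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.universe = tuple(self.universe)
        unknown = set(self.signals) - set(self.universe)
        if unknown:
            raise DataError(f"bound genes outside the universe: {sorted(unknown)[:5]}")

    def bound(self, gene: str) -> bool:
        return gene in self.signals

    def signal(self, gene: str) -> float | None:
        return self.signals.get(gene)

    @property
    def bound_genes(self) -> set[str]:
        return set(self.signals)


@dataclass(frozen=True)
class DifferentialPartition:
    """Disjoint exclusive/shared gene sets over all bound genes."""

    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]
    shared: frozenset[str]
    fc_low: float = 0.5
    fc_high: float = 2.0

    def __post_init__(self):
        sets = (self.exclusive_a, self.exclusive_b, self.shared)
        total = sum(len(s) for s in sets)
        if len(self.exclusive_a | self.exclusive_b | self.shared) != total:
            raise DataError("partition sets are not pairwise disjoint")

    @property
    def bound_genes(self) -> frozenset[str]:
        return self.exclusive_a | self.exclusive_b | self.shared


# ---------------------------------------------------------------------------

def _best_q_at(peaks: Sequence[Peak], locus: Interval) -> float | None:
    """Minimum q among peaks overlapping the locus; None if no overlap."""
    qs = [p.q for p in peaks if p.overlaps(locus.chrom, locus.start, locus.end)]
    return min(qs) if qs else None


def calibrate_q_threshold(
    peaks_by_sample: Mapping[str, Sequence[Peak]], spec: CalibrationSpec
) -> float:
    """Largest threshold t such that "called iff q < t" detects the positive
    control locus in every positive sample, in no negative sample, and never
    calls the negative control locus in any sample.

    When no negative-side peak constrains t, the spec's ``cap`` is returned.
    Because the calling rule is a strict inequality, the returned t is the
    limiting negative q itself (an open bound).
    """
    pos_best: dict[str, float] = {}
    for s in spec.positive_samples:
        best = _best_q_at(peaks_by_sample.get(s, ()), spec.positive_locus)
        if best is None:
            raise CalibrationError(
                f"positive sample '{s}' has no peak at the positive control locus"
            )
        pos_best[s] = best
    lower = max(pos_best.values())  # t must exceed every positive best q

    upper = spec.cap
    for s in spec.negative_samples:
        best = _best_q_at(peaks_by_sample.get(s, ()), spec.positive_locus)
        if best is not None:
            upper = min(upper, best)
    for s, peaks in peaks_by_sample.items():
        best = _best_q_at(peaks, spec.negative_locus)
        if best is not None:
            upper = min(upper, best)

    if upper <= lower:
        raise CalibrationError(
            f"controls not separable: max positive best q = {lower} but the "
            f"limiting negative q = {upper}"
        )
    return upper


def filter_peaks(peaks: Sequence[Peak], threshold: float) -> list[Peak]:
    """Keep peaks with q strictly below the threshold, preserving order."""
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold {threshold} outside (0, 1]")
    return [p for p in peaks if p.q < threshold]


def call_consensus_arbs(
    peaks_by_replicate: Mapping[str, Sequence[Peak]],
    min_support: int = 2,
    condition: str = "",
    replicate_conditions: Mapping[str, str] | None = None,
) -> list[ConsensusARBS]:
    """Merge peaks across replicates into consensus binding sites.

    Peaks are clustered per chromosome by single-linkage on >= 1 bp overlap
    (a chain of pairwise-overlapping peaks forms one maximal cluster).
    ``support`` counts distinct replicates contributing at least one peak;
    clusters below ``min_support`` are discarded.  ``mean_signal`` is the
    arithmetic mean over all contributing peaks.
    """
    if replicate_conditions is not None:
        conds = {replicate_conditions[r] for r in peaks_by_replicate}
        if len(conds) > 1:
            raise DataError(f"replicates from mixed conditions: {sorted(conds)}")
        if not condition and conds:
            condition = next(iter(conds))
    if len(peaks_by_replicate) < min_support:
        raise ConfigError(
            f"need >= min_support={min_support} replicates, "
            f"got {len(peaks_by_replicate)}"
        )

    by_chrom: dict[str, list[tuple[int, int, str, float]]] = {}
    for rep, peaks in peaks_by_replicate.items():
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end, rep, p.signal))

    out: list[ConsensusARBS] = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        # sweep: a sorted chain belongs to one cluster while start < current end
        cur: list[tuple[int, int, str, float]] = []
        cur_end = -1
        for row in rows:
            if cur and row[0] >= cur_end:
                out.append(_finish_cluster(chrom, cur, condition))
                cur = []
            cur.append(row)
            cur_end = max(cur_end, row[1])
        if cur:
            out.append(_finish_cluster(chrom, cur, condition))
    return [a for a in out if a.support >= min_support]


def _finish_cluster(
    chrom: str, rows: list[tuple[int, int, str, float]], condition: str
) -> ConsensusARBS:
    return ConsensusARBS(
        chrom=chrom,
        start=min(r[0] for r in rows),
        end=max(r[1] for r in rows),
        support=len({r[2] for r in rows}),
        condition=condition,
        mean_signal=sum(r[3] for r in rows) / len(rows),
    )


def _annotation_windows(
    gene: GeneModel, upstream_window: int, mode: str
) -> list[tuple[int, int]]:
    """Intervals (0-based half-open) in which a site annotates this gene."""
    windows = [(gene.start, gene.end)]
    if upstream_window > 0:
        if mode == "upstream":
            if gene.strand == "+":
                windows.append((max(0, gene.tss - upstream_window), gene.tss))
            else:
                # upstream of a - gene is (tss, tss + w] -> half-open [tss+1, tss+w+1)
                windows.append((gene.tss + 1, gene.tss + 1 + upstream_window))
        elif mode == "symmetric":
            windows = [(max(0, gene.start - upstream_window), gene.end + upstream_window)]
        else:
            raise ConfigError(f"unknown annotation mode '{mode}'")
    return windows


def annotate_arbs_to_genes(
    arbs: Sequence[ConsensusARBS],
    genes: Sequence[GeneModel],
    upstream_window: int = 20_000,
    mode: str = "upstream",
    condition: str | None = None,
) -> GeneBindingTable:
    """Annotate consensus sites to genes; a gene is bound iff some site
    overlaps its body or its strand-aware upstream window.

    ``mode='upstream'`` is the default promoter rule (in-gene OR <= 20 kb
    upstream of the TSS); ``mode='symmetric'`` extends the gene body by the
    window on both sides, strand-agnostic.  One site may annotate several
    genes; the per-gene signal is the max mean_signal over annotating sites.
    """
    if upstream_window < 0:
        raise ConfigError("upstream_window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for a in arbs:
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end, a)

    signals: dict[str, float] = {}
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        best: float | None = None
        for lo, hi in _annotation_windows(gene, upstream_window, mode):
            for hit in tree.overlap(lo, hi):
                sig = hit.data.mean_signal
                best = sig if best is None else max(best, sig)
        if best is not None:
            signals[gene.gene_id] = best
    cond = condition if condition is not None else (arbs[0].condition if arbs else "")
    return GeneBindingTable(
        condition=cond,
        universe=tuple(g.gene_id for g in genes),
        signals=signals,
    )


def classify_differential_genes(
    table_a: GeneBindingTable,
    table_b: GeneBindingTable,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    pseudocount: float = 0.01,
) -> DifferentialPartition:
    """Partition bound genes into exclusive-A / exclusive-B / shared.

    Genes bound in only one condition are exclusive by presence.  Genes bound
    in both are classified by signal fold change FC = (sigA+eps)/(sigB+eps):
    FC >= fc_high -> exclusive A, FC <= fc_low -> exclusive B (boundaries
    inclusive), otherwise shared.  Genes unbound in both are omitted.
    """
    if fc_low >= fc_high:
        raise ConfigError(f"fc_low {fc_low} must be < fc_high {fc_high}")
    if set(table_a.universe) != set(table_b.universe):
        raise DataError("binding tables cover different gene universes")
    excl_a, excl_b, shared = set(), set(), set()
    for gene in table_a.universe:
        in_a, in_b = table_a.bound(gene), table_b.bound(gene)
        if in_a and not in_b:
            excl_a.add(gene)
        elif in_b and not in_a:
            excl_b.add(gene)
        elif in_a and in_b:
            fc = (table_a.signals[gene] + pseudocount) / (
                table_b.signals[gene] + pseudocount
            )
            if fc >= fc_high:
                excl_a.add(gene)
            elif fc <= fc_low:
                excl_b.add(gene)
            else:
                shared.add(gene)
    return DifferentialPartition(
        frozenset(excl_a), frozenset(excl_b), frozenset(shared), fc_low, fc_high
    )


def venn_counts(
    partition: DifferentialPartition | tuple[int, int, int],
) -> tuple[int, int, int, int]:
    """(only_A, only_B, shared, total) from a partition or raw counts."""
    if isinstance(partition, DifferentialPartition):
        a, b, s = (
            len(partition.exclusive_a),
            len(partition.exclusive_b),
            len(partition.shared),
        )
    else:
        a, b, s = partition
        if min(a, b, s) < 0:
            raise DataError("venn counts must be non-negative")
    return a, b, s, a + b + s


def cross_study_overlap(
    query: Iterable[str], reference: Sequence[str]
) -> tuple[int, int, float]:
    """Overlap of a query gene set with a reference list.

    Returns (n_overlap, n_reference, percent) where percent is
    100 * n_overlap / n_reference rounded half-up to one decimal, matching
    how such concordance percentages are conventionally printed.
    """
    reference = list(reference)
    if not reference:
        raise DataError("reference gene list is empty")
    ref = set(reference)
    n_overlap = len(set(query) & ref)
    n_reference = len(ref)
    percent = float(
        (Decimal(100 * n_overlap) / Decimal(n_reference)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return n_overlap, n_reference, percent
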