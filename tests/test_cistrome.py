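"""Consensus calling, calibration, annotation and classification checks,
each against an independent oracle where the logic is non-trivial."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from cistroscreen.cistrome import (
    CalibrationSpec,
    ConsensusARBS,
    GeneBindingTable,
    Interval,
    annotate_arbs_to_genes,
    calibrate_q_threshold,
    call_consensus_arbs,
    classify_differential_genes,
    cross_study_overlap,
    filter_peaks,
    venn_counts,
)
from cistroscreen.errors import CalibrationError, ConfigError, DataError
from cistroscreen.io import GeneModel, Peak


def mkpeak(start, end, sample="s1", q=0.01, signal=1.0, chrom="chr1"):
    return Peak(chrom, start, end, f"p{start}", signal, q, sample)


LOCUS_POS = Interval("chr1", 1000, 1400)
LOCUS_NEG = Interval("chr1", 9000, 9400)


def spec(cap=0.25):
    return CalibrationSpec(LOCUS_POS, LOCUS_NEG, ("pos1", "pos2"), ("neg1",), cap=cap)


def brute_force_threshold(peaks_by_sample, sp):
    """Oracle: scan every observed q value (and the cap) for the largest
    feasible threshold under the strict calling rule."""
    candidates = sorted(
        {p.q for peaks in peaks_by_sample.values() for p in peaks} | {sp.cap}
    )

    def feasible(t):
        if t > sp.cap:
            return False
        for s in sp.positive_samples:
            hits = [p for p in peaks_by_sample.get(s, []) if p.overlaps(*_iv(sp.positive_locus))]
            if not any(p.q < t for p in hits):
                return False
        for s in sp.negative_samples:
            for p in peaks_by_sample.get(s, []):
                if p.overlaps(*_iv(sp.positive_locus)) and p.q < t:
                    return False
        for peaks in peaks_by_sample.values():
            for p in peaks:
                if p.overlaps(*_iv(sp.negative_locus)) and p.q < t:
                    return False
        return True

    ok = [t for t in candidates if feasible(t)]
    return max(ok) if ok else None


def _iv(interval):
    return interval.chrom, interval.start, interval.end


class TestCalibration:
    def test_limiting_negative_q_is_returned(self):
        peaks = {
            "pos1": [mkpeak(1000, 1400, "pos1", q=0.03)],
            "pos2": [mkpeak(1100, 1500, "pos2", q=0.07)],
            "neg1": [mkpeak(1000, 1400, "neg1", q=0.129)],
        }
        t = calibrate_q_threshold(peaks, spec())
        assert t == 0.129
        assert t == brute_force_threshold(peaks, spec())

    def test_inseparable_controls_raise(self):
        peaks = {
            "pos1": [mkpeak(1000, 1400, "pos1", q=0.20)],
            "pos2": [mkpeak(1000, 1400, "pos2", q=0.05)],
            "neg1": [mkpeak(1000, 1400, "neg1", q=0.10)],
        }
        with pytest.raises(CalibrationError, match="0.2"):
            calibrate_q_threshold(peaks, spec())

    def test_unconstrained_falls_back_to_cap(self):
        peaks = {
            "pos1": [mkpeak(1000, 1400, "pos1", q=0.01)],
            "pos2": [mkpeak(1000, 1400, "pos2", q=0.01)],
            "neg1": [],
        }
        assert calibrate_q_threshold(peaks, spec(cap=0.25)) == 0.25

    def test_negative_locus_peak_lowers_threshold(self):
        peaks = {
            "pos1": [mkpeak(1000, 1400, "pos1", q=0.01)],
            "pos2": [mkpeak(1000, 1400, "pos2", q=0.02)],
            "neg1": [],
            "other": [mkpeak(9000, 9400, "other", q=0.10)],
        }
        t = calibrate_q_threshold(peaks, spec())
        assert t == 0.10
        assert t == brute_force_threshold(peaks, spec())

    def test_missing_positive_peak_raises(self):
        peaks = {"pos1": [], "pos2": [mkpeak(1000, 1400, "pos2")], "neg1": []}
        with pytest.raises(CalibrationError, match="pos1"):
            calibrate_q_threshold(peaks, spec())

    def test_random_instances_match_scan_oracle(self):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(100):
            peaks = {}
            for s in ("pos1", "pos2", "neg1", "bystander"):
                sample_peaks = []
                if s.startswith("pos") or rng.random() < 0.7:
                    sample_peaks.append(
                        mkpeak(1000, 1400, s, q=float(rng.uniform(0.001, 0.4)))
                    )
                if rng.random() < 0.3:
                    sample_peaks.append(
                        mkpeak(9000, 9400, s, q=float(rng.uniform(0.001, 0.4)))
                    )
                peaks[s] = sample_peaks
            # the returned threshold is always either an observed q or the
            # cap, so the scan oracle's maximum feasible candidate must
            # coincide with it exactly (None <-> inseparable)
            expected = brute_force_threshold(peaks, spec())
            try:
                got = calibrate_q_threshold(peaks, spec())
            except CalibrationError:
                got = None
            assert got == expected
            agree += 1
        assert agree == 100


class TestFilterPeaks:
    def test_strict_inequality_at_threshold(self):
        peaks = [mkpeak(0, 10, q=0.05), mkpeak(20, 30, q=0.129), mkpeak(40, 50, q=0.3)]
        kept = filter_peaks(peaks, 0.129)
        assert [p.q for p in kept] == [0.05]

    def test_threshold_one_keeps_all_below(self):
        peaks = [mkpeak(0, 10, q=0.99), mkpeak(20, 30, q=0.5)]
        assert filter_peaks(peaks, 1.0) == peaks

    def test_empty_input(self):
        assert filter_peaks([], 0.1) == []

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            filter_peaks([], 0.0)


def brute_force_consensus(peaks_by_replicate):
    """Oracle: pairwise-overlap graph connected components via scipy."""
    rows = [
        (p.chrom, p.start, p.end, rep, p.signal)
        for rep, peaks in peaks_by_replicate.items()
        for p in peaks
    ]
    n = len(rows)
    i_idx, j_idx = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                i_idx.append(i)
                j_idx.append(j)
    graph = coo_matrix(
        (np.ones(len(i_idx)), (i_idx, j_idx)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    clusters = {}
    for lab, row in zip(labels, rows):
        clusters.setdefault(lab, []).append(row)
    out = set()
    for rows_ in clusters.values():
        out.add(
            (
                rows_[0][0],
                min(r[1] for r in rows_),
                max(r[2] for r in rows_),
                len({r[3] for r in rows_}),
                round(sum(r[4] for r in rows_) / len(rows_), 9),
            )
        )
    return out


class TestConsensus:
    def test_two_of_three_rule(self):
        reps = {
            "r1": [mkpeak(100, 200, "r1", signal=4)],
            "r2": [mkpeak(150, 250, "r2", signal=6)],
            "r3": [mkpeak(400, 500, "r3", signal=8)],
        }
        arbs = call_consensus_arbs(reps, min_support=2)
        assert len(arbs) == 1
        (a,) = arbs
        assert (a.start, a.end, a.support, a.mean_signal) == (100, 250, 2, 5.0)

    def test_chained_overlap_merges_transitively(self):
        reps = {
            "r1": [mkpeak(0, 10, "r1")],
            "r2": [mkpeak(9, 20, "r2")],
            "r3": [mkpeak(19, 30, "r3")],
        }
        (a,) = call_consensus_arbs(reps, min_support=2)
        assert (a.start, a.end, a.support) == (0, 30, 3)

    def test_same_replicate_counts_once(self):
        reps = {
            "r1": [mkpeak(0, 10, "r1"), mkpeak(5, 15, "r1")],
            "r2": [],
            "r3": [],
        }
        assert call_consensus_arbs(reps, min_support=2) == []

    def test_mixed_conditions_rejected(self):
        reps = {"r1": [], "r2": []}
        with pytest.raises(DataError, match="mixed"):
            call_consensus_arbs(
                reps, replicate_conditions={"r1": "AD", "r2": "CR"}
            )

    def test_random_instances_match_component_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n_peaks = int(rng.integers(1, 201))
            reps = {f"r{k}": [] for k in range(3)}
            for i in range(n_peaks):
                start = int(rng.integers(0, 5_000))
                width = int(rng.integers(1, 300))
                chrom = f"chr{int(rng.integers(1, 3))}"
                rep = f"r{int(rng.integers(0, 3))}"
                reps[rep].append(
                    mkpeak(start, start + width, rep, signal=float(rng.uniform(1, 9)), chrom=chrom)
                )
            got = {
                (a.chrom, a.start, a.end, a.support, round(a.mean_signal, 9))
                for a in call_consensus_arbs(reps, min_support=1)
            }
            assert got == brute_force_consensus(reps)


def plus_gene(start=10_000, end=15_000, gene_id="g1"):
    return GeneModel(gene_id, gene_id.upper(), "chr1", start, end, "+")


def arbs(start, end, signal=5.0, chrom="chr1", condition="AD"):
    return ConsensusARBS(chrom, start, end, support=2, condition=condition, mean_signal=signal)


class TestAnnotation:
    def test_upstream_window_binds_plus_gene(self):
        table = annotate_arbs_to_genes([arbs(5_000, 6_000)], [plus_gene()])
        assert table.bound("g1")

    def test_downstream_excluded_in_upstream_mode(self):
        table = annotate_arbs_to_genes([arbs(31_000, 32_000)], [plus_gene()])
        assert not table.bound("g1")

    def test_downstream_included_in_symmetric_mode(self):
        table = annotate_arbs_to_genes(
            [arbs(31_000, 32_000)], [plus_gene()], mode="symmetric"
        )
        assert table.bound("g1")

    def test_minus_strand_upstream_is_rightward(self):
        gene = GeneModel("g1", "G1", "chr1", 10_000, 15_000, "-")
        assert annotate_arbs_to_genes([arbs(20_000, 21_000)], [gene]).bound("g1")
        assert not annotate_arbs_to_genes([arbs(4_000, 5_000)], [gene]).bound("g1")

    def test_signal_is_max_over_annotating_sites(self):
        table = annotate_arbs_to_genes(
            [arbs(11_000, 11_400, signal=3.0), arbs(12_000, 12_400, signal=9.0)],
            [plus_gene()],
        )
        assert table.signal("g1") == 9.0

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and flipping strands leaves the set of
        bound genes invariant."""
        rng = np.random.default_rng(3)
        size = 1_000_000
        genes, sites = [], []
        pos = 30_000
        for i in range(8):
            length = int(rng.integers(1_000, 5_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i}", f"G{i}", "chr1", pos, pos + length, strand))
            pos += length + 60_000
        for _ in range(25):
            start = int(rng.integers(0, size - 500))
            sites.append(arbs(start, start + 500))
        bound = annotate_arbs_to_genes(sites, genes).bound_genes

        flip = {"+": "-", "-": "+"}
        mirrored_genes = [
            GeneModel(g.gene_id, g.symbol, g.chrom, size - g.end, size - g.start,
                      flip[g.strand])
            for g in genes
        ]
        mirrored_sites = [arbs(size - a.end, size - a.start) for a in sites]
        mirrored = annotate_arbs_to_genes(mirrored_sites, mirrored_genes).bound_genes
        assert bound == mirrored


class TestClassification:
    def _tables(self, sig_a, sig_b, universe=("g1", "g2")):
        ta = GeneBindingTable("AD", universe, dict(sig_a))
        tb = GeneBindingTable("CR", universe, dict(sig_b))
        return ta, tb

    @pytest.mark.parametrize(
        "sa,sb,expected",
        [
            (10.0, 4.0, "a"),   # FC 2.5
            (6.0, 5.0, "shared"),  # FC 1.2
            (4.0, 10.0, "b"),
        ],
    )
    def test_fold_change_rule(self, sa, sb, expected):
        ta, tb = self._tables({"g1": sa}, {"g1": sb})
        part = classify_differential_genes(ta, tb, pseudocount=0.0)
        got = (
            "a" if "g1" in part.exclusive_a
            else "b" if "g1" in part.exclusive_b
            else "shared"
        )
        assert got == expected

    def test_boundary_fold_change_is_exclusive(self):
        ta, tb = self._tables({"g1": 8.0}, {"g1": 4.0})
        part = classify_differential_genes(ta, tb, pseudocount=0.0)
        assert "g1" in part.exclusive_a  # FC exactly 2.0: inclusive

    def test_presence_only_exclusivity(self):
        ta, tb = self._tables({"g1": 1.0}, {})
        part = classify_differential_genes(ta, tb)
        assert "g1" in part.exclusive_a

    def test_unbound_genes_omitted(self):
        ta, tb = self._tables({}, {})
        part = classify_differential_genes(ta, tb)
        assert part.bound_genes == frozenset()

    def test_bad_thresholds(self):
        ta, tb = self._tables({}, {})
        with pytest.raises(ConfigError):
            classify_differential_genes(ta, tb, fc_low=2.0, fc_high=0.5)


class TestSummaries:
    def test_venn_counts_from_partition(self):
        part = classify_differential_genes(
            GeneBindingTable("AD", ("g1", "g2", "g3", "g4"), {"g1": 1, "g3": 1, "g4": 1}),
            GeneBindingTable("CR", ("g1", "g2", "g3", "g4"), {"g2": 1, "g3": 1, "g4": 1}),
        )
        assert venn_counts(part) == (1, 1, 2, 4)

    @pytest.mark.parametrize(
        "counts,total",
        [((3131, 1850, 6102), 11083), ((2938, 717, 1751), 5406)],
    )
    def test_venn_totals_from_raw_counts(self, counts, total):
        assert venn_counts(counts)[3] == total

    @pytest.mark.parametrize(
        "n_overlap,n_ref,pct",
        [(810, 1371, 59.1), (730, 1371, 53.2), (59, 396, 14.9), (52, 396, 13.1), (0, 7, 0.0)],
    )
    def test_overlap_percent_rounds_half_up(self, n_overlap, n_ref, pct):
        query = [f"q{i}" for i in range(n_overlap)]
        reference = query + [f"r{i}" for i in range(n_ref - n_overlap)]
        assert cross_study_overlap(query, reference) == (n_overlap, n_ref, pct)

    def test_exact_half_rounds_up(self):
        # 25/200 = 12.5% -> half-up at the hundredths would matter at e.g.
        # 0.05: 1/2000 of 100% ... use 0.25%: 1 of 400 = 0.25 -> 0.3
        assert cross_study_overlap(["a"], ["a"] + [f"r{i}" for i in range(399)])[2] == 0.3

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            cross_study_overlap(["a"], [])
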