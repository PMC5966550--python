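"""Expanding-window array detection."""

import random

import pytest

from oracle import qualifying_windows, reference_detect
from conftest import make_contig, make_genes, random_instance

from trna_arrays.detector import (
    ArrayUnit,
    DetectorConfig,
    detect_arrays,
    detect_genome,
    span_and_density,
)
from trna_arrays.trna_io import ContigCalls, GeneCall


class TestSpanAndDensity:
    def test_three_gene_window(self):
        genes = make_genes([(100, 175), (300, 375), (1000, 1075)])
        span, density = span_and_density(genes, 0, 2)
        assert span == 976
        assert density == pytest.approx(3.0738, abs=1e-4)

    def test_single_gene(self):
        genes = make_genes([(100, 175)])
        span, density = span_and_density(genes, 0, 0)
        assert span == 76
        assert density == pytest.approx(13.1579, abs=1e-4)

    def test_translation_invariance(self):
        base = [(100, 175), (300, 375), (1000, 1075)]
        shifted = [(s + 10_000, e + 10_000) for s, e in base]
        assert span_and_density(make_genes(base), 0, 2) == \
            span_and_density(make_genes(shifted), 0, 2)

    def test_bad_window_rejected(self):
        genes = make_genes([(100, 175), (300, 375)])
        with pytest.raises(ValueError):
            span_and_density(genes, 1, 0)

    def test_unsorted_input_rejected(self):
        genes = [GeneCall("c1", 300, 375, "+", "tRNA", "G", "gcc"),
                 GeneCall("c1", 100, 175, "+", "tRNA", "G", "gcc")]
        with pytest.raises(ValueError, match="sorted"):
            span_and_density(genes, 0, 1)


class TestDetectArrays:
    def test_growth_stops_at_distant_gene(self, small_cfg):
        """Three tight genes qualify; growing to a gene 4 kb away drops the
        density below threshold, so the partial array is finalized."""
        contig = make_contig([(100, 175), (300, 375), (500, 575),
                              (5000, 5075)])
        (array,) = detect_arrays(contig, small_cfg)
        assert [g.start for g in array.genes] == [100, 300, 500]
        assert array.span == 476
        assert array.density == pytest.approx(6.3025, abs=1e-4)

    def test_window_slides_past_sparse_prefix(self, small_cfg):
        """The first window (genes 1-3) is too sparse and slides; the next
        window (genes 2-4) qualifies."""
        contig = make_contig([(100, 175), (2000, 2075), (2200, 2275),
                              (2400, 2475)])
        (array,) = detect_arrays(contig, small_cfg)
        assert [g.start for g in array.genes] == [2000, 2200, 2400]
        assert array.span == 476
        assert array.density == pytest.approx(6.3025, abs=1e-4)

    def test_nineteen_genes_is_not_an_array(self, default_cfg):
        intervals = [(100 + 100 * k, 174 + 100 * k) for k in range(19)]
        assert detect_arrays(make_contig(intervals), default_cfg) == []

    def test_twenty_genes_is_an_array(self, default_cfg):
        intervals = [(100 + 100 * k, 174 + 100 * k) for k in range(20)]
        (array,) = detect_arrays(make_contig(intervals), default_cfg)
        assert array.count == 20

    def test_empty_contig(self, default_cfg):
        assert detect_arrays(ContigCalls("c1", 1, []), default_cfg) == []

    def test_tmrna_not_counted_but_reported_inside(self, small_cfg):
        calls = make_genes([(100, 175), (300, 375), (700, 775)]) + [
            GeneCall("c1", 400, 650, "+", "tmRNA", "X", "nnn"),
            GeneCall("c1", 5000, 5300, "+", "tmRNA", "X", "nnn"),
        ]
        contig = ContigCalls("c1", 1, calls)
        (array,) = detect_arrays(contig, small_cfg)
        assert array.count == 3  # tmRNA does not count toward size
        assert [t.start for t in array.tmrna_inside] == [400]

    def test_tmrna_counted_when_configured(self):
        cfg = DetectorConfig(min_trnas=3, min_density=2.0, count_tmrna=True)
        calls = make_genes([(100, 175), (300, 375)]) + [
            GeneCall("c1", 500, 575, "+", "tmRNA", "X", "nnn")]
        (array,) = detect_arrays(ContigCalls("c1", 1, calls), cfg)
        assert array.count == 3

    def test_exact_density_boundary_inclusive(self):
        """A 20-gene window spanning exactly 10 kb has density exactly 2.0
        and must be reported (inclusive threshold)."""
        intervals = [(1 + 500 * k, 76 + 500 * k) for k in range(19)]
        intervals.append((9925, 10_000))  # last end makes span exactly 10000
        (array,) = detect_arrays(make_contig(intervals), DetectorConfig())
        assert array.span == 10_000 and array.density == pytest.approx(2.0)
        # one bp wider -> density below 2 -> nothing reported
        intervals[-1] = (9925, 10_001)
        assert detect_arrays(make_contig(intervals), DetectorConfig()) == []


def _arrays_on(intervals, min_trnas, min_density):
    cfg = DetectorConfig(min_trnas=min_trnas, min_density=min_density)
    return detect_arrays(make_contig(intervals), cfg)


class TestDetectorProperties:
    def test_oracle_equivalence_on_random_instances(self):
        """detect_arrays must agree, window for window, with the literal
        step-by-step reference simulation on 1,000 random instances."""
        rng = random.Random(20180517)
        for _ in range(1000):
            genes = random_instance(rng, max_genes=200)
            min_trnas = rng.choice([3, 5, 20])
            got = _arrays_on(genes, min_trnas, 2.0)
            expected = reference_detect(genes, min_trnas, 2.0)
            got_windows = [
                (g.genes[0].start, g.genes[-1].end) for g in got]
            exp_windows = [
                (genes[i][0], genes[j][1]) for i, j in expected]
            assert got_windows == exp_windows

    def test_reported_arrays_are_valid_disjoint_and_ordered(self):
        rng = random.Random(42)
        for _ in range(300):
            genes = random_instance(rng, max_genes=120)
            min_trnas = rng.choice([3, 5, 20])
            arrays = _arrays_on(genes, min_trnas, 2.0)
            prev_end = -1
            for a in arrays:
                assert a.count >= min_trnas
                assert a.density >= 2.0
                assert a.span == a.end - a.begin + 1
                assert a.begin > prev_end  # disjoint, ascending
                prev_end = a.end

    def test_brute_force_membership(self):
        """Every reported window is in the exhaustively enumerated set of
        qualifying (size, density) windows."""
        rng = random.Random(7)
        for _ in range(200):
            genes = random_instance(rng, max_genes=200)
            min_trnas = rng.choice([3, 5, 20])
            qualifying = qualifying_windows(genes, min_trnas, 2.0)
            for a in _arrays_on(genes, min_trnas, 2.0):
                i = genes.index((a.genes[0].start, a.genes[0].end))
                j = genes.index((a.genes[-1].start, a.genes[-1].end))
                assert (i, j) in qualifying

    def test_translation_invariance(self):
        rng = random.Random(99)
        genes = random_instance(rng, max_genes=100)
        shift = 123_456
        shifted = [(s + shift, e + shift) for s, e in genes]
        a1 = _arrays_on(genes, 3, 2.0)
        a2 = _arrays_on(shifted, 3, 2.0)
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            assert (x.begin + shift, x.end + shift) == (y.begin, y.end)
            assert (x.count, x.span) == (y.count, y.span)
            assert x.density == pytest.approx(y.density)


class TestDetectGenome:
    def test_ordinals_across_contigs(self, small_cfg):
        tight = [(100 + 200 * k, 175 + 200 * k) for k in range(5)]
        contigs = [make_contig(tight, "c1", 1),
                   make_contig(tight, "c2", 2)]
        rows = detect_genome(contigs, small_cfg, "g1")
        assert [r.array_ordinal for r in rows] == [1, 2]
        assert [r.contig_number for r in rows] == [1, 2]

    def test_dispersed_genome_one_empty_row(self, default_cfg):
        sparse = [(100 + 20_000 * k, 175 + 20_000 * k) for k in range(30)]
        rows = detect_genome([make_contig(sparse)], default_cfg, "g1")
        assert len(rows) == 1
        assert not rows[0].has_array
        assert rows[0].total_trnas == 30

    def test_total_trnas_excludes_tmrna(self, small_cfg):
        calls = make_genes([(100, 175), (300, 375), (500, 575)]) + [
            GeneCall("c1", 900, 1200, "+", "tmRNA", "X", "nnn")]
        rows = detect_genome([ContigCalls("c1", 1, calls)], small_cfg, "g")
        assert rows[0].total_trnas == 3

    def test_deterministic(self, small_cfg):
        tight = [(100 + 200 * k, 175 + 200 * k) for k in range(6)]
        contigs = [make_contig(tight)]
        assert detect_genome(contigs, small_cfg, "g") == \
            detect_genome(contigs, small_cfg, "g")

    def test_duplicate_contig_index_rejected(self, small_cfg):
        contigs = [make_contig([(1, 76)], "c1", 1),
                   make_contig([(1, 76)], "c2", 1)]
        with pytest.raises(ValueError, match="contig_index"):
            detect_genome(contigs, small_cfg, "g")
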