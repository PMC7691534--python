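"""Cytoband tables, karyotype parsing, CNV extraction and interval matching."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litvariant.cnv import (
    CnvCitation,
    CytobandError,
    GenomicInterval,
    classify_overlap,
    detect_cytoband_mentions,
    detect_gene_level_cnv,
    expand_band_range,
    extract_cnv_citations,
    load_cytoband_table,
    match_cnv_query,
    parse_karyotype,
)
from litvariant.corpus import normalize_text
from litvariant.synth import toy_cytoband_rows


class TestCytobandTable:
    def test_published_coordinates(self, cytobands):
        assert cytobands.lookup("22q11.2") == GenomicInterval("chr22", 17_400_000, 25_500_000)
        assert cytobands.lookup("11q23") == GenomicInterval("chr11", 110_600_000, 121_300_000)

    def test_unknown_band_misses(self, cytobands):
        assert cytobands.lookup("5z99") is None
        assert cytobands.lookup("22q99") is None

    def test_band_prefix_spans_subbands(self, cytobands):
        # "22q11" covers q11.1 + q11.2
        assert cytobands.lookup("22q11") == GenomicInterval("chr22", 14_700_000, 25_500_000)

    def test_whole_arm_union(self, cytobands):
        q = cytobands.lookup("22q")
        assert q == GenomicInterval("chr22", 14_700_000, 50_818_467)

    def test_overlapping_bands_rejected(self):
        rows = ["chr1\t0\t100\tp1\tgneg", "chr1\t50\t200\tp2\tgneg"]
        with pytest.raises(CytobandError, match="overlap"):
            load_cytoband_table(rows)

    def test_one_based_conversion(self):
        rows = ["chr1\t1\t100\tp1\tgneg"]
        bands = load_cytoband_table(rows, one_based=True)
        assert bands.lookup("1p1").start == 0

    def test_interval_to_band_roundtrip(self, cytobands):
        for lst in cytobands.by_chrom.values():
            for band in lst:
                assert cytobands.band_of(band.chrom, band.start) == band
                assert cytobands.lookup(band.token) == band.interval


class TestCytobandMentions:
    def test_single_band(self):
        ms = detect_cytoband_mentions("deletion of 1p36.33 in patients")
        assert [(m.chrom, m.start_band) for m in ms] == [("1", "p36.33")]

    def test_range(self):
        ms = detect_cytoband_mentions("loss of 11q23-q25 was seen")
        assert [(m.chrom, m.start_band, m.end_band) for m in ms] == [("11", "q23", "q25")]

    def test_chromosome_required(self):
        assert detect_cytoband_mentions("p36 patients improved") == []

    def test_figure_and_decimal_suppression(self):
        assert detect_cytoband_mentions("see Fig. 1p3 for details") == []
        assert detect_cytoband_mentions("a value of 1.2q1 units") == []


class TestKaryotype:
    def test_iscn_subset(self):
        evs = parse_karyotype(normalize_text("46,XX,del(22)(q11.2),t(9;22)(q34;q11),+8"))
        kinds = [(e.kind, e.chroms, e.bands) for e in evs]
        assert ("del", ("22",), ("q11.2",)) in kinds
        assert ("gain", ("8",), ()) in kinds
        assert ("translocation", ("9", "22"), ("q34", "q11")) in kinds

    def test_band_range_events(self):
        evs = parse_karyotype("47,XY,del(5)(q13q33),dup(1)(q21q32)")
        assert [(e.kind, e.bands) for e in evs if e.kind != "gain"] == [
            ("del", ("q13", "q33")), ("dup", ("q21", "q32"))
        ]

    def test_translocation_excluded_from_cnv_intervals(self, cytobands):
        cits = extract_cnv_citations("46,XX,t(9;22)(q34;q11)", cytobands)
        assert cits == []

    def test_del_event_normalizes_to_band_interval(self, cytobands):
        cits = extract_cnv_citations("46,XX,del(22)(q11.2)", cytobands)
        assert len(cits) == 1
        assert cits[0].interval == GenomicInterval("chr22", 17_400_000, 25_500_000)
        assert cits[0].level == "KARYOTYPE" and cits[0].direction == "DEL"

    def test_whole_chromosome_gain(self, cytobands):
        cits = extract_cnv_citations("47,XY,+8", cytobands)
        assert cits[0].interval == cytobands.chrom_interval("chr8")
        assert cits[0].direction == "AMP"


class TestGeneLevel:
    def test_deletion_and_amplification(self, gene_lexicon, keywords):
        text = normalize_text(
            "Homozygous deletion of PTEN was found. KRAS amplification was frequent."
        )
        cits = detect_gene_level_cnv(text, gene_lexicon, keywords)
        got = {(c.gene, c.level, c.direction) for c in cits}
        assert got == {("PTEN", "GENE", "DEL"), ("KRAS", "GENE", "AMP")}

    def test_exon_level(self, gene_lexicon, keywords):
        cits = detect_gene_level_cnv(
            "The exon 2 deletion of PTEN was recurrent.", gene_lexicon, keywords
        )
        assert [(c.gene, c.level, c.direction) for c in cits] == [("PTEN", "EXON", "DEL")]

    def test_expression_vocabulary_excluded(self, gene_lexicon, keywords):
        cits = detect_gene_level_cnv(
            "PTEN expression decreased after treatment.", gene_lexicon, keywords
        )
        assert cits == []


class TestBandRangeExpansion:
    def test_inclusive_run(self, cytobands):
        run = expand_band_range("11", "q23", "q25", cytobands)
        assert [b.name for b in run] == ["q23", "q24", "q25"]

    def test_degenerate_range(self, cytobands):
        run = expand_band_range("11", "q23", "q23", cytobands)
        assert [b.name for b in run] == ["q23"]

    def test_union_interval_is_contiguous(self, cytobands):
        run = expand_band_range("5", "q13", "q33", cytobands)
        for a, b in zip(run, run[1:]):
            assert a.end == b.start
        assert run[0].start == 48_800_000 and run[-1].end == 159_000_000

    def test_unresolvable_endpoint_raises(self, cytobands):
        with pytest.raises(CytobandError):
            expand_band_range("11", "q23", "q99", cytobands)


def brute_force_classify(qs, qe, cs, ce):
    """Set-relation oracle on integer grids."""
    q = set(range(qs, qe))
    c = set(range(cs, ce))
    if not (q & c):
        return None
    if q == c:
        return "EXACT"
    if c < q:
        return "CONTAINED"
    if q < c:
        return "SURROUNDING"
    return "INTERSECTING"


class TestMatching:
    def test_forced_geometry(self):
        q = GenomicInterval("chr22", 17_400_000, 25_500_000)
        cases = {
            (17_400_000, 25_500_000): "EXACT",
            (18_000_000, 20_000_000): "CONTAINED",
            (16_000_000, 26_000_000): "SURROUNDING",
            (25_000_000, 27_000_000): "INTERSECTING",
        }
        for (s, e), expected in cases.items():
            assert classify_overlap(q, GenomicInterval("chr22", s, e)) == expected
        assert classify_overlap(q, GenomicInterval("chr22", 25_500_000, 26_000_000)) is None
        assert classify_overlap(q, GenomicInterval("chr1", 17_400_000, 25_500_000)) is None

    def test_equivalence_with_set_relation_oracle_100k_pairs(self):
        rng = random.Random(123)
        n = 100_000
        for _ in range(n):
            qs = rng.randrange(0, 60)
            qe = qs + rng.randrange(1, 40)
            cs = rng.randrange(0, 60)
            ce = cs + rng.randrange(1, 40)
            got = classify_overlap(
                GenomicInterval("chr1", qs, qe), GenomicInterval("chr1", cs, ce)
            )
            assert got == brute_force_classify(qs, qe, cs, ce)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 100), st.integers(1, 50), st.integers(0, 100), st.integers(1, 50))
    def test_types_partition_overlap_geometry(self, qs, ql, cs, cl):
        q = GenomicInterval("chr1", qs, qs + ql)
        c = GenomicInterval("chr1", cs, cs + cl)
        got = classify_overlap(q, c)
        assert got == brute_force_classify(qs, qs + ql, cs, cs + cl)

    def test_ordering_type_then_fraction_then_size(self):
        q = GenomicInterval("chr1", 100, 200)
        cits = [
            CnvCitation("small_int", GenomicInterval("chr1", 190, 220), "COORDS"),
            CnvCitation("exact", GenomicInterval("chr1", 100, 200), "COORDS"),
            CnvCitation("surr_big", GenomicInterval("chr1", 0, 500), "COORDS"),
            CnvCitation("surr_small", GenomicInterval("chr1", 90, 210), "COORDS"),
            CnvCitation("cont_big", GenomicInterval("chr1", 110, 190), "COORDS"),
            CnvCitation("cont_small", GenomicInterval("chr1", 120, 130), "COORDS"),
            CnvCitation("big_int", GenomicInterval("chr1", 150, 400), "COORDS"),
            CnvCitation("miss", GenomicInterval("chr1", 300, 400), "COORDS"),
        ]
        got = [m.citation.pmid for m in match_cnv_query(q, cits)]
        assert got == ["exact", "cont_big", "cont_small", "surr_small", "surr_big",
                       "big_int", "small_int"]

    def test_exact_match_has_fraction_one(self):
        q = GenomicInterval("chr1", 10, 20)
        m = match_cnv_query(q, [CnvCitation("a", q, "COORDS")])[0]
        assert m.match_type == "EXACT" and m.overlap_fraction == 1.0


class TestRoundtripConvention:
    def test_toy_band_table_contiguous_per_arm(self):
        bands = load_cytoband_table(toy_cytoband_rows())
        for chrom, lst in bands.by_chrom.items():
            for a, b in zip(lst, lst[1:]):
                if a.name[0] == b.name[0]:  # same arm
                    assert a.end == b.start, (chrom, a.name, b.name)
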