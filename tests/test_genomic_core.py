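"""Interval arithmetic, BED IO, tag coverage and quartile splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindover.genomic_core import (
    BedParseError,
    GeneAnnotation,
    GenomicInterval,
    PeakRecord,
    coverage_counts,
    extend_tag,
    overlap_bp,
    quartile_split,
    read_bed,
    read_gene_table,
    standardize,
    write_bed,
    write_gene_table,
)


class TestIntervalTypes:
    def test_empty_and_inverted_intervals_are_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_center_floors_midpoint(self):
        assert GenomicInterval("chr1", 100, 250).center() == 175
        assert GenomicInterval("chr1", 0, 3).center() == 1

    def test_tss_follows_strand(self):
        plus = GeneAnnotation("g1", "G1", GenomicInterval("chr1", 100, 500, strand="+"))
        minus = GeneAnnotation("g2", "G2", GenomicInterval("chr1", 100, 500, strand="-"))
        assert plus.tss == 100
        assert minus.tss == 499
        with pytest.raises(ValueError):
            GeneAnnotation("g3", "G3", GenomicInterval("chr1", 0, 10))  # strand mandatory


class TestBedIO:
    def test_single_line_maps_fields(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t250\tpk1\t8.5\n")
        (rec,) = read_bed(path)
        assert (rec.chrom, rec.start, rec.end, rec.name) == ("chr1", 100, 250, "pk1")
        assert rec.enrichment == 8.5

    def test_empty_interval_line_is_an_error_with_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\tok\t1\nchr1\t50\t50\tempty\t1\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(path)

    def test_non_integer_coordinates_are_an_error(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\tten\t20\n")
        with pytest.raises(BedParseError):
            read_bed(path)

    def test_write_then_read_round_trips(self, tmp_path):
        rng = np.random.default_rng(0)
        records = []
        for i in range(20):
            start = int(rng.integers(0, 10_000))
            width = int(rng.integers(1, 500))
            iv = GenomicInterval(f"chr{1 + i % 3}", start, start + width,
                                 strand="+-."[i % 3], name=f"pk{i}")
            records.append(PeakRecord(iv, enrichment=float(rng.uniform(0, 50)),
                                      significance=float(rng.uniform(0, 0.01))))
        cols = {"enrichment": 4, "significance": 6}
        path = tmp_path / "rt.bed"
        write_bed(path, records, cols)
        back = read_bed(path, cols)
        assert back == records

    def test_gene_table_round_trips(self, tmp_path):
        genes = [
            GeneAnnotation("g1", "ABC1", GenomicInterval("chr1", 100, 5000, strand="+", name="g1")),
            GeneAnnotation("g2", "XYZ2", GenomicInterval("chr2", 400, 900, strand="-", name="g2")),
        ]
        path = tmp_path / "genes.tsv"
        write_gene_table(path, genes)
        assert read_gene_table(path) == genes


class TestOverlap:
    def test_identity_and_half_open_adjacency(self):
        a = GenomicInterval("chr1", 0, 100)
        assert overlap_bp(a, a) == 100
        assert overlap_bp(a, GenomicInterval("chr1", 100, 200)) == 0
        assert overlap_bp(a, GenomicInterval("chr2", 0, 100)) == 0

    def test_matches_per_base_counting_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            s1, s2 = rng.integers(0, 500, size=2)
            a = GenomicInterval("c", int(s1), int(s1 + rng.integers(1, 200)))
            b = GenomicInterval("c", int(s2), int(s2 + rng.integers(1, 200)))
            per_base = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
            assert overlap_bp(a, b) == per_base == overlap_bp(b, a)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 1000), st.integers(1, 300), st.integers(0, 1000), st.integers(1, 300))
    def test_symmetry_property(self, s1, w1, s2, w2):
        a = GenomicInterval("c", s1, s1 + w1)
        b = GenomicInterval("c", s2, s2 + w2)
        assert overlap_bp(a, b) == overlap_bp(b, a)


class TestStandardize:
    def test_clips_at_chromosome_start(self):
        peak = PeakRecord(GenomicInterval("chr1", 100, 250))
        out = standardize(peak, 1000)  # center 175, would start at -325
        assert (out.start, out.end) == (0, 675)

    def test_already_standard_interval_is_a_fixpoint(self):
        peak = PeakRecord(GenomicInterval("chr1", 1000, 1150))
        out = standardize(peak, 150)
        assert (out.start, out.end) == (1000, 1150)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(2000, 100_000), st.integers(1, 999), st.integers(1, 2001))
    def test_width_and_parity_follow_direct_arithmetic(self, start, span, width):
        iv = GenomicInterval("c", start, start + span)
        out = standardize(iv, width)
        center = (iv.start + iv.end) // 2
        assert out.start == center - width // 2
        assert out.width == width  # extra base rightward for odd widths


class TestCoverage:
    def test_no_tags_means_all_zero(self):
        loci = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 700)]
        assert coverage_counts([], loci) == [0, 0]

    def test_three_prime_extension_reaches_downstream_locus(self):
        tag = GenomicInterval("c", 100, 136, strand="+")
        assert extend_tag(tag, 250).end == 350
        locus = GenomicInterval("c", 300, 400)
        assert coverage_counts([tag], [locus], extension=250) == [1]
        assert coverage_counts([tag], [locus], extension=0) == [0]

    def test_minus_strand_extends_upstream(self):
        tag = GenomicInterval("c", 300, 336, strand="-")
        ext = extend_tag(tag, 250)
        assert (ext.start, ext.end) == (86, 336)

    def test_matches_naive_double_loop_on_random_fixture(self):
        rng = np.random.default_rng(2)
        tags = []
        for _ in range(500):
            start = int(rng.integers(0, 50_000))
            strand = "+-."[int(rng.integers(0, 3))]
            tags.append(GenomicInterval("c", start, start + 36, strand=strand))
        loci = []
        for _ in range(40):
            start = int(rng.integers(0, 50_000))
            loci.append(GenomicInterval("c", start, start + int(rng.integers(100, 1000))))
        got = coverage_counts(tags, loci, extension=250)
        expected = [
            sum(1 for t in tags if overlap_bp(extend_tag(t, 250), locus) >= 1)
            for locus in loci
        ]
        assert got == expected

    def test_adding_a_tag_never_decreases_counts(self):
        rng = np.random.default_rng(3)
        loci = [GenomicInterval("c", int(s), int(s) + 200) for s in rng.integers(0, 10_000, 10)]
        tags = [GenomicInterval("c", int(s), int(s) + 36, strand="+") for s in rng.integers(0, 10_000, 50)]
        before = coverage_counts(tags, loci)
        after = coverage_counts(tags + [GenomicInterval("c", 5000, 5036, strand="+")], loci)
        assert all(b2 >= b1 for b1, b2 in zip(before, after))


class TestQuartileSplit:
    @staticmethod
    def _peaks(scores):
        return [
            PeakRecord(GenomicInterval("c", 100 * i + 1, 100 * i + 51, name=f"p{i}"), enrichment=s)
            for i, s in enumerate(scores)
        ]

    def test_even_split_in_score_order(self):
        groups = quartile_split(self._peaks([8, 7, 6, 5, 4, 3, 2, 1]))
        assert [len(g) for g in groups] == [2, 2, 2, 2]
        assert [p.enrichment for p in groups[0]] == [8, 7]
        assert [p.enrichment for p in groups[3]] == [2, 1]

    def test_remainder_goes_to_strongest_quartiles(self):
        groups = quartile_split(self._peaks(range(10, 0, -1)))
        assert [len(g) for g in groups] == [3, 3, 2, 2]

    def test_groups_partition_the_input_and_ties_are_stable(self):
        peaks = self._peaks([5, 5, 5, 5, 5, 5, 5, 5])
        groups = quartile_split(peaks)
        flat = [p for g in groups for p in g]
        assert flat == peaks  # stable: ties keep input order
        assert quartile_split(peaks) == groups  # deterministic across runs

    def test_fewer_than_four_peaks_is_an_error(self):
        with pytest.raises(ValueError):
            quartile_split(self._peaks([1, 2, 3]))
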