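"""Variant container, VCF/BED I/O and interval annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enumapper.variant_model import (
    FunctionalAnnotation,
    GenomeLayout,
    IntervalSet,
    Variant,
    annotate_by_intervals,
    read_bed,
    read_vcf,
    write_vcf,
)

from conftest import make_variant


class TestVariant:
    @pytest.mark.parametrize(
        "depth,alt_depth,expected",
        [(10, 10, 1.0), (12, 9, 0.75), (20, 10, 0.5), (5, 0, 0.0)],
    )
    def test_naf_arithmetic(self, depth, alt_depth, expected):
        v = make_variant(depth=depth, alt_depth=alt_depth)
        assert v.naf == pytest.approx(expected)

    def test_naf_undefined_at_zero_depth(self):
        assert make_variant(depth=0, alt_depth=0).naf is None

    def test_alt_depth_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_variant(depth=5, alt_depth=6)

    @given(depth=st.integers(1, 1000), alt=st.integers(0, 1000), k=st.integers(1, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_naf_invariant_under_depth_scaling(self, depth, alt, k):
        alt = min(alt, depth)
        v1 = make_variant(depth=depth, alt_depth=alt)
        v2 = make_variant(depth=depth * k, alt_depth=alt * k)
        assert v1.naf == pytest.approx(v2.naf)

    def test_multiallelic_flag(self):
        assert make_variant(alts=("T", "G")).is_multiallelic
        assert not make_variant(alts=("T",)).is_multiallelic


class TestAnnotationType:
    def test_category_closed_set(self):
        with pytest.raises(ValueError):
            FunctionalAnnotation(category="nonsense_category")

    def test_aa_change_only_for_coding(self):
        with pytest.raises(ValueError):
            FunctionalAnnotation(category="intergenic", aa_change="A1>B")


class TestGenomeLayout:
    def test_rejects_duplicates_and_bad_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout((("1", 10), ("1", 20)))
        with pytest.raises(ValueError):
            GenomeLayout((("1", 0),))

    def test_autosomes_exclude_sex(self, layout):
        assert [c for c, _ in layout.autosomes()] == ["1", "2", "3"]

    def test_tsv_round_trip(self, layout, tmp_path):
        p = tmp_path / "genome.tsv"
        layout.to_tsv(p)
        back = GenomeLayout.from_tsv(p)
        assert back.chromosomes == layout.chromosomes


class TestVcfIO:
    def _fixture_variants(self):
        return [
            make_variant("1", 100, "A", ("T",), qual=45.5, depth=10, alt_depth=10),
            make_variant("1", 2000, "C", ("G",), qual=60, depth=12, alt_depth=9,
                         category="exonic_nonsynonymous", gene="Clcn1"),
            make_variant("2", 500, "G", ("A", "C"), qual=30, depth=8, alt_depth=4),
            make_variant("2", 900, "T", ("A",), qual=20, depth=4, alt_depth=1,
                         in_known_db=True),
            make_variant("3", 1_000_000, "G", ("T",), qual=99, depth=30, alt_depth=15,
                         in_repeat=True, category="splicing", gene="Abca12"),
        ]

    def test_round_trip_preserves_fields(self, layout, tmp_path):
        variants = self._fixture_variants()
        path = write_vcf(variants, layout, tmp_path / "a.vcf")
        back = read_vcf(path)
        assert len(back) == len(variants)
        for orig, rt in zip(variants, back):
            assert (rt.chrom, rt.pos, rt.ref, rt.alts) == (
                orig.chrom, orig.pos, orig.ref, orig.alts)
            assert rt.qual == pytest.approx(orig.qual)
            assert (rt.depth, rt.alt_depth) == (orig.depth, orig.alt_depth)
            assert rt.naf == pytest.approx(orig.naf)
            assert rt.in_known_db == orig.in_known_db
            assert rt.in_repeat == orig.in_repeat
            if orig.annotation is not None:
                assert rt.annotation.category == orig.annotation.category
                assert rt.annotation.gene == orig.annotation.gene

    def test_rewrite_is_byte_identical(self, layout, tmp_path):
        """write -> read -> write reproduces the body columns exactly."""
        p1 = write_vcf(self._fixture_variants()[:3], layout, tmp_path / "a.vcf")
        p2 = write_vcf(read_vcf(p1), layout, tmp_path / "b.vcf")
        body1 = [l for l in p1.read_text().splitlines() if not l.startswith("#")]
        body2 = [l for l in p2.read_text().splitlines() if not l.startswith("#")]
        assert body1 == body2
        assert len(body1) == 3

    def test_empty_list_gives_header_only(self, layout, tmp_path):
        path = write_vcf([], layout, tmp_path / "empty.vcf")
        lines = path.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)
        assert read_vcf(path) == []

    def test_unsorted_input_rejected(self, layout, tmp_path):
        vs = [make_variant("1", 2000), make_variant("1", 100)]
        with pytest.raises(ValueError, match="sorted"):
            write_vcf(vs, layout, tmp_path / "bad.vcf")

    def test_missing_depth_warns_and_zeroes(self, tmp_path):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tT\t50\t.\t.\n"
        )
        with pytest.warns(UserWarning, match="depth"):
            vs = read_vcf(path)
        assert vs[0].depth == 0 and vs[0].naf is None

    def test_dp4_fallback_for_alt_reads(self, tmp_path):
        path = tmp_path / "dp4.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=DP4,Number=4,Type=Integer,Description="d">\n'
            '##contig=<ID=1,length=1000000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tT\t50\t.\tDP=12;DP4=2,1,5,4\n"
        )
        v = read_vcf(path)[0]
        assert v.depth == 12 and v.alt_depth == 9
        assert v.naf == pytest.approx(0.75)


class TestIntervalSet:
    def test_overlapping_rows_merge(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        s = read_bed(p)
        assert s.intervals("chr1") == [(100, 300)]

    def test_empty_file_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        s = read_bed(p)
        assert len(s) == 0
        assert not s.contains("chr1", 5)

    def test_invalid_interval_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t300\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_membership_matches_linear_scan(self, rng, tmp_path):
        intervals = []
        for _ in range(1000):
            s = int(rng.integers(0, 1_000_000))
            e = s + int(rng.integers(1, 5000))
            intervals.append((s, e))
        p = tmp_path / "rand.bed"
        p.write_text("".join(f"c\t{s}\t{e}\n" for s, e in intervals))
        iset = read_bed(p)
        probes = rng.integers(0, 1_005_000, size=10_000)
        for pos in probes.tolist():
            naive = any(s <= pos < e for s, e in intervals)
            assert iset.contains("c", pos) == naive


class TestAnnotateByIntervals:
    @pytest.fixture
    def exons(self):
        # gene A: exons [1000,1200) and [2000,2200); gene B: [5000,5100)
        return IntervalSet(
            {"1": [(1000, 1200), (2000, 2200), (5000, 5100)]},
            {"1": ["A", "A", "B"]},
        )

    def test_exon_start_is_exonic(self, exons):
        v = make_variant("1", pos=1001)  # 1-based; 0-based 1000 = exon start
        ann = annotate_by_intervals(v, exons)
        assert ann.category == "unknown" and ann.gene == "A"

    def test_splice_boundary_at_ten_bp(self, exons):
        # exon [1000,1200): last base is 1-based 1200; +10 => 1210 in, +11 out
        assert annotate_by_intervals(make_variant("1", pos=1210), exons).category == "splicing"
        ann = annotate_by_intervals(make_variant("1", pos=1211), exons)
        assert ann.category != "splicing"

    def test_upstream_splice_margin(self, exons):
        assert annotate_by_intervals(make_variant("1", pos=991), exons).category == "splicing"
        assert annotate_by_intervals(make_variant("1", pos=990), exons).category == "intergenic"

    def test_intron_vs_intergenic(self, exons):
        assert annotate_by_intervals(make_variant("1", pos=1600), exons).category == "intronic"
        assert annotate_by_intervals(make_variant("1", pos=9000), exons).category == "intergenic"

    def test_unknown_chromosome_warns_intergenic(self, exons):
        with pytest.warns(UserWarning):
            ann = annotate_by_intervals(make_variant("9", pos=100), exons)
        assert ann.category == "intergenic"

    def test_matches_naive_distance_computation(self, exons, rng):
        pairs = exons.intervals("1")
        bodies = {"A": (1000, 2200), "B": (5000, 5100)}
        for pos in rng.integers(1, 10_000, size=500).tolist():
            pos0 = pos - 1
            if any(s <= pos0 < e for s, e in pairs):
                expected = "unknown"
            elif any(
                (pos0 >= e and pos0 - e + 1 <= 10) or (pos0 < s and s - pos0 <= 10)
                for s, e in pairs
            ):
                expected = "splicing"
            elif any(s <= pos0 < e for s, e in bodies.values()):
                expected = "intronic"
            else:
                expected = "intergenic"
            got = annotate_by_intervals(make_variant("1", pos=pos), exons).category
            assert got == expected, pos
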