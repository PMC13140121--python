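"""Transcript model, HGVS parsing, windows and coordinate mapping."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from minisplice.gene_model import (
    CoordinateError,
    CVariant,
    Domain,
    HgvsParseError,
    NonCodingError,
    TranscriptModel,
    compute_region_windows,
    format_hgvs_c,
    map_cdna_to_protein,
    parse_hgvs_c,
    variant_in_extended_region,
)


@pytest.fixture(scope="module")
def toy_plus():
    # 3 exons of 100/90/110 nt, introns 200/150, CDS covers all 300 nt
    return TranscriptModel(
        transcript_id="TOY+",
        strand="+",
        exons=((1000, 1100), (1300, 1390), (1540, 1650)),
        cds_start_cdna=1,
        cds_end_cdna=300,
        domains=(Domain("D", 10, 20, critical=True),),
    )


@pytest.fixture(scope="module")
def toy_minus():
    # same exon lengths on the minus strand (descending genomic order)
    return TranscriptModel(
        transcript_id="TOY-",
        strand="-",
        exons=((1550, 1650), (1310, 1400), (1000, 1110)),
        cds_start_cdna=1,
        cds_end_cdna=300,
    )


class TestParsing:
    @pytest.mark.parametrize(
        "text, pos, off, pos2, off2, edit, ref, alt",
        [
            ("c.6558+4A>G", 6558, 4, 6558, 4, "substitution", "A", "G"),
            ("c.592+33_593-31del", 592, 33, 593, -31, "deletion", None, None),
            ("c.2075_2079delinsGTA", 2075, 0, 2079, 0, "delins", None, "GTA"),
            ("c.1200G>A", 1200, 0, 1200, 0, "substitution", "G", "A"),
            ("c.6052-51_6052-11del", 6052, -51, 6052, -11, "deletion", None, None),
            ("c.100_105dup", 100, 0, 105, 0, "duplication", None, None),
            ("c.100_101insTTA", 100, 0, 101, 0, "insertion", None, "TTA"),
        ],
    )
    def test_examples(self, text, pos, off, pos2, off2, edit, ref, alt, myo7a):
        v = parse_hgvs_c(text, myo7a)
        assert (v.start_pos, v.start_offset) == (pos, off)
        assert (v.end_pos, v.end_offset) == (pos2, off2)
        assert v.edit == edit and v.ref == ref and v.alt == alt

    def test_unicode_hyphen_normalized(self, myo7a):
        v = parse_hgvs_c("c.6052‐51_6052‐11del", myo7a)
        assert (v.start_offset, v.end_offset) == (-51, -11)

    @pytest.mark.parametrize(
        "bad", ["c.abc>G", "g.100A>G", "c.100A>", "c.100_102A>G", "c.100ins"]
    )
    def test_malformed(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(bad)

    def test_beyond_transcript(self, myo7a):
        with pytest.raises(CoordinateError):
            parse_hgvs_c("c.9999A>G", myo7a)

    def test_offset_requires_exon_edge(self, myo7a):
        # c.600 is internal to exon 7; an intronic offset cannot anchor there
        with pytest.raises(CoordinateError):
            parse_hgvs_c("c.600+4A>G", myo7a)

    def test_round_trip_on_curated_strings(self, probands):
        for pb in probands:
            for v in pb.variants:
                assert format_hgvs_c(parse_hgvs_c(v.hgvs)) == v.hgvs


class TestWindows:
    def test_counts_and_spans(self, toy_plus):
        ws = compute_region_windows(toy_plus)
        assert len(ws) == 4  # 2 junctions x 2 sides
        donor1 = next(w for w in ws if w.junction_id == 1 and w.side == "donor")
        assert donor1.exonic_span == (51, 100)  # last 50 nt of the 100-nt exon
        assert donor1.intronic_span == (3, 50)

    def test_short_exon_truncates(self):
        t = TranscriptModel("T", "+", ((0, 30), (200, 260)), 1, 90)
        donor = compute_region_windows(t)[0]
        assert donor.exonic_span == (1, 30)  # whole 30-nt exon

    def test_single_exon_warns_empty(self):
        t = TranscriptModel("T", "+", ((0, 90),), 1, 90)
        with pytest.warns(UserWarning):
            assert compute_region_windows(t) == []

    def test_canonical_positions_in_no_window(self, toy_plus):
        for w in compute_region_windows(toy_plus):
            if w.intronic_span:
                o1, o2 = w.intronic_span
                assert all(abs(o) >= 3 for o in (o1, o2))

    @given(st.integers(0, 2**31 - 1))
    def test_window_completeness_random_transcripts(self, seed):
        """Every |offset| in 3..50 falls in exactly one window per junction."""
        import numpy as np

        r = np.random.default_rng(seed)
        n = int(r.integers(2, 6))
        exon_lens = r.integers(20, 200, size=n)
        intron_lens = r.integers(104, 400, size=n - 1)
        exons, g = [], 0
        for i, ln in enumerate(exon_lens):
            exons.append((g, g + int(ln)))
            g += int(ln) + (int(intron_lens[i]) if i < n - 1 else 0)
        total = int(exon_lens.sum())
        t = TranscriptModel("R", "+", tuple(exons), 1, total - total % 3)
        ws = compute_region_windows(t)
        for j in range(1, n):
            for off in list(range(3, 51)) + list(range(-50, -2)):
                hits = [
                    w
                    for w in ws
                    if w.junction_id == j
                    and w.intronic_span
                    and w.intronic_span[0] <= off <= w.intronic_span[1]
                ]
                assert len(hits) == 1
            for off in (-2, -1, 1, 2):
                assert not any(
                    w.intronic_span
                    and w.junction_id == j
                    and w.intronic_span[0] <= off <= w.intronic_span[1]
                    for w in ws
                )


class TestMapping:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cdna_genomic_round_trip(self, strand, toy_plus, toy_minus):
        t = toy_plus if strand == "+" else toy_minus
        for pos in range(1, t.cdna_length + 1):
            g = t.cdna_to_genomic(pos)
            assert t.genomic_to_cdna(g) == (pos, 0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intronic_offsets_round_trip(self, strand, toy_plus, toy_minus):
        t = toy_plus if strand == "+" else toy_minus
        for off in (1, 2, 3, 50):
            g = t.cdna_to_genomic(100, off)
            assert t.genomic_to_cdna(g) == (100, off)
        for off in (-1, -3, -50):
            g = t.cdna_to_genomic(101, off)
            assert t.genomic_to_cdna(g) == (101, off)

    def test_protein_mapping(self, toy_plus):
        assert map_cdna_to_protein(3, toy_plus)[0] == 1
        codon, dom = map_cdna_to_protein(43, toy_plus)  # codon 15
        assert codon == 15 and dom.name == "D"

    def test_protein_mapping_published_example(self, myo7a):
        codon, dom = map_cdna_to_protein(1200, myo7a)
        assert codon == 400  # p.Lys400=
        assert dom.name == "myosin motor"

    def test_utr_rejected(self):
        t = TranscriptModel("T", "+", ((0, 100),), 10, 99)
        with pytest.raises(NonCodingError):
            t.codon_of(5)


class TestExtendedRegion:
    def _hit(self, myo7a, windows, text):
        return variant_in_extended_region(parse_hgvs_c(text, myo7a), windows, myo7a)

    @pytest.mark.parametrize(
        "text",
        [
            "c.6558+4A>G",
            "c.6052-51_6052-11del",  # 5' end at -51 still overlaps -50..-3
            "c.592+33_593-31del",
            "c.1200G>A",  # last exonic base
            "c.1553A>G",  # 30 nt into the exon
            "c.3630+45C>T",
        ],
    )
    def test_in_region(self, myo7a, windows, text):
        assert self._hit(myo7a, windows, text).in_region

    def test_canonical_excluded(self, myo7a, windows):
        hit = self._hit(myo7a, windows, "c.6051+1G>A")
        assert not hit.in_region and hit.reason == "canonical"

    def test_boundary_plus_51_outside(self, myo7a, windows):
        hit = self._hit(myo7a, windows, "c.6558+51A>G")
        assert not hit.in_region and hit.reason == "outside"

    def test_deep_intronic_outside(self, myo7a, windows):
        assert not self._hit(myo7a, windows, "c.6558+300A>G").in_region

    def test_deep_exonic_outside(self, myo7a, windows):
        # c.5552 sits >50 nt from both junctions of its exon
        assert not self._hit(myo7a, windows, "c.5552T>C").in_region

    def test_range_touching_canonical_is_flagged(self, myo7a, windows):
        hit = self._hit(myo7a, windows, "c.592+1_592+10del")
        assert hit.in_region and hit.canonical_overlapping

    def test_transcript_mismatch(self, myo7a, windows):
        from minisplice.gene_model import TranscriptMismatchError

        v = CVariant("OTHER", 100, 0, 100, 0, "substitution", "A", "G")
        with pytest.raises(TranscriptMismatchError):
            variant_in_extended_region(v, windows, myo7a)

    def test_minus_strand_symmetry(self, toy_minus):
        ws = compute_region_windows(toy_minus)
        v = CVariant("TOY-", 100, 4, 100, 4, "substitution", "A", "G")
        assert variant_in_extended_region(v, ws, toy_minus).in_region
        v = CVariant("TOY-", 100, 1, 100, 1, "substitution", "G", "A")
        assert variant_in_extended_region(v, ws, toy_minus).reason == "canonical"


class TestIO:
    def test_hgvs_list_reader(self, tmp_path, myo7a):
        p = tmp_path / "variants.txt"
        p.write_text("# header\nc.6558+4A>G\nc.1200G>A  # trailing comment\n\n")
        from minisplice.gene_model import read_hgvs_list

        vs = read_hgvs_list(p, myo7a)
        assert [format_hgvs_c(v) for v in vs] == ["c.6558+4A>G", "c.1200G>A"]

    def test_vcf_reader_snv(self, tmp_path, toy_plus):
        from minisplice.gene_model import variants_from_vcf

        g = toy_plus.cdna_to_genomic(100, 4)  # intronic +4
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=2000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"chr1\t{g + 1}\t.\tA\tG\t50\tPASS\t.\n"
        )
        (v,) = variants_from_vcf(vcf, toy_plus)
        assert (v.start_pos, v.start_offset) == (100, 4)

    def test_gff3_loader(self, tmp_path):
        from minisplice.gene_model import transcript_from_gff3

        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t1001\t1650\t.\t+\t.\tID=tx1\n"
            "chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tParent=tx1\n"
            "chr1\tsrc\texon\t1301\t1390\t.\t+\t.\tParent=tx1\n"
            "chr1\tsrc\texon\t1541\t1650\t.\t+\t.\tParent=tx1\n"
            "chr1\tsrc\tCDS\t1001\t1100\t.\t+\t0\tParent=tx1\n"
            "chr1\tsrc\tCDS\t1301\t1390\t.\t+\t2\tParent=tx1\n"
            "chr1\tsrc\tCDS\t1541\t1650\t.\t+\t.\tParent=tx1\n"
        )
        t = transcript_from_gff3(gff, "tx1")
        assert t.cdna_length == 300
        assert (t.cds_start_cdna, t.cds_end_cdna) == (1, 300)
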