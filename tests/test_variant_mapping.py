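import numpy as np
import pytest

from modsplice import (
    Exon,
    Gene,
    Genome,
    GenomeAnnotation,
    RegionSequence,
    Variant,
    WindowSpec,
    apply_variant,
    map_variants_to_exons,
    read_vcf,
    reverse_complement,
    split_region,
)


def _hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="module")
def two_exon_gene():
    """One plus-strand gene with a 150-nt intron between two exons."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    genome = Genome({"c": seq})
    exons = [
        Exon("e1", "g", "c", "+", 200, 260),
        Exon("e2", "g", "c", "+", 410, 470),
    ]
    ann = GenomeAnnotation(genes=[Gene("g", "c", "+", 200, 470)], exons=exons)
    return genome, ann


class TestMapping:
    def test_variant_outside_window_yields_no_pair(self, two_exon_gene):
        genome, ann = two_exon_gene
        v = Variant("c", 200 - 150 + 1, genome.fetch("c", 50, 51), "A" if genome.fetch("c", 50, 51) != "A" else "C")
        assert map_variants_to_exons([v], ann, la=100, ld=100) == []

    def test_exonic_snv_yields_one_pair(self, two_exon_gene):
        genome, ann = two_exon_gene
        ref = genome.fetch("c", 220, 221)
        v = Variant("c", 221, ref, "A" if ref != "A" else "C")
        pairs = map_variants_to_exons([v], ann, la=100, ld=100)
        assert len(pairs) == 1
        assert pairs[0].exon.exon_id == "e1"

    def test_intronic_snv_between_exons_pairs_with_both(self, two_exon_gene):
        """60 nt past e1's donor and 90 nt before e2's acceptor: both
        exon windows contain the variant, so it is scored twice."""
        genome, ann = two_exon_gene
        pos0 = 260 + 60  # 0-based; 90 nt from the downstream acceptor at 410
        ref = genome.fetch("c", pos0, pos0 + 1)
        v = Variant("c", pos0 + 1, ref, "A" if ref != "A" else "C")
        pairs = map_variants_to_exons([v], ann, la=100, ld=100)
        assert {p.exon.exon_id for p in pairs} == {"e1", "e2"}

    def test_zero_flanks_keep_only_exonic_variants(self, two_exon_gene):
        genome, ann = two_exon_gene
        variants = []
        for pos0 in range(150, 520):
            ref = genome.fetch("c", pos0, pos0 + 1)
            variants.append(Variant("c", pos0 + 1, ref, "A" if ref != "A" else "C"))
        pairs = map_variants_to_exons(variants, ann, la=0, ld=0)
        for p in pairs:
            assert p.exon.start <= p.variant.start < p.exon.end


class TestApplyVariant:
    def test_snv_hamming_distance_one(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        pos0 = exon.start + 3
        ref = genome.fetch("c", pos0, pos0 + 1)
        alt = "A" if ref != "A" else "C"
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, alt), la=20, ld=20)
        assert len(pair.ref_region.sequence) == len(pair.alt_region.sequence)
        assert _hamming(pair.ref_region.sequence, pair.alt_region.sequence) == 1
        assert pair.alt_region.sequence[pair.alt_region.la + 3] == alt

    def test_exonic_insertion_preserves_flanks(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        pos0 = exon.start + 10
        ref = genome.fetch("c", pos0, pos0 + 1)
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, ref + "G"), la=25, ld=25)
        r, a = pair.ref_region, pair.alt_region
        assert a.exon_end - a.exon_start == (r.exon_end - r.exon_start) + 1
        assert (a.la, a.ld) == (r.la, r.ld) == (25, 25)
        assert a.sequence[:a.exon_start] == r.sequence[:r.exon_start]
        assert a.sequence[a.exon_end:] == r.sequence[r.exon_end:]

    def test_intronic_deletion_shortens_flank_source_only(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        pos0 = exon.end + 30  # donor-side intron, away from the splice site
        ref = genome.fetch("c", pos0, pos0 + 4)
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, ref[0]), la=20, ld=50)
        r, a = pair.ref_region, pair.alt_region
        assert a.exon_seq == r.exon_seq
        assert (a.la, a.ld) == (20, 50)
        # bases up to and including the anchor survive; the deleted span
        # is replaced by more distal intronic sequence
        kept = pos0 + 1 - exon.end
        assert a.sequence[a.exon_end:] == (
            r.sequence[r.exon_end:r.exon_end + kept]
            + genome.fetch("c", pos0 + 4, pos0 + 4 + 50 - kept)
        )

    def test_deletion_spanning_donor_relocates_splice_site(self, two_exon_gene):
        """Deleting the last 2 exonic and first 3 intronic nucleotides
        moves the donor to the deletion boundary; the donor-side flank
        is re-extracted beyond the deletion."""
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        anchor = exon.end - 3  # REF covers [end-2, end+3)
        ref = genome.fetch("c", anchor, anchor + 6)
        pair = apply_variant(genome, exon, Variant("c", anchor + 1, ref, ref[0]), la=20, ld=20)
        a = pair.alt_region
        assert a.exon_end - a.exon_start == len(exon) - 2
        assert (a.la, a.ld) == (20, 20)
        assert a.sequence[a.exon_end:] == genome.fetch("c", exon.end + 3, exon.end + 3 + 20)

    def test_deletion_containing_exon_rejected(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        anchor = exon.start - 2
        ref = genome.fetch("c", anchor, exon.end + 3)
        with pytest.raises(ValueError, match="deletes exon"):
            apply_variant(genome, exon, Variant("c", anchor + 1, ref, ref[0]), la=20, ld=20)

    def test_ref_mismatch_rejected(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]
        pos0 = exon.start + 3
        ref = genome.fetch("c", pos0, pos0 + 1)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="REF mismatch"):
            apply_variant(genome, exon, Variant("c", pos0 + 1, wrong, ref), la=10, ld=10)

    def test_minus_strand_is_reverse_complement_of_plus(self, two_exon_gene):
        """The same genomic locus read as a minus-strand exon gives the
        reverse-complemented regions for the same variant."""
        genome, ann = two_exon_gene
        plus = ann.exons[0]
        minus = Exon("em", "gm", "c", "-", plus.start, plus.end)
        pos0 = plus.start + 7
        ref = genome.fetch("c", pos0, pos0 + 1)
        v = Variant("c", pos0 + 1, ref, "A" if ref != "A" else "C")
        p_plus = apply_variant(genome, plus, v, la=15, ld=15)
        p_minus = apply_variant(genome, minus, v, la=15, ld=15)
        assert p_minus.ref_region.sequence == reverse_complement(p_plus.ref_region.sequence)
        assert p_minus.alt_region.sequence == reverse_complement(p_plus.alt_region.sequence)


class TestSplitRegion:
    def test_default_window_lengths(self, two_exon_gene):
        genome, ann = two_exon_gene
        exon = ann.exons[0]  # 60 nt
        from modsplice import extract_region

        region = extract_region(genome, exon, la=100, ld=100)
        parts = split_region(region)
        assert len(parts["donor"]) == 18
        assert len(parts["acceptor"]) == 53
        assert len(parts["exon"]) == 60
        assert len(parts["intron3p"]) == 100
        assert len(parts["intron5p"]) == 100
        # windows tile the region consistently
        assert parts["donor"] == region.sequence[region.exon_end - 5:region.exon_end + 13]
        assert parts["acceptor"] == region.sequence[region.exon_start - 50:region.exon_start + 3]

    def test_zero_flanks_pad_splice_windows(self):
        region = RegionSequence("ACGTACGTAC", 0, 10)
        parts = split_region(region)
        assert parts["intron3p"] == "" and parts["intron5p"] == ""
        assert len(parts["donor"]) == 18 and parts["donor"].endswith("N" * 13)
        assert len(parts["acceptor"]) == 53 and parts["acceptor"].startswith("N" * 50)

    def test_short_exon_padded_not_rejected(self):
        region = RegionSequence("A" * 20 + "CG" + "T" * 20, 20, 22)
        parts = split_region(region)
        assert len(parts["donor"]) == 18 and len(parts["acceptor"]) == 53
        assert parts["exon"] == "CG"


class TestVcfReading:
    def test_multiallelic_decomposed(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t10\trs1\tA\tC,G\t.\tPASS\t.\n"
            "c\t20\t.\tAT\tA\t.\tPASS\t.\n"
        )
        variants = read_vcf(vcf)
        assert len(variants) == 3
        assert [v.alt for v in variants] == ["C", "G", "A"]
        assert variants[0].id == "rs1.1" and variants[1].id == "rs1.2"
        assert variants[2].ref == "AT"
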