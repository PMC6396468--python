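"""Variant-to-exon pairing and alternative-allele sequence construction.

A variant is paired with every exon whose scoring window (exon plus
``la`` acceptor-side and ``ld`` donor-side intronic nucleotides) its
reference-allele interval intersects; one variant can therefore yield
zero, one, or many variant-exon pairs, each scored independently.

Alternative sequences always keep the structure of the reference
sequence: an exon of flexible length flanked by exactly ``la`` and
``ld`` intronic nucleotides. For deletions that span a splice site the
new splice site is placed at the deletion boundary and the flanks are
re-extracted downstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import (
    Exon,
    Genome,
    GenomeAnnotation,
    RegionSequence,
    reverse_complement,
)


@dataclass(frozen=True)
class Variant:
    """A normalized variant: 1-based VCF position, single ALT allele."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")

    @property
    def start(self) -> int:
        """0-based start of the REF interval."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the REF interval."""
        return self.pos - 1 + len(self.ref)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


def read_vcf(vcf_path: str | Path) -> list[Variant]:
    """Read a VCF 4.x file; multi-allelic records are decomposed into
    one :class:`Variant` per ALT allele."""
    from cyvcf2 import VCF

    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    out: list[Variant] = []
    for rec in VCF(str(path)):
        for k, alt in enumerate(rec.ALT):
            vid = rec.ID if rec.ID else None
            if vid is not None and len(rec.ALT) > 1:
                vid = f"{vid}.{k + 1}"
            out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt, id=vid))
    return out


@dataclass
class VariantExonPair:
    """One variant applied to one candidate exon (the unit of prediction)."""

    variant: Variant
    exon: Exon
    ref_region: RegionSequence | None = None
    alt_region: RegionSequence | None = None

    @property
    def filled(self) -> bool:
        return self.ref_region is not None and self.alt_region is not None


def _exon_window(exon: Exon, la: int, ld: int) -> tuple[int, int]:
    """Genomic interval of the exon's scoring window."""
    if exon.strand == "+":
        return exon.start - la, exon.end + ld
    return exon.start - ld, exon.end + la


def map_variants_to_exons(
    variants: Iterable[Variant],
    annotation: GenomeAnnotation,
    la: int = 100,
    ld: int = 100,
) -> list[VariantExonPair]:
    """Pair each variant with every exon whose window it intersects.

    The intersection rule uses the variant's REF interval, so an
    insertion occupies its single anchor base. Regions are left unfilled
    (use :func:`apply_variant` to fill them).
    """
    if la < 0 or ld < 0:
        raise ValueError("la and ld must be >= 0")
    by_contig: dict[str, list[Exon]] = {}
    for exon in annotation.exons:
        by_contig.setdefault(exon.contig, []).append(exon)
    pairs = []
    for var in variants:
        for exon in by_contig.get(var.contig, ()):
            w0, w1 = _exon_window(exon, la, ld)
            if var.start < w1 and var.end > w0:
                pairs.append(VariantExonPair(variant=var, exon=exon))
    return pairs


def _mutated_slice(
    genome: Genome,
    contig: str,
    variant: Variant,
    m_start: int,
    m_end: int,
) -> str:
    """Slice ``[m_start, m_end)`` of the mutated contig.

    Mutated coordinates equal genomic coordinates up to ``variant.start``;
    the ALT allele occupies ``[variant.start, variant.start+len(alt))``;
    beyond it, coordinates are shifted by the length change.
    """
    v0 = variant.start
    alt = variant.alt
    shift = variant.length_change
    parts = []
    if m_start < v0:
        parts.append(genome.fetch(contig, m_start, min(m_end, v0)))
    a0, a1 = max(m_start - v0, 0), min(m_end - v0, len(alt))
    if a1 > a0:
        parts.append(alt[a0:a1])
    tail_start = max(m_start, v0 + len(alt))
    if m_end > tail_start:
        parts.append(genome.fetch(contig, tail_start - shift, m_end - shift))
    return "".join(parts)


def apply_variant(
    genome: Genome,
    exon: Exon,
    variant: Variant,
    la: int = 100,
    ld: int = 100,
) -> VariantExonPair:
    """Construct reference and alternative regions for one pair.

    SNVs change one base in place. Insertions and deletions confined to
    one segment lengthen or shorten that segment; the other segments are
    unchanged. A deletion overlapping a splice site removes the deleted
    span and relocates the splice site to the deletion boundary, after
    which the intronic flanks are re-extracted so the alternative region
    again has exactly ``la`` and ``ld`` intronic nucleotides.
    """
    observed = genome.fetch(exon.contig, variant.start, variant.end)
    if observed != variant.ref.upper():
        raise ValueError(
            f"REF mismatch at {exon.contig}:{variant.pos}: "
            f"VCF says {variant.ref!r}, genome has {observed!r}"
        )
    w0, w1 = _exon_window(exon, la, ld)
    if not (variant.start < w1 and variant.end > w0):
        raise ValueError("variant does not intersect the exon's window")

    ref_seq = genome.fetch(exon.contig, w0, w1)

    v0, v1 = variant.start, variant.end
    shift = variant.length_change
    alt_end_in_m = v0 + len(variant.alt)

    def move(boundary: int) -> int:
        # map an exon boundary into mutated coordinates; boundaries that
        # fall strictly inside a length-changing variant snap to the end
        # of the ALT allele ("the new splice site is defined as the
        # boundaries of the deletion")
        if boundary <= v0 or shift == 0:
            return boundary
        if boundary >= v1:
            return boundary + shift
        return alt_end_in_m

    m_exon_start = move(exon.start)
    m_exon_end = move(exon.end)
    if m_exon_end - m_exon_start < 1:
        raise ValueError(
            f"variant {variant.contig}:{variant.pos} deletes exon "
            f"{exon.exon_id} entirely; no exon remains to score"
        )
    if exon.strand == "+":
        m_w0, m_w1 = m_exon_start - la, m_exon_end + ld
    else:
        m_w0, m_w1 = m_exon_start - ld, m_exon_end + la
    alt_seq = _mutated_slice(genome, exon.contig, variant, m_w0, m_w1)

    if exon.strand == "-":
        ref_region = RegionSequence(reverse_complement(ref_seq), la, la + len(exon))
        alt_exon_len = m_exon_end - m_exon_start
        alt_region = RegionSequence(
            reverse_complement(alt_seq), la, la + alt_exon_len
        )
    else:
        ref_region = RegionSequence(ref_seq, la, la + len(exon))
        alt_region = RegionSequence(alt_seq, la, la + (m_exon_end - m_exon_start))
    return VariantExonPair(variant, exon, ref_region, alt_region)


@dataclass(frozen=True)
class WindowSpec:
    """Widths of the splice-site scoring windows (nucleotides).

    The donor window spans the last ``donor_exonic`` exonic and first
    ``donor_intronic`` intronic nucleotides; the acceptor window spans
    the last ``acceptor_intronic`` intronic and first ``acceptor_exonic``
    exonic nucleotides (chosen to cover most branchpoints).
    """

    donor_exonic: int = 5
    donor_intronic: int = 13
    acceptor_intronic: int = 50
    acceptor_exonic: int = 3

    @property
    def donor_len(self) -> int:
        return self.donor_exonic + self.donor_intronic

    @property
    def acceptor_len(self) -> int:
        return self.acceptor_intronic + self.acceptor_exonic


def _padded_window(seq: str, start: int, end: int) -> str:
    """``seq[start:end]`` with N-padding where the span leaves the string."""
    left = "N" * max(0, -start)
    right = "N" * max(0, end - len(seq))
    return left + seq[max(start, 0):min(end, len(seq))] + right


def split_region(region: RegionSequence, windows: WindowSpec = WindowSpec()) -> dict[str, str]:
    """Cut a region into the five module inputs.

    Returns donor and acceptor splice-site windows (fixed length,
    N-padded when the exon or flank is shorter than the window), the
    full exon segment, and the two intronic flanks.
    """
    s, es, ee = region.sequence, region.exon_start, region.exon_end
    return {
        "donor": _padded_window(s, ee - windows.donor_exonic, ee + windows.donor_intronic),
        "acceptor": _padded_window(s, es - windows.acceptor_intronic, es + windows.acceptor_exonic),
        "exon": s[es:ee],
        "intron3p": s[:es],
        "intron5p": s[ee:],
    }


def overlap_indicators(
    variant: Variant, exon: Exon, windows: WindowSpec = WindowSpec()
) -> tuple[int, int, int]:
    """Indicators for the doubly-scored windows a variant falls in.

    Returns ``(exon_ss, intron5p_donor, intron3p_acceptor)``: whether the
    variant's REF interval intersects the exonic part of a splice-site
    window, the intronic part of the donor window, or the intronic part
    of the acceptor window. These feed the interaction terms that keep
    doubly-scored variants from being double counted.
    """
    v0, v1 = variant.start, variant.end
    if exon.strand == "+":
        acc_ex = (exon.start, exon.start + windows.acceptor_exonic)
        don_ex = (exon.end - windows.donor_exonic, exon.end)
        don_in = (exon.end, exon.end + windows.donor_intronic)
        acc_in = (exon.start - windows.acceptor_intronic, exon.start)
    else:
        acc_ex = (exon.end - windows.acceptor_exonic, exon.end)
        don_ex = (exon.start, exon.start + windows.donor_exonic)
        don_in = (exon.start - windows.donor_intronic, exon.start)
        acc_in = (exon.end, exon.end + windows.acceptor_intronic)

    def hits(iv):
        return int(v0 < iv[1] and v1 > iv[0])

    exon_ss = int(hits(acc_ex) or hits(don_ex))
    return exon_ss, hits(don_in), hits(acc_in)


def pairs_from_table(
    rows: Sequence[tuple[Variant, Exon]],
    genome: Genome,
    la: int = 100,
    ld: int = 100,
) -> list[VariantExonPair]:
    """Fill regions for assay-defined (variant, exon) pairings."""
    return [apply_variant(genome, exon, var, la, ld) for var, exon in rows]
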