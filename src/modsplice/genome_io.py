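"""Genome, annotation and sequence I/O.

All coordinates are 0-based half-open internally. GTF input is read as
1-based inclusive, VCF as 1-based with a REF anchor. Every extracted
region is returned in transcript 5'->3' orientation, so downstream
scoring modules never see strand.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")

# column order of the one-hot encoding; fixed so fixtures are bit-exact
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Random-access view of a reference genome.

    Wraps either an indexed FASTA file (via pyfaidx) or an in-memory
    mapping of contig name to sequence. Sequences are uppercased on
    access; slices use 0-based half-open intervals.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, fasta_path: str | Path) -> "Genome":
        import pyfaidx

        path = Path(fasta_path)
        if not path.exists():
            raise FileNotFoundError(f"FASTA not found: {path}")
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, contig: str) -> int:
        self._check(contig)
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig[start:end)``; errors outside bounds."""
        self._check(contig)
        seq = self._contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def reverse_complemented(self) -> "Genome":
        """A genome with every contig reverse-complemented (testing aid)."""
        return Genome({c: reverse_complement(s) for c, s in self._contigs.items()})

    def _check(self, contig: str) -> None:
        if contig not in self._contigs:
            raise KeyError(f"unknown contig {contig!r}")


def load_genome(fasta_path: str | Path) -> Genome:
    """Load an (indexable) FASTA file into a :class:`Genome`."""
    return Genome.from_fasta(fasta_path)


@dataclass(frozen=True)
class Exon:
    """An annotated exon with internal 0-based half-open coordinates."""

    exon_id: str
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"exon start {self.start} !< end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int


@dataclass
class GenomeAnnotation:
    """Genes and their (deduplicated) stranded exon intervals."""

    genes: list[Gene]
    exons: list[Exon]

    def exons_of(self, gene_id: str) -> list[Exon]:
        return [e for e in self.exons if e.gene_id == gene_id]

    def validate_against(self, genome: Genome) -> None:
        for exon in self.exons:
            if exon.contig not in genome.contigs:
                raise ValueError(f"exon {exon.exon_id} on unknown contig {exon.contig}")
            if exon.end > genome.contig_length(exon.contig):
                raise ValueError(f"exon {exon.exon_id} extends past contig end")


def load_annotation(gtf_path: str | Path) -> GenomeAnnotation:
    """Read exon records from a GTF (Ensembl dialect) file.

    Exons sharing (contig, strand, start, end) across transcripts are
    collapsed to one record. Coordinates are converted from GTF 1-based
    inclusive to internal 0-based half-open.
    """
    import gffutils

    path = Path(gtf_path)
    if not path.exists():
        raise FileNotFoundError(f"GTF not found: {path}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    seen: dict[tuple, Exon] = {}
    gene_span: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        if "gene_id" not in feat.attributes:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks gene_id")
        gene_id = feat.attributes["gene_id"][0]
        start, end = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
        if start >= end:
            raise ValueError(f"exon with start {feat.start} > end {feat.end}")
        key = (feat.seqid, feat.strand, start, end)
        if key not in seen:
            seen[key] = Exon(
                exon_id=f"{gene_id}.e{len(seen) + 1}",
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
            )
        span = gene_span.setdefault(gene_id, [feat.seqid, feat.strand, start, end])
        span[2] = min(span[2], start)
        span[3] = max(span[3], end)

    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        genes.append(Gene(gid, feat.seqid, feat.strand, feat.start - 1, feat.end))
        gene_span.pop(gid, None)
    # genes not declared explicitly: infer spans from their exons
    for gid, (contig, strand, start, end) in gene_span.items():
        genes.append(Gene(gid, contig, strand, start, end))

    return GenomeAnnotation(genes=genes, exons=list(seen.values()))


@dataclass
class RegionSequence:
    """An exon with its intronic flanks, in transcript orientation.

    ``sequence`` reads acceptor-side flank, exon, donor-side flank in
    the transcript 5'->3' direction; ``la`` and ``ld`` are the flank
    lengths on the acceptor and donor sides.
    """

    sequence: str
    exon_start: int
    exon_end: int

    def __post_init__(self):
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        if self.exon_start < 0 or self.exon_end > len(self.sequence):
            raise ValueError("exon offsets outside sequence")
        if self.exon_end - self.exon_start < 1:
            raise ValueError("exon length must be >= 1")

    @property
    def la(self) -> int:
        return self.exon_start

    @property
    def ld(self) -> int:
        return len(self.sequence) - self.exon_end

    @property
    def exon_seq(self) -> str:
        return self.sequence[self.exon_start:self.exon_end]


def extract_region(genome: Genome, exon: Exon, la: int = 100, ld: int = 100) -> RegionSequence:
    """Exon sequence plus ``la``/``ld`` intronic flanking nucleotides.

    For minus-strand exons the genomic slice is reverse-complemented so
    that the acceptor-side flank comes first; all strand handling is
    confined to this function.
    """
    if la < 0 or ld < 0:
        raise ValueError("flank lengths must be >= 0")
    if exon.strand == "+":
        g_start, g_end = exon.start - la, exon.end + ld
    else:
        g_start, g_end = exon.start - ld, exon.end + la
    seq = genome.fetch(exon.contig, g_start, g_end)
    if exon.strand == "-":
        seq = reverse_complement(seq)
    return RegionSequence(sequence=seq, exon_start=la, exon_end=la + len(exon))


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a nucleotide string.

    Rows are positions, columns are A, C, G, T in that fixed order.
    ``N`` encodes as an all-zero row. Case-insensitive.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"characters outside A/C/G/T/N alphabet: {sorted(bad)}")
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    for i, base in enumerate(seq):
        if base != "N":
            mat[i, BASE_INDEX[base]] = 1.0
    return mat


def one_hot_batch(sequences: Iterable[str]) -> np.ndarray:
    """Stack equal-length sequences into a (n, length, 4) array."""
    mats = [one_hot(s) for s in sequences]
    lengths = {m.shape[0] for m in mats}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.stack(mats)
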