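"""Synthetic genomes, MPRA-like libraries and variant truth sets.

Everything the tool consumes can be generated here from a seed: a mini
genome with stranded multi-exon genes and canonical GT/AG boundaries at
a configurable rate, random 25-nt reporter libraries whose PSI labels
come from a planted-motif ground-truth model, and VCF variant sets
whose true effects are simulated from known composition-model
coefficients applied to actual module score differences. Each generator
is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition_models import ModuleDeltaScores, feature_matrix, module_delta_scores, sigmoid
from .genome_io import Genome, GenomeAnnotation, reverse_complement
from .neural_modules import LabeledSequenceSet, ScoringModule
from .variant_mapping import Variant, apply_variant

BASES = np.array(list("ACGT"))


@dataclass
class GroundTruth:
    """Everything that determines the generated labels up to noise."""

    seed: int
    canonical_rate: float | None = None
    motif: str | None = None
    motif_strength: float | None = None
    plant_probs: tuple[float, ...] | None = None
    noise_sd: float | None = None
    true_beta: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# mini genome


@dataclass
class MiniGenome:
    fasta_path: Path
    gtf_path: Path
    truth: GroundTruth


def generate_mini_genome(
    out_dir: str | Path,
    n_genes: int = 12,
    exons_per_gene: int = 3,
    intron_len: int = 120,
    exon_len: int = 40,
    canonical_rate: float = 1.0,
    seed: int = 0,
    utr_margin: int = 150,
    spacer: int = 60,
) -> MiniGenome:
    """Write a single-contig mini genome (FASTA) and annotation (GTF).

    Genes alternate between strands. In transcript orientation each
    intron starts with GT and ends with AG with probability
    ``canonical_rate`` (independently per dinucleotide); otherwise a
    random non-canonical dinucleotide is used. ``utr_margin`` random
    bases surround each gene so 100-nt flanks always stay on-contig.
    """
    if exons_per_gene < 1 or exon_len < 8 or intron_len < 20:
        raise ValueError("infeasible gene geometry")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    contig_parts: list[str] = []
    gtf_lines: list[str] = []
    offset = 0
    contig = "chrS"

    def non_canonical(canon: str) -> str:
        while True:
            d = _random_seq(rng, 2)
            if d != canon:
                return d

    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"g{g + 1}"
        # build gene in transcript orientation
        tx_parts: list[str] = []
        exon_bounds: list[tuple[int, int]] = []  # transcript coordinates
        pos = 0
        for e in range(exons_per_gene):
            exon_seq = _random_seq(rng, exon_len)
            tx_parts.append(exon_seq)
            exon_bounds.append((pos, pos + exon_len))
            pos += exon_len
            if e < exons_per_gene - 1:
                donor = "GT" if rng.random() < canonical_rate else non_canonical("GT")
                acceptor = "AG" if rng.random() < canonical_rate else non_canonical("AG")
                intron = donor + _random_seq(rng, intron_len - 4) + acceptor
                tx_parts.append(intron)
                pos += intron_len
        gene_seq = "".join(tx_parts)
        gene_len = len(gene_seq)

        margin_seq = _random_seq(rng, utr_margin)
        contig_parts.append(margin_seq)
        offset += utr_margin
        gene_start = offset  # genomic, 0-based
        contig_parts.append(gene_seq if strand == "+" else reverse_complement(gene_seq))
        offset += gene_len
        contig_parts.append(_random_seq(rng, spacer))
        offset += spacer

        gtf_exons = []
        for (t0, t1) in exon_bounds:
            if strand == "+":
                g0, g1 = gene_start + t0, gene_start + t1
            else:
                g0, g1 = gene_start + gene_len - t1, gene_start + gene_len - t0
            gtf_exons.append((g0, g1))
        gtf_exons.sort()
        attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
        g0, g1 = gene_start, gene_start + gene_len
        gtf_lines.append(
            f"{contig}\tmodsplice\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t{attrs}"
        )
        gtf_lines.append(
            f"{contig}\tmodsplice\ttranscript\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t{attrs}"
        )
        for (e0, e1) in gtf_exons:
            gtf_lines.append(
                f"{contig}\tmodsplice\texon\t{e0 + 1}\t{e1}\t.\t{strand}\t.\t{attrs}"
            )

    contig_parts.append(_random_seq(rng, utr_margin))
    sequence = "".join(contig_parts)

    fasta_path = out_dir / "mini_genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i:i + 60] + "\n")
    gtf_path = out_dir / "mini_genome.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + "\n")

    truth = GroundTruth(seed=seed, canonical_rate=canonical_rate,
                        extra={"n_genes": n_genes, "exons_per_gene": exons_per_gene})
    return MiniGenome(fasta_path=fasta_path, gtf_path=gtf_path, truth=truth)


# ---------------------------------------------------------------------------
# MPRA-like library


@dataclass
class MpraLibrary:
    """A labeled random-sequence library with its noise-free truth."""

    dataset: LabeledSequenceSet
    psi_true: np.ndarray  # noise-free sigma(strength * occurrences)
    occurrences: np.ndarray
    truth: GroundTruth


def _count_occurrences(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        hit = seq.find(motif, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1  # overlapping matches count


def generate_mpra_like(
    n: int,
    seq_len: int = 25,
    motif: str = "GAAGAA",
    strength: float = 4.0,
    plant_probs: Sequence[float] = (0.5, 0.3, 0.2),
    noise_sd: float = 0.3,
    seed: int = 0,
    task: str | None = None,
) -> MpraLibrary:
    """Random reporter sequences with planted-motif PSI labels.

    Each sequence receives 0, 1 or 2 planted copies of the consensus
    motif (probabilities ``plant_probs``); the label is
    sigma(strength * total_occurrences + Normal(0, noise_sd)), counting
    every occurrence in the final sequence. A sequence without the
    motif therefore has noise-free PSI of exactly sigma(0) = 0.5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(motif) > seq_len:
        raise ValueError("motif longer than sequence")
    probs = np.asarray(plant_probs, dtype=np.float64)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("plant_probs must be a probability vector")
    rng = np.random.default_rng(seed)
    k = len(motif)

    sequences = []
    for _ in range(n):
        seq = list(_random_seq(rng, seq_len))
        copies = int(rng.choice(len(probs), p=probs))
        if copies:
            max_slots = seq_len // k
            copies = min(copies, max_slots)
            # non-overlapping slots keep planted copies intact
            slots = rng.choice(max_slots, size=copies, replace=False)
            for s in slots:
                seq[s * k:(s + 1) * k] = motif
        sequences.append("".join(seq))

    occ = np.array([_count_occurrences(s, motif) for s in sequences])
    score_true = strength * occ
    psi_true = sigmoid(score_true)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    psi = sigmoid(score_true + noise)
    split = np.where(rng.random(n) < 0.8, "train", "val")
    dataset = LabeledSequenceSet(
        sequences=sequences,
        labels=psi,
        split=split,
        task=np.full(n, task) if task else None,
    )
    truth = GroundTruth(
        seed=seed, motif=motif, motif_strength=strength,
        plant_probs=tuple(probs), noise_sd=noise_sd,
    )
    return MpraLibrary(dataset=dataset, psi_true=np.asarray(psi_true), occurrences=occ, truth=truth)


# ---------------------------------------------------------------------------
# variant truth set


@dataclass
class VariantTruthSet:
    vcf_path: Path
    table_path: Path
    table: "object"  # pandas DataFrame
    scores: list[ModuleDeltaScores]
    truth: GroundTruth


def _write_vcf(path: Path, contig_lengths: Mapping[str, int], variants: Sequence[Variant]) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
        lines.append(f"{v.contig}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t.")
    path.write_text("\n".join(lines) + "\n")


def generate_variant_truth_set(
    genome: Genome,
    annotation: GenomeAnnotation,
    modules: Mapping[str, ScoringModule],
    out_dir: str | Path,
    n_variants: int = 300,
    indel_frac: float = 0.2,
    true_beta: np.ndarray | None = None,
    noise_sd: float = 0.0,
    psi_ref_range: tuple[float, float] = (0.1, 0.9),
    la: int = 100,
    ld: int = 100,
    exon_head: str = "exon5p",
    max_indel: int = 10,
    seed: int = 0,
) -> VariantTruthSet:
    """Variants with ground-truth effects from known coefficients.

    SNVs and short indels (up to ``max_indel`` nt, with 5% of indels
    drawn as deletions spanning a splice site to exercise boundary
    relocation) are placed across exons and their 100-nt intronic
    flanks. The true delta-logit(PSI) of each variant is the
    nine-parameter linear model with ``true_beta`` applied to the actual
    module score differences, plus Gaussian noise of ``noise_sd``.
    """
    import pandas as pd

    if not annotation.exons:
        raise ValueError("annotation has no exons")
    if not 0.0 <= indel_frac <= 1.0:
        raise ValueError("indel_frac must be in [0, 1]")
    if true_beta is None:
        true_beta = np.array([0.1, -0.8, -1.2, -1.0, -1.5, -0.9, 0.5, 0.6, 0.4])
    true_beta = np.asarray(true_beta, dtype=np.float64)
    if true_beta.size != 9:
        raise ValueError("true_beta must have nine entries (intercept + 8)")

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    variants, exon_ids, scores_rows = [], [], []
    i = 0
    attempts = 0
    while i < n_variants:
        attempts += 1
        if attempts > 100 * n_variants:
            raise RuntimeError("could not place the requested number of variants")
        exon = annotation.exons[rng.integers(len(annotation.exons))]
        w0 = max(exon.start - la, 1)
        w1 = min(exon.end + ld, genome.contig_length(exon.contig) - max_indel - 1)
        if w1 <= w0:
            continue
        is_indel = rng.random() < indel_frac
        if not is_indel:
            p = int(rng.integers(w0, w1))
            ref = genome.fetch(exon.contig, p, p + 1)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            length = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.05:
                # deletion spanning a splice site: anchor just before a boundary
                boundary = exon.start if rng.random() < 0.5 else exon.end
                p = boundary - int(rng.integers(1, min(length, 3) + 1))
                if p < 1:
                    continue
                ref = genome.fetch(exon.contig, p, p + 1 + length)
                alt = ref[0]
            elif rng.random() < 0.5:  # plain deletion
                p = int(rng.integers(w0, w1))
                if p + 1 + length > genome.contig_length(exon.contig):
                    continue
                ref = genome.fetch(exon.contig, p, p + 1 + length)
                alt = ref[0]
            else:  # insertion
                p = int(rng.integers(w0, w1))
                ref = genome.fetch(exon.contig, p, p + 1)
                alt = ref + _random_seq(rng, length)
        var = Variant(exon.contig, p + 1, ref, alt, id=f"v{i + 1}")
        try:
            pair = apply_variant(genome, exon, var, la, ld)
        except ValueError:
            continue
        scores = module_delta_scores(pair, modules, exon_head=exon_head)
        variants.append(var)
        exon_ids.append(exon.exon_id)
        scores_rows.append(scores)
        i += 1

    X = feature_matrix(scores_rows, "delta")
    noise = rng.normal(0.0, noise_sd, size=n_variants) if noise_sd > 0 else np.zeros(n_variants)
    dlogit = true_beta[0] + X @ true_beta[1:] + noise
    psi_ref = rng.uniform(*psi_ref_range, size=n_variants)

    vcf_path = out_dir / "truth_variants.vcf"
    _write_vcf(vcf_path, {c: genome.contig_length(c) for c in genome.contigs}, variants)

    table = pd.DataFrame({
        "variant_id": [v.id for v in variants],
        "contig": [v.contig for v in variants],
        "pos": [v.pos for v in variants],
        "ref": [v.ref for v in variants],
        "alt": [v.alt for v in variants],
        "exon_id": exon_ids,
        "dS_intron3p": [s.dS_intron3p for s in scores_rows],
        "dS_acceptor": [s.dS_acceptor for s in scores_rows],
        "dS_exon": [s.dS_exon for s in scores_rows],
        "dS_donor": [s.dS_donor for s in scores_rows],
        "dS_intron5p": [s.dS_intron5p for s in scores_rows],
        "ind_exon_ss": [s.ind_exon_ss for s in scores_rows],
        "ind_intron5p_donor": [s.ind_intron5p_donor for s in scores_rows],
        "ind_intron3p_acceptor": [s.ind_intron3p_acceptor for s in scores_rows],
        "delta_logit_psi": dlogit,
        "psi_ref": psi_ref,
    })
    table_path = out_dir / "truth_effects.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    truth = GroundTruth(seed=seed, true_beta=true_beta, noise_sd=noise_sd,
                        extra={"indel_frac": indel_frac, "n_variants": n_variants})
    return VariantTruthSet(vcf_path=vcf_path, table_path=table_path, table=table,
                           scores=scores_rows, truth=truth)


def scores_from_frame(df) -> list[ModuleDeltaScores]:
    """Rebuild ModuleDeltaScores rows from an effects table."""
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(ModuleDeltaScores(
            dS_intron3p=rec.dS_intron3p,
            dS_acceptor=rec.dS_acceptor,
            dS_exon=rec.dS_exon,
            dS_donor=rec.dS_donor,
            dS_intron5p=rec.dS_intron5p,
            ind_exon_ss=int(rec.ind_exon_ss),
            ind_intron5p_donor=int(rec.ind_intron5p_donor),
            ind_intron3p_acceptor=int(rec.ind_intron3p_acceptor),
        ))
    return rows
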