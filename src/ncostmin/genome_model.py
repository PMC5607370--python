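"""Genome sequences, gene annotations, and coordinate arithmetic.

All internal coordinates are 0-based half-open genome offsets. GFF3 input
(1-based inclusive) is converted on load; BED output is written 0-based
half-open per the BED standard. Strands are ``+`` / ``-``; strand-agnostic
intervals use ``.``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .errors import AlphabetError, CoordinateError, FastaFormatError, FrameError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon: identifier plus an upper-case DNA sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; reverse-complemented for ``-``."""
        seq = self.sequence[start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene with 0-based half-open genomic coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    is_coding: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic offset of the gene's first transcribed/translated base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GenomicInterval:
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_sequence(seq: str, record_id: str) -> None:
    for offset, base in enumerate(seq):
        if base not in VALID_BASES:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {base!r} at offset {offset}"
            )


def load_genome(fasta_path: str | os.PathLike) -> GenomeRecord:
    """Load the first record of a FASTA file as a validated GenomeRecord.

    Lowercase bases are normalized to uppercase. Only {A, C, G, T, N} are
    accepted; the first offending position is reported.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FastaFormatError(f"{fasta_path}: no FASTA records found")
    if len(records) > 1:
        logger.warning(
            "%s: %d records found; single-replicon mode uses the first (%s)",
            fasta_path, len(records), records[0].id,
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise FastaFormatError(f"{fasta_path}: record {rec.id!r} has empty sequence")
    _validate_sequence(seq, rec.id)
    return GenomeRecord(id=rec.id, sequence=seq)


_ID_KEYS = ("locus_tag", "ID", "gene_id", "Name", "gene")


def _feature_id(feat) -> str:
    for key in _ID_KEYS:
        if key in feat.attributes:
            return feat.attributes[key][0]
    return f"{feat.featuretype}:{feat.seqid}:{feat.start}-{feat.end}"


def load_annotation(gff_path: str | os.PathLike, genome: GenomeRecord) -> list[GeneFeature]:
    """Load CDS/gene features from GFF3, converting to 0-based half-open.

    CDS features are taken as coding genes; ``gene`` features without a CDS
    of the same identifier become non-coding entries. Features without a
    strand are rejected with a warning; features exceeding the genome raise
    CoordinateError.
    """
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:",
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # malformed coordinates surface from gffutils/sqlite
        raise CoordinateError(f"{gff_path}: failed to parse GFF3 ({exc})") from exc

    features: dict[str, GeneFeature] = {}
    noncoding: dict[str, GeneFeature] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        gene_id = _feature_id(feat)
        if feat.strand not in ("+", "-"):
            logger.warning("%s: feature %s has no strand; rejected", gff_path, gene_id)
            continue
        start0, end0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if start0 >= end0:
            raise CoordinateError(f"{gene_id}: start {feat.start} > end {feat.end}")
        if start0 < 0 or end0 > genome.length:
            raise CoordinateError(
                f"{gene_id}: span [{feat.start}, {feat.end}] exceeds genome "
                f"length {genome.length}"
            )
        gf = GeneFeature(gene_id=gene_id, start=start0, end=end0,
                         strand=feat.strand, is_coding=feat.featuretype == "CDS")
        (features if gf.is_coding else noncoding)[gene_id] = gf
    for gene_id, gf in noncoding.items():
        features.setdefault(gene_id, gf)
    return sorted(features.values(), key=lambda g: (g.start, g.end, g.gene_id))


def upstream_region(gene: GeneFeature, length_bp: int, genome_length: int) -> GenomicInterval:
    """Strand-aware upstream interval of ``length_bp``, clipped to the genome."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if gene.strand == "+":
        return GenomicInterval(max(0, gene.start - length_bp), gene.start, "+")
    return GenomicInterval(gene.end, min(genome_length, gene.end + length_bp), "-")


def noncoding_regions(genome: GenomeRecord, genes: list[GeneFeature]) -> list[GenomicInterval]:
    """Strand-agnostic complement of the union of gene bodies."""
    spans = sorted((g.start, g.end) for g in genes)
    out: list[GenomicInterval] = []
    cursor = 0
    for start, end in spans:
        if start > cursor:
            out.append(GenomicInterval(cursor, start))
        cursor = max(cursor, end)
    if cursor < genome.length:
        out.append(GenomicInterval(cursor, genome.length))
    return out


def coding_codons(gene: GeneFeature, genome: GenomeRecord) -> list[str]:
    """Codons of a coding gene in reading order (codon 0 is the initiator).

    The trailing stop codon is retained so codon statistics stay consistent
    with the annotated CDS span; translation strips it.
    """
    if not gene.is_coding:
        raise ValueError(f"{gene.gene_id}: not a coding gene")
    seq = genome.slice(gene.start, gene.end, gene.strand)
    if len(seq) % 3 != 0:
        raise FrameError(
            f"{gene.gene_id}: CDS length {len(seq)} not divisible by 3"
        )
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def write_bed(intervals, path: str | os.PathLike, names=None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"genome\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")
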