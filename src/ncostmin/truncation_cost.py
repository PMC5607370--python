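"""Truncated protein isoforms from internal TSSs and their nitrogen budgets.

An internal TSS inside a coding gene implies a shortened transcript; under
the assumption that translation initiates at methionine, the truncated
isoform begins at the nearest in-frame Met codon at or downstream of the
TSS. Both isoforms are translated (bacterial code, table 11; near-cognate
initiators such as GTG/TTG are read as Met at the annotated start only)
and their nitrogen content is accounted atom-by-atom: every residue
contributes one backbone N, plus side-chain increments of +3 for Arg, +2
for His, and +1 each for Lys, Asn, Gln, and Trp. The saving of a
truncation is the N content of the removed N-terminal prefix.

Optional parallel accounting: carbon atoms per residue, and the N content
of the removed 5' RNA segment (per-base N: A=5, G=5, C=3, U=2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio.Data import CodonTable

from .errors import NcostminError, TranslationError
from .genome_model import GeneFeature, GenomeRecord, coding_codons

logger = logging.getLogger(__name__)

# mol N per mol residue in peptide linkage (backbone + side chain)
NITROGEN_PER_RESIDUE = {
    "A": 1, "C": 1, "D": 1, "E": 1, "F": 1, "G": 1, "I": 1, "L": 1,
    "M": 1, "P": 1, "S": 1, "T": 1, "V": 1, "Y": 1,
    "K": 2, "N": 2, "Q": 2, "W": 2, "H": 3, "R": 4,
}

# carbon atoms per residue (optional parallel accounting)
CARBON_PER_RESIDUE = {
    "A": 3, "R": 6, "N": 4, "D": 4, "C": 3, "E": 5, "Q": 5, "G": 2,
    "H": 6, "I": 6, "L": 6, "K": 6, "M": 5, "F": 9, "P": 5, "S": 3,
    "T": 4, "W": 11, "Y": 9, "V": 5,
}

# mol N per mol nucleotide (ring N); T given the U value for transcripts
RNA_NITROGEN_PER_BASE = {"A": 5, "G": 5, "C": 3, "U": 2, "T": 2}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


@dataclass
class TruncationRecord:
    gene_id: str
    internal_tss_position: int
    start_codon_offset_aa: int
    full_protein: str
    truncated_protein: str
    n_full: int
    n_trunc: int
    n_saving: int
    pct_saving: float
    rna_n_saving: int | None = None


def translate(codons: list[str], initiator_as_met: bool = True) -> str:
    """Translate a stop-terminated codon list with bacterial table 11.

    The initiator codon is read as Met when it is a table-11 start codon
    (covers GTG/TTG starts); the terminal stop is excluded; an internal
    stop raises TranslationError naming the codon index.
    """
    if not codons:
        raise TranslationError("empty codon list")
    if codons[-1] not in _TABLE11.stop_codons:
        raise TranslationError(f"final codon {codons[-1]} is not a stop codon")
    residues = []
    for i, codon in enumerate(codons[:-1]):
        if codon in _TABLE11.stop_codons:
            raise TranslationError(f"internal stop codon {codon} at index {i}")
        try:
            aa = _TABLE11.forward_table[codon]
        except KeyError as exc:
            raise TranslationError(f"untranslatable codon {codon!r} at index {i}") from exc
        if i == 0 and initiator_as_met and codon in _TABLE11.start_codons:
            aa = "M"
        residues.append(aa)
    return "".join(residues)


def nitrogen_atoms(protein: str, side_chain_only: bool = False) -> int:
    """Total mol N per mol protein over the 20 standard residues."""
    total = 0
    for i, aa in enumerate(protein):
        try:
            n = NITROGEN_PER_RESIDUE[aa]
        except KeyError as exc:
            raise NcostminError(
                f"non-standard residue {aa!r} at position {i}"
            ) from exc
        total += n - 1 if side_chain_only else n
    return total


def carbon_atoms(protein: str) -> int:
    try:
        return sum(CARBON_PER_RESIDUE[aa] for aa in protein)
    except KeyError as exc:
        raise NcostminError(f"non-standard residue {exc.args[0]!r}") from exc


def nearest_downstream_met(gene: GeneFeature, genome: GenomeRecord,
                           internal_tss_position: int) -> int | None:
    """Index of the first in-frame ATG at or downstream of the internal TSS.

    "Downstream" is strand-aware; a TSS landing exactly on a Met codon's
    first base selects that Met. Returns None when no in-frame Met exists
    before the stop (no isoform; the record is excluded upstream).
    """
    if not gene.start <= internal_tss_position < gene.end:
        raise NcostminError(
            f"TSS {internal_tss_position} outside gene body "
            f"[{gene.start}, {gene.end}) of {gene.gene_id}"
        )
    codons = coding_codons(gene, genome)
    if gene.strand == "+":
        offset = internal_tss_position - gene.start
    else:
        offset = (gene.end - 1) - internal_tss_position
    first = math.ceil(offset / 3)
    for i in range(first, len(codons) - 1):  # exclude the terminal stop
        if codons[i] == "ATG":
            return i
    logger.info("%s: no in-frame Met downstream of TSS %d",
                gene.gene_id, internal_tss_position)
    return None


def truncation_saving(gene: GeneFeature, genome: GenomeRecord,
                      internal_tss: int, side_chain_only: bool = False,
                      include_rna: bool = False) -> TruncationRecord | None:
    """Build the TruncationRecord for one internal TSS (None when no Met)."""
    codons = coding_codons(gene, genome)
    met = nearest_downstream_met(gene, genome, internal_tss)
    if met is None:
        return None
    full = translate(codons)
    truncated = full[met:]
    n_full = nitrogen_atoms(full, side_chain_only)
    n_trunc = nitrogen_atoms(truncated, side_chain_only)
    saving = n_full - n_trunc
    rna_saving = None
    if include_rna:
        removed_nt = "".join(codons[:met])
        rna_saving = sum(RNA_NITROGEN_PER_BASE[b] for b in removed_nt)
    return TruncationRecord(
        gene_id=gene.gene_id, internal_tss_position=internal_tss,
        start_codon_offset_aa=met, full_protein=full,
        truncated_protein=truncated, n_full=n_full, n_trunc=n_trunc,
        n_saving=saving, pct_saving=100.0 * saving / n_full,
        rna_n_saving=rna_saving,
    )


def aggregate_savings(records: list[TruncationRecord]) -> dict:
    """Summarize N savings over a set of truncations.

    Reports the total saving, the pooled percent (100 * sum saving / sum
    full N), the mean of per-record percents, and the per-record percent
    range. Pooled and mean-of-percents aggregations generally differ; both
    are reported.
    """
    if not records:
        raise ValueError("aggregate_savings requires at least one record")
    total_saving = sum(r.n_saving for r in records)
    total_full = sum(r.n_full for r in records)
    pcts = [r.pct_saving for r in records]
    return {
        "n_proteins": len(records),
        "total_n_saving": total_saving,
        "pooled_pct_saving": 100.0 * total_saving / total_full,
        "mean_pct_saving": sum(pcts) / len(pcts),
        "pct_range": (min(pcts), max(pcts)),
    }
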