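"""Genome-scale motif statistics for translation-rate and N-stress signals.

Three families of statistics:

* Gly-Gly codon pairs. Adjacent in-frame glycine codon pairs act as
  Shine-Dalgarno mimics that pause ribosomes; the 16 ordered pairs over
  {GGT, GGC, GGA, GGG} are counted against an independence null built
  from genome-wide codon frequencies, then pooled into bins by affinity
  of the hexamer to the anti-Shine-Dalgarno sequence of the 16S rRNA.

* Pyrimidine-rich (and purine-rich) k-mers. Overlapping length-k windows
  whose pyrimidine (purine) fraction is at least a threshold (default 80%)
  are counted over a region set, against a binomial composition null fit
  on the same regions; enrichment is assessed with Fisher's exact test on
  rounded (normalized) counts.

* NtcA promoter boxes. An IUPAC-degenerate pattern (default GTA-N8-TAC) is
  scanned on the coding strand strictly less than 100 bp upstream of
  translational starts.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .genome_model import (GeneFeature, GenomeRecord, GenomicInterval,
                           coding_codons, upstream_region)

logger = logging.getLogger(__name__)

GLY_CODONS = ("GGT", "GGC", "GGA", "GGG")
GLY_PAIRS = tuple((a, b) for a in GLY_CODONS for b in GLY_CODONS)

CLASS_BASES = {"pyrimidine": frozenset("CT"), "purine": frozenset("AG")}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class CodonPairStats:
    observed: dict[tuple[str, str], int]
    expected: dict[tuple[str, str], float]

    @property
    def o_e(self) -> dict[tuple[str, str], float | None]:
        return {p: (self.observed[p] / self.expected[p] if self.expected[p] > 0 else None)
                for p in GLY_PAIRS}

    @property
    def total_observed(self) -> int:
        return sum(self.observed.values())

    @property
    def total_expected(self) -> float:
        return sum(self.expected.values())


@dataclass
class AffinityTable:
    """Per-hexamer anti-SD affinity scores and bin edges (ascending)."""

    scores: dict[str, float]
    bin_edges: tuple[float, ...]

    def bin_of(self, hexamer: str) -> int:
        if hexamer not in self.scores:
            raise ConfigurationError(f"hexamer {hexamer!r} not in affinity table")
        return int(np.digitize(self.scores[hexamer], self.bin_edges))

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) + 1


@dataclass
class MotifReport:
    label: str
    k: int
    threshold: float
    alphabet_class: str
    observed: int
    expected: float
    o_e_ratio: float
    fisher_p: float | None = None


@dataclass(frozen=True)
class NtcaHit:
    gene_id: str
    site_position: int  # genomic offset of the motif's 5'-most base (reading orientation)
    distance_to_start: int
    matched_sequence: str


# ---------------------------------------------------------------------------
# Gly-Gly codon-pair statistics
# ---------------------------------------------------------------------------

def genome_codon_lists(genome: GenomeRecord, genes: list[GeneFeature]) -> list[list[str]]:
    """Frame-correct codon lists for all coding genes; CDSs containing
    ambiguous bases are excluded with a warning."""
    out = []
    for gene in genes:
        if not gene.is_coding:
            continue
        codons = coding_codons(gene, genome)
        if any("N" in c for c in codons):
            logger.warning("%s: ambiguous bases in CDS; excluded from codon statistics",
                           gene.gene_id)
            continue
        out.append(codons)
    return out


def codon_usage(codon_lists: list[list[str]]) -> tuple[Counter, int, int]:
    """(codon counts, total codons, total adjacent in-gene codon pairs)."""
    counts: Counter = Counter()
    n_adjacent = 0
    for codons in codon_lists:
        counts.update(codons)
        n_adjacent += max(0, len(codons) - 1)
    return counts, sum(counts.values()), n_adjacent


def gly_gly_pairs(codon_lists: list[list[str]]) -> dict[tuple[str, str], int]:
    """Observed adjacent in-frame Gly-Gly pair counts (never spanning genes)."""
    observed = {p: 0 for p in GLY_PAIRS}
    gly = set(GLY_CODONS)
    for codons in codon_lists:
        for a, b in zip(codons, codons[1:]):
            if a in gly and b in gly:
                observed[(a, b)] += 1
    return observed


def expected_pair_counts(codon_counts: Counter, total_codons: int,
                         n_adjacent: int) -> dict[tuple[str, str], float]:
    """Independence null: E[(a,b)] = P(a) * P(b) * N_adjacent."""
    if total_codons == 0:
        raise ValueError("total_codons is zero")
    return {
        (a, b): (codon_counts.get(a, 0) / total_codons)
                * (codon_counts.get(b, 0) / total_codons) * n_adjacent
        for a, b in GLY_PAIRS
    }


def codon_pair_stats(genome: GenomeRecord, genes: list[GeneFeature]) -> CodonPairStats:
    lists = genome_codon_lists(genome, genes)
    counts, total, n_adj = codon_usage(lists)
    return CodonPairStats(observed=gly_gly_pairs(lists),
                          expected=expected_pair_counts(counts, total, n_adj))


def default_affinity_table(max_bins: int = 4) -> AffinityTable:
    """Rank the 16 Gly-Gly hexamers by similarity to the SD consensus AGGAGG.

    The score is the best ungapped alignment of the hexamer against
    AGGAGG (the reverse complement of the anti-SD core at the 16S rRNA 3'
    terminus), with exact matches scoring 1 and G opposite a template A
    scoring 0.5 (G:U wobble with the anti-SD U). GGA/GGG-built pairs
    (GGAGG/GGGGG-like runs) rank high; GGT/GGC-built pairs rank low. This
    is a heuristic rank order, not a free-energy computation, and is fully
    overridable.

    Bin edges sit at midpoints between distinct score levels (up to
    ``max_bins`` bins); the default scores occupy three levels:
    GGT/GGC-initiated (low), GGG-initiated (mid), and GGA-initiated plus
    GGGGGG (high).
    """
    template = "AGGAGG"
    scores: dict[str, float] = {}
    for a, b in GLY_PAIRS:
        hexamer = a + b
        best = 0.0
        for shift in range(-5, 6):
            s = 0.0
            for i in range(6):
                j = i + shift
                if 0 <= j < 6:
                    if hexamer[i] == template[j]:
                        s += 1.0
                    elif hexamer[i] == "G" and template[j] == "A":
                        s += 0.5
            best = max(best, s)
        scores[hexamer] = best
    levels = sorted(set(scores.values()))
    if len(levels) > max_bins:  # collapse to quantile edges
        edges = tuple(float(np.quantile(levels, q))
                      for q in np.linspace(0, 1, max_bins + 1)[1:-1])
    else:
        edges = tuple((a + b) / 2 for a, b in zip(levels, levels[1:]))
    return AffinityTable(scores=scores, bin_edges=edges)


def bin_by_affinity(pair_stats: CodonPairStats,
                    affinity_table: AffinityTable) -> list[dict]:
    """Pooled O/E per affinity bin, ordered low to high affinity.

    Bins with zero pooled expectation are excluded with a warning.
    """
    pooled_o = [0.0] * affinity_table.n_bins
    pooled_e = [0.0] * affinity_table.n_bins
    for (a, b) in GLY_PAIRS:
        idx = affinity_table.bin_of(a + b)
        pooled_o[idx] += pair_stats.observed[(a, b)]
        pooled_e[idx] += pair_stats.expected[(a, b)]
    out = []
    for idx in range(affinity_table.n_bins):
        if pooled_e[idx] == 0:
            logger.warning("affinity bin %d has zero expectation; excluded", idx)
            continue
        out.append({"bin": idx, "observed": pooled_o[idx],
                    "expected": pooled_e[idx],
                    "o_e": pooled_o[idx] / pooled_e[idx]})
    return out


# ---------------------------------------------------------------------------
# Pyrimidine/purine-rich k-mers
# ---------------------------------------------------------------------------

def _class_threshold(k: int, fraction_threshold: float) -> int:
    # ceiling rule with a guard against float artifacts (0.8*10 must give 8)
    return math.ceil(fraction_threshold * k - 1e-9)


def rich_motif_count(regions: list[GenomicInterval], genome: GenomeRecord,
                     k: int, fraction_threshold: float = 0.8,
                     alphabet_class: str = "pyrimidine",
                     collapse: bool = False) -> int:
    """Number of length-k windows with class fraction >= threshold.

    Every start offset fully inside a region is a window (overlaps
    allowed); regions shorter than k contribute none. With ``collapse``,
    overlapping qualifying windows merge into maximal runs and runs are
    counted instead.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    bases = CLASS_BASES[alphabet_class]
    need = _class_threshold(k, fraction_threshold)
    total = 0
    kernel = np.ones(k, dtype=int)
    for region in regions:
        if region.length < k:
            continue
        seq = genome.sequence[region.start:region.end]
        flags = np.frombuffer(seq.encode(), dtype=np.uint8)
        mask = np.zeros(len(seq), dtype=int)
        for b in bases:
            mask |= flags == ord(b)
        window_sums = np.convolve(mask, kernel, mode="valid")
        qualifying = np.flatnonzero(window_sums >= need)
        if collapse and qualifying.size:
            total += 1 + int(np.count_nonzero(np.diff(qualifying) >= k))
        else:
            total += int(qualifying.size)
    return total


def expected_motif_count(regions: list[GenomicInterval], genome: GenomeRecord,
                         k: int, fraction_threshold: float = 0.8,
                         alphabet_class: str = "pyrimidine",
                         null: str = "region") -> float:
    """Binomial composition null: N_windows * P(X >= ceil(threshold*k)).

    X ~ Binomial(k, p_hat) with p_hat the class fraction of the region set
    (``null='region'``) or of the whole genome (``null='genome'``).
    """
    if not regions:
        raise ValueError("empty region set")
    bases = CLASS_BASES[alphabet_class]
    if null == "genome":
        pool = genome.sequence
    elif null == "region":
        pool = "".join(genome.sequence[r.start:r.end] for r in regions)
    else:
        raise ConfigurationError(f"unknown null {null!r}")
    acgt = sum(pool.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("region set contains no unambiguous bases")
    p_hat = sum(pool.count(b) for b in bases) / acgt
    n_windows = sum(max(0, r.length - k + 1) for r in regions)
    need = _class_threshold(k, fraction_threshold)
    return float(n_windows * stats.binom.sf(need - 1, k, p_hat))


def fisher_normalized(observed_a: int, expected_a: float,
                      observed_b: int, expected_b: float) -> float:
    """Two-sided Fisher's exact test on [[obs_a, round(exp_a)], [obs_b, round(exp_b)]].

    Expected counts are rounded to the nearest integer so the exact test is
    well defined. A degenerate table (zero margin) reports p = 1 with a
    warning.
    """
    table = [[int(observed_a), int(round(expected_a))],
             [int(observed_b), int(round(expected_b))]]
    if any(x < 0 for row in table for x in row):
        raise ValueError("counts must be non-negative")
    rows = [sum(r) for r in table]
    cols = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in rows or 0 in cols:
        logger.warning("degenerate 2x2 table %s; p = 1 reported", table)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def motif_report(regions, genome, k, fraction_threshold=0.8,
                 alphabet_class="pyrimidine", label="", null="region") -> MotifReport:
    obs = rich_motif_count(regions, genome, k, fraction_threshold, alphabet_class)
    exp = expected_motif_count(regions, genome, k, fraction_threshold,
                               alphabet_class, null)
    oe = obs / exp if exp > 0 else math.nan
    return MotifReport(label=label or alphabet_class, k=k,
                       threshold=fraction_threshold,
                       alphabet_class=alphabet_class, observed=obs,
                       expected=exp, o_e_ratio=oe)


# ---------------------------------------------------------------------------
# NtcA promoter scan
# ---------------------------------------------------------------------------

def compile_iupac(pattern: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ConfigurationError(
            f"malformed IUPAC pattern {pattern!r}: bad symbol {exc.args[0]!r}"
        ) from exc
    return re.compile(f"(?=({body}))")


def ntca_scan(genes: list[GeneFeature], genome: GenomeRecord,
              motif_pattern: str = "GTANNNNNNNNTAC",
              max_upstream: int = 100) -> tuple[list[NtcaHit], int]:
    """Scan coding-strand upstream regions for NtcA boxes.

    A hit counts when the motif's 5'-most base lies strictly less than
    ``max_upstream`` bp upstream of the gene's translational start.
    Returns (hits, number of distinct genes with at least one hit).
    """
    regex = compile_iupac(motif_pattern)
    hits: list[NtcaHit] = []
    genes_hit: set[str] = set()
    for gene in genes:
        iv = upstream_region(gene, max_upstream, genome.length)
        if iv.length == 0:
            continue
        seq = genome.slice(iv.start, iv.end, gene.strand)
        for m in regex.finditer(seq):
            j = m.start()
            matched = m.group(1)
            if gene.strand == "+":
                site = iv.start + j
                distance = gene.start - site
            else:
                site = iv.end - 1 - j
                distance = site - (gene.end - 1)
            if 0 < distance < max_upstream:
                hits.append(NtcaHit(gene.gene_id, site, distance, matched))
                genes_hit.add(gene.gene_id)
    return hits, len(genes_hit)
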