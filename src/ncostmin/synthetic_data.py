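"""Synthetic genomes, annotations, and 5'-end coverage with planted truth.

The generator emulates the inputs of a bacterial primary-transcriptome
experiment: an AT-rich single-replicon genome with coding genes drawn
codon-by-codon from a configurable codon-usage distribution, intergenic
sequence with a controlled pyrimidine fraction, optional planted NtcA
promoter boxes, and per-library 5'-end pileups in which every true TSS
produces the characteristic saw-tooth: a Poisson point mass at the start
position followed by a geometrically decaying downstream tail, with a
configurable enriched:non-enriched contrast.

Truth objects record everything planted, so detection, classification,
ratio estimation, conservation, and motif recovery can all be scored
against known ground truth. For a fixed seed the entire fixture is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import FivePrimeCoverage, write_bedgraph
from .errors import ConfigurationError
from .genome_model import GeneFeature, GenomeRecord, reverse_complement, upstream_region

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)
NTCA_PATTERN = "GTANNNNNNNNTAC"  # canonical cyanobacterial NtcA box
_NTCA_REGEX = re.compile("(?=(GTA[ACGT]{8}TAC))")


def default_codon_weights(gc: float = 0.31) -> dict[str, float]:
    """Independence-model codon weights for a genome of the given GC content.

    The default 0.31 mirrors the AT-rich genomes of streamlined marine
    picocyanobacteria.
    """
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    w = {c: p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS}
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


@dataclass(frozen=True)
class PlantedTss:
    """A true transcription start site planted in a simulated library."""

    position: int
    strand: str
    kind: str  # primary | internal | antisense | downstream | orphan
    gene_id: str | None
    mean_5prime_count: float
    enrichment_factor: float

    def __post_init__(self) -> None:
        if self.mean_5prime_count < 0:
            raise ConfigurationError("mean_5prime_count must be >= 0")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1 for a true TSS")


@dataclass
class LibraryPlan:
    condition: str
    timepoint_h: float
    tss: list[PlantedTss] = field(default_factory=list)


@dataclass
class SimTruth:
    """Everything planted into a fixture, serializable bit-identically."""

    seed: int
    libraries: dict[str, LibraryPlan] = field(default_factory=dict)
    true_ratio: dict[str, dict[str, float]] = field(default_factory=dict)
    ntca_sites: list[dict] = field(default_factory=list)
    codon_weights: dict[str, float] = field(default_factory=dict)
    intergenic_pyr_fraction: float = 0.5

    @staticmethod
    def library_key(condition: str, timepoint_h: float) -> str:
        return f"{condition}_{timepoint_h:g}h"

    def add_library(self, condition: str, timepoint_h: float) -> str:
        key = self.library_key(condition, timepoint_h)
        self.libraries.setdefault(key, LibraryPlan(condition, timepoint_h))
        return key

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        libs = {
            k: LibraryPlan(v["condition"], v["timepoint_h"],
                           [PlantedTss(**t) for t in v["tss"]])
            for k, v in d["libraries"].items()
        }
        return cls(seed=d["seed"], libraries=libs, true_ratio=d["true_ratio"],
                   ntca_sites=d["ntca_sites"], codon_weights=d["codon_weights"],
                   intergenic_pyr_fraction=d["intergenic_pyr_fraction"])


def _intergenic(rng: np.random.Generator, length: int, pyr_fraction: float) -> list[str]:
    is_pyr = rng.random(length) < pyr_fraction
    pyr = rng.choice(list("CT"), size=length)
    pur = rng.choice(list("AG"), size=length)
    return [p if f else q for f, p, q in zip(is_pyr, pyr, pur)]


def simulate_genome(
    n_genes: int,
    mean_gene_len: int = 300,
    intergenic_len: int = 200,
    codon_weights: dict[str, float] | None = None,
    intergenic_pyr_fraction: float = 0.5,
    ntca_sites: int = 0,
    glygly_keep: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[GenomeRecord, list[GeneFeature], SimTruth]:
    """Simulate a single-replicon genome with annotated coding genes.

    Genes alternate with fixed-length intergenic spacers on random strands.
    Each CDS starts with ATG, ends with a single stop codon, and draws its
    interior codons i.i.d. from ``codon_weights`` (no internal stops by
    construction). When ``ntca_sites > 0``, that many genes receive an NtcA
    box (GTA-N8-TAC) planted on the coding strand within 100 bp of their
    start, and all other pattern matches inside scanned upstream windows
    are scrubbed so the planted sites are exactly the recoverable ones.

    ``glygly_keep`` maps a Gly-Gly hexamer (e.g. ``"GGAGGA"``) to a keep
    probability: each drawn adjacency matching the hexamer survives with
    that probability, otherwise its second codon is swapped with a random
    interior codon. Swapping preserves codon counts, so depletion acts on
    the pair adjacency relative to the independence expectation.
    """
    if not 0 <= intergenic_pyr_fraction <= 1:
        raise ConfigurationError("intergenic_pyr_fraction must lie in [0, 1]")
    if ntca_sites > 0 and intergenic_len < 120:
        raise ConfigurationError(
            f"intergenic_len={intergenic_len} too small to host a planted NtcA "
            "site inside a 100 bp upstream window (need >= 120)"
        )
    if ntca_sites > n_genes:
        raise ConfigurationError("ntca_sites exceeds n_genes")
    weights = dict(codon_weights) if codon_weights else default_codon_weights()
    missing = [c for c in weights if c not in SENSE_CODONS]
    if missing:
        raise ConfigurationError(f"codon_weights contains non-sense codons: {missing}")
    rng = np.random.default_rng(seed)
    codons = sorted(weights)
    probs = np.array([weights[c] for c in codons])
    probs = probs / probs.sum()

    mean_interior = max(8, round(mean_gene_len / 3) - 2)
    pieces: list[str] = []
    genes: list[GeneFeature] = []
    cursor = 0
    for i in range(n_genes):
        spacer = "".join(_intergenic(rng, intergenic_len, intergenic_pyr_fraction))
        pieces.append(spacer)
        cursor += intergenic_len
        n_interior = max(8, int(rng.poisson(mean_interior)))
        interior = list(rng.choice(codons, size=n_interior, p=probs))
        if glygly_keep:
            for j in range(1, n_interior):
                pair = interior[j - 1] + interior[j]
                keep = glygly_keep.get(pair)
                if keep is not None and rng.random() > keep:
                    k = int(rng.integers(0, n_interior))
                    interior[j], interior[k] = interior[k], interior[j]
        cds = "ATG" + "".join(interior) + str(rng.choice(STOP_CODONS))
        strand = str(rng.choice(["+", "-"]))
        genomic = cds if strand == "+" else reverse_complement(cds)
        pieces.append(genomic)
        genes.append(GeneFeature(f"SYN{i:04d}", cursor, cursor + len(cds), strand))
        cursor += len(cds)
    pieces.append("".join(_intergenic(rng, intergenic_len, intergenic_pyr_fraction)))
    cursor += intergenic_len

    seq = list("".join(pieces))
    truth = SimTruth(seed=seed, codon_weights=weights,
                     intergenic_pyr_fraction=intergenic_pyr_fraction)

    if ntca_sites > 0:
        chosen = rng.choice(len(genes), size=ntca_sites, replace=False)
        planted_spans: list[tuple[int, int]] = []
        for gi in sorted(int(x) for x in chosen):
            gene = genes[gi]
            distance = int(rng.integers(20, 90))
            core = "".join(str(b) for b in rng.choice(list(_BASES), size=8))
            motif = "GTA" + core + "TAC"
            if gene.strand == "+":
                g0 = gene.start - distance  # motif occupies [g0, g0+14)
                seq[g0:g0 + 14] = list(motif)
                span = (g0, g0 + 14)
            else:
                m = gene.end - 1 + distance  # reading-orientation motif start
                g0 = m - 13
                seq[g0:g0 + 14] = list(reverse_complement(motif))
                span = (g0, g0 + 14)
            planted_spans.append(span)
            truth.ntca_sites.append(
                {"gene_id": gene.gene_id, "position": span[0],
                 "distance": distance, "sequence": motif}
            )
        _scrub_spurious_ntca(seq, genes, planted_spans, rng)

    genome = GenomeRecord(id=f"synthetic_seed{seed}", sequence="".join(seq))
    return genome, genes, truth


def _scrub_spurious_ntca(seq: list[str], genes: list[GeneFeature],
                         planted_spans: list[tuple[int, int]],
                         rng: np.random.Generator, max_rounds: int = 200) -> None:
    """Mutate away chance NtcA-pattern matches inside scanned upstream windows."""
    length = len(seq)

    def overlaps_planted(a: int, b: int) -> bool:
        return any(a < pe and ps < b for ps, pe in planted_spans)

    for _ in range(max_rounds):
        dirty = False
        for gene in genes:
            iv = upstream_region(gene, 100, length)
            window = "".join(seq[iv.start:iv.end])
            oriented = reverse_complement(window) if gene.strand == "-" else window
            for m in _NTCA_REGEX.finditer(oriented):
                j = m.start()
                if gene.strand == "+":
                    g0 = iv.start + j
                else:
                    g0 = iv.end - 1 - j - 13
                if overlaps_planted(g0, g0 + 14):
                    continue
                # break the fixed GTA prefix at a base outside any planted span
                for off in (0, 1, 2, 11, 12, 13):
                    if not overlaps_planted(g0 + off, g0 + off + 1):
                        current = seq[g0 + off]
                        seq[g0 + off] = str(rng.choice([b for b in _BASES if b != current]))
                        dirty = True
                        break
        if not dirty:
            return
    raise ConfigurationError("could not scrub spurious NtcA matches; genome too dense")


# ---------------------------------------------------------------------------
# TSS planting
# ---------------------------------------------------------------------------

def plant_gene_tss(
    truth: SimTruth,
    gene: GeneFeature,
    library_key: str,
    genome_length: int,
    *,
    primary_mean: float | None = None,
    primary_offset: int = 50,
    internal_mean: float | None = None,
    internal_offset: int | None = None,
    enrichment_factor: float = 10.0,
) -> None:
    """Plant a primary and/or internal TSS for one gene in one library.

    ``primary_offset`` is the strand-aware distance (nt) of the primary TSS
    upstream of the gene's 5' end (0 = leaderless). ``internal_offset`` is
    the distance into the gene body (default: the midpoint). When both TSSs
    are planted the true internal:primary ratio is recorded in the truth.
    """
    plan = truth.libraries[library_key]
    if primary_mean is not None:
        if gene.strand == "+":
            pos = max(0, gene.start - primary_offset)
        else:
            pos = min(genome_length - 1, gene.end - 1 + primary_offset)
        plan.tss.append(PlantedTss(pos, gene.strand, "primary", gene.gene_id,
                                   primary_mean, enrichment_factor))
    if internal_mean is not None:
        off = internal_offset if internal_offset is not None else gene.length // 2
        if not 0 <= off < gene.length:
            raise ConfigurationError(
                f"{gene.gene_id}: internal offset {off} outside gene body"
            )
        pos = gene.start + off if gene.strand == "+" else gene.end - 1 - off
        plan.tss.append(PlantedTss(pos, gene.strand, "internal", gene.gene_id,
                                   internal_mean, enrichment_factor))
    if primary_mean and internal_mean:
        truth.true_ratio.setdefault(gene.gene_id, {})[library_key] = (
            internal_mean / primary_mean
        )


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    genome: GenomeRecord,
    truth: SimTruth,
    noise_rate: float = 0.5,
    library_depth: float = 1.0,
    seed: int = 0,
    decay: float = 0.5,
    tail_len: int = 5,
) -> dict[str, FivePrimeCoverage]:
    """Simulate enriched and non-enriched 5'-end pileups for every planned library.

    Per position the count is Poisson with mean ``noise_rate * library_depth``
    plus, at planted TSSs, the TSS mean (enriched) or mean/enrichment_factor
    (non-enriched), each followed by a geometric downstream tail
    (``mean * decay**d`` for d = 1..tail_len) that produces the saw-tooth
    shape. Deterministic for a fixed seed.
    """
    if noise_rate < 0:
        raise ConfigurationError("noise_rate must be >= 0")
    length = genome.length
    out: dict[str, FivePrimeCoverage] = {}
    names = []
    for key in sorted(truth.libraries):
        for role in ("enriched", "control"):
            names.append((key, role))
    for li, (key, role) in enumerate(names):
        plan = truth.libraries[key]
        lam_fwd = np.full(length, noise_rate * library_depth, dtype=float)
        lam_rev = np.full(length, noise_rate * library_depth, dtype=float)
        for t in plan.tss:
            mean = t.mean_5prime_count if role == "enriched" \
                else t.mean_5prime_count / t.enrichment_factor
            lam = lam_fwd if t.strand == "+" else lam_rev
            step = 1 if t.strand == "+" else -1
            for d in range(tail_len + 1):
                p = t.position + step * d
                if 0 <= p < length:
                    lam[p] += mean * (decay ** d) * library_depth
        rng = np.random.default_rng([seed, li])
        out[f"{key}_{role}"] = FivePrimeCoverage(
            fwd=rng.poisson(lam_fwd), rev=rng.poisson(lam_rev),
            library_label=f"{key}_{role}", condition=plan.condition,
            timepoint_h=plan.timepoint_h,
        )
    return out


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(outdir, genome: GenomeRecord, genes: list[GeneFeature],
                  coverage: dict[str, FivePrimeCoverage], truth: SimTruth) -> dict:
    """Write FASTA, GFF3, per-library bedGraphs, and the truth; return a manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    fasta = os.path.join(outdir, "genome.fa")
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                fasta, "fasta")
    paths["fasta"] = fasta

    gff = os.path.join(outdir, "annotation.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in genes:
            ftype = "CDS" if g.is_coding else "gene"
            fh.write(
                f"{genome.id}\tncostmin_sim\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id};locus_tag={g.gene_id}\n"
            )
    paths["gff"] = gff

    for name, cov in coverage.items():
        for strand, arr in (("fwd", cov.fwd), ("rev", cov.rev)):
            p = os.path.join(outdir, f"{name}.{strand}.bedgraph")
            write_bedgraph(arr, p, chrom=genome.id)
            paths[f"{name}.{strand}"] = p

    truth_json = os.path.join(outdir, "truth.json")
    with open(truth_json, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    paths["truth"] = truth_json

    tss_tsv = os.path.join(outdir, "truth_tss.tsv")
    with open(tss_tsv, "w") as fh:
        fh.write("library\tposition\tstrand\tkind\tgene_id\tmean\tenrichment\n")
        for key in sorted(truth.libraries):
            for t in truth.libraries[key].tss:
                fh.write(f"{key}\t{t.position}\t{t.strand}\t{t.kind}\t"
                         f"{t.gene_id}\t{t.mean_5prime_count:g}\t"
                         f"{t.enrichment_factor:g}\n")
    paths["truth_tss"] = tss_tsv

    manifest = {"seed": truth.seed, "paths": paths,
                "libraries": sorted(coverage), "n_genes": len(genes),
                "genome_length": genome.length}
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = manifest_path
    return manifest


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------

def evaluate_calls(calls, planted: list[PlantedTss], merge_range: int = 5
                   ) -> tuple[float, float]:
    """(recall, precision) of detected calls against planted TSSs.

    A planted TSS is recovered if a call on its strand lies within
    ``merge_range`` nt; a call is correct if it matches any planted TSS.
    """
    def matched(pos, strand, others):
        return any(o.strand == strand and abs(o.position - pos) <= merge_range
                   for o in others)

    recall = (sum(matched(t.position, t.strand, calls) for t in planted)
              / len(planted)) if planted else float("nan")
    precision = (sum(matched(c.position, c.strand, planted) for c in calls)
                 / len(calls)) if calls else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# Standard study-condition fixtures
# ---------------------------------------------------------------------------

def fixture_tss_recovery(seed: int = 0, n_genes: int = 50,
                         primary_mean: float = 1000.0, enrichment: float = 10.0,
                         noise_rate: float = 0.5):
    """50 genes, planted primary + internal TSSs (mean 1000, 10x enrichment)."""
    genome, genes, truth = simulate_genome(n_genes=n_genes, seed=seed)
    key = truth.add_library("deplete", 12.0)
    for g in genes:
        plant_gene_tss(truth, g, key, genome.length,
                       primary_mean=primary_mean, internal_mean=primary_mean,
                       enrichment_factor=enrichment)
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov


def fixture_ratio_recovery(seed: int = 0,
                           ratios: tuple[float, ...] = (0.05, 0.1, 0.4, 0.8),
                           internal_mean: float = 1000.0,
                           enrichment: float = 10.0, noise_rate: float = 0.5):
    """One gene per planted internal:primary ratio; internal mean fixed at 1000."""
    genome, genes, truth = simulate_genome(n_genes=len(ratios), seed=seed)
    key = truth.add_library("deplete", 12.0)
    for g, r in zip(genes, ratios):
        plant_gene_tss(truth, g, key, genome.length,
                       primary_mean=internal_mean / r, internal_mean=internal_mean,
                       enrichment_factor=enrichment)
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov


def fixture_direction_census(seed: int = 0, n_up: int = 64, n_down: int = 13,
                             n_similar: int = 8, primary_mean: float = 2500.0,
                             enrichment: float = 10.0, noise_rate: float = 0.5):
    """Genes partitioned into up-in-deplete / up-in-replete / similar ratios.

    Planted ratios: 0.2 vs 0.8 (up in deplete), 0.8 vs 0.2 (up in replete),
    0.4 in both (similar). Returns (genome, genes, truth, coverage, labels).
    """
    n = n_up + n_down + n_similar
    genome, genes, truth = simulate_genome(n_genes=n, seed=seed)
    key_rep = truth.add_library("replete", 12.0)
    key_dep = truth.add_library("deplete", 12.0)
    labels: dict[str, str] = {}
    plans = ([("up_in_deplete", 0.2, 0.8)] * n_up
             + [("up_in_replete", 0.8, 0.2)] * n_down
             + [("similar", 0.4, 0.4)] * n_similar)
    for g, (label, r_rep, r_dep) in zip(genes, plans):
        labels[g.gene_id] = label
        plant_gene_tss(truth, g, key_rep, genome.length,
                       primary_mean=primary_mean,
                       internal_mean=r_rep * primary_mean,
                       enrichment_factor=enrichment)
        plant_gene_tss(truth, g, key_dep, genome.length,
                       primary_mean=primary_mean,
                       internal_mean=r_dep * primary_mean,
                       enrichment_factor=enrichment)
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov, labels


def fixture_internal_only(seed: int = 0, n_genes: int = 160, n_tss: int = 187,
                          n_up: int = 117, base_mean: float = 500.0,
                          up_fold: float = 3.0, enrichment: float = 10.0,
                          noise_rate: float = 0.5):
    """Internal-only TSSs (no primary), a known subset higher under depletion.

    Returns (genome, genes, truth, coverage, tss_index) where tss_index is a
    list of (gene_id, position, strand, is_up) for every planted internal TSS.
    """
    if n_tss < n_genes or n_tss > 2 * n_genes:
        raise ConfigurationError("need n_genes <= n_tss <= 2*n_genes")
    genome, genes, truth = simulate_genome(n_genes=n_genes, seed=seed)
    key_rep = truth.add_library("replete", 12.0)
    key_dep = truth.add_library("deplete", 12.0)
    n_double = n_tss - n_genes
    tss_index = []
    k = 0
    for gi, g in enumerate(genes):
        offsets = [g.length // 3, 2 * g.length // 3] if gi < n_double else [g.length // 2]
        for off in offsets:
            is_up = k < n_up
            rep_mean = base_mean if is_up else base_mean * up_fold
            dep_mean = base_mean * up_fold if is_up else base_mean
            plant_gene_tss(truth, g, key_rep, genome.length,
                           internal_mean=rep_mean, internal_offset=off,
                           enrichment_factor=enrichment)
            plant_gene_tss(truth, g, key_dep, genome.length,
                           internal_mean=dep_mean, internal_offset=off,
                           enrichment_factor=enrichment)
            pos = g.start + off if g.strand == "+" else g.end - 1 - off
            tss_index.append((g.gene_id, pos, g.strand, is_up))
            k += 1
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov, tss_index


def fixture_conservation(seed: int = 0, n_internal: int = 81,
                         n_conserved: int = 72, mean: float = 1000.0,
                         enrichment: float = 10.0, noise_rate: float = 0.5):
    """Internal TSSs at 12 h, a known subset re-planted identically at 24 h."""
    genome, genes, truth = simulate_genome(n_genes=n_internal, seed=seed)
    key_12 = truth.add_library("deplete", 12.0)
    key_24 = truth.add_library("deplete", 24.0)
    for gi, g in enumerate(genes):
        plant_gene_tss(truth, g, key_12, genome.length,
                       internal_mean=mean, enrichment_factor=enrichment)
        if gi < n_conserved:
            plant_gene_tss(truth, g, key_24, genome.length,
                           internal_mean=mean, enrichment_factor=enrichment)
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov


def fixture_leaderless(seed: int = 0, n_primary: int = 20, n_leaderless: int = 2,
                       mean: float = 1000.0, enrichment: float = 10.0,
                       noise_rate: float = 0.5):
    """Primary TSSs, a known subset within 10 nt of the translational start."""
    genome, genes, truth = simulate_genome(n_genes=n_primary, seed=seed)
    key = truth.add_library("deplete", 12.0)
    for gi, g in enumerate(genes):
        offset = (7 * gi) % 11 if gi < n_leaderless else 50  # 0, 7, ... vs far
        plant_gene_tss(truth, g, key, genome.length,
                       primary_mean=mean, primary_offset=offset,
                       enrichment_factor=enrichment)
    cov = simulate_coverage(genome, truth, noise_rate=noise_rate, seed=seed)
    return genome, genes, truth, cov
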