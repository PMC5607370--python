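# ncostmin

Transcription start site (TSS) analysis and nitrogen cost accounting for
bacterial primary transcriptomes.

Oligotrophic marine cyanobacteria such as *Prochlorococcus* carry
genomes that are already nitrogen cost-minimized: their proteomes favor
amino acids with fewer N atoms. This package implements the
*transcriptomic* counterpart of that idea — detecting whether, under
acute N deprivation, cells shift transcription initiation from a gene's
primary start to start sites *inside* the gene, producing shortened
transcripts whose truncated protein isoforms cost fewer nitrogen atoms —
and the genome-scale motif statistics that bear on the accompanying
translation-rate hypothesis. It is written for microbial
transcriptomics researchers working with differential 5′-end (dRNA-seq /
tagRNA-seq) coverage.

## What it computes

* **TSS detection.** At each position the difference between the
  TSS-enriched and non-enriched library's 5′-end counts is tested
  against a Skellam null, `D ~ Skellam(λ_e, λ_c)` with per-strand
  background rates `λ`; significant positions (default `P < 10⁻¹⁰`,
  enriched count ≥ 4) are merged within 5 nt and filtered to an
  enriched-minus-control difference ≥ 100. Calls are classified as
  primary (≤ 250 nt upstream of a gene's 5′ end), internal, antisense,
  downstream (< 30 nt), or orphan — possibly several at once.
* **Internal transcription dynamics.** Per gene, the internal
  transcription ratio `r = abundance(internal TSS) / abundance(primary
  TSS)`; genes with `r > 10%` are compared between N-replete and
  N-deprived conditions (Wilcoxon rank-sum on per-offset
  internal:primary count ratios; direction from the fold change), and
  12 h internal TSSs are checked for conservation at 24 h.
* **Nitrogen accounting.** The truncated isoform implied by an internal
  TSS starts at the nearest in-frame downstream Met; both isoforms are
  translated (bacterial code) and nitrogen is counted per residue
  (backbone 1 N; side chains: Arg +3, His +2, Lys/Asn/Gln/Trp +1), giving
  per-protein and aggregate `mol N (mol protein)⁻¹` savings.
* **Motif statistics.** Observed:expected ratios of adjacent Gly–Gly
  codon pairs binned by anti-Shine–Dalgarno affinity (ribosome-pausing
  signal); pyrimidine- and purine-rich 10/12-mer counts (≥ 80% class
  bases) against a binomial composition null with Fisher's exact tests
  (S1-mediated translation-initiation signal); and NtcA promoter boxes
  (default GTA-N8-TAC) strictly < 100 bp upstream of translational
  starts.
* **Synthetic data.** A generator that plants all of the above as ground
  truth — saw-tooth 5′ pileups with known enriched:control contrast,
  known internal:primary ratios per condition, controlled codon usage
  and intergenic composition, planted NtcA sites — so every stage is
  testable without downloads.

## Worked example

```python
from ncostmin import synthetic_data as sim, tss_caller as tss, \
    internal_dynamics as dyn, truncation_cost as tc

# a 10-gene fixture: internal:primary ratios planted to rise under
# N deprivation in 6 genes, fall in 2, stay flat in 2
genome, genes, truth, cov = sim.fixture_direction_census(
    seed=42, n_up=6, n_down=2, n_similar=2)[:4]

calls = tss.classify_all(
    tss.call_tss(cov["deplete_12h_enriched"], cov["deplete_12h_control"]),
    genes)
print("census:", tss.category_census(calls))

results = []
for gene in genes:
    planted = {t.kind: t for t in truth.libraries["deplete_12h"].tss
               if t.gene_id == gene.gene_id}
    results.append(dyn.compare_conditions(
        gene.gene_id, planted["internal"].position,
        planted["primary"].position, gene.strand,
        cov["deplete_12h_enriched"], cov["replete_12h_enriched"]))
print("direction census:", dyn.direction_census(results))
r = results[0]
print(f"{r.gene_id}: ratio {r.ratio_replete:.3f} -> {r.ratio_deplete:.3f}, "
      f"fold {r.ratio_fold_change:.2f}, p = {r.wilcoxon_p:.2e}")
```

prints

```
census: {'Internal': 10, 'Primary': 10}
direction census: {'up_in_deplete': 6, 'up_in_replete': 2, 'similar': 2}
SYN0000: ratio 0.215 -> 0.799, fold 3.71, p = 2.16e-03
```

All 20 planted TSSs are recovered and classified (each gene contributes
one primary and one internal call); the cross-condition comparison
reproduces the planted 6/2/2 direction partition exactly, and for the
first gene the internal transcription ratio rises from 0.215 to 0.799
under N deprivation (fold 3.71, rank-sum p ≈ 0.002 — the floor of an
exact test on six window offsets per condition). Feeding each gene's
internal TSS to the nitrogen accounting:

```python
records = [tc.truncation_saving(g, genome, res.internal_tss_position)
           for g, res in zip(genes, results)]
summary = tc.aggregate_savings([rec for rec in records if rec is not None])
print("N savings:", summary)
```

```
N savings: {'n_proteins': 8, 'total_n_saving': 794,
            'pooled_pct_saving': 66.7, 'mean_pct_saving': 66.8,
            'pct_range': (54.4, 87.6)}
```

Eight of the ten genes have an in-frame Met downstream of their
(mid-gene) internal TSS; translating from it would save 794 mol N per
mol of the eight-protein set, 67% of their full-length nitrogen budget —
large because these fixture TSSs sit at gene midpoints.

The same stages are scriptable from the shell (`ncostmin simulate`,
`call-tss`, `n-savings`, `motifs`, `validate`, `run-all`); `ncostmin
run-all config.yaml` executes the whole pipeline from FASTA + GFF3 +
bedGraph inputs and writes per-stage TSV/JSON reports plus a manifest.

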