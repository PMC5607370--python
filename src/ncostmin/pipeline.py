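"""End-to-end orchestration: TSS calling -> classification -> internal
dynamics -> truncation N accounting -> motif statistics.

The pipeline is a pure function of (inputs, config, seed): reruns with the
same config produce byte-identical outputs. Every number in the summary is
traceable to a stage TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from types import SimpleNamespace

import pandas as pd
import yaml

from . import coverage as cov_io
from . import genome_model as gm
from . import internal_dynamics as dyn
from . import motif_stats as ms
from . import truncation_cost as tc
from . import tss_caller as tcall
from .errors import NcostminError

logger = logging.getLogger(__name__)


@dataclass
class LibrarySpec:
    label: str
    condition: str  # replete | deplete
    timepoint_h: float
    enriched_fwd: str
    enriched_rev: str
    control_fwd: str
    control_rev: str


@dataclass
class PipelineConfig:
    fasta: str
    gff: str
    libraries: list[LibrarySpec]
    out_dir: str
    seed: int = 0
    tss: tcall.TssCallerParams = field(default_factory=tcall.TssCallerParams)
    ratio: dyn.RatioParams = field(default_factory=dyn.RatioParams)
    motif_k: tuple[int, ...] = (10, 12)
    motif_fraction: float = 0.8
    ntca_pattern: str = "GTANNNNNNNNTAC"
    ntca_max_upstream: int = 100


def validate_config(path: str) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML config; errors are aggregated, not fail-fast."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config {path}: {exc}"]

    for key in ("fasta", "gff", "libraries", "out_dir"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    for key in ("fasta", "gff"):
        if key in raw and not os.path.exists(str(raw[key])):
            errors.append(f"{key}: path does not exist: {raw[key]}")

    libraries: list[LibrarySpec] = []
    labels: set[str] = set()
    for i, lib in enumerate(raw.get("libraries", []) or []):
        missing = [k for k in ("label", "condition", "timepoint_h", "enriched_fwd",
                               "enriched_rev", "control_fwd", "control_rev")
                   if k not in lib]
        if missing:
            errors.append(f"libraries[{i}]: missing keys {missing}")
            continue
        if lib["label"] in labels:
            errors.append(f"libraries[{i}]: duplicate label {lib['label']!r}")
        labels.add(lib["label"])
        if lib["condition"] not in ("replete", "deplete"):
            errors.append(f"libraries[{i}]: condition must be replete|deplete")
        for k in ("enriched_fwd", "enriched_rev", "control_fwd", "control_rev"):
            if not os.path.exists(str(lib[k])):
                errors.append(f"libraries[{i}].{k}: path does not exist: {lib[k]}")
        libraries.append(LibrarySpec(
            label=str(lib["label"]), condition=str(lib["condition"]),
            timepoint_h=float(lib["timepoint_h"]),
            enriched_fwd=str(lib["enriched_fwd"]), enriched_rev=str(lib["enriched_rev"]),
            control_fwd=str(lib["control_fwd"]), control_rev=str(lib["control_rev"]),
        ))

    tss_params = tcall.TssCallerParams()
    try:
        tss_params = tcall.TssCallerParams(**(raw.get("tss") or {}))
    except (TypeError, NcostminError) as exc:
        errors.append(f"tss: {exc}")
    ratio_params = dyn.RatioParams()
    try:
        ratio_params = dyn.RatioParams(**(raw.get("ratio") or {}))
    except (TypeError, NcostminError) as exc:
        errors.append(f"ratio: {exc}")

    if errors:
        return None, errors
    motifs = raw.get("motifs") or {}
    cfg = PipelineConfig(
        fasta=str(raw["fasta"]), gff=str(raw["gff"]), libraries=libraries,
        out_dir=str(raw["out_dir"]), seed=int(raw.get("seed", 0)),
        tss=tss_params, ratio=ratio_params,
        motif_k=tuple(motifs.get("k", (10, 12))),
        motif_fraction=float(motifs.get("fraction", 0.8)),
        ntca_pattern=str(motifs.get("ntca_pattern", "GTANNNNNNNNTAC")),
        ntca_max_upstream=int(motifs.get("max_upstream", 100)),
    )
    return cfg, []


def _calls_frame(calls: list[tcall.TssCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "position_1based": c.position + 1, "strand": c.strand,
            "enriched_count": c.enriched_count,
            "control_count_scaled": round(c.control_count, 4),
            "p_value": c.p_value,
            "categories": ",".join(k for k in tcall.CATEGORY_ORDER if k in c.categories),
            "gene_ids": ";".join(
                f"{k}:{','.join(v)}" for k, v in sorted(c.gene_ids.items()) if v),
        })
    return pd.DataFrame(rows, columns=["position_1based", "strand", "enriched_count",
                                       "control_count_scaled", "p_value",
                                       "categories", "gene_ids"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest of outputs and stage counts."""
    os.makedirs(config.out_dir, exist_ok=True)
    genome = gm.load_genome(config.fasta)
    genes = gm.load_annotation(config.gff, genome)
    by_id = {g.gene_id: g for g in genes}
    stage_counts: dict[str, int] = {"genes": len(genes)}
    outputs: dict[str, str] = {}

    # --- stage 1: TSS calling & classification per library -----------------
    calls_by_label: dict[str, list[tcall.TssCall]] = {}
    lib_meta: dict[str, LibrarySpec] = {}
    enriched_cov: dict[str, cov_io.FivePrimeCoverage] = {}
    for lib in config.libraries:
        enriched = cov_io.load_coverage(lib.enriched_fwd, lib.enriched_rev,
                                        genome.length, f"{lib.label}_enriched",
                                        lib.condition, lib.timepoint_h)
        control = cov_io.load_coverage(lib.control_fwd, lib.control_rev,
                                       genome.length, f"{lib.label}_control",
                                       lib.condition, lib.timepoint_h)
        calls = tcall.classify_all(tcall.call_tss(enriched, control, config.tss),
                                   genes, config.tss)
        calls_by_label[lib.label] = calls
        lib_meta[lib.label] = lib
        enriched_cov[lib.label] = enriched
        stage_counts[f"tss_calls.{lib.label}"] = len(calls)
        path = os.path.join(config.out_dir, f"tss_calls.{lib.label}.tsv")
        _calls_frame(calls).to_csv(path, sep="\t", index=False)
        outputs[f"tss_calls.{lib.label}"] = path
        census = tcall.category_census(calls)
        cpath = os.path.join(config.out_dir, f"tss_census.{lib.label}.json")
        with open(cpath, "w") as fh:
            json.dump(census, fh, indent=1, sort_keys=True)
        outputs[f"tss_census.{lib.label}"] = cpath

    # --- stage 2: internal dynamics (deplete vs replete per timepoint) -----
    ratio_rows = []
    results: list[dyn.InternalRatioResult] = []
    timepoints = sorted({lib.timepoint_h for lib in config.libraries})
    for tp in timepoints:
        dep = [l for l in config.libraries if l.timepoint_h == tp and l.condition == "deplete"]
        rep = [l for l in config.libraries if l.timepoint_h == tp and l.condition == "replete"]
        if not dep or not rep:
            continue
        dep_label, rep_label = dep[0].label, rep[0].label
        cov_dep, cov_rep = enriched_cov[dep_label], enriched_cov[rep_label]

        def per_gene_sites(calls):
            internal: dict[str, list[int]] = {}
            primary: dict[str, list[int]] = {}
            for c in calls:
                for gid in c.gene_ids.get("internal", ()):
                    internal.setdefault(gid, []).append(c.position)
                for gid in c.gene_ids.get("primary", ()):
                    primary.setdefault(gid, []).append(c.position)
            return internal, primary

        int_dep, prim_dep = per_gene_sites(calls_by_label[dep_label])
        int_rep, prim_rep = per_gene_sites(calls_by_label[rep_label])
        both = sorted(set(int_dep) & set(int_rep) & set(prim_dep) & set(prim_rep))
        stage_counts[f"genes_with_primary_and_internal.{tp:g}h"] = len(both)
        kept = 0
        for gid in both:
            gene = by_id[gid]
            primary_pos = prim_dep[gid][0]
            for internal_pos in sorted(int_dep[gid]):
                if internal_pos == primary_pos:
                    continue
                res = dyn.compare_conditions(gid, internal_pos, primary_pos,
                                             gene.strand, cov_dep, cov_rep,
                                             config.ratio)
                if not (dyn.passes_ratio_filter(res.ratio_deplete, config.ratio)
                        or dyn.passes_ratio_filter(res.ratio_replete, config.ratio)):
                    continue
                kept += 1
                results.append(res)
                ratio_rows.append(dataclasses.asdict(res) | {"timepoint_h": tp})
        stage_counts[f"internal_ratios_kept.{tp:g}h"] = kept

    # conservation of 12 h internal TSSs against the 24 h deplete call set
    dep_24 = [l for l in config.libraries
              if l.timepoint_h == 24.0 and l.condition == "deplete"]
    if dep_24:
        calls_24 = calls_by_label[dep_24[0].label]
        early = [(res, row) for res, row in zip(results, ratio_rows)
                 if row["timepoint_h"] != 24.0]
        sites = [SimpleNamespace(position=r.internal_tss_position, strand=r.strand)
                 for r, _ in early]
        flags = dyn.conservation(sites, calls_24, config.tss.merge_range)
        for (res, row), flag in zip(early, flags):
            res.conserved_24h = flag
            row["conserved_24h"] = flag
        stage_counts["internal_tss_conserved_24h"] = sum(flags)
    if ratio_rows:
        census = dyn.direction_census(results)
        stage_counts |= {f"direction.{k}": v for k, v in census.items()}
    rpath = os.path.join(config.out_dir, "internal_ratios.tsv")
    pd.DataFrame(ratio_rows).to_csv(rpath, sep="\t", index=False)
    outputs["internal_ratios"] = rpath

    # --- stage 3: truncation N accounting on qualifying internal TSSs ------
    records = []
    seen = set()
    for res in results:
        key = (res.gene_id, res.internal_tss_position)
        if key in seen:
            continue
        seen.add(key)
        gene = by_id[res.gene_id]
        rec = tc.truncation_saving(gene, genome, res.internal_tss_position,
                                   include_rna=True)
        if rec is not None:
            records.append(rec)
    stage_counts["truncation_records"] = len(records)
    tpath = os.path.join(config.out_dir, "truncations.tsv")
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        tpath, sep="\t", index=False)
    outputs["truncations"] = tpath
    summary = tc.aggregate_savings(records) if records else {}
    spath = os.path.join(config.out_dir, "n_savings_summary.json")
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    outputs["n_savings_summary"] = spath

    # --- stage 4: motif statistics ------------------------------------------
    pair_stats = ms.codon_pair_stats(genome, genes)
    table = ms.default_affinity_table()
    bins = ms.bin_by_affinity(pair_stats, table)
    noncoding = gm.noncoding_regions(genome, genes)
    motif_reports = []
    for k in config.motif_k:
        for cls in ("pyrimidine", "purine"):
            motif_reports.append(ms.motif_report(
                noncoding, genome, k, config.motif_fraction, cls,
                label=f"noncoding_{cls}_{k}mer"))
    fisher = {}
    for k in config.motif_k:
        pyr = next(r for r in motif_reports if r.label == f"noncoding_pyrimidine_{k}mer")
        pur = next(r for r in motif_reports if r.label == f"noncoding_purine_{k}mer")
        fisher[f"pyr_vs_pur_{k}mer"] = ms.fisher_normalized(
            pyr.observed, pyr.expected, pur.observed, pur.expected)
    hits, n_genes_hit = ms.ntca_scan(genes, genome, config.ntca_pattern,
                                     config.ntca_max_upstream)
    stage_counts["ntca_genes"] = n_genes_hit
    motif_out = {
        "glygly_pairs_observed": pair_stats.total_observed,
        "glygly_pairs_expected": pair_stats.total_expected,
        "glygly_global_o_e": (pair_stats.total_observed / pair_stats.total_expected
                              if pair_stats.total_expected else None),
        "affinity_bins": bins,
        "rich_motifs": [dataclasses.asdict(r) for r in motif_reports],
        "fisher_pyr_vs_pur": fisher,
        "ntca_pattern": config.ntca_pattern,
        "ntca_hits": len(hits),
        "ntca_genes": n_genes_hit,
    }
    mpath = os.path.join(config.out_dir, "motif_stats.json")
    with open(mpath, "w") as fh:
        json.dump(motif_out, fh, indent=1, sort_keys=True)
    outputs["motif_stats"] = mpath
    npath = os.path.join(config.out_dir, "ntca_hits.tsv")
    pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
        npath, sep="\t", index=False)
    outputs["ntca_hits"] = npath

    manifest = {
        "seed": config.seed,
        "parameters": {
            "tss": dataclasses.asdict(config.tss),
            "ratio": dataclasses.asdict(config.ratio),
            "motif_k": list(config.motif_k),
            "motif_fraction": config.motif_fraction,
            "ntca_pattern": config.ntca_pattern,
            "ntca_max_upstream": config.ntca_max_upstream,
        },
        "stage_counts": stage_counts,
        "outputs": outputs,
    }
    man_path = os.path.join(config.out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
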