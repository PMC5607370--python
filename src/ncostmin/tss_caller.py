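"""Transcription start site detection from enriched vs non-enriched 5'-end coverage.

The detector follows the differential dRNA-seq logic of TSSAR-style
callers: at each candidate position the difference between the 5'-end
count in the TSS-enriched library and the (depth-scaled) count in the
non-enriched library is tested against a Skellam null whose rates are the
per-strand background 5'-end densities of the two libraries. Significant
positions are merged within a small range, classified positionally
against the annotation, and finally filtered by a minimum enriched-minus-
control count difference (the automated analogue of hand curation).

Default parameters: P-value threshold 1e-10, noise threshold 4 (minimum
enriched count at a candidate), merge range 5 nt, curation minimum
difference 100, primary window 250 nt upstream (inclusive), downstream
window strictly < 30 nt past the gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coverage import FivePrimeCoverage
from .errors import ConfigurationError, NcostminError
from .genome_model import GeneFeature

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("internal", "antisense", "primary", "downstream", "orphan")


@dataclass
class TssCallerParams:
    p_threshold: float = 1e-10
    noise_threshold: int = 4
    merge_range: int = 5
    curation_min_diff: float = 100.0
    primary_window: int = 250
    downstream_window: int = 30
    depth_norm: str = "background"  # background | total | none
    background_floor: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        if self.depth_norm not in ("background", "total", "none"):
            raise ConfigurationError("depth_norm must be background|total|none")
        for name in ("noise_threshold", "merge_range", "curation_min_diff",
                     "primary_window", "downstream_window"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.background_floor <= 0:
            raise ConfigurationError("background_floor must be positive")


@dataclass
class TssCall:
    position: int
    strand: str
    enriched_count: int
    control_count: float  # depth-scaled when normalization is on
    p_value: float
    categories: set[str] = field(default_factory=set)
    gene_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def diff(self) -> float:
        return self.enriched_count - self.control_count


def estimate_background(coverage: FivePrimeCoverage,
                        floor: float = 0.01) -> dict[str, float]:
    """Robust per-strand background 5'-end rate.

    Mean of counts at positions at or below the 95th percentile of nonzero
    counts (zeros included in the mean), floored at ``floor`` so the
    Skellam null always has positive rates. TSS spikes, being above the
    95th percentile of nonzero counts, do not inflate the estimate.
    """
    rates = {}
    for strand in "+-":
        counts = coverage.counts(strand)
        nonzero = counts[counts > 0]
        if nonzero.size == 0:
            logger.warning("%s strand %s: all-zero coverage; background floored",
                           coverage.library_label, strand)
            rates[strand] = floor
            continue
        cutoff = np.quantile(nonzero, 0.95)
        rates[strand] = max(float(counts[counts <= cutoff].mean()), floor)
    return rates


def skellam_pvalue(enriched_count: float, control_count: float,
                   rate_e: float, rate_c: float) -> float:
    """Upper-tail P(D >= enriched - control) for D ~ Skellam(rate_e, rate_c)."""
    for r in (rate_e, rate_c):
        if not (math.isfinite(r) and r > 0):
            raise ConfigurationError(f"Skellam rates must be finite and positive, got {r}")
    if enriched_count < 0 or control_count < 0:
        raise ValueError("counts must be non-negative")
    d = math.ceil(enriched_count - control_count - 1e-9)
    return float(stats.skellam.sf(d - 1, rate_e, rate_c))


def merge_calls(calls: list[TssCall], merge_range: int) -> list[TssCall]:
    """Merge same-strand calls within ``merge_range`` nt.

    Each chained cluster collapses to the call with maximal enriched count
    (ties broken toward the smaller coordinate). Idempotent.
    """
    out: list[TssCall] = []
    for strand in "+-":
        group = sorted((c for c in calls if c.strand == strand),
                       key=lambda c: c.position)
        cluster: list[TssCall] = []
        for call in group:
            if cluster and call.position - cluster[-1].position > merge_range:
                out.append(max(cluster, key=lambda c: (c.enriched_count, -c.position)))
                cluster = []
            cluster.append(call)
        if cluster:
            out.append(max(cluster, key=lambda c: (c.enriched_count, -c.position)))
    return sorted(out, key=lambda c: (c.strand, c.position))


def call_tss(enriched: FivePrimeCoverage, control: FivePrimeCoverage,
             params: TssCallerParams | None = None) -> list[TssCall]:
    """Detect TSSs by the Skellam test, merge, and apply the curation filter.

    Control counts are depth-scaled before both the test and the curation
    difference. The default scale is the per-strand ratio of background
    rates (enriched/control): background noise tracks sequencing depth
    while the signal does not, so this estimator stays valid even though
    enrichment changes the libraries' total-count composition. ``total``
    scales by the ratio of total 5'-end counts instead, and ``none``
    compares raw counts.
    """
    params = params or TssCallerParams()
    if enriched.length != control.length:
        raise NcostminError("enriched and control coverage lengths differ")
    bg_e = estimate_background(enriched, params.background_floor)
    bg_c = estimate_background(control, params.background_floor)
    total_scale = 1.0
    if params.depth_norm == "total" and control.total() > 0:
        total_scale = enriched.total() / control.total()

    calls: list[TssCall] = []
    for strand in "+-":
        e_counts = enriched.counts(strand)
        c_counts = control.counts(strand)
        if params.depth_norm == "background":
            scale = bg_e[strand] / bg_c[strand]
        elif params.depth_norm == "total":
            scale = total_scale
        else:
            scale = 1.0
        logger.info("strand %s depth scale enriched/control = %.4f", strand, scale)
        rate_e = bg_e[strand]
        rate_c = max(bg_c[strand] * scale, params.background_floor)
        candidates = np.flatnonzero(e_counts >= params.noise_threshold)
        if candidates.size == 0:
            continue
        e = e_counts[candidates].astype(float)
        c = c_counts[candidates].astype(float) * scale
        d = np.ceil(e - c - 1e-9)
        pvals = stats.skellam.sf(d - 1, rate_e, rate_c)
        keep = pvals < params.p_threshold
        for pos, ec, cc, p in zip(candidates[keep], e[keep], c[keep], pvals[keep]):
            calls.append(TssCall(int(pos), strand, int(ec), float(cc), float(p)))

    merged = merge_calls(calls, params.merge_range)
    curated = [c for c in merged if c.diff >= params.curation_min_diff]
    logger.info("%d significant positions -> %d merged -> %d after curation",
                len(calls), len(merged), len(curated))
    return curated


def classify_tss(call: TssCall, genes: list[GeneFeature],
                 params: TssCallerParams | None = None) -> TssCall:
    """Assign positional categories (a call may hold several).

    primary: same strand, within ``primary_window`` nt upstream of the
    gene's 5' end (inclusive of the window edge and of distance 0);
    internal: within the gene body on the gene's strand; antisense: within
    the gene body on the opposite strand; downstream: same strand, strictly
    less than ``downstream_window`` nt past the gene's 3' end; orphan: none
    of the above.
    """
    params = params or TssCallerParams()
    cats: dict[str, list[str]] = {}
    pos = call.position
    for gene in genes:
        in_body = gene.start <= pos < gene.end
        same = call.strand == gene.strand
        if in_body:
            cats.setdefault("internal" if same else "antisense", []).append(gene.gene_id)
        if same:
            if gene.strand == "+":
                up_dist = gene.start - pos
                down_dist = pos - gene.end
            else:
                up_dist = pos - (gene.end - 1)
                down_dist = (gene.start - 1) - pos
            if 0 <= up_dist <= params.primary_window:
                cats.setdefault("primary", []).append(gene.gene_id)
            if 0 <= down_dist < params.downstream_window:
                cats.setdefault("downstream", []).append(gene.gene_id)
    if not cats:
        cats["orphan"] = []
    call.categories = set(cats)
    call.gene_ids = {k: tuple(v) for k, v in cats.items()}
    return call


def classify_all(calls: list[TssCall], genes: list[GeneFeature],
                 params: TssCallerParams | None = None) -> list[TssCall]:
    for call in calls:
        classify_tss(call, genes, params)
    return calls


def category_census(calls: list[TssCall]) -> dict[str, int]:
    """Counts per observed category combination (each call counted once)."""
    census: dict[str, int] = {}
    for call in calls:
        ordered = [c for c in CATEGORY_ORDER if c in call.categories]
        label = " ".join(ordered).capitalize()
        census[label] = census.get(label, 0) + 1
    return dict(sorted(census.items()))


def leaderless_fraction(calls: list[TssCall], genes: list[GeneFeature],
                        window_nt: int = 10) -> float | None:
    """Fraction of primary calls within ``window_nt`` of a translational start.

    Distance is strand-aware from the call to the associated gene's 5' end.
    Returns None when there are no primary calls.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    by_id = {g.gene_id: g for g in genes}
    primary = [c for c in calls if "primary" in c.categories]
    if not primary:
        return None
    n_leaderless = 0
    for call in primary:
        for gid in call.gene_ids.get("primary", ()):
            gene = by_id[gid]
            dist = (gene.start - call.position if gene.strand == "+"
                    else call.position - (gene.end - 1))
            if 0 <= dist <= window_nt:
                n_leaderless += 1
                break
    return n_leaderless / len(primary)
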