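"""Target-gene assignment and the sharing taxonomy.

A gene is a putative target when at least one binding site lies within
a fixed distance of its TSS (100 kb by default). Comparing target sets
across species splits targets into three categories:

* ``directly_shared`` — at least one of the gene's sites is retained
  at the orthologous locus;
* ``indirectly_shared`` — the orthologous gene is also a target, but
  only via species-specific sites (compensatory binding-site turnover);
* ``species_specific`` — the ortholog is not a target (or absent).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from bindover.chain_liftover import ChainAlignment, lift_interval
from bindover.genomic_core import GeneAnnotation, GenomicInterval, PeakRecord, overlap_bp
from bindover.retention_analysis import RetentionLabel
from bindover.stats_enrichment import welch_t

logger = logging.getLogger(__name__)

CATEGORIES = ("species_specific", "indirectly_shared", "directly_shared")


@dataclass
class TargetRecord:
    gene: GeneAnnotation
    sites: list[str] = field(default_factory=list)
    min_tss_distance: int | None = None  # signed: negative = upstream of TSS
    category: str | None = None
    ortholog_gene: str | None = None


def _signed_tss_distance(site_center: int, gene: GeneAnnotation) -> int:
    """Distance from TSS to site, signed by gene orientation.

    Positive = downstream of the TSS in the direction of transcription.
    """
    raw = site_center - gene.tss
    return raw if gene.strand == "+" else -raw


def assign_targets(
    sites: Sequence[PeakRecord],
    genes: Sequence[GeneAnnotation],
    max_tss_distance: int = 100_000,
) -> list[TargetRecord]:
    """Genes with >= 1 site center within range of the TSS (inclusive).

    Every qualifying site is listed on every gene it reaches; the
    single-nearest-gene view is a separate report
    (:func:`nearest_gene_report`).
    """
    if max_tss_distance <= 0:
        raise ValueError("max_tss_distance must be positive")
    by_chrom: dict[str, list[PeakRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for group in by_chrom.values():
        group.sort(key=lambda s: s.center())
    records: list[TargetRecord] = []
    for gene in genes:
        group = by_chrom.get(gene.chrom, [])
        centers = [s.center() for s in group]
        lo = bisect.bisect_left(centers, gene.tss - max_tss_distance)
        hi = bisect.bisect_right(centers, gene.tss + max_tss_distance)
        hits = group[lo:hi]
        if not hits:
            continue
        distances = [_signed_tss_distance(s.center(), gene) for s in hits]
        best = min(range(len(hits)), key=lambda i: abs(distances[i]))
        records.append(
            TargetRecord(
                gene=gene,
                sites=[s.name for s in hits],
                min_tss_distance=distances[best],
            )
        )
    return records


def nearest_gene_report(
    sites: Sequence[PeakRecord],
    genes: Sequence[GeneAnnotation],
    max_tss_distance: int = 100_000,
) -> list[dict]:
    """Per-site nearest gene within range (the classic site-level table)."""
    tss_by_chrom: dict[str, tuple[list[int], list[GeneAnnotation]]] = {}
    grouped: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        grouped.setdefault(g.chrom, []).append(g)
    for chrom, group in grouped.items():
        group.sort(key=lambda g: g.tss)
        tss_by_chrom[chrom] = ([g.tss for g in group], group)
    rows = []
    for site in sites:
        entry = tss_by_chrom.get(site.chrom)
        best, best_dist = None, None
        if entry is not None:
            tss_list, group = entry
            pos = bisect.bisect_left(tss_list, site.center())
            for idx in (pos - 1, pos):
                if 0 <= idx < len(group):
                    dist = abs(tss_list[idx] - site.center())
                    if best_dist is None or dist < best_dist:
                        best, best_dist = group[idx], dist
        if best is not None and best_dist is not None and best_dist <= max_tss_distance:
            rows.append(
                {
                    "site_id": site.name,
                    "gene_id": best.gene_id,
                    "symbol": best.symbol,
                    "tss_distance": _signed_tss_distance(site.center(), best),
                }
            )
        else:
            rows.append({"site_id": site.name, "gene_id": None, "symbol": None, "tss_distance": None})
    return rows


def map_orthologs(
    genes_a: Sequence[GeneAnnotation],
    genes_b: Sequence[GeneAnnotation],
    chains: Sequence[ChainAlignment],
    min_match: float = 0.1,
) -> dict[str, str]:
    """Orthology by lifting gene spans from A and overlapping B genes.

    Each A gene span (txStart-txEnd) is lifted A->B; the B gene whose
    span overlaps the lifted span the most wins, with case-insensitive
    symbol equality as a tie-breaker. Genes that fail liftover or hit
    no B gene are absent from the map.
    """
    b_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes_b:
        b_by_chrom.setdefault(g.chrom, []).append(g)
    mapping: dict[str, str] = {}
    for gene in genes_a:
        result = lift_interval(gene.interval, chains, min_match=min_match)
        if result.status != "mapped":
            continue
        lifted = result.mapped
        candidates = b_by_chrom.get(lifted.chrom, [])
        scored = []
        for cand in candidates:
            ov = overlap_bp(lifted, cand.interval)
            if ov > 0:
                symbol_tie = 0 if cand.symbol.lower() == gene.symbol.lower() else 1
                scored.append((-ov, symbol_tie, cand.gene_id))
        if scored:
            scored.sort()
            mapping[gene.gene_id] = scored[0][2]
    return mapping


def classify_sharing(
    targets_a: Sequence[TargetRecord],
    targets_b: Sequence[TargetRecord],
    retention_labels_a: Sequence[RetentionLabel],
    gene_ortholog_map: Mapping[str, str],
) -> list[TargetRecord]:
    """Attach sharing categories to A-side targets (partitioning them).

    directly_shared iff any of the gene's sites is retained; otherwise
    indirectly_shared iff the ortholog is a target in B; otherwise
    species_specific. A retained site whose gene lacks an ortholog
    still classifies as directly_shared (warning logged).
    """
    retained_sites = {l.site_id for l in retention_labels_a if l.label == "retained"}
    b_target_genes = {t.gene.gene_id for t in targets_b}
    out: list[TargetRecord] = []
    for record in targets_a:
        ortholog = gene_ortholog_map.get(record.gene.gene_id)
        has_retained = any(s in retained_sites for s in record.sites)
        if has_retained:
            category = "directly_shared"
            if ortholog is None:
                logger.warning(
                    "gene %s has a retained site but no ortholog", record.gene.gene_id
                )
        elif ortholog is not None and ortholog in b_target_genes:
            category = "indirectly_shared"
        else:
            category = "species_specific"
        out.append(
            TargetRecord(
                gene=record.gene,
                sites=list(record.sites),
                min_tss_distance=record.min_tss_distance,
                category=category,
                ortholog_gene=ortholog,
            )
        )
    return out


def tss_distance_histogram(
    sites: Sequence[PeakRecord],
    genes: Sequence[GeneAnnotation],
    bins: Sequence[int],
    site_classes: Mapping[str, str] | None = None,
) -> dict[str, list[int]]:
    """Counts of sites per |TSS distance| bin, split by site class.

    ``bins`` are strictly increasing breakpoints; the last bin is
    open-ended. ``site_classes`` maps site name -> class label (all
    sites fall into class "all" when omitted).
    """
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly increasing")
    report = nearest_gene_report(sites, genes, max_tss_distance=10**12)
    n_bins = len(bins)  # bins[i]..bins[i+1], plus open-ended tail
    counts: dict[str, list[int]] = {}
    for site, row in zip(sites, report):
        cls = site_classes.get(site.name, "all") if site_classes else "all"
        dist = abs(row["tss_distance"]) if row["tss_distance"] is not None else None
        per_class = counts.setdefault(cls, [0] * n_bins)
        if dist is None:
            continue
        idx = bisect.bisect_right(bins, dist) - 1
        if idx >= 0:
            per_class[min(idx, n_bins - 1)] += 1
    return counts


def partner_counts_per_gene(
    partner_sites: Sequence[PeakRecord],
    targets: Sequence[TargetRecord],
    max_tss_distance: int = 100_000,
) -> dict[str, int]:
    """Number of partner-factor sites within range of each target's TSS."""
    by_chrom: dict[str, list[int]] = {}
    for s in partner_sites:
        by_chrom.setdefault(s.chrom, []).append(s.center())
    for centers in by_chrom.values():
        centers.sort()
    counts: dict[str, int] = {}
    for t in targets:
        centers = by_chrom.get(t.gene.chrom, [])
        lo = bisect.bisect_left(centers, t.gene.tss - max_tss_distance)
        hi = bisect.bisect_right(centers, t.gene.tss + max_tss_distance)
        counts[t.gene.gene_id] = hi - lo
    return counts


def partner_counts_by_category(
    partner_sites: Sequence[PeakRecord],
    targets: Sequence[TargetRecord],
    max_tss_distance: int = 100_000,
) -> dict:
    """Category means of per-gene partner counts with pairwise Welch t-tests."""
    counts = partner_counts_per_gene(partner_sites, targets, max_tss_distance)
    per_cat: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    for t in targets:
        if t.category in per_cat:
            per_cat[t.category].append(counts[t.gene.gene_id])
    means = {c: (sum(v) / len(v) if v else None) for c, v in per_cat.items()}
    tests = {}
    for i, c1 in enumerate(CATEGORIES):
        for c2 in CATEGORIES[i + 1 :]:
            if len(per_cat[c1]) >= 2 and len(per_cat[c2]) >= 2:
                t, df, p = welch_t(per_cat[c1], per_cat[c2])
                tests[(c1, c2)] = {"t": t, "df": df, "p": p}
    return {"counts": per_cat, "means": means, "tests": tests}
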