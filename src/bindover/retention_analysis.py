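"""Retention classification of binding sites across genomes.

"Retention" is the physical presence of binding at orthologous loci in
both species — empirically, a site in genome A whose (standardized)
interval overlaps a site lifted over from genome B — as opposed to
sequence conservation of the underlying DNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from bindover.genomic_core import GenomicInterval, PeakRecord, coverage_counts, quartile_split, standardize


@dataclass(frozen=True)
class RetentionLabel:
    site_id: str
    label: str  # retained | species_specific | unliftable
    partner_site: str | None = None

    def __post_init__(self) -> None:
        if (self.label == "retained") != (self.partner_site is not None):
            raise ValueError("retained iff partner_site present")


def classify_retention(
    sites_a: Sequence[PeakRecord],
    sites_b_lifted: Sequence[PeakRecord],
    width_a: int = 1000,
) -> list[RetentionLabel]:
    """Label each genome-A site retained or species-specific.

    Sites in A are standardized to ``width_a`` bp around their centers;
    a site is retained iff it overlaps (>= 1 bp) any lifted genome-B
    site, with the partner being the nearest lifted site by center.
    """
    tree_by_chrom: dict[str, IntervalTree] = {}
    for b in sites_b_lifted:
        tree_by_chrom.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    labels: list[RetentionLabel] = []
    for site in sites_a:
        iv = standardize(site, width_a)
        tree = tree_by_chrom.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree is not None else ()
        if hits:
            partner = min(hits, key=lambda h: abs(h.data.center() - site.center())).data
            labels.append(RetentionLabel(site.name, "retained", partner.name))
        else:
            labels.append(RetentionLabel(site.name, "species_specific"))
    return labels


def retention_fraction(labels: Sequence[RetentionLabel]) -> tuple[int, int, float]:
    """(retained count, classifiable total, fraction); unliftable excluded."""
    classifiable = [l for l in labels if l.label != "unliftable"]
    k = sum(1 for l in classifiable if l.label == "retained")
    n = len(classifiable)
    return k, n, k / n if n else float("nan")


def retention_by_quartile(
    labels: Sequence[RetentionLabel],
    peaks: Sequence[PeakRecord],
) -> list[dict]:
    """Retained fraction per enrichment quartile (Q1 = strongest).

    Returns one dict per quartile with retained count, size, and
    fraction; counts across quartiles sum to the total retained count.
    """
    retained_ids = {l.site_id for l in labels if l.label == "retained"}
    rows = []
    for q, group in enumerate(quartile_split(peaks), start=1):
        k = sum(1 for p in group if p.name in retained_ids)
        rows.append({"quartile": q, "retained": k, "n": len(group), "fraction": k / len(group)})
    return rows


def threshold_robustness(
    site_sets: Mapping[float, Sequence[PeakRecord]],
    opposite_sets: Mapping[float, Sequence[PeakRecord]],
    width_a: int = 1000,
) -> list[dict]:
    """Retention fraction for every pair of site-calling thresholds."""
    rows = []
    for thr_a, sites_a in site_sets.items():
        for thr_b, sites_b in opposite_sets.items():
            labels = classify_retention(sites_a, sites_b, width_a=width_a)
            k, n, frac = retention_fraction(labels)
            rows.append(
                {"threshold_a": thr_a, "threshold_b": thr_b, "retained": k, "n": n, "fraction": frac}
            )
    return rows


def cross_species_signal(
    tag_sets: Mapping[str, Sequence[GenomicInterval]],
    loci_sets: Mapping[str, Sequence[GenomicInterval]],
    loci_genomes: Mapping[str, str],
    extension: int = 250,
) -> dict[tuple[str, str], list[int]]:
    """Raw per-locus tag-count distributions per (library, locus class).

    ``loci_genomes`` names the genome each locus class is expressed in;
    a library is only counted against locus classes on its own genome
    (lift loci upstream to compare across genomes). Summaries are the
    caller's business; no outliers are dropped here.
    """
    out: dict[tuple[str, str], list[int]] = {}
    for lib, tags in tag_sets.items():
        for label, loci in loci_sets.items():
            genome = loci_genomes.get(label)
            if genome is None:
                raise ValueError(f"locus class {label!r} has no genome label")
            if genome != lib.split(":")[0]:
                continue
            out[(lib, label)] = coverage_counts(tags, list(loci), extension=extension)
    return out
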