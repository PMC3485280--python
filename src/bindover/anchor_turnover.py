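"""The anchor model: does retention of a co-binding lineage factor
stratify the fate of nomadic binding sites?

Each nomadic (receptor) site is joined with its co-occupancy status,
the retention label of the co-binding anchor site, its own retention
label, the sharing category of its nearest target gene, and motif
presence at the orthologous locus in both species. The "anchor
gradient" is the proportion of retained anchors among co-occupied
sites, stratified by site fate: retained sites, then species-specific
sites at indirectly shared vs species-specific target genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from bindover.peak_processing import CooccupancyFlag
from bindover.retention_analysis import RetentionLabel
from bindover.stats_enrichment import fisher_exact_2x2
from bindover.target_genes import TargetRecord

STRATA = ("retained", "indirectly_shared", "species_specific")
MOTIF_KEYS = ("nomadic_a", "nomadic_b", "anchor_a", "anchor_b")


@dataclass(frozen=True)
class AnchorSiteRecord:
    site_id: str
    site_retained: bool
    cooccupied: bool
    anchor_retained: bool | None  # None = indeterminate (anchor unliftable / unlabeled)
    target_category: str | None
    motif_flags: Mapping[str, bool | None]
    flagged: bool = False  # any unresolved dependency

    @property
    def stratum(self) -> str | None:
        if self.site_retained:
            return "retained"
        return self.target_category


def _more_shared(categories: Sequence[str]) -> str:
    order = {"directly_shared": 2, "indirectly_shared": 1, "species_specific": 0}
    return max(categories, key=lambda c: order.get(c, -1))


def nearest_target_category(
    site_id: str,
    site_center: int,
    chrom: str,
    targets: Sequence[TargetRecord],
) -> str | None:
    """Category of the nearest target gene among genes the site targets.

    Ties in TSS distance go to the more-shared category.
    """
    candidates = [
        t for t in targets if site_id in t.sites and t.gene.chrom == chrom and t.category
    ]
    if not candidates:
        return None
    dists = [abs(t.gene.tss - site_center) for t in candidates]
    best = min(dists)
    tied = [t.category for t, d in zip(candidates, dists) if d == best]
    return _more_shared(tied)


def build_anchor_records(
    sites,
    cooccupancy: Sequence[CooccupancyFlag],
    anchor_retention_labels: Sequence[RetentionLabel],
    site_retention_labels: Sequence[RetentionLabel],
    targets: Sequence[TargetRecord],
    motif_table: pd.DataFrame | None = None,
) -> list[AnchorSiteRecord]:
    """Join all per-site annotations into AnchorSiteRecords.

    All joins are by site identifier; a record with an unresolved
    dependency (unliftable anchor, no target gene, missing motif call)
    is flagged, never dropped. Raises if the co-occupancy or retention
    annotations were computed on a different site universe.
    """
    site_ids = [getattr(s, "name", None) or s.interval.name for s in sites]
    universe = set(site_ids)
    coocc_by_id = {f.site.name: f for f in cooccupancy}
    orphans = sorted(universe.symmetric_difference(coocc_by_id))
    if orphans:
        raise ValueError(f"site universe mismatch with co-occupancy annotation: {orphans[:5]}")
    site_ret = {l.site_id: l.label for l in site_retention_labels}
    missing = sorted(universe - set(site_ret))
    if missing:
        raise ValueError(f"site universe mismatch with retention labels: {missing[:5]}")
    anchor_ret = {l.site_id: l.label for l in anchor_retention_labels}
    motif_by_id = {}
    if motif_table is not None:
        for _, row in motif_table.iterrows():
            motif_by_id[row["site_id"]] = row
    targets_by_site: dict[str, list[TargetRecord]] = {}
    for t in targets:
        for sid in t.sites:
            targets_by_site.setdefault(sid, []).append(t)

    records: list[AnchorSiteRecord] = []
    for site, site_id in zip(sites, site_ids):
        center = site.center() if hasattr(site, "center") else site.interval.center()
        chrom = getattr(site, "chrom", None) or site.interval.chrom
        flag = coocc_by_id[site_id]
        retained = site_ret[site_id] == "retained"
        flagged = False
        if flag.cooccupied and flag.partner is not None:
            label = anchor_ret.get(flag.partner.name)
            if label is None or label == "unliftable":
                anchor_retained, flagged = None, True
            else:
                anchor_retained = label == "retained"
        else:
            anchor_retained = None
        category = nearest_target_category(
            site_id, center, chrom, targets_by_site.get(site_id, [])
        )
        if category is None and not retained:
            flagged = True
        motif_flags: dict[str, bool | None] = {}
        if motif_table is not None:
            row = motif_by_id.get(site_id)
            if row is None:
                flagged = True
            else:
                for col in motif_table.columns:
                    if col in ("site_id", "lift_status"):
                        continue
                    value = row[col]
                    motif_flags[col] = None if pd.isna(value) else bool(value)
                    if motif_flags[col] is None:
                        flagged = True
        records.append(
            AnchorSiteRecord(
                site_id=site_id,
                site_retained=retained,
                cooccupied=flag.cooccupied,
                anchor_retained=anchor_retained,
                target_category=category,
                motif_flags=motif_flags,
                flagged=flagged,
            )
        )
    return records


def anchor_gradient(records: Sequence[AnchorSiteRecord]) -> dict:
    """Proportion of retained anchors among co-occupied sites, per stratum.

    Records whose anchor retention is indeterminate are excluded from
    both numerator and denominator. Pairwise Fisher tests and a
    monotonicity flag are attached; empty strata yield proportion None
    and skip their comparisons.
    """
    per_stratum: dict[str, dict] = {}
    for stratum in STRATA:
        members = [
            r
            for r in records
            if r.cooccupied and r.anchor_retained is not None and r.stratum == stratum
        ]
        k = sum(1 for r in members if r.anchor_retained)
        n = len(members)
        per_stratum[stratum] = {"k": k, "n": n, "proportion": k / n if n else None}
    tests = {}
    for i, s1 in enumerate(STRATA):
        for s2 in STRATA[i + 1 :]:
            g1, g2 = per_stratum[s1], per_stratum[s2]
            if g1["n"] and g2["n"]:
                table = [[g1["k"], g1["n"] - g1["k"]], [g2["k"], g2["n"] - g2["k"]]]
                try:
                    tests[(s1, s2)] = fisher_exact_2x2(table).p_two_sided
                except ValueError:
                    tests[(s1, s2)] = 1.0
    proportions = [per_stratum[s]["proportion"] for s in STRATA]
    defined = [p for p in proportions if p is not None]
    monotone = all(a > b for a, b in zip(defined, defined[1:])) if len(defined) > 1 else False
    return {"strata": per_stratum, "fisher_p": tests, "strictly_decreasing": monotone}


def motif_gain_loss(records: Sequence[AnchorSiteRecord]) -> dict:
    """Cross-tabulate motif fates at orthologous loci.

    Counts records by (nomadic motif in A, in B) x (anchor motif in A,
    in B) x anchor retention; only records with all four motif calls
    resolved enter the table. Marginal summaries report the nomadic
    motif-loss rate at species-specific vs retained sites and the
    anchor-motif both-species rate for retained vs species-specific
    anchors.
    """
    cells: dict[tuple, int] = {}
    resolved = []
    for r in records:
        mf = r.motif_flags
        if any(mf.get(k) is None for k in MOTIF_KEYS):
            continue
        key = (
            (mf["nomadic_a"], mf["nomadic_b"]),
            (mf["anchor_a"], mf["anchor_b"]),
            r.anchor_retained,
        )
        cells[key] = cells.get(key, 0) + 1
        resolved.append(r)

    def _loss_rate(rs):
        have_a = [r for r in rs if r.motif_flags.get("nomadic_a")]
        if not have_a:
            return None
        lost = sum(1 for r in have_a if not r.motif_flags.get("nomadic_b"))
        return lost / len(have_a)

    def _anchor_motif_both(rs):
        if not rs:
            return None
        both = sum(
            1 for r in rs if r.motif_flags.get("anchor_a") and r.motif_flags.get("anchor_b")
        )
        return both / len(rs)

    specific = [r for r in resolved if not r.site_retained]
    retained = [r for r in resolved if r.site_retained]
    anchor_retained = [r for r in resolved if r.anchor_retained is True]
    anchor_specific = [r for r in resolved if r.anchor_retained is False]
    return {
        "cells": cells,
        "n_resolved": len(resolved),
        "nomadic_motif_loss_specific": _loss_rate(specific),
        "nomadic_motif_loss_retained": _loss_rate(retained),
        "anchor_motif_both_given_retained": _anchor_motif_both(anchor_retained),
        "anchor_motif_both_given_specific": _anchor_motif_both(anchor_specific),
    }
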