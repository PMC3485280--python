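"""Constructed fixtures that carry known classification counts.

``make_fixture`` builds minimal synthetic inputs (peaks, genes,
retention labels, gene sets) whose counts at each pipeline stage are
fixed by the caller, then pushes them through the *real*
classification and reporting code paths. This separates the
arithmetic of the reporting layer (proportions, Fisher tests,
rounding) from the geometry of real data: any reported percentage can
be traced to a planted numerator and denominator.

Denominators that the fixture spec leaves open (for example the
per-stratum totals behind the anchor-gradient percentages) are chosen
by the fixture and are synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from bindover.anchor_turnover import AnchorSiteRecord, anchor_gradient
from bindover.chain_liftover import ChainAlignment, ChainBlock, ChainSide, lift_set
from bindover.expression_response import category_response_rates
from bindover.genomic_core import GeneAnnotation, GenomicInterval, PeakRecord
from bindover.peak_processing import annotate_cooccupancy, filter_by_support
from bindover.pipeline import proportion
from bindover.retention_analysis import RetentionLabel, classify_retention, retention_fraction
from bindover.target_genes import assign_targets, classify_sharing

#: the published genome-scale counts, used as fixture inputs
PRINTED_COUNTS: dict = {
    "total_primary": 4302,
    "supported": 2133,
    "retained": 94,
    "cooccupied": 1293,
    "other_total": 1961,
    "other_lifted": 1548,
    "targets": {"species_specific": 944, "indirectly_shared": 186, "directly_shared": 70},
    "responsive": {"species_specific": 107, "indirectly_shared": 31, "directly_shared": 23},
    "gradient": {
        "retained": (85, 100),
        "indirectly_shared": (41, 100),
        "species_specific": (25, 100),
    },
}

_SITE_PITCH = 10_000
_GENE_PITCH = 500_000


class FixtureSpecError(ValueError):
    """The requested counts violate an internal identity."""


def _validate(spec: dict) -> None:
    if spec["supported"] > spec["total_primary"]:
        raise FixtureSpecError("supported sites cannot exceed primary peaks")
    for key in ("retained", "cooccupied"):
        if spec[key] > spec["supported"]:
            raise FixtureSpecError(f"{key} cannot exceed the supported site count")
    if spec["other_lifted"] > spec["other_total"]:
        raise FixtureSpecError("lifted sites cannot exceed the other species' total")
    if "shared" in spec:
        t = spec["targets"]
        if spec["shared"] != t["indirectly_shared"] + t["directly_shared"]:
            raise FixtureSpecError(
                f"shared ({spec['shared']}) != indirect ({t['indirectly_shared']}) "
                f"+ direct ({t['directly_shared']})"
            )
    for cat, k in spec["responsive"].items():
        if k > spec["targets"][cat]:
            raise FixtureSpecError(f"responsive {cat} count exceeds its target count")
    for stratum, (k, n) in spec["gradient"].items():
        if k > n:
            raise FixtureSpecError(f"gradient {stratum}: k > n")


@dataclass
class Fixture:
    spec: dict
    primary: list = field(default_factory=list)
    support: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    lifted_partners: list = field(default_factory=list)
    anchors: list = field(default_factory=list)
    other_sites: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    genes_a: list = field(default_factory=list)
    genes_b: list = field(default_factory=list)
    gene_sites: list = field(default_factory=list)
    gene_sites_b: list = field(default_factory=list)
    gene_retention: list = field(default_factory=list)
    ortholog_map: dict = field(default_factory=dict)
    responsive: set = field(default_factory=set)
    gradient_records: list = field(default_factory=list)

    def summary(self) -> dict:
        """Run every stage's real code path and report its proportions."""
        spec = self.spec
        out: dict = {}
        supported = filter_by_support(self.primary, self.support, 500, 2.0)
        out["support_filter"] = proportion(len(supported), len(self.primary))
        labels = classify_retention(self.sites, self.lifted_partners, width_a=1000)
        k, n, _ = retention_fraction(labels)
        out["retention"] = proportion(k, n)
        coocc = annotate_cooccupancy(self.sites, self.anchors, 150)
        out["cooccupancy"] = proportion(sum(f.cooccupied for f in coocc), len(coocc))
        _, lift_stats = lift_set(self.other_sites, self.chains, min_match=0.1, pre_extend=1000)
        out["liftover"] = proportion(lift_stats["mapped"], len(self.other_sites))
        targets_a = assign_targets(self.gene_sites, self.genes_a, 100_000)
        targets_b = assign_targets(self.gene_sites_b, self.genes_b, 100_000)
        targets = classify_sharing(targets_a, targets_b, self.gene_retention, self.ortholog_map)
        counts = {c: sum(1 for t in targets if t.category == c)
                  for c in ("species_specific", "indirectly_shared", "directly_shared")}
        n_shared = counts["indirectly_shared"] + counts["directly_shared"]
        out["targets"] = {
            "counts": counts,
            "total": len(targets),
            "shared": proportion(n_shared, len(targets)),
            "direct_of_shared": proportion(counts["directly_shared"], n_shared),
            "indirect_of_shared": proportion(counts["indirectly_shared"], n_shared),
        }
        rates = category_response_rates(targets, self.responsive)
        out["responsiveness"] = {
            "categories": rates["categories"],
            "fisher_p": {f"{a}_vs_{b}": v for (a, b), v in rates["fisher_p"].items()},
        }
        gradient = anchor_gradient(self.gradient_records)
        out["anchor_gradient"] = {
            "strata": gradient["strata"],
            "fisher_p": {f"{a}_vs_{b}": v for (a, b), v in gradient["fisher_p"].items()},
            "strictly_decreasing": gradient["strictly_decreasing"],
        }
        return out


def make_fixture(spec: dict | None = None) -> Fixture:
    """Build a fixture whose stage counts equal the requested spec."""
    spec = dict(PRINTED_COUNTS if spec is None else spec)
    _validate(spec)
    fx = Fixture(spec)

    # --- support filter stage -------------------------------------------
    for i in range(spec["total_primary"]):
        center = (i + 1) * _SITE_PITCH
        iv = GenomicInterval("chrP", center - 75, center + 75, name=f"pk_{i:05d}")
        fx.primary.append(PeakRecord(iv, enrichment=10.0))
        if i < spec["supported"]:
            siv = GenomicInterval("chrP", center + 25, center + 175, name=f"sup_{i:05d}")
            fx.support.append(PeakRecord(siv, enrichment=5.0))

    # --- retention / co-occupancy on the supported universe --------------
    for i in range(spec["supported"]):
        center = (i + 1) * _SITE_PITCH
        iv = GenomicInterval("chrS", center - 75, center + 75, name=f"site_{i:05d}")
        fx.sites.append(PeakRecord(iv, enrichment=10.0))
        if i < spec["retained"]:
            piv = GenomicInterval("chrS", center - 75, center + 75, name=f"b_site_{i:05d}")
            fx.lifted_partners.append(PeakRecord(piv, enrichment=8.0))
        if i < spec["cooccupied"]:
            aiv = GenomicInterval("chrS", center - 25, center + 125, name=f"an_{i:05d}")
            fx.anchors.append(PeakRecord(aiv, enrichment=6.0))

    # --- liftover stage: one chain covers exactly the liftable sites -----
    covered_end = spec["other_lifted"] * 1_000 + 500
    total_end = (spec["other_total"] + 2) * 1_000
    fx.chains = [
        ChainAlignment(
            score=1000.0,
            target=ChainSide("chrO", total_end, "+", 0, covered_end),
            query=ChainSide("chrO2", covered_end, "+", 0, covered_end),
            blocks=(ChainBlock(covered_end, 0, 0),),
            chain_id=1,
        )
    ]
    for i in range(spec["other_total"]):
        if i < spec["other_lifted"]:
            center = i * 1_000 + 100  # inside the chain span even at 1 kb width
        else:
            center = covered_end + (i - spec["other_lifted"] + 2) * 1_000
        iv = GenomicInterval("chrO", max(0, center - 75), center + 75, name=f"o_{i:05d}")
        fx.other_sites.append(PeakRecord(iv, enrichment=4.0))

    # --- sharing taxonomy -------------------------------------------------
    order = ("directly_shared", "indirectly_shared", "species_specific")
    g = 0
    for cat in order:
        for _ in range(spec["targets"][cat]):
            tss = (g + 1) * _GENE_PITCH
            gene_id, symbol = f"ga_{g:05d}", f"GA{g:05d}"
            fx.genes_a.append(
                GeneAnnotation(gene_id, symbol, GenomicInterval("chrG", tss, tss + 2_000, strand="+", name=gene_id))
            )
            site_iv = GenomicInterval("chrG", tss + 1_000 - 75, tss + 1_000 + 75, name=f"ts_{g:05d}")
            fx.gene_sites.append(PeakRecord(site_iv, enrichment=9.0))
            if cat == "directly_shared":
                fx.gene_retention.append(RetentionLabel(f"ts_{g:05d}", "retained", f"bs_{g:05d}"))
            else:
                fx.gene_retention.append(RetentionLabel(f"ts_{g:05d}", "species_specific"))
            if cat in ("directly_shared", "indirectly_shared"):
                b_id = f"gb_{g:05d}"
                fx.ortholog_map[gene_id] = b_id
                fx.genes_b.append(
                    GeneAnnotation(b_id, symbol, GenomicInterval("chrH", tss, tss + 2_000, strand="+", name=b_id))
                )
                if cat == "indirectly_shared":
                    biv = GenomicInterval("chrH", tss + 5_000, tss + 5_150, name=f"bsp_{g:05d}")
                    fx.gene_sites_b.append(PeakRecord(biv, enrichment=7.0))
            g += 1

    # --- responsiveness ---------------------------------------------------
    g = 0
    for cat in order:
        n_cat, k_cat = spec["targets"][cat], spec["responsive"][cat]
        for j in range(n_cat):
            if j < k_cat:
                fx.responsive.add(f"GA{g:05d}")
            g += 1

    # --- anchor gradient --------------------------------------------------
    r = 0
    for stratum, (k, n) in spec["gradient"].items():
        for j in range(n):
            fx.gradient_records.append(
                AnchorSiteRecord(
                    site_id=f"gr_{r:05d}",
                    site_retained=stratum == "retained",
                    cooccupied=True,
                    anchor_retained=j < k,
                    target_category=None if stratum == "retained" else stratum,
                    motif_flags={},
                )
            )
            r += 1
    return fx
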