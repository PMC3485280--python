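"""Anchor-record joins, the anchor gradient, and motif gain/loss."""

import numpy as np
import pandas as pd
import pytest

from bindover.anchor_turnover import (
    AnchorSiteRecord,
    anchor_gradient,
    build_anchor_records,
    motif_gain_loss,
)
from bindover.genomic_core import GeneAnnotation, GenomicInterval, PeakRecord
from bindover.peak_processing import annotate_cooccupancy
from bindover.retention_analysis import RetentionLabel
from bindover.target_genes import TargetRecord, assign_targets


def peak(center, name, chrom="chr1"):
    return PeakRecord(GenomicInterval(chrom, center - 75, center + 75, name=name), enrichment=5.0)


def gene(tss, gene_id, category):
    iv = GenomicInterval("chr1", tss, tss + 2_000, strand="+", name=gene_id)
    g = GeneAnnotation(gene_id, gene_id.upper(), iv)
    return g, category


def make_fixture_inputs():
    """Ten fully resolved sites with hand-known joins."""
    sites = [peak(1_000_000 * (i + 1), f"s{i}") for i in range(10)]
    anchors = [peak(1_000_000 * (i + 1) + 50, f"a{i}") for i in range(6)]  # first 6 co-occupied
    coocc = annotate_cooccupancy(sites, anchors, 150)
    anchor_labels = [
        RetentionLabel(f"a{i}", "retained", f"ba{i}") if i < 3
        else RetentionLabel(f"a{i}", "species_specific")
        for i in range(6)
    ]
    site_labels = [
        RetentionLabel(f"s{i}", "retained", f"b{i}") if i < 2
        else RetentionLabel(f"s{i}", "species_specific")
        for i in range(10)
    ]
    genes = [gene(1_000_000 * (i + 1) + 10_000, f"g{i}",
                  "indirectly_shared" if i % 2 else "species_specific") for i in range(10)]
    targets = []
    raw = assign_targets(sites, [g for g, _ in genes])
    by_id = {t.gene.gene_id: t for t in raw}
    for g, cat in genes:
        t = by_id[g.gene_id]
        targets.append(TargetRecord(gene=t.gene, sites=t.sites,
                                    min_tss_distance=t.min_tss_distance, category=cat))
    motif_table = pd.DataFrame(
        [
            {"site_id": f"s{i}", "lift_status": "mapped",
             "nomadic_a": True, "nomadic_b": i < 2,
             "anchor_a": i < 6, "anchor_b": i < 3}
            for i in range(10)
        ]
    )
    return sites, coocc, anchor_labels, site_labels, targets, motif_table


class TestBuildRecords:
    def test_ten_site_fixture_matches_manual_merge(self):
        sites, coocc, anchor_labels, site_labels, targets, motif_table = make_fixture_inputs()
        records = build_anchor_records(sites, coocc, anchor_labels, site_labels, targets, motif_table)
        assert len(records) == 10
        by_id = {r.site_id: r for r in records}
        assert by_id["s0"].site_retained and by_id["s0"].anchor_retained
        assert by_id["s3"].cooccupied and by_id["s3"].anchor_retained is False
        assert by_id["s7"].cooccupied is False and by_id["s7"].anchor_retained is None
        assert by_id["s2"].target_category == "species_specific"
        assert by_id["s3"].target_category == "indirectly_shared"
        assert not any(r.flagged for r in records)

    def test_unlabeled_anchor_partner_is_indeterminate_and_flagged(self):
        sites, coocc, anchor_labels, site_labels, targets, motif_table = make_fixture_inputs()
        # drop the label of anchor a1: its site becomes indeterminate
        trimmed = [l for l in anchor_labels if l.site_id != "a1"]
        records = build_anchor_records(sites, coocc, trimmed, site_labels, targets, motif_table)
        by_id = {r.site_id: r for r in records}
        assert by_id["s1"].anchor_retained is None and by_id["s1"].flagged

    def test_site_universe_mismatch_raises_with_orphans(self):
        sites, coocc, anchor_labels, site_labels, targets, motif_table = make_fixture_inputs()
        with pytest.raises(ValueError, match="s9"):
            build_anchor_records(sites, coocc[:-1], anchor_labels, site_labels, targets, motif_table)

    def test_stratum_prefers_retained_over_category(self):
        sites, coocc, anchor_labels, site_labels, targets, motif_table = make_fixture_inputs()
        records = build_anchor_records(sites, coocc, anchor_labels, site_labels, targets, motif_table)
        by_id = {r.site_id: r for r in records}
        assert by_id["s0"].stratum == "retained"
        assert by_id["s5"].stratum == "indirectly_shared"


class TestGradient:
    @staticmethod
    def _records(spec):
        """spec: list of (stratum, k, n)."""
        records = []
        for stratum, k, n in spec:
            for j in range(n):
                records.append(
                    AnchorSiteRecord(
                        site_id=f"{stratum}_{j}",
                        site_retained=stratum == "retained",
                        cooccupied=True,
                        anchor_retained=j < k,
                        target_category=None if stratum == "retained" else stratum,
                        motif_flags={},
                    )
                )
        return records

    def test_planted_gradient_is_recovered_and_monotone(self):
        records = self._records(
            [("retained", 85, 100), ("indirectly_shared", 41, 100), ("species_specific", 25, 100)]
        )
        out = anchor_gradient(records)
        assert out["strata"]["retained"]["proportion"] == 0.85
        assert out["strata"]["indirectly_shared"]["proportion"] == 0.41
        assert out["strata"]["species_specific"]["proportion"] == 0.25
        assert out["strictly_decreasing"]
        assert out["fisher_p"][("retained", "indirectly_shared")] < 1e-6
        assert out["fisher_p"][("indirectly_shared", "species_specific")] < 0.05

    def test_all_retained_anchors_is_flat_at_one(self):
        records = self._records(
            [("retained", 10, 10), ("indirectly_shared", 10, 10), ("species_specific", 10, 10)]
        )
        out = anchor_gradient(records)
        assert all(v["proportion"] == 1.0 for v in out["strata"].values())
        assert not out["strictly_decreasing"]

    def test_invariant_under_record_order(self):
        records = self._records([("retained", 3, 5), ("species_specific", 1, 4)])
        fwd = anchor_gradient(records)
        rev = anchor_gradient(records[::-1])
        assert fwd["strata"] == rev["strata"]

    def test_empty_stratum_skips_comparisons(self):
        records = self._records([("retained", 3, 5)])
        out = anchor_gradient(records)
        assert out["strata"]["indirectly_shared"]["proportion"] is None
        assert out["fisher_p"] == {}

    def test_indeterminate_anchors_are_excluded_from_both_sides(self):
        records = self._records([("retained", 3, 5)])
        records.append(
            AnchorSiteRecord("x", True, True, None, None, {})
        )
        out = anchor_gradient(records)
        assert out["strata"]["retained"]["n"] == 5


class TestMotifGainLoss:
    @staticmethod
    def _record(i, nomadic, anchor, site_retained=False, anchor_retained=False, coocc=True):
        return AnchorSiteRecord(
            site_id=f"r{i}",
            site_retained=site_retained,
            cooccupied=coocc,
            anchor_retained=anchor_retained if coocc else None,
            target_category=None if site_retained else "indirectly_shared",
            motif_flags={
                "nomadic_a": nomadic[0], "nomadic_b": nomadic[1],
                "anchor_a": anchor[0], "anchor_b": anchor[1],
            },
        )

    def test_cell_counts_sum_to_resolved_records(self):
        records = [self._record(i, (True, i % 2 == 0), (True, i % 3 == 0)) for i in range(12)]
        out = motif_gain_loss(records)
        assert sum(out["cells"].values()) == out["n_resolved"] == 12

    def test_unresolved_motif_flags_are_excluded(self):
        records = [self._record(0, (True, True), (True, True))]
        records.append(
            AnchorSiteRecord("u", False, True, True, "indirectly_shared",
                             {"nomadic_a": True, "nomadic_b": None,
                              "anchor_a": True, "anchor_b": True})
        )
        assert motif_gain_loss(records)["n_resolved"] == 1

    def test_loss_concentrates_where_planted(self):
        # species-specific sites lose the nomadic motif in B; retained keep it
        records = [self._record(i, (True, False), (True, True)) for i in range(10)]
        records += [self._record(10 + i, (True, True), (True, True), site_retained=True)
                    for i in range(5)]
        out = motif_gain_loss(records)
        assert out["nomadic_motif_loss_specific"] == 1.0
        assert out["nomadic_motif_loss_retained"] == 0.0

    def test_anchor_motif_contrast_representable(self):
        # the pattern of a co-bound locus at an indirectly shared gene:
        # anchor motif in both species, nomadic motif in one
        rec = self._record(0, (True, False), (True, True), anchor_retained=True)
        out = motif_gain_loss([rec])
        assert out["anchor_motif_both_given_retained"] == 1.0
        key = ((True, False), (True, True), True)
        assert out["cells"][key] == 1
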