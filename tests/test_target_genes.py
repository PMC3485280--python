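"""Target assignment, orthology mapping, and the sharing taxonomy."""

import logging

import numpy as np
import pytest

from bindover.genomic_core import GeneAnnotation, GenomicInterval, PeakRecord
from bindover.retention_analysis import RetentionLabel
from bindover.target_genes import (
    assign_targets,
    classify_sharing,
    map_orthologs,
    nearest_gene_report,
    partner_counts_by_category,
    partner_counts_per_gene,
    tss_distance_histogram,
)


def gene(tss, gene_id, chrom="chr1", strand="+", span=2000):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + span, strand="+", name=gene_id)
    else:
        iv = GenomicInterval(chrom, tss - span + 1, tss + 1, strand="-", name=gene_id)
    return GeneAnnotation(gene_id, gene_id.upper(), iv)


def peak(center, name, chrom="chr1"):
    return PeakRecord(GenomicInterval(chrom, center - 75, center + 75, name=name), enrichment=5.0)


class TestAssignTargets:
    def test_site_50kb_downstream_of_plus_strand_tss(self):
        (t,) = assign_targets([peak(150_000, "s1")], [gene(100_000, "g1")])
        assert t.min_tss_distance == 50_000

    def test_distance_boundary_is_inclusive_at_100kb(self):
        assert assign_targets([peak(200_000, "s1")], [gene(100_000, "g1")])
        assert not assign_targets([peak(200_001, "s1")], [gene(100_000, "g1")])

    def test_signed_distance_respects_gene_strand(self):
        (t,) = assign_targets([peak(150_000, "s1")], [gene(100_000, "g1", strand="-")])
        assert t.min_tss_distance == -50_000  # upstream of a minus-strand gene

    def test_matches_brute_force_on_a_30_gene_fixture(self):
        rng = np.random.default_rng(25)
        genes = [gene(int(t), f"g{i}", strand="+-"[i % 2])
                 for i, t in enumerate(rng.integers(10_000, 2_000_000, 30))]
        sites = [peak(int(c), f"s{i}") for i, c in enumerate(rng.integers(10_000, 2_000_000, 60))]
        records = {t.gene.gene_id: t for t in assign_targets(sites, genes)}
        for g in genes:
            expected = [s.name for s in sites if abs(s.center() - g.tss) <= 100_000]
            if expected:
                assert set(records[g.gene_id].sites) == set(expected)
            else:
                assert g.gene_id not in records

    def test_one_site_can_serve_multiple_genes(self):
        genes = [gene(100_000, "g1"), gene(140_000, "g2")]
        records = assign_targets([peak(120_000, "s1")], genes)
        assert [t.gene.gene_id for t in records] == ["g1", "g2"]

    def test_nearest_gene_report_assigns_each_site_once(self):
        genes = [gene(100_000, "g1"), gene(140_000, "g2")]
        rows = nearest_gene_report([peak(130_000, "s1")], genes)
        assert rows == [
            {"site_id": "s1", "gene_id": "g2", "symbol": "G2", "tss_distance": -10_000}
        ]


class TestClassifySharing:
    @staticmethod
    def _setup(retained=False, ortholog_bound=False, with_ortholog=True):
        genes_a = [gene(100_000, "ga")]
        sites = [peak(110_000, "s1")]
        targets_a = assign_targets(sites, genes_a)
        label = (
            RetentionLabel("s1", "retained", "b1")
            if retained
            else RetentionLabel("s1", "species_specific")
        )
        genes_b = [gene(500_000, "gb", chrom="chr5")]
        sites_b = [peak(510_000, "bs1", chrom="chr5")] if ortholog_bound else []
        targets_b = assign_targets(sites_b, genes_b)
        orth = {"ga": "gb"} if with_ortholog else {}
        return classify_sharing(targets_a, targets_b, [label], orth)

    def test_retained_site_makes_the_gene_directly_shared(self):
        (t,) = self._setup(retained=True)
        assert t.category == "directly_shared"

    def test_species_specific_site_with_bound_ortholog_is_indirect(self):
        # the compensatory-turnover pattern: both species bind the gene,
        # but at non-orthologous sites
        (t,) = self._setup(ortholog_bound=True)
        assert t.category == "indirectly_shared"

    def test_unbound_ortholog_leaves_the_gene_species_specific(self):
        (t,) = self._setup(ortholog_bound=False)
        assert t.category == "species_specific"

    def test_retained_site_without_ortholog_still_direct_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            (t,) = self._setup(retained=True, with_ortholog=False)
        assert t.category == "directly_shared"
        assert "no ortholog" in caplog.text

    def test_categories_partition_the_target_set(self, summary):
        targets = summary["_objects"]["targets"]
        assert all(t.category in
                   ("species_specific", "indirectly_shared", "directly_shared")
                   for t in targets)
        counts = summary["targets"]["counts"]
        assert sum(counts.values()) == summary["targets"]["total"] == len(targets)


class TestOrthologMapping:
    def test_identity_chain_maps_genes_by_overlap(self, bundle):
        orth = map_orthologs(bundle.genes_a, bundle.genes_b, bundle.chains_a_to_b)
        # generator emits B genes under the same ids at orthologous spans
        assert len(orth) == len(bundle.genes_b)
        assert all(a == b for a, b in orth.items())


class TestHistogram:
    def test_single_site_lands_in_first_bin(self):
        counts = tss_distance_histogram(
            [peak(105_000, "s1")], [gene(100_000, "g1")], bins=[0, 10_000, 100_000]
        )
        assert counts["all"] == [1, 0, 0]

    def test_counts_invariant_under_site_reordering(self):
        rng = np.random.default_rng(26)
        genes = [gene(int(t), f"g{i}") for i, t in enumerate(rng.integers(10_000, 900_000, 10))]
        sites = [peak(int(c), f"s{i}") for i, c in enumerate(rng.integers(10_000, 900_000, 40))]
        bins = [0, 1_000, 10_000, 100_000]
        fwd = tss_distance_histogram(sites, genes, bins)
        rev = tss_distance_histogram(sites[::-1], genes, bins)
        assert fwd == rev

    def test_class_counts_sum_to_class_sizes(self):
        sites = [peak(5_000 + 200 * i, f"s{i}") for i in range(10)]
        classes = {f"s{i}": ("retained" if i < 3 else "specific") for i in range(10)}
        counts = tss_distance_histogram(sites, [gene(4_000, "g1")], [0, 10_000], classes)
        assert sum(counts["retained"]) == 3
        assert sum(counts["specific"]) == 7

    def test_bins_must_increase(self):
        with pytest.raises(ValueError):
            tss_distance_histogram([], [], bins=[0, 10, 10])


class TestPartnerCounts:
    def test_gene_without_partners_counts_zero(self):
        counts = partner_counts_per_gene([], assign_targets([peak(110_000, "s1")], [gene(100_000, "g1")]))
        assert counts == {"g1": 0}

    def test_counts_equal_brute_force(self):
        rng = np.random.default_rng(27)
        genes = [gene(int(t), f"g{i}") for i, t in enumerate(rng.integers(10_000, 3_000_000, 20))]
        sites = [peak(int(c), f"s{i}") for i, c in enumerate(rng.integers(10_000, 3_000_000, 40))]
        partners = [peak(int(c), f"a{i}") for i, c in enumerate(rng.integers(10_000, 3_000_000, 300))]
        targets = assign_targets(sites, genes)
        counts = partner_counts_per_gene(partners, targets)
        for t in targets:
            expected = sum(1 for p in partners if abs(p.center() - t.gene.tss) <= 100_000)
            assert counts[t.gene.gene_id] == expected

    def test_boosted_anchor_density_separates_shared_from_specific(self, summary):
        """The generator doubles anchor density at shared targets; the
        category means and the Welch test must pick that up."""
        means = summary["anchor_density_by_category"]["means"]
        assert means["directly_shared"] > means["species_specific"]
        assert means["indirectly_shared"] > means["species_specific"]
        p = summary["anchor_density_by_category"]["welch_p"]["species_specific_vs_indirectly_shared"]
        assert p < 0.05
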