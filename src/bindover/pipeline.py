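"""End-to-end analysis: support filter -> liftover -> retention ->
motifs -> conservation -> targets -> expression -> co-occupancy ->
anchor gradient -> enrichment.

The stage driver works on an in-memory bundle (as produced by
:mod:`bindover.synthetic_data` or loaded from files) and returns a
machine-readable summary in which every proportion carries its
numerator, denominator, raw fraction, and half-up-rounded percent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np

from bindover.anchor_turnover import anchor_gradient, build_anchor_records, motif_gain_loss
from bindover.chain_liftover import lift_interval, lift_set, parse_chain
from bindover.conservation import ScoreTrack, annotate_elements, compare_score_distributions, mean_scores
from bindover.expression_response import ExpressionMatrix, call_responsive, category_response_rates
from bindover.genomic_core import read_bed, read_gene_table, standardize
from bindover.motif_scan import ortholog_motif_table, read_meme
from bindover.peak_processing import annotate_cooccupancy, filter_by_support
from bindover.retention_analysis import classify_retention, retention_fraction
from bindover.stats_enrichment import term_enrichment, two_proportion_test
from bindover.target_genes import (
    assign_targets,
    classify_sharing,
    map_orthologs,
    partner_counts_by_category,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Analysis thresholds; defaults follow the pipeline's standard setup."""

    support_distance: int = 500  # bp, center-to-center, heterodimer support
    min_support_enrichment: float = 2.0  # fold
    site_width: int = 1000  # bp, retention comparison width for nomadic sites
    anchor_width: int = 150  # bp, retention comparison width for anchor sites
    lift_pre_extend: int = 1000  # bp, intervals lifted at this width
    min_match: float = 0.1  # liftover minimum remap ratio
    cooccupancy_distance: int = 150  # bp
    max_tss_distance: int = 100_000  # bp
    motif_window: int = 200  # bp
    motif_alpha: float = 1e-4
    fold_threshold: float = 1.5
    site_core_width: int = 150  # bp, conservation scoring interval


def _total_length(genome) -> int:
    keys = genome.keys() if hasattr(genome, "keys") else [r.name for r in genome]
    return sum(len(genome[k]) for k in keys)


def proportion(k: int, n: int) -> dict:
    """A count with its fraction and half-up-rounded percent."""
    frac = k / n if n else None
    return {
        "k": int(k),
        "n": int(n),
        "fraction": frac,
        "percent": int(math.floor(frac * 100 + 0.5)) if frac is not None else None,
    }


def analyze_bundle(bundle, params: AnalysisParams | None = None) -> dict:
    """Run every analysis stage on a bundle; returns the summary document."""
    p = params or AnalysisParams()
    summary: dict = {"params": asdict(p)}

    # 1. heterodimer support filter
    supported = filter_by_support(
        bundle.primary_a, bundle.support_a, p.support_distance, p.min_support_enrichment
    )
    sites = [s.peak for s in supported]
    summary["support_filter"] = proportion(len(sites), len(bundle.primary_a))
    logger.info("support filter: %d of %d primary peaks retained", len(sites), len(bundle.primary_a))

    # 2. liftover of the other species' sites and retention classification
    lifted_b, lift_summary = lift_set(
        bundle.nomadic_b, bundle.chains_b_to_a, min_match=p.min_match, pre_extend=p.lift_pre_extend
    )
    labels = classify_retention(sites, lifted_b, width_a=p.site_width)
    k, n, _ = retention_fraction(labels)
    summary["liftover_b_to_a"] = {**lift_summary, "mapped_fraction": lift_summary["mapped"] / max(1, len(bundle.nomadic_b))}
    summary["retention"] = proportion(k, n)
    logger.info("retention: %d of %d sites retained", k, n)

    # 3. anchor co-occupancy and anchor retention
    coocc = annotate_cooccupancy(sites, bundle.anchor_a, p.cooccupancy_distance)
    n_coocc = sum(1 for f in coocc if f.cooccupied)
    summary["cooccupancy"] = proportion(n_coocc, len(sites))
    lifted_anchor_b, anchor_lift_summary = lift_set(
        bundle.anchor_b, bundle.chains_b_to_a, min_match=p.min_match, pre_extend=p.lift_pre_extend
    )
    anchor_labels = classify_retention(bundle.anchor_a, lifted_anchor_b, width_a=p.anchor_width)
    ak, an, _ = retention_fraction(anchor_labels)
    summary["anchor_retention"] = proportion(ak, an)
    # proportion test: anchor-factor co-occupancy vs the anchor's genome-wide density
    genome_bp = _total_length(bundle.genome_a)
    expected_rate = min(
        1.0, len(bundle.anchor_a) * 2 * p.cooccupancy_distance / max(1, genome_bp)
    )
    z, pz = two_proportion_test(n_coocc, len(sites), int(expected_rate * len(sites)), len(sites))
    summary["cooccupancy_vs_random"] = {"z": z, "p": pz, "expected_rate": expected_rate}

    # 4. motif presence at orthologous loci
    lift_results = {
        s.name: lift_interval(standardize(s, p.lift_pre_extend), bundle.chains_a_to_b, p.min_match)
        for s in sites
    }
    motif_tab = ortholog_motif_table(
        sites, lift_results, bundle.genome_a, bundle.genome_b, bundle.pwms,
        window=p.motif_window, alpha=p.motif_alpha,
    )
    retained_ids = {l.site_id for l in labels if l.label == "retained"}
    summary["motif"] = _motif_summary(motif_tab, retained_ids)

    # 5. conservation
    cores = [standardize(s, p.site_core_width) for s in sites]
    element_flags = annotate_elements(cores, bundle.elements_a)
    summary["conserved_element_overlap"] = proportion(sum(element_flags), len(element_flags))
    retained_flags = [s.name in retained_ids for s in sites]
    n_cons_and_ret = sum(1 for e, r in zip(element_flags, retained_flags) if e and r)
    summary["retained_given_conserved"] = proportion(n_cons_and_ret, max(1, sum(element_flags)))
    cons = mean_scores(cores, bundle.score_track_a)
    scores_ret = [c.mean_score for c, r in zip(cons, retained_flags) if r]
    scores_spec = [c.mean_score for c, r in zip(cons, retained_flags) if not r]
    if len(scores_ret) >= 2 and len(scores_spec) >= 2:
        summary["conservation_scores"] = compare_score_distributions(scores_ret, scores_spec)

    # 6. target genes and sharing categories
    targets_a_raw = assign_targets(sites, bundle.genes_a, p.max_tss_distance)
    targets_b_raw = assign_targets(bundle.nomadic_b, bundle.genes_b, p.max_tss_distance)
    orthologs = map_orthologs(bundle.genes_a, bundle.genes_b, bundle.chains_a_to_b, p.min_match)
    targets = classify_sharing(targets_a_raw, targets_b_raw, labels, orthologs)
    cat_counts = {c: sum(1 for t in targets if t.category == c) for c in
                  ("species_specific", "indirectly_shared", "directly_shared")}
    n_targets = len(targets)
    n_shared = cat_counts["indirectly_shared"] + cat_counts["directly_shared"]
    summary["targets"] = {
        "total": n_targets,
        "counts": cat_counts,
        "shared": proportion(n_shared, n_targets),
        "direct_of_shared": proportion(cat_counts["directly_shared"], max(1, n_shared)),
        "indirect_of_shared": proportion(cat_counts["indirectly_shared"], max(1, n_shared)),
    }

    # 7. expression responsiveness by category
    responsive, _ratios = call_responsive(bundle.expression, p.fold_threshold, "up")
    rates = category_response_rates(targets, responsive)
    summary["responsiveness"] = {
        "n_responsive": len(responsive),
        "categories": rates["categories"],
        "fisher_p": {f"{a}_vs_{b}": v for (a, b), v in rates["fisher_p"].items()},
    }

    # 8. anchor gradient and motif turnover attribution
    records = build_anchor_records(sites, coocc, anchor_labels, labels, targets, motif_tab)
    gradient = anchor_gradient(records)
    summary["anchor_gradient"] = {
        "strata": gradient["strata"],
        "fisher_p": {f"{a}_vs_{b}": v for (a, b), v in gradient["fisher_p"].items()},
        "strictly_decreasing": gradient["strictly_decreasing"],
    }
    gainloss = motif_gain_loss(records)
    summary["motif_turnover"] = {key: val for key, val in gainloss.items() if key != "cells"}

    # 9. partner-site density by category
    pc = partner_counts_by_category(bundle.anchor_a, targets, p.max_tss_distance)
    summary["anchor_density_by_category"] = {
        "means": pc["means"],
        "welch_p": {f"{a}_vs_{b}": v["p"] for (a, b), v in pc["tests"].items()},
    }

    # 10. term enrichment of shared targets
    background = {t.gene.symbol for t in targets} | set(bundle.terms)
    shared_genes = {t.gene.symbol for t in targets if t.category != "species_specific"}
    if shared_genes:
        rows = term_enrichment(shared_genes, bundle.terms, background)
        summary["term_enrichment"] = [
            {"term": r.term, "observed": r.observed, "expected": round(r.expected, 3),
             "fold": round(r.fold, 3), "p": r.p}
            for r in rows[:10]
        ]
    summary["_objects"] = {
        "sites": sites,
        "labels": labels,
        "anchor_labels": anchor_labels,
        "targets": targets,
        "records": records,
        "motif_table": motif_tab,
        "responsive": responsive,
        "cooccupancy": coocc,
    }
    return summary


def _motif_summary(motif_tab, retained_ids: set[str]) -> dict:
    present_a = motif_tab["nomadic_a"].astype(bool)
    mapped = motif_tab["lift_status"] == "mapped"
    summary = {"present_a": proportion(int(present_a.sum()), len(motif_tab))}
    is_ret = motif_tab["site_id"].isin(retained_ids)
    for label, mask in (("retained", is_ret), ("species_specific", ~is_ret)):
        sub = motif_tab[mask & mapped]
        if len(sub):
            present_b = sub["nomadic_b"].astype(bool)
            summary[f"present_b_{label}"] = proportion(int(present_b.sum()), len(sub))
            with_a = sub[sub["nomadic_a"].astype(bool)]
            if len(with_a):
                summary[f"present_b_given_a_{label}"] = proportion(
                    int(with_a["nomadic_b"].astype(bool).sum()), len(with_a)
                )
    # concordance: same presence call in both species among mapped sites
    sub = motif_tab[mapped]
    if len(sub):
        agree = (sub["nomadic_a"].astype(bool) == sub["nomadic_b"].astype(bool)).sum()
        summary["concordance"] = proportion(int(agree), len(sub))
    return summary


# ---------------------------------------------------------------------------
# file-based entry point
# ---------------------------------------------------------------------------


@dataclass
class FileBundle:
    """The analyze_bundle input surface, loaded from files on disk."""

    genome_a: dict
    genome_b: dict
    chains_a_to_b: list
    chains_b_to_a: list
    genes_a: list
    genes_b: list
    primary_a: list
    support_a: list
    nomadic_b: list
    anchor_a: list
    anchor_b: list
    elements_a: list
    score_track_a: ScoreTrack
    expression: ExpressionMatrix
    terms: dict
    pwms: dict


def load_bundle(indir) -> FileBundle:
    """Load a bundle directory written by ``SimulationBundle.write``."""
    import os

    from pyfaidx import Fasta

    def p(name: str) -> str:
        return os.path.join(indir, name)

    cols = {"enrichment": 4, "significance": 6}
    terms: dict[str, list[str]] = {}
    with open(p("terms.tsv")) as fh:
        for line in fh:
            gene, term = line.rstrip("\n").split("\t")
            terms.setdefault(gene, []).append(term)
    pwm_list = read_meme(p("motifs.meme"))
    pwms = {"nomadic": pwm_list[0], "anchor": pwm_list[1]}
    return FileBundle(
        genome_a=Fasta(p("genome_a.fa")),
        genome_b=Fasta(p("genome_b.fa")),
        chains_a_to_b=parse_chain(p("a_to_b.chain")),
        chains_b_to_a=parse_chain(p("b_to_a.chain")),
        genes_a=read_gene_table(p("genes_a.tsv")),
        genes_b=read_gene_table(p("genes_b.tsv")),
        primary_a=read_bed(p("nomadic_primary_a.bed"), cols),
        support_a=read_bed(p("nomadic_support_a.bed"), cols),
        nomadic_b=read_bed(p("nomadic_b.bed"), cols),
        anchor_a=read_bed(p("anchor_a.bed"), cols),
        anchor_b=read_bed(p("anchor_b.bed"), cols),
        elements_a=[r.interval for r in read_bed(p("elements_a.bed"), {})],
        score_track_a=ScoreTrack.from_tsv(p("scores_a.tsv")),
        expression=ExpressionMatrix.from_tsv(p("expression.tsv"), p("samples.tsv"), p("probe_map.tsv")),
        terms=terms,
        pwms=pwms,
    )


def summary_to_json(summary: dict, path) -> None:
    """Serialize a summary, dropping the in-memory object cache."""
    clean = {k: v for k, v in summary.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def run_pipeline(indir, outdir, params: AnalysisParams | None = None) -> dict:
    """Load a bundle directory, analyze it, and write the summary files."""
    import os

    bundle = load_bundle(indir)
    summary = analyze_bundle(bundle, params)
    os.makedirs(outdir, exist_ok=True)
    summary_to_json(summary, os.path.join(outdir, "summary.json"))
    objs = summary["_objects"]
    with open(os.path.join(outdir, "retention_labels.tsv"), "w") as fh:
        fh.write("site_id\tlabel\tpartner_site\n")
        for l in objs["labels"]:
            fh.write(f"{l.site_id}\t{l.label}\t{l.partner_site or ''}\n")
    with open(os.path.join(outdir, "targets.tsv"), "w") as fh:
        fh.write("gene_id\tsymbol\tcategory\tortholog\tmin_tss_distance\tsites\n")
        for t in objs["targets"]:
            fh.write(
                f"{t.gene.gene_id}\t{t.gene.symbol}\t{t.category}\t{t.ortholog_gene or ''}"
                f"\t{t.min_tss_distance}\t{','.join(t.sites)}\n"
            )
    objs["motif_table"].to_csv(os.path.join(outdir, "motif_table.tsv"), sep="\t", index=False)
    return summary
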