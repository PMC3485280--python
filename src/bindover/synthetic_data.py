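"""Paired-genome simulator with full ground truth.

Generates two genomes related by block-wise orthology (genome B is
genome A with blocks deleted and short segments inserted, recorded
exactly in a chain file), plants binding sites for a "nomadic"
receptor-like factor and an "anchor" lineage-factor, seeds their
motifs into the sequence, and emits every input the analysis pipeline
consumes: peak tables, tag libraries, gene annotations, conserved
elements and per-base conservation scores, an expression time course,
and a term-annotation map — alongside the ground truth of every
planted label.

Layout: genes live in well-separated neighborhood "cores" (100 kb of
genes and sites followed by a >=150 kb gene-free buffer), so that the
100-kb TSS targeting rule cannot leak sharing categories between
neighborhoods; all genes of one core share a planted category. Binding
sites, their co-binding anchors, decoy peaks and standalone anchors
are placed on a 1.2-kb lattice, which keeps every planted distance
relation (co-occupancy within 150 bp, retention overlap within 1 kb,
support within 500 bp) exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bindover.chain_liftover import ChainAlignment, ChainBlock, ChainSide
from bindover.conservation import ScoreTrack
from bindover.expression_response import ExpressionMatrix
from bindover.genomic_core import GeneAnnotation, GenomicInterval, PeakRecord, write_bed, write_gene_table
from bindover.motif_scan import BASES, PWM, write_meme

CORE_SPACING = 250_000
CORE_WIDTH = 100_000
CORE_OFFSET = (CORE_SPACING - CORE_WIDTH) // 2  # core start within its slot
FEATURE_BAND = (10_000, 90_000)  # site/anchor band, relative to core start
CELL = 1_200  # feature lattice pitch; keeps retention/co-occupancy radii exact
SAFE_MARGIN = 800  # distance a liftable feature keeps from block edges

CATEGORY_ORDER = ("directly_shared", "indirectly_shared", "species_specific", "nontarget")

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_pwms() -> dict[str, PWM]:
    """Sharp PWMs for the two planted factors.

    The nomadic motif is a direct-repeat nuclear-receptor element
    (DR1-like, 13 bp); the anchor motif is an ETS-family purine-rich
    core (10 bp). 90% consensus weight per position.
    """

    def sharp(consensus: str) -> np.ndarray:
        counts = np.full((len(consensus), 4), 2 / 3)
        for j, base in enumerate(consensus):
            counts[j, BASES.index(base)] = 18.0
        return counts

    return {
        "nomadic": PWM("nomadic_dr1", sharp("AGGTCAAAGGTCA")),
        "anchor": PWM("anchor_ets", sharp("AAAGAGGAAGTG")),
    }


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the seed fully determines the output."""

    seed: int = 0
    n_chroms: int = 2
    genome_length_per_chrom: int = 2_000_000
    block_length_mean: int = 10_000
    block_loss_rate: float = 0.2
    insertion_prob: float = 0.08
    n_genes: int = 300
    genes_per_core: int = 20
    gene_span: int = 2_000
    n_anchor_sites: int = 2_000
    anchor_retention_prob: float = 0.19
    anchor_shared_boost: float = 2.0
    n_nomadic_sites: int = 400
    nomadic_retention_prob: float = 0.05
    anchor_cooccupancy_prob: float = 0.6
    anchor_retention_by_stratum: dict = field(
        default_factory=lambda: {
            "retained": 0.85,
            "indirectly_shared": 0.41,
            "species_specific": 0.25,
        }
    )
    motif_plant_prob: float = 0.6
    motif_mutation_rate: float = 0.63
    gene_category_counts: dict | None = None  # category -> gene count; default derived
    stratum_site_counts: tuple | None = None  # (retained, indirect, specific) site counts
    comps_per_indirect_core: int = 2
    n_decoy_sites: int | None = None  # default: n_nomadic_sites
    gc_content: float = 0.5
    tags_per_site: int = 20
    n_background_tags: int = 2_000
    conserved_element_prob: dict = field(
        default_factory=lambda: {"retained": 0.75, "species_specific": 0.38}
    )
    conservation_mean: dict = field(
        default_factory=lambda: {"retained": 0.6, "species_specific": 0.4}
    )
    n_background_elements: int = 150
    responsive_prob_by_category: dict = field(
        default_factory=lambda: {
            "directly_shared": 0.33,
            "indirectly_shared": 0.17,
            "species_specific": 0.11,
            "nontarget": 0.05,
        }
    )
    expression_noise_sd: float = 0.1
    responsive_effect_log2: float = 1.0
    n_replicates: int = 3
    timepoints: tuple = (0.5, 1.5, 3.0, 8.0, 12.0)
    pwms: dict | None = None

    def validate(self) -> None:
        probs = [
            self.block_loss_rate,
            self.insertion_prob,
            self.anchor_retention_prob,
            self.nomadic_retention_prob,
            self.anchor_cooccupancy_prob,
            self.motif_plant_prob,
            self.motif_mutation_rate,
            self.gc_content,
            *self.anchor_retention_by_stratum.values(),
            *self.responsive_prob_by_category.values(),
            *self.conserved_element_prob.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.n_chroms, self.genome_length_per_chrom, self.n_genes, self.n_nomadic_sites) <= 0:
            raise ValueError("counts and lengths must be positive")

    def category_counts(self) -> dict[str, int]:
        if self.gene_category_counts is not None:
            counts = dict(self.gene_category_counts)
            for cat in CATEGORY_ORDER:
                counts.setdefault(cat, 0)
            return counts
        # default proportions: 20% non-target; targets split like a
        # strongly species-specific landscape (~79/15/6)
        n_targets = int(round(0.8 * self.n_genes))
        direct = max(1, int(round(0.0583 * n_targets)))
        indirect = max(1, int(round(0.155 * n_targets)))
        specific = n_targets - direct - indirect
        return {
            "directly_shared": direct,
            "indirectly_shared": indirect,
            "species_specific": specific,
            "nontarget": self.n_genes - n_targets,
        }


# ---------------------------------------------------------------------------
# internal genome scaffolding
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    a_start: int
    a_end: int
    deleted: bool
    b_start: int = -1  # filled during B assembly (kept blocks only)
    insertion_after: int = 0


@dataclass
class _Core:
    core_id: int
    chrom_idx: int
    start: int  # genome-A coordinate of core start
    category: str = "unused"
    gene_ids: list = field(default_factory=list)


@dataclass
class _Cell:
    chrom_idx: int
    pos: int
    safe: bool
    core_id: int | None  # set when inside a core's feature band
    used: bool = False


class _ChromScaffold:
    """Blocks, cores, cells and the A->B coordinate map of one chromosome."""

    def __init__(self, name: str, length: int):
        self.name = name
        self.a_len = length
        self.b_len = 0
        self.blocks: list[_Block] = []
        self.kept_a_starts: np.ndarray | None = None
        self.kept_a_ends: np.ndarray | None = None
        self.kept_b_starts: np.ndarray | None = None

    def finalize_map(self) -> None:
        kept = [b for b in self.blocks if not b.deleted]
        self.kept_a_starts = np.array([b.a_start for b in kept], dtype=np.int64)
        self.kept_a_ends = np.array([b.a_end for b in kept], dtype=np.int64)
        self.kept_b_starts = np.array([b.b_start for b in kept], dtype=np.int64)

    def map_a_to_b(self, pos: int) -> int | None:
        idx = int(np.searchsorted(self.kept_a_starts, pos, side="right")) - 1
        if idx < 0 or pos >= self.kept_a_ends[idx]:
            return None
        return int(self.kept_b_starts[idx] + (pos - self.kept_a_starts[idx]))


def _partition_blocks(rng, length: int, mean: int) -> list[_Block]:
    blocks, pos = [], 0
    while pos < length:
        size = int(np.clip(rng.exponential(mean), 1_000, 5 * mean))
        end = min(pos + size, length)
        blocks.append(_Block(pos, end, deleted=False))
        pos = end
    return blocks


def _mark_deletions(rng, blocks: list[_Block], loss_rate: float) -> None:
    for b in blocks:
        b.deleted = bool(rng.random() < loss_rate)


def _repair_region(blocks: list[_Block], start: int, end: int, min_kept: int) -> None:
    """Un-delete blocks until the region keeps at least ``min_kept`` bases."""

    def kept() -> int:
        return sum(
            max(0, min(b.a_end, end) - max(b.a_start, start))
            for b in blocks
            if not b.deleted
        )

    if kept() >= min_kept:
        return
    candidates = [
        b
        for b in blocks
        if b.deleted and min(b.a_end, end) - max(b.a_start, start) > 0
    ]
    candidates.sort(key=lambda b: -(min(b.a_end, end) - max(b.a_start, start)))
    for b in candidates:
        b.deleted = False
        if kept() >= min_kept:
            return
    if kept() < min_kept:
        raise ValueError("cannot guarantee enough orthologous sequence in a region")


def _build_cells(scaffold: _ChromScaffold, chrom_idx: int, cores: Sequence[_Core]) -> list[_Cell]:
    core_by_range = [
        (c.start + FEATURE_BAND[0], c.start + FEATURE_BAND[1], c.core_id)
        for c in cores
        if c.chrom_idx == chrom_idx
    ]
    starts = np.array([b.a_start for b in scaffold.blocks])
    cells = []
    for pos in range(CELL // 2, scaffold.a_len - CELL // 2, CELL):
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        block = scaffold.blocks[idx]
        safe = (
            not block.deleted
            and block.a_start + SAFE_MARGIN <= pos
            and pos + SAFE_MARGIN <= block.a_end
        )
        core_id = None
        for lo, hi, cid in core_by_range:
            if lo <= pos < hi:
                core_id = cid
                break
        cells.append(_Cell(chrom_idx, pos, safe, core_id))
    return cells


class _CellPools:
    """Deterministic random allocation of lattice cells.

    Cells are bucketed once (per-core safe cells; shared-core vs other
    cells, safe and any) and each bucket shuffled; allocation pops from
    the end, skipping cells already taken through another bucket.
    """

    def __init__(self, rng, cells: Sequence[_Cell], shared_core_ids: set[int]):
        self.rng = rng
        self.buckets: dict = {}

        def bucket(key, members):
            members = list(members)
            rng.shuffle(members)
            self.buckets[key] = members

        core_ids = {c.core_id for c in cells if c.core_id is not None}
        for cid in core_ids:
            bucket(("core", cid), (c for c in cells if c.core_id == cid and c.safe))
        in_shared = lambda c: c.core_id in shared_core_ids
        bucket("shared_safe", (c for c in cells if in_shared(c) and c.safe))
        bucket("shared_any", (c for c in cells if in_shared(c)))
        bucket("other_safe", (c for c in cells if not in_shared(c) and c.safe))
        bucket("other_any", (c for c in cells if not in_shared(c)))
        bucket("all_any", cells)

    def free(self, key) -> int:
        # upper bound (stale cells are skipped at pop time); good enough
        # to weight placement choices
        return len(self.buckets[key])

    def pop(self, key) -> _Cell:
        stack = self.buckets[key]
        while stack:
            cell = stack.pop()
            if not cell.used:
                cell.used = True
                return cell
        raise ValueError(f"feature placement infeasible: bucket {key!r} exhausted")


# ---------------------------------------------------------------------------
# bundle containers
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    sites: pd.DataFrame  # one row per planted feature
    genes: pd.DataFrame  # one row per gene


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    chains_a_to_b: list[ChainAlignment]
    chains_b_to_a: list[ChainAlignment]
    genes_a: list[GeneAnnotation]
    genes_b: list[GeneAnnotation]
    primary_a: list[PeakRecord]  # real nomadic peaks + decoys, shuffled
    support_a: list[PeakRecord]
    nomadic_b: list[PeakRecord]
    anchor_a: list[PeakRecord]
    anchor_b: list[PeakRecord]
    tags_a: list[GenomicInterval]
    tags_b: list[GenomicInterval]
    elements_a: list[GenomicInterval]
    score_track_a: ScoreTrack
    score_rows_a: list[tuple]
    expression: ExpressionMatrix
    terms: dict[str, list[str]]
    pwms: dict[str, PWM]
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Materialize the bundle as plain-text files; returns a manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)

        def p(name: str) -> str:
            return os.path.join(outdir, name)

        from bindover.chain_liftover import write_chain

        _write_fasta(p("genome_a.fa"), self.genome_a)
        _write_fasta(p("genome_b.fa"), self.genome_b)
        write_chain(p("a_to_b.chain"), self.chains_a_to_b)
        write_chain(p("b_to_a.chain"), self.chains_b_to_a)
        write_gene_table(p("genes_a.tsv"), self.genes_a)
        write_gene_table(p("genes_b.tsv"), self.genes_b)
        cols = {"enrichment": 4, "significance": 6}
        write_bed(p("nomadic_primary_a.bed"), self.primary_a, cols)
        write_bed(p("nomadic_support_a.bed"), self.support_a, cols)
        write_bed(p("nomadic_b.bed"), self.nomadic_b, cols)
        write_bed(p("anchor_a.bed"), self.anchor_a, cols)
        write_bed(p("anchor_b.bed"), self.anchor_b, cols)
        _write_intervals(p("tags_a.bed"), self.tags_a)
        _write_intervals(p("tags_b.bed"), self.tags_b)
        _write_intervals(p("elements_a.bed"), self.elements_a)
        with open(p("scores_a.tsv"), "w") as fh:
            for chrom, pos, score in self.score_rows_a:
                fh.write(f"{chrom}\t{pos}\t{score:.4f}\n")
        self.expression.values.to_csv(p("expression.tsv"), sep="\t")
        self.expression.samples.to_csv(p("samples.tsv"), sep="\t")
        with open(p("probe_map.tsv"), "w") as fh:
            for probe, gene in self.expression.probe_map.items():
                fh.write(f"{probe}\t{gene}\n")
        with open(p("terms.tsv"), "w") as fh:
            for gene, terms in self.terms.items():
                for term in terms:
                    fh.write(f"{gene}\t{term}\n")
        write_meme(p("motifs.meme"), list(self.pwms.values()))
        self.truth.sites.to_csv(p("truth_sites.tsv"), sep="\t", index=False)
        self.truth.genes.to_csv(p("truth_genes.tsv"), sep="\t", index=False)
        return {"outdir": str(outdir)}


def _write_fasta(path, genome: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_intervals(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate a complete, internally consistent input bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pwms = config.pwms or default_pwms()
    nomadic_pwm, anchor_pwm = pwms["nomadic"], pwms["anchor"]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    # --- geometry: cores and gene-category allocation --------------------
    cores_per_chrom = config.genome_length_per_chrom // CORE_SPACING
    all_cores: list[_Core] = []
    for ci in range(config.n_chroms):
        for slot in range(cores_per_chrom):
            all_cores.append(
                _Core(len(all_cores), ci, slot * CORE_SPACING + CORE_OFFSET)
            )
    counts = config.category_counts()
    cores_needed = {
        cat: math.ceil(counts[cat] / config.genes_per_core) if counts[cat] else 0
        for cat in CATEGORY_ORDER
    }
    if sum(cores_needed.values()) > len(all_cores):
        raise ValueError(
            f"need {sum(cores_needed.values())} gene neighborhoods for "
            f"{sum(counts.values())} genes but the genome only fits {len(all_cores)}"
        )
    core_iter = iter(all_cores)
    cores_by_cat: dict[str, list[_Core]] = {cat: [] for cat in CATEGORY_ORDER}
    for cat in CATEGORY_ORDER:
        for _ in range(cores_needed[cat]):
            core = next(core_iter)
            core.category = cat
            cores_by_cat[cat].append(core)

    # --- genome A sequence and block structure ---------------------------
    base_probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    seq_a = [
        rng.choice(4, size=config.genome_length_per_chrom, p=base_probs).astype(np.uint8)
        for _ in range(config.n_chroms)
    ]
    scaffolds = []
    for ci, name in enumerate(chrom_names):
        sc = _ChromScaffold(name, config.genome_length_per_chrom)
        sc.blocks = _partition_blocks(rng, sc.a_len, config.block_length_mean)
        _mark_deletions(rng, sc.blocks, config.block_loss_rate)
        chrom_cores = [c for c in all_cores if c.chrom_idx == ci and c.category != "unused"]
        for core in chrom_cores:
            _repair_region(
                sc.blocks, core.start + FEATURE_BAND[0], core.start + FEATURE_BAND[1], 70_000
            )
        chrom_cores_sorted = sorted(chrom_cores, key=lambda c: c.start)
        for c1, c2 in zip(chrom_cores_sorted, chrom_cores_sorted[1:]):
            _repair_region(sc.blocks, c1.start + CORE_WIDTH, c2.start, 110_000)
        scaffolds.append(sc)

    shared_core_ids = {
        c.core_id for c in cores_by_cat["directly_shared"] + cores_by_cat["indirectly_shared"]
    }
    cells: list[_Cell] = []
    for ci, sc in enumerate(scaffolds):
        cells.extend(_build_cells(sc, ci, all_cores))
    pools = _CellPools(rng, cells, shared_core_ids)

    # --- genes ------------------------------------------------------------
    genes_a: list[GeneAnnotation] = []
    gene_meta: list[dict] = []
    gene_counter = 0
    for cat in CATEGORY_ORDER:
        n_cat, cat_cores = counts[cat], cores_by_cat[cat]
        if n_cat == 0:
            continue
        base, rem = divmod(n_cat, len(cat_cores))
        for k, core in enumerate(cat_cores):
            n_here = base + (1 if k < rem else 0)
            sc = scaffolds[core.chrom_idx]
            segments = [
                (max(b.a_start, core.start) + 100, min(b.a_end, core.start + CORE_WIDTH) - 100)
                for b in sc.blocks
                if not b.deleted
                and min(b.a_end, core.start + CORE_WIDTH) - max(b.a_start, core.start) > config.gene_span + 200
            ]
            total = sum(e - s for s, e in segments)
            if total < n_here * (config.gene_span + 200):
                raise ValueError("not enough orthologous sequence for genes in a neighborhood")
            for g in range(n_here):
                # even spacing in "retained" coordinate space avoids overlap
                offset = int((g + 0.5) / n_here * total) - config.gene_span // 2
                offset = max(0, min(offset, total - config.gene_span - 1))
                for s, e in segments:
                    if offset < (e - s):
                        start = s + min(offset, e - s - config.gene_span - 1)
                        break
                    offset -= e - s
                strand = "+" if rng.random() < 0.5 else "-"
                gene_id = f"g{gene_counter:05d}"
                gene_counter += 1
                iv = GenomicInterval(sc.name, start, start + config.gene_span, strand=strand, name=gene_id)
                genes_a.append(GeneAnnotation(gene_id, f"GENE{gene_counter:05d}", iv))
                core.gene_ids.append(gene_id)
                gene_meta.append(
                    {"gene": genes_a[-1], "category": cat, "core_id": core.core_id, "chrom_idx": core.chrom_idx}
                )

    # --- nomadic site allocation -----------------------------------------
    n_direct_cores = len(cores_by_cat["directly_shared"])
    n_indirect_cores = len(cores_by_cat["indirectly_shared"])
    n_specific_cores = len(cores_by_cat["species_specific"])
    if config.stratum_site_counts is not None:
        n_ret, n_ind, n_spec = config.stratum_site_counts
        if n_ret + n_ind + n_spec != config.n_nomadic_sites:
            raise ValueError("stratum_site_counts must sum to n_nomadic_sites")
    else:
        # exact-count planting: the realized rate equals the parameter up
        # to rounding, so recovery tests measure the pipeline, not the draw
        n_ret = int(round(config.n_nomadic_sites * config.nomadic_retention_prob))
        n_ret = max(n_ret, n_direct_cores) if n_direct_cores else 0
        rest = config.n_nomadic_sites - n_ret
        denom = max(1, n_indirect_cores + n_specific_cores)
        n_ind = max(n_indirect_cores, int(round(rest * n_indirect_cores / denom)))
        n_spec = rest - n_ind
    if (n_ret and not n_direct_cores) or (n_ind and not n_indirect_cores) or (n_spec and not n_specific_cores):
        raise ValueError("site counts require neighborhoods of the matching category")
    for n_cat, n_cores_cat, label in (
        (n_ret, n_direct_cores, "directly shared"),
        (n_ind, n_indirect_cores, "indirectly shared"),
        (n_spec, n_specific_cores, "species-specific"),
    ):
        if n_cores_cat and n_cat < n_cores_cat:
            raise ValueError(
                f"{label} neighborhoods outnumber their sites ({n_cat} sites, "
                f"{n_cores_cat} neighborhoods); every target neighborhood needs a site"
            )

    def spread(n: int, cores_list: list[_Core]) -> list[tuple[_Core, int]]:
        if not cores_list or n == 0:
            return []
        base, rem = divmod(n, len(cores_list))
        return [(c, base + (1 if i < rem else 0)) for i, c in enumerate(cores_list)]

    site_rows: list[dict] = []
    site_counter = 0

    def place_site(core: _Core, retained: bool, stratum: str) -> dict:
        nonlocal site_counter
        cell = pools.pop(("core", core.core_id))
        site_id = f"site_{site_counter:05d}"
        site_counter += 1
        row = {
            "site_id": site_id,
            "factor": "nomadic",
            "kind": "site",
            "chrom_idx": cell.chrom_idx,
            "center_a": cell.pos,
            "retained": retained,
            "stratum": stratum,
            "category": core.category,
            "core_id": core.core_id,
            "cooccupied": False,
            "anchor_id": None,
            "anchor_retained": None,
            "motif_a": False,  # assigned by exact count below
            "motif_b": None,
        }
        site_rows.append(row)
        return row

    for core, n_here in spread(n_ret, cores_by_cat["directly_shared"]):
        for _ in range(n_here):
            place_site(core, True, "retained")
    for core, n_here in spread(n_ind, cores_by_cat["indirectly_shared"]):
        for _ in range(n_here):
            place_site(core, False, "indirectly_shared")
    for core, n_here in spread(n_spec, cores_by_cat["species_specific"]):
        for _ in range(n_here):
            place_site(core, False, "species_specific")

    # compensatory B-only sites make indirect-core genes targets in B
    comp_rows: list[dict] = []
    for core in cores_by_cat["indirectly_shared"]:
        for k in range(config.comps_per_indirect_core):
            cell = pools.pop(("core", core.core_id))
            comp_rows.append(
                {
                    "site_id": f"comp_{core.core_id:03d}_{k}",
                    "factor": "nomadic",
                    "kind": "compensatory",
                    "chrom_idx": cell.chrom_idx,
                    "center_a": cell.pos,
                    "retained": False,
                    "stratum": None,
                    "category": core.category,
                    "core_id": core.core_id,
                    "cooccupied": False,
                    "anchor_id": None,
                    "anchor_retained": None,
                    "motif_a": False,  # motif exists in genome B only
                    "motif_b": True,
                }
            )

    # plant the motif at an exact fraction of sites; fate in B: retained
    # sites keep it, species-specific sites lose it at the mutation rate
    # (again as an exact count)
    for group in (
        [r for r in site_rows if r["retained"]],
        [r for r in site_rows if not r["retained"]],
    ):
        k_motif = int(round(config.motif_plant_prob * len(group)))
        for i in rng.permutation(len(group))[:k_motif]:
            group[int(i)]["motif_a"] = True
    for row in site_rows:
        row["motif_b"] = bool(row["motif_a"] and row["retained"])
    mutable = [r for r in site_rows if r["motif_a"] and not r["retained"]]
    k_survive = int(round((1 - config.motif_mutation_rate) * len(mutable)))
    for j, idx in enumerate(rng.permutation(len(mutable))):
        if j < k_survive:
            mutable[int(idx)]["motif_b"] = True

    # --- anchors ----------------------------------------------------------
    anchor_rows: list[dict] = []
    anchor_counter = 0

    def new_anchor_id() -> str:
        nonlocal anchor_counter
        anchor_counter += 1
        return f"anchor_{anchor_counter:05d}"

    # co-binding anchors next to an exact fraction of nomadic sites; per
    # stratum, an exact fraction of those anchors is retained
    k_coocc = int(round(config.anchor_cooccupancy_prob * len(site_rows)))
    coocc_idx = sorted(int(i) for i in rng.permutation(len(site_rows))[:k_coocc])
    chosen = [site_rows[i] for i in coocc_idx]
    by_stratum: dict[str, list[dict]] = {}
    for row in chosen:
        by_stratum.setdefault(row["stratum"], []).append(row)
    anchor_retained_for: dict[str, bool] = {}
    for stratum, rows_s in by_stratum.items():
        p_ret = config.anchor_retention_by_stratum.get(stratum, config.anchor_retention_prob)
        k_ret_s = int(round(p_ret * len(rows_s)))
        for j, idx in enumerate(rng.permutation(len(rows_s))):
            anchor_retained_for[rows_s[int(idx)]["site_id"]] = j < k_ret_s
    for row in chosen:
        retained = anchor_retained_for[row["site_id"]]
        delta = int(rng.integers(20, 101)) * (1 if rng.random() < 0.5 else -1)
        aid = new_anchor_id()
        row["cooccupied"] = True
        row["anchor_id"] = aid
        row["anchor_retained"] = retained
        anchor_rows.append(
            {
                "site_id": aid,
                "factor": "anchor",
                "kind": "anchor",
                "chrom_idx": row["chrom_idx"],
                "center_a": row["center_a"] + delta,
                "retained": retained,
                "stratum": row["stratum"],
                "category": row["category"],
                "core_id": row["core_id"],
                "cooccupied": True,
                "anchor_id": None,
                "anchor_retained": None,
                "motif_a": True,
                "motif_b": None,  # assigned by exact count below
            }
        )
    n_coocc = len(anchor_rows)
    n_standalone = config.n_anchor_sites - n_coocc
    if n_standalone < 0:
        raise ValueError("n_anchor_sites too small for the drawn co-occupancy count")

    def pick_standalone_cell(retained: bool) -> _Cell:
        suffix = "safe" if retained else "any"
        free_shared = pools.free(f"shared_{suffix}")
        free_other = pools.free(f"other_{suffix}")
        w_shared = config.anchor_shared_boost * free_shared
        go_shared = free_shared > 0 and rng.random() < w_shared / max(w_shared + free_other, 1e-9)
        first, second = ("shared", "other") if go_shared else ("other", "shared")
        try:
            return pools.pop(f"{first}_{suffix}")
        except ValueError:
            return pools.pop(f"{second}_{suffix}")

    k_standalone_ret = int(round(config.anchor_retention_prob * n_standalone))
    standalone_flags = rng.permutation(n_standalone) < k_standalone_ret
    for retained in standalone_flags:
        retained = bool(retained)
        cell = pick_standalone_cell(retained)
        retained = retained and cell.safe  # a deleted locus cannot retain binding
        anchor_rows.append(
            {
                "site_id": new_anchor_id(),
                "factor": "anchor",
                "kind": "anchor",
                "chrom_idx": cell.chrom_idx,
                "center_a": cell.pos,
                "retained": retained,
                "stratum": None,
                "category": None,
                "core_id": cell.core_id,
                "cooccupied": False,
                "anchor_id": None,
                "anchor_retained": None,
                "motif_a": True,
                "motif_b": None,
            }
        )

    # anchor motif fate in B: retained anchors keep it; an exact fraction
    # of the non-retained ones escape motif destruction
    non_ret_anchors = [r for r in anchor_rows if not r["retained"]]
    for r in anchor_rows:
        r["motif_b"] = bool(r["retained"])
    k_anchor_survive = int(round((1 - config.motif_mutation_rate) * len(non_ret_anchors)))
    for j, idx in enumerate(rng.permutation(len(non_ret_anchors))):
        if j < k_anchor_survive:
            non_ret_anchors[int(idx)]["motif_b"] = True

    # decoy primary peaks without partner-factor support
    n_decoys = config.n_decoy_sites if config.n_decoy_sites is not None else config.n_nomadic_sites
    decoy_rows = []
    for k in range(n_decoys):
        cell = pools.pop("all_any")
        decoy_rows.append(
            {
                "site_id": f"decoy_{k:05d}",
                "factor": "nomadic",
                "kind": "decoy",
                "chrom_idx": cell.chrom_idx,
                "center_a": cell.pos,
                "retained": False,
                "stratum": None,
                "category": None,
                "core_id": cell.core_id,
                "cooccupied": False,
                "anchor_id": None,
                "anchor_retained": None,
                "motif_a": False,
                "motif_b": False,
            }
        )

    # --- plant motifs in genome A ----------------------------------------
    def plant(chrom_idx: int, center: int, pwm: PWM) -> None:
        cons = pwm.consensus()
        start = center - len(cons) // 2
        codes = np.array([BASES.index(b) for b in cons], dtype=np.uint8)
        seq_a[chrom_idx][start : start + len(cons)] = codes

    for row in site_rows:
        if row["motif_a"]:
            plant(row["chrom_idx"], row["center_a"], nomadic_pwm)
    for row in anchor_rows:
        plant(row["chrom_idx"], row["center_a"], anchor_pwm)

    # --- assemble genome B, chains, coordinate maps ----------------------
    chains_a_to_b: list[ChainAlignment] = []
    seq_b: list[np.ndarray] = []
    for ci, sc in enumerate(scaffolds):
        kept = [b for b in sc.blocks if not b.deleted]
        pieces, b_pos = [], 0
        for i, block in enumerate(kept):
            block.b_start = b_pos
            pieces.append(seq_a[ci][block.a_start : block.a_end].copy())
            b_pos += block.a_end - block.a_start
            if i < len(kept) - 1 and rng.random() < config.insertion_prob:
                ins_len = 50 + int(rng.exponential(200))
                ins_len = min(ins_len, 500)
                pieces.append(rng.choice(4, size=ins_len, p=base_probs).astype(np.uint8))
                block.insertion_after = ins_len
                b_pos += ins_len
        sc.b_len = b_pos
        seq_b.append(np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8))
        sc.finalize_map()

        # chain blocks: kept segments with dt = deleted gap, dq = insertion
        chain_blocks = []
        for i, block in enumerate(kept):
            if i < len(kept) - 1:
                dt = kept[i + 1].a_start - block.a_end
                dq = block.insertion_after
            else:
                dt = dq = 0
            chain_blocks.append(ChainBlock(block.a_end - block.a_start, dt, dq))
        merged: list[ChainBlock] = []
        for blk in chain_blocks:
            if merged and merged[-1].dt == 0 and merged[-1].dq == 0:
                merged[-1] = ChainBlock(merged[-1].size + blk.size, blk.dt, blk.dq)
            else:
                merged.append(blk)
        if merged:
            t_start, t_end = kept[0].a_start, kept[-1].a_end
            q_start = kept[0].b_start
            q_end = kept[-1].b_start + (kept[-1].a_end - kept[-1].a_start)
            chains_a_to_b.append(
                ChainAlignment(
                    score=1_000 + t_end - t_start,
                    target=ChainSide(sc.name, sc.a_len, "+", t_start, t_end),
                    query=ChainSide(sc.name, sc.b_len, "+", q_start, q_end),
                    blocks=tuple(merged),
                    chain_id=ci + 1,
                )
            )
    from bindover.chain_liftover import invert_chain

    chains_b_to_a = [invert_chain(c) for c in chains_a_to_b]

    # --- apply B-side sequence edits -------------------------------------
    def b_center(row) -> int | None:
        return scaffolds[row["chrom_idx"]].map_a_to_b(row["center_a"])

    def destroy(chrom_idx: int, center_b: int, pwm: PWM) -> None:
        cons = pwm.consensus()
        start = center_b - len(cons) // 2
        arr = seq_b[chrom_idx]
        for j in range(0, len(cons), 2):
            old = arr[start + j]
            arr[start + j] = (old + 1 + int(rng.integers(0, 3))) % 4

    for row in site_rows + anchor_rows:
        cb = b_center(row)
        row["center_b"] = cb
        if cb is None:
            continue
        if row["motif_a"] and not row["motif_b"]:
            destroy(row["chrom_idx"], cb, pwms[row["factor"]])
    for row in comp_rows:
        cb = b_center(row)
        row["center_b"] = cb
        if cb is None:
            raise RuntimeError("compensatory site placed on a deleted block")
        cons = nomadic_pwm.consensus()
        start = cb - len(cons) // 2
        seq_b[row["chrom_idx"]][start : start + len(cons)] = np.array(
            [BASES.index(b) for b in cons], dtype=np.uint8
        )
    for row in decoy_rows:
        row["center_b"] = b_center(row)

    genome_a = {
        sc.name: seq_a[ci].tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
        for ci, sc in enumerate(scaffolds)
    }
    genome_b = {
        sc.name: seq_b[ci].tobytes().translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
        for ci, sc in enumerate(scaffolds)
    }

    # --- genes in B -------------------------------------------------------
    genes_b = []
    for meta in gene_meta:
        gene = meta["gene"]
        sc = scaffolds[meta["chrom_idx"]]
        b_start = sc.map_a_to_b(gene.interval.start)
        b_last = sc.map_a_to_b(gene.interval.end - 1)
        if b_start is None or b_last is None:
            continue
        iv = GenomicInterval(sc.name, b_start, b_last + 1, strand=gene.strand, name=gene.gene_id)
        genes_b.append(GeneAnnotation(gene.gene_id, gene.symbol, iv))

    # --- peaks ------------------------------------------------------------
    def peak(chrom: str, center: int, name: str, enr: float, width: int = 150) -> PeakRecord:
        start = max(0, center - width // 2)
        return PeakRecord(
            GenomicInterval(chrom, start, start + width, name=name),
            enrichment=float(enr),
            significance=float(rng.uniform(0, 0.01)),
        )

    primary_real, support_a, nomadic_b = [], [], []
    for row in site_rows:
        chrom = scaffolds[row["chrom_idx"]].name
        mu = 2.7 if row["retained"] else 2.0
        enr = rng.lognormal(mu, 0.5)
        primary_real.append(peak(chrom, row["center_a"], row["site_id"], enr))
        support_a.append(
            peak(chrom, row["center_a"] + int(rng.integers(-100, 101)), "rx_" + row["site_id"], rng.uniform(3, 10))
        )
        if row["retained"]:
            nomadic_b.append(peak(chrom, row["center_b"], "b_" + row["site_id"], rng.lognormal(2.5, 0.5)))
    for row in comp_rows:
        chrom = scaffolds[row["chrom_idx"]].name
        nomadic_b.append(peak(chrom, row["center_b"], row["site_id"], rng.lognormal(2.0, 0.5)))
    decoy_peaks = [
        peak(scaffolds[row["chrom_idx"]].name, row["center_a"], row["site_id"], rng.lognormal(1.8, 0.5))
        for row in decoy_rows
    ]
    primary_a = primary_real + decoy_peaks
    order = rng.permutation(len(primary_a))
    primary_a = [primary_a[i] for i in order]

    anchor_a, anchor_b = [], []
    for row in anchor_rows:
        chrom = scaffolds[row["chrom_idx"]].name
        anchor_a.append(peak(chrom, row["center_a"], row["site_id"], rng.lognormal(2.2, 0.6)))
        if row["retained"]:
            anchor_b.append(peak(chrom, row["center_b"], "b_" + row["site_id"], rng.lognormal(2.2, 0.6)))

    # --- tag libraries ----------------------------------------------------
    def make_tags(rows_with_peaks, genome_key: str) -> list[GenomicInterval]:
        tags = []
        chrom_len = {sc.name: (sc.a_len if genome_key == "a" else sc.b_len) for sc in scaffolds}
        for chrom, center in rows_with_peaks:
            for _ in range(config.tags_per_site):
                tc = center + int(rng.normal(0, 100))
                tc = min(max(tc, 20), chrom_len[chrom] - 20)
                strand = "+" if rng.random() < 0.5 else "-"
                tags.append(GenomicInterval(chrom, tc - 18, tc + 18, strand=strand, name="t"))
        for _ in range(config.n_background_tags):
            ci = int(rng.integers(0, config.n_chroms))
            limit = chrom_len[scaffolds[ci].name]
            pos = int(rng.integers(20, limit - 20))
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append(GenomicInterval(scaffolds[ci].name, pos - 18, pos + 18, strand=strand, name="t"))
        return tags

    tags_a = make_tags(
        [(scaffolds[r["chrom_idx"]].name, r["center_a"]) for r in site_rows], "a"
    )
    tags_b = make_tags(
        [(scaffolds[r["chrom_idx"]].name, r["center_b"]) for r in site_rows if r["retained"]]
        + [(scaffolds[r["chrom_idx"]].name, r["center_b"]) for r in comp_rows],
        "b",
    )

    # --- conservation -----------------------------------------------------
    # an exact fraction of each retention class overlaps an element
    has_element: dict[str, bool] = {r["site_id"]: False for r in site_rows}
    for label in ("retained", "species_specific"):
        group = [r for r in site_rows if (r["retained"]) == (label == "retained")]
        k_el = int(round(config.conserved_element_prob[label] * len(group)))
        for j, idx in enumerate(rng.permutation(len(group))):
            if j < k_el:
                has_element[group[int(idx)]["site_id"]] = True
    elements_a, score_rows = [], []
    for row in site_rows:
        chrom = scaffolds[row["chrom_idx"]].name
        label = "retained" if row["retained"] else "species_specific"
        if has_element[row["site_id"]]:
            start = row["center_a"] - 100 + int(rng.integers(-30, 31))
            elements_a.append(GenomicInterval(chrom, start, start + 200, name=f"el_{row['site_id']}"))
        level = float(np.clip(rng.normal(config.conservation_mean[label], 0.1), 0.02, 0.98))
        for pos in range(row["center_a"] - 75, row["center_a"] + 75):
            score_rows.append((chrom, pos, float(np.clip(level + rng.normal(0, 0.02), 0.0, 1.0))))
    for _ in range(config.n_background_elements):
        ci = int(rng.integers(0, config.n_chroms))
        pos = int(rng.integers(0, scaffolds[ci].a_len - 250))
        elements_a.append(GenomicInterval(scaffolds[ci].name, pos, pos + 200, name="el_bg"))
    score_track = ScoreTrack.from_rows(score_rows)

    # --- expression -------------------------------------------------------
    # an exact fraction of each category responds to the ligand
    gene_responsive = {meta["gene"].symbol: False for meta in gene_meta}
    by_category: dict[str, list] = {}
    for meta in gene_meta:
        by_category.setdefault(meta["category"], []).append(meta)
    for category, members in by_category.items():
        p_resp = config.responsive_prob_by_category.get(category, 0.05)
        k_resp = int(round(p_resp * len(members)))
        for j, idx in enumerate(rng.permutation(len(members))):
            if j < k_resp:
                gene_responsive[members[int(idx)]["gene"].symbol] = True
    sample_ids, sample_rows = [], []
    for tp in config.timepoints:
        for cond in ("treated", "vehicle"):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{cond}_t{tp:g}_r{rep}"
                sample_ids.append(sid)
                sample_rows.append({"sample": sid, "condition": cond, "timepoint": tp})
    samples = pd.DataFrame(sample_rows).set_index("sample")
    sample_cond = [r["condition"] for r in sample_rows]
    sample_tp = [r["timepoint"] for r in sample_rows]
    probe_map, values = {}, {}
    for meta in gene_meta:
        symbol = meta["gene"].symbol
        responsive = gene_responsive[symbol]
        resp_tps = set()
        if responsive:
            resp_tps = {tp for tp in config.timepoints if rng.random() < 0.6}
            if not resp_tps:
                resp_tps = {config.timepoints[int(rng.integers(0, len(config.timepoints)))]}
        baseline = 2.0 ** rng.uniform(6, 10)
        n_probes = 2 if rng.random() < 0.1 else 1
        for pi in range(n_probes):
            probe = f"pr{pi}_{meta['gene'].gene_id}"
            probe_map[probe] = symbol
            row_values = []
            for cond, tp in zip(sample_cond, sample_tp):
                effect = config.responsive_effect_log2 if (cond == "treated" and tp in resp_tps) else 0.0
                row_values.append(baseline * 2.0 ** (effect + rng.normal(0, config.expression_noise_sd)))
            values[probe] = row_values
    expr_values = pd.DataFrame.from_dict(values, orient="index", columns=sample_ids)
    expression = ExpressionMatrix(expr_values, samples, probe_map)

    # --- term annotation --------------------------------------------------
    generic_terms = [f"term_{k:02d}" for k in range(10)]
    terms: dict[str, list[str]] = {}
    for meta in gene_meta:
        symbol = meta["gene"].symbol
        assigned = [generic_terms[int(rng.integers(0, len(generic_terms)))]]
        p_lipid = 0.35 if meta["category"] in ("directly_shared", "indirectly_shared") else 0.08
        if rng.random() < p_lipid:
            assigned.append("lipid_metabolic_process")
        terms[symbol] = assigned

    # --- ground truth -----------------------------------------------------
    all_rows = site_rows + comp_rows + anchor_rows + decoy_rows
    for row in all_rows:
        row["chrom"] = scaffolds[row["chrom_idx"]].name
    truth_sites = pd.DataFrame(all_rows)[
        [
            "site_id",
            "factor",
            "kind",
            "chrom",
            "center_a",
            "center_b",
            "retained",
            "stratum",
            "category",
            "core_id",
            "cooccupied",
            "anchor_id",
            "anchor_retained",
            "motif_a",
            "motif_b",
        ]
    ]
    truth_genes = pd.DataFrame(
        [
            {
                "gene_id": meta["gene"].gene_id,
                "symbol": meta["gene"].symbol,
                "chrom": meta["gene"].chrom,
                "tss": meta["gene"].tss,
                "category": meta["category"],
                "core_id": meta["core_id"],
                "responsive": gene_responsive[meta["gene"].symbol],
            }
            for meta in gene_meta
        ]
    )

    return SimulationBundle(
        config=config,
        genome_a=genome_a,
        genome_b=genome_b,
        chains_a_to_b=chains_a_to_b,
        chains_b_to_a=chains_b_to_a,
        genes_a=genes_a,
        genes_b=genes_b,
        primary_a=primary_a,
        support_a=support_a,
        nomadic_b=nomadic_b,
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        tags_a=tags_a,
        tags_b=tags_b,
        elements_a=elements_a,
        score_track_a=score_track,
        score_rows_a=score_rows,
        expression=expression,
        terms=terms,
        pwms=pwms,
        truth=GroundTruth(truth_sites, truth_genes),
    )


def truth_report(bundle: SimulationBundle, outdir=None) -> GroundTruth:
    """Ground-truth tables keyed by the ids used in the emitted files."""
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        bundle.truth.sites.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
        bundle.truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
    return bundle.truth
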