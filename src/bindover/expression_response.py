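"""Ligand-responsiveness calling from an expression time course.

A gene is responsive when its treated/vehicle log2 ratio exceeds the
fold threshold at one or more timepoints. Probe-level ratios are
collapsed to genes by maximum absolute ratio. The per-category
response rates with pairwise Fisher tests quantify the gradient across
target sharing categories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bindover.stats_enrichment import fisher_exact_2x2
from bindover.target_genes import CATEGORIES, TargetRecord


@dataclass
class ExpressionMatrix:
    """Probes x samples intensities plus sample and probe metadata.

    ``values``: DataFrame indexed by probe id, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``condition`` (treated/vehicle) and ``timepoint``.
    ``probe_map``: probe id -> gene symbol, total on the probes used.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_map: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing columns: {sorted(missing)[:5]}")
        unmapped = set(self.values.index) - set(self.probe_map)
        if unmapped:
            raise ValueError(f"probe map missing probes: {sorted(unmapped)[:5]}")
        if (self.values <= 0).any().any():
            raise ValueError("intensities must be positive")

    @classmethod
    def from_tsv(cls, values_path, samples_path, probe_map_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        probe_map = dict(
            pd.read_csv(probe_map_path, sep="\t", header=None, names=["probe", "gene"]).values
        )
        return cls(values, samples, probe_map)


def call_responsive(
    expr: ExpressionMatrix,
    fold_threshold: float = 1.5,
    direction: str = "up",
) -> tuple[set[str], pd.DataFrame]:
    """Genes whose fold change exceeds the threshold at >= 1 timepoint.

    Per timepoint and probe, log2 ratio = log2(mean treated / mean
    vehicle); probes collapse to genes by maximum |log2 ratio|. With
    ``direction="up"`` a gene is responsive when its ratio exceeds
    log2(fold_threshold) at some timepoint; ``"any"`` uses |ratio|.
    Timepoints lacking vehicle (or treated) samples are skipped with a
    warning. Returns (responsive gene set, per-gene-per-timepoint
    log2-ratio table).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if direction not in ("up", "any"):
        raise ValueError("direction must be 'up' or 'any'")
    log_cutoff = math.log2(fold_threshold)
    ratios = {}
    for timepoint, sheet in expr.samples.groupby("timepoint"):
        treated = sheet.index[sheet["condition"] == "treated"]
        vehicle = sheet.index[sheet["condition"] == "vehicle"]
        if len(treated) == 0 or len(vehicle) == 0:
            warnings.warn(f"timepoint {timepoint}: missing treated or vehicle samples; skipped")
            continue
        ratio = np.log2(expr.values[treated].mean(axis=1) / expr.values[vehicle].mean(axis=1))
        ratios[timepoint] = ratio
    probe_table = pd.DataFrame(ratios)
    gene_ids = pd.Series({p: expr.probe_map[p] for p in probe_table.index})
    # collapse probes to genes: keep, per gene and timepoint, the ratio of largest magnitude
    def _max_abs(col: pd.Series) -> pd.Series:
        frame = pd.DataFrame({"gene": gene_ids, "ratio": col})
        idx = frame.groupby("gene")["ratio"].apply(lambda s: s.iloc[s.abs().values.argmax()])
        return idx

    gene_table = probe_table.apply(_max_abs)
    if direction == "up":
        responsive_mask = (gene_table > log_cutoff).any(axis=1)
    else:
        responsive_mask = (gene_table.abs() > log_cutoff).any(axis=1)
    return set(gene_table.index[responsive_mask]), gene_table


def pool_sets(sets: Mapping[str, set[str]]) -> tuple[set[str], dict[str, list[str]]]:
    """Union of named gene sets with per-gene provenance."""
    union: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for name, genes in sets.items():
        union |= set(genes)
        for g in genes:
            provenance.setdefault(g, []).append(name)
    return union, provenance


def category_response_rates(
    targets: Sequence[TargetRecord],
    responsive: set[str],
    by: str = "symbol",
) -> dict:
    """Per-category responsiveness with pairwise Fisher's exact tests.

    Returns per-category (n, k, fraction, rounded percent) plus
    pairwise 2x2 Fisher p-values. Empty categories are flagged with
    fraction None and excluded from comparisons. Percent is rounded
    half-up.
    """
    per_cat: dict[str, dict] = {}
    for cat in CATEGORIES:
        members = [t for t in targets if t.category == cat]
        names = [getattr(t.gene, by) for t in members]
        k = sum(1 for name in names if name in responsive)
        n = len(members)
        frac = k / n if n else None
        pct = int(math.floor(frac * 100 + 0.5)) if frac is not None else None
        per_cat[cat] = {"n": n, "k": k, "fraction": frac, "percent": pct}
    tests = {}
    for i, c1 in enumerate(CATEGORIES):
        for c2 in CATEGORIES[i + 1 :]:
            g1, g2 = per_cat[c1], per_cat[c2]
            if g1["n"] and g2["n"]:
                table = [[g1["k"], g1["n"] - g1["k"]], [g2["k"], g2["n"] - g2["k"]]]
                try:
                    tests[(c1, c2)] = fisher_exact_2x2(table).p_two_sided
                except ValueError:
                    # a zero margin (nobody / everybody responsive) is trivially even
                    tests[(c1, c2)] = 1.0
    return {"categories": per_cat, "fisher_p": tests}
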