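"""Statistical tests backing every printed percentage and p-value.

Fisher's exact 2x2 (two-sided by the minimum-likelihood rule),
pooled-variance two-proportion z-test, Welch's t-test, and
hypergeometric term overrepresentation. The heavy lifting is delegated
to scipy.stats; this module fixes the conventions (two-sided rules,
pooled variance, upper-tail enrichment) used throughout the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    observed: int
    expected: float
    fold: float
    p: float
    q: float | None = None


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided p sums the hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's (minimum-likelihood rule, with a small relative
    tolerance), the convention of R's ``fisher.test``.
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("all margins must be positive")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p))


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, float(min(p, 1.0))


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(a.size + b.size - 2), 0.0
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)


def term_enrichment(
    query: set[str],
    annotation: Mapping[str, Sequence[str]],
    background: set[str],
    with_fdr: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of annotation terms in a query set.

    ``annotation`` maps gene -> terms. For each term, the upper-tail
    hypergeometric p of the observed query/term overlap against the
    background is reported, with fold = observed/expected. Terms with no
    annotated gene in the background are skipped with a warning. Rows
    come back sorted by p ascending. ``with_fdr`` adds Benjamini-
    Hochberg q-values.
    """
    if not query <= background:
        raise ValueError("query must be a subset of background")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    n_bg, n_query = len(background), len(query)
    rows: list[EnrichmentRow] = []
    for term, genes in sorted(term_genes.items()):
        in_bg = genes & background
        if not in_bg:
            warnings.warn(f"term {term!r} has no genes in background; skipped")
            continue
        observed = len(genes & query)
        expected = n_query * len(in_bg) / n_bg
        # P(X >= observed) for X ~ Hypergeom(N=n_bg, K=|term|, n=n_query)
        p = float(stats.hypergeom.sf(observed - 1, n_bg, len(in_bg), n_query))
        fold = observed / expected if expected > 0 else math.inf
        rows.append(EnrichmentRow(term, observed, expected, fold, min(p, 1.0)))
    rows.sort(key=lambda r: (r.p, r.term))
    if with_fdr and rows:
        ps = np.array([r.p for r in rows])
        m = len(ps)
        order = np.argsort(ps)
        q = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            q[i] = running
        rows = [EnrichmentRow(r.term, r.observed, r.expected, r.fold, r.p, float(q[i])) for i, r in enumerate(rows)]
    return rows
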