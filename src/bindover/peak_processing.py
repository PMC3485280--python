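"""Heterodimer support filtering and partner-factor co-occupancy.

A nuclear receptor that binds DNA only as a heterodimer leaves a
signature in two ChIP libraries at once; requiring nearby enrichment
in the partner library yields the high-confidence site set. The same
center-distance machinery annotates co-occupancy with an independent
partner factor (the lineage "anchor").
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from bindover.genomic_core import PeakRecord


@dataclass(frozen=True)
class SupportedPeak:
    peak: PeakRecord
    support_peak: PeakRecord | None = None
    support_distance: int | None = None

    def __post_init__(self) -> None:
        if (self.support_peak is None) != (self.support_distance is None):
            raise ValueError("support_distance present iff support_peak present")


@dataclass(frozen=True)
class CooccupancyFlag:
    site: PeakRecord
    cooccupied: bool
    partner: PeakRecord | None = None
    signed_distance: int | None = None  # partner center - site center


def _center_index(peaks: Sequence[PeakRecord]) -> dict[str, tuple[list[int], list[PeakRecord]]]:
    by_chrom: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    index = {}
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda p: p.center())
        index[chrom] = ([p.center() for p in group], group)
    return index


def _nearest(index, chrom: str, center: int) -> tuple[PeakRecord | None, int | None]:
    entry = index.get(chrom)
    if entry is None:
        return None, None
    centers, group = entry
    pos = bisect.bisect_left(centers, center)
    best, best_dist = None, None
    for idx in (pos - 1, pos):
        if 0 <= idx < len(group):
            dist = abs(centers[idx] - center)
            if best_dist is None or dist < best_dist:
                best, best_dist = group[idx], dist
    return best, best_dist


def filter_by_support(
    primary: Sequence[PeakRecord],
    support: Sequence[PeakRecord],
    max_center_distance: int = 500,
    min_support_enrichment: float = 2.0,
) -> list[SupportedPeak]:
    """Retain primary peaks backed by nearby partner-library enrichment.

    A primary peak is kept iff some support peak with enrichment
    strictly above ``min_support_enrichment`` has its center within
    ``max_center_distance`` bp (inclusive) of the primary center; the
    nearest qualifying support peak is recorded. Output preserves the
    input order of retained peaks.
    """
    if max_center_distance <= 0:
        raise ValueError("max_center_distance must be positive")
    qualifying = [s for s in support if s.enrichment > min_support_enrichment]
    index = _center_index(qualifying)
    out: list[SupportedPeak] = []
    for peak in primary:
        partner, dist = _nearest(index, peak.chrom, peak.center())
        if partner is not None and dist is not None and dist <= max_center_distance:
            out.append(SupportedPeak(peak, partner, dist))
    return out


def annotate_cooccupancy(
    sites: Sequence[PeakRecord],
    partner: Sequence[PeakRecord],
    max_center_distance: int = 150,
) -> list[CooccupancyFlag]:
    """Flag sites whose nearest partner center is within range.

    The boundary is inclusive; distances are signed (partner center
    minus site center) for downstream distance histograms. Sites on
    chromosomes without partners get flag False and no distance.
    """
    if max_center_distance <= 0:
        raise ValueError("max_center_distance must be positive")
    index = _center_index(partner)
    flags: list[CooccupancyFlag] = []
    for site in sites:
        nearest, dist = _nearest(index, site.chrom, site.center())
        if nearest is None or dist is None:
            flags.append(CooccupancyFlag(site, False))
        else:
            signed = nearest.center() - site.center()
            flags.append(CooccupancyFlag(site, dist <= max_center_distance, nearest, signed))
    return flags
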