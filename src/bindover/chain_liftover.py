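"""UCSC chain-file parsing and cross-genome interval mapping.

A chain records a gapless-block alignment between a *target* genome
(the genome coordinates are lifted FROM) and a *query* genome (lifted
TO). ``lift_interval`` walks the blocks of the single best chain, in
the manner of the UCSC liftOver tool with its default single-mapping
behaviour and a minimum remap ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from bindover.genomic_core import GenomicInterval, PeakRecord, standardize


class ChainParseError(ValueError):
    pass


class ChainSide(NamedTuple):
    name: str
    size: int
    strand: str
    start: int
    end: int


class ChainBlock(NamedTuple):
    size: int
    dt: int  # gap on target after the block
    dq: int  # gap on query after the block


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: header plus ordered gapless blocks.

    Invariants (enforced at construction): block sizes plus target gaps
    span the target interval; sizes plus query gaps span the query
    interval; the final block has zero trailing gaps.
    """

    score: float
    target: ChainSide
    query: ChainSide
    blocks: tuple[ChainBlock, ...]
    chain_id: int = 0

    def __post_init__(self) -> None:
        tspan = sum(b.size + b.dt for b in self.blocks)
        qspan = sum(b.size + b.dq for b in self.blocks)
        if tspan != self.target.end - self.target.start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {tspan} on target, "
                f"header says {self.target.end - self.target.start}"
            )
        if qspan != self.query.end - self.query.start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks span {qspan} on query, "
                f"header says {self.query.end - self.query.start}"
            )
        if self.blocks and (self.blocks[-1].dt != 0 or self.blocks[-1].dq != 0):
            raise ChainParseError(f"chain {self.chain_id}: last block must have dt = dq = 0")


def parse_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; block-sum invariants are checked."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        chain_id = int(rest[0]) if rest else 0
        chains.append(
            ChainAlignment(
                score=float(score),
                target=ChainSide(t_name, int(t_size), t_strand, int(t_start), int(t_end)),
                query=ChainSide(q_name, int(q_size), q_strand, int(q_start), int(q_end)),
                blocks=tuple(blocks),
                chain_id=chain_id,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) < 12:
                    raise ChainParseError(f"malformed chain header: {line!r}")
            else:
                parts = line.split()
                if len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0]), 0, 0))
                else:
                    raise ChainParseError(f"malformed block line: {line!r}")
    finish()
    return chains


def write_chain(path, chains: Iterable[ChainAlignment]) -> None:
    """Write chains in UCSC chain format (inverse of :func:`parse_chain`)."""
    with open(path, "w") as fh:
        for c in chains:
            t, q = c.target, c.query
            fh.write(
                f"chain {c.score:g} {t.name} {t.size} {t.strand} {t.start} {t.end} "
                f"{q.name} {q.size} {q.strand} {q.start} {q.end} {c.chain_id}\n"
            )
            for i, b in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{b.size}\n")
                else:
                    fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write("\n")


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query, producing the reverse-direction chain.

    Only forward-strand chains on both sides are invertible this way;
    these are the chains the synthetic generator emits.
    """
    if chain.target.strand != "+" or chain.query.strand != "+":
        raise ValueError("invert_chain supports ++ chains only")
    blocks = tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks)
    return ChainAlignment(chain.score, chain.query, chain.target, blocks, chain.chain_id)


@dataclass(frozen=True)
class LiftResult:
    """Outcome of mapping one interval: a status plus the image, if any."""

    status: str  # mapped | unmapped | below_min_match | split
    mapped: GenomicInterval | None = None
    matched_fraction: float = 0.0


def _chain_t_range(chain: ChainAlignment) -> tuple[int, int]:
    return chain.target.start, chain.target.end


def lift_interval(
    iv: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_match: float = 0.1,
) -> LiftResult:
    """Map an interval through the best overlapping chain.

    The single highest-scoring chain overlapping ``iv`` on the target
    side is used (ties broken by lower chain_id); the image is the
    bounding span of all mapped bases on the query genome. If more than
    one chain overlaps and the best chain maps fewer than ``min_match``
    of the bases while another also overlaps, the interval is reported
    as ``split`` only when the best chain maps none of it but others
    would. Negative-strand query coordinates are normalised to
    forward-strand (pos' = qSize - pos - 1).
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    overlapping = [
        c
        for c in chains
        if c.target.name == iv.chrom and c.target.start < iv.end and iv.start < c.target.end
    ]
    if not overlapping:
        return LiftResult("unmapped")
    best = min(overlapping, key=lambda c: (-c.score, c.chain_id))

    # walk the gapless blocks, collecting query images of iv's bases
    t_pos = best.target.start
    q_pos = best.query.start
    mapped_bases = 0
    q_min: int | None = None
    q_max: int | None = None
    for block in best.blocks:
        t_block_end = t_pos + block.size
        lo = max(iv.start, t_pos)
        hi = min(iv.end, t_block_end)
        if lo < hi:
            off_lo = lo - t_pos
            off_hi = hi - t_pos
            q_lo = q_pos + off_lo
            q_hi = q_pos + off_hi
            mapped_bases += hi - lo
            q_min = q_lo if q_min is None else min(q_min, q_lo)
            q_max = q_hi if q_max is None else max(q_max, q_hi)
        t_pos = t_block_end + block.dt
        q_pos += block.size + block.dq
        if t_pos >= iv.end:
            break

    fraction = mapped_bases / iv.width
    if mapped_bases == 0:
        others = [c for c in overlapping if c is not best]
        if others:
            return LiftResult("split", matched_fraction=0.0)
        return LiftResult("below_min_match", matched_fraction=0.0)
    if fraction < min_match:
        return LiftResult("below_min_match", matched_fraction=fraction)

    assert q_min is not None and q_max is not None
    if best.query.strand == "-":
        q_size = best.query.size
        q_min, q_max = q_size - q_max, q_size - q_min
    image = GenomicInterval(best.query.name, q_min, q_max, strand=iv.strand, name=iv.name)
    return LiftResult("mapped", mapped=image, matched_fraction=fraction)


def lift_set(
    peaks: Sequence[PeakRecord],
    chains: Sequence[ChainAlignment],
    min_match: float = 0.1,
    pre_extend: int | None = None,
) -> tuple[list[PeakRecord], dict[str, int]]:
    """Lift a peak set, optionally standardizing widths first.

    Returns the successfully mapped peaks (source identifiers and
    scores kept) plus a status summary that partitions the input.
    """
    mapped: list[PeakRecord] = []
    summary = {"mapped": 0, "unmapped": 0, "below_min_match": 0, "split": 0}
    for peak in peaks:
        iv = standardize(peak, pre_extend) if pre_extend else peak.interval
        result = lift_interval(iv, chains, min_match=min_match)
        summary[result.status] += 1
        if result.status == "mapped":
            mapped.append(
                PeakRecord(
                    result.mapped,
                    enrichment=peak.enrichment,
                    significance=peak.significance,
                    library=peak.library,
                )
            )
    return mapped, summary
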