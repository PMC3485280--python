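"""PWM scanning with an exact, DP-derived null score distribution.

Scores are log2 odds of the pseudocount-regularised position
frequencies against a background base composition. Significance is
calibrated FIMO-style: the null distribution of single-position,
single-strand scores under the background model is computed exactly by
dynamic programming over discretised scores, and a hit's p-value is
the null tail probability at its score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: width of one discretisation bin of log-odds score (bits)
DEFAULT_SCORE_BIN = 1e-3

_ENCODE = np.full(256, 4, dtype=np.int8)  # 4 = N / unknown
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes 0..3 (ACGT); anything else becomes 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(comp)[::-1]


class PWM:
    """Position weight matrix with background model and pseudocount.

    ``counts`` is a width x 4 array of per-position base counts (or
    frequencies); the log-odds entry for base b at position j is

        log2( (counts[j,b] + pseudocount*bg[b]) / (total_j + pseudocount) / bg[b] )
    """

    def __init__(
        self,
        id: str,
        counts: np.ndarray | Sequence[Sequence[float]],
        background: Sequence[float] | None = None,
        pseudocount: float = 0.1,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a width x 4 matrix")
        if counts.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        bg = np.asarray([0.25] * 4 if background is None else background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-6 or np.any(bg <= 0):
            raise ValueError("background must be 4 positive frequencies summing to 1")
        if pseudocount == 0 and np.any(counts == 0):
            raise ValueError("zero counts require a positive pseudocount")
        self.id = id
        self.counts = counts
        self.background = bg
        self.pseudocount = pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount * bg) / (totals + pseudocount)
        self.log_odds = np.log2(probs / bg)  # width x 4
        self._null_cache: dict[float, tuple[np.ndarray, int, float]] = {}

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.id + "_rc",
            self.counts[::-1, ::-1].copy(),
            background=self.background[::-1],  # complement swaps A<->T, C<->G
            pseudocount=self.pseudocount,
        )

    # -- null distribution ------------------------------------------------

    def _null(self, score_bin: float = DEFAULT_SCORE_BIN) -> tuple[np.ndarray, int, float]:
        """Exact null score distribution over discretised scores.

        Returns (probabilities, offset, bin width): probabilities[i] is
        the null mass of the score bin (i + offset) * bin width.
        """
        cached = self._null_cache.get(score_bin)
        if cached is not None:
            return cached
        bins = np.rint(self.log_odds / score_bin).astype(np.int64)  # width x 4
        dist = np.array([1.0])
        offset = 0
        for j in range(self.width):
            row = bins[j]
            lo, hi = int(row.min()), int(row.max())
            new = np.zeros(dist.size + (hi - lo), dtype=float)
            for base in range(4):
                shift = int(row[base]) - lo
                new[shift : shift + dist.size] += self.background[base] * dist
            dist = new
            offset += lo
        self._null_cache[score_bin] = (dist, offset, score_bin)
        return dist, offset, score_bin

    def score_pvalue(self, score: float, score_bin: float = DEFAULT_SCORE_BIN) -> float:
        """Null tail probability P(S >= score) for one position, one strand."""
        if not math.isfinite(score):
            return 1.0 if score == -math.inf else 0.0
        dist, offset, binw = self._null(score_bin)
        # rounding each position separately can shift the binned sum by
        # up to width/2 bins against the float score; include that slack
        # so an achievable score always covers its own probability mass
        slack = self.width // 2 + 1
        idx = int(round(score / binw)) - offset - slack
        if idx <= 0:
            return 1.0
        if idx >= dist.size:
            return 0.0
        return float(dist[idx:].sum())


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring motif occurrence in a scanned window."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


@dataclass(frozen=True)
class MotifPresence:
    present: bool
    best: MotifHit | None
    clipped: bool = False


def score_scan(pwm: PWM, sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset log-odds scores on both strands.

    Returns (plus, minus), each of length len(sequence) - width + 1.
    ``minus[i]`` scores the reverse complement of sequence[i:i+width].
    Offsets whose window contains an N score -inf. A sequence shorter
    than the motif yields empty arrays.
    """
    width = pwm.width
    codes = encode_sequence(sequence)
    n_offsets = codes.size - width + 1
    if n_offsets <= 0:
        return np.empty(0), np.empty(0)
    # 5th column = -inf sentinel for N
    lo_plus = np.hstack([pwm.log_odds, np.full((width, 1), -np.inf)])
    lo_minus = np.hstack([pwm.log_odds[::-1, ::-1], np.full((width, 1), -np.inf)])
    plus = np.zeros(n_offsets)
    minus = np.zeros(n_offsets)
    for j in range(width):
        window = codes[j : j + n_offsets]
        plus += lo_plus[j, window]
        minus += lo_minus[j, window]
    return plus, minus


def pvalue_threshold(pwm: PWM, alpha: float, score_bin: float = DEFAULT_SCORE_BIN) -> float:
    """Smallest score whose null tail probability is <= alpha."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    dist, offset, binw = pwm._null(score_bin)
    tail = np.cumsum(dist[::-1])[::-1]
    qualifying = np.nonzero(tail <= alpha + 1e-12)[0]
    if qualifying.size == 0:
        return math.inf  # alpha smaller than the rarest score's mass
    return float((qualifying[0] + offset) * binw)


def best_hit(pwm: PWM, sequence: str, window_start: int, chrom: str) -> MotifHit | None:
    """Best-scoring position over both strands of a window sequence."""
    plus, minus = score_scan(pwm, sequence)
    if plus.size == 0:
        return None
    i_p = int(np.argmax(plus))
    i_m = int(np.argmax(minus))
    if plus[i_p] >= minus[i_m]:
        i, strand, score = i_p, "+", float(plus[i_p])
    else:
        i, strand, score = i_m, "-", float(minus[i_m])
    if score == -math.inf:
        return None
    return MotifHit(
        chrom=chrom,
        start=window_start + i,
        end=window_start + i + pwm.width,
        strand=strand,
        score=score,
        pvalue=pwm.score_pvalue(score),
    )


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract a subsequence from a dict of strings or a pyfaidx.Fasta."""
    if isinstance(genome, Mapping):
        return str(genome[chrom][start:end])
    return str(genome[chrom][start:end])  # pyfaidx shares the slice protocol


def genome_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def motif_present(
    site,
    genome,
    pwm: PWM,
    window: int = 200,
    alpha: float = 1e-4,
) -> MotifPresence:
    """Is the motif present in a window centered on the site?

    ``site`` is a GenomicInterval (or PeakRecord); the window is
    centered on its center. Windows running past a chromosome end are
    clipped and flagged. Presence means the best hit on either strand
    has p-value <= alpha.
    """
    if window < pwm.width:
        raise ValueError("window must be at least the motif width")
    interval = getattr(site, "interval", site)
    center = interval.center()
    start = center - window // 2
    end = start + window
    clipped = False
    if start < 0:
        start, clipped = 0, True
    chrom_len = genome_length(genome, interval.chrom)
    if end > chrom_len:
        end, clipped = chrom_len, True
    seq = fetch_sequence(genome, interval.chrom, start, end)
    hit = best_hit(pwm, seq, start, interval.chrom)
    present = hit is not None and hit.pvalue <= alpha
    return MotifPresence(present=present, best=hit, clipped=clipped)


def ortholog_motif_table(
    sites,
    lift_results,
    genome_a,
    genome_b,
    pwms: Mapping[str, PWM],
    window: int = 200,
    alpha: float = 1e-4,
):
    """Per-site motif presence in both species for each factor.

    ``lift_results`` maps site name -> LiftResult on genome B.
    Presence in B is None (indeterminate) for unmapped sites; such
    sites are excluded when proportions are computed from the table.
    Returns a pandas DataFrame with columns site_id, lift_status, and
    <factor>_a / <factor>_b per factor.
    """
    import pandas as pd

    rows = []
    for site in sites:
        interval = getattr(site, "interval", site)
        res = lift_results.get(interval.name)
        row: dict = {
            "site_id": interval.name,
            "lift_status": res.status if res is not None else "unmapped",
        }
        for factor, pwm in pwms.items():
            row[f"{factor}_a"] = motif_present(interval, genome_a, pwm, window, alpha).present
            if res is not None and res.status == "mapped":
                row[f"{factor}_b"] = motif_present(res.mapped, genome_b, pwm, window, alpha).present
            else:
                row[f"{factor}_b"] = None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PWM IO
# ---------------------------------------------------------------------------


def read_meme(path, pseudocount: float = 0.1) -> list[PWM]:
    """Read PWMs from MEME minimal motif format.

    Letter-probability rows are rescaled by ``nsites`` (default 20) to
    approximate counts; the file's background line is honoured.
    """
    pwms: list[PWM] = []
    background = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq_line = lines[i + 1].split()
            background = [float(freq_line[j]) for j in (1, 3, 5, 7)]
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            nsites = 20.0
            width = None
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i < len(lines):
                header = lines[i]
                for token, key in (("w=", "w"), ("nsites=", "nsites")):
                    if token in header:
                        value = header.split(token)[1].split()[0]
                        if key == "w":
                            width = int(value)
                        else:
                            nsites = float(value)
                i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(f"motif {name}: expected {width} rows, found {len(rows)}")
            counts = np.asarray(rows) * nsites
            pwms.append(PWM(name, counts, background=background, pseudocount=pseudocount))
            continue
        i += 1
    return pwms


def write_meme(path, pwms: Sequence[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else [0.25] * 4
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            totals = pwm.counts.sum(axis=1)
            nsites = float(totals[0]) if totals.size else 20.0
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {nsites:g}\n")
            probs = pwm.counts / totals[:, None]
            for row in probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_count_matrix(path, id: str | None = None, pseudocount: float = 0.1) -> PWM:
    """Read a plain count-matrix TSV: one row per position, columns A C G T."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue
            rows.append([float(x) for x in line.split()])
    import os

    return PWM(id or os.path.basename(str(path)), np.asarray(rows), pseudocount=pseudocount)
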