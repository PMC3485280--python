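"""PWM scanning, the DP null distribution, and presence calls."""

import itertools
import math

import numpy as np
import pytest

from bindover.genomic_core import GenomicInterval
from bindover.motif_scan import (
    PWM,
    best_hit,
    motif_present,
    ortholog_motif_table,
    pvalue_threshold,
    read_count_matrix,
    read_meme,
    reverse_complement,
    score_scan,
    write_meme,
)
from bindover.synthetic_data import default_pwms

BASES = "ACGT"


def sharp_pwm(consensus, weight=18.0, off=2 / 3):
    counts = np.full((len(consensus), 4), off)
    for j, b in enumerate(consensus):
        counts[j, BASES.index(b)] = weight
    return PWM("test", counts)


def random_pwm(rng, width):
    return PWM("rand", rng.uniform(0.5, 20, size=(width, 4)))


def naive_score(pwm, word):
    """Direct per-position product evaluation of the log-odds score."""
    total = 0.0
    for j, base in enumerate(word):
        bi = BASES.index(base)
        col = pwm.counts[j]
        prob = (col[bi] + pwm.pseudocount * pwm.background[bi]) / (col.sum() + pwm.pseudocount)
        total += math.log2(prob / pwm.background[bi])
    return total


class TestScoreScan:
    def test_consensus_scores_highest_at_offset_zero_plus_strand(self):
        pwm = sharp_pwm("ACGTACGTAC")
        seq = "ACGTACGTAC" + "TTTTTTTTTT"
        plus, minus = score_scan(pwm, seq)
        assert int(np.argmax(plus)) == 0
        assert plus[0] > minus.max()

    def test_palindrome_scores_equal_on_both_strands(self):
        pwm = sharp_pwm("ACGCGT")  # reverse complement of ACGCGT is ACGCGT
        rng = np.random.default_rng(13)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 60))
        plus, minus = score_scan(pwm, seq)
        assert np.allclose(plus, minus)

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(14)
        pwm = random_pwm(rng, 7)
        for _ in range(20):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, 50))
            plus, minus = score_scan(pwm, seq)
            for i in range(len(seq) - 6):
                assert plus[i] == pytest.approx(naive_score(pwm, seq[i : i + 7]), abs=1e-9)
                rc = reverse_complement(seq[i : i + 7])
                assert minus[i] == pytest.approx(naive_score(pwm, rc), abs=1e-9)

    def test_sequence_shorter_than_motif_gives_empty_result(self):
        plus, minus = score_scan(sharp_pwm("ACGTACGT"), "ACG")
        assert plus.size == 0 and minus.size == 0

    def test_n_bases_make_windows_unscorable(self):
        pwm = sharp_pwm("ACGT")
        plus, _ = score_scan(pwm, "ACGTNACGT")
        assert np.isfinite(plus[0]) and np.isfinite(plus[5])
        assert plus[1] == -np.inf and plus[4] == -np.inf

    def test_reverse_complementing_pwm_and_sequence_preserves_best_score(self):
        rng = np.random.default_rng(15)
        pwm = random_pwm(rng, 8)
        for _ in range(10):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, 40))
            s1 = np.maximum(*score_scan(pwm, seq)).max()
            s2 = np.maximum(*score_scan(pwm.reverse_complement(), reverse_complement(seq))).max()
            assert s1 == pytest.approx(s2, abs=1e-9)


class TestNullDistribution:
    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(16)
        for width in (4, 8, 13):
            dist, _, _ = random_pwm(rng, width)._null()
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_alpha_one_gives_minimum_attainable_score(self):
        pwm = sharp_pwm("ACGT")
        cutoff = pvalue_threshold(pwm, 1.0)
        worst = sum(pwm.log_odds[j].min() for j in range(4))
        assert cutoff == pytest.approx(worst, abs=1e-2)

    def test_tail_matches_exhaustive_enumeration_small_widths(self):
        rng = np.random.default_rng(17)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        pwm = PWM("w4", rng.uniform(0.5, 20, size=(4, 4)), background=bg)
        words = ["".join(w) for w in itertools.product(BASES, repeat=4)]
        scores = np.array([naive_score(pwm, w) for w in words])
        probs = np.array([np.prod([bg[BASES.index(b)] for b in w]) for w in words])
        for alpha in (0.5, 0.1, 0.01, 0.001):
            cutoff = pvalue_threshold(pwm, alpha)
            assert probs[scores >= cutoff - 1e-6].sum() <= alpha + 1e-9
            # including the next achievable score below the cutoff
            # would push the tail above alpha
            below = scores[scores < cutoff - 1e-6]
            if below.size:
                assert probs[scores >= below.max() - 1e-9].sum() > alpha - 1e-9
        # the survival function never understates the true tail and
        # overstates it by at most the discretisation slack window
        for s in np.quantile(scores, [0.1, 0.5, 0.9]):
            exact = probs[scores >= s - 1e-9].sum()
            got = pwm.score_pvalue(float(s))
            assert exact - 1e-9 <= got <= exact + 6e-3

    def test_cutoff_monotone_in_alpha(self):
        pwm = default_pwms()["nomadic"]
        cutoffs = [pvalue_threshold(pwm, a) for a in (1e-6, 1e-4, 1e-2, 0.5, 1.0)]
        assert cutoffs == sorted(cutoffs, reverse=True)


class TestPresence:
    def test_planted_consensus_is_present(self):
        pwm = default_pwms()["nomadic"]
        rng = np.random.default_rng(18)
        seq = list("".join(BASES[i] for i in rng.integers(0, 4, 400)))
        seq[193 : 193 + pwm.width] = pwm.consensus()
        genome = {"chr1": "".join(seq)}
        site = GenomicInterval("chr1", 190, 210, name="s1")
        res = motif_present(site, genome, pwm, window=200, alpha=1e-4)
        assert res.present and not res.clipped
        assert res.best.pvalue <= 1e-4

    def test_false_positive_rate_is_controlled(self):
        pwm = default_pwms()["nomadic"]  # sharp 13-mer
        rng = np.random.default_rng(19)
        alpha, window, hits = 1e-6, 200, 0
        genome = {"chr1": "".join(BASES[i] for i in rng.integers(0, 4, 250_000))}
        for i in range(1000):
            site = GenomicInterval("chr1", i * 250 + 100, i * 250 + 130, name=f"w{i}")
            if motif_present(site, genome, pwm, window=window, alpha=alpha).present:
                hits += 1
        assert hits <= 10 * alpha * 2 * window * 1000  # = 4 windows

    def test_clipping_at_chromosome_edge_is_flagged(self):
        pwm = sharp_pwm("ACGTACGTACGTA")
        genome = {"chr1": "ACGT" * 30}
        res = motif_present(GenomicInterval("chr1", 0, 20), genome, pwm, window=200)
        assert res.clipped

    def test_ortholog_table_matches_hand_tally_on_ten_sites(self, bundle):
        from bindover.chain_liftover import lift_interval
        from bindover.genomic_core import standardize

        sites = [p for p in bundle.primary_a if p.name.startswith("site_")][:10]
        lifts = {
            s.name: lift_interval(standardize(s, 1000), bundle.chains_a_to_b, 0.1)
            for s in sites
        }
        table = ortholog_motif_table(
            sites, lifts, bundle.genome_a, bundle.genome_b, bundle.pwms
        )
        assert len(table) == 10
        for _, row in table.iterrows():
            truth = bundle.truth.sites.set_index("site_id").loc[row["site_id"]]
            assert row["nomadic_a"] == truth["motif_a"]
            if row["lift_status"] == "mapped":
                assert row["nomadic_b"] == truth["motif_b"]


class TestPwmIO:
    def test_meme_round_trip(self, tmp_path):
        pwms = list(default_pwms().values())
        path = tmp_path / "m.meme"
        write_meme(path, pwms)
        back = read_meme(path)
        assert [p.id for p in back] == [p.id for p in pwms]
        for orig, rt in zip(pwms, back):
            orig_probs = orig.counts / orig.counts.sum(axis=1, keepdims=True)
            rt_probs = rt.counts / rt.counts.sum(axis=1, keepdims=True)
            assert np.allclose(orig_probs, rt_probs, atol=1e-5)

    def test_count_matrix_tsv(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#A\tC\tG\tT\n10\t1\t1\t1\n1\t10\t1\t1\n1\t1\t10\t1\n1\t1\t1\t10\n")
        pwm = read_count_matrix(path, id="acgt")
        assert pwm.width == 4
        assert pwm.consensus() == "ACGT"
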