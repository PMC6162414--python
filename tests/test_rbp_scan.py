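import math

import numpy as np
import pytest

from compete_scan.rbp_scan import (
    DEFAULT_BIN_WIDTH,
    MotifFormatError,
    MotifModel,
    PWMScanner,
    load_motifs,
    log_odds,
    scan_rbp,
    score_distribution,
    site_pvalue,
    write_motifs,
)
from compete_scan.sequence_io import NamedSequence, encode
from compete_scan.synthetic_data import random_motif
from conftest import random_rna
from oracles import enumerate_pwm, naive_window_scan, pwm_sf

MEME_ONE_MOTIF = """MEME version 4

ALPHABET= ACGU

Background letter frequencies
A 0.25 C 0.25 G 0.25 U 0.25

MOTIF demo
letter-probability matrix: alength= 4 w= 5 nsites= 20 E= 0
0.8 0.1 0.05 0.05
0.0 1.0 0.0 0.0
0.25 0.25 0.25 0.25
0.1 0.1 0.1 0.7
0.5 0.5 0.0 0.0
"""


class TestMotifIO:
    def test_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_ONE_MOTIF)
        (m,) = load_motifs(p, "meme")
        assert m.rbp_name == "demo" and m.k == 5
        probs = m.pfm / m.pfm.sum(axis=1, keepdims=True)
        assert probs[0] == pytest.approx([0.8, 0.1, 0.05, 0.05])

    def test_tsv_probability_row_must_sum_to_one(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(">bad\n0.5\t0.5\t0.5\t0.5\n0.25\t0.25\t0.25\t0.25\n"
                     "0.25\t0.25\t0.25\t0.25\n")
        with pytest.raises(MotifFormatError, match="sums to 2"):
            load_motifs(p, "tsv")

    def test_width_below_three_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(">tiny\n1\t0\t0\t0\n0\t1\t0\t0\n")
        with pytest.raises(MotifFormatError, match="width 2"):
            load_motifs(p, "tsv")

    @pytest.mark.parametrize("fmt", ["meme", "tsv"])
    def test_roundtrip(self, tmp_path, fmt):
        original = [random_motif(6, 0.5, seed=s, name=f"m{s}") for s in (1, 2)]
        path = tmp_path / f"x.{fmt}"
        write_motifs(original, path, fmt)
        loaded = load_motifs(path, fmt)
        for a, b in zip(original, loaded):
            assert a.rbp_name == b.rbp_name
            pa = a.pfm / a.pfm.sum(axis=1, keepdims=True)
            pb = b.pfm / b.pfm.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(pa, pb, atol=1e-5)


class TestLogOdds:
    def test_certain_column_no_pseudocount(self):
        m = MotifModel("m", np.array([[1.0, 0, 0, 0]] * 3), pseudocount=0.0)
        lo = log_odds(m)
        assert lo[0, 0] == pytest.approx(2.0)  # log2(1/0.25)
        assert np.isneginf(lo[0, 1:]).all()

    def test_uniform_column_scores_zero(self):
        m = MotifModel("m", np.full((3, 4), 0.25), pseudocount=0.0)
        assert np.allclose(log_odds(m), 0.0)

    def test_pseudocount_formula_by_hand(self):
        m = MotifModel("m", np.array([[0.5, 0.5, 0.0, 0.0]] * 3),
                       pseudocount=0.01)
        lo = log_odds(m)
        expected_hi = math.log2((0.51 / 1.04) / 0.25)
        expected_lo = math.log2((0.01 / 1.04) / 0.25)
        assert lo[0, 0] == pytest.approx(expected_hi)
        assert lo[0, 2] == pytest.approx(expected_lo)


class TestScoreDistribution:
    def test_gc_consensus_mass(self, gc_motif):
        dist = score_distribution(gc_motif)
        ((score, prob),) = list(dist.items())
        assert score == pytest.approx(4.0)
        assert prob == pytest.approx(1 / 16)

    def test_total_mass_one_with_pseudocount(self):
        m = random_motif(7, 0.3, seed=9)
        assert score_distribution(m).total_mass == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        pc = float(rng.choice([0.0, 0.01, 0.5]))
        m = MotifModel(f"m{seed}", rng.dirichlet([0.4] * 4, size=k),
                       pseudocount=pc)
        dist = score_distribution(m)
        oracle = enumerate_pwm(m.pfm, m.background, pc, DEFAULT_BIN_WIDTH)
        got = {
            int(round(score / DEFAULT_BIN_WIDTH)): p
            for score, p in dist.items()
        }
        assert set(got) == set(oracle)
        for idx in oracle:
            assert got[idx] == pytest.approx(oracle[idx], abs=1e-12)
            assert dist.sf_index(idx) == pytest.approx(
                pwm_sf(oracle, idx), abs=1e-12
            )

    def test_invalid_bin_width(self, gc_motif):
        with pytest.raises(ValueError):
            score_distribution(gc_motif, bin_width=0)


class TestSitePvalue:
    def test_minimum_score_has_pvalue_one(self):
        m = random_motif(5, 0.5, seed=3)
        dist = score_distribution(m)
        assert site_pvalue(m, dist.min_index * dist.bin_width, dist) == \
            pytest.approx(1.0, abs=1e-9)

    def test_gc_consensus_pvalue(self, gc_motif):
        assert site_pvalue(gc_motif, 4.0) == pytest.approx(0.0625)

    def test_above_maximum_is_zero(self, gc_motif):
        assert site_pvalue(gc_motif, 4.1) == 0.0

    def test_monotone_non_increasing_in_score(self):
        m = random_motif(6, 0.5, seed=4)
        dist = score_distribution(m)
        scores = np.linspace(dist.min_index, dist.max_index, 50) * dist.bin_width
        ps = [site_pvalue(m, s, dist) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_gc_window_found_at_loose_cutoff(self, gc_motif):
        t = NamedSequence("t", "AAGCAA")
        sites = scan_rbp(t, gc_motif, 0.0625)
        assert [(s.start, s.end) for s in sites] == [(2, 4)]
        assert sites[0].pvalue == pytest.approx(0.0625)

    def test_gc_window_rejected_at_strict_cutoff(self, gc_motif):
        t = NamedSequence("t", "AAGCAA")
        assert scan_rbp(t, gc_motif, 0.01) == []

    def test_transcript_shorter_than_motif(self, gc_motif, caplog):
        m = random_motif(8, 0.5, seed=1)
        assert scan_rbp(NamedSequence("t", "ACG"), m, 0.5) == []

    def test_site_count_monotone_in_cutoff(self, rng):
        t = NamedSequence("t", random_rna(rng, 2000))
        m = random_motif(7, 0.3, seed=8)
        counts = [len(scan_rbp(t, m, c)) for c in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_window_rescoring(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_rna(rng, int(rng.integers(50, 400)))
        m = MotifModel(
            "m", rng.dirichlet([0.4] * 4, size=int(rng.integers(3, 9)))
        )
        scanner = PWMScanner(m)
        codes = encode(t)
        assert list(scanner.window_scores(codes)) == naive_window_scan(
            codes, scanner.lodds_q
        )
        cutoff = 0.05
        hits = scan_rbp(NamedSequence("t", t), m, cutoff)
        naive = [
            i
            for i, s in enumerate(naive_window_scan(codes, scanner.lodds_q))
            if scanner.dist.sf_index(s) <= cutoff
        ]
        assert [h.start for h in hits] == naive

    def test_triple_consensus_repeat_recovers_three_hits(self):
        m = random_motif(6, 0.05, seed=6)
        word = m.consensus
        t = NamedSequence("t", word * 3)
        hits = scan_rbp(t, m, 0.01)
        starts = {h.start for h in hits}
        assert {0, 6, 12} <= starts

    def test_hit_rate_matches_background_expectation(self, rng):
        """On i.i.d. sequence the hit count is Poisson around (L-k+1)*sf."""
        t = NamedSequence("t", random_rna(rng, 30_000))
        m = random_motif(8, 1.0, seed=42)  # smooth score distribution
        cutoff = 0.05
        scanner = PWMScanner(m)
        attained = scanner.dist.sf_index(scanner.dist.threshold_index(cutoff))
        assert attained <= cutoff
        mean = (len(t) - m.k + 1) * attained
        n = len(scan_rbp(t, m, cutoff))
        assert abs(n - mean) <= 3 * math.sqrt(mean)
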