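import itertools

import numpy as np
import pytest

from chromaproteo import motifscan
from chromaproteo.motifscan import (PWM, MotifHit, ScoreTable, UnsupportedAlphabetError,
                                    build_pwm, classify_opr, read_meme_motif, scan,
                                    score_pvalue_table, write_meme_motif)
from chromaproteo.quantio import AMINO_ACIDS, FormatError
from chromaproteo.synthetic import OPR_CONSENSUS, opr_pwm


class TestBuildPwm:
    def test_single_instance_indicator(self):
        pwm = build_pwm(["ACDE"], pseudocount=1e-9)
        for i, r in enumerate("ACDE"):
            assert pwm.probs[i, AMINO_ACIDS.index(r)] == pytest.approx(1.0)

    def test_two_instances_split_evenly(self):
        pwm = build_pwm(["AAAA", "CCCC"], pseudocount=1e-9)
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert np.allclose(pwm.probs[:, a], 0.5) and np.allclose(pwm.probs[:, c], 0.5)

    def test_pseudocount_formula(self):
        pwm = build_pwm(["A"], pseudocount=0.1)
        a = AMINO_ACIDS.index("A")
        assert pwm.probs[0, a] == pytest.approx((1 + 0.1 * 0.05) / 1.1)
        assert pwm.probs[0, AMINO_ACIDS.index("C")] == pytest.approx(0.1 * 0.05 / 1.1)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACDE", "ACDEF"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])


class TestMemeFormat:
    def test_roundtrip(self, tmp_path):
        pwms = [opr_pwm(), build_pwm(["ACD", "ACD", "AGD"], pseudocount=0.1)]
        pwms[1].name = "mini"
        write_meme_motif(pwms, tmp_path / "m.meme")
        back = read_meme_motif(tmp_path / "m.meme")
        assert [p.name for p in back] == ["OPR38", "mini"]
        assert back[0].length == 38 and back[1].length == 3
        assert np.allclose(back[0].probs, pwms[0].probs, atol=1e-5)
        assert np.allclose(back[0].probs.sum(axis=1), 1.0, atol=1e-12)

    def test_dna_alphabet_rejected(self, tmp_path):
        (tmp_path / "dna.meme").write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF m1\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            "0.25 0.25 0.25 0.25\n0.25 0.25 0.25 0.25\n")
        with pytest.raises(UnsupportedAlphabetError):
            read_meme_motif(tmp_path / "dna.meme")

    def test_bad_row_sum_rejected(self, tmp_path):
        rows = ["0.05"] * 16  # sums to 0.8
        (tmp_path / "bad.meme").write_text(
            "MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\nMOTIF m1\n"
            "letter-probability matrix: alength= 20 w= 1\n"
            + " ".join(["0.05"] * 20).replace("0.05", "0.04", 5) + "\n")
        with pytest.raises(FormatError, match="sums to"):
            read_meme_motif(tmp_path / "bad.meme")

    def test_not_meme_rejected(self, tmp_path):
        (tmp_path / "x.txt").write_text("hello\n")
        with pytest.raises(FormatError):
            read_meme_motif(tmp_path / "x.txt")


def brute_force_pvalues(pwm, granularity=1e-3):
    """Null tail probabilities by full enumeration of all 20^L words.

    Returns (unique integer scores descending, P(score >= s) for each, table).
    """
    table = ScoreTable(pwm, granularity)
    L = pwm.length
    grids = np.meshgrid(*[np.arange(20)] * L, indexing="ij")
    scores = sum(table.int_scores[i][g] for i, g in enumerate(grids)).ravel()
    weights = np.ones_like(scores, dtype=float)
    for i, g in enumerate(grids):
        weights *= pwm.background[g.ravel()]
    uniq, inv = np.unique(scores, return_inverse=True)
    mass = np.bincount(inv, weights=weights)
    uniq, mass = uniq[::-1], mass[::-1]  # descending scores
    return uniq, np.cumsum(mass), table


class TestScoreTable:
    def test_length_one_best_residue(self):
        probs = np.full((1, 20), 0.02 / 19)
        probs[0, 0] = 0.98
        table = ScoreTable(PWM(probs=probs))
        assert table.pvalue_int(table.max_int) == pytest.approx(0.05)

    def test_minimum_score_has_p_one(self):
        table = ScoreTable(opr_pwm())
        assert table.pvalue_int(table.offset) == pytest.approx(1.0)
        assert table.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_monotone_nonincreasing(self):
        table = ScoreTable(build_pwm(["ACD", "AGD", "ACE"], pseudocount=0.2))
        ps = [table.pvalue_int(s) for s in range(table.offset, table.max_int + 1)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_dp_matches_brute_force_dipeptides(self):
        pwm = build_pwm(["AC", "AD", "LC"], pseudocount=0.3)
        scores, tail, table = brute_force_pvalues(pwm)
        # every one of the 400 dipeptide scores must get the enumerated tail p
        for s, p_brute in zip(scores, tail):
            assert table.pvalue_int(int(s)) == pytest.approx(p_brute, rel=1e-9)

    def test_ten_forced_positions_consensus_p(self):
        # an indicator-style PWM constraining 10 positions: consensus p = 20^-10,
        # matching the 10 fully conserved letters of the OPR repeat motif
        assert sum(1 for r in OPR_CONSENSUS if r != "x") == 10
        probs = np.full((10, 20), 0.02 / 19)
        probs[:, 3] = 0.98
        table = ScoreTable(PWM(probs=probs))
        assert table.pvalue_int(table.max_int) == pytest.approx(20.0 ** -10, rel=1e-9)

    def test_bad_granularity(self):
        with pytest.raises(ValueError):
            ScoreTable(opr_pwm(), granularity=0)


class TestScan:
    def test_planted_consensus_found(self):
        pwm = opr_pwm()
        table = score_pvalue_table(pwm)
        consensus = "".join("P" if r == "x" else r for r in OPR_CONSENSUS)
        seq = "N" * 9 + consensus.replace("x", "") + "N" * (200 - 9 - 38)
        hits = scan(seq, pwm, p_threshold=1e-10, table=table, protein_id="P1")
        assert any(h.start == 10 and h.pvalue < 1e-10 for h in hits)

    def test_sequence_shorter_than_pwm(self):
        assert scan("MKV", opr_pwm()) == []

    def test_hit_rate_calibrated(self, rng):
        # uniform-background sequences: per-position hit rate at threshold 1e-3
        # must sit within 3 binomial SD of 1e-3
        pwm = build_pwm(["WYWYW", "WYWYA", "WFWYW"], pseudocount=0.5)
        table = score_pvalue_table(pwm)
        n_pos = 0
        n_hit = 0
        for _ in range(300):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=400))
            hits = scan(seq, pwm, 1e-3, table)
            n_pos += 400 - pwm.length + 1
            n_hit += len(hits)
        rate = n_hit / n_pos
        sd = (1e-3 * (1 - 1e-3) / n_pos) ** 0.5
        assert abs(rate - 1e-3) < 3 * sd + 1e-5  # +granularity slack at the cut

    def test_no_reverse_scanning(self):
        # proteins have no strands: a hit at the start of seq must not imply
        # one in the reversed sequence
        pwm = opr_pwm()
        table = score_pvalue_table(pwm)
        consensus = "".join("A" if r == "x" else r for r in OPR_CONSENSUS)
        seq = consensus + "N" * 100
        fwd = scan(seq, pwm, 1e-10, table)
        rev = scan(seq[::-1], pwm, 1e-10, table)
        assert fwd and not rev


class TestClassifyOpr:
    def _hits(self, pvals, spacing=38):
        return [MotifHit("P", 1 + i * spacing, 40.0, p) for i, p in enumerate(pvals)]

    def test_five_weak_repeats_is_candidate(self):
        rec = classify_opr(self._hits([1e-11] * 5))
        assert rec.is_candidate and rec.n_weak == 5 and rec.n_strong == 0

    def test_single_strong_repeat_is_candidate(self):
        rec = classify_opr(self._hits([1e-21]))
        assert rec.is_candidate and rec.n_strong == 1

    def test_four_weak_not_candidate(self):
        rec = classify_opr(self._hits([1e-11] * 4))
        assert not rec.is_candidate

    def test_overlapping_hits_collapsed_greedily(self):
        hits = [MotifHit("P", 1, 40.0, 1e-12), MotifHit("P", 10, 39.0, 1e-11),
                MotifHit("P", 40, 41.0, 1e-13)]
        rec = classify_opr(hits)
        assert [h.start for h in rec.hits] == [1, 40]  # the p=1e-11 overlap is dropped
        assert rec.n_weak == 2

    def test_counts_nested(self):
        rec = classify_opr(self._hits([1e-21, 1e-11, 1e-5]))
        assert rec.n_strong <= rec.n_weak <= len(rec.hits)
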