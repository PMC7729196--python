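import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaproteo import seqfeatures
from chromaproteo.quantio import AMINO_ACIDS, ProteinMeta, TopologyAnnotation
from chromaproteo.seqfeatures import (FAUCHERE_PLISKA, HelixWheelParams,
                                      amphipathic_scan, classify_group1,
                                      classify_orphan, count_tmh, find_cys_motifs,
                                      find_gas_xxx_gas, mean_hydrophobic_moment,
                                      net_charge, predict_tmh_fallback,
                                      small_fraction)


def moment_oracle(segment, delta=100.0, scale=FAUCHERE_PLISKA):
    """Independent complex-arithmetic hydrophobic-moment computation."""
    z = sum(scale[r] * cmath.exp(1j * math.radians(delta) * n)
            for n, r in enumerate(segment))
    return abs(z) / len(segment)


class TestFallbackPredictor:
    def test_poly_ile_stretch_detected(self):
        seq = "KKKK" + "I" * 19 + "KKKK"
        ann = predict_tmh_fallback(seq)
        assert len(ann.segments) == 1
        start, end = ann.segments[0]
        assert start <= 5 and end >= 23  # covers the hydrophobic core

    def test_polar_sequence_has_no_tmh(self):
        assert predict_tmh_fallback("K" * 30).segments == []

    def test_two_separated_runs_give_two_segments(self):
        seq = "L" * 19 + "N" * 25 + "L" * 19
        ann = predict_tmh_fallback(seq)
        assert len(ann.segments) == 2
        (s1, e1), (s2, e2) = ann.segments
        assert s1 <= 1 and e1 < s2 and e2 >= len(seq) - 1

    def test_short_sequence_empty(self):
        assert predict_tmh_fallback("MKV").segments == []

    def test_source_is_fallback(self):
        assert predict_tmh_fallback("L" * 30).source == "fallback"


class TestCountTmh:
    def test_zero(self):
        assert count_tmh(TopologyAnnotation("P", [])) == 0

    def test_crtp_exclusion(self):
        ann = TopologyAnnotation("P", [(5, 25)])
        assert count_tmh(ann, crtp_span=(1, 30)) == 0

    def test_transporter_like(self):
        ann = TopologyAnnotation("P", [(5, 25), (40, 60), (70, 90), (100, 120)])
        assert count_tmh(ann) == 4
        assert seqfeatures.is_transporter_like(ann)
        assert seqfeatures.is_multi_spanning(ann)


class TestResiduePrimitives:
    @pytest.mark.parametrize("seq, charge", [("KRDE", 0), ("MDD", -2), ("HHKK", 2)])
    def test_net_charge(self, seq, charge):
        assert net_charge(seq) == charge

    @pytest.mark.parametrize("seq, frac", [("GASGAS", 1.0), ("LLLLGA", 1 / 3), ("LLLLLL", 0.0)])
    def test_small_fraction(self, seq, frac):
        assert small_fraction(seq) == pytest.approx(frac)

    @pytest.mark.parametrize("seq, starts", [
        ("GLLLA", [1]), ("GLLLALLLS", [1, 5]), ("LLLLLLLL", []), ("GAS", [])])
    def test_gas_xxx_gas(self, seq, starts):
        assert find_gas_xxx_gas(seq) == starts

    @pytest.mark.parametrize("seq, expected", [
        ("CPKCG", {"CxxC": 1, "CxxxxC": 0, "CPxCG": 1}),
        ("CAAAAC", {"CxxC": 0, "CxxxxC": 1, "CPxCG": 0}),
        ("CCCCCC", {"CxxC": 3, "CxxxxC": 1, "CPxCG": 0}),
    ])
    def test_cys_motifs(self, seq, expected):
        assert find_cys_motifs(seq) == expected

    def test_empty_inputs_rejected(self):
        for fn in (net_charge, small_fraction, find_cys_motifs):
            with pytest.raises(ValueError):
                fn("")


class TestHydrophobicMoment:
    @pytest.mark.parametrize("residue", list(AMINO_ACIDS))
    def test_homopolymer_vanishes_at_full_turns(self, residue):
        # 18 residues x 100 deg = 5 full turns: the geometric sum cancels
        assert mean_hydrophobic_moment(residue * 18) < 1e-12

    def test_single_residue_window(self):
        p = HelixWheelParams(window=1)
        assert mean_hydrophobic_moment("W", p) == pytest.approx(abs(FAUCHERE_PLISKA["W"]))

    def test_matches_complex_oracle(self):
        seg = "LKKLLKKLLKKLLKKLLK"
        assert mean_hydrophobic_moment(seg) == pytest.approx(moment_oracle(seg), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seg=st.text(alphabet=AMINO_ACIDS, min_size=18, max_size=18),
           phase=st.floats(min_value=0, max_value=360))
    def test_phase_rotation_invariance(self, seg, phase):
        # adding a constant phase to every residue leaves the magnitude fixed
        z = sum(FAUCHERE_PLISKA[r] * cmath.exp(1j * math.radians(100 * n + phase))
                for n, r in enumerate(seg))
        assert abs(z) / 18 == pytest.approx(mean_hydrophobic_moment(seg), abs=1e-9)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            mean_hydrophobic_moment("LK")

    def test_amphipathic_helix_scores_high(self):
        # ideal periodicity: hydrophobic face vs charged face
        helix = "".join("L" if (100 * n) % 360 < 90 or (100 * n) % 360 > 270 else "K"
                        for n in range(18))
        mu, amphi = amphipathic_scan(helix)
        assert mu >= 0.35 and amphi

    def test_hydrophobic_window_not_amphipathic(self):
        mu, amphi = amphipathic_scan("L" * 18)
        assert not amphi  # mean hydrophobicity exceeds h_max


def _group1_fixture(length=80):
    # TMH at (10, 32): 23 residues, 7 small (frac 0.304), midpoint 21 <= 53.3
    tmh = "LLGLLALLSLLGLLALLSLLGLL"
    assert len(tmh) == 23 and small_fraction(tmh) > 0.2
    nterm = "MDELSTQQN"  # net charge -2
    seq = (nterm + tmh).ljust(length, "N")
    return seq, TopologyAnnotation("P", [(10, 32)])


class TestClassifyGroup1:
    def test_positive_case(self):
        seq, ann = _group1_fixture()
        ok, ev = classify_group1(ProteinMeta("P", sequence=seq), ann)
        assert ok
        assert ev["nterm_net_charge"] == -2
        assert ev["small_frac_tmh"] == pytest.approx(7 / 23)

    def test_length_gate(self):
        seq, ann = _group1_fixture(length=120)
        assert not classify_group1(ProteinMeta("P", sequence=seq), ann)[0]

    def test_charge_gate(self):
        seq, ann = _group1_fixture()
        seq = "MKKLS" + seq[5:]  # N-terminus now +2
        assert not classify_group1(ProteinMeta("P", sequence=seq), ann)[0]

    def test_midpoint_gate(self):
        tmh = "LLGLLALLSLLGLLALLSLLGLL"
        seq = ("N" * 50 + tmh).ljust(80, "N")  # midpoint 61.5 > 53.3
        ann = TopologyAnnotation("P", [(51, 73)])
        assert not classify_group1(ProteinMeta("P", sequence=seq), ann)[0]

    def test_requires_single_tmh(self):
        seq, _ = _group1_fixture()
        ann = TopologyAnnotation("P", [(10, 32), (50, 70)])
        assert not classify_group1(ProteinMeta("P", sequence=seq), ann)[0]


class TestClassifyOrphan:
    def test_group1_precedence_over_cys(self):
        seq, ann = _group1_fixture()
        seq = seq[:70] + "CAAC" + seq[74:]  # add one CxxC
        call = classify_orphan(ProteinMeta("P", sequence=seq), ann)
        assert call.group == "group1"

    def test_motif_hit_gives_group3(self):
        meta = ProteinMeta("P", sequence="N" * 60)
        call = classify_orphan(meta, TopologyAnnotation("P", []),
                               group2_motif_p=None, group3_motif_p=1e-6)
        assert call.group == "group3"

    def test_group2_beats_group3(self):
        meta = ProteinMeta("P", sequence="N" * 60)
        call = classify_orphan(meta, TopologyAnnotation("P", []),
                               group2_motif_p=1e-8, group3_motif_p=1e-9)
        assert call.group == "group2"

    def test_weak_motif_p_not_enough(self):
        meta = ProteinMeta("P", sequence="N" * 60)
        call = classify_orphan(meta, TopologyAnnotation("P", []),
                               group2_motif_p=1e-3, group3_motif_p=None)
        assert call.group == "other"

    def test_cxxc_gives_group4(self):
        meta = ProteinMeta("P", sequence="N" * 30 + "CAAC" + "N" * 30)
        call = classify_orphan(meta, TopologyAnnotation("P", []))
        assert call.group == "group4"
        assert call.evidence["cxxc_count"] == 1

    def test_three_cxxc_not_group4(self):
        meta = ProteinMeta("P", sequence="CAACNNNCAACNNNCAACNNN" + "N" * 30)
        call = classify_orphan(meta, TopologyAnnotation("P", []))
        assert call.group != "group4"

    def test_featureless_is_other(self):
        meta = ProteinMeta("P", sequence="N" * 60)
        call = classify_orphan(meta, TopologyAnnotation("P", []))
        assert call.group == "other"
        assert call.evidence["max_mean_hydrophobic_moment"] < 0.35
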