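"""Sequence-derived classifiers for short chromatophore import candidates.

Covers transmembrane-helix (TMH) counting with a Kyte–Doolittle hydropathy
fallback predictor, the transporter (>=4 TMHs) and multi-spanning (>1 TMH)
criteria, the four orphan groups of short (<90 aa) import candidates:

  group 1   one small-residue-rich TMH in the N-terminal 2/3, net N-terminal
            charge <= 0, usually carrying a (small)xxx(small) motif
  group 2/3 a conserved sequence motif (PWM scan p < 1e-4)
  group 4   one or two CxxC mini-motifs (often CPxCG)
  amphipathic  a predicted amphipathic helix (high hydrophobic moment at
            moderate mean hydrophobicity, no TMH)

plus the primitives they share: net charge (K/R = +1, D/E = −1, H neutral,
termini ignored), small-residue (G/A/S) fraction, overlapping Cys-motif
counts, and the helical-wheel hydrophobic moment on the Fauchère–Pliska
scale at 100° per residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .quantio import ProteinMeta, TopologyAnnotation

SMALL_RESIDUES = frozenset("GAS")

#: Fauchère & Pliska (1983) octanol/water hydrophobicity, the HeliQuest scale.
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

GROUPS = ("group1", "group2", "group3", "group4", "amphipathic", "other")
SHORT_PROTEIN_MAX = 90  # "short" import candidates are < 90 aa
MOTIF_P_THRESHOLD = 1e-4  # FIMO default report threshold


@dataclass(frozen=True)
class HelixWheelParams:
    """Helical-wheel projection parameters.

    ``delta`` is the rotation per residue (100° for an ideal α-helix),
    ``window`` the projected segment length, ``mu_threshold`` the minimum
    hydrophobic moment and ``h_max`` the maximum mean hydrophobicity for an
    amphipathic call (an out-and-out hydrophobic window is a TMH candidate,
    not an amphipathic one).
    """

    scale: dict = field(default_factory=lambda: dict(FAUCHERE_PLISKA))
    delta: float = 100.0
    window: int = 18
    mu_threshold: float = 0.35
    h_max: float = 0.6

    def __post_init__(self) -> None:
        if set(self.scale) < set(FAUCHERE_PLISKA):
            raise ValueError("scale must cover all 20 residues")
        if not (0 < self.delta < 360):
            raise ValueError("delta must be in (0, 360)")


@dataclass
class GroupCall:
    protein_id: str
    group: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def predict_tmh_fallback(seq: str, window: int = 19, cutoff: float = 1.6,
                         min_len: int = 15) -> TopologyAnnotation:
    """Internal hydropathy-based TMH predictor (documented stand-in).

    Kyte–Doolittle hydropathy is averaged over a sliding window; maximal
    runs of window centers with mean above ``cutoff`` are expanded by half a
    window on each side, overlapping segments merged, and segments shorter
    than ``min_len`` discarded.  Parsed external predictions always take
    precedence over this fallback.
    """
    if len(seq) < window:
        return TopologyAnnotation("", [], source="fallback")
    vals = np.array([KYTE_DOOLITTLE[r] for r in seq])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")  # means[i] = window starting at i
    half = window // 2
    hot = means > cutoff  # index i == center i + half (0-based)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            # centers i+half .. j+half, expanded +-half, converted to 1-based
            start, end = i + 1, j + 2 * half + 1
            if segments and start <= segments[-1][1]:
                segments[-1] = (segments[-1][0], end)
            else:
                segments.append((start, end))
            i = j + 1
        else:
            i += 1
    segments = [s for s in segments if s[1] - s[0] + 1 >= min_len]
    return TopologyAnnotation("", segments, source="fallback")


def count_tmh(annot: TopologyAnnotation, crtp_span: tuple[int, int] | None = None) -> int:
    """Number of TMH segments outside the chromatophore transit peptide span."""
    if crtp_span is None:
        return annot.tmh_count
    cs, ce = crtp_span
    return sum(1 for s, e in annot.segments if e < cs or s > ce)


def is_multi_spanning(annot: TopologyAnnotation, crtp_span=None) -> bool:
    return count_tmh(annot, crtp_span) > 1


def is_transporter_like(annot: TopologyAnnotation, crtp_span=None) -> bool:
    """>= 4 TMHs, the classical polytopic-transporter regime."""
    return count_tmh(annot, crtp_span) >= 4


def net_charge(segment: str) -> int:
    """Integer net charge: +1 per K/R, −1 per D/E; His and termini neutral."""
    if not segment:
        raise ValueError("empty segment")
    return sum(+1 if r in "KR" else -1 if r in "DE" else 0 for r in segment)


def small_fraction(segment: str) -> float:
    """Fraction of small residues (Gly, Ala, Ser)."""
    if not segment:
        raise ValueError("empty segment")
    return sum(r in SMALL_RESIDUES for r in segment) / len(segment)


def find_gas_xxx_gas(segment: str) -> list[int]:
    """1-based start positions of (small)xxx(small), overlapping allowed."""
    return [
        i + 1
        for i in range(len(segment) - 4)
        if segment[i] in SMALL_RESIDUES and segment[i + 4] in SMALL_RESIDUES
    ]


def find_cys_motifs(seq: str) -> dict[str, int]:
    """Overlapping counts of the CxxC, CxxxxC and CPxCG mini-motifs."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {"CxxC": 0, "CxxxxC": 0, "CPxCG": 0}
    n = len(seq)
    for i in range(n):
        if seq[i] != "C":
            continue
        if i + 3 < n and seq[i + 3] == "C":
            counts["CxxC"] += 1
        if i + 5 < n and seq[i + 5] == "C":
            counts["CxxxxC"] += 1
        if i + 4 < n and seq[i + 1] == "P" and seq[i + 3] == "C" and seq[i + 4] == "G":
            counts["CPxCG"] += 1
    return counts


def mean_hydrophobic_moment(segment: str, p: HelixWheelParams = HelixWheelParams()) -> float:
    """Per-residue hydrophobic moment μH of a window-length segment.

    μH = |Σ_n H_n e^{i n δ}| / N with residues placed δ degrees apart on the
    helical wheel; 0 for any homopolymer whenever N·δ is a multiple of 360°.
    """
    if len(segment) != p.window:
        raise ValueError(f"segment length {len(segment)} != window {p.window}")
    try:
        h = np.array([p.scale[r] for r in segment])
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in hydrophobicity scale") from None
    ang = np.deg2rad(p.delta) * np.arange(len(segment))
    return float(np.hypot((h * np.sin(ang)).sum(), (h * np.cos(ang)).sum()) / len(segment))


def amphipathic_scan(seq: str, p: HelixWheelParams = HelixWheelParams()) -> tuple[float, bool]:
    """Slide the helical-wheel window along the sequence.

    Returns (max μH over all windows, whether any window is amphipathic,
    i.e. μH >= mu_threshold with mean hydrophobicity <= h_max).
    """
    if len(seq) < p.window:
        return 0.0, False
    best = 0.0
    amphipathic = False
    for i in range(len(seq) - p.window + 1):
        win = seq[i : i + p.window]
        mu = mean_hydrophobic_moment(win, p)
        best = max(best, mu)
        if mu >= p.mu_threshold:
            mean_h = float(np.mean([p.scale[r] for r in win]))
            if mean_h <= p.h_max:
                amphipathic = True
    return best, amphipathic


def classify_group1(meta: ProteinMeta, annot: TopologyAnnotation) -> tuple[bool, dict]:
    """Group-1 rule for short single-TMH import candidates.

    True iff length < 90, exactly one TMH whose midpoint lies in the
    N-terminal 2/3, the TMH is > 20% small residues, and the region N-terminal
    of the TMH has net charge <= 0 (an empty region counts as charge 0).
    """
    if meta.sequence is None:
        raise ValueError(f"{meta.protein_id}: sequence required")
    seq = meta.sequence
    ev: dict = {"tmh_count": annot.tmh_count}
    if annot.tmh_count != 1:
        return False, ev
    start, end = annot.segments[0]
    midpoint = (start + end) / 2.0
    tmh_seq = seq[start - 1 : end]
    nterm = seq[: start - 1]
    ev.update(
        tmh_mid_fraction=midpoint / len(seq),
        small_frac_tmh=small_fraction(tmh_seq),
        nterm_net_charge=net_charge(nterm) if nterm else 0,
        gas_xxx_gas_count=len(find_gas_xxx_gas(tmh_seq)),
    )
    ok = (
        len(seq) < SHORT_PROTEIN_MAX
        and midpoint <= (2.0 / 3.0) * len(seq)
        and ev["small_frac_tmh"] > 0.20
        and ev["nterm_net_charge"] <= 0
    )
    return ok, ev


def classify_orphan(meta: ProteinMeta, annot: TopologyAnnotation,
                    group2_motif_p: float | None = None,
                    group3_motif_p: float | None = None,
                    p: HelixWheelParams = HelixWheelParams()) -> GroupCall:
    """Assign a short orphan import candidate to its sequence-feature group.

    Precedence: group1 > group2 > group3 > group4 > amphipathic > other.
    Group 2/3 require a motif-scan best p below the FIMO default report
    threshold (1e-4); group 4 requires exactly one or two CxxC motifs; the
    amphipathic call requires no TMH.
    """
    if meta.sequence is None:
        raise ValueError(f"{meta.protein_id}: sequence required")
    seq = meta.sequence
    is_g1, ev = classify_group1(meta, annot)
    cys = find_cys_motifs(seq)
    max_mu, is_amphi = amphipathic_scan(seq, p)
    ev.update(
        cxxc_count=cys["CxxC"],
        cxxxxc_count=cys["CxxxxC"],
        cpxcg_count=cys["CPxCG"],
        group2_motif_p=group2_motif_p,
        group3_motif_p=group3_motif_p,
        max_mean_hydrophobic_moment=max_mu,
    )
    if is_g1:
        group = "group1"
    elif group2_motif_p is not None and group2_motif_p < MOTIF_P_THRESHOLD:
        group = "group2"
    elif group3_motif_p is not None and group3_motif_p < MOTIF_P_THRESHOLD:
        group = "group3"
    elif cys["CxxC"] in (1, 2):
        group = "group4"
    elif annot.tmh_count == 0 and is_amphi:
        group = "amphipathic"
    else:
        group = "other"
    return GroupCall(meta.protein_id, group, ev)
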