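"""Position-weight-matrix scanning with exact p-values, and the OPR rule.

A PWM over the 20-letter amino-acid alphabet is scored as log2 odds against
a background composition.  Scores are discretized (default 1e-3 bits) and
the exact null distribution of the total window score is obtained by
position-wise convolution (dynamic programming), giving an exact p-value
P(score >= s) for every attainable score — the same construction FIMO uses.

Octotrico peptide repeat (OPR) proteins carry tandem copies of a degenerate
38-aa motif; a protein is an OPR candidate when it has at least five
non-overlapping repeats at p < 1e-10 or at least one at p < 1e-20.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantio import AMINO_ACIDS, FormatError

_AA_INDEX = {r: i for i, r in enumerate(AMINO_ACIDS)}

WEAK_P = 1e-10
STRONG_P = 1e-20
MIN_WEAK_REPEATS = 5


class UnsupportedAlphabetError(FormatError):
    """Motif file alphabet is not the 20-letter protein alphabet."""


@dataclass
class PWM:
    """Probability matrix (length × 20, rows sum to 1) with background."""

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must be length x 20")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.probs <= 0).any() or (self.background <= 0).any():
            raise ValueError("probabilities must be strictly positive (apply a pseudocount)")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """Per-position log2(prob/background) score matrix (bits)."""
        return np.log2(self.probs / self.background[None, :])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.probs.argmax(axis=1))


@dataclass
class MotifHit:
    protein_id: str
    start: int  # 1-based
    score: float  # bits
    pvalue: float


@dataclass
class OPRRecord:
    protein_id: str
    hits: list[MotifHit]
    n_weak: int
    n_strong: int
    is_candidate: bool


def build_pwm(instances: list[str], pseudocount: float = 0.1,
              background: np.ndarray | None = None, name: str = "motif") -> PWM:
    """Count matrix from aligned equal-length instances, with a
    background-weighted pseudocount:

        probs[i][r] = (count(i, r) + pseudocount * background[r]) / (n + pseudocount)
    """
    if not instances:
        raise ValueError("at least one instance required")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("instances must all have the same length")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)
    counts = np.zeros((length, 20))
    for s in instances:
        for i, r in enumerate(s):
            if r not in _AA_INDEX:
                raise ValueError(f"non-canonical residue {r!r} in motif instance")
            counts[i, _AA_INDEX[r]] += 1
    n = len(instances)
    probs = (counts + pseudocount * background[None, :]) / (n + pseudocount)
    return PWM(probs=probs, background=background, pseudocount=pseudocount, name=name)


_MEME_HEADER_RE = re.compile(
    r"letter-probability matrix:.*?alength=\s*(\d+).*?w=\s*(\d+)", re.DOTALL
)


def read_meme_motif(path: str | Path) -> list[PWM]:
    """Parse MEME minimal motif format (protein alphabet) into PWMs.

    Rows are validated to sum to 1 (tolerance 1e-3, then renormalized);
    a DNA/RNA alphabet raises :class:`UnsupportedAlphabetError`.
    """
    text = Path(path).read_text()
    if "MEME version" not in text:
        raise FormatError("not a MEME minimal-format file (no 'MEME version' line)")
    alpha_m = re.search(r"^ALPHABET=\s*(\S+)", text, re.MULTILINE)
    if alpha_m:
        alphabet = alpha_m.group(1)
        if set(alphabet) != set(AMINO_ACIDS):
            raise UnsupportedAlphabetError(f"unsupported alphabet {alphabet!r}; protein required")
    else:
        alphabet = AMINO_ACIDS
    bg = np.full(20, 0.05)
    bg_m = re.search(r"Background letter frequencies.*?\n([\sA-Z0-9.eE+-]+?)\n\s*\n",
                     text + "\n\n", re.DOTALL)
    if bg_m:
        toks = bg_m.group(1).split()
        freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)}
        if set(freq) == set(AMINO_ACIDS):
            bg = np.array([freq[r] for r in AMINO_ACIDS])
            bg = bg / bg.sum()

    pwms = []
    blocks = re.split(r"^MOTIF\s+", text, flags=re.MULTILINE)[1:]
    for block in blocks:
        name = block.split()[0]
        m = _MEME_HEADER_RE.search(block)
        if not m:
            raise FormatError(f"motif {name!r}: no letter-probability matrix header")
        alength, width = int(m.group(1)), int(m.group(2))
        if alength != 20:
            raise UnsupportedAlphabetError(f"motif {name!r}: alength={alength}, protein requires 20")
        rest = block[m.end():]
        rest = rest[rest.find("\n") + 1:]  # drop the remainder of the header line
        lines = rest.strip().splitlines()
        rows = []
        for line in lines[:width]:
            vals = line.split()
            if len(vals) != alength:
                raise FormatError(f"motif {name!r}: matrix row with {len(vals)} values, expected {alength}")
            try:
                row = np.array([float(v) for v in vals])
            except ValueError:
                raise FormatError(f"motif {name!r}: non-numeric matrix entry") from None
            if abs(row.sum() - 1.0) > 1e-3:
                raise FormatError(f"motif {name!r}: matrix row sums to {row.sum():.4g}, not 1")
            rows.append(row / row.sum())
        if len(rows) != width:
            raise FormatError(f"motif {name!r}: expected {width} matrix rows, found {len(rows)}")
        probs = np.stack(rows)
        # map file alphabet order onto the canonical order
        order = [alphabet.index(r) for r in AMINO_ACIDS]
        probs = probs[:, order]
        probs = np.clip(probs, 1e-9, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        pwms.append(PWM(probs=probs, background=bg, name=name))
    if not pwms:
        raise FormatError("no MOTIF blocks found")
    return pwms


def write_meme_motif(pwms: list[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 5\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{r} {bg[i]:.6f}" for i, r in enumerate(AMINO_ACIDS)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {p.length} nsites= 20 E= 0\n")
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


class ScoreTable:
    """Exact null distribution of the window log-odds score.

    Per-position scores are rounded to integer multiples of ``granularity``
    (bits); the distribution of their sum under the background model is
    computed by convolution.  ``pvalue(score)`` returns P(score >= s); the
    discretization bound on any reported score is length × granularity / 2.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.pwm = pwm
        self.granularity = float(granularity)
        self.int_scores = np.rint(pwm.log_odds() / granularity).astype(np.int64)
        mins = self.int_scores.min(axis=1)
        maxs = self.int_scores.max(axis=1)
        self.offset = int(mins.sum())
        size = int((maxs - mins).sum()) + 1
        dist = np.zeros(1)
        dist[0] = 1.0
        for i in range(pwm.length):
            pos = np.zeros(int(maxs[i] - mins[i]) + 1)
            for r in range(20):
                pos[self.int_scores[i, r] - mins[i]] += pwm.background[r]
            dist = np.convolve(dist, pos)
        assert len(dist) == size
        self.total_mass = float(dist.sum())
        # tail[k] = P(int score >= offset + k)
        self.tail = np.cumsum(dist[::-1])[::-1]
        self.max_int = self.offset + size - 1

    def window_int_score(self, idx: np.ndarray) -> int:
        return int(self.int_scores[np.arange(self.pwm.length), idx].sum())

    def pvalue_int(self, s: int) -> float:
        if s <= self.offset:
            return 1.0
        if s > self.max_int:
            return 0.0
        return float(min(self.tail[s - self.offset], 1.0))

    def pvalue(self, score_bits: float) -> float:
        """P(window score >= score_bits) under the background model."""
        return self.pvalue_int(int(np.rint(score_bits / self.granularity)))


def score_pvalue_table(pwm: PWM, granularity: float = 1e-3) -> ScoreTable:
    return ScoreTable(pwm, granularity)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[r] for r in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


def scan(seq: str, pwm: PWM, p_threshold: float = 1e-4,
         table: ScoreTable | None = None, protein_id: str = "") -> list[MotifHit]:
    """Score every window of ``seq`` against the PWM; return positions with
    exact p-value <= threshold, sorted by position (1-based starts)."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    L = pwm.length
    if len(seq) < L:
        return []
    if table is None:
        table = ScoreTable(pwm)
    idx = encode(seq)
    n_win = len(seq) - L + 1
    # windowed sum of per-position integer scores, vectorized over windows
    per_pos = table.int_scores[np.arange(L)[None, :],
                               np.lib.stride_tricks.sliding_window_view(idx, L)]
    totals = per_pos.sum(axis=1)
    hits = []
    for i in range(n_win):
        p = table.pvalue_int(int(totals[i]))
        if p <= p_threshold:
            hits.append(MotifHit(protein_id, i + 1,
                                 float(totals[i] * table.granularity), p))
    return hits


def classify_opr(hits: list[MotifHit], motif_length: int = 38,
                 weak_p: float = WEAK_P, strong_p: float = STRONG_P,
                 min_weak: int = MIN_WEAK_REPEATS, protein_id: str = "") -> OPRRecord:
    """Apply the OPR candidate rule to one protein's 38-aa-motif hits.

    Non-overlapping repeats are selected greedily by ascending p-value;
    a candidate has >= ``min_weak`` repeats at p < weak_p and/or >= 1 repeat
    at p < strong_p.
    """
    chosen: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.pvalue, h.start)):
        if all(abs(hit.start - c.start) >= motif_length for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.start)
    n_weak = sum(1 for h in chosen if h.pvalue < weak_p)
    n_strong = sum(1 for h in chosen if h.pvalue < strong_p)
    pid = protein_id or (hits[0].protein_id if hits else "")
    return OPRRecord(pid, chosen, n_weak, n_strong,
                     is_candidate=(n_weak >= min_weak) or (n_strong >= 1))
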