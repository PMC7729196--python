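"""Synthetic proteomes and fraction-quantitation experiments with planted truth.

The generator emulates the study design the analysis assumes: two MS
experiments × three fractions (CM = chromatophore membranes, PM = whole-cell
membranes, CL = chromatophore lysate) × three replicates, lognormal protein
abundance, fraction-specific enrichment of chromatophore-localized proteins,
abundance-dependent (left-censored) missingness, and planted sequence
classes — multi-TM membrane proteins, the four groups of short orphan import
candidates, amphipathic shorts, and OPR repeat proteins built as
crTP + CR1 + k×(38-aa repeat) + CR2 + RAP.

Every planted feature is re-detectable by the matching analysis operation
(group-1 sequences are rejection-sampled against the fallback TMH predictor
itself), so the pipeline can be exercised end-to-end with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantio import AMINO_ACIDS, ProteinMeta, TopologyAnnotation, validate_quant_table
from . import motifscan, seqfeatures

CLASSES = (
    "ce_soluble", "ce_multitm",
    "ne_host_soluble", "ne_host_multitm",
    "ne_import_soluble",
    "ne_group1", "ne_group2", "ne_group3", "ne_group4",
    "ne_amphipathic", "ne_opr",
    "mito_contaminant",
)

CHROMATOPHORE_CLASSES = frozenset({
    "ce_soluble", "ce_multitm", "ne_import_soluble",
    "ne_group1", "ne_group2", "ne_group3", "ne_group4",
    "ne_amphipathic", "ne_opr",
})
MEMBRANE_CLASSES = frozenset({"ce_multitm", "ne_host_multitm", "ne_group1"})

#: Residue composition of the non-membrane (soluble/cytosolic) background.
#: Deliberately leaner in Ile/Leu/Val/Phe than whole-proteome averages, as
#: soluble proteins are: the hydropathy fallback then predicts spurious TMHs
#: in well under 1% of short random sequences (mean Kyte-Doolittle ~ -0.59).
BACKGROUND_COMPOSITION = {
    "A": 0.080, "C": 0.016, "D": 0.058, "E": 0.070, "F": 0.033,
    "G": 0.072, "H": 0.022, "I": 0.042, "K": 0.064, "L": 0.078,
    "M": 0.020, "N": 0.056, "P": 0.050, "Q": 0.046, "R": 0.052,
    "S": 0.080, "T": 0.065, "V": 0.056, "W": 0.010, "Y": 0.030,
}
_COMP_TOTAL = sum(BACKGROUND_COMPOSITION.values())
BACKGROUND_COMPOSITION = {r: v / _COMP_TOTAL for r, v in BACKGROUND_COMPOSITION.items()}

#: Most conserved residues of the 38-aa OPR repeat.
OPR_CONSENSUS = "xxxPxxxxLxxxxxxxxxxxxxFxxQxxxxxLNAxAKL"
#: Synthetic conserved motifs for orphan groups 2 and 3 (group 3 encompasses
#: the CxxxxC and CxxC mini-motifs, as the real one does).
GROUP2_CONSENSUS = "xxWLDxNHGxxKRPExxYQxIFxx"
GROUP3_CONSENSUS = "xCxxxxCxxCxxCxxWLNKxxFxxDG"

CRTP_LENGTH = 200
CR1_LENGTH = 105
CR2_LENGTH = 110
RAP_LENGTH = 60


def _consensus_pwm(consensus: str, conserved_prob: float = 0.9, name: str = "motif") -> motifscan.PWM:
    """PWM with ``conserved_prob`` on each consensus letter, uniform elsewhere."""
    probs = np.full((len(consensus), 20), 0.05)
    for i, r in enumerate(consensus):
        if r != "x":
            probs[i] = (1.0 - conserved_prob) / 19.0
            probs[i, AMINO_ACIDS.index(r)] = conserved_prob
    return motifscan.PWM(probs=probs, name=name)


def opr_pwm() -> motifscan.PWM:
    return _consensus_pwm(OPR_CONSENSUS, name="OPR38")


def group2_pwm() -> motifscan.PWM:
    return _consensus_pwm(GROUP2_CONSENSUS, name="group2")


def group3_pwm() -> motifscan.PWM:
    return _consensus_pwm(GROUP3_CONSENSUS, name="group3")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    ``enrich_cm_vs_pm`` is the median CM:PM fold of chromatophore-localized
    proteins, ``deplete_host`` the CM fold of host proteins,
    ``membrane_cm_vs_cl`` the extra CM:CL fold of membrane proteins in the
    carbonate-washed membrane fraction.  Detection is logistic in log10
    abundance (``detect_tau``/``detect_slope``); MS experiment 2 probes one
    decade-third deeper (3× sample load).  ``class_mix`` defaults to a mix
    derived from ``fraction_ce``.
    """

    n_proteins: int = 1000
    fraction_ce: float = 0.15
    class_mix: dict | None = None
    abundance_mu: float = 7.0
    abundance_sigma: float = 0.7
    enrich_cm_vs_pm: float = 5.0
    deplete_host: float = 0.2
    membrane_cm_vs_cl: float = 3.0
    detect_tau: float = 6.0
    detect_slope: float = 0.2
    cv: float = 0.25
    spc_rate: float = 1.0
    opr_k: int | None = None  # force the repeat count (default: uniform 2..13)
    seed: int = 0

    def resolved_mix(self) -> dict[str, float]:
        if self.class_mix is not None:
            mix = dict(self.class_mix)
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"class_mix sums to {total}, not 1")
            bad = set(mix) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown class(es) {sorted(bad)}")
            return mix
        # Minority-import composition: chromatophore-localized proteins stay a
        # modest share of total protein mass, so sum-normalization preserves
        # the planted CM:PM fold (normInt ratios are compositional).
        ce, ne = self.fraction_ce, 1.0 - self.fraction_ce
        return {
            "ce_soluble": ce * 0.72,
            "ce_multitm": ce * 0.28,
            "ne_host_soluble": ne * 0.766,
            "ne_host_multitm": ne * 0.12,
            "ne_import_soluble": ne * 0.04,
            "ne_group1": ne * 0.01,
            "ne_group2": ne * 0.01,
            "ne_group3": ne * 0.01,
            "ne_group4": ne * 0.01,
            "ne_amphipathic": ne * 0.01,
            "ne_opr": ne * 0.012,
            "mito_contaminant": ne * 0.012,
        }


def _class_counts(cfg: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_proteins over the class mix."""
    mix = cfg.resolved_mix()
    raw = {c: cfg.n_proteins * p for c, p in mix.items()}
    counts = {c: int(v) for c, v in raw.items()}
    short = cfg.n_proteins - sum(counts.values())
    for c, _ in sorted(raw.items(), key=lambda kv: kv[1] - int(kv[1]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def _draw_seq(rng: np.random.Generator, n: int, composition: dict[str, float] | None = None,
              exclude: str = "") -> str:
    comp = dict(composition or BACKGROUND_COMPOSITION)
    for r in exclude:
        comp.pop(r, None)
    letters = sorted(comp)
    p = np.array([comp[r] for r in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


_HYDROPHOBIC = "LIVFMA"
_HYDROPHOBIC_W = np.array([0.30, 0.22, 0.20, 0.12, 0.08, 0.08])
_POLAR = "DEKRNQSTGPHY"
_NEUTRAL_ACIDIC = "STNQGPADE"  # no K/R: net charge <= 0 guaranteed


def _draw_tmh(rng: np.random.Generator, n: int = 21) -> str:
    return "".join(rng.choice(list(_HYDROPHOBIC), size=n, p=_HYDROPHOBIC_W))


def _draw_polar(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_POLAR), size=n))


def _sample_pwm_instance(rng: np.random.Generator, consensus: str) -> str:
    """Planted motif instance: consensus letters fixed (full fidelity at the
    conserved positions), degenerate positions drawn from polar residues so a
    planted motif cannot double as a hydrophobic TMH stretch (the PWM's
    degenerate columns are uniform, so scan scores are unaffected)."""
    out = []
    for r in consensus:
        out.append(_draw_polar(rng, 1) if r == "x" else r)
    return "".join(out)


def _make_group1(rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """Short single-TMH protein satisfying every group-1 clause; validated
    against the fallback predictor and resampled on the rare miss."""
    for _ in range(200):
        length = int(rng.integers(55, 90))
        tmh_len = 21
        nterm_len = int(rng.integers(3, 12))
        cterm_len = length - nterm_len - tmh_len
        if cterm_len < 5:
            continue
        tmh = []
        for _ in range(tmh_len):
            if rng.random() < 0.35:
                tmh.append(rng.choice(list("GAS"), p=[0.4, 0.4, 0.2]))
            else:
                tmh.append(rng.choice(list("LIVF")))
        if rng.random() < 0.95:  # plant a (small)xxx(small) pair explicitly
            j = int(rng.integers(0, tmh_len - 4))
            small = list("GAS")
            tmh[j] = str(rng.choice(small))
            tmh[j + 4] = str(rng.choice(small))
        tmh = "".join(tmh)
        seq = _draw_seq(rng, nterm_len, exclude="KRC") + tmh + _draw_polar(rng, cterm_len)
        annot = seqfeatures.predict_tmh_fallback(seq)
        meta = ProteinMeta("tmp", sequence=seq)
        ok, _ = seqfeatures.classify_group1(meta, annot)
        if ok:
            return seq, annot.segments[0]
    raise RuntimeError("group-1 rejection sampling failed")  # pragma: no cover


def _make_multitm(rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    n_tmh = int(rng.integers(4, 13))
    parts = [_draw_polar(rng, int(rng.integers(25, 45)))]
    spans = []
    pos = len(parts[0])
    for _ in range(n_tmh):
        tmh = _draw_tmh(rng)
        spans.append((pos + 1, pos + len(tmh)))
        parts.append(tmh)
        pos += len(tmh)
        loop = _draw_polar(rng, int(rng.integers(30, 50)))
        parts.append(loop)
        pos += len(loop)
    return "".join(parts), spans


def _make_amphipathic(rng: np.random.Generator) -> str:
    """Polar short protein with a planted 18-residue amphipathic helix."""
    helix = []
    phase = float(rng.uniform(0, 360))
    for n in range(18):
        ang = (phase + 100.0 * n) % 360.0
        if ang < 90 or ang > 270:
            helix.append(rng.choice(list("LIF")))
        else:
            helix.append(rng.choice(list("KEQS")))
    length = int(rng.integers(50, 90))
    pre = int(rng.integers(0, length - 18))
    return (_draw_seq(rng, pre, exclude="C") + "".join(helix)
            + _draw_seq(rng, length - 18 - pre, exclude="C"))


def _make_group4(rng: np.random.Generator) -> str:
    length = int(rng.integers(45, 90))
    seq = list(_draw_seq(rng, length, exclude="C"))
    n_motifs = int(rng.integers(1, 3))
    starts = []
    for _ in range(n_motifs):
        for _ in range(50):
            s = int(rng.integers(0, length - 5))
            if all(abs(s - t) >= 7 for t in starts):  # >=7 so no spurious cross-motif CxxC
                starts.append(s)
                break
    for k, s in enumerate(starts):
        if k == 0 and rng.random() < 0.5:  # one of them is often CPxCG
            seq[s : s + 5] = list("CP" + _draw_seq(rng, 1, exclude="C") + "CG")
        else:
            seq[s] = "C"
            seq[s + 3] = "C"
            seq[s + 1 : s + 3] = list(_draw_seq(rng, 2, exclude="C"))
    return "".join(seq)


def generate_proteome(cfg: SimConfig):
    """Generate sequences, metadata and planted truth.

    Returns ``(records, truth, pwms)``: a list of :class:`ProteinMeta` with
    sequences and CE/NE encoding, a truth DataFrame (class, localization,
    membrane flag, planted TMH spans / motif start / repeat count, base
    abundance), and the generator's motif models keyed ``OPR38``/``group2``/
    ``group3``.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _class_counts(cfg)
    pwms = {"OPR38": opr_pwm(), "group2": group2_pwm(), "group3": group3_pwm()}
    # conserved blocks shared by all OPR proteins of this proteome
    crtp = _draw_seq(rng, CRTP_LENGTH)
    cr1 = _draw_seq(rng, CR1_LENGTH)
    cr2 = _draw_seq(rng, CR2_LENGTH)
    rap = _draw_seq(rng, RAP_LENGTH)

    records: list[ProteinMeta] = []
    rows = []
    idx = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            idx += 1
            pid = f"syn{idx:05d}"
            tmh_spans: list[tuple[int, int]] = []
            motif_start = None
            opr_k = 0
            if cls in ("ce_soluble", "ne_host_soluble", "ne_import_soluble", "mito_contaminant"):
                seq = _draw_seq(rng, int(rng.integers(120, 600)))
            elif cls in ("ce_multitm", "ne_host_multitm"):
                seq, tmh_spans = _make_multitm(rng)
            elif cls == "ne_group1":
                seq, span = _make_group1(rng)
                tmh_spans = [span]
            elif cls == "ne_group2":
                inst = _sample_pwm_instance(rng, GROUP2_CONSENSUS)
                length = int(rng.integers(len(inst) + 20, 90))
                pre = int(rng.integers(5, length - len(inst) - 5))
                seq = (_draw_seq(rng, pre, exclude="C") + inst
                       + _draw_seq(rng, length - pre - len(inst), exclude="C"))
                motif_start = pre + 1
            elif cls == "ne_group3":
                inst = _sample_pwm_instance(rng, GROUP3_CONSENSUS)
                length = int(rng.integers(len(inst) + 20, 90))
                pre = int(rng.integers(5, length - len(inst) - 5))
                seq = (_draw_seq(rng, pre, exclude="C") + inst
                       + _draw_seq(rng, length - pre - len(inst), exclude="C"))
                motif_start = pre + 1
            elif cls == "ne_group4":
                seq = _make_group4(rng)
            elif cls == "ne_amphipathic":
                seq = _make_amphipathic(rng)
            elif cls == "ne_opr":
                opr_k = cfg.opr_k if cfg.opr_k is not None else int(rng.integers(2, 14))
                variable = _draw_seq(rng, int(rng.integers(0, 150)))
                repeats = "".join(_sample_pwm_instance(rng, OPR_CONSENSUS) for _ in range(opr_k))
                seq = crtp + variable + cr1 + repeats + cr2 + rap
                motif_start = len(crtp) + len(variable) + CR1_LENGTH + 1
            else:  # pragma: no cover
                raise AssertionError(cls)
            encoding = "CE" if cls.startswith("ce_") else "NE"
            localization = ("chromatophore" if cls in CHROMATOPHORE_CLASSES
                            else "mito" if cls == "mito_contaminant" else "host")
            log_abund = float(rng.normal(cfg.abundance_mu, cfg.abundance_sigma))
            records.append(ProteinMeta(pid, encoding=encoding, sequence=seq))
            rows.append({
                "protein_id": pid,
                "class": cls,
                "localization": localization,
                "encoding": encoding,
                "length": len(seq),
                "membrane": cls in MEMBRANE_CLASSES,
                "tmh_spans": ";".join(f"{s}-{e}" for s, e in tmh_spans),
                "motif_start": motif_start,
                "opr_repeats": opr_k,
                "log10_abundance": log_abund,
            })
    truth = pd.DataFrame(rows)
    return records, truth, pwms


def truth_topology(truth: pd.DataFrame) -> dict[str, TopologyAnnotation]:
    """Planted TMH spans as TopologyAnnotation objects (source 'parsed')."""
    out = {}
    for row in truth.itertuples():
        spans = []
        if row.tmh_spans:
            for part in row.tmh_spans.split(";"):
                s, e = part.split("-")
                spans.append((int(s), int(e)))
        out[row.protein_id] = TopologyAnnotation(row.protein_id, spans, source="parsed")
    return out


def _fraction_means(row, cfg: SimConfig) -> dict[str, float]:
    a = 10.0 ** row.log10_abundance
    if row.localization == "chromatophore":
        cm = a * cfg.enrich_cm_vs_pm
        cl = cm / cfg.membrane_cm_vs_cl if row.membrane else cm
        pm = a
    elif row.localization == "host":
        pm = a
        cm = cl = a * cfg.deplete_host
    else:  # mito: mild contamination of the chromatophore membrane prep
        pm = a
        cm = a * 0.35
        cl = a * 0.1
    return {"CM": cm, "PM": pm, "CL": cl}


def generate_quant(truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Simulate the 2-experiment × 3-fraction × 3-replicate QuantTable.

    Replicate values are the fraction mean times lognormal noise exp(N(0,
    cv²)); a cell is detected with probability logistic((log10 v − τ)/slope)
    (a hard threshold when slope = 0), experiment 2 using τ − log10(3);
    undetected cells carry intensity 0, peptides 0, SpC 0.  Detected cells
    get peptides ~ 1 + Poisson(length/200) and SpC ~ max(1,
    Poisson(spc_rate · log10 v)).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    taus = {1: cfg.detect_tau, 2: cfg.detect_tau - math.log10(3.0)}
    rows = []
    for row in truth.itertuples():
        means = _fraction_means(row, cfg)
        for exp in (1, 2):
            tau = taus[exp]
            for frac in ("CM", "PM", "CL"):
                for rep in (1, 2, 3):
                    value = means[frac] * math.exp(rng.normal(0.0, cfg.cv))
                    lg = math.log10(value)
                    if cfg.detect_slope <= 0:
                        p_det = 1.0 if lg > tau else 0.0
                    else:
                        p_det = 1.0 / (1.0 + math.exp(-(lg - tau) / cfg.detect_slope))
                    detected = rng.random() < p_det
                    if detected:
                        peptides = 1 + int(rng.poisson(row.length / 200.0))
                        spc = max(1, int(rng.poisson(cfg.spc_rate * max(lg, 0.0))))
                        rows.append((row.protein_id, exp, frac, rep, value, peptides, spc))
                    else:
                        rows.append((row.protein_id, exp, frac, rep, 0.0, 0, 0))
    df = pd.DataFrame(rows, columns=["protein_id", "experiment", "fraction", "replicate",
                                     "intensity", "peptides", "spectral_count"])
    return validate_quant_table(df)


def evaluate_calls(calls: set[str] | dict, truth_positive: set[str],
                   universe: set[str]) -> dict:
    """Confusion-matrix summary of a classifier against planted truth.

    ``calls`` is the positive-call set (or an id -> bool mapping); ids must
    all belong to ``universe``.  Undefined ratios are returned as NaN.
    """
    if isinstance(calls, dict):
        calls = {k for k, v in calls.items() if v}
    calls = set(calls)
    truth_positive = set(truth_positive)
    if not calls <= universe or not truth_positive <= universe:
        raise ValueError("calls/truth ids not contained in the evaluation universe")
    tp = len(calls & truth_positive)
    fp = len(calls - truth_positive)
    fn = len(truth_positive - calls)
    tn = len(universe) - tp - fp - fn
    def ratio(num, den):
        return num / den if den else float("nan")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "fdr_realized": ratio(fp, tp + fp),
    }
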