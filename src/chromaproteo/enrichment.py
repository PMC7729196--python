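"""Normalization, intensity levels, enrichment factors and the rule-based
chromatophore-enrichment classification.

Each protein's intensity in a run is divided by that run's summed intensity
over proteins identified with >=2 distinct peptides (normInt).  Replicate
means of normInt (missing runs excluded) give per-fraction abundance; the
ratio of CM to PM means is the enrichment factor E_CM/PM, and the rule

    SpC >= 3 in the chromatophore (CM+CL) and
    E_CM/PM > 1.5 in >= 1 experiment        -> enriched (high confidence)
    0.5 < E_CM/PM < 1.5 in both experiments -> enriched (low confidence)

classifies proteins as chromatophore-enriched.  A protein detected in CM
but never in PM carries the sentinel ONLY_IN_CM, which counts as maximal
evidence of enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantio import EXPERIMENTS, FRACTIONS, validate_quant_table

logger = logging.getLogger(__name__)

#: Sentinel for "detected in the numerator fraction, never in the denominator".
ONLY_IN_CM = "ONLY_IN_CM"

ENRICHMENT_CLASSES = ("enriched_HC", "enriched_LC", "depleted", "unclear", "not_evaluated")


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Classification thresholds; defaults are the published rule."""

    spc_min: int = 3
    e_hi: float = 1.5
    e_lo: float = 0.5


def normalize(quant: pd.DataFrame) -> pd.DataFrame:
    """Add a ``norm_intensity`` column (normInt).

    Within each run (experiment, fraction, replicate) the denominator is the
    summed intensity of proteins with >=2 peptides; every protein's intensity
    (including 1-peptide proteins) is divided by it.  A run whose denominator
    is 0 gets all-zero normInt and a logged warning.
    """
    quant = validate_quant_table(quant)
    out = quant.copy()
    out["norm_intensity"] = 0.0
    for key, idx in out.groupby(["experiment", "fraction", "replicate"]).groups.items():
        sub = out.loc[idx]
        denom = sub.loc[sub["peptides"] >= 2, "intensity"].sum()
        if denom > 0:
            out.loc[idx, "norm_intensity"] = sub["intensity"] / denom
        else:
            logger.warning("run %s has no >=2-peptide protein detected; normInt set to 0", key)
    return out


def intensity_level(mean_norm: float) -> float:
    """log10(mean normInt) + 7 — an abundance rank on a roughly 0–6 scale.

    Undefined (NaN) for non-positive input; never clipped.
    """
    if mean_norm is None or not mean_norm > 0:
        return float("nan")
    return math.log10(mean_norm) + 7.0


def enrichment_factor(norm_a, norm_b):
    """Ratio of replicate means, missing values (NaN) excluded per side.

    Returns a positive float, the sentinel :data:`ONLY_IN_CM` when the
    numerator is present but the denominator side was never detected, or
    NaN when the numerator side was never detected.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    mean_a = np.nanmean(a) if np.isfinite(a).any() else np.nan
    mean_b = np.nanmean(b) if np.isfinite(b).any() else np.nan
    if not np.isfinite(mean_a) or mean_a <= 0:
        return float("nan")
    if not np.isfinite(mean_b) or mean_b <= 0:
        return ONLY_IN_CM
    return float(mean_a / mean_b)


def classify_enrichment(e_by_exp: dict, spc_by_exp: dict,
                        thresholds: EnrichmentThresholds = EnrichmentThresholds()) -> str:
    """Apply the enrichment decision rule across both MS experiments.

    ``e_by_exp`` maps experiment -> E_CM/PM (float, NaN, or ONLY_IN_CM);
    ``spc_by_exp`` maps experiment -> summed chromatophore SpC.  The
    high-confidence branch counts an experiment only when its own SpC gate
    passes; the LC/depleted branches consider every defined E.
    """
    t = thresholds
    exps = sorted(set(e_by_exp) | set(spc_by_exp))
    spc = {e: int(spc_by_exp.get(e, 0)) for e in exps}
    if all(spc[e] < t.spc_min for e in exps):
        return "not_evaluated"

    def coerce(v):
        if v == ONLY_IN_CM:
            return v
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    def is_defined(v) -> bool:
        return v == ONLY_IN_CM or (isinstance(v, float) and math.isfinite(v))

    def exceeds_hi(v) -> bool:
        return v == ONLY_IN_CM or (isinstance(v, float) and math.isfinite(v) and v > t.e_hi)

    e = {x: coerce(e_by_exp.get(x, float("nan"))) for x in exps}
    # HC: E > e_hi (ONLY_IN_CM counts) in >=1 experiment passing its SpC gate
    if any(exceeds_hi(e[x]) and spc[x] >= t.spc_min for x in exps):
        return "enriched_HC"
    defined = {x: e[x] for x in exps if is_defined(e[x])}
    # LC: E defined in both experiments and strictly between e_lo and e_hi in both
    if len(defined) == len(exps) and all(
        isinstance(v, float) and t.e_lo < v < t.e_hi for v in defined.values()
    ):
        return "enriched_LC"
    if defined and all(isinstance(v, float) and v <= t.e_lo for v in defined.values()):
        return "depleted"
    return "unclear"


def _replicate_vector(sub: pd.DataFrame) -> np.ndarray:
    """normInt replicate vector with missing runs (intensity 0 or absent) as NaN."""
    vec = np.full(3, np.nan)
    for row in sub.itertuples():
        if row.intensity > 0:
            vec[row.replicate - 1] = row.norm_intensity
    return vec


def compute_enrichment(norm: pd.DataFrame,
                       thresholds: EnrichmentThresholds = EnrichmentThresholds()) -> pd.DataFrame:
    """Build the per-protein enrichment table from a normalized QuantTable.

    Columns: per (experiment, fraction) mean normInt and intensity level,
    per experiment E_CM/PM, E_CM/CL (object columns carrying floats, NaN or
    the ONLY_IN_CM sentinel) and chromatophore SpC, plus the final
    ``enrichment_class``.
    """
    if "norm_intensity" not in norm.columns:
        raise ValueError("input must come from normalize()")
    records = []
    grouped = {k: g for k, g in norm.groupby(["protein_id", "experiment", "fraction"])}
    spc_sum = (
        norm[norm["fraction"].isin(["CM", "CL"])]
        .groupby(["protein_id", "experiment"])["spectral_count"]
        .sum()
    )
    for pid in norm["protein_id"].unique():
        rec: dict = {"protein_id": pid}
        e_cm_pm: dict = {}
        spc: dict = {}
        for exp in EXPERIMENTS:
            vecs = {}
            for frac in FRACTIONS:
                sub = grouped.get((pid, exp, frac))
                vec = _replicate_vector(sub) if sub is not None else np.full(3, np.nan)
                vecs[frac] = vec
                mean = np.nanmean(vec) if np.isfinite(vec).any() else np.nan
                rec[f"mean_norm_e{exp}_{frac.lower()}"] = mean
                rec[f"level_e{exp}_{frac.lower()}"] = intensity_level(mean)
            rec[f"e_cm_pm_e{exp}"] = enrichment_factor(vecs["CM"], vecs["PM"])
            rec[f"e_cm_cl_e{exp}"] = enrichment_factor(vecs["CM"], vecs["CL"])
            rec[f"spc_chromatophore_e{exp}"] = int(spc_sum.get((pid, exp), 0))
            e_cm_pm[exp] = rec[f"e_cm_pm_e{exp}"]
            spc[exp] = rec[f"spc_chromatophore_e{exp}"]
        rec["enrichment_class"] = classify_enrichment(e_cm_pm, spc, thresholds)
        records.append(rec)
    return pd.DataFrame(records)


def enriched_ids(enrichment: pd.DataFrame, include_lc: bool = True) -> set[str]:
    """Protein ids classified as chromatophore-enriched."""
    classes = {"enriched_HC"} | ({"enriched_LC"} if include_lc else set())
    return set(enrichment.loc[enrichment["enrichment_class"].isin(classes), "protein_id"])


def format_enrichment_table(enr: pd.DataFrame) -> pd.DataFrame:
    """Serialize sentinels for TSV output (ONLY_IN_CM stays literal; NaN -> NA
    via the writer); levels are kept at full precision."""
    out = enr.copy()
    for col in out.columns:
        if col.startswith("e_cm_"):
            out[col] = out[col].map(
                lambda v: v if v == ONLY_IN_CM else (float(v) if pd.notna(v) else np.nan)
            )
    return out
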