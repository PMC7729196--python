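"""End-to-end orchestration: quantitation + sequences -> enrichment classes
-> differential statistics -> topology tally (with the CE-vs-NE multi-TM
Fisher test among enriched proteins) -> orphan groups -> OPR scan -> summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffstats, enrichment, motifscan, quantio, seqfeatures

logger = logging.getLogger(__name__)

TMH_BINS = (("0", 0, 0), ("1", 1, 1), ("2-3", 2, 3), (">=4", 4, 10**9))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    quant: str | Path
    meta: str | Path
    fasta: str | Path | None = None
    topology: str | Path | None = None  # TMHMM file; None -> hydropathy fallback
    motifs: str | Path | None = None  # MEME minimal file (group2, group3, OPR38 ...)
    out_dir: str | Path = "results"
    quant_dialect: str = "long"
    seed: int = 0
    thresholds: enrichment.EnrichmentThresholds = field(
        default_factory=enrichment.EnrichmentThresholds)
    diff: diffstats.DiffConfig = field(default_factory=diffstats.DiffConfig)
    wheel: seqfeatures.HelixWheelParams = field(default_factory=seqfeatures.HelixWheelParams)
    opr_weak: float = motifscan.WEAK_P
    opr_strong: float = motifscan.STRONG_P
    opr_min_weak: int = motifscan.MIN_WEAK_REPEATS

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from TOML or YAML (flat keys matching the field names)."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib
            data = tomllib.loads(path.read_text())
        else:
            import yaml
            data = yaml.safe_load(path.read_text())
        return cls(**data)


def get_topology(cfg: PipelineConfig,
                 meta: dict[str, quantio.ProteinMeta]) -> dict[str, quantio.TopologyAnnotation]:
    """Parsed TMHMM predictions take precedence; proteins without a parsed
    annotation (or without any topology file) get the hydropathy fallback."""
    annotations: dict[str, quantio.TopologyAnnotation] = {}
    if cfg.topology is not None:
        for ann in quantio.read_tmhmm(cfg.topology):
            annotations[ann.protein_id] = ann
    for pid, m in meta.items():
        if pid not in annotations and m.sequence is not None:
            ann = seqfeatures.predict_tmh_fallback(m.sequence)
            annotations[pid] = quantio.TopologyAnnotation(pid, ann.segments, source="fallback")
    return annotations


def summarize_tm_by_encoding(enriched: set[str],
                             topology: dict[str, quantio.TopologyAnnotation],
                             meta: dict[str, quantio.ProteinMeta]):
    """2×2 table (rows CE/NE among enriched, columns multi-TM yes/no) and its
    two-sided Fisher exact p."""
    if not enriched:
        raise ValueError("empty enriched set")
    counts = {"CE": [0, 0], "NE": [0, 0]}
    for pid in enriched:
        m = meta.get(pid)
        if m is None or m.encoding is None:
            continue
        ann = topology.get(pid, quantio.TopologyAnnotation(pid, []))
        multi = seqfeatures.is_multi_spanning(ann)
        counts[m.encoding][0 if multi else 1] += 1
    a, b = counts["CE"]
    c, d = counts["NE"]
    p = diffstats.fisher_exact(a, b, c, d)
    return (a, b, c, d), p


def _tmh_bin(n: int) -> str:
    for name, lo, hi in TMH_BINS:
        if lo <= n <= hi:
            return name
    raise AssertionError(n)  # pragma: no cover


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, writing each stage's TSV plus summary.{json,tsv} and a
    MANIFEST to ``cfg.out_dir``.  Returns the summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {}

    def finish_stage(name: str, filename: str | None = None) -> None:
        if filename:
            manifest.append(filename)
        (out / "MANIFEST").write_text(
            "\n".join(manifest) + f"\n# last completed stage: {name}\n")

    try:
        stage = "load"
        for p in (cfg.quant, cfg.meta):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        quant = quantio.read_quant_table(cfg.quant, dialect=cfg.quant_dialect)
        meta = quantio.read_protein_meta(cfg.meta, fasta=cfg.fasta)

        stage = "normalize"
        norm = enrichment.normalize(quant)
        quantio.write_results(norm, out / "normalized.tsv")
        finish_stage(stage, "normalized.tsv")

        stage = "enrich"
        logger.info("enrichment thresholds: %s", cfg.thresholds)
        enr = enrichment.compute_enrichment(norm, cfg.thresholds)
        quantio.write_results(enrichment.format_enrichment_table(enr), out / "enrichment.tsv")
        class_counts = enr["enrichment_class"].value_counts().to_dict()
        summary["enrichment_class_counts"] = {c: int(class_counts.get(c, 0))
                                              for c in enrichment.ENRICHMENT_CLASSES}
        enriched = enrichment.enriched_ids(enr)
        finish_stage(stage, "enrichment.tsv")

        stage = "diffstats"
        for exp in (1, 2):
            cfg.diff.impute = diffstats.ImputeConfig(
                width=cfg.diff.impute.width, downshift=cfg.diff.impute.downshift,
                seed=cfg.seed + exp)
            try:
                diff = diffstats.run_diff(norm, (exp, "CM"), (exp, "PM"), cfg.diff)
            except KeyError:
                continue
            quantio.write_results(diff, out / f"diff_cm_pm_exp{exp}.tsv")
            summary[f"sam_significant_exp{exp}"] = int(diff["significant"].sum())
            finish_stage(stage, f"diff_cm_pm_exp{exp}.tsv")

        stage = "topology"
        topology = get_topology(cfg, meta)
        tally: dict[str, dict[str, int]] = {}
        for pid in sorted(enriched):
            m = meta.get(pid)
            if m is None or m.encoding is None:
                continue
            ann = topology.get(pid, quantio.TopologyAnnotation(pid, []))
            b = _tmh_bin(ann.tmh_count)
            tally.setdefault(m.encoding, {})[b] = tally.setdefault(m.encoding, {}).get(b, 0) + 1
        summary["enriched_tmh_bins"] = tally
        table, fisher_p = summarize_tm_by_encoding(enriched, topology, meta)
        summary["multitm_table_ce_ne"] = list(table)
        summary["fisher_p_multitm"] = fisher_p
        summary["ne_multitm_among_enriched"] = int(table[2])
        pd.DataFrame(
            [{"encoding": enc, "tmh_bin": b, "count": n}
             for enc, bins in tally.items() for b, n in sorted(bins.items())]
        ).to_csv(out / "topology_summary.tsv", sep="\t", index=False)
        finish_stage(stage, "topology_summary.tsv")

        stage = "groups"
        pwms = {}
        if cfg.motifs is not None:
            for pwm in motifscan.read_meme_motif(cfg.motifs):
                pwms[pwm.name] = pwm
        tables = {name: motifscan.score_pvalue_table(p) for name, p in pwms.items()}
        group_rows = []
        for pid in sorted(enriched):
            m = meta.get(pid)
            if (m is None or m.sequence is None or m.encoding != "NE"
                    or m.length >= seqfeatures.SHORT_PROTEIN_MAX):
                continue
            ann = topology.get(pid, quantio.TopologyAnnotation(pid, []))
            best_p = {}
            for gname in ("group2", "group3"):
                if gname in pwms:
                    hits = motifscan.scan(m.sequence, pwms[gname], p_threshold=1.0,
                                          table=tables[gname], protein_id=pid)
                    best_p[gname] = min((h.pvalue for h in hits), default=None)
                else:
                    best_p[gname] = None
            call = seqfeatures.classify_orphan(m, ann, best_p["group2"], best_p["group3"],
                                               cfg.wheel)
            group_rows.append({"protein_id": pid, "group": call.group, **call.evidence})
        groups_df = pd.DataFrame(group_rows)
        quantio.write_results(groups_df, out / "groups.tsv")
        summary["group_counts"] = (
            groups_df["group"].value_counts().to_dict() if not groups_df.empty else {})
        finish_stage(stage, "groups.tsv")

        stage = "oprscan"
        opr_rows = []
        n_candidates = 0
        if "OPR38" in pwms:
            pwm = pwms["OPR38"]
            table38 = tables["OPR38"]
            for pid, m in sorted(meta.items()):
                if m.sequence is None or len(m.sequence) < pwm.length:
                    continue
                hits = motifscan.scan(m.sequence, pwm, p_threshold=cfg.opr_weak,
                                      table=table38, protein_id=pid)
                rec = motifscan.classify_opr(hits, motif_length=pwm.length,
                                             weak_p=cfg.opr_weak, strong_p=cfg.opr_strong,
                                             min_weak=cfg.opr_min_weak, protein_id=pid)
                if rec.hits:
                    opr_rows.append({"protein_id": pid, "n_repeats": len(rec.hits),
                                     "n_weak": rec.n_weak, "n_strong": rec.n_strong,
                                     "is_candidate": rec.is_candidate})
                    n_candidates += int(rec.is_candidate)
        quantio.write_results(pd.DataFrame(opr_rows), out / "opr.tsv")
        summary["opr_candidates"] = n_candidates
        finish_stage(stage, "opr.tsv")

        stage = "report"
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
        pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
        finish_stage(stage, "summary.json")
        manifest.append("summary.tsv")
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n# complete\n")
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        (out / "MANIFEST").write_text("\n".join(manifest) + f"\n# INCOMPLETE at stage {stage}\n")
        raise PipelineError(stage, str(exc)) from exc
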