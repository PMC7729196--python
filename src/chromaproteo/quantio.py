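"""Readers/writers and the canonical in-memory data model.

The pipeline's tabular data live in plain :class:`pandas.DataFrame` objects
with fixed column sets; this module owns their validation and all on-disk
formats (long/wide quantitation TSV, FASTA, TMHMM long-format text, results
TSV).  Coordinates are 1-based inclusive throughout; an intensity of 0 is
the sole encoding of "not detected".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

FRACTIONS = ("CM", "PM", "CL")
EXPERIMENTS = (1, 2)
REPLICATES = (1, 2, 3)

#: Canonical column order of a long-format quantitation table.
QUANT_COLUMNS = [
    "protein_id",
    "experiment",
    "fraction",
    "replicate",
    "intensity",
    "peptides",
    "spectral_count",
]

KEY_COLUMNS = ["protein_id", "experiment", "fraction", "replicate"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)


class FormatError(ValueError):
    """Malformed input file (missing column, bad line, wrong alphabet)."""


class DataIntegrityError(ValueError):
    """Structurally valid input violating a table invariant (e.g. duplicate keys)."""


@dataclass
class ProteinMeta:
    """Identity, genome of origin and (optionally) sequence of one protein.

    ``encoding`` is ``"CE"`` (chromatophore-encoded) or ``"NE"``
    (nucleus-encoded); ``None`` when the metadata table has not been joined
    yet.  Sequences are restricted to the 20 canonical residues because every
    downstream scale (charge, hydropathy, PWM scores) is defined only there.
    """

    protein_id: str
    encoding: str | None = None
    sequence: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.encoding not in (None, "CE", "NE"):
            raise ValueError(f"encoding must be CE or NE, got {self.encoding!r}")
        if self.sequence is not None:
            bad = set(self.sequence) - _AA_SET
            if bad:
                raise FormatError(
                    f"non-canonical residue(s) {sorted(bad)} in record {self.protein_id!r}"
                )
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise ValueError("length field disagrees with sequence")


@dataclass
class TopologyAnnotation:
    """Predicted transmembrane helices of one protein.

    ``segments`` are 1-based inclusive ``(start, end)`` residue spans,
    sorted and non-overlapping; ``source`` records whether they were parsed
    from an external predictor ("parsed") or produced by the internal
    hydropathy fallback ("fallback").
    """

    protein_id: str
    segments: list[tuple[int, int]] = field(default_factory=list)
    source: str = "parsed"

    def __post_init__(self) -> None:
        if self.source not in ("parsed", "fallback"):
            raise ValueError(f"bad topology source {self.source!r}")
        prev_end = 0
        for start, end in self.segments:
            if not (1 <= start <= end):
                raise ValueError(f"bad segment ({start},{end}) for {self.protein_id}")
            if start <= prev_end:
                raise ValueError(f"overlapping/unsorted segments for {self.protein_id}")
            prev_end = end

    @property
    def tmh_count(self) -> int:
        return len(self.segments)


def validate_quant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the QuantTable invariants; returns the (re-typed) frame."""
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    df = df[QUANT_COLUMNS].copy()
    if len(df) == 0:
        return df.astype(
            {
                "experiment": int,
                "replicate": int,
                "intensity": float,
                "peptides": int,
                "spectral_count": int,
            }
        )
    df["intensity"] = df["intensity"].fillna(0.0).astype(float)
    for col in ("peptides", "spectral_count"):
        df[col] = df[col].fillna(0).astype(int)
    df["experiment"] = df["experiment"].astype(int)
    df["replicate"] = df["replicate"].astype(int)

    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise ValueError(f"negative intensity at row {neg[0]}")
    if (df["peptides"] < 0).any() or (df["spectral_count"] < 0).any():
        raise ValueError("negative peptide or spectral count")
    bad_frac = set(df["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"unknown fraction label(s): {sorted(bad_frac)}")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        key = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise DataIntegrityError(f"duplicate (protein, experiment, fraction, replicate) key {key}")
    zero_pep = (df["peptides"] == 0) & (df["intensity"] > 0)
    if zero_pep.any():
        raise DataIntegrityError(
            "intensity > 0 with peptides = 0 violates the missingness invariant "
            f"(first at row {int(zero_pep.idxmax())})"
        )
    return df


_WIDE_RE = re.compile(r"^(Intensity|Peptides|SpC) (\d+)_(CM|PM|CL)_(\d+)$")


def read_quant_table(path: str | Path, dialect: str = "long") -> pd.DataFrame:
    """Read a quantitation table.

    ``dialect="long"`` expects the seven canonical columns; ``"wide"``
    expects one row per protein with run columns named
    ``"Intensity <EXP>_<FRACTION>_<REP>"`` (likewise ``Peptides``/``SpC``)
    and is melted to long form.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if dialect == "long":
        return validate_quant_table(df)

    if "protein_id" not in df.columns:
        raise FormatError("missing column(s): protein_id")
    runs: dict[tuple[int, str, int], dict[str, str]] = {}
    for col in df.columns:
        m = _WIDE_RE.match(col)
        if m:
            kind, exp, frac, rep = m.groups()
            runs.setdefault((int(exp), frac, int(rep)), {})[kind] = col
    if not runs:
        raise FormatError("missing column(s): no 'Intensity <EXP>_<FRACTION>_<REP>' columns found")
    rows = []
    for (exp, frac, rep), cols in sorted(runs.items()):
        if "Intensity" not in cols:
            raise FormatError(f"missing column(s): Intensity {exp}_{frac}_{rep}")
        chunk = pd.DataFrame(
            {
                "protein_id": df["protein_id"],
                "experiment": exp,
                "fraction": frac,
                "replicate": rep,
                "intensity": df[cols["Intensity"]],
                "peptides": df[cols["Peptides"]] if "Peptides" in cols else 0,
                "spectral_count": df[cols["SpC"]] if "SpC" in cols else 0,
            }
        )
        rows.append(chunk)
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=QUANT_COLUMNS)
    if df["protein_id"].duplicated().any():
        dup_id = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise DataIntegrityError(f"duplicate protein row {dup_id!r} in wide table")
    return validate_quant_table(long)


def read_fasta(path: str | Path) -> list[ProteinMeta]:
    """Parse a protein FASTA into sequence-bearing :class:`ProteinMeta`.

    The first whitespace-delimited header token is the protein id; wrapped
    lines are concatenated; order is preserved.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        bad = set(seq) - _AA_SET
        if bad:
            raise ValueError(
                f"non-canonical residue {sorted(bad)[0]!r} in record {rec.id!r}"
            )
        records.append(ProteinMeta(protein_id=rec.id, sequence=seq))
    return records


def read_protein_meta(path: str | Path, fasta: str | Path | None = None) -> dict[str, ProteinMeta]:
    """Read the CE/NE metadata TSV (columns protein_id, encoding) and
    optionally attach sequences from a FASTA."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "encoding"):
        if col not in df.columns:
            raise FormatError(f"missing column(s): {col}")
    if df["protein_id"].duplicated().any():
        raise DataIntegrityError("duplicate protein_id in metadata table")
    meta = {
        row.protein_id: ProteinMeta(protein_id=row.protein_id, encoding=row.encoding)
        for row in df.itertuples()
    }
    if fasta is not None:
        for rec in read_fasta(fasta):
            if rec.protein_id in meta:
                m = meta[rec.protein_id]
                m.sequence = rec.sequence
                m.length = rec.length
            else:
                meta[rec.protein_id] = rec
    return meta


_TMHMM_LABELS = {"inside", "outside", "TMhelix"}


def read_tmhmm(path: str | Path) -> list[TopologyAnnotation]:
    """Parse TMHMM 2.0 long-format output.

    Data lines look like ``<id>\\tTMHMM2.0\\t<label>\\t<start>\\t<end>``;
    only ``TMhelix`` lines become segments.  Comment lines start with ``#``.
    """
    per_protein: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5 or parts[2] not in _TMHMM_LABELS:
                raise FormatError(f"unparseable TMHMM line {lineno}: {line!r}")
            pid, _, label, start_s, end_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"unparseable TMHMM line {lineno}: {line!r}") from None
            if pid not in per_protein:
                per_protein[pid] = []
                order.append(pid)
            if label == "TMhelix":
                per_protein[pid].append((start, end))
    return [
        TopologyAnnotation(pid, sorted(per_protein[pid]), source="parsed") for pid in order
    ]


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write any stage output as tab-separated UTF-8 with ``NA`` for missing
    values; reals are serialized to 12 significant digits so a round-trip
    through :func:`read_results` is the identity up to that precision."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g", encoding="utf-8")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_quant_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_quant_table(df)
    write_results(df, path)


def write_fasta(records: Iterable[ProteinMeta], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.sequence is None:
                raise ValueError(f"record {rec.protein_id!r} has no sequence")
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_tmhmm(annotations: Sequence[TopologyAnnotation], path: str | Path,
                lengths: dict[str, int] | None = None) -> None:
    """Write topology annotations in TMHMM long format (TMhelix lines only,
    with inside/outside filler so the file is well-formed for re-parsing)."""
    with open(path, "w") as fh:
        for ann in annotations:
            pos = 1
            for start, end in ann.segments:
                if start > pos:
                    fh.write(f"{ann.protein_id}\tTMHMM2.0\toutside\t{pos}\t{start - 1}\n")
                fh.write(f"{ann.protein_id}\tTMHMM2.0\tTMhelix\t{start}\t{end}\n")
                pos = end + 1
            length = (lengths or {}).get(ann.protein_id)
            if length is None or length >= pos:
                fh.write(
                    f"{ann.protein_id}\tTMHMM2.0\tinside\t{pos}\t{length if length else pos}\n"
                )
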