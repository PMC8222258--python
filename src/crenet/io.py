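"""Readers and writers for every external format the pipeline touches.

Coordinate convention: all genomic coordinates are 0-based half-open
([start, end)) everywhere in memory, matching BED.  Any 1-based source would
have to be converted at this boundary; none of the supported formats is.

Formats:

* peaks: BED6+3 — chrom, start, end, name, score, strand, plus three
  extension columns carrying the accessibility statistics (log2 fold change
  on the NR-over-RPE orientation, BH-adjusted p-value, mean accessibility).
* gene models: TSV with gene_id, chrom, tss, strand, is_tf, is_cytoskeletal.
* expression: TSV with gene_id, one column per condition (FPKM-like), one
  ``lfc_<contrast>`` / ``q_<contrast>`` column pair per contrast, and the two
  gene-category flags.
* sequences: FASTA keyed by peak name (via Bio.SeqIO; uppercased on read).
* motifs: JASPAR PFM text, both the bracketed (``A [ 1 2 3 ]``) and the
  bracket-free whitespace dialect.

Every reader validates its input and raises :class:`FormatError` with the
offending line number; every reader/writer pair round-trips valid tables
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ConfigError, PipelineConfig, load_config, save_config  # noqa: F401

VALID_BASES = set("ACGTN")
BASES = "ACGT"

PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "score", "strand",
    "log2fc", "adjusted_p", "mean_accessibility",
]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "is_tf", "is_cytoskeletal"]


class FormatError(ValueError):
    """Malformed input file (message carries file, line number, field)."""


def _float_repr(x: float) -> str:
    """Shortest representation that round-trips the float64 exactly."""
    return repr(float(x))


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PositionFrequencyMatrix:
    """Base counts for a binding motif, rows A, C, G, T by column."""

    pwm_id: str
    counts: np.ndarray  # shape (4, L)
    name: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.pwm_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.pwm_id}: motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.pwm_id}: counts must be nonnegative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"{self.pwm_id}: every column needs a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def column_probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# peaks (BED6+3)
# ---------------------------------------------------------------------------

def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED6+3 peak table, sorted by (chrom, start).

    Comment (``#``) and ``track`` lines are skipped.  Malformed rows raise
    :class:`FormatError` naming the 1-based line number.
    """
    rows = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns (BED6 plus log2fc, "
                    f"adjusted_p, mean_accessibility), got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if not 0 <= start < end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if name in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate peak_id {name!r}")
            seen_ids.add(name)
            try:
                log2fc = float(fields[6])
                adjusted_p = float(fields[7])
                mean_acc = float(fields[8])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric extension column"
                ) from None
            if not 0 <= adjusted_p <= 1:
                raise FormatError(
                    f"{path}:{lineno}: adjusted_p {adjusted_p} outside [0, 1]"
                )
            if mean_acc < 0:
                raise FormatError(f"{path}:{lineno}: negative mean_accessibility")
            rows.append((chrom, start, end, name, float(score_s), strand,
                         log2fc, adjusted_p, mean_acc))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "peak_id"]).reset_index(drop=True)


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    df = peaks[PEAK_COLUMNS].sort_values(
        ["chrom", "start", "end", "peak_id"]
    ).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PEAK_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  float_format=_float_repr)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene-table columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    if len(df) and not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"])].index[0] + 2  # header line
        raise FormatError(f"{path}:{bad}: gene strand must be + or -")
    if len(df) and (df["tss"] < 0).any():
        bad = df.index[df["tss"] < 0][0] + 2
        raise FormatError(f"{path}:{bad}: negative TSS")
    df = df[GENE_COLUMNS].copy()
    df["tss"] = df["tss"].astype(int)
    df["is_tf"] = df["is_tf"].astype(bool)
    df["is_cytoskeletal"] = df["is_cytoskeletal"].astype(bool)
    return df.reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    df = genes[GENE_COLUMNS].copy()
    df["is_tf"] = df["is_tf"].astype(int)
    df["is_cytoskeletal"] = df["is_cytoskeletal"].astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

FLAG_COLUMNS = ["is_tf", "is_cytoskeletal"]


def expression_condition_columns(df: pd.DataFrame) -> list[str]:
    """The condition (expression-level) columns of an expression table."""
    return [
        c for c in df.columns
        if c != "gene_id" and c not in FLAG_COLUMNS
        and not c.startswith("lfc_") and not c.startswith("q_")
    ]


def expression_contrasts(df: pd.DataFrame) -> list[str]:
    return [c[len("lfc_"):] for c in df.columns if c.startswith("lfc_")]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    conditions = expression_condition_columns(df)
    if len(conditions) != 5:
        raise FormatError(
            f"{path}: expected 5 condition columns, found {conditions}"
        )
    contrasts = expression_contrasts(df)
    for ct in contrasts:
        qcol = f"q_{ct}"
        if qcol not in df.columns:
            raise FormatError(f"{path}: lfc_{ct} present but {qcol} missing")
        bad = df.index[(df[qcol] < 0) | (df[qcol] > 1)]
        if len(bad):
            raise FormatError(
                f"{path}:{bad[0] + 2}: {qcol} value {df.loc[bad[0], qcol]} "
                f"outside [0, 1]"
            )
    for cond in conditions:
        bad = df.index[df[cond] < 0]
        if len(bad):
            raise FormatError(f"{path}:{bad[0] + 2}: negative expression in {cond}")
    for flag in FLAG_COLUMNS:
        if flag not in df.columns:
            raise FormatError(f"{path}: missing flag column {flag}")
        df[flag] = df[flag].astype(bool)
    return df.reset_index(drop=True)


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    df = expr.copy()
    for flag in FLAG_COLUMNS:
        df[flag] = df[flag].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=_float_repr)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence mapping (uppercased)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} has invalid characters {sorted(bad)}"
            )
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate record {record.id!r}")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def _parse_count_row(line: str, expect_base: str, pwm_id: str,
                     path, lineno: int) -> list[float]:
    tokens = line.replace("[", " ").replace("]", " ").split()
    if not tokens:
        raise FormatError(f"{path}:{lineno}: empty count row in {pwm_id!r}")
    if tokens[0].upper() in ("A", "C", "G", "T"):
        base, tokens = tokens[0].upper(), tokens[1:]
        if base != expect_base:
            raise FormatError(
                f"{path}:{lineno}: {pwm_id!r}: expected row {expect_base}, got {base}"
            )
    try:
        return [float(t) for t in tokens]
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: {pwm_id!r}: non-numeric count"
        ) from None


def read_jaspar_pfm(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-format PFM records (bracketed or plain-whitespace rows)."""
    motifs: list[PositionFrequencyMatrix] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}:{i + 1}: expected '>' header, got {line!r}")
        header = line[1:].split(None, 1)
        if not header or not header[0]:
            raise FormatError(f"{path}:{i + 1}: empty motif id")
        pwm_id = header[0]
        name = header[1] if len(header) > 1 else ""
        rows = []
        for j, base in enumerate("ACGT"):
            lineno = i + 1 + j + 1
            if i + 1 + j >= n:
                raise FormatError(
                    f"{path}: {pwm_id!r}: truncated record (missing row {base})"
                )
            rows.append(_parse_count_row(lines[i + 1 + j], base, pwm_id,
                                         path, lineno))
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}: {pwm_id!r}: A/C/G/T rows have unequal lengths "
                f"{sorted(len(r) for r in rows)}"
            )
        try:
            motifs.append(PositionFrequencyMatrix(pwm_id, np.array(rows), name))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
        i += 5
    return motifs


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_jaspar_pfm(motifs: Iterable[PositionFrequencyMatrix],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            header = f">{m.pwm_id}" + (f" {m.name}" if m.name else "")
            fh.write(header + "\n")
            for base, row in zip(BASES, m.counts):
                fh.write(f"{base} [ " + " ".join(_format_count(x) for x in row)
                         + " ]\n")
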