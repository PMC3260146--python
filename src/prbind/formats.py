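"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates held in memory are 0-based, half-open ``[start, end)``,
the BED convention. Readers validate eagerly and raise :class:`FormatError`
with the offending line number; writers produce files that round-trip to
equal records.

Formats supported:

* BED6 intervals, with an optional 7th column carrying the summit offset
  (bp from ``start``) as reported by peak callers such as MACS;
* FASTA genomes (multi-record, case-insensitive, ``N`` allowed), via
  Biopython;
* TRANSFAC flat-file motif libraries, via ``Bio.motifs``, with an optional
  per-matrix threshold sidecar TSV;
* a simple gene-annotation TSV (gene_id, chrom, strand, tss, exons) —
  a deliberate reduction of GTF to the fields the analysis needs (TSS,
  strand, exon structure). A GTF importer is a documented extension point.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "PWM",
    "GeneRecord",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "parse_transfac",
    "write_transfac",
    "read_thresholds",
    "read_gene_table",
    "write_gene_table",
    "read_expression",
    "write_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A binding or background site: 0-based half-open interval.

    ``summit`` is an optional offset from ``start`` (the peak-caller summit);
    downstream analyses fall back to the interval midpoint when it is absent.
    """

    chrom: str
    start: int
    end: int
    id: str = "."
    score: float = 0.0
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise FormatError(
                f"summit offset {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def refpoint(self) -> int:
        """Absolute reference coordinate: summit if present, else midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return self.start + self.length // 2


@dataclass
class PWM:
    """A position frequency matrix in TRANSFAC layout.

    ``counts`` is an ``(L, 4)`` array of non-negative base counts in
    A, C, G, T column order. ``core_threshold`` and ``matrix_threshold``
    are the per-matrix MATCH cut-offs in [0, 1].
    """

    matrix_id: str
    factor_name: str
    counts: np.ndarray
    core_threshold: float = 0.90
    matrix_threshold: float = 0.85

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] == 0:
            raise FormatError(
                f"{self.matrix_id}: counts must be a non-empty (L, 4) matrix"
            )
        if (self.counts < 0).any():
            raise FormatError(f"{self.matrix_id}: negative count")
        if (self.counts.sum(axis=1) <= 0).any():
            raise FormatError(f"{self.matrix_id}: position with zero total count")
        for name in ("core_threshold", "matrix_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{self.matrix_id}: {name}={v} outside [0, 1]")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def frequencies(self, pseudocount: float = 0.01) -> np.ndarray:
        """Column frequencies after adding ``pseudocount`` to every cell."""
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass
class GeneRecord:
    """Gene annotation reduced to what TSS-distance analyses need."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise FormatError(f"{self.gene_id}: empty exon [{a}, {b})")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise FormatError(f"{self.gene_id}: overlapping exons")

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, as 0-based half-open intervals."""
        return [
            (b1, a2)
            for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
            if a2 > b1
        ]


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals (3-7 columns); column 7, if present, is the summit
    offset. Track and comment lines are skipped; input order is preserved."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                summit = int(fields[6]) if len(fields) > 6 and fields[6] != "." else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                out.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.id,
                    format(iv.score, "g"), iv.strand]
            if iv.summit is not None:
                cols.append(str(iv.summit))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{chrom: sequence}``, upper-cased.

    Duplicate chromosome names are rejected.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate chromosome {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TRANSFAC

def _flatten(value) -> str:
    # Bio.motifs stores multi-occurrence TRANSFAC tags as (nested) lists
    while isinstance(value, (list, tuple)) and value:
        value = value[0]
    return str(value)


def _pwm_from_bio_motif(m) -> PWM:
    matrix_id = _flatten(m.get("ID") or m.get("AC") or "?")
    factor = m.get("BF") or m.name or matrix_id
    counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
    return PWM(matrix_id=matrix_id, factor_name=_flatten(factor), counts=counts)


def parse_transfac(path: str | Path) -> list[PWM]:
    """Parse a TRANSFAC flat matrix file into :class:`PWM` records.

    Counts are read row-wise in A C G T column order; each record must have
    at least one position and no negative counts.
    """
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC")
        except Exception as exc:  # Bio raises bare ValueError on bad rows
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no matrix records found")
    return [_pwm_from_bio_motif(m) for m in records]


def write_transfac(pwms: Sequence[PWM], path: str | Path) -> None:
    buf = io.StringIO()
    for p in pwms:
        buf.write(f"ID  {p.matrix_id}\nXX\nBF  {p.factor_name}\nXX\n")
        buf.write("P0      A      C      G      T\n")
        for i, row in enumerate(p.counts, start=1):
            cons = BASES[int(np.argmax(row))]
            buf.write(
                f"{i:02d} {row[0]:10.2f} {row[1]:10.2f} {row[2]:10.2f} {row[3]:10.2f}"
                f"      {cons}\n"
            )
        buf.write("XX\n//\n")
    Path(path).write_text(buf.getvalue())


def read_thresholds(pwms: Sequence[PWM], path: str | Path) -> None:
    """Apply a per-matrix threshold sidecar TSV (matrix_id, core, matrix)
    in place. Matrices absent from the sidecar keep their defaults."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["matrix_id", "core_thr", "matrix_thr"], header=None)
    table = {r.matrix_id: (float(r.core_thr), float(r.matrix_thr))
             for r in df.itertuples()}
    for p in pwms:
        if p.matrix_id in table:
            p.core_threshold, p.matrix_threshold = table[p.matrix_id]


# ---------------------------------------------------------------------------
# Gene table / expression / generic TSV

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exons"]


def _format_exons(exons: list[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in exons) if exons else "."


def _parse_exons(text: str) -> list[tuple[int, int]]:
    if not text or text == ".":
        return []
    out = []
    for chunk in text.split(","):
        a, _, b = chunk.partition("-")
        out.append((int(a), int(b)))
    return out


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the gene-annotation TSV. Duplicate gene ids are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneRecord(
            gene_id=r.gene_id,
            chrom=r.chrom,
            strand=r.strand,
            tss=int(r.tss),
            exons=_parse_exons(r.exons),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "exons": _format_exons(g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a normalized expression TSV with columns gene_id, mean_control,
    mean_treated, present (bool)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_control", "mean_treated", "present"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["present"] = df["present"].astype(bool)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
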