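"""Sequence and annotation I/O.

Coordinate convention used throughout the package: 1-based, inclusive, on
the forward strand.  Genomes are plain nucleotide strings over {A,C,G,T,N};
lowercase and RNA input are normalised on read, IUPAC ambiguity codes are
collapsed to N, and anything else is rejected with the offending position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "CdsRecord",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "cds_sequence",
    "reverse_complement",
]

_DNA = set("ACGTN")
_AMBIGUITY = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_COLUMNS = ["genome_id", "start", "end", "strand", "gene_name"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalise_seq(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if set(seq) <= _DNA:
        return seq
    out = []
    for i, ch in enumerate(seq, start=1):
        if ch in _DNA:
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
        else:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {i}"
            )
    return "".join(out)


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with topology flag."""

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"genome {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(f"genome {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence: 1-based inclusive coordinates on the forward strand."""

    genome_id: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(
                f"CDS {self.gene_name or ''} on {self.genome_id}: start {self.start} "
                "violates the 1-based convention"
            )
        if self.start > self.end:
            raise ValueError(
                f"CDS {self.gene_name or ''} on {self.genome_id}: start > end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS strand must be '+' or '-', got {self.strand!r}")
        if self.protein is not None and self.nt_length % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_name or ''}: length {self.nt_length} not divisible "
                "by 3 but a translation is attached"
            )

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (multi-)FASTA file into Genome records, order preserved."""
    path = Path(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(Genome(id=rec.id, seq=_normalise_seq(str(rec.seq), rec.id)))
    if not genomes:
        raise ValueError(f"{path}: no records")
    return genomes


def write_fasta(genomes: Sequence[Genome], path: str | Path, width: int = 70) -> None:
    """Write genomes as wrapped FASTA. Byte output is deterministic."""
    if not genomes:
        raise ValueError("no genomes to write")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    with open(path, "w", newline="\n") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


def _norm_strand(s: str) -> str:
    # U+2212 minus sign / en dash occur in copy-pasted tables
    return "-" if s in {"−", "–", "-"} else s


def read_feature_table(path: str | Path) -> list[CdsRecord]:
    """Read a TSV feature table (genome_id, start, end, strand, gene_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in FEATURE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CdsRecord(
                genome_id=row.genome_id,
                start=int(row.start),
                end=int(row.end),
                strand=_norm_strand(row.strand),
                gene_name=getattr(row, "gene_name", "") or None,
            )
        )
    return records


def write_feature_table(records: Iterable[CdsRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "gene_name": r.gene_name or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def cds_sequence(genome: Genome, cds: CdsRecord) -> str:
    """Extract the coding-strand nucleotide sequence of a CDS."""
    if cds.end > genome.length:
        raise ValueError(
            f"CDS {cds.gene_name or ''} end {cds.end} beyond genome "
            f"{genome.id} length {genome.length}"
        )
    sub = genome.seq[cds.start - 1 : cds.end]
    return reverse_complement(sub) if cds.strand == "-" else sub
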