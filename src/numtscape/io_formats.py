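"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: every interval in memory is 0-based, half-open
(``[start, end)``), the native BED convention.  Writers that emit 1-based
inclusive coordinates say so in their file header.

Soft-masking is carried as lowercase characters and preserved verbatim by
the FASTA reader/writer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N} with case carrying soft-masks."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomicInterval:
    """Half-open interval on a named sequence, optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class NumtHit:
    """One local alignment between the mitochondrial query and a nuclear locus.

    ``mstart``/``mend`` are coordinates on the (possibly doubled) forward
    mitochondrial axis once the hit is strand-normalized; before
    normalization a minus-strand hit carries coordinates on the
    reverse-complemented query axis.  ``mstart_folded``/``mend_folded`` are
    the circular coordinates on ``[0, L)`` with ``wrap`` set for hits
    crossing the origin.
    """

    hit_id: str
    chrom: str
    nstart: int
    nend: int
    strand: str
    mstart: int
    mend: int
    score: int
    evalue: float
    identity: float
    mstart_folded: int = -1
    mend_folded: int = -1
    wrap: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.nend <= self.nstart:
            raise ValueError("hit nuclear end must exceed start")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0,1]")

    @property
    def nuclear_length(self) -> int:
        return self.nend - self.nstart


HIT_COLUMNS = [
    "hit_id", "chrom", "nstart", "nend", "strand", "mstart", "mend",
    "mstart_folded", "mend_folded", "wrap", "score", "evalue", "identity",
    "normalized",
]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA preserving case; enforce non-empty, unique record ids."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = None
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise ParseError(f"{path}: empty FASTA (no records)")
    if not first_content[1].startswith(">"):
        raise ParseError(
            f"{path}: line {first_content[0]}: expected '>' FASTA header"
        )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ParseError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED; name column holds the label, strand written when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.strand is not None:
                fields.append(iv.label if iv.label is not None else ".")
            if iv.strand is not None:
                fields.extend(["0", iv.strand])
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ParseError(
                    f"{path}: line {lineno}: end <= start ({start}, {end})"
                )
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            intervals.append(GenomicInterval(fields[0], start, end,
                                             strand=strand, label=label))
    return intervals


def read_repeat_annotation(path: str | Path,
                           dialect: str = "bed") -> list[GenomicInterval]:
    """Import repeat-element intervals labeled with their repeat class.

    ``bed``: the BED name column is the class (e.g. ``SINE/tRNA``).
    ``repeatmasker_out``: the whitespace table written by RepeatMasker
    (3 header lines; query coordinates 1-based inclusive; class/family in
    column 11).
    """
    if dialect == "bed":
        return read_bed(path)
    if dialect != "repeatmasker_out":
        raise ValueError(f"unknown repeat annotation dialect {dialect!r}")
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header rows: "SW perc perc ..." / "score div. del. ..." / blank
            if not fields[0].replace(".", "").isdigit():
                continue
            if len(fields) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: too few RepeatMasker columns"
                )
            chrom = fields[4]
            start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            repeat_class = fields[10]
            intervals.append(GenomicInterval(chrom, start, end,
                                             strand=strand, label=repeat_class))
    return intervals


def hits_to_frame(hits: Sequence[NumtHit]) -> pd.DataFrame:
    rows = [
        {c: getattr(h, c) for c in HIT_COLUMNS}
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: Sequence[NumtHit], path: str | Path,
               header_comments: Iterable[str] = ()) -> None:
    """Self-describing TSV with a header line; '#' comments hold provenance."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False)


def read_hits(path: str | Path) -> list[NumtHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(NumtHit(
            hit_id=str(row.hit_id), chrom=str(row.chrom),
            nstart=int(row.nstart), nend=int(row.nend), strand=str(row.strand),
            mstart=int(row.mstart), mend=int(row.mend),
            mstart_folded=int(row.mstart_folded),
            mend_folded=int(row.mend_folded), wrap=bool(row.wrap),
            score=int(row.score), evalue=float(row.evalue),
            identity=float(row.identity), normalized=bool(row.normalized),
        ))
    return hits


def write_table(df: pd.DataFrame, path: str | Path,
                header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
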