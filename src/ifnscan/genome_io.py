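"""Genome I/O: FASTA and GFF3 reading/writing and intergenic-region extraction.

All coordinates inside the package are 0-based half-open on the forward
strand; GFF3's 1-based inclusive convention is converted at the I/O boundary
and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the expected format; message names the offending line."""


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence over {A, C, G, T, N}, upper-cased on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedInterval:
    """A genomic feature: 0-based half-open span with strand and attributes."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "gene"
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def symbol(self) -> str:
        """Gene symbol: Name= attribute if present, else ID=."""
        return self.attributes.get("symbol", "")


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a FASTA file into GenomicSequence records, preserving order.

    Line wrapping is collapsed and sequences are upper-cased. Raises
    FormatError on an empty file or sequence data before the first header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: line 1: empty file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(GenomicSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[GenomicSequence], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_protein_fasta(named_seqs: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (label, protein) pairs as FASTA (no DNA alphabet check)."""
    with open(path, "w") as fh:
        for name, seq in named_seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into (label, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    if "Name" in attrs:
        attrs["symbol"] = attrs["Name"]
    elif "ID" in attrs:
        attrs["symbol"] = attrs["ID"]
    return attrs


def read_gff3(path: str | Path) -> list[AnnotatedInterval]:
    """Read GFF3 features as AnnotatedIntervals (converted to 0-based half-open).

    Columns 4/5 (1-based inclusive) become (start-1, end). The gene symbol is
    taken from Name= when present, else ID=. Raises FormatError, naming the
    line number, on end < start or an unknown strand symbol.
    """
    path = Path(path)
    intervals: list[AnnotatedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated columns")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}: line {lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: unknown strand {strand!r}")
            intervals.append(
                AnnotatedInterval(seq_id, start1 - 1, end1, strand, ftype, _parse_gff3_attributes(attr_s))
            )
    return intervals


def write_gff3(intervals: Iterable[AnnotatedInterval], path: str | Path, source: str = "ifnscan") -> None:
    """Write intervals as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attrs = ";".join(f"{k}={v}" for k, v in iv.attributes.items() if k != "symbol")
            if not attrs and iv.symbol:
                attrs = f"Name={iv.symbol}"
            fh.write(
                f"{iv.seq_id}\t{source}\t{iv.feature_type}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs or '.'}\n"
            )


def extract_intergenic(
    genes: list[AnnotatedInterval], seq: GenomicSequence, min_len: int = 1
) -> list[AnnotatedInterval]:
    """Complement of the union of gene spans on ``seq``, both strands merged.

    Returns sorted, non-overlapping intervals clipped to [0, length), dropping
    pieces shorter than ``min_len``. Strand of the result is reported as '+'
    (intergenic DNA is strandless; downstream scanning handles both strands).
    """
    n = seq.length
    spans = []
    for g in genes:
        if g.seq_id != seq.id:
            raise ValueError(f"gene on {g.seq_id!r} does not belong to sequence {seq.id!r}")
        if g.end > n:
            raise ValueError(f"gene interval [{g.start}, {g.end}) outside sequence of length {n}")
        spans.append((g.start, g.end))
    spans.sort()
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out: list[AnnotatedInterval] = []
    prev = 0
    for s, e in merged + [(n, n)]:
        if s - prev >= min_len and s > prev:
            out.append(AnnotatedInterval(seq.id, prev, s, "+", "intergenic_region", {}))
        prev = max(prev, e)
    return out


def write_intervals_tsv(intervals: Iterable[AnnotatedInterval], path: str | Path) -> None:
    """Dump intervals as a TSV (seq_id, start, end, strand, type, symbol)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tfeature_type\tsymbol\n")
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t{iv.feature_type}\t{iv.symbol}\n")
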