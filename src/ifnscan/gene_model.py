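"""Exon-structured gene models: splicing, translation and intron phases.

The intron phase is the position of an intron relative to codon boundaries
of the coding sequence: phase 0 falls between codons, phases 1 and 2 fall
after the first and second base of a codon. Phase of intron *i* equals the
cumulative length of the coding exons upstream of it, mod 3. Class II
cytokine genes of the kind this package hunts for are five-coding-exon
genes in which every phase is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .genome_io import AnnotatedInterval, GenomicSequence

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA


class TranslationError(ValueError):
    """CDS violates the clean-ORF contract (frameshift or premature stop)."""


@dataclass(frozen=True)
class GeneModel:
    """Coding-exon structure of a gene on one strand.

    ``coding_exons`` are (start, end) 0-based half-open genomic intervals
    listed 5'→3' in *transcript* order: ascending starts on '+', descending
    on '-'. UTRs are not modeled.
    """

    seq_id: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.coding_exons)
        object.__setattr__(self, "coding_exons", exons)
        if not exons:
            raise ValueError("gene model needs at least one coding exon")
        for s, e in exons:
            if e - s < 3:
                raise ValueError(f"coding exon [{s}, {e}) shorter than one codon")
        genomic_order = exons if self.strand == "+" else exons[::-1]
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if s2 - e1 < 1:
                raise ValueError("exons must be separated by introns of length >= 1")

    @property
    def n_exons(self) -> int:
        return len(self.coding_exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        """Lengths in transcript order."""
        return tuple(e - s for s, e in self.coding_exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all exons."""
        starts = [s for s, _ in self.coding_exons]
        ends = [e for _, e in self.coding_exons]
        return min(starts), max(ends)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        order = self.coding_exons if self.strand == "+" else self.coding_exons[::-1]
        gaps = tuple(s2 - e1 for (_, e1), (s2, _) in zip(order, order[1:]))
        return gaps if self.strand == "+" else gaps[::-1]


@dataclass(frozen=True)
class IntronPhaseVector:
    phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(p not in (0, 1, 2) for p in self.phases):
            raise ValueError("phases must be in {0, 1, 2}")

    @property
    def all_zero(self) -> bool:
        return all(p == 0 for p in self.phases)


def intron_phases(model: GeneModel) -> IntronPhaseVector:
    """Phase of each intron: cumulative upstream coding length mod 3.

    Phases are reported 5'→3' in transcript orientation. A single-exon model
    yields an empty vector.
    """
    cum = 0
    phases = []
    for length in model.exon_lengths[:-1]:
        cum += length
        phases.append(cum % 3)
    return IntronPhaseVector(tuple(phases))


def splice(seq: GenomicSequence, model: GeneModel) -> str:
    """Concatenate exon substrings in transcript order; reverse-complement on '-'."""
    for s, e in model.coding_exons:
        if not (0 <= s < e <= seq.length):
            raise ValueError(f"exon [{s}, {e}) out of bounds for {seq.id!r} (length {seq.length})")
    if model.strand == "+":
        return "".join(seq.sequence[s:e] for s, e in model.coding_exons)
    return "".join(str(Seq(seq.sequence[s:e]).reverse_complement()) for s, e in model.coding_exons)


def translate_cds(cds: str) -> str:
    """Translate a clean ORF with the standard genetic code.

    The CDS must be a multiple of 3, start with ATG, end with a stop codon
    and contain no internal in-frame stop. The terminal stop is not emitted,
    so the protein has length(CDS)/3 - 1 residues.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"frameshift: CDS length {len(cds)} not a multiple of 3")
    if len(cds) < 6:
        raise TranslationError("CDS must contain at least a start and a stop codon")
    if not cds.startswith("ATG"):
        raise TranslationError(f"CDS does not start with ATG (got {cds[:3]})")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in STOP_CODONS:
        raise TranslationError(f"CDS does not end with a stop codon (got {codons[-1]})")
    for i, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS:
            raise TranslationError(f"premature termination at codon {i}")
    return str(Seq(cds[:-3]).translate(table=1))


@dataclass(frozen=True)
class FrameshiftReport:
    """Outcome of deleting ``del_len`` bases from a CDS at ``offset``."""

    in_frame: bool
    new_stop_codon_index: int | None


def apply_deletion(cds: str, offset: int, del_len: int) -> FrameshiftReport:
    """Model a genomic deletion inside a CDS (e.g. a CRISPR-induced lesion).

    A deletion whose length is a multiple of 3 preserves the reading frame.
    Otherwise the downstream frame shifts and translation usually hits an
    early stop: the report carries the codon index (in the mutated CDS) of
    the first in-frame stop, or None if the shifted frame is stop-free.
    """
    cds = cds.upper()
    if offset < 0 or del_len < 0 or offset + del_len > len(cds):
        raise ValueError(f"deletion [{offset}, {offset + del_len}) outside CDS of length {len(cds)}")
    in_frame = del_len % 3 == 0
    if in_frame:
        return FrameshiftReport(True, None)
    mutated = cds[:offset] + cds[offset + del_len :]
    for i in range(0, len(mutated) - 2, 3):
        if mutated[i : i + 3] in STOP_CODONS:
            return FrameshiftReport(False, i // 3)
    return FrameshiftReport(False, None)


def model_to_gff3_lines(model: GeneModel, source: str = "ifnscan") -> list[str]:
    """GFF3 rows for one gene: a gene feature plus per-exon CDS features.

    The CDS phase column follows the GFF3 convention (bases to remove from
    the start of the feature to reach the next codon boundary), derived from
    the intron phase vector: phase_column = (3 - upstream_cum mod 3) mod 3.
    """
    span = model.span
    gid = model.label or f"{model.seq_id}:{span[0]}-{span[1]}"
    lines = [
        f"{model.seq_id}\t{source}\tgene\t{span[0] + 1}\t{span[1]}\t.\t{model.strand}\t.\tID={gid}"
    ]
    cum = 0
    for (s, e), length in zip(model.coding_exons, model.exon_lengths):
        gff_phase = (3 - cum % 3) % 3
        lines.append(
            f"{model.seq_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t{gff_phase}\tParent={gid}"
        )
        cum += length
    return lines


def model_as_intervals(model: GeneModel) -> list[AnnotatedInterval]:
    """Exons as AnnotatedIntervals (for TSV dumps and overlap bookkeeping)."""
    return [
        AnnotatedInterval(model.seq_id, s, e, model.strand, "CDS", {"symbol": model.label})
        for s, e in model.coding_exons
    ]
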