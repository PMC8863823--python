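"""Synteny-anchor analysis of candidate loci.

A locus map is the ordered list of gene symbols (with transcription
direction) around a focal gene. Cross-species conservation of the flanking
anchors identifies a locus: the four interferon locus types are recognized
by their published anchor genes — ADARB2/PFKP (type IV), HACD4/ARHGAP27
(type I), DYRK2 (type II) and SYCN/SUPT5H (type III). Symbol matching is
exact after case-folding; no orthology inference is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genome_io import AnnotatedInterval

IFN_LOCUS_ANCHORS: dict[str, frozenset[str]] = {
    "type_I": frozenset({"HACD4", "ARHGAP27"}),
    "type_II": frozenset({"DYRK2"}),
    "type_III": frozenset({"SYCN", "SUPT5H"}),
    "type_IV": frozenset({"ADARB2", "PFKP"}),
}


@dataclass(frozen=True)
class LocusMap:
    species: str
    genes: tuple[tuple[str, str], ...]  # (symbol, strand) in genomic order
    focal_index: int

    def __post_init__(self) -> None:
        genes = tuple((sym.upper(), strand) for sym, strand in self.genes)
        object.__setattr__(self, "genes", genes)
        if not (0 <= self.focal_index < len(genes)):
            raise ValueError("focal_index outside gene list")

    @property
    def focal_symbol(self) -> str:
        return self.genes[self.focal_index][0]

    @property
    def non_focal_symbols(self) -> frozenset[str]:
        return frozenset(sym for i, (sym, _) in enumerate(self.genes) if i != self.focal_index)

    @property
    def left_symbols(self) -> frozenset[str]:
        return frozenset(sym for sym, _ in self.genes[: self.focal_index])

    @property
    def right_symbols(self) -> frozenset[str]:
        return frozenset(sym for sym, _ in self.genes[self.focal_index + 1 :])


@dataclass(frozen=True)
class SyntenyReport:
    shared_anchors: frozenset[str]
    flanking_conserved: bool
    inverted: bool
    jaccard: float


def locus_neighbors(
    annotation: list[AnnotatedInterval], focal_symbol: str, k: int = 5, species: str = ""
) -> LocusMap:
    """The k genes on each side of the focal gene, in genomic order.

    The focal gene must be present exactly once on its sequence; a shorter
    map is returned when fewer than k neighbors exist.
    """
    focal_symbol = focal_symbol.upper()
    hits = [iv for iv in annotation if iv.symbol.upper() == focal_symbol]
    if not hits:
        raise ValueError(f"focal gene {focal_symbol!r} not found")
    if len(hits) > 1:
        raise ValueError(f"focal gene {focal_symbol!r} occurs {len(hits)} times")
    focal = hits[0]
    same_seq = sorted(
        (iv for iv in annotation if iv.seq_id == focal.seq_id), key=lambda iv: iv.start
    )
    idx = same_seq.index(focal)
    lo = max(0, idx - k)
    window = same_seq[lo : idx + k + 1]
    return LocusMap(
        species=species,
        genes=tuple((iv.symbol.upper(), iv.strand) for iv in window),
        focal_index=idx - lo,
    )


def compare_loci(a: LocusMap, b: LocusMap) -> SyntenyReport:
    """Anchor conservation between two locus maps.

    shared_anchors is the intersection of non-focal symbols; jaccard the
    intersection/union ratio; flanking_conserved requires at least one shared
    anchor on each side of the focal gene in both maps; inverted is true when
    the shared anchors appear in reversed relative order between the maps.
    """
    sa, sb = a.non_focal_symbols, b.non_focal_symbols
    shared = sa & sb
    union = sa | sb
    jaccard = len(shared) / len(union) if union else 1.0
    flanking = bool(
        (a.left_symbols & shared and a.right_symbols & shared)
        and (b.left_symbols & shared and b.right_symbols & shared)
    )
    inverted = False
    if len(shared) >= 2:
        order_a = [sym for sym, _ in a.genes if sym in shared]
        order_b = [sym for sym, _ in b.genes if sym in shared]
        if set(order_a) == set(order_b) == shared and len(order_a) == len(set(order_a)):
            inverted = order_a == order_b[::-1] and order_a != order_b
    return SyntenyReport(frozenset(shared), flanking, inverted, jaccard)


def classify_ifn_locus(
    candidate: LocusMap,
    references: dict[str, frozenset[str]] = IFN_LOCUS_ANCHORS,
) -> str:
    """Classify a candidate locus by its strongest anchor overlap.

    Returns the locus type whose reference anchors intersect the candidate's
    non-focal symbols with the highest count (at least one required);
    "novel" when no anchors match, or on a tie (with a warning).
    """
    symbols = candidate.non_focal_symbols
    counts = {t: len(anchors & symbols) for t, anchors in references.items()}
    best = max(counts.values(), default=0)
    if best == 0:
        return "novel"
    winners = sorted(t for t, c in counts.items() if c == best)
    if len(winners) > 1:
        warnings.warn(f"anchor tie between {winners}; classifying as novel")
        return "novel"
    return winners[0]
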