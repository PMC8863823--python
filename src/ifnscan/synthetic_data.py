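"""Synthetic genomes, protein families and locus maps with machine-readable truth.

The generator plants class II cytokine-like genes — five coding exons, all
intron phases zero, GT–AG introns, a signal-peptide-like N-terminus, a
helix-rich core and one CXXXXX[W/L] motif — into i.i.d. background DNA,
alongside decoy genes that each violate exactly one screening criterion:

* ``wrong_exon_count``  — four coding exons instead of five;
* ``nonzero_phase``     — one internal exon boundary shifted by +1 nt
                          (compensated in the next exon), making one phase 1;
* ``no_start``          — the first codon is CTG, not ATG;
* ``internal_stop``     — an in-frame TAA inside the third exon;
* ``no_signal_peptide`` — a polar, acidic N-terminus in place of the
                          signal peptide (protein-level; the gene is found
                          by the scanner but fails criterion 3);
* ``low_helix``         — a helix-poor core (found, but fails criterion 4).

Random background DNA is *not* free of accidental five-exon phase-zero
chains — at the default bounds it contains many, and a few of their protein
products even pass the feature screen. The generator therefore verifies its
own truth record by running the scanner + screen on the finished genome and
re-drawing the offending background (or intron-interior) windows until the
scan output matches the planted truth exactly; the number of repaired
collisions is reported on the truth object. This keeps every generated
genome a deterministic function of (parameters, seed) while guaranteeing
the planted truth is the complete set of passing candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .candidate_search import SearchParams, scan_genome
from .gene_model import GeneModel, intron_phases
from .genome_io import AnnotatedInterval, GenomicSequence, extract_intergenic
from .phylogeny import Node, PhyloTree, parse_newick
from .protein_features import FeatureParams, screen_candidate
from .synteny import LocusMap

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()
_STOPS = ("TAA", "TAG", "TGA")

DEFECT_CLASSES = (
    "wrong_exon_count",
    "nonzero_phase",
    "no_start",
    "internal_stop",
    "no_signal_peptide",
    "low_helix",
)
_STRUCTURAL_DEFECTS = frozenset(
    {"wrong_exon_count", "nonzero_phase", "no_start", "internal_stop"}
)
_SCREEN_DEFECTS = frozenset({"no_signal_peptide", "low_helix"})


@dataclass(frozen=True)
class PlantedGene:
    model: GeneModel
    cls: str          # 'positive' | 'decoy'
    defect: str       # 'none' or a DEFECT_CLASSES member
    protein: str      # intended translation (of the un-defective design)

    @property
    def span(self) -> tuple[int, int]:
        return self.model.span


@dataclass
class SyntheticTruth:
    planted: list[PlantedGene]
    seed: int
    params: SearchParams
    repaired_collisions: int = 0

    @property
    def positives(self) -> list[PlantedGene]:
        return [p for p in self.planted if p.cls == "positive"]

    @property
    def decoys(self) -> list[PlantedGene]:
        return [p for p in self.planted if p.cls == "decoy"]


@dataclass
class SyntheticGenome:
    genome: GenomicSequence
    annotation: list[AnnotatedInterval]  # dummy 'annotated genes' masking the scan
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# protein design

_HELIX_ALPHABET = "AEELKKL"      # Chou-Fasman P(alpha) >= 1.16 throughout
_LINKER = "GNPGS"                # strong helix breakers
_POLAR_N = "STNQK"               # polar, non-hydrophobic (for SP-less decoys)


def _design_protein(rng: np.random.Generator, defect: str = "none") -> str:
    """A protein satisfying (or deliberately violating) the screen.

    Layout: signal peptide (positively charged n-region, poly-L h-region,
    A-S-A cleavage box) + 5–6 amphipathic helix blocks separated by G/P/N
    linkers; one block carries a CXXXXX[W/L] motif. Lengths are randomized
    within the 120–250 residue window; genes carrying a structural defect
    are kept short (<= 135 residues) so that no alternative exon chain
    through their locus can stay above the 120-residue search floor after
    intronizing part of the coding sequence.
    """
    # signal peptide: M K K T L...L A S A  (cleavage at the residue after ASA)
    h_len = int(rng.integers(9, 13))
    sp = "MKKT" + "L" * h_len + "ASA"
    if defect == "no_signal_peptide":
        # polar N-terminus of the same length: no h-region window can form
        body = "".join(rng.choice(list(_POLAR_N), size=len(sp) - 3))
        sp = "MDD" + body
    compact = defect in _STRUCTURAL_DEFECTS
    n_blocks = 5 if compact else int(rng.integers(5, 7))
    blocks = []
    for b in range(n_blocks):
        blen = int(rng.integers(14, 17) if compact else rng.integers(14, 22))
        seq = "".join(_HELIX_ALPHABET[int(x) % len(_HELIX_ALPHABET)]
                      for x in rng.integers(0, len(_HELIX_ALPHABET), size=blen))
        blocks.append(seq)
    # plant the conserved cysteine/tryptophan motif inside the first block
    motif = "C" + "".join(rng.choice(list("AELK"), size=5)) + str(rng.choice(["W", "L"]))
    blocks[0] = blocks[0][:3] + motif + blocks[0][3 + len(motif):]
    if len(blocks[0]) < 14:
        blocks[0] = blocks[0] + "AEELK"[: 14 - len(blocks[0])]
    if defect == "low_helix":
        blocks = ["".join(rng.choice(list("GSNPT"), size=len(b))) for b in blocks]
    core = _LINKER.join(blocks)
    protein = sp + _LINKER + core
    lo, hi = (122, 135) if compact else (125, 240)
    pad = "AEELKKLA"
    while len(protein) < lo:
        protein += pad[: lo - len(protein)] if defect != "low_helix" else "GSNPT"[: lo - len(protein)]
    if len(protein) > hi:
        protein = protein[:hi]
    return protein


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice, plus a random stop codon."""
    codons = [
        _CODONS_BY_AA[aa][int(rng.integers(0, len(_CODONS_BY_AA[aa])))] for aa in protein
    ]
    return "".join(codons) + str(rng.choice(_STOPS))


def _split_exons(n_codons: int, n_exons: int, params: SearchParams,
                 rng: np.random.Generator) -> list[int]:
    """Exon lengths in nt (multiples of 3) summing to the CDS length."""
    min_c = max(params.min_exon // 3 + (params.min_exon % 3 > 0), 1)
    max_c = params.max_exon // 3
    for _ in range(1000):
        cuts = np.sort(rng.integers(1, n_codons, size=n_exons - 1))
        parts = np.diff(np.concatenate([[0], cuts, [n_codons]]))
        if np.all(parts >= min_c) and np.all(parts <= max_c):
            return [int(p) * 3 for p in parts]
    raise RuntimeError("could not split CDS into exons within bounds")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at]))


def _make_intron(rng: np.random.Generator, ilen: int) -> str:
    """A GT...AG intron offering no competing splice signal.

    The interior is built so it contains no GT and no AG dinucleotide:
    after a G the next base is never T, after an A never G. Together with
    the fixed intron length (70 nt: one above the scanner's shortest legal
    intron class and ≡ 1 mod 3, which frame-breaks any exon merge across
    it) this makes the planted exon boundaries the unique chainable
    segmentation through the intron.
    """
    bases = "ACGT"
    out = []
    prev = "T"  # the donor GT's T
    for _ in range(ilen - 4):
        if prev == "G":
            allowed = "ACG"
        elif prev == "A":
            allowed = "ACT"
        else:
            allowed = bases
        nxt = allowed[int(rng.integers(0, len(allowed)))]
        out.append(nxt)
        prev = nxt
    return "GT" + "".join(out) + "AG"


@dataclass(frozen=True)
class _Cassette:
    """A planted gene before placement: forward-strand sequence + local exons."""

    seq: str
    exons: tuple[tuple[int, int], ...]  # local coords, ascending
    strand: str
    cls: str
    defect: str
    protein: str


def _build_cassette(rng: np.random.Generator, cls: str, defect: str,
                    params: SearchParams) -> _Cassette:
    protein = _design_protein(rng, defect)
    cds = _reverse_translate(protein, rng)
    n_exons = 4 if defect == "wrong_exon_count" else 5
    lengths = _split_exons(len(cds) // 3, n_exons, params, rng)
    if defect == "nonzero_phase":
        # +1 nt to exon 3, -1 from exon 4: total preserved, one phase becomes 1
        lengths[2] += 1
        lengths[3] -= 1
    if defect == "no_start":
        cds = "CTG" + cds[3:]
    if defect == "internal_stop":
        # replace a mid-exon-3 codon with TAA (codon-aligned)
        exon3_start = sum(lengths[:2])
        codon_at = (exon3_start + (lengths[2] // 2)) // 3 * 3
        cds = cds[:codon_at] + "TAA" + cds[codon_at + 3:]
    intron_hi = min(2 * params.min_intron, params.max_intron)
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    off = 0
    for k, L in enumerate(lengths):
        exon_seq = cds[off : off + L]
        exons.append((pos, pos + L))
        pieces.append(exon_seq)
        pos += L
        off += L
        if k < len(lengths) - 1:
            pieces.append(_make_intron(rng, intron_hi))
            pos += intron_hi
    strand = "+" if rng.random() < 0.5 else "-"
    seq = "".join(pieces)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        total = len(seq)
        exons = [(total - e, total - s) for s, e in exons]  # still ascending after reverse
        exons = exons[::-1]
    return _Cassette(seq, tuple(exons), strand, cls, defect, protein)


# ---------------------------------------------------------------------------
# genome assembly + self-verification

def generate_genome(
    n_pos: int = 8,
    n_decoy: int = 16,
    genome_len: int = 2_000_000,
    gc: float = 0.4,
    params: SearchParams | None = None,
    seed: int = 42,
    feature_params: FeatureParams = FeatureParams(),
    seq_id: str = "chrSYN",
    max_repair_rounds: int = 40,
    verify: bool = True,
) -> SyntheticGenome:
    """Generate a synthetic genome with planted positives and decoys.

    Planted genes alternate with dummy "annotated genes" (which the scanner
    masks out as non-intergenic), everything separated by at least 1 kb. The
    two annotated genes flanking each planted positive are named after the
    real type IV interferon locus anchors (ADARB2, PFKP) so the synteny stage
    can classify recovered loci. See the module docstring for the
    verify-and-repair contract.
    """
    if params is None:
        params = SearchParams(min_intron=60, max_intron=70)
    rng = np.random.default_rng(seed)

    cassettes: list[_Cassette] = []
    for i in range(n_pos):
        cassettes.append(_build_cassette(rng, "positive", "none", params))
    for i in range(n_decoy):
        defect = DEFECT_CLASSES[i % len(DEFECT_CLASSES)]
        cassettes.append(_build_cassette(rng, "decoy", defect, params))
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]

    # layout: annot, gene, annot, gene, ..., gene, annot  (gaps >= 1 kb)
    annot_lens = [int(rng.integers(2000, 5001)) for _ in range(len(cassettes) + 1)]
    items: list[tuple[str, object]] = []
    for i, cas in enumerate(cassettes):
        items.append(("annot", annot_lens[i]))
        items.append(("gene", cas))
    items.append(("annot", annot_lens[-1]))
    min_gap = 1000
    fixed = sum(
        payload if kind == "annot" else len(payload.seq) for kind, payload in items
    )
    slack = genome_len - fixed - (len(items) + 1) * min_gap
    if slack < 0:
        raise ValueError(
            f"genome_len {genome_len} too small to place {len(cassettes)} genes "
            f"and {len(annot_lens)} annotated spans with 1 kb spacing"
        )
    gap_weights = rng.dirichlet(np.ones(len(items) + 1))
    extra = (gap_weights * slack).astype(int)

    genome = np.frombuffer(_random_dna(rng, genome_len, gc).encode(), dtype=np.uint8).copy()
    annotation: list[AnnotatedInterval] = []
    planted: list[PlantedGene] = []
    pos = 0
    annot_i = 0
    gene_flanks: list[tuple[int, PlantedGene]] = []
    for idx, (kind, payload) in enumerate(items):
        pos += min_gap + int(extra[idx])
        if kind == "annot":
            length = int(payload)
            annotation.append(
                AnnotatedInterval(seq_id, pos, pos + length,
                                  "+" if rng.random() < 0.5 else "-",
                                  "gene", {"symbol": f"GENE{annot_i}"})
            )
            annot_i += 1
            pos += length
        else:
            cas: _Cassette = payload
            genome[pos : pos + len(cas.seq)] = np.frombuffer(cas.seq.encode(), dtype=np.uint8)
            exons = tuple((pos + s, pos + e) for s, e in cas.exons)
            if cas.strand == "-":
                exons = exons[::-1]  # transcript order: descending starts on '-'
            model = GeneModel(seq_id, cas.strand, exons, label=f"{cas.cls}_{len(planted)}")
            planted.append(PlantedGene(model, cas.cls, cas.defect, cas.protein))
            pos += len(cas.seq)
    # name the annotated genes flanking each positive after the IFNU anchors
    for pg in planted:
        if pg.cls != "positive":
            continue
        s, e = pg.span
        left = max((a for a in annotation if a.end <= s), key=lambda a: a.end)
        right = min((a for a in annotation if a.start >= e), key=lambda a: a.start)
        annotation[annotation.index(left)] = replace(
            left, attributes={"symbol": "ADARB2"})
        annotation[annotation.index(right)] = replace(
            right, attributes={"symbol": "PFKP"})

    truth = SyntheticTruth(planted, seed, params)
    syn = SyntheticGenome(
        GenomicSequence(seq_id, genome.tobytes().decode()), annotation, truth
    )
    if verify:
        _verify_and_repair(syn, genome, rng, gc, feature_params, max_repair_rounds)
    return syn


def _immutable_mask(syn: SyntheticGenome, n: int) -> np.ndarray:
    """True where the generator must not touch: entire planted cassettes.

    Intron interiors are part of the cassette design (their ends are built
    wobble-free, see _make_intron), so repair only ever re-draws background.
    """
    mask = np.zeros(n, dtype=bool)
    for pg in syn.truth.planted:
        s, e = pg.span
        mask[s:e] = True
    return mask


def _rebuild_cassette(pg: PlantedGene, rng: np.random.Generator) -> str:
    """Re-draw a planted cassette in place: same protein, same coordinates.

    Synonymous codons and intron interiors are re-sampled; exon/intron
    layout, the encoded protein and the planted defect are reproduced
    exactly, so the truth record stays valid while any accidental splice
    signal inside the cassette is re-rolled.
    """
    lengths = list(pg.model.exon_lengths)
    introns = list(pg.model.intron_lengths)
    cds = _reverse_translate(pg.protein, rng)
    if pg.defect == "nonzero_phase":
        pass  # the shift is encoded in `lengths`; the CDS itself is unchanged
    if pg.defect == "no_start":
        cds = "CTG" + cds[3:]
    if pg.defect == "internal_stop":
        exon3_start = sum(lengths[:2])
        codon_at = (exon3_start + (lengths[2] // 2)) // 3 * 3
        cds = cds[:codon_at] + "TAA" + cds[codon_at + 3:]
    assert sum(lengths) == len(cds), "cassette layout out of sync with protein"
    pieces = []
    off = 0
    for k, L in enumerate(lengths):
        pieces.append(cds[off : off + L])
        off += L
        if k < len(lengths) - 1:
            pieces.append(_make_intron(rng, introns[k]))
    seq = "".join(pieces)
    if pg.model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _verify_and_repair(
    syn: SyntheticGenome,
    genome: np.ndarray,
    rng: np.random.Generator,
    gc: float,
    feature_params: FeatureParams,
    max_rounds: int,
) -> None:
    """Re-draw windows whose accidental chains corrupt the truth record."""
    params = syn.truth.params
    immutable = _immutable_mask(syn, len(genome))
    pos_spans = {pg.span: pg for pg in syn.truth.positives}
    screen_decoy_spans = {
        pg.span: pg for pg in syn.truth.decoys if pg.defect in _SCREEN_DEFECTS
    }
    exact = {tuple(pg.model.coding_exons): pg
             for pg in list(pos_spans.values()) + list(screen_decoy_spans.values())}
    repaired = 0
    for round_ in range(max_rounds):
        seq = GenomicSequence(syn.genome.id, genome.tobytes().decode())
        intergenic = extract_intergenic(syn.annotation, seq, min_len=200)
        candidates = scan_genome(seq, intergenic, params)
        bad_spans: list[tuple[int, int]] = []
        recovered_exact: set[tuple] = set()
        for cand in candidates:
            key = tuple(cand.model.coding_exons)
            if key in exact and cand.model.strand == exact[key].model.strand:
                recovered_exact.add(key)
                continue
            report = screen_candidate(cand, intron_phases(cand.model), feature_params)
            if report.passed:
                bad_spans.append(cand.span)
        for key, pg in exact.items():
            if key not in recovered_exact:
                s, e = pg.span
                bad_spans.append((max(0, s - 400), min(len(genome), e + 400)))
        if not bad_spans:
            syn.truth.repaired_collisions = repaired
            syn.genome = GenomicSequence(syn.genome.id, genome.tobytes().decode())
            return
        rerolled: set[tuple[int, int]] = set()
        for s, e in bad_spans:
            # re-roll any planted cassette the offending span touches
            for pg in syn.truth.planted:
                ps, pe = pg.span
                if ps < e and s < pe and (ps, pe) not in rerolled:
                    cassette = _rebuild_cassette(pg, rng)
                    genome[ps:pe] = np.frombuffer(cassette.encode(), dtype=np.uint8)
                    rerolled.add((ps, pe))
            window = np.arange(s, e)
            mutable = window[~immutable[s:e]]
            fresh = _random_dna(rng, len(mutable), gc)
            genome[mutable] = np.frombuffer(fresh.encode(), dtype=np.uint8)
            repaired += 1
    raise RuntimeError(
        f"could not reconcile scan output with planted truth after {max_rounds} rounds"
    )


# ---------------------------------------------------------------------------
# protein family simulator

def generate_protein_family(
    tree: str | PhyloTree,
    root_seq: str,
    rate: float,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a protein down a tree under a Poisson substitution process.

    Along a branch of length t each site substitutes independently with
    probability 1 - exp(-rate * t); a substituted site takes a uniformly
    random residue among the other 19. Returns {leaf label: sequence}.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if isinstance(tree, str):
        tree = parse_newick(tree)
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out: dict[str, str] = {}

    def evolve(seq: np.ndarray, node: Node) -> None:
        p = 1.0 - np.exp(-rate * node.length)
        hit = rng.random(len(seq)) < p
        if hit.any():
            seq = seq.copy()
            for i in np.nonzero(hit)[0]:
                choices = aas[aas != seq[i]]
                seq[i] = choices[int(rng.integers(0, 19))]
        if node.is_leaf:
            out[node.name] = "".join(seq)
        else:
            for child in node.children:
                evolve(seq, child)

    root = np.array(list(root_seq))
    for child in tree.root.children:
        evolve(root, child)
    if not out:  # degenerate single-node tree
        out[tree.root.name or "root"] = root_seq
    return out


# ---------------------------------------------------------------------------
# locus-map scenarios

def generate_locus_maps(scenario: str, seed: int = 0) -> tuple[LocusMap, LocusMap]:
    """Toy two-species locus maps realizing a conservation scenario.

    Scenarios: 'conserved' (anchors shared, same order, focal flanked),
    'inverted' (shared anchors in reversed order), 'shuffled' (anchors
    present but scrambled, flanking broken), 'novel' (no shared anchors).
    """
    rng = np.random.default_rng(seed)
    filler = [f"FILL{int(x)}" for x in rng.integers(0, 1000, size=8)]
    a = LocusMap(
        species="species_a",
        genes=(("ADARB2", "+"), (filler[0], "-"), ("IFNU_CAND", "+"),
               (filler[1], "+"), ("PFKP", "-")),
        focal_index=2,
    )
    if scenario == "conserved":
        b_genes = (("ADARB2", "+"), (filler[2], "+"), ("IFNU", "+"),
                   (filler[3], "-"), ("PFKP", "-"))
    elif scenario == "inverted":
        b_genes = (("PFKP", "+"), (filler[2], "+"), ("IFNU", "-"),
                   (filler[3], "-"), ("ADARB2", "+"))
    elif scenario == "shuffled":
        b_genes = (("ADARB2", "+"), ("PFKP", "+"), ("IFNU", "+"),
                   (filler[2], "-"), (filler[3], "+"))
    elif scenario == "novel":
        b_genes = ((filler[4], "+"), (filler[5], "+"), ("IFNU", "+"),
                   (filler[6], "-"), (filler[7], "+"))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    b = LocusMap(species="species_b", genes=b_genes, focal_index=2)
    return a, b
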