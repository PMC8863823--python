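"""Protein-feature screening: signal peptides, helix content, motifs, TM segments.

Classical sequence-only predictors stand behind each call:

* signal peptides — a tripartite n/h/c-region model: a non-negatively charged
  N-terminus, a hydrophobic h-region (Kyte–Doolittle window), and a cleavage
  site obeying the von Heijne (-3, -1) small-residue rule;
* alpha helices — Chou–Fasman P(alpha) propensities averaged over a sliding
  window;
* transmembrane segments — long high-hydropathy Kyte–Doolittle windows.

The four-criterion screen combines gene structure (five coding exons, all
intron phases zero) with protein features (signal peptide, multiple alpha
helices). Motif scans (CXXXXX[W/L], box1 PXXL) annotate but never gate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .candidate_search import CandidateGene
from .gene_model import IntronPhaseVector

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Chou & Fasman helix propensities, 1978 table
CHOU_FASMAN_ALPHA = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69,
}

_SMALL_CLEAVAGE = frozenset("AGSCT")  # allowed at the -3 and -1 positions

MOTIFS = {
    "CXXXXX_WL": re.compile(r"(?=(C.....[WL]))"),
    "BOX1_PXXL": re.compile(r"(?=(P..L))"),
}


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds of the feature surrogates (all configurable)."""

    sp_h_window: int = 8          # residues; minimum h-region window
    sp_h_threshold: float = 1.5   # mean Kyte-Doolittle hydropathy of h-region
    sp_n_region: int = 5          # residues considered for N-terminal charge
    sp_search_end: int = 20       # h-region must lie within residues 2..20 (1-based)
    sp_cleavage_min: int = 15     # 1-based cleavage position bounds
    sp_cleavage_max: int = 35
    helix_window: int = 7
    helix_threshold: float = 1.03  # window-mean Chou-Fasman P(alpha)
    helix_min_segment: int = 7
    min_helix_segments: int = 4    # 'multiple alpha helices' criterion
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_run: int = 15


@dataclass(frozen=True)
class SignalPeptideCall:
    has_sp: bool
    cleavage_pos: int                 # 1-based; 0 when absent
    h_region: tuple[int, int] | None  # 0-based half-open residue interval
    score: float


@dataclass(frozen=True)
class HelixProfile:
    per_residue_helix: tuple[bool, ...]
    segments: tuple[tuple[int, int], ...]  # 0-based half-open
    helix_fraction: float


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int  # 0-based residue index of the first residue
    matched: str


@dataclass(frozen=True)
class ScreenReport:
    criteria: dict
    motif_hits: tuple[MotifHit, ...]

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


def _check_protein(protein: str) -> str:
    protein = protein.upper()
    bad = set(protein) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    return protein


def call_signal_peptide(protein: str, params: FeatureParams = FeatureParams()) -> SignalPeptideCall:
    """Tripartite signal-peptide call on the N-terminal region.

    has_sp requires all of:
      (i)   net charge of the first ``sp_n_region`` residues >= 0
            (K, R count +1; D, E count -1);
      (ii)  a window of >= ``sp_h_window`` residues inside positions
            2..``sp_search_end`` (1-based) with mean hydropathy >=
            ``sp_h_threshold`` — the h-region (widest such window, leftmost
            on ties);
      (iii) a cleavage position p in [cleavage_min, cleavage_max] whose -1
            and -3 residues (p-1 and p-3, 1-based) are small (A, G, S, C, T);
            the smallest valid p is reported.

    The score is the mean h-region hydropathy (0 when there is none).
    """
    protein = _check_protein(protein)
    if len(protein) < 20:
        raise ValueError("too short for signal-peptide call (need >= 20 residues)")
    charge = sum({"K": 1, "R": 1, "D": -1, "E": -1}.get(aa, 0) for aa in protein[: params.sp_n_region])
    n_ok = charge >= 0

    kd = np.array([KYTE_DOOLITTLE[aa] for aa in protein])
    lo, hi = 1, min(params.sp_search_end, len(protein))  # 0-based slice bounds of 2..search_end
    h_region = None
    best_len = 0
    for w in range(hi - lo, params.sp_h_window - 1, -1):
        for s in range(lo, hi - w + 1):
            if kd[s : s + w].mean() >= params.sp_h_threshold:
                if w > best_len:
                    best_len, h_region = w, (s, s + w)
                break
        if h_region is not None:
            break

    cleavage = 0
    for p in range(params.sp_cleavage_min, min(params.sp_cleavage_max, len(protein)) + 1):
        if protein[p - 2] in _SMALL_CLEAVAGE and protein[p - 4] in _SMALL_CLEAVAGE:
            cleavage = p
            break

    has_sp = n_ok and h_region is not None and cleavage > 0
    score = float(kd[h_region[0] : h_region[1]].mean()) if h_region else 0.0
    return SignalPeptideCall(has_sp, cleavage if has_sp else 0, h_region, score)


def helix_profile(protein: str, params: FeatureParams = FeatureParams()) -> HelixProfile:
    """Window-averaged Chou–Fasman helix propensity profile.

    A residue is helical when the centered window of ``helix_window``
    residues around it (fully inside the sequence) has mean P(alpha) >=
    ``helix_threshold``. Segments are maximal helical runs of at least
    ``helix_min_segment`` residues.
    """
    protein = _check_protein(protein)
    w = params.helix_window
    if len(protein) < w:
        raise ValueError(f"protein shorter than helix window ({w})")
    pa = np.array([CHOU_FASMAN_ALPHA[aa] for aa in protein])
    means = np.convolve(pa, np.ones(w) / w, mode="valid")  # index i -> window [i, i+w)
    half = w // 2
    helical = np.zeros(len(protein), dtype=bool)
    helical[half : half + len(means)] = means >= params.helix_threshold
    segments = []
    i = 0
    n = len(protein)
    while i < n:
        if helical[i]:
            j = i
            while j < n and helical[j]:
                j += 1
            if j - i >= params.helix_min_segment:
                segments.append((i, j))
            i = j
        else:
            i += 1
    frac = float(helical.sum()) / n
    return HelixProfile(tuple(bool(x) for x in helical), tuple(segments), frac)


def find_motif(protein: str, motif_name: str) -> list[MotifHit]:
    """All (possibly overlapping) hits of a named motif, left to right.

    CXXXXX_WL: C, five arbitrary residues, then W or L (the conserved
    cysteine/tryptophan-leucine pattern of the interferon family).
    BOX1_PXXL: the box1 membrane-proximal receptor motif P-x-x-L.
    """
    protein = _check_protein(protein)
    if motif_name not in MOTIFS:
        raise ValueError(f"unknown motif {motif_name!r}; known: {sorted(MOTIFS)}")
    pattern = MOTIFS[motif_name]
    return [MotifHit(motif_name, m.start(), m.group(1)) for m in pattern.finditer(protein)]


def find_tm_segments(protein: str, params: FeatureParams = FeatureParams()) -> list[tuple[int, int]]:
    """Transmembrane-like segments: long runs of high Kyte–Doolittle windows.

    A residue is TM-like when its centered ``tm_window`` mean hydropathy is
    >= ``tm_threshold``; windows are truncated at the sequence ends (so a
    TM helix flush against a terminus is still seen). Maximal runs shorter
    than ``tm_min_run`` are discarded; proteins shorter than the window
    yield an empty list.
    """
    protein = _check_protein(protein)
    w = params.tm_window
    if len(protein) < w:
        return []
    kd = np.array([KYTE_DOOLITTLE[aa] for aa in protein])
    half = w // 2
    cum = np.concatenate([[0.0], np.cumsum(kd)])
    n = len(protein)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    marked = (cum[hi] - cum[lo]) / (hi - lo) >= params.tm_threshold
    segments = []
    i = 0
    while i < len(protein):
        if marked[i]:
            j = i
            while j < len(protein) and marked[j]:
                j += 1
            if j - i >= params.tm_min_run:
                segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def screen_candidate(
    cand: CandidateGene,
    phases: IntronPhaseVector,
    params: FeatureParams = FeatureParams(),
    n_exons: int = 5,
) -> ScreenReport:
    """Apply the four-criterion class II cytokine screen to a candidate.

    1. five coding exons; 2. all intron phases zero; 3. signal peptide at the
    N-terminus; 4. multiple alpha helices (>= ``min_helix_segments`` segments).
    Motif hits are attached as annotation and do not affect pass/fail.
    """
    criteria = {
        "five_exons": cand.model.n_exons == n_exons,
        "phase_zero": phases.all_zero,
    }
    try:
        criteria["signal_peptide"] = call_signal_peptide(cand.protein, params).has_sp
    except ValueError:
        criteria["signal_peptide"] = False
    try:
        prof = helix_profile(cand.protein, params)
        criteria["multi_helix"] = len(prof.segments) >= params.min_helix_segments
    except ValueError:
        criteria["multi_helix"] = False
    hits = tuple(find_motif(cand.protein, "CXXXXX_WL")) if cand.protein else ()
    return ScreenReport(criteria, hits)
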