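"""Pairwise and progressive protein alignment with percent-identity statistics.

Pairwise alignment is global Needleman–Wunsch with affine gap costs (Gotoh's
three-state recursion); multiple alignment is classic progressive alignment:
pairwise p-distances → UPGMA guide tree → profile–profile merges. Percent
identity is defined as 100 × identical columns / columns in which at least
one row has a residue (terminal gaps therefore count in the denominator);
this convention is used consistently for identity matrices and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}
# dense 20x20 copy of BLOSUM62 for profile scoring
_B62 = np.array([[float(BLOSUM62[a][b]) for b in _AA] for a in _AA])

GAP_OPEN = 10.0    # cost of the first residue of a gap
GAP_EXTEND = 0.5   # cost of each subsequent gap residue


def _check(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {name}")
    seq = seq.upper()
    bad = set(seq) - set(_AA)
    if bad:
        raise ValueError(f"non-amino-acid characters in {name}: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column with two gaps")

    @property
    def identity_pct(self) -> float:
        return percent_identity(self)


def global_align(
    a: str,
    b: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (BLOSUM62, NW end-gap costs).

    A gap of length L costs gap_open + (L-1) * gap_extend; end gaps are
    penalized like internal ones. The first optimal alignment in the
    aligner's deterministic enumeration order is returned.
    """
    from Bio.Align import PairwiseAligner

    a, b = _check(a, "first sequence"), _check(b, "second sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = next(iter(aligner.align(a, b)))
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def global_align_dp(
    a: str,
    b: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> PairwiseAlignment:
    """Reference Gotoh three-state dynamic program (pure Python).

    Same scoring convention as :func:`global_align`; used as an independent
    cross-check. Ties are broken in traceback preferring match/mismatch,
    then a gap in the first sequence.
    """
    a, b = _check(a, "first sequence"), _check(b, "second sequence")
    n, m = len(a), len(b)
    NEG = -1e30
    ai = np.array([_AA_INDEX[c] for c in a])
    bi = np.array([_AA_INDEX[c] for c in b])
    S = _B62[np.ix_(ai, bi)]  # S[i,j] = score(a[i], b[j])

    # M: a[i-1]~b[j-1]; X: gap in b (a residue unmatched); Y: gap in a
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)

    # traceback, preferring match/mismatch, then gap-in-a, then gap-in-b
    i, j = n, m
    score = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] == score:
        state = "M"
    elif Y[n, m] == score:
        state = "Y"
    else:
        state = "X"
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target, eps)
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(here - (M[i, j] - gap_open)) < eps:
                state = "M"
            elif abs(here - (X[i, j] - gap_extend)) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(here - (M[i, j] - gap_open)) < eps:
                state = "M"
            elif abs(here - (Y[i, j] - gap_extend)) < eps:
                state = "Y"
            else:
                state = "X"
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


def _pick_state(m: float, x: float, y: float, target: float, eps: float) -> str:
    if abs(m - target) < eps:
        return "M"
    if abs(y - target) < eps:
        return "Y"
    return "X"


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 × identical columns / columns with at least one residue."""
    cols = [(x, y) for x, y in zip(aln.aligned_a, aln.aligned_b)]
    if not cols:
        raise ValueError("zero-length alignment")
    denom = sum(1 for x, y in cols if x != "-" or y != "-")
    ident = sum(1 for x, y in cols if x == y and x != "-")
    return round(100.0 * ident / denom, 1)


def pairwise_identity_from_rows(row_a: str, row_b: str) -> float:
    """Percent identity of two rows of an MSA under the package convention."""
    denom = sum(1 for x, y in zip(row_a, row_b) if x != "-" or y != "-")
    if denom == 0:
        raise ValueError("rows share no residue columns")
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return round(100.0 * ident / denom, 1)


# ---------------------------------------------------------------------------
# progressive MSA

def _profile(rows: list[str]) -> np.ndarray:
    """(L, 21) residue-frequency profile; column 20 is the gap fraction."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for row in rows:
        for i, c in enumerate(row):
            prof[i, 20 if c == "-" else _AA_INDEX[c]] += 1
    return prof / len(rows)


def _profile_align(rows_a: list[str], rows_b: list[str],
                   gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (expected BLOSUM62 score)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = len(pa), len(pb)
    # expected substitution score between columns, gaps scoring 0
    S = pa[:, :20] @ _B62 @ pb[:, :20].T
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        ptrY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + S[i - 1, j - 1]
            ptrM[i, j] = k
            opts = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptrX[i, j] = k
            opts = (M[i, j - 1] - gap_open, X[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptrY[i, j] = k
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    cols_a: list[int] = []  # 1 = consume column, 0 = gap
    cols_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            cols_a.append(1)
            cols_b.append(1)
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            cols_a.append(1)
            cols_b.append(0)
            i -= 1
            state = prev
        else:
            prev = ptrY[i, j]
            cols_a.append(0)
            cols_b.append(1)
            j -= 1
            state = prev
    cols_a.reverse()
    cols_b.reverse()

    def expand(rows: list[str], cols: list[int]) -> list[str]:
        out = []
        for row in rows:
            it = iter(row)
            out.append("".join(next(it) if c else "-" for c in cols))
        return out

    return expand(rows_a, cols_a), expand(rows_b, cols_b)


def progressive_msa(seqs: dict[str, str] | list[tuple[str, str]],
                    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND) -> dict[str, str]:
    """Progressive multiple alignment guided by a UPGMA tree of p-distances.

    Returns label → gapped row, all rows of equal length. Two sequences reduce
    to the pairwise global alignment.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    labels = [lab for lab, _ in items]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels in MSA input")
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    checked = [(lab, _check(s, lab)) for lab, s in items]
    if len(checked) == 2:
        aln = global_align(checked[0][1], checked[1][1], gap_open, gap_extend)
        return {checked[0][0]: aln.aligned_a, checked[1][0]: aln.aligned_b}

    n = len(checked)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(checked[i][1], checked[j][1], gap_open, gap_extend)
            dist[i, j] = dist[j, i] = 1.0 - aln.identity_pct / 100.0

    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    Z = average(squareform(dist, checks=False))
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([checked[i][0]], [checked[i][1]]) for i in range(n)
    }
    for k, (ia, ib, _, _) in enumerate(Z):
        la, ra = clusters.pop(int(ia))
        lb, rb = clusters.pop(int(ib))
        merged_a, merged_b = _profile_align(ra, rb, gap_open, gap_extend)
        clusters[n + k] = (la + lb, merged_a + merged_b)
    labs, rows = clusters.popitem()[1]
    out = dict(zip(labs, rows))
    return {lab: out[lab] for lab in labels}


# ---------------------------------------------------------------------------
# matrices

def identity_matrix(msa: dict[str, str]) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix from MSA rows (diag 100)."""
    labels = list(msa)
    mat = pd.DataFrame(100.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            v = pairwise_identity_from_rows(msa[a], msa[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def distance_matrix(msa: dict[str, str], correction: str = "p") -> pd.DataFrame:
    """Evolutionary distances from an MSA: d = 1 - identity/100 (p-distance)
    or -ln(1 - p) (Poisson correction; p = 1 is saturated and an error).
    """
    if len(msa) < 3:
        raise ValueError("distance matrix needs at least 3 labels")
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    idm = identity_matrix(msa)
    p = 1.0 - idm.to_numpy() / 100.0
    np.fill_diagonal(p, 0.0)
    if correction == "poisson":
        if np.any(p >= 1.0):
            raise ValueError("saturated distance: p-distance of 1 cannot be Poisson-corrected")
        p = -np.log(1.0 - p)
    return pd.DataFrame(p, index=idm.index, columns=idm.columns)


def matrix_to_tsv(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.4f")


def write_aligned_fasta(msa: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for lab, row in msa.items():
            fh.write(f">{lab}\n{row}\n")
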