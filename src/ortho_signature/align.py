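"""Pairwise and progressive multiple protein alignment.

Pairwise alignment is true global (Needleman-Wunsch/Gotoh) with affine gaps
and penalised terminal gaps: the presence or absence of N/C-terminal tails
is biological signal here and must not be hidden by free end gaps.  The
multiple aligner is a classic progressive scheme (k-mer distance -> UPGMA
guide tree -> profile-profile merges); a pre-aligned FASTA can bypass it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .errors import LookupMissingError, ValidationError
from .seqio import AMINO_ACIDS, GAP, MasterAlignment, ProteinSequence


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValidationError("require gap_open <= gap_extend < 0")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")

    @property
    def identity_pct(self) -> float:
        """100 x identical pairs / columns where neither row is a gap."""
        pairs = [(x, y) for x, y in zip(self.aligned_a, self.aligned_b)
                 if x != GAP and y != GAP]
        if not pairs:
            return 0.0
        return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = scheme.matrix
    al.open_gap_score = scheme.gap_open
    al.extend_gap_score = scheme.gap_extend
    return al


def global_align(a: ProteinSequence, b: ProteinSequence,
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein sequences.

    Tie-breaking among co-optimal alignments is the aligner's fixed
    enumeration order, so results are deterministic.
    """
    al = _aligner(scheme)
    res = al.align(a.residues, b.residues)
    best = res[0]
    return PairwiseAlignment(aligned_a=best[0], aligned_b=best[1], score=best.score)


def alignment_score(aln: PairwiseAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Recompute the affine-gap score of an emitted alignment (self-consistency)."""
    M = scheme.matrix
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP:
            score += scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += scheme.gap_extend if in_gap_b else scheme.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += M[x, y]
            in_gap_a = in_gap_b = False
    return score


def percent_identity(a: ProteinSequence, b: ProteinSequence,
                     scheme: ScoringScheme = DEFAULT_SCHEME, ndigits: int = 1) -> float:
    """Percent identity over mutually aligned (non-gap) columns; symmetric."""
    return round(global_align(a, b, scheme).identity_pct, ndigits)


# ---------------------------------------------------------------------------
# Progressive multiple alignment

_AA_INDEX = {ch: i for i, ch in enumerate(AMINO_ACIDS)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if min(len(a), len(b)) <= k:
        return 0.0 if a == b else 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequencies per column, denominators = n_rows.

    Gap and 'X' mass is simply absent, so gappy columns score weakly —
    which is the behaviour we want when stacking terminal tails.
    """
    L = len(rows[0])
    F = np.zeros((L, 20))
    for row in rows:
        for j, ch in enumerate(row):
            i = _AA_INDEX.get(ch)
            if i is not None:
                F[j, i] += 1.0
    return F / len(rows)


def _blosum_array(matrix) -> np.ndarray:
    S = np.zeros((20, 20))
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            S[i, j] = matrix[x, y]
    return S


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Affine-gap global profile-profile alignment (Gotoh), deterministic.

    Tie order at each cell: diagonal (match) > gap in B (consume A column)
    > gap in A (consume B column).
    """
    S = _blosum_array(scheme.matrix)
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    C = FA @ S @ FB.T  # column-pair scores
    la, lb = C.shape
    go, ge = scheme.gap_open, scheme.gap_extend
    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (A column vs gap)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    # 0 = diag, 1 = up (X), 2 = left (Y); per-state tracebacks
    ptr = np.zeros((3, la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + ge * (i - 1)
        ptr[1, i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = go + ge * (j - 1)
        ptr[2, 0, j] = 2
    for i in range(1, la + 1):
        Ci = C[i - 1]
        for j in range(1, lb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + Ci[j - 1]
            if best_prev == M[i - 1, j - 1]:
                ptr[0, i, j] = 0
            elif best_prev == X[i - 1, j - 1]:
                ptr[0, i, j] = 1
            else:
                ptr[0, i, j] = 2
            xo, xe = M[i - 1, j] + go, X[i - 1, j] + ge
            if xe > xo:
                X[i, j], ptr[1, i, j] = xe, 1
            else:
                X[i, j], ptr[1, i, j] = xo, 0
            yo, ye = M[i, j - 1] + go, Y[i, j - 1] + ge
            if ye > yo:
                Y[i, j], ptr[2, i, j] = ye, 2
            else:
                Y[i, j], ptr[2, i, j] = yo, 0
    finals = (M[la, lb], X[la, lb], Y[la, lb])
    state = int(np.argmax(finals))
    i, j = la, lb
    ops: list[int] = []  # 0 diag, 1 up, 2 left
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == 0:
            ops.append(0)
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            i -= 1
        else:
            ops.append(2)
            j -= 1
        state = int(prev)
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += GAP
    return out_a, out_b


def progressive_msa(seqs: list[ProteinSequence],
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> MasterAlignment:
    """Progressive multiple alignment via k-mer distance + UPGMA guide tree."""
    if not seqs:
        raise ValidationError("no sequences to align")
    if len(seqs) == 1:
        return MasterAlignment(ids=[seqs[0].id], rows=[seqs[0].residues])
    n = len(seqs)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(_kmer_distance(seqs[i].residues, seqs[j].residues))
    Z = linkage(np.asarray(cond), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].residues]) for i in range(n)
    }
    nxt = n
    for a, b, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b, scheme)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (ids, rows), = clusters.values()
    order = {s.id: k for k, s in enumerate(seqs)}
    pairs = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return MasterAlignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


# ---------------------------------------------------------------------------
# Query -> master-alignment coordinates

def map_query_to_master(query: ProteinSequence, master: MasterAlignment,
                        anchor_id: str,
                        scheme: ScoringScheme = DEFAULT_SCHEME) -> dict[int, str]:
    """Project a query onto master columns through a pairwise anchor alignment.

    Returns {master column (1-based) -> query residue or '-'}.  Columns where
    the anchor row itself has a gap map to '-'; query residues falling in
    insertions relative to the anchor are not representable and are dropped.
    """
    if anchor_id not in master.ids:
        raise LookupMissingError(f"anchor {anchor_id!r} not in master alignment")
    anchor_row = master.row(anchor_id)
    anchor_seq = anchor_row.replace(GAP, "")
    aln = global_align(query, ProteinSequence(id=anchor_id, residues=anchor_seq), scheme)
    # anchor residue index (0-based) -> query char
    per_anchor: dict[int, str] = {}
    qi = ai = 0
    for qc, ac in zip(aln.aligned_a, aln.aligned_b):
        if ac != GAP:
            per_anchor[ai] = qc if qc != GAP else GAP
            ai += 1
        if qc != GAP:
            qi += 1
    mapping: dict[int, str] = {}
    k = 0
    for col, ch in enumerate(anchor_row, start=1):
        if ch == GAP:
            mapping[col] = GAP
        else:
            mapping[col] = per_anchor.get(k, GAP)
            k += 1
    return mapping


def anchor_position_to_column(master: MasterAlignment, anchor_id: str,
                              residue_pos: int) -> int:
    """1-based residue number on the (ungapped) anchor -> master column."""
    row = master.row(anchor_id)
    k = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            k += 1
            if k == residue_pos:
                return col
    raise ValidationError(
        f"anchor {anchor_id!r} has only {k} residues; position {residue_pos} out of range")
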