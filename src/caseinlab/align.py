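"""Pairwise and progressive multiple alignment of protein panels.

The pairwise stage is optimal global alignment under BLOSUM62 with affine gap
penalties (open 10, extend 0.5, matrix units). The multiple-alignment stage is
classic progressive alignment: a UPGMA guide tree built from pairwise
alignment distances, then profile-profile merging along the guide tree with
sum-of-pairs BLOSUM62 column scores and a linear gap cost ("once a gap,
always a gap" — gaps introduced at a merge are never removed).

A pre-computed alignment (e.g. from an external aligner) can always be
supplied downstream instead; every consumer takes an :class:`Alignment`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import ALPHABET, FormatError, ProteinSequence

GAP = "-"

_RES_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 restricted to the 20 canonical residues, fixed order.
BLOSUM62 = np.array(
    [[_BLOSUM62[a][b] for b in ALPHABET] for a in ALPHABET], dtype=float
)

#: Affine gap penalties (matrix units) shared by both alignment stages.
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: ordered labels and equal-length rows."""

    ids: tuple[str, ...]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment labels must be unique")
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) != 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[self.ids[0]])

    def __len__(self) -> int:
        return len(self.ids)

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace(GAP, "")

    def matrix(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) uint8 byte matrix (row order = ids)."""
        return np.array(
            [np.frombuffer(self.rows[i].encode(), dtype=np.uint8) for i in self.ids]
        )

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label in self.ids:
                fh.write(f">{label}\n")
                row = self.rows[label]
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.description.strip() or rec.id)
            rows[ids[-1]] = str(rec.seq).upper()
        if not ids:
            raise FormatError(f"{path}: no alignment records found")
        return cls(ids=tuple(ids), rows=rows)


def _aligner() -> _bioalign.PairwiseAligner:
    al = _bioalign.PairwiseAligner()
    al.substitution_matrix = _BLOSUM62
    al.mode = "global"
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def _label(seq: ProteinSequence | str, fallback: str) -> str:
    return seq.label if isinstance(seq, ProteinSequence) else fallback


def _residues(seq: ProteinSequence | str) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else seq


def pairwise_global_align(
    a: ProteinSequence | str, b: ProteinSequence | str
) -> Alignment:
    """Optimal global alignment of two sequences (BLOSUM62, affine gaps).

    Among co-optimal alignments the first in the aligner's deterministic
    enumeration order is returned, so results are reproducible.
    """
    la, lb = _label(a, "a"), _label(b, "b")
    if la == lb:
        la, lb = la + "/1", lb + "/2"
    aln = _aligner().align(_residues(a), _residues(b))[0]
    ra, rb = str(aln[0]), str(aln[1])
    return Alignment(ids=(la, lb), rows={la: ra, lb: rb})


def pairwise_score(a: ProteinSequence | str, b: ProteinSequence | str) -> float:
    """Optimal global alignment score (symmetric in its arguments)."""
    return float(_aligner().score(_residues(a), _residues(b)))


def _pairwise_p_distance(a: str, b: str) -> float:
    aln = pairwise_global_align(a, b)
    ra, rb = aln.rows[aln.ids[0]], aln.rows[aln.ids[1]]
    comparable = ident = 0
    for x, y in zip(ra, rb):
        if x != GAP and y != GAP:
            comparable += 1
            if x == y:
                ident += 1
    if comparable == 0:
        return 1.0
    return 1.0 - ident / comparable


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(n_cols, 20) residue-count matrix of a profile (gaps contribute nothing)."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _RES_INDEX[ch]] += 1
    return counts


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh alignment of two profiles: sum-of-pairs BLOSUM62 column scores
    with affine gaps; returns the two row sets with merge gaps inserted."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    score = (ca @ BLOSUM62 @ cb.T) / (na * nb)
    m, n = score.shape
    go, ge = GAP_OPEN, GAP_EXTEND
    neg = -np.inf
    M = np.full((m + 1, n + 1), neg)   # ends in a column pair
    X = np.full((m + 1, n + 1), neg)   # ends with gap in profile b (consumes a)
    Y = np.full((m + 1, n + 1), neg)   # ends with gap in profile a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -go - ge * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = -go - ge * (j - 1)
    # pointers: per state, where it came from (0=M, 1=X, 2=Y)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(1, m + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        srow = score[i - 1]
        pMi, pXi, pYi = pM[i], pX[i], pY[i]
        for j in range(1, n + 1):
            # match state
            dm, dx, dy = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            best, src = dm, 0
            if dx > best:
                best, src = dx, 1
            if dy > best:
                best, src = dy, 2
            Mi[j] = best + srow[j - 1]
            pMi[j] = src
            # gap in b (move down)
            open_x, ext_x = Mi1[j] - go, Xi1[j] - ge
            if open_x >= ext_x:
                Xi[j], pXi[j] = open_x, 0
            else:
                Xi[j], pXi[j] = ext_x, 1
            # gap in a (move right)
            open_y, ext_y = Mi[j - 1] - go, Yi[j - 1] - ge
            if open_y >= ext_y:
                Yi[j], pYi[j] = open_y, 0
            else:
                Yi[j], pYi[j] = ext_y, 2
    # traceback from the best final state
    finals = (M[m, n], X[m, n], Y[m, n])
    state = int(np.argmax(finals))
    i, j = m, n
    path: list[int] = []  # 0 diag, 1 up, 2 left
    while i or j:
        if i == 0:
            path.append(2); j -= 1; continue
        if j == 0:
            path.append(1); i -= 1; continue
        if state == 0:
            path.append(0)
            state = int(pM[i, j]); i -= 1; j -= 1
        elif state == 1:
            path.append(1)
            state = int(pX[i, j]); i -= 1
        else:
            path.append(2)
            state = int(pY[i, j]); j -= 1
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ai = bi = 0
    for move in path:
        take_a = move in (0, 1)
        take_b = move in (0, 2)
        for k, row in enumerate(rows_a):
            out_a[k] += row[ai] if take_a else GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[bi] if take_b else GAP
        ai += take_a
        bi += take_b
    return out_a, out_b


def progressive_align(seqs: list[ProteinSequence]) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Guide distances are p-distances from pairwise optimal global alignments;
    clusters are merged by profile-profile alignment, so gaps opened at any
    merge persist to the final alignment.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    labels = [_label(s, f"seq{i}") for i, s in enumerate(seqs)]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")
    residues = [_residues(s) for s in seqs]
    n = len(seqs)
    if n == 2:
        aln = pairwise_global_align(residues[0], residues[1])
        rows = dict(zip(labels, (aln.rows[i] for i in aln.ids)))
        return Alignment(ids=tuple(labels), rows=rows)

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _pairwise_p_distance(residues[i], residues[j])
    merges = linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [residues[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(merges):
        la, ra = clusters.pop(int(a))
        lb, rb = clusters.pop(int(b))
        ma, mb = _merge_profiles(ra, rb)
        clusters[n + k] = (la + lb, ma + mb)
    (_, (final_labels, final_rows)), = clusters.items()
    rows = dict(zip(final_labels, final_rows))
    # present rows in input order
    return Alignment(ids=tuple(labels), rows=rows)


def stack_alignment(seqs: list[ProteinSequence]) -> Alignment:
    """Gap-free alignment of equal-length sequences (for indel-free families)."""
    labels = [_label(s, f"seq{i}") for i, s in enumerate(seqs)]
    lengths = {len(_residues(s)) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("stack_alignment requires equal-length sequences")
    return Alignment(
        ids=tuple(labels), rows={l: _residues(s) for l, s in zip(labels, seqs)}
    )
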