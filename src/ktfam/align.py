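"""Multiple alignment, conserved-block filtering and identity distances.

The multiple aligner is a plain progressive method: a UPGMA guide tree
on pairwise-identity distances, then profile-profile global alignment
with linear gap costs.  It is adequate for the low-divergence synthetic
families this package simulates; for real proteomes use any external
aligner and feed the aligned FASTA in through ``msa_from_aligned``.

The block filter removes low-quality alignment regions the way
GBlocks-style filters do, with the parameter set used for the K+
transporter families: conserved/flank thresholds at half the number of
sequences (ceiling), maximum run of contiguous non-conserved positions
20, minimum block length 2, and gap characters counted like any other
symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .curation import make_aligner, pair_score
from .seqio import ProteinRecord


@dataclass
class Msa:
    """An aligned block: parallel ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class BlockFilterParams:
    """GBlocks-style filter parameters; None thresholds mean ceil(n/2)."""

    min_conserved: int | None = None
    min_flank: int | None = None
    max_nonconserved_run: int = 20
    min_block_len: int = 2
    gaps_allowed: bool = True

    def resolved(self, n_rows: int) -> tuple[int, int]:
        half = math.ceil(n_rows / 2)
        conserved = self.min_conserved if self.min_conserved is not None else half
        flank = self.min_flank if self.min_flank is not None else half
        if not 1 <= conserved <= n_rows:
            raise ValueError("min_conserved out of range")
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")
        return conserved, flank


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # gap handled separately
_SYM_INDEX = {sym: k for k, sym in enumerate(_ALPHABET)}
_BLOSUM_RAW = substitution_matrices.load("BLOSUM62")
_S21 = np.array(
    [[float(_BLOSUM_RAW[a][b]) for b in _ALPHABET] for a in _ALPHABET]
)


def _profile_counts(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue counts (ncols, 21) and non-gap totals."""
    ncols = len(rows[0])
    counts = np.zeros((ncols, len(_ALPHABET)))
    for row in rows:
        for j, sym in enumerate(row):
            if sym != "-":
                counts[j, _SYM_INDEX[sym]] += 1
    return counts, counts.sum(axis=1)


def _profile_score(col_a: str, col_b: str) -> float:
    """Mean BLOSUM62 score over non-gap residue pairs of two columns."""
    fa, na = _profile_counts(list(col_a))  # each residue as a 1-column row
    fb, nb = _profile_counts(list(col_b))
    denom = na[0] * nb[0]
    return float(fa[0] @ _S21 @ fb[0] / denom) if denom else 0.0


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_score: float = -8.0
) -> tuple[list[str], list[str]]:
    """Global alignment of two profiles, linear gaps, deterministic ties.

    Column-vs-column score is the mean BLOSUM62 score over non-gap
    residue pairs (precomputed as one matrix product).  Tie preference:
    diagonal, then gap in B (up), then gap in A (left).
    """
    cols_a = ["".join(r[j] for r in rows_a) for j in range(len(rows_a[0]))] if rows_a[0] else []
    cols_b = ["".join(r[j] for r in rows_b) for j in range(len(rows_b[0]))] if rows_b[0] else []
    la, lb = len(cols_a), len(cols_b)
    fa, na = _profile_counts(rows_a)
    fb, nb = _profile_counts(rows_b)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        match = np.where(denom > 0, fa @ _S21 @ fb.T / np.maximum(denom, 1e-300), 0.0)

    score = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i][0] = i * gap_score
        move[i][0] = 1
    for j in range(1, lb + 1):
        score[0][j] = j * gap_score
        move[0][j] = 2
    for i in range(1, la + 1):
        prev = score[i - 1]
        cur = score[i]
        mrow = match[i - 1]
        mv = move[i]
        for j in range(1, lb + 1):
            diag = prev[j - 1] + mrow[j - 1]
            up = prev[j] + gap_score
            left = cur[j - 1] + gap_score
            if diag >= up and diag >= left:
                cur[j] = diag
                mv[j] = 0
            elif up >= left:
                cur[j] = up
                mv[j] = 1
            else:
                cur[j] = left
                mv[j] = 2
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    i, j = la, lb
    while i > 0 or j > 0:
        step = move[i][j]
        if i > 0 and j > 0 and step == 0:
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and (step == 1 or j == 0):
            out_a.append(cols_a[i - 1])
            out_b.append(gap_b)
            i -= 1
        else:
            out_a.append(gap_a)
            out_b.append(cols_b[j - 1])
            j -= 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b


def progressive_msa(proteins: list[ProteinRecord]) -> Msa:
    """Progressive alignment: UPGMA guide tree, profile-profile merging."""
    from .trees import upgma  # local import: trees depends on align for DistanceMatrix

    if len(proteins) < 2:
        raise ValueError("need >= 2 sequences")
    proteins = sorted(proteins, key=lambda p: p.id)
    if len(proteins) == 2:
        aligner = make_aligner()
        alignment = aligner.align(proteins[0].sequence, proteins[1].sequence)[0]
        return Msa(
            ids=[proteins[0].id, proteins[1].id],
            rows=[str(alignment[0]), str(alignment[1])],
        )

    aligner = make_aligner()
    ids = [p.id for p in proteins]
    n = len(proteins)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            identity = pair_score(proteins[i].sequence, proteins[j].sequence, aligner)
            dmat[i][j] = dmat[j][i] = 1.0 - identity / 100.0
    guide = upgma(DistanceMatrix(ids=ids, d=dmat))

    by_id = {p.id: p for p in proteins}
    profiles: dict[int, tuple[list[str], list[str]]] = {}

    def build(node) -> tuple[list[str], list[str]]:
        if not node.children:
            return [node.label], [by_id[node.label].sequence]
        (ids_l, rows_l) = build(node.children[0])
        (ids_r, rows_r) = build(node.children[1])
        new_l, new_r = _align_profiles(rows_l, rows_r)
        return ids_l + ids_r, new_l + new_r

    out_ids, out_rows = build(guide.root)
    order = {pid: k for k, pid in enumerate(ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return Msa(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


def msa_from_aligned(ids: list[str], rows: list[str]) -> Msa:
    """External-aligner hook: wrap a pre-aligned FASTA as an Msa."""
    return Msa(ids=list(ids), rows=[r.upper() for r in rows])


def column_status(msa: Msa, params: BlockFilterParams = BlockFilterParams()) -> list[str]:
    """Label each column CONSERVED / NONCONSERVED by majority-symbol count.

    With gaps_allowed (the default, matching "positions with gaps were
    not treated differently") the gap is an ordinary 21st symbol;
    otherwise any gap-containing column is NONCONSERVED.
    """
    conserved_min, _ = params.resolved(msa.n_rows)
    labels = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        if not params.gaps_allowed and "-" in col:
            labels.append("NONCONSERVED")
            continue
        top = max(col.count(sym) for sym in set(col))
        labels.append("CONSERVED" if top >= conserved_min else "NONCONSERVED")
    return labels


def block_filter(
    msa: Msa, params: BlockFilterParams = BlockFilterParams()
) -> tuple[Msa, list[int]]:
    """Remove low-quality regions; return (filtered Msa, retained indices).

    Steps: (1) label columns; (2) delete maximal NONCONSERVED runs longer
    than max_nonconserved_run; (3) trim every remaining segment so it
    begins and ends on a column whose majority count >= min_flank;
    (4) delete segments shorter than min_block_len.
    """
    _, flank_min = params.resolved(msa.n_rows)
    labels = column_status(msa, params)
    ncols = msa.n_cols

    removed = [False] * ncols
    j = 0
    while j < ncols:
        if labels[j] == "NONCONSERVED":
            k = j
            while k < ncols and labels[k] == "NONCONSERVED":
                k += 1
            if k - j > params.max_nonconserved_run:
                for t in range(j, k):
                    removed[t] = True
            j = k
        else:
            j += 1

    def majority(j: int) -> int:
        col = msa.column(j)
        if not params.gaps_allowed and "-" in col:
            return 0
        return max(col.count(sym) for sym in set(col))

    retained: list[int] = []
    j = 0
    while j < ncols:
        if removed[j]:
            j += 1
            continue
        k = j
        while k < ncols and not removed[k]:
            k += 1
        segment = list(range(j, k))
        while segment and majority(segment[0]) < flank_min:
            segment.pop(0)
        while segment and majority(segment[-1]) < flank_min:
            segment.pop()
        if len(segment) >= params.min_block_len:
            retained.extend(segment)
        j = k

    filtered = Msa(
        ids=list(msa.ids),
        rows=["".join(row[j] for j in retained) for row in msa.rows],
    )
    return filtered, retained


def identity_distance(msa: Msa) -> DistanceMatrix:
    """1 - pairwise identity over columns where both rows are non-gap.

    Pairs with zero comparable columns get distance 1.
    """
    if msa.n_rows < 2:
        raise ValueError("need >= 2 rows")
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            matches = 0
            for a, b in zip(msa.rows[i], msa.rows[j]):
                if a != "-" and b != "-":
                    comparable += 1
                    if a == b:
                        matches += 1
            dist = 1.0 - matches / comparable if comparable else 1.0
            d[i][j] = d[j][i] = dist
    return DistanceMatrix(ids=list(msa.ids), d=d)
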