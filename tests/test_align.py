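"""Progressive alignment, conserved-block filtering, identity distances."""

import numpy as np
import pytest

from ktfam.align import (
    BlockFilterParams,
    Msa,
    block_filter,
    column_status,
    identity_distance,
    msa_from_aligned,
    progressive_msa,
)
from ktfam.seqio import ProteinRecord

from conftest import random_protein_seq


def protein(pid, seq):
    return ProteinRecord(id=pid, species="syn", sequence=seq)


class TestProgressiveMsa:
    def test_two_sequences_is_pairwise(self):
        msa = progressive_msa([protein("a", "ACDEFGHIKL"), protein("b", "ACDEGHIKL")])
        assert msa.n_rows == 2
        assert msa.ungapped(0) == "ACDEFGHIKL"
        assert msa.ungapped(1) == "ACDEGHIKL"

    def test_identical_sequences_gap_free(self, rng):
        seq = random_protein_seq(rng, 60)
        msa = progressive_msa([protein(f"p{i}", seq) for i in range(5)])
        assert msa.n_cols == 60
        assert all("-" not in row for row in msa.rows)

    def test_rows_reproduce_inputs(self, rng):
        seqs = {f"p{i}": random_protein_seq(rng, int(rng.integers(40, 60))) for i in range(4)}
        msa = progressive_msa([protein(pid, s) for pid, s in seqs.items()])
        for pid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == seqs[pid]

    def test_low_divergence_family_aligns_planted_columns(self, rng):
        # same-length family: mutate a common backbone at scattered sites;
        # the aligned block should stay gap-free, keeping columns homologous
        backbone = random_protein_seq(rng, 80)
        members = []
        for i in range(5):
            residues = list(backbone)
            for pos in rng.choice(80, size=8, replace=False):
                residues[pos] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
            members.append(protein(f"m{i}", "".join(residues)))
        msa = progressive_msa(members)
        assert msa.n_cols == 80
        assert all("-" not in row for row in msa.rows)


class TestColumnStatus:
    def test_conserved_column(self):
        msa = msa_from_aligned(list("abcd"), ["A", "A", "A", "A"])
        assert column_status(msa) == ["CONSERVED"]

    def test_all_distinct_column(self):
        msa = msa_from_aligned(list("abcd"), ["A", "C", "D", "E"])
        assert column_status(msa) == ["NONCONSERVED"]

    def test_gap_counts_as_ordinary_symbol(self):
        msa = msa_from_aligned(list("abcd"), ["A", "-", "A", "-"])
        assert column_status(msa) == ["CONSERVED"]

    def test_gaps_not_allowed_mode(self):
        msa = msa_from_aligned(list("abcd"), ["A", "-", "A", "-"])
        params = BlockFilterParams(gaps_allowed=False)
        assert column_status(msa, params) == ["NONCONSERVED"]


def oracle_block_filter(rows, params: BlockFilterParams):
    """Independent step-by-step re-implementation of the filter."""
    import math

    n = len(rows)
    ncols = len(rows[0])
    conserved_min = params.min_conserved if params.min_conserved is not None else math.ceil(n / 2)
    flank_min = params.min_flank if params.min_flank is not None else math.ceil(n / 2)

    def top_count(j):
        col = [r[j] for r in rows]
        if not params.gaps_allowed and "-" in col:
            return 0
        return max(col.count(s) for s in set(col))

    conserved = [top_count(j) >= conserved_min for j in range(ncols)]

    keep = set(range(ncols))
    j = 0
    while j < ncols:
        if not conserved[j]:
            k = j
            while k < ncols and not conserved[k]:
                k += 1
            if k - j > params.max_nonconserved_run:
                keep -= set(range(j, k))
            j = k
        else:
            j += 1

    segments = []
    current = []
    for j in range(ncols):
        if j in keep:
            current.append(j)
        elif current:
            segments.append(current)
            current = []
    if current:
        segments.append(current)

    retained = []
    for seg in segments:
        while seg and top_count(seg[0]) < flank_min:
            seg = seg[1:]
        while seg and top_count(seg[-1]) < flank_min:
            seg = seg[:-1]
        if len(seg) >= params.min_block_len:
            retained.extend(seg)
    return retained


class TestBlockFilter:
    def test_fully_conserved_all_retained(self):
        msa = msa_from_aligned(list("abcd"), ["AAAA"] * 4)
        filtered, retained = block_filter(msa)
        assert retained == [0, 1, 2, 3]
        assert filtered.rows == msa.rows

    def test_long_nonconserved_stretch_removed(self, rng):
        # 10 conserved + 25 all-distinct-ish + 10 conserved columns, 4 rows
        distinct = ["", "", "", ""]
        choices = "ACDE", "FGHI", "KLMN", "PQRS"
        for j in range(25):
            for r in range(4):
                distinct[r] += choices[r][j % 4]
        rows = ["W" * 10 + distinct[r] + "Y" * 10 for r in range(4)]
        msa = msa_from_aligned(list("abcd"), rows)
        params = BlockFilterParams(max_nonconserved_run=20)
        filtered, retained = block_filter(msa, params)
        assert retained == list(range(10)) + list(range(35, 45))
        assert retained == oracle_block_filter(rows, params)

    def test_isolated_conserved_column_dropped_by_min_block_len(self):
        # single conserved column between long nonconserved runs
        rows = []
        choices = "ACDE", "FGHI", "KLMN", "PQRS"
        for r in range(4):
            left = "".join(choices[r][j % 4] for j in range(21))
            right = "".join(choices[(r + 1) % 4][j % 4] for j in range(21))
            rows.append(left + "W" + right)
        params = BlockFilterParams(max_nonconserved_run=20, min_block_len=2)
        msa = msa_from_aligned(list("abcd"), rows)
        filtered, retained = block_filter(msa, params)
        assert retained == []
        assert retained == oracle_block_filter(rows, params)
        assert filtered.n_cols == 0

    def test_matches_oracle_on_random_alignments(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 7))
            ncols = int(rng.integers(1, 60))
            alphabet = "AC-"  # small alphabet provokes ties and runs
            rows = ["".join(alphabet[i] for i in rng.integers(3, size=ncols)) for _ in range(n)]
            params = BlockFilterParams(
                max_nonconserved_run=int(rng.integers(1, 8)),
                min_block_len=int(rng.integers(1, 4)),
            )
            msa = msa_from_aligned([f"r{i}" for i in range(n)], rows)
            _, retained = block_filter(msa, params)
            assert retained == oracle_block_filter(rows, params)

    def test_idempotent(self, rng):
        rows = ["".join("AC-"[i] for i in rng.integers(3, size=50)) for _ in range(5)]
        msa = msa_from_aligned([f"r{i}" for i in range(5)], rows)
        params = BlockFilterParams(max_nonconserved_run=5, min_block_len=2)
        once, retained = block_filter(msa, params)
        twice, retained2 = block_filter(once, params)
        assert twice.rows == once.rows
        assert retained2 == list(range(once.n_cols))

    def test_retained_segments_respect_parameters(self, rng):
        rows = ["".join("AC-"[i] for i in rng.integers(3, size=80)) for _ in range(4)]
        params = BlockFilterParams(max_nonconserved_run=4, min_block_len=3)
        msa = msa_from_aligned([f"r{i}" for i in range(4)], rows)
        _, retained = block_filter(msa, params)
        assert retained == sorted(set(retained))
        # maximal contiguous runs of retained input columns
        segments, current = [], []
        for idx in retained:
            if current and idx != current[-1] + 1:
                segments.append(current)
                current = []
            current.append(idx)
        if current:
            segments.append(current)
        for seg in segments:
            assert len(seg) >= params.min_block_len


class TestIdentityDistance:
    def test_identical_rows(self):
        msa = msa_from_aligned(["a", "b"], ["ACDE", "ACDE"])
        assert identity_distance(msa).d[0, 1] == 0

    def test_gap_excluded_definition(self):
        msa = msa_from_aligned(["a", "b"], ["AC-E", "ACD-"])
        assert identity_distance(msa).d[0, 1] == 0  # comparable columns {0,1} identical

    def test_no_comparable_columns(self):
        msa = msa_from_aligned(["a", "b"], ["A-", "-A"])
        assert identity_distance(msa).d[0, 1] == 1.0

    def test_matches_positionwise_recount(self, rng):
        rows = [random_protein_seq(rng, 40) for _ in range(4)]
        msa = msa_from_aligned([f"r{i}" for i in range(4)], rows)
        d = identity_distance(msa)
        for i in range(4):
            for j in range(4):
                matches = sum(a == b for a, b in zip(rows[i], rows[j]))
                assert d.d[i, j] == pytest.approx(1 - matches / 40)
        assert np.allclose(d.d, d.d.T) and np.all(np.diag(d.d) == 0)
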