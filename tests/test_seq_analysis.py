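"""Percent identity (blastp-style local alignment) and motif conservation."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from taarsite.seq_analysis import (
    AlignParams,
    MotifBlock,
    ProteinSeq,
    column_conservation,
    find_conserved_blocks,
    identity_matrix,
    pairwise_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Affine-gap Smith–Waterman optimal score; independent DP oracle."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b
    Iy = np.full((n + 1, m + 1), neg)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                           Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                           Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def _rand_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestPairwiseIdentity:
    def test_self_identity_100(self):
        s = ProteinSeq("x", AA * 3)
        assert pairwise_identity(s, ProteinSeq("y", s.residues)) == 100

    def test_local_alignment_covers_shared_core(self):
        # the unrelated tail stays unaligned, so identity is over the core only
        a = ProteinSeq("a", "ACDE")
        b = ProteinSeq("b", "ACDE" + "GGGG")
        assert pairwise_identity(a, b) == 100

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = ProteinSeq("a", _rand_seq(rng, int(rng.integers(20, 60))))
            b = ProteinSeq("b", _rand_seq(rng, int(rng.integers(20, 60))))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_alignment_score_matches_dp_oracle(self):
        """Optimal local score equals an independent affine-gap DP."""
        from taarsite.seq_analysis import _aligner

        rng = np.random.default_rng(1)
        aligner = _aligner(AlignParams())
        for _ in range(15):
            a = _rand_seq(rng, int(rng.integers(8, 30)))
            b = _rand_seq(rng, int(rng.integers(8, 30)))
            assert aligner.score(a, b) == pytest.approx(sw_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinSeq("x", "")

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            ProteinSeq("x", "AC-DE")


class TestIdentityMatrix:
    def test_identical_pair(self):
        seqs = [ProteinSeq("a", AA * 2), ProteinSeq("b", AA * 2)]
        m = identity_matrix(seqs)
        assert m.values == ((100, 100), (100, 100))

    def test_symmetric_with_diagonal_100(self):
        rng = np.random.default_rng(2)
        seqs = [ProteinSeq(f"s{i}", _rand_seq(rng, 100)) for i in range(3)]
        m = identity_matrix(seqs)
        arr = np.array(m.values)
        assert (arr == arr.T).all()
        assert (np.diag(arr) == 100).all()
        assert ((arr >= 0) & (arr <= 100)).all()

    def test_duplicate_labels_error(self):
        seqs = [ProteinSeq("a", AA), ProteinSeq("a", AA)]
        with pytest.raises(ValueError, match="duplicate"):
            identity_matrix(seqs)

    def test_lookup_by_label(self):
        seqs = [ProteinSeq("a", AA * 2), ProteinSeq("b", AA * 2)]
        assert identity_matrix(seqs)[("a", "b")] == 100


def _fingerprint_block(name="fingerprint_1"):
    from taarsite.seq_analysis import load_family_fingerprints

    blocks, groups = load_family_fingerprints()
    return blocks[name], groups


class TestColumnConservation:
    def test_family_fingerprint_universal_columns(self):
        """The first family fingerprint conserves F, K, L, P across all members."""
        block, _ = _fingerprint_block()
        out = column_conservation(block)
        assert out.universal_columns() == {5: "F", 6: "K", 8: "L", 11: "P"}

    def test_single_member_all_universal(self):
        block = MotifBlock("solo", (("x", "ACDEF"),))
        out = column_conservation(block)
        assert set(out.column_classes) == {"universal"}

    def test_fully_variable(self):
        block = MotifBlock("pair", (("x", "ACD"), ("y", "DFA")))
        out = column_conservation(block)
        assert set(out.column_classes) == {"variable"}

    def test_subset_class_for_group_uniform_column(self):
        block = MotifBlock(
            "g", (("h1", "AC"), ("h2", "AC"), ("m1", "AD"), ("m2", "AE"))
        )
        groups = {"h1": "human", "h2": "human", "m1": "mouse", "m2": "mouse"}
        out = column_conservation(block, groups)
        assert out.column_classes == ("universal", "subset:human")

    def test_member_order_invariance_and_idempotence(self):
        block, groups = _fingerprint_block()
        out1 = column_conservation(block, groups)
        shuffled = MotifBlock(block.name, tuple(reversed(block.members)))
        out2 = column_conservation(shuffled, groups)
        assert out1.column_classes == out2.column_classes
        assert column_conservation(out1, groups).column_classes == out1.column_classes

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            MotifBlock("bad", (("x", "ACD"), ("y", "AC")))


class TestFindConservedBlocks:
    def _msa_with_motifs(self, rng, motifs, n_seqs=6, spacer=15):
        """Random gapped MSA with fully conserved motifs planted in order."""
        cols = []
        offsets = []
        for motif in motifs:
            for _ in range(spacer):
                col = [rng.choice(list(AA)) for _ in range(n_seqs)]
                col[rng.integers(n_seqs)] = "-"  # keep background gappy
                cols.append(col)
            offsets.append(len(cols))
            for ch in motif:
                cols.append([ch] * n_seqs)
        for _ in range(spacer):
            col = [rng.choice(list(AA)) for _ in range(n_seqs)]
            col[rng.integers(n_seqs)] = "-"
            cols.append(col)
        seqs = ["".join(col[i] for col in cols) for i in range(n_seqs)]
        return [(f"s{i}", s) for i, s in enumerate(seqs)], offsets

    def test_single_planted_motif_found_at_offset(self):
        rng = np.random.default_rng(3)
        msa, offsets = self._msa_with_motifs(rng, ["SISHFKQLHTP"])
        blocks = find_conserved_blocks(msa, window=11, min_universal=11)
        assert len(blocks) == 1
        assert blocks[0].name.endswith(f"@{offsets[0] + 1}")
        assert blocks[0].members[0][1] == "SISHFKQLHTP"

    def test_three_motifs_recovered_in_order(self):
        rng = np.random.default_rng(4)
        motifs = ["SISHFKQLHTP", "SMVRSAEHCWYFG", "DPFLHYIIPPTLND"]
        msa, offsets = self._msa_with_motifs(rng, motifs)
        blocks = find_conserved_blocks(msa, window=11, min_universal=11)
        assert [b.members[0][1] for b in blocks] == motifs
        starts = [int(b.name.split("@")[1]) for b in blocks]
        assert starts == [o + 1 for o in offsets]

    def test_window_larger_than_alignment_empty(self):
        msa = [("a", "ACDEF"), ("b", "ACDEF")]
        assert find_conserved_blocks(msa, window=10, min_universal=1) == []

    def test_unaligned_input_error(self):
        with pytest.raises(ValueError, match="unaligned"):
            find_conserved_blocks([("a", "ACDE"), ("b", "ACD")])
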