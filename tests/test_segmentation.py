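import numpy as np
import pytest

from satarray.segmentation import (
    AnchorSpec,
    align_units,
    hamming,
    refine,
    scan_anchors,
    segment,
)
from satarray.simulate import ArrayConfig, gen_array, gen_unit


def units_of(pieces):
    return [p for p in pieces if "fragment" not in p.flags]


class TestScanAnchors:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("CAGCTAAACAGCT", [0, 8]),
            ("CAGCCAAA", [0]),  # explicit variant
            ("CATGTAAA", [0]),  # explicit variant
            ("AAAAA", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert scan_anchors(seq) == expected

    def test_max_hamming_widens_scan(self):
        assert scan_anchors("CAGAT") == []
        assert scan_anchors("CAGAT", AnchorSpec(max_hamming=1)) == [0]


class TestSegment:
    def test_three_exact_units(self, consensus_units):
        u = consensus_units["L49"]
        pieces = segment(u * 3)
        assert [(p.start, p.end) for p in pieces] == [(0, 49), (49, 98), (98, 147)]
        assert all(p.ok for p in pieces)

    def test_greedy_skips_close_anchor(self):
        # anchors at 0 and 20; min_len 40 keeps only the first
        seq = "CAGCT" + "A" * 15 + "CAGCT" + "A" * 55  # length 80
        pieces = segment(seq)
        assert [(p.start, p.end) for p in pieces] == [(0, 80)]
        assert pieces[0].flags == frozenset({"irregular_long"})

    def test_leading_fragment_flagged(self, consensus_units):
        u = consensus_units["L50"]
        pieces = segment("TTTTTTTTTT" + u * 2)
        assert pieces[0].flags == frozenset({"fragment"})
        assert (pieces[0].start, pieces[0].end) == (0, 10)
        assert len(units_of(pieces)) == 2

    def test_no_anchors_yields_single_fragment(self):
        pieces = segment("TTTTTTTT")
        assert len(pieces) == 1
        assert pieces[0].flags == frozenset({"fragment"})

    def test_contains_n_flagged(self, consensus_units):
        u = consensus_units["L53"]
        noisy = u[:20] + "N" + u[21:]
        pieces = segment(noisy + u)
        assert "contains_N" in pieces[0].flags
        assert pieces[1].ok

    def test_boundaries_match_generator_truth(self):
        cfg = ArrayConfig(unit_type="L47", n_units=25, substitution=0.0, seed=9)
        rec, truth = gen_array(cfg)
        seq = rec.residues[truth.element[1] : truth.element[2]]
        pieces = units_of(segment(seq))
        got = [(truth.element[1] + p.start, truth.element[1] + p.end) for p in pieces]
        assert got == [(u.start, u.end) for u in truth.units]

    def test_bases_conserved_under_noise(self):
        cfg = ArrayConfig(
            unit_type="L53", n_units=30, substitution=0.05,
            anchor_protection=False, n_decoys=2, seed=3,
        )
        rec, truth = gen_array(cfg)
        seq = rec.residues[truth.element[1] : truth.element[2]]
        pieces = segment(seq)
        assert "".join(p.sequence for p in pieces) == seq


class TestAlignUnits:
    def test_identical_units_gapless(self, consensus_units):
        u = consensus_units["L50"]
        pieces = segment(u * 4)
        aln = align_units(pieces)
        assert all("-" not in row for row in aln.rows)
        assert aln.consensus() == u

    def test_single_insertion_gets_one_gap_column(self, consensus_units):
        u49 = consensus_units["L49"]
        u50 = u49[:30] + "T" + u49[30:]
        pieces = segment(u49 + u50 + u49)
        aln = align_units(pieces)
        assert aln.ncols == 50
        gap_counts = [row.count("-") for row in aln.rows]
        assert sorted(gap_counts) == [0, 1, 1]

    def test_alignment_score_matches_affine_oracle(self, consensus_units):
        # pairwise score implied by the multiple alignment must equal the
        # optimum from an independent affine-gap DP on the two sequences
        u49 = consensus_units["L49"]
        u50 = u49[:30] + "T" + u49[30:]
        pieces = segment(u49 + u50)
        aln = align_units(pieces)
        implied = _score_gapped_pair(aln.rows[0], aln.rows[1])
        assert implied == _affine_oracle(u49, u50)

    def test_rows_degap_to_units(self, consensus_units):
        u = consensus_units["L53"]
        rng = np.random.default_rng(0)
        variants = [gen_unit("L53", rng, substitution=0.05) for _ in range(6)]
        pieces = segment("".join(variants))
        aln = align_units(pieces)
        by_id = dict(zip(aln.unit_ids, aln.rows))
        for p in pieces:
            assert by_id[p.id].replace("-", "") == p.sequence

    def test_consensus_invariant_to_input_order(self, consensus_units):
        rng = np.random.default_rng(7)
        variants = [gen_unit("L50", rng, substitution=0.04) for _ in range(8)]
        pieces = segment("".join(variants))
        fwd = align_units(pieces).consensus()
        rev = align_units(pieces[::-1]).consensus()
        assert fwd == rev

    def test_fewer_than_two_ok_units_rejected(self, consensus_units):
        pieces = segment(consensus_units["L47"])
        with pytest.raises(ValueError):
            align_units(pieces)


def _score_gapped_pair(a: str, b: str) -> float:
    """Score two aligned rows under the package's affine scheme."""
    score, gap_a, gap_b = 0, False, False
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-":
            score += -1 if gap_a else -3
            gap_a, gap_b = True, False
        elif y == "-":
            score += -1 if gap_b else -3
            gap_b, gap_a = True, False
        else:
            score += 1 if x == y else -1
            gap_a = gap_b = False
    return score


def _affine_oracle(a: str, b: str) -> float:
    """Independent O(nm) global affine alignment (Gotoh) for the same scheme."""
    inf = float("inf")
    n, m = len(a), len(b)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -3 - (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -3 - (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - 3, X[i - 1][j] - 1)
            Y[i][j] = max(M[i][j - 1] - 3, Y[i][j - 1] - 1)
    return max(M[n][m], X[n][m], Y[n][m])


class TestRefine:
    def test_clean_array_converges_immediately(self, consensus_units):
        u = consensus_units["L50"]
        pieces, aln, cons = refine(u * 10)
        assert len(units_of(pieces)) == 10
        assert cons == u

    def test_corrupted_anchor_recovered(self, consensus_units):
        # 2-mismatch anchor corruption, invisible to the motif scan
        u = consensus_units["L49"]
        corrupt = "CTGCA" + u[5:]
        assert hamming(corrupt[:5], "CAGCT") == 2
        arr = u * 5 + corrupt + u * 5
        plain = units_of(segment(arr))
        assert sum(p.ok for p in plain) == 9  # two units fused around the corruption
        pieces, aln, cons = refine(arr, rounds=2)
        ok = [p for p in pieces if p.ok]
        assert len(ok) == 11
        assert {len(p) for p in ok} == {49}

    def test_rounds_zero_equals_plain_segment(self, consensus_units):
        u = consensus_units["L53"]
        arr = u * 4 + "T" * 30
        pieces, _, _ = refine(arr, rounds=0)
        assert [(p.start, p.end, p.flags) for p in pieces] == [
            (p.start, p.end, p.flags) for p in segment(arr)
        ]

    def test_unprotected_anchor_lower_bound(self):
        cfg = ArrayConfig(
            unit_type="L53", n_units=80, substitution=0.05,
            anchor_protection=False, seed=21,
        )
        rec, truth = gen_array(cfg)
        seq = rec.residues[truth.element[1] : truth.element[2]]
        intact = 0
        for u in truth.units:
            anchor = rec.residues[u.start : u.start + 5]
            if anchor in ("CAGCT", "CAGCC", "CATGT"):
                intact += 1
        pieces, _, _ = refine(seq)
        assert len(units_of(pieces)) >= intact
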