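import math

import numpy as np
import pytest

from satarray.io import RepeatAnnotation, SequenceRecord
from satarray.profile import (
    annotation_delta,
    build_profile,
    calibrate,
    dotplot,
    evalue,
    score_viterbi,
    search,
)
from satarray.segmentation import UnitAlignment, refine, segment
from satarray.simulate import gen_unit, type_consensus_unit


def aln_of(rows):
    return UnitAlignment([f"u{i}" for i in range(len(rows))], rows)


class TestBuildProfile:
    def test_identical_rows_zero_pseudocount(self):
        model = build_profile(aln_of(["ACGT"] * 4), pseudocount=0.0)
        expected = np.eye(4)[[0, 1, 2, 3]]
        assert np.allclose(model.match_emission, expected)

    def test_identical_rows_default_pseudocount(self):
        model = build_profile(aln_of(["ACGT"] * 4), pseudocount=0.25)
        for k, b in enumerate([0, 1, 2, 3]):
            assert model.match_emission[k, b] == pytest.approx(4.25 / 5.0)

    def test_split_column(self):
        model = build_profile(aln_of(["AA", "AA", "AC", "AC"]), pseudocount=0.0)
        assert model.match_emission[1, 0] == pytest.approx(0.5)
        assert model.match_emission[1, 1] == pytest.approx(0.5)

    def test_majority_gap_column_becomes_insert(self):
        model = build_profile(aln_of(["A-T", "AGT", "A-T", "A-T"]))
        assert model.ncols == 2

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(aln_of(["--", "--"]))


from oracles import brute_force_viterbi as _brute_force_viterbi


@pytest.fixture(scope="module")
def tiny_model():
    rows = ["ACGT", "ACGT", "AC-T", "AGGT", "ACGA"]
    return build_profile(aln_of(rows))


class TestViterbi:
    def test_matches_exhaustive_enumeration(self, tiny_model):
        bases = "ACGT"
        windows = [""]
        for _ in range(4):
            windows = [w + b for w in windows for b in bases]
        for w in windows:  # all 256 windows of length 4
            assert score_viterbi(tiny_model, w) == pytest.approx(
                _brute_force_viterbi(tiny_model, w), abs=1e-9
            )

    def test_gap_free_consensus_closed_form(self):
        model = build_profile(aln_of(["ACGT"] * 4))
        per_col = np.log2(model.match_emission / model.background[None, :]).max(axis=1)
        closed = per_col.sum() + np.log2(model.t_mm[:-1]).sum()
        assert score_viterbi(model, model.consensus) == pytest.approx(closed)

    def test_background_windows_score_below_consensus(self, consensus_units):
        pieces = segment(consensus_units["L53"] * 10)
        model = build_profile(__import__("satarray").align_units(pieces))
        cons_score = score_viterbi(model, model.consensus)
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        scores = [
            score_viterbi(model, "".join(bases[rng.integers(4, size=80)]))
            for _ in range(30)
        ]
        assert np.mean(scores) < cons_score
        assert max(scores) < cons_score


class TestCalibration:
    def test_deterministic_under_seed(self, tiny_model):
        a = calibrate(tiny_model, n_random=300, len_random=60, seed=5)
        b = calibrate(tiny_model, n_random=300, len_random=60, seed=5)
        assert a == b

    def test_lambda_stable_in_sample_size(self, consensus_units):
        pieces = segment(consensus_units["L53"] * 10)
        from satarray import align_units

        model = build_profile(align_units(pieces))
        lam1, _ = calibrate(model, n_random=2000, len_random=150, seed=8)
        lam2, _ = calibrate(model, n_random=4000, len_random=150, seed=8)
        assert abs(lam2 - lam1) / lam1 < 0.05

    def test_consensus_significant_in_10kb(self, consensus_units):
        pieces = segment(consensus_units["L53"] * 10)
        from satarray import align_units

        model = build_profile(align_units(pieces))
        calibrate(model, n_random=2000, len_random=150, seed=8)
        e = evalue(model, score_viterbi(model, model.consensus), 10_000)
        assert e < 0.01


@pytest.fixture(scope="module")
def calibrated_l53():
    u = type_consensus_unit("L53")
    pieces, aln, _ = refine(u * 15)
    model = build_profile(aln)
    calibrate(model, n_random=2000, len_random=150, seed=13)
    return model, u


class TestSearch:
    def test_planted_unit_recovered(self, calibrated_l53):
        model, u = calibrated_l53
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        bg = "".join(bases[rng.integers(4, size=500)])
        seq = bg[:250] + u + bg[250:]
        hits = search(model, [SequenceRecord("x", seq)])
        assert len(hits) == 1
        h = hits[0]
        overlap = min(h.end, 250 + len(u)) - max(h.start, 250)
        assert overlap >= 0.9 * len(u)
        assert h.evalue < 0.01

    def test_self_recovery_at_least_ok_units(self, calibrated_l53):
        model, u = calibrated_l53
        seq = u * 15
        n_ok = sum(p.ok for p in segment(seq))
        hits = search(model, [SequenceRecord("elem", seq)])
        assert len(hits) >= n_ok

    def test_empty_input(self, calibrated_l53):
        model, _ = calibrated_l53
        assert search(model, []) == []

    def test_uncalibrated_model_rejected(self, tiny_model):
        model = build_profile(
            aln_of(["ACGT", "ACGT", "ACGA"])
        )
        with pytest.raises(ValueError, match="calibrate"):
            search(model, [SequenceRecord("x", "ACGT")])

    def test_hit_set_invariant_to_record_order(self, calibrated_l53):
        model, u = calibrated_l53
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        recs = []
        for name in ("a", "b"):
            bg = "".join(bases[rng.integers(4, size=300)])
            recs.append(SequenceRecord(name, bg[:150] + u + bg[150:]))
        fwd = search(model, recs)
        rev = search(model, recs[::-1])
        assert sorted((h.chrom, h.start, h.end) for h in fwd) == sorted(
            (h.chrom, h.start, h.end) for h in rev
        )


def iv(chrom, s, e):
    return RepeatAnnotation(chrom, s, e, "+", "D20S16")


class TestAnnotationDelta:
    def test_identical_sets(self):
        a = [iv("chr1", 0, 100)]
        assert annotation_delta(a, a) == (0, 0)

    def test_half_overlap(self):
        assert annotation_delta([iv("c", 0, 100)], [iv("c", 50, 150)]) == (50, 50)

    def test_swap_symmetry(self):
        old = [iv("c", 0, 100), iv("c", 300, 400)]
        new = [iv("c", 50, 250)]
        added, removed = annotation_delta(old, new)
        assert annotation_delta(new, old) == (removed, added)

    def test_decoy_fragmented_annotations(self):
        from satarray.simulate import ArrayConfig, gen_array

        cfg = ArrayConfig(unit_type="L49", n_units=20, n_decoys=3, seed=6)
        rec, truth = gen_array(cfg)
        # recovered units (incl. irregular pieces spanning decoys) vs fragments
        seq = rec.residues[truth.element[1] : truth.element[2]]
        off = truth.element[1]
        pieces = [
            iv(cfg.chrom, off + p.start, off + p.end)
            for p in segment(seq)
            if "fragment" not in p.flags
        ]
        added, removed = annotation_delta(truth.annotations, pieces)
        decoy_bp = sum(d.end - d.start for d in truth.decoys)
        assert added == decoy_bp
        assert removed == 0


class TestDotplot:
    def test_tandem_offsets(self, consensus_units):
        u = consensus_units["L49"]
        pts = dotplot(u * 3, k=12)
        fwd = [(i, j) for i, j, o in pts if o == "+"]
        assert fwd and all(j - i in (49, 98) for i, j in fwd)

    def test_reverse_matches_brute_force(self):
        seq = "ACGTACGTACGTACGTACGT"
        k = 4
        pts = set(dotplot(seq, k))
        rc = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        brute = set()
        for i in range(len(seq) - k + 1):
            for j in range(i + 1, len(seq) - k + 1):
                if seq[i : i + k] == seq[j : j + k]:
                    brute.add((i, j, "+"))
                if seq[i : i + k] == rc(seq[j : j + k]):
                    brute.add((i, j, "-"))
        assert pts == brute
        assert any(o == "-" for _, _, o in pts)

    def test_random_sequence_near_zero(self):
        rng = np.random.default_rng(11)
        seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=200)])
        assert len(dotplot(seq, k=12)) <= 2

    def test_short_sequence_and_small_k(self):
        assert dotplot("ACGT", k=12) == []
        with pytest.raises(ValueError):
            dotplot("ACGTACGT", k=3)
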