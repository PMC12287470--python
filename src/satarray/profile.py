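"""Profile model over a unit alignment, and profile search with empirical E-values.

A per-column match/insert/delete profile (in the profile-HMM sense) is built
from the unit alignment and used to rescan sequence for units that anchor
segmentation missed. Scores are log2-odds Viterbi scores against a background
base composition, aligned locally both in the sequence and in the profile
(units may be truncated at element edges). Statistical significance uses an
explicit empirical calibration: maximum local scores on seeded random
background sequences are fitted to a Gumbel, giving E(S) = K * m * n * 2^(-lambda*S).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SequenceRecord
from .segmentation import UnitAlignment

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -1.0e9  # forbidden emission (N or masked residue)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


@dataclass(frozen=True)
class ProfileHit:
    """One significant profile match on a sequence (0-based half-open)."""

    chrom: str
    start: int
    end: int
    bitscore: float
    evalue: float


@dataclass
class ProfileModel:
    """Consensus profile: per-column emissions, transitions, and calibration.

    ``match_emission`` is (ncols, 4) row-stochastic; transition arrays hold,
    per column k, the probabilities of leaving column k toward column k+1
    (match->match/insert/delete, insert->insert/match, delete->delete/match).
    ``calibration`` is the fitted Gumbel (lambda, K) together with the seed and
    random-sequence dimensions that produced it.
    """

    ncols: int
    match_emission: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_ii: np.ndarray
    t_im: np.ndarray
    t_dd: np.ndarray
    t_dm: np.ndarray
    background: np.ndarray
    calibration: tuple[float, float] | None = None
    calibration_seed: int | None = None
    calibration_len: int | None = None
    _score_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not np.allclose(self.match_emission.sum(axis=1), 1.0):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[int(k)] for k in self.match_emission.argmax(axis=1))

    def _scores(self):
        """Cached log2-odds emission matrix and log2 transition arrays."""
        if "sm" not in self._score_cache:
            sm = np.full((self.ncols, 5), _NEG)
            sm[:, :4] = np.log2(self.match_emission / self.background[None, :])
            with np.errstate(divide="ignore"):
                self._score_cache.update(
                    sm=sm,
                    mm=np.log2(self.t_mm),
                    mi=np.log2(self.t_mi),
                    md=np.log2(self.t_md),
                    ii=np.log2(self.t_ii),
                    im=np.log2(self.t_im),
                    dd=np.log2(self.t_dd),
                    dm=np.log2(self.t_dm),
                )
        return self._score_cache

    # --- serialization ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "ncols": self.ncols,
            "match_emission": self.match_emission.tolist(),
            "transitions": {
                name: getattr(self, f"t_{name}").tolist()
                for name in ("mm", "mi", "md", "ii", "im", "dd", "dm")
            },
            "background": self.background.tolist(),
            "calibration": list(self.calibration) if self.calibration else None,
            "calibration_seed": self.calibration_seed,
            "calibration_len": self.calibration_len,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ProfileModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ncols=d["ncols"],
            match_emission=np.asarray(d["match_emission"]),
            background=np.asarray(d["background"]),
            calibration=tuple(d["calibration"]) if d["calibration"] else None,
            calibration_seed=d["calibration_seed"],
            calibration_len=d["calibration_len"],
            **{f"t_{k}": np.asarray(v) for k, v in d["transitions"].items()},
        )


UNIFORM_BACKGROUND = np.full(4, 0.25)


def build_profile(
    aln: UnitAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> ProfileModel:
    """Estimate a profile from a unit alignment.

    Columns with >= 50% gaps become insert states; the rest are match columns.
    Emissions are (count + pseudocount) / (depth + 4 * pseudocount); transition
    probabilities use the same additive scheme over the options available from
    each state.
    """
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    match_cols = aln.match_columns()
    if not match_cols:
        raise ValueError("alignment has no match columns (all-gap?)")
    ncols = len(match_cols)
    match_set = set(match_cols)

    counts = np.zeros((ncols, 4))
    for row in aln.rows:
        for j, c in enumerate(match_cols):
            b = _BASE_INDEX.get(row[c], 4)
            if b < 4:
                counts[j, b] += 1
    with np.errstate(invalid="ignore"):
        emission = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )

    # transition counts out of column k (into k+1), per row
    tc = {name: np.zeros(ncols) for name in ("mm", "mi", "md", "ii", "im", "dd", "dm")}
    for row in aln.rows:
        states = ["M" if row[c] != "-" else "D" for c in match_cols]
        n_ins = [0] * ncols
        j = -1
        for c in range(aln.ncols):
            if c in match_set:
                j += 1
            elif row[c] != "-" and 0 <= j < ncols:
                n_ins[j] += 1
        for k in range(ncols - 1):
            a, b = states[k], states[k + 1]
            if n_ins[k] == 0:
                if a == "M":
                    tc["mm" if b == "M" else "md"][k] += 1
                else:
                    tc["dm" if b == "M" else "dd"][k] += 1
            else:
                # insert openings from D are rare; counted with the match opening
                tc["mi"][k] += 1
                tc["ii"][k] += n_ins[k] - 1
                tc["im"][k] += 1

    pc = pseudocount
    with np.errstate(invalid="ignore"):
        from_m = tc["mm"] + tc["mi"] + tc["md"]
        t_mm = (tc["mm"] + pc) / (from_m + 3 * pc)
        t_mi = (tc["mi"] + pc) / (from_m + 3 * pc)
        t_md = (tc["md"] + pc) / (from_m + 3 * pc)
        from_i = tc["ii"] + tc["im"]
        t_ii = (tc["ii"] + pc) / (from_i + 2 * pc)
        t_im = (tc["im"] + pc) / (from_i + 2 * pc)
        from_d = tc["dd"] + tc["dm"]
        t_dd = (tc["dd"] + pc) / (from_d + 2 * pc)
        t_dm = (tc["dm"] + pc) / (from_d + 2 * pc)
    if pc == 0:
        # avoid 0/0 for columns with no observed transitions of a class
        for arr, default in (
            (t_mm, 1.0), (t_mi, 0.0), (t_md, 0.0),
            (t_ii, 0.0), (t_im, 1.0), (t_dd, 0.0), (t_dm, 1.0),
        ):
            arr[np.isnan(arr)] = default

    return ProfileModel(
        ncols=ncols,
        match_emission=emission,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_ii=t_ii, t_im=t_im, t_dd=t_dd, t_dm=t_dm,
        background=background,
    )


# --- Viterbi ---------------------------------------------------------------------


def _viterbi_batch(model: ProfileModel, enc: np.ndarray) -> np.ndarray:
    """Best local Viterbi score per row of an encoded (nbatch, L) matrix.

    Local on both sides: paths may enter and leave the profile at any match
    column for free. Vectorized over the batch and the profile columns.
    """
    sc = model._scores()
    sm, mm, mi, md = sc["sm"], sc["mm"], sc["mi"], sc["md"]
    ii, im, dd, dm = sc["ii"], sc["im"], sc["dd"], sc["dm"]
    nb, L = enc.shape
    K = model.ncols
    cum = np.concatenate([[0.0], np.cumsum(dd[:-1])])  # cum[k] = sum dd[:k]

    vm = np.full((nb, K), _NEG)
    vi = np.full((nb, K), _NEG)
    vd = np.full((nb, K), _NEG)
    best = np.full(nb, _NEG)
    for i in range(L):
        e = sm[:, enc[:, i]].T  # (nb, K)
        stay = np.full((nb, K), 0.0)  # free entry
        stay[:, 1:] = np.maximum.reduce(
            [
                np.zeros((nb, K - 1)),
                vm[:, :-1] + mm[None, :-1],
                vi[:, :-1] + im[None, :-1],
                vd[:, :-1] + dm[None, :-1],
            ]
        )
        new_vm = e + stay
        new_vi = np.maximum(vm + mi[None, :], vi + ii[None, :])
        # delete chain within the new row: prefix max along k
        g = new_vm[:, :-1] + md[None, :-1] - cum[None, 1:]
        run = np.maximum.accumulate(g, axis=1)
        new_vd = np.full((nb, K), _NEG)
        new_vd[:, 1:] = run + cum[None, 1:]
        vm, vi, vd = new_vm, new_vi, new_vd
        best = np.maximum(best, vm.max(axis=1))
    return best


def score_viterbi(model: ProfileModel, window: str) -> float:
    """Best local log2-odds alignment score of ``window`` against the profile."""
    if not window:
        return float("-inf")
    return float(_viterbi_batch(model, _encode(window)[None, :])[0])


def _viterbi_traceback(
    model: ProfileModel, enc: np.ndarray
) -> tuple[float, int, int, int]:
    """Best local score, its (start, end) window interval, and its column span."""
    sc = model._scores()
    sm, mm, mi, md = sc["sm"], sc["mm"], sc["mi"], sc["md"]
    ii, im, dd, dm = sc["ii"], sc["im"], sc["dd"], sc["dm"]
    L, K = len(enc), model.ncols

    vm = np.full((L, K), _NEG)
    vi = np.full((L, K), _NEG)
    vd = np.full((L, K), _NEG)
    # entry (position, column) producing each cell, propagated along the path
    em = np.zeros((L, K, 2), dtype=np.int32)
    ei = np.zeros((L, K, 2), dtype=np.int32)
    ed = np.zeros((L, K, 2), dtype=np.int32)

    for i in range(L):
        for k in range(K):
            e = sm[k, enc[i]]
            cands = [(0.0, (i, k))]
            if i > 0 and k > 0:
                cands.append((vm[i - 1, k - 1] + mm[k - 1], tuple(em[i - 1, k - 1])))
                cands.append((vi[i - 1, k - 1] + im[k - 1], tuple(ei[i - 1, k - 1])))
                cands.append((vd[i - 1, k - 1] + dm[k - 1], tuple(ed[i - 1, k - 1])))
            best, origin = max(cands, key=lambda t: t[0])
            vm[i, k] = e + best
            em[i, k] = origin
            if i > 0:
                a = vm[i - 1, k] + mi[k]
                b = vi[i - 1, k] + ii[k]
                vi[i, k], ei[i, k] = (a, em[i - 1, k]) if a >= b else (b, ei[i - 1, k])
            if k > 0:
                a = vm[i, k - 1] + md[k - 1]
                b = vd[i, k - 1] + dd[k - 1]
                vd[i, k], ed[i, k] = (a, em[i, k - 1]) if a >= b else (b, ed[i, k - 1])

    flat = int(np.argmax(vm))
    i_end, k_end = divmod(flat, K)
    i0, k0 = (int(x) for x in em[i_end, k_end])
    return float(vm[i_end, k_end]), i0, i_end + 1, k_end - k0 + 1


def calibrate(
    model: ProfileModel,
    n_random: int = 5000,
    len_random: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit a Gumbel to max local scores on seeded random background sequences.

    Stores (lambda, K) on the model, such that E(S) = K * m * n * 2^(-lambda*S)
    for a search over n residues with an m-column profile.
    """
    rng = np.random.default_rng(seed)
    enc = rng.choice(4, size=(n_random, len_random), p=model.background).astype(np.int8)
    scores = _viterbi_batch(model, enc)
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / (scale * math.log(2))
    kappa = math.exp(loc / scale) / (model.ncols * len_random)
    if lam <= 0 or not math.isfinite(lam) or not math.isfinite(kappa):
        raise ValueError("degenerate Gumbel calibration")
    model.calibration = (lam, kappa)
    model.calibration_seed = seed
    model.calibration_len = len_random
    return lam, kappa


def evalue(model: ProfileModel, score: float, n_residues: int) -> float:
    if model.calibration is None:
        raise ValueError("model is not calibrated")
    lam, kappa = model.calibration
    return kappa * model.ncols * n_residues * 2.0 ** (-lam * score)


def search(
    model: ProfileModel,
    seqs: list[SequenceRecord],
    evalue_max: float = 0.01,
    min_span_cols: int | None = None,
) -> list[ProfileHit]:
    """Scan sequences for significant, non-overlapping profile matches.

    Sequences are scored in overlapping windows (vectorized); each promising
    region is resolved by traceback, recorded, masked, and the affected
    windows rescored, which realizes greedy best-score-first non-overlap
    selection. All reported hits satisfy evalue < ``evalue_max`` and must span
    at least ``min_span_cols`` profile columns (default: half the profile) —
    the search targets repeat units, possibly edge-truncated, not short local
    fragments whose significance the Gumbel tail fit cannot support.
    """
    if min_span_cols is None:
        min_span_cols = model.ncols // 2
    if model.calibration is None:
        raise ValueError("calibrate the model before searching")
    n_total = sum(len(s.residues) for s in seqs)
    if n_total == 0:
        return []
    lam, kappa = model.calibration
    min_score = math.log2(kappa * model.ncols * n_total / evalue_max) / lam

    win = 3 * model.ncols
    step = model.ncols
    hits: list[ProfileHit] = []
    for rec in seqs:
        enc_full = _encode(rec.residues).copy()
        L = len(enc_full)
        starts = list(range(0, max(L - win, 0) + 1, step))
        if not starts or starts[-1] + win < L:
            starts.append(max(L - win, 0))
        starts = sorted(set(starts))

        def window_matrix():
            return np.stack(
                [np.pad(enc_full[s : s + win], (0, max(0, win - (L - s))), constant_values=4)
                 for s in starts]
            )

        scores = _viterbi_batch(model, window_matrix())
        active = scores > min_score
        while active.any():
            w = int(np.argmax(np.where(active, scores, -np.inf)))
            s0 = starts[w]
            sub = enc_full[s0 : s0 + win]
            sc, a, b, span = _viterbi_traceback(model, sub)
            if sc <= min_score:
                active[w] = False
                continue
            g_start, g_end = s0 + a, s0 + b
            if span >= min_span_cols:
                hits.append(
                    ProfileHit(rec.name, g_start, g_end, sc, evalue(model, sc, n_total))
                )
            enc_full[g_start:g_end] = 4  # mask the region either way
            touched = [
                j for j, s in enumerate(starts) if s < g_end and s + win > g_start
            ]
            mats = np.stack(
                [np.pad(enc_full[starts[j] : starts[j] + win],
                        (0, max(0, win - (L - starts[j]))), constant_values=4)
                 for j in touched]
            )
            new_scores = _viterbi_batch(model, mats)
            for j, ns in zip(touched, new_scores):
                scores[j] = ns
                active[j] = ns > min_score
    hits.sort(key=lambda h: (h.evalue, h.chrom, h.start))
    return hits


# --- interval arithmetic and dot plot ---------------------------------------------


def _merged(intervals: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(m) for m in merged]
    return out


def _coords(items) -> list[tuple[str, int, int]]:
    return [(it.chrom, it.start, it.end) for it in items]


def _difference_bp(a: dict, b: dict) -> int:
    """Total bases covered by a but not b."""
    total = 0
    for chrom, ivs in a.items():
        other = b.get(chrom, [])
        for s, e in ivs:
            covered = 0
            for os, oe in other:
                lo, hi = max(s, os), min(e, oe)
                if lo < hi:
                    covered += hi - lo
            total += (e - s) - covered
    return total


def annotation_delta(old_annots, new_items) -> tuple[int, int]:
    """(added_bp, removed_bp) between two interval sets on one coordinate system."""
    old = _merged(_coords(old_annots))
    new = _merged(_coords(new_items))
    return _difference_bp(new, old), _difference_bp(old, new)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def dotplot(seq: str, k: int = 12) -> list[tuple[int, int, str]]:
    """Self-alignment dot plot: all off-diagonal k-mer matches.

    Returns (i, j, orientation) with i < j for forward matches ("+") and
    i <= j for reverse-complement matches ("-"); the main diagonal (i == j)
    is excluded.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if len(seq) < k:
        return []
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    out: list[tuple[int, int, str]] = []
    for kmer, ps in pos.items():
        for ai in range(len(ps)):
            for bi in range(ai + 1, len(ps)):
                out.append((ps[ai], ps[bi], "+"))
        rc = kmer.translate(_COMPLEMENT)[::-1]
        if rc in pos:
            for i in ps:
                for j in pos[rc]:
                    if i < j or (i == j and rc != kmer):
                        out.append((i, j, "-"))
    out.sort()
    return out
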