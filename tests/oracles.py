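"""Independent brute-force oracles used by the test suite."""

import math

import numpy as np


def brute_force_viterbi(model, window: str) -> float:
    """Best local profile alignment score by exhaustive path enumeration.

    Enumerates every state path (match/insert/delete, free entry and exit at
    match states) over every start position, independently of the dynamic
    program it checks. Only feasible for tiny profiles and windows.
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    sm = np.log2(model.match_emission / model.background[None, :])
    mm, mi, md = np.log2(model.t_mm), np.log2(model.t_mi), np.log2(model.t_md)
    ii, im = np.log2(model.t_ii), np.log2(model.t_im)
    dd, dm = np.log2(model.t_dd), np.log2(model.t_dm)
    K, n = model.ncols, len(window)
    w = [idx[c] for c in window]
    best = [-math.inf]

    def rec(state, k, i, score):
        if state == "M":
            best[0] = max(best[0], score)  # free exit after any match
            if i < n and k + 1 < K:
                rec("M", k + 1, i + 1, score + mm[k] + sm[k + 1][w[i]])
            if i < n:
                rec("I", k, i + 1, score + mi[k])
            if k + 1 < K:
                rec("D", k + 1, i, score + md[k])
        elif state == "I":
            if i < n:
                rec("I", k, i + 1, score + ii[k])
            if i < n and k + 1 < K:
                rec("M", k + 1, i + 1, score + im[k] + sm[k + 1][w[i]])
        else:
            if k + 1 < K:
                rec("D", k + 1, i, score + dd[k])
            if i < n and k + 1 < K:
                rec("M", k + 1, i + 1, score + dm[k] + sm[k + 1][w[i]])

    for i0 in range(n):
        for k0 in range(K):
            rec("M", k0, i0 + 1, sm[k0][w[i0]])
    return best[0]
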