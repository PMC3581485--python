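"""Brute-force path-enumeration oracle for the local multihit profile model.

Enumerates every state path that emits the given sequence and reaches the
terminal state, multiplying plain (non-log) probabilities. Completely
independent of the dynamic-programming kernels: no recurrences, no shared
code. Feasible only for tiny models and sequences; used to pin down the
forward path-sum and the Viterbi path-max.

Model conventions (shared with the implementation by definition, not by code):
flanking states N/J/C emit one background residue per self-loop; entry is
B -> M_k with the model's entry distribution; the last match state and the
last delete state exit to E with probability 1; E re-enters via J with the
re-entry probability.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np


def _ploop_pmove(L: int) -> Tuple[float, float]:
    return L / (L + 2.0), 2.0 / (L + 2.0)


def enumerate_paths(h, codes: np.ndarray) -> Tuple[float, float]:
    """Return (sum, max) of P(path, sequence | model) over all complete paths."""
    L = len(codes)
    M = h.M
    ploop, pmove = _ploop_pmove(L)
    me = h.match_exit
    tc = h.t_core
    ent = h.entry
    reentry = h.reentry
    nf = h.null_freqs

    def bg(x):
        return 1.0 if x == 20 else nf[x]

    def em_match(k, x):
        return 1.0 if x == 20 else h.match_emissions[k, x]

    def em_ins(k, x):
        return 1.0 if x == 20 else h.insert_emissions[k + 1, x]

    total = 0.0
    best = 0.0

    # state encodings: ("N",) ("B",) ("M",k) ("I",k) ("D",k) ("E",) ("J",) ("C",)
    def go(state, i, p):
        nonlocal total, best
        if p == 0.0:
            return
        tag = state[0]
        if tag == "N":
            if i < L:
                go(("N",), i + 1, p * ploop * bg(codes[i]))
            go(("B",), i, p * pmove)
        elif tag == "B":
            if i < L:
                for k in range(M):
                    go(("M", k), i + 1, p * ent[k] * em_match(k, codes[i]))
        elif tag == "M":
            k = state[1]
            go(("E",), i, p * me[k])
            if k + 1 < M:
                if i < L:
                    go(("M", k + 1), i + 1, p * tc[k, 0] * em_match(k + 1, codes[i]))
                    go(("I", k), i + 1, p * tc[k, 1] * em_ins(k, codes[i]))
                go(("D", k + 1), i, p * tc[k, 2])
        elif tag == "I":
            k = state[1]
            if i < L:
                go(("M", k + 1), i + 1, p * tc[k, 3] * em_match(k + 1, codes[i]))
                go(("I", k), i + 1, p * tc[k, 4] * em_ins(k, codes[i]))
        elif tag == "D":
            k = state[1]
            if k == M - 1:
                go(("E",), i, p)
            else:
                if i < L:
                    go(("M", k + 1), i + 1, p * tc[k, 5] * em_match(k + 1, codes[i]))
                go(("D", k + 1), i, p * tc[k, 6])
        elif tag == "E":
            if reentry > 0:
                go(("J",), i, p * reentry)
            go(("C",), i, p * (1.0 - reentry))
        elif tag == "J":
            if i < L:
                go(("J",), i + 1, p * ploop * bg(codes[i]))
            go(("B",), i, p * pmove)
        elif tag == "C":
            if i < L:
                go(("C",), i + 1, p * ploop * bg(codes[i]))
            else:
                prob = p * pmove  # C -> T, complete path
                total += prob
                if prob > best:
                    best = prob

    go(("N",), 0, 1.0)
    return total, best


def null_prob(h, codes: np.ndarray) -> float:
    L = len(codes)
    r = L / (L + 1.0)
    p = (r ** L) * (1.0 - r)
    for x in codes:
        p *= 1.0 if x == 20 else h.null_freqs[x]
    return p


def oracle_bits(h, codes: np.ndarray) -> Tuple[float, float]:
    """(forward bits, Viterbi bits) by exhaustive enumeration."""
    total, best = enumerate_paths(h, codes)
    null = null_prob(h, codes)
    return math.log2(total / null), math.log2(best / null)
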