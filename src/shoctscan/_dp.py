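"""Log-space forward and Viterbi dynamic programming for the local multihit
profile architecture.

State machine (per target sequence of length L):

    S -> N -> B -> { match/insert/delete core, entered at any match state,
                     exited from any match state or the final delete } -> E
    E -> J -> B   (multihit re-entry)   or   E -> C -> T

N, J and C emit flanking residues at background frequency on their self-loops;
their loop/move probabilities follow a target-length model (loop = L/(L+2)).
All recurrences run in natural log space; scores are converted to bits by the
caller. Kernels are JIT-compiled with numba when available and fall back to
the identical pure-Python code otherwise.
"""

from __future__ import annotations

import math

import numpy as np

NEG = -1.0e30  # log-probability sentinel for impossible states

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=False)
def _lse(a: float, b: float) -> float:
    """log(exp(a) + exp(b)), stable, with an early-out for tiny terms."""
    if a < b:
        a, b = b, a
    d = b - a
    if d < -36.0:
        return a
    return a + math.log1p(math.exp(d))


@njit(cache=True)
def forward_ln(codes, lmat, lins, lf, ltr, lme, lbm, lej, lec, lloop, lmove):
    """ln P(sequence | profile) under the local multihit path ensemble.

    ltr columns: 0=MM 1=MI 2=MD 3=IM 4=II 5=DM 6=DD (ln probabilities,
    node-indexed 0..M-1; row M-1 core entries are NEG).
    """
    L = codes.shape[0]
    M = lmat.shape[0]
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    curM = np.empty(M)
    curI = np.empty(M)
    curD = np.empty(M)
    prevN = 0.0
    prevJ = NEG
    prevC = NEG
    prevB = lmove  # N(0) -> B

    for i in range(L):
        x = codes[i]
        for k in range(M):
            s = prevB + lbm[k]
            if k > 0:
                s = _lse(s, prevM[k - 1] + ltr[k - 1, 0])
                s = _lse(s, prevI[k - 1] + ltr[k - 1, 3])
                s = _lse(s, prevD[k - 1] + ltr[k - 1, 5])
            curM[k] = s + lmat[k, x]
            ti = _lse(prevM[k] + ltr[k, 1], prevI[k] + ltr[k, 4])
            curI[k] = ti + lins[k, x]
        curD[0] = NEG
        for k in range(1, M):
            curD[k] = _lse(curM[k - 1] + ltr[k - 1, 2], curD[k - 1] + ltr[k - 1, 6])
        e = NEG
        for k in range(M):
            e = _lse(e, curM[k] + lme[k])
        e = _lse(e, curD[M - 1])  # D_M -> E with probability 1
        curN = prevN + lloop + lf[x]
        curJ = _lse(prevJ + lloop + lf[x], e + lej)
        curC = _lse(prevC + lloop + lf[x], e + lec)
        curB = _lse(curN + lmove, curJ + lmove)
        for k in range(M):
            prevM[k] = curM[k]
            prevI[k] = curI[k]
            prevD[k] = curD[k]
        prevN = curN
        prevJ = curJ
        prevC = curC
        prevB = curB

    return prevC + lmove  # C(L) -> T


@njit(cache=True)
def viterbi_ln(codes, lmat, lins, lf, ltr, lme, lbm, lej, lec, lloop, lmove):
    """Best-path score plus backpointers for traceback.

    Returns (score, ptrM, ptrI, ptrD, ptrE, ptrB, ptrJ, ptrC) where pointer
    codes are: ptrM 0=B 1=M 2=D 3=I; ptrI 0=M 1=I; ptrD 0=M 1=D;
    ptrE k in [0,M) = exit from M_k, M = exit from D_M; ptrB 0=N 1=J;
    ptrJ/ptrC 0=self-loop 1=from E. Ties prefer match > delete > insert and
    continuation over a new entry (strict-greater replacement).
    """
    L = codes.shape[0]
    M = lmat.shape[0]
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    curM = np.empty(M)
    curI = np.empty(M)
    curD = np.empty(M)
    prevN = 0.0
    prevJ = NEG
    prevC = NEG
    prevB = lmove

    ptrM = np.zeros((L, M), dtype=np.int8)
    ptrI = np.zeros((L, M), dtype=np.int8)
    ptrD = np.zeros((L, M), dtype=np.int8)
    ptrE = np.zeros(L, dtype=np.int32)
    ptrB = np.zeros(L + 1, dtype=np.int8)
    ptrJ = np.zeros(L, dtype=np.int8)
    ptrC = np.zeros(L, dtype=np.int8)

    for i in range(L):
        x = codes[i]
        for k in range(M):
            # candidate order encodes the tie-break preference
            best = NEG
            bp = 0
            if k > 0:
                v = prevM[k - 1] + ltr[k - 1, 0]
                if v > best:
                    best = v
                    bp = 1
                v = prevD[k - 1] + ltr[k - 1, 5]
                if v > best:
                    best = v
                    bp = 2
                v = prevI[k - 1] + ltr[k - 1, 3]
                if v > best:
                    best = v
                    bp = 3
            v = prevB + lbm[k]
            if v > best:
                best = v
                bp = 0
            elif k == 0:
                best = v
                bp = 0
            curM[k] = best + lmat[k, x]
            ptrM[i, k] = 1 if bp == 1 else (3 if bp == 3 else (2 if bp == 2 else 0))

            vm = prevM[k] + ltr[k, 1]
            vi = prevI[k] + ltr[k, 4]
            if vm >= vi:
                curI[k] = vm + lins[k, x]
                ptrI[i, k] = 0
            else:
                curI[k] = vi + lins[k, x]
                ptrI[i, k] = 1
        curD[0] = NEG
        for k in range(1, M):
            vm = curM[k - 1] + ltr[k - 1, 2]
            vd = curD[k - 1] + ltr[k - 1, 6]
            if vm >= vd:
                curD[k] = vm
                ptrD[i, k] = 0
            else:
                curD[k] = vd
                ptrD[i, k] = 1
        e = NEG
        ke = 0
        for k in range(M):
            v = curM[k] + lme[k]
            if v > e:
                e = v
                ke = k
        if curD[M - 1] > e:
            e = curD[M - 1]
            ke = M
        ptrE[i] = ke
        curN = prevN + lloop + lf[x]
        vj_loop = prevJ + lloop + lf[x]
        vj_e = e + lej
        if vj_loop >= vj_e:
            curJ = vj_loop
            ptrJ[i] = 0
        else:
            curJ = vj_e
            ptrJ[i] = 1
        vc_loop = prevC + lloop + lf[x]
        vc_e = e + lec
        if vc_loop >= vc_e:
            curC = vc_loop
            ptrC[i] = 0
        else:
            curC = vc_e
            ptrC[i] = 1
        vb_n = curN + lmove
        vb_j = curJ + lmove
        if vb_n >= vb_j:
            curB = vb_n
            ptrB[i + 1] = 0
        else:
            curB = vb_j
            ptrB[i + 1] = 1
        for k in range(M):
            prevM[k] = curM[k]
            prevI[k] = curI[k]
            prevD[k] = curD[k]
        prevN = curN
        prevJ = curJ
        prevC = curC
        prevB = curB

    return prevC + lmove, ptrM, ptrI, ptrD, ptrE, ptrB, ptrJ, ptrC


def null_ln(codes: np.ndarray, lf: np.ndarray) -> float:
    """ln P(sequence | null): background emissions with a geometric length model
    r = L/(L+1), as used for profile bit scores."""
    L = codes.shape[0]
    r = L / (L + 1.0)
    return float(lf[codes].sum() + L * math.log(r) + math.log(1.0 - r))


def length_params(L: int) -> tuple:
    """(ln loop, ln move) for the N/J/C flanking states at target length L."""
    return math.log(L / (L + 2.0)), math.log(2.0 / (L + 2.0))
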