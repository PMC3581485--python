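"""Profile HMM construction and bit-score search.

The model is a local multihit profile: match/insert/delete core nodes with
uniform entry over match states, a fixed per-match-state exit probability, and
a geometric multihit re-entry (E->J) probability. Scores are log2 likelihood
ratios against a background null model ("bits"). Two inclusion thresholds
gate search output: a full-sequence threshold (default 24.0 bits) and a
per-domain-envelope threshold (default 15.4 bits).

Bit scores here are approximations in the spirit of HMMER, not reproductions
of HMMER values: emissions use add-k pseudocounts (or BLOSUM62 conditionals
for single-sequence models) rather than Dirichlet mixture priors, and no
posterior envelope widening is performed.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from pathlib import Path
from typing import List, Optional, Sequence as TSequence, Tuple, Union

import numpy as np

from . import _dp
from .alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND_FREQS, GAP_CHARS, X_CODE, encode
from .seqdata_io import Alignment, Sequence

LN2 = math.log(2.0)

DEFAULT_SEQUENCE_BITS = 24.0
DEFAULT_DOMAIN_BITS = 15.4
DEFAULT_EXIT_PROB = 0.05
DEFAULT_REENTRY = 0.5

# fixed core transitions for single-sequence (round-0) models
_SINGLE_SEQ_TRANS = dict(mm=0.97, mi=0.015, md=0.015, im=0.85, ii=0.15, dm=0.85, dd=0.15)


@dataclasses.dataclass(frozen=True)
class SearchThresholds:
    """Sequence- and domain-level bit-score inclusion thresholds."""

    sequence_bits: float = DEFAULT_SEQUENCE_BITS
    domain_bits: float = DEFAULT_DOMAIN_BITS

    def __post_init__(self):
        if not (math.isfinite(self.sequence_bits) and math.isfinite(self.domain_bits)):
            raise ValueError("thresholds must be finite")


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One model pass on a target: 1-based inclusive envelope plus its bits."""

    env_start: int
    env_end: int
    score: float

    def __post_init__(self):
        if self.env_start > self.env_end:
            raise ValueError("env_start must be <= env_end")


@dataclasses.dataclass(frozen=True)
class SequenceHit:
    seq_id: str
    full_score: float
    domains: Tuple[DomainHit, ...]


@dataclasses.dataclass(eq=False)
class ProfileHMM:
    """A local multihit profile HMM over the 20-letter amino-acid alphabet.

    match_emissions: (M, 20); insert_emissions: (M+1, 20) (inserts score at
    background by construction); t_core: (M, 7) columns [MM MI MD IM II DM DD],
    already scaled so that MM+MI+MD+match_exit = 1 per node; entry: (M,)
    uniform begin->match distribution; reentry: E->J probability (0 = unihit).
    """

    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_core: np.ndarray
    match_exit: np.ndarray
    entry: np.ndarray
    reentry: float
    null_freqs: np.ndarray
    name: str = "profile"
    _pack: Optional[tuple] = dataclasses.field(default=None, repr=False)

    def validate(self, tol: float = 1e-9) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("insert emission rows must sum to 1")
        if abs(self.entry.sum() - 1.0) > tol:
            raise ValueError("entry distribution must sum to 1")
        if abs(self.null_freqs.sum() - 1.0) > tol:
            raise ValueError("null frequencies must sum to 1")
        mm, mi, md = self.t_core[:, 0], self.t_core[:, 1], self.t_core[:, 2]
        if not np.allclose(mm + mi + md + self.match_exit, 1.0, atol=tol):
            raise ValueError("match-state transition rows must sum to 1")
        if not np.allclose(self.t_core[:, 3] + self.t_core[:, 4], 1.0, atol=tol):
            raise ValueError("insert-state transition rows must sum to 1")
        if not np.allclose(self.t_core[:, 5] + self.t_core[:, 6], 1.0, atol=tol):
            raise ValueError("delete-state transition rows must sum to 1")

    # -- log-space parameter pack for the DP kernels -----------------------
    def logpack(self) -> tuple:
        if self._pack is None:
            M = self.M

            def _ln(p):
                out = np.full(p.shape, _dp.NEG)
                pos = p > 0
                out[pos] = np.log(p[pos])
                return out

            lmat = np.full((M, 21), 0.0)
            lmat[:, :20] = _ln(self.match_emissions)
            lins = np.full((M, 21), 0.0)
            # kernel insert node k corresponds to insert_emissions row k+1
            lins[:, :20] = _ln(self.insert_emissions[1 : M + 1])
            lf = np.zeros(21)
            lf[:20] = np.log(self.null_freqs)
            ltr = _ln(self.t_core.copy())
            # last node: no interior transitions (forced exit to E)
            ltr[M - 1, :] = _dp.NEG
            lme = _ln(self.match_exit.copy())
            lme[M - 1] = 0.0
            lbm = _ln(self.entry)
            if self.reentry > 0:
                lej = math.log(self.reentry)
                lec = math.log(1.0 - self.reentry)
            else:
                lej, lec = _dp.NEG, 0.0
            object.__setattr__(self, "_pack", (lmat, lins, lf, ltr, lme, lbm, lej, lec))
        return self._pack


def _occupancy(a: Alignment) -> np.ndarray:
    occ = np.zeros(a.ncol)
    for _, row in a.rows:
        occ += np.fromiter((c not in GAP_CHARS for c in row), dtype=float, count=a.ncol)
    return occ / a.nrow


def build_hmm(
    a: Alignment,
    occupancy_rule: float = 0.5,
    pseudocount: float = 1.0,
    null_freqs: Optional[np.ndarray] = None,
    exit_prob: float = DEFAULT_EXIT_PROB,
    multihit: bool = True,
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose non-gap occupancy is >= occupancy_rule become match states;
    emission and transition counts receive add-`pseudocount` smoothing. Insert
    states emit at background frequency.
    """
    if null_freqs is None:
        null_freqs = BACKGROUND_FREQS
    occ = _occupancy(a)
    match_cols = np.nonzero(occ >= occupancy_rule)[0]
    M = len(match_cols)
    if M == 0:
        raise ValueError("alignment has no match column under the occupancy rule")
    is_match = np.zeros(a.ncol, dtype=bool)
    is_match[match_cols] = True

    k = pseudocount
    em_counts = np.zeros((M, 20))
    # transition counts per node: columns [MM MI MD IM II DM DD]
    tr_counts = np.zeros((M, 7))
    _PAIR = {
        ("M", "M"): 0, ("M", "I"): 1, ("M", "D"): 2,
        ("I", "M"): 3, ("I", "I"): 4,
        ("D", "M"): 5, ("D", "D"): 6,
    }
    for _, row in a.rows:
        events = []  # (state, node) with node = 0-based match-node index
        node = -1
        for j, c in enumerate(row):
            gap = c in GAP_CHARS
            if is_match[j]:
                node += 1
                if gap:
                    events.append(("D", node))
                else:
                    events.append(("M", node))
                    code = AA_INDEX.get(c.upper(), X_CODE)
                    if code != X_CODE:
                        em_counts[node, code] += 1
            elif not gap:
                events.append(("I", node))
        for (s1, n1), (s2, n2) in zip(events, events[1:]):
            idx = _PAIR.get((s1, s2))
            if idx is None:  # I->D / D->I adjacency: not representable, skipped
                continue
            src = n1 if s1 != "D" else n1
            if 0 <= src < M:
                tr_counts[src, idx] += 1

    totals = em_counts.sum(axis=1, keepdims=True)
    match_em = (em_counts + k) / (totals + 20.0 * k)

    insert_em = np.tile(null_freqs, (M + 1, 1))

    t_core = np.zeros((M, 7))
    core = tr_counts[:, 0:3] + k
    core = core / core.sum(axis=1, keepdims=True)
    ins = tr_counts[:, 3:5] + k
    ins = ins / ins.sum(axis=1, keepdims=True)
    dele = tr_counts[:, 5:7] + k
    dele = dele / dele.sum(axis=1, keepdims=True)
    me = np.full(M, exit_prob)
    me[M - 1] = 1.0
    t_core[:, 0:3] = core * (1.0 - me)[:, None]
    t_core[:, 3:5] = ins
    t_core[:, 5:7] = dele
    t_core[M - 1, 0:3] = 0.0
    t_core[M - 1, 3:5] = (1.0, 0.0)
    t_core[M - 1, 5:7] = (1.0, 0.0)

    h = ProfileHMM(
        M=M,
        match_emissions=match_em,
        insert_emissions=insert_em,
        t_core=t_core,
        match_exit=me,
        entry=np.full(M, 1.0 / M),
        reentry=DEFAULT_REENTRY if multihit else 0.0,
        null_freqs=np.asarray(null_freqs, dtype=float),
        name=name,
    )
    h.validate()
    return h


@lru_cache(maxsize=1)
def _blosum62_conditionals() -> np.ndarray:
    """P(b | a) implied by BLOSUM62 half-bit scores and the package background."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    f = BACKGROUND_FREQS
    joint = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            joint[i, j] = f[i] * f[j] * 2.0 ** (m[a, b] / 2.0)
    joint /= joint.sum()
    cond = joint / joint.sum(axis=1, keepdims=True)
    return cond


def single_sequence_hmm(
    query: Union[Sequence, str],
    null_freqs: Optional[np.ndarray] = None,
    exit_prob: float = DEFAULT_EXIT_PROB,
    multihit: bool = True,
) -> ProfileHMM:
    """Round-0 model for iterative search: one match state per query residue,
    emissions from BLOSUM62 conditional probabilities, fixed core transitions.
    """
    if null_freqs is None:
        null_freqs = BACKGROUND_FREQS
    residues = query.residues if isinstance(query, Sequence) else query
    name = query.id if isinstance(query, Sequence) else "query"
    codes = encode(residues)
    M = len(codes)
    if M < 1:
        raise ValueError("empty query")
    cond = _blosum62_conditionals()
    match_em = np.empty((M, 20))
    for i, c in enumerate(codes):
        match_em[i] = null_freqs if c == X_CODE else cond[c]
    t = _SINGLE_SEQ_TRANS
    me = np.full(M, exit_prob)
    me[M - 1] = 1.0
    t_core = np.zeros((M, 7))
    core = np.array([t["mm"], t["mi"], t["md"]])
    t_core[:, 0:3] = core[None, :] * (1.0 - me)[:, None]
    t_core[:, 3:5] = (t["im"], t["ii"])
    t_core[:, 5:7] = (t["dm"], t["dd"])
    t_core[M - 1, 0:3] = 0.0
    t_core[M - 1, 3:5] = (1.0, 0.0)
    t_core[M - 1, 5:7] = (1.0, 0.0)
    h = ProfileHMM(
        M=M,
        match_emissions=match_em,
        insert_emissions=np.tile(null_freqs, (M + 1, 1)),
        t_core=t_core,
        match_exit=me,
        entry=np.full(M, 1.0 / M),
        reentry=DEFAULT_REENTRY if multihit else 0.0,
        null_freqs=np.asarray(null_freqs, dtype=float),
        name=name,
    )
    h.validate()
    return h


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _codes_of(s: Union[Sequence, str]) -> np.ndarray:
    residues = s.residues if isinstance(s, Sequence) else s
    if not residues:
        raise ValueError("empty sequence")
    return encode(residues.upper())


def forward_bitscore(h: ProfileHMM, s: Union[Sequence, str]) -> float:
    """log2 [ P(s | model, local multihit ensemble) / P(s | null) ]."""
    codes = _codes_of(s)
    lmat, lins, lf, ltr, lme, lbm, lej, lec = h.logpack()
    lloop, lmove = _dp.length_params(len(codes))
    ln_f = _dp.forward_ln(codes, lmat, lins, lf, ltr, lme, lbm, lej, lec, lloop, lmove)
    return (ln_f - _dp.null_ln(codes, lf)) / LN2


@dataclasses.dataclass
class _Pass:
    """One begin->end model pass from a Viterbi trace."""

    env_start: int
    env_end: int
    score: float
    match_map: dict  # model node (0-based) -> (seq position 1-based, residue code)


def _viterbi_passes(h: ProfileHMM, codes: np.ndarray) -> Tuple[float, List[_Pass]]:
    lmat, lins, lf, ltr, lme, lbm, lej, lec = h.logpack()
    lloop, lmove = _dp.length_params(len(codes))
    score_ln, ptrM, ptrI, ptrD, ptrE, ptrB, ptrJ, ptrC = _dp.viterbi_ln(
        codes, lmat, lins, lf, ltr, lme, lbm, lej, lec, lloop, lmove
    )
    M = h.M
    L = len(codes)
    bits = (score_ln - _dp.null_ln(codes, lf)) / LN2

    passes: List[_Pass] = []
    i = L
    state: tuple = ("C",)
    cur: Optional[dict] = None
    while True:
        tag = state[0]
        if tag == "C":
            if i == 0:
                break
            if ptrC[i - 1] == 0:
                i -= 1
            else:
                state = ("E",)
        elif tag == "E":
            ke = int(ptrE[i - 1])
            cur = {"path": [], "emis": []}
            if ke == M:
                cur["path"].append(("Dexit",))
                state = ("D", M - 1)
            else:
                cur["path"].append(("Mexit", ke))
                state = ("M", ke)
        elif tag == "M":
            k = state[1]
            cur["emis"].append((i, "M", k))
            p = ptrM[i - 1, k]
            if p == 0:
                cur["entry"] = k
                cur["start"] = i
                state = ("B",)
                i -= 1
            elif p == 1:
                cur["path"].append(("MM", k - 1))
                state = ("M", k - 1)
                i -= 1
            elif p == 2:
                cur["path"].append(("DM", k - 1))
                state = ("D", k - 1)
                i -= 1
            else:
                cur["path"].append(("IM", k - 1))
                state = ("I", k - 1)
                i -= 1
        elif tag == "D":
            k = state[1]
            if ptrD[i - 1, k] == 0:
                cur["path"].append(("MD", k - 1))
                state = ("M", k - 1)
            else:
                cur["path"].append(("DD", k - 1))
                state = ("D", k - 1)
        elif tag == "I":
            k = state[1]
            cur["emis"].append((i, "I", k))
            if ptrI[i - 1, k] == 0:
                cur["path"].append(("MI", k))
                state = ("M", k)
            else:
                cur["path"].append(("II", k))
                state = ("I", k)
            i -= 1
        elif tag == "B":
            passes.append(_finish_pass(h, codes, cur, lmat, lins, lf, ltr, lme, lbm))
            cur = None
            if ptrB[i] == 0:
                break  # N consumes the remaining prefix
            state = ("J",)
        elif tag == "J":
            if ptrJ[i - 1] == 0:
                i -= 1
            else:
                state = ("E",)
    passes.reverse()
    return bits, passes


def _finish_pass(h, codes, cur, lmat, lins, lf, ltr, lme, lbm) -> _Pass:
    """Sum one pass's bits: entry + internal transitions + exit + emission
    log-odds (insert emissions are background, contributing 0)."""
    _TRIDX = {"MM": 0, "MI": 1, "MD": 2, "IM": 3, "II": 4, "DM": 5, "DD": 6}
    total = lbm[cur["entry"]]
    for step in cur["path"]:
        if step[0] == "Mexit":
            total += lme[step[1]]
        elif step[0] == "Dexit":
            pass  # D_M -> E with probability 1
        else:
            total += ltr[step[1], _TRIDX[step[0]]]
    match_map = {}
    positions = []
    for pos, kind, k in cur["emis"]:
        x = codes[pos - 1]
        positions.append(pos)
        if kind == "M":
            total += lmat[k, x] - lf[x]
            match_map[k] = (pos, int(x))
        else:
            total += lins[k, x] - lf[x]
    return _Pass(
        env_start=min(positions),
        env_end=max(positions),
        score=total / LN2,
        match_map=match_map,
    )


def viterbi_decode(h: ProfileHMM, s: Union[Sequence, str]) -> Tuple[float, List[DomainHit]]:
    """Best multihit path score in bits plus one DomainHit per model pass."""
    codes = _codes_of(s)
    bits, passes = _viterbi_passes(h, codes)
    hits = [DomainHit(p.env_start, p.env_end, p.score) for p in passes]
    hits.sort(key=lambda d: (d.env_start, d.env_end))
    return bits, hits


def score_database(h: ProfileHMM, db: TSequence) -> np.ndarray:
    """Forward bit score of every database sequence, in database order."""
    return np.array([forward_bitscore(h, s) for s in db], dtype=float)


def search(
    h: ProfileHMM,
    db: TSequence,
    t: SearchThresholds = SearchThresholds(),
) -> List[SequenceHit]:
    """Threshold-gated database search.

    Returns sequences with forward full score >= t.sequence_bits, each carrying
    the Viterbi domain envelopes scoring >= t.domain_bits, sorted by descending
    full score (ties by id).
    """
    ids = [s.id for s in db]
    if len(set(ids)) != len(ids):
        raise ValueError("database ids must be unique")
    if h.M < 1:
        raise ValueError("empty model")
    hits: List[SequenceHit] = []
    for s in db:
        full = forward_bitscore(h, s)
        if full >= t.sequence_bits:
            _, doms = viterbi_decode(h, s)
            doms = tuple(d for d in doms if d.score >= t.domain_bits)
            hits.append(SequenceHit(seq_id=s.id, full_score=full, domains=doms))
    hits.sort(key=lambda x: (-x.full_score, x.seq_id))
    return hits


# ---------------------------------------------------------------------------
# Plain-text serialization (round-trip guaranteed)
# ---------------------------------------------------------------------------

def write_hmm(h: ProfileHMM, path) -> None:
    def g(x):
        return format(float(x), ".17g")

    with open(path, "w") as fh:
        fh.write("SHOCTSCAN-HMM 1\n")
        fh.write(f"name {h.name}\n")
        fh.write(f"M {h.M}\n")
        fh.write(f"alphabet {AMINO_ACIDS}\n")
        fh.write(f"reentry {g(h.reentry)}\n")
        fh.write("null " + " ".join(g(x) for x in h.null_freqs) + "\n")
        fh.write("entry " + " ".join(g(x) for x in h.entry) + "\n")
        fh.write("exit " + " ".join(g(x) for x in h.match_exit) + "\n")
        for k in range(h.M):
            fh.write(f"match {k} " + " ".join(g(x) for x in h.match_emissions[k]) + "\n")
        for k in range(h.M + 1):
            fh.write(f"insert {k} " + " ".join(g(x) for x in h.insert_emissions[k]) + "\n")
        for k in range(h.M):
            fh.write(f"trans {k} " + " ".join(g(x) for x in h.t_core[k]) + "\n")
        fh.write("//\n")


def read_hmm(path) -> ProfileHMM:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("SHOCTSCAN-HMM"):
        raise ValueError(f"{path}: not a shoctscan HMM file")
    fields = {}
    match_rows, insert_rows, trans_rows = {}, {}, {}
    for ln in lines[1:]:
        if ln.strip() == "//" or not ln.strip():
            continue
        key, rest = ln.split(" ", 1)
        if key in ("match", "insert", "trans"):
            k, vals = rest.split(" ", 1)
            arr = np.array([float(v) for v in vals.split()])
            {"match": match_rows, "insert": insert_rows, "trans": trans_rows}[key][int(k)] = arr
        else:
            fields[key] = rest
    M = int(fields["M"])
    h = ProfileHMM(
        M=M,
        match_emissions=np.vstack([match_rows[k] for k in range(M)]),
        insert_emissions=np.vstack([insert_rows[k] for k in range(M + 1)]),
        t_core=np.vstack([trans_rows[k] for k in range(M)]),
        match_exit=np.array([float(v) for v in fields["exit"].split()]),
        entry=np.array([float(v) for v in fields["entry"].split()]),
        reentry=float(fields["reentry"]),
        null_freqs=np.array([float(v) for v in fields["null"].split()]),
        name=fields.get("name", "profile"),
    )
    h.validate()
    return h
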