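"""Jackhmmer-style iterative profile search from a single query.

Round 0 builds a single-sequence model from the query (BLOSUM62 conditional
emissions — the standard device for single-query profile searches). Each
subsequent round searches the database, includes every sequence meeting the
thresholds (the query is always retained), re-aligns the included sequences to
the current model via their best Viterbi pass (match columns only), rebuilds
the profile, and repeats until the included set is unchanged between rounds or
max_iter is reached. Inclusion sets may shrink between rounds; convergence is
set equality between consecutive rounds.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence as TSequence, Set, Tuple

import numpy as np

from .profile_hmm import (
    ProfileHMM,
    SearchThresholds,
    _viterbi_passes,
    build_hmm,
    search,
    single_sequence_hmm,
)
from .seqdata_io import Alignment, Sequence
from .alphabet import AMINO_ACIDS, encode

logger = logging.getLogger(__name__)

MIN_QUERY_LENGTH = 10


@dataclasses.dataclass(frozen=True)
class IterationState:
    round: int
    included_ids: frozenset
    alignment: Alignment
    hmm: ProfileHMM


@dataclasses.dataclass(frozen=True)
class JackhmmerResult:
    final: IterationState
    history: Tuple[IterationState, ...]
    converged: bool

    @property
    def rounds(self) -> int:
        return self.final.round


def _realign(hmm: ProfileHMM, seqs: TSequence) -> Alignment:
    """One row per sequence: residues of its best Viterbi pass at the model's
    match columns, gaps elsewhere. Deterministic given (hmm, seqs)."""
    rows = []
    for s in seqs:
        _, passes = _viterbi_passes(hmm, encode(s.residues))
        best = max(passes, key=lambda p: p.score)
        chars = ["-"] * hmm.M
        for k, (_, code) in best.match_map.items():
            chars[k] = AMINO_ACIDS[code] if code < 20 else "X"
        rows.append((s.id, "".join(chars)))
    return Alignment.from_rows(rows)


def jackhmmer_like(
    query: Sequence,
    db: TSequence,
    t: SearchThresholds = SearchThresholds(),
    max_iter: int = 5,
    pseudocount: float = 1.0,
    occupancy_rule: float = 0.5,
) -> JackhmmerResult:
    """Iterative search seeded from a single query sequence."""
    if len(query) < MIN_QUERY_LENGTH:
        raise ValueError(
            f"query {query.id!r} shorter than {MIN_QUERY_LENGTH} residues"
        )
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    by_id: Dict[str, Sequence] = {s.id: s for s in db}
    if len(by_id) != len(db):
        raise ValueError("database ids must be unique")
    by_id.setdefault(query.id, query)

    hmm = single_sequence_hmm(query)
    aln = Alignment.from_rows([(query.id, query.residues)])
    included: Set[str] = {query.id}
    state = IterationState(0, frozenset(included), aln, hmm)
    history: List[IterationState] = [state]
    converged = False

    for rnd in range(1, max_iter + 1):
        hits = search(state.hmm, db, t)
        new_ids = {h.seq_id for h in hits} | {query.id}
        logger.info("round %d: %d sequences included", rnd, len(new_ids))
        seqs = [by_id[i] for i in sorted(new_ids)]
        aln = _realign(state.hmm, seqs)
        hmm = build_hmm(aln, occupancy_rule=occupancy_rule, pseudocount=pseudocount)
        prev_ids = state.included_ids
        state = IterationState(rnd, frozenset(new_ids), aln, hmm)
        history.append(state)
        if new_ids == set(prev_ids):
            converged = True
            break
    return JackhmmerResult(final=state, history=tuple(history), converged=converged)


@dataclasses.dataclass(frozen=True)
class NoveltyReport:
    """Fraction of sequences found per re-search that were not already known
    family members, and the arithmetic mean over queries."""

    per_query_fraction: Tuple[float, ...]
    mean_fraction: float
    new_ids: Tuple[str, ...] = ()


def subsample_validation(
    family_ids: TSequence,
    db: TSequence,
    t: SearchThresholds = SearchThresholds(),
    n: int = 100,
    rng_seed: int = 0,
    max_iter: int = 5,
) -> NoveltyReport:
    """Re-search validation: run iterative searches from n randomly chosen
    known members and measure, per query, the fraction of finally included
    sequences that are not in the known set ("new")."""
    if n == 0:
        raise ValueError("n must be >= 1")
    family = sorted(set(family_ids))
    if n > len(family):
        raise ValueError("n exceeds the number of known family members")
    by_id = {s.id: s for s in db}
    missing = [i for i in family if i not in by_id]
    if missing:
        raise ValueError(f"family ids not present in db: {missing[:3]}")
    rng = np.random.default_rng(rng_seed)
    chosen = [family[i] for i in rng.choice(len(family), size=n, replace=False)]
    fractions = []
    new_all: Set[str] = set()
    fam_set = set(family)
    for qid in chosen:
        result = jackhmmer_like(by_id[qid], db, t, max_iter=max_iter)
        found = result.final.included_ids
        new = {i for i in found if i not in fam_set}
        new_all |= new
        fractions.append(len(new) / len(found))
    mean = float(np.mean(fractions))
    return NoveltyReport(
        per_query_fraction=tuple(fractions),
        mean_fraction=mean,
        new_ids=tuple(sorted(new_all)),
    )
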