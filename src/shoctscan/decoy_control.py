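"""Reversed-seed-alignment decoy control.

Reversing the column order of the seed alignment preserves per-row residue
composition (and hence the model's emission inventory) while destroying the
positional signal, so a search with the reversed-alignment profile gauges the
false-positive bit-score regime empirically. The control passes when no
sequence reaches the sequence inclusion threshold under the decoy model while
the forward model recovers the planted family, and the forward search shows an
excess of sub-threshold hits (low-scoring true relatives) over the decoy.

The score floor plays the role of a reporting threshold: it bounds the
histogram support above the bulk of the background score distribution, so the
retained sub-threshold hits are candidate homologs rather than background
noise. The default of 10 bits sits several standard deviations above the
background mode while staying well under the 24-bit inclusion threshold.
"""

from __future__ import annotations

import dataclasses
import json
from typing import List, Optional, Sequence as TSequence, Tuple

import numpy as np

from .profile_hmm import ProfileHMM, SearchThresholds, build_hmm, score_database
from .seqdata_io import Alignment, reverse_alignment


@dataclasses.dataclass(frozen=True)
class DecoyReport:
    """Score distributions of the forward and decoy searches at one threshold.

    Scores below score_floor are dropped from both lists; all counts refer to
    the retained lists. excess_below = (#forward < threshold) - (#decoy <
    threshold): the surplus of sub-threshold forward hits attributable to
    low-scoring family relatives.
    """

    forward_scores: Tuple[float, ...]
    decoy_scores: Tuple[float, ...]
    threshold: float
    score_floor: float
    n_forward_at_or_above: int
    n_decoy_at_or_above: int
    excess_below: int

    def __post_init__(self):
        nf = sum(1 for s in self.forward_scores if s >= self.threshold)
        nd = sum(1 for s in self.decoy_scores if s >= self.threshold)
        if nf != self.n_forward_at_or_above or nd != self.n_decoy_at_or_above:
            raise ValueError("counts inconsistent with score lists")
        eb = (len(self.forward_scores) - nf) - (len(self.decoy_scores) - nd)
        if eb != self.excess_below:
            raise ValueError("excess_below inconsistent with score lists")

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["forward_scores"] = list(self.forward_scores)
        payload["decoy_scores"] = list(self.decoy_scores)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


DEFAULT_SCORE_FLOOR = 10.0


def run_decoy_control(
    seed: Alignment,
    db: TSequence,
    t: SearchThresholds = SearchThresholds(),
    score_floor: float = DEFAULT_SCORE_FLOOR,
    pseudocount: float = 1.0,
    occupancy_rule: float = 0.5,
) -> DecoyReport:
    """Build forward and reversed-seed profiles with identical parameters,
    score every database sequence under both, and report the comparison."""
    if not db:
        raise ValueError("empty database")
    if score_floor >= t.sequence_bits:
        raise ValueError("score_floor must be below the sequence threshold")
    fwd = build_hmm(seed, occupancy_rule=occupancy_rule, pseudocount=pseudocount, name="forward")
    dec = build_hmm(
        reverse_alignment(seed),
        occupancy_rule=occupancy_rule,
        pseudocount=pseudocount,
        name="decoy",
    )
    f_scores = score_database(fwd, db)
    d_scores = score_database(dec, db)
    f_keep = tuple(float(s) for s in f_scores if s >= score_floor)
    d_keep = tuple(float(s) for s in d_scores if s >= score_floor)
    thr = t.sequence_bits
    nf = sum(1 for s in f_keep if s >= thr)
    nd = sum(1 for s in d_keep if s >= thr)
    return DecoyReport(
        forward_scores=f_keep,
        decoy_scores=d_keep,
        threshold=thr,
        score_floor=score_floor,
        n_forward_at_or_above=nf,
        n_decoy_at_or_above=nd,
        excess_below=(len(f_keep) - nf) - (len(d_keep) - nd),
    )


def excess_below_threshold(r: DecoyReport) -> int:
    """Surplus of sub-threshold forward hits over decoy hits."""
    return r.excess_below


def bitscore_histogram(
    scores: TSequence, bin_width: float = 2.0, floor: float = 0.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Half-open bins [edge, edge + width) from floor upwards; total count
    equals the number of scores >= floor."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kept = np.array([s for s in scores if s >= floor], dtype=float)
    if kept.size == 0:
        edges = np.array([floor, floor + bin_width])
        return edges, np.zeros(1, dtype=int)
    nbins = int(np.floor((kept.max() - floor) / bin_width)) + 1
    edges = floor + bin_width * np.arange(nbins + 1)
    idx = np.floor((kept - floor) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    return edges, counts


def histogram_table(report: DecoyReport, bin_width: float = 2.0):
    """Two-series histogram (forward vs decoy) on shared bin edges."""
    floor = report.score_floor
    all_scores = list(report.forward_scores) + list(report.decoy_scores)
    edges, _ = bitscore_histogram(all_scores, bin_width, floor)
    nbins = len(edges) - 1

    def _count(scores):
        _, c = bitscore_histogram(scores, bin_width, floor)
        out = np.zeros(nbins, dtype=int)
        out[: len(c)] = c
        return out

    return edges, _count(report.forward_scores), _count(report.decoy_scores)


def plot_decoy_histogram(report: DecoyReport, path, bin_width: float = 2.0) -> None:
    """Unfilled (forward) vs filled (decoy) score histograms with the sequence
    inclusion threshold as a vertical line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, fwd, dec = histogram_table(report, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, fwd, width=bin_width, fill=False, edgecolor="black", label="seed profile")
    ax.bar(centers, dec, width=bin_width, color="green", alpha=0.6, label="reversed seed (decoy)")
    ax.axvline(report.threshold, color="red", linestyle="--", label=f"threshold {report.threshold:g} bits")
    ax.set_xlabel("bit score")
    ax.set_ylabel("sequences")
    ax.set_yscale("symlog")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
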