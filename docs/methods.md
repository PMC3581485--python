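# Methods

`shoctscan` re-implements, as a tested reusable pipeline, the computational
procedure by which short C-terminal (SHOCT-like) protein domains are
discovered and validated: a seed alignment is turned into a profile hidden
Markov model, the model is searched against a protein database in bits under
dual inclusion thresholds, the family is expanded iteratively from a single
query, false positives are calibrated with a reversed-seed-alignment decoy,
and the resulting annotations feed positional, taxonomic, architectural and
copy-number censuses. Because the original analyses were run against specific
UniProtKB/Pfam releases, the pipeline here is exercised end-to-end on
synthetic proteomes with planted domains and full ground truth.

## The profile model and its scores

The profile is a local multihit architecture. A core of M match states (with
per-node insert and delete states) is flanked by background-emitting states:
N before the first model pass, J between passes, C after the last, each
emitting one background residue per self-loop. Entry is uniform over match
states (B→M_k = 1/M); every match state carries a fixed exit probability to E
(default 0.05, with the last match and last delete states exiting with
probability 1); E re-enters the core through J with probability 0.5 per
completed pass (multihit; 0 disables re-entry). Flank loop probabilities
follow a target-length model, loop = L/(L+2), and the null model emits L
background residues with a geometric length term r = L/(L+1).

Scores are log2 likelihood ratios ("bits") against that null. The full-
sequence score comes from the forward algorithm over the whole local multihit
path ensemble; domain envelopes and per-domain scores come from the Viterbi
path, one `DomainHit` per B→…→E pass, the pass score being its entry, internal
and exit transitions plus emission log-odds (insert emissions equal the
background, so inserts cost only their transitions). Ties in the Viterbi
recursion prefer match over delete over insert, and continuation over a new
entry, making envelopes deterministic. All dynamic programming runs in
natural-log space (converted to bits at the end) and is JIT-compiled with
numba, with an identical pure-Python fallback.

Two inclusion thresholds gate search output, following the Pfam-style
convention: a sequence threshold of 24.0 bits on the forward score and a
domain threshold of 15.4 bits on each envelope. Both are parameters;
these defaults are the values used in the original study.

### Estimation choices

* Match columns: alignment columns with non-gap occupancy ≥ 0.5 (parameter).
* Emissions: add-k pseudocounts (default k = 1) on observed match-column
  counts, i.e. P(a) = (c_a + k)/(n + 20k). This deliberately replaces
  Dirichlet-mixture priors; bit scores therefore approximate, not reproduce,
  HMMER's values (exact HMMER compatibility is a non-goal).
* Insert emissions are fixed at the background composition, so insertions are
  scored through their transitions only.
* Transitions: counted along each row's match/insert/delete path with the same
  add-k smoothing; the two adjacencies the architecture cannot represent
  (insert→delete, delete→insert) are skipped during counting.
* The null/background table is a standard database amino-acid composition
  (Swiss-Prot-like); a uniform 1/20 table can be supplied instead. Non-standard
  residues (B, Z, X, U, O, J) score at background under model and null alike,
  contributing exactly zero bits.
* The per-match-state exit probability is a length-independent constant
  (0.05) rather than 1/M. A fixed exit keeps partial-coverage alignments
  viable when the model is much longer than the conserved region — the exact
  situation of a round-0 single-query model, where a ~30-residue motif must be
  found inside a ~300-state profile.

### A score budget, for intuition

For a ~300-residue target, the structural cost of one local pass — entry
(log2 1/M), exit, flank moves and length terms net of the null — is roughly
17–19 bits. Reaching the 24-bit sequence threshold therefore requires about
40–45 bits of emission log-odds, i.e. ~1.4 bits per column for a 30-column
model. This budget drives several design decisions below and matches what
real curated seed alignments of short domains deliver.

## Iterative (jackhmmer-style) search

Round 0 builds a single-sequence model from the query: one match state per
residue, with emissions set to BLOSUM62 conditional probabilities
P(b | a) ∝ f_a f_b 2^(s_ab/2) / f_a — the standard device that makes a
single-query profile behave like a substitution-matrix search. (An add-k
single-sequence model carries well under one bit per identical residue, so no
homolog could ever reach 24 bits and the iteration could never leave the
query; matrix conditionals give 2–3 bits per identity, which is what makes
single-query discovery possible at these thresholds.) Core transitions of the
round-0 model are fixed (match→match 0.97) since a single sequence carries no
gap information.

Each round searches the database, includes every sequence meeting the
thresholds (the query is always retained), re-aligns the included sequences to
the current model using each one's best-scoring Viterbi pass projected onto
the match columns, rebuilds the profile with the standard estimator, and
repeats. Convergence is set equality of the included set between consecutive
rounds, guarded by max_iter (default 5); inclusion sets may shrink. Profile
narrowing is automatic: columns covered only by the query fall below the
occupancy rule once true homologs dominate the alignment, so a long round-0
model collapses to the conserved motif in round 1.

The re-search ("novelty") validation samples n known members without
replacement, runs the full iteration from each, and reports per query the
fraction of finally-included sequences that are not in the known set, plus the
arithmetic mean. Fractions count sequences, not domain regions, and are
measured at convergence.

## The reversed-alignment decoy control

The decoy profile is built from the column-reversed seed alignment with
identical estimation parameters — same M, same pseudocounts, same null — so it
preserves the emission inventory while destroying the positional signal.
Every database sequence is scored under both profiles; scores at or above a
floor are retained and compared against the sequence inclusion threshold. The
control is sound when (i) no sequence reaches the threshold under the decoy,
(ii) the forward profile recovers the planted family, and (iii) forward hits
show an excess below the threshold (low-scoring true relatives).

The floor (default 10 bits) acts like a reporting threshold: it sits several
standard deviations above the background score bulk (~12% of background
sequences score above 0 bits, essentially none above 10), so the sub-threshold
comparison counts candidate homologs rather than background noise. At floor 0
the two profiles' slightly different background tail rates, multiplied by a
10,000-sequence database, would dominate the handful of genuine sub-threshold
relatives and make the excess sign-indeterminate; the floor is exposed as a
parameter. On databases with no planted signal the forward and decoy score
distributions are statistically indistinguishable (checked with a two-sample
Mann–Whitney U test at α = 0.01).

## Censuses

* Terminal bias: a protein counts as "within the window" iff every one of its
  target-domain envelopes satisfies protein_length − env_start + 1 ≤ window
  (default 50), i.e. the whole domain lies in the final window. Denominators
  are proteins, and the fraction is non-decreasing in the window.
* Taxonomy: species identity is the clade path's terminal label (strains are
  not collapsed); counts are distinct species per clade at an integer path
  rank, with percentages relative to species classified at that rank.
* Architectures: the N-to-C tuple of domain ids ordered by envelope start
  (ties by end, with a warning on overlap), counted over proteins containing
  the target domain; repeats are kept.
* Copy number: per-protein copy counts with region/protein totals; region
  totals are cross-checked against the raw records.

## The synthetic proteome generator

The generator defines the study conditions; its defaults are fixed, not tuned.

The planted motif is 30 columns long: two helix blocks (columns 3–14 and
19–30) joined by a 4-residue loop. One invariant glycine (column 8) and one
invariant glutamate (column 24); two charged-class-preferring columns (5, 21)
and five hydrophobic-class-preferring columns (4, 11, 13, 22, 27) that emit
their class with probability p_cons (default 0.8), the class's modal residue
taking 70% of the class mass (sharpening to a point mass as p_cons → 1, so
full conservation yields the consensus string). The remaining 21 "framework"
columns carry a modal residue at conservation p_cons + 0.05 (default 0.85).
Framework conservation is deliberate: by the score budget above, a motif
informative only at its nine annotated positions (~11 bits) could never cross
the 24-bit threshold, whereas framework columns at 0.85 give a 60-row seed
profile ~2.4 bits per column — the regime in which the published thresholds
are meaningful, and typical of real seed alignments of short domains. Indels
are forbidden inside both helices and the loop; only the two N-terminal
boundary columns may be deleted (rate 0.02 each) and a single background
insertion may precede column 1. Weakened homologs are sampled from the same
modal residues at p_cons 0.35 (invariants decay to p_cons + 0.2), placing
them overwhelmingly below the 24-bit threshold but well above background —
the sub-threshold excess the decoy control is meant to reveal.

Background proteins are i.i.d. draws from the same composition table as the
HMM null, so background scores centre near zero bits; lengths are log-normal
(median 300, σ = 0.5, clipped to [60, 2000]). Family proteins realise one of
five default architectures over the target domain and two decoy domain
families (single, two two-domain, one three-domain, and a tandem two-copy
architecture); decoy domains are 40-column conserved families with no special
positions. The protein's most C-terminal family instance is placed entirely
within the final 50 residues with probability p (default 0.9); otherwise it is
placed uniformly with its start strictly before the window, so the measured
terminal-bias fraction estimates p exactly. Taxonomy labels draw species from
a pool whose clade weights echo the published phylum proportions. The gold
seed alignment collects every full-strength planted instance with its true
column map. All output is reproducible byte-for-byte from (config, seed).

What the generator does not emulate: phylogenetic correlation between family
members (instances are i.i.d. given the column model), compositional bias or
repeats in background sequences, real secondary structure, and database-scale
redundancy. Passing tests therefore demonstrate the pipeline's correctness
and calibration under a clean, well-specified family model — not performance
on real proteomes, where neighbour-correlation and biased composition make
both recovery and false-positive behaviour harsher.

## Problem sizes used in the shipped analyses

The package's own study conditions are desk-scale: the decoy control runs on
10,000 background + 60 family + 40 weak-homolog proteins; iterative recovery
on 2,000 background + 50 family; the novelty validation on a 52-member family
with 2 members withheld from the known set, 5 random queries over 500
background proteins (2/52 ≈ 3.8% expected novelty); the terminal-bias check on
500 single-copy family proteins at p = 0.9. The published full-scale numbers
(1,403 regions on 1,381 proteins from 882 species; 89.2% within 50 residues;
63 architectures; 3.9% novelty) depend on database releases not shipped here
and are context, not targets.

## Numerical notes and limitations

* Log-sum-exp uses an early-out at 36 nats; forward/Viterbi agree with
  brute-force path enumeration to better than 1e-12 relative on enumerable
  instances, and forward ≥ Viterbi always.
* Emission and transition distributions are validated to 1e-9 after every
  build; a degenerate all-gap alignment, an empty sequence, and an empty
  database are errors, not silent no-ops.
* Domain envelopes come from the single best Viterbi path; no posterior
  envelope widening is performed, so envelope edges can be a residue or two
  tighter than a posterior-decoding method would give.
* E-values are not computed; all gating is in bits, as in the original
  procedure.
* With very small families (≲ 10 members) an iterative search can converge to
  a stable core subfamily: an add-k profile estimated from a handful of rows
  sits near the 24-bit threshold, so the marginal members it misses are never
  added. The shipped study conditions use 50–60-member families, where round-1
  recall from a single query is high enough that this fixed point is the full
  family.
* Searching is O(L·M) per sequence with a small constant; the 10,000-sequence
  decoy control completes in about a minute on one core.
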