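import numpy as np
import pytest

from conftest import random_hmm
from oracle_paths import oracle_bits

from shoctscan.alphabet import AMINO_ACIDS, sample_background
from shoctscan.profile_hmm import (
    SearchThresholds,
    build_hmm,
    forward_bitscore,
    read_hmm,
    score_database,
    search,
    single_sequence_hmm,
    viterbi_decode,
    write_hmm,
)
from shoctscan.seqdata_io import Alignment, Sequence
from shoctscan.synthetic_data import generate_proteome


class TestBuild:
    def test_ungapped_single_row_has_one_match_state_per_column(self):
        a = Alignment.from_rows([("r", "ACDEFGHIKL")])
        assert build_hmm(a).M == 10

    def test_pseudocount_arithmetic_on_two_identical_rows(self):
        a = Alignment.from_rows([("r1", "A"), ("r2", "A")])
        h = build_hmm(a, pseudocount=1.0)
        em = h.match_emissions[0]
        assert em[0] == pytest.approx(3 / 22)
        assert em[1:] == pytest.approx(np.full(19, 1 / 22))

    def test_synthetic_seed_yields_thirty_match_states(self, small_proteome):
        _, _, seed_aln, _ = small_proteome
        assert build_hmm(seed_aln).M == 30

    def test_all_gap_alignment_is_an_error(self):
        a = Alignment.from_rows([("r1", "--."), ("r2", ".--")])
        with pytest.raises(ValueError, match="occupancy"):
            build_hmm(a)

    def test_low_occupancy_columns_become_inserts(self):
        a = Alignment.from_rows([("r1", "AC-DE"), ("r2", "AC-DE"), ("r3", "ACWDE")])
        assert build_hmm(a, occupancy_rule=0.5).M == 4

    def test_normalization_after_build(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ncol = int(rng.integers(3, 15))
            nrow = int(rng.integers(1, 8))
            rows = []
            for r in range(nrow):
                chars = [
                    "-" if rng.random() < 0.25 else AMINO_ACIDS[rng.integers(20)]
                    for _ in range(ncol)
                ]
                rows.append((f"r{r}", "".join(chars)))
            try:
                h = build_hmm(Alignment.from_rows(rows))
            except ValueError:
                continue  # all-gap under the occupancy rule
            h.validate(tol=1e-9)


class TestScoringAgainstOracle:
    def test_forward_and_viterbi_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for M in (1, 2, 3):
            for L in (1, 2, 3, 6):
                for _ in range(2):
                    h = random_hmm(rng, M)
                    codes = rng.integers(0, 4, size=L)
                    seq = "".join(AMINO_ACIDS[c] for c in codes)
                    fb_o, vb_o = oracle_bits(h, codes)
                    assert forward_bitscore(h, seq) == pytest.approx(fb_o, rel=1e-9, abs=1e-9)
                    vb, _ = viterbi_decode(h, seq)
                    assert vb == pytest.approx(vb_o, rel=1e-9, abs=1e-9)

    def test_unihit_mode_matches_oracle(self):
        rng = np.random.default_rng(11)
        h = random_hmm(rng, 2, reentry=0.0)
        codes = rng.integers(0, 4, size=4)
        seq = "".join(AMINO_ACIDS[c] for c in codes)
        fb_o, vb_o = oracle_bits(h, codes)
        assert forward_bitscore(h, seq) == pytest.approx(fb_o, rel=1e-9)
        assert viterbi_decode(h, seq)[0] == pytest.approx(vb_o, rel=1e-9)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            h = random_hmm(rng, int(rng.integers(1, 6)))
            seq = sample_background(rng, int(rng.integers(1, 30)))
            assert forward_bitscore(h, seq) >= viterbi_decode(h, seq)[0] - 1e-9


@pytest.fixture(scope="module")
def peaked():
    rows = [(f"r{i}", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL") for i in range(20)]
    return build_hmm(Alignment.from_rows(rows))


class TestScoringBehaviour:

    def test_consensus_beats_its_shuffle(self, peaked):
        consensus = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        rng = np.random.default_rng(0)
        shuffled = "".join(rng.permutation(list(consensus)))
        assert forward_bitscore(peaked, consensus) > forward_bitscore(peaked, shuffled)

    def test_two_planted_copies_give_two_envelopes(self, peaked):
        rng = np.random.default_rng(1)
        consensus = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        seq = (
            sample_background(rng, 15)
            + consensus
            + sample_background(rng, 20)
            + consensus
            + sample_background(rng, 15)
        )
        _, doms = viterbi_decode(peaked, seq)
        strong = [d for d in doms if d.score >= 15.4]
        assert len(strong) == 2
        assert strong[0].env_end < strong[1].env_start

    def test_background_has_no_domain_above_threshold(self, peaked):
        rng = np.random.default_rng(2)
        seq = sample_background(rng, 200)
        _, doms = viterbi_decode(peaked, seq)
        assert [d for d in doms if d.score >= 15.4] == []

    def test_empty_sequence_is_an_error(self, peaked):
        with pytest.raises(ValueError):
            forward_bitscore(peaked, "")

    def test_nonstandard_residues_score_zero_bits(self, peaked):
        # X scores at background under model and null alike
        sx = forward_bitscore(peaked, "X" * 40)
        assert sx == pytest.approx(forward_bitscore(peaked, "X" * 40))
        assert np.isfinite(sx)


class TestSearch:
    def test_empty_db(self, small_proteome):
        _, _, seed_aln, _ = small_proteome
        h = build_hmm(seed_aln)
        assert search(h, [], SearchThresholds()) == []

    def test_default_thresholds_are_the_inclusion_thresholds(self):
        t = SearchThresholds()
        assert t.sequence_bits == 24.0 and t.domain_bits == 15.4

    def test_planted_family_found_and_background_excluded(self, small_proteome):
        _, db, seed_aln, truth = small_proteome
        h = build_hmm(seed_aln)
        hits = search(h, db, SearchThresholds())
        hit_ids = {x.seq_id for x in hits}
        fam = set(truth.family_protein_ids)
        assert fam <= hit_ids
        assert not any(i.startswith(("BG", "DEC")) for i in hit_ids)

    def test_order_invariance_and_sorting(self, small_proteome):
        _, db, seed_aln, _ = small_proteome
        h = build_hmm(seed_aln)
        sub = db[:80]
        a = search(h, sub, SearchThresholds())
        b = search(h, list(reversed(sub)), SearchThresholds())
        assert a == b
        scores = [x.full_score for x in a]
        assert scores == sorted(scores, reverse=True)

    def test_threshold_monotonicity(self, small_proteome):
        _, db, seed_aln, _ = small_proteome
        h = build_hmm(seed_aln)
        sub = [s for s in db if s.id.startswith(("FAM", "WEAK"))]
        n_prev = None
        for seq_bits in (10.0, 24.0, 40.0):
            hits = search(h, sub, SearchThresholds(seq_bits, 15.4))
            if n_prev is not None:
                assert len(hits) <= n_prev
            n_prev = len(hits)
        n_dom_prev = None
        for dom_bits in (5.0, 15.4, 30.0):
            hits = search(h, sub, SearchThresholds(24.0, dom_bits))
            n_dom = sum(len(x.domains) for x in hits)
            if n_dom_prev is not None:
                assert n_dom <= n_dom_prev
            n_dom_prev = n_dom

    def test_duplicate_ids_rejected(self, small_proteome):
        _, db, seed_aln, _ = small_proteome
        h = build_hmm(seed_aln)
        with pytest.raises(ValueError, match="unique"):
            search(h, [db[0], db[0]], SearchThresholds())


class TestSerialization:
    def test_round_trip(self, tmp_path, small_proteome):
        _, db, seed_aln, _ = small_proteome
        h = build_hmm(seed_aln)
        p = tmp_path / "model.hmm"
        write_hmm(h, p)
        h2 = read_hmm(p)
        assert h2.M == h.M
        np.testing.assert_array_equal(h2.match_emissions, h.match_emissions)
        np.testing.assert_array_equal(h2.t_core, h.t_core)
        s = db[0]
        assert forward_bitscore(h2, s) == forward_bitscore(h, s)

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "bad.hmm"
        p.write_text("HMMER3/f\n")
        with pytest.raises(ValueError):
            read_hmm(p)


def test_single_sequence_model_prefers_its_own_query():
    rng = np.random.default_rng(9)
    q = sample_background(rng, 60)
    other = sample_background(rng, 60)
    h = single_sequence_hmm(Sequence("q", q))
    assert forward_bitscore(h, q) > forward_bitscore(h, other) + 10
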