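import numpy as np
import pytest

from shoctscan.annotation_analysis import (
    architecture_census,
    copy_number_census,
    taxon_breakdown,
    terminal_bias,
)
from shoctscan.seqdata_io import DomainAnnotationRecord as Rec


def _rec(pid, L, dom, start, end, score=20.0):
    return Rec(pid, L, dom, start, end, score)


class TestTerminalBias:
    def test_flush_c_terminal_domain_counts_as_within(self):
        recs = [_rec("p1", 100, "SHOCT", 71, 100)]
        r = terminal_bias(recs, "SHOCT", window=50)
        assert r.fraction == 1.0 and r.n_proteins == 1

    def test_hand_counted_toy_table(self):
        recs = [
            _rec("p1", 200, "SHOCT", 160, 190),   # within (200-160+1=41)
            _rec("p2", 300, "SHOCT", 260, 290),   # within
            _rec("p3", 300, "SHOCT", 100, 130),   # not within
            _rec("p4", 150, "SHOCT", 120, 149),   # within (31)
            _rec("p5", 400, "SHOCT", 340, 370),   # not within (61)
        ]
        r = terminal_bias(recs, "SHOCT", window=50)
        assert (r.n_proteins, r.n_within) == (5, 3)
        assert r.fraction == pytest.approx(0.6)

    def test_every_envelope_must_be_within(self):
        recs = [
            _rec("p1", 300, "SHOCT", 270, 299),
            _rec("p1", 300, "SHOCT", 100, 129),  # second copy far from C-terminus
        ]
        assert terminal_bias(recs, "SHOCT").fraction == 0.0

    def test_order_invariance_and_window_monotonicity(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(60):
            L = int(rng.integers(100, 500))
            start = int(rng.integers(1, L - 30))
            recs.append(_rec(f"p{i}", L, "SHOCT", start, start + 29))
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        assert terminal_bias(recs, "SHOCT").fraction == terminal_bias(shuffled, "SHOCT").fraction
        fracs = [terminal_bias(recs, "SHOCT", w).fraction for w in (30, 50, 100, 400)]
        assert fracs == sorted(fracs)

    def test_absent_domain_is_an_error(self):
        with pytest.raises(ValueError, match="no records"):
            terminal_bias([_rec("p1", 100, "OTHER", 1, 30)], "SHOCT")

    def test_other_domains_do_not_affect_the_census(self):
        recs = [
            _rec("p1", 300, "SHOCT", 270, 299),
            _rec("p1", 300, "DOM_A", 10, 50),
        ]
        assert terminal_bias(recs, "SHOCT").fraction == 1.0


class TestTaxonBreakdown:
    def _tax(self, mapping):
        return {pid: path for pid, path in mapping.items()}

    def test_single_clade_is_one_hundred_percent(self):
        recs = [_rec("p1", 100, "SHOCT", 50, 80), _rec("p2", 100, "SHOCT", 50, 80)]
        tax = self._tax({"p1": "Bacteria;Firmicutes;Sp A", "p2": "Bacteria;Firmicutes;Sp B"})
        r = taxon_breakdown(recs, tax, rank=1)
        assert r.percentages == {"Firmicutes": 100.0}

    def test_hand_counted_phylum_split(self):
        recs, tax = [], {}
        phyla = ["Firmicutes"] * 6 + ["Proteobacteria"] * 3 + ["Actinobacteria"]
        for i, ph in enumerate(phyla):
            pid = f"p{i}"
            recs.append(_rec(pid, 100, "SHOCT", 50, 80))
            tax[pid] = f"Bacteria;{ph};Species {i}"
        r = taxon_breakdown(recs, tax, rank=1)
        assert r.percentages["Firmicutes"] == pytest.approx(60.0)
        assert r.percentages["Proteobacteria"] == pytest.approx(30.0)
        assert r.percentages["Actinobacteria"] == pytest.approx(10.0)

    def test_species_with_many_proteins_counted_once(self):
        recs = [_rec(f"p{i}", 100, "SHOCT", 50, 80) for i in range(4)]
        tax = {f"p{i}": "Bacteria;Firmicutes;Same species" for i in range(4)}
        r = taxon_breakdown(recs, tax, rank=1)
        assert r.counts == {"Firmicutes": 1}
        assert r.n_species_total == 1

    def test_rank_absent_everywhere_is_an_error(self):
        recs = [_rec("p1", 100, "SHOCT", 50, 80)]
        tax = {"p1": "Bacteria;Species only"}
        with pytest.raises(ValueError, match="rank"):
            taxon_breakdown(recs, tax, rank=1)

    def test_no_coverage_is_an_error(self):
        recs = [_rec("p1", 100, "SHOCT", 50, 80)]
        with pytest.raises(ValueError, match="covers"):
            taxon_breakdown(recs, {"other": "Bacteria;F;S"}, rank=1)


class TestArchitectureCensus:
    def test_hand_grouping(self):
        recs = [
            _rec("p1", 300, "A", 10, 60), _rec("p1", 300, "SHOCT", 260, 290),
            _rec("p2", 300, "A", 10, 60), _rec("p2", 300, "SHOCT", 260, 290),
            _rec("p3", 300, "SHOCT", 10, 40), _rec("p3", 300, "B", 100, 200),
        ]
        c = architecture_census(recs, "SHOCT")
        assert c.n_distinct == 2
        assert c.architectures[("A", "SHOCT")] == 2
        assert c.architectures[("SHOCT", "B")] == 1

    def test_single_protein(self):
        c = architecture_census([_rec("p1", 100, "SHOCT", 50, 80)], "SHOCT")
        assert c.n_distinct == 1 and c.architectures == {("SHOCT",): 1}

    def test_repeats_kept_and_ordered_n_to_c(self):
        recs = [
            _rec("p1", 300, "SHOCT", 200, 230),
            _rec("p1", 300, "SHOCT", 100, 130),
        ]
        c = architecture_census(recs, "SHOCT")
        assert list(c.architectures) == [("SHOCT", "SHOCT")]

    def test_proteins_without_target_domain_excluded(self):
        recs = [
            _rec("p1", 100, "SHOCT", 50, 80),
            _rec("p2", 100, "A", 10, 40),
        ]
        c = architecture_census(recs, "SHOCT")
        assert sum(c.architectures.values()) == 1

    def test_overlap_warns_but_orders_deterministically(self):
        recs = [
            _rec("p1", 300, "A", 100, 200),
            _rec("p1", 300, "SHOCT", 150, 180),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            c = architecture_census(recs, "SHOCT")
        assert list(c.architectures) == [("A", "SHOCT")]

    def test_totals_equal_target_protein_count(self, small_proteome):
        _, _, _, truth = small_proteome
        c = architecture_census(truth.records, "SHOCT")
        n_target = len({r.protein_id for r in truth.records if r.domain_id == "SHOCT"})
        assert sum(c.architectures.values()) == n_target


class TestCopyNumber:
    def test_all_single_copy(self):
        recs = [_rec(f"p{i}", 100, "SHOCT", 50, 80) for i in range(7)]
        c = copy_number_census(recs, "SHOCT")
        assert c.copies == {1: 7}
        assert c.n_regions == c.n_proteins == 7

    def test_repeat_rich_toy_table(self):
        recs = []
        for s in range(8):  # one protein with eight repeats
            recs.append(_rec("p_eight", 900, "SHOCT", 100 * s + 1, 100 * s + 30))
        for pid in ("p_three_a", "p_three_b"):
            for s in range(3):
                recs.append(_rec(pid, 400, "SHOCT", 100 * s + 1, 100 * s + 30))
        c = copy_number_census(recs, "SHOCT")
        assert c.copies == {8: 1, 3: 2}
        assert c.max_copies == 8
        assert c.n_regions == 14 and c.n_proteins == 3

    def test_region_count_conserved_against_raw_records(self, small_proteome):
        _, _, _, truth = small_proteome
        c = copy_number_census(truth.records, "SHOCT")
        assert c.n_regions == sum(1 for r in truth.records if r.domain_id == "SHOCT")
        assert c.n_regions >= c.n_proteins
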