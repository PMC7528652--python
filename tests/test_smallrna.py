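"""Small-RNA quantification: filtering, mapping, fractional counting,
spike-in normalization, fold changes, partition and composition."""

import numpy as np
import pandas as pd
import pytest

import yeastrnai as y
from yeastrnai.io import Locus, SpikeInStandard
from yeastrnai.mapping import AlignmentRecord, GenomeIndex, Hit
from yeastrnai.smallrna import (
    CompositionStats, abundance_table, composition_stats, filter_by_length,
    fold_change_table, fractional_count, partition_by_class, spikein_scale,
)

SIZE_MARKER_26 = "AGCGUGUACUCCGAAGAGGAUCCAAA"   # 26-nt ligation standard


class TestLengthFilter:
    def test_short_reads_removed_and_boundary_retained(self):
        out = filter_by_length(["ACGTACGT", SIZE_MARKER_26, "A" * 27])
        assert list(out) == [SIZE_MARKER_26.replace("U", "T")]

    def test_identical_reads_collapse_with_summed_counts(self):
        out = filter_by_length(["ACGT" * 5 + "ACG"] * 2)
        assert out == {"ACGT" * 5 + "ACG": 2}

    def test_empty_input_is_empty_output(self):
        assert filter_by_length([]) == {}


class TestMapping:
    def test_unique_read_has_one_site(self, genome, genome_index):
        row = genome.duplexes[genome.duplexes["cls"] == "non_palindromic"].iloc[0]
        hits = genome_index.find(row["guide"])
        assert len(hits) == 1

    def test_palindrome_read_hits_both_arms(self, genome, genome_index):
        row = genome.duplexes[genome.duplexes["cls"] == "palindromic"].iloc[0]
        hits = genome_index.find(row["guide"])
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}

    def test_spikein_routed_to_tally_not_genome(self, genome_index, spikeins):
        mir427 = spikeins[0]
        res = y.map_reads({mir427.sequence: 7, "N" * 22: 3}, genome_index, spikeins)
        assert res.spike_counts[mir427.name] == 7
        assert res.n_skipped == 3
        assert all(a.sequence != mir427.sequence for a in res.alignments)

    def test_spikeins_absent_from_synthetic_genome(self, genome_index, spikeins):
        for s in spikeins:
            assert genome_index.find(s.sequence) == ()


def _rec(seq, count, hits):
    return AlignmentRecord(seq, count, tuple(Hit(*h) for h in hits))


LOCI = [
    Locus("chr1", 100, 300, "locA", "palindromic"),
    Locus("chr1", 500, 700, "locB", "non_palindromic"),
    Locus("chr2", 100, 300, "locC", "y_prime"),
]


class TestFractionalCounting:
    def test_multimapper_contributes_hit_share(self):
        rec = _rec("A" * 22, 1, [("chr1", 150, 172, "+"), ("chr1", 900, 922, "+"),
                                 ("chr2", 10, 32, "+"), ("chr2", 400, 422, "+")])
        fc = fractional_count([rec], LOCI)
        assert fc.counts["locA"] == pytest.approx(0.25)
        assert fc.unassigned == pytest.approx(0.75)

    def test_unique_hit_counts_fully(self):
        rec = _rec("A" * 22, 3, [("chr1", 510, 532, "+")])
        fc = fractional_count([rec], LOCI)
        assert fc.counts["locB"] == pytest.approx(3.0)

    def test_boundary_rule_majority_of_bases_inside(self):
        inside = _rec("A" * 22, 1, [("chr1", 285, 307, "+")])   # 15/22 inside
        outside = _rec("C" * 22, 1, [("chr1", 292, 314, "+")])  # 8/22 inside
        fc = fractional_count([inside, outside], LOCI)
        assert fc.counts["locA"] == pytest.approx(1.0)
        assert fc.unassigned == pytest.approx(1.0)

    def test_mass_conservation_on_simulated_study(self, mappings, genome):
        fc = fractional_count(mappings["WT"].alignments, genome.loci)
        total_assigned = sum(fc.counts.values()) + fc.unassigned
        assert total_assigned == pytest.approx(fc.total, abs=1e-9)

    def test_locus_hits_denominator_assigns_full_weight(self):
        rec = _rec("A" * 22, 1, [("chr1", 150, 172, "+"), ("chr1", 900, 922, "+")])
        fc = fractional_count([rec], LOCI, denominator="locus_hits")
        assert fc.counts["locA"] == pytest.approx(1.0)


STANDARDS = [
    SpikeInStandard("s1", "ACGTACGTACGTACGTACGTAC", 0.5),
    SpikeInStandard("s2", "TGCATGCATGCATGCATGCATG", 0.5),
]


class TestSpikeinScale:
    def test_identical_recovery_gives_unit_ratio(self):
        f = spikein_scale({"a": {"s1": 100, "s2": 50}, "b": {"s1": 100, "s2": 50}},
                          STANDARDS)
        assert f == {"a": 1.0, "b": pytest.approx(1.0)}

    def test_half_recovery_doubles_factor(self):
        f = spikein_scale({"ref": {"s1": 100, "s2": 40}, "lo": {"s1": 50, "s2": 20}},
                          STANDARDS, reference="ref")
        assert f["lo"] == pytest.approx(2.0)

    def test_factor_invariant_to_standard_relabeling(self):
        tallies = {"a": {"s1": 120, "s2": 30}, "b": {"s1": 60, "s2": 90}}
        swapped = {smp: {"s1": t["s2"], "s2": t["s1"]} for smp, t in tallies.items()}
        assert spikein_scale(tallies, STANDARDS) == spikein_scale(swapped, STANDARDS)

    def test_factor_scales_inversely_with_subsampling(self):
        full = {"a": {"s1": 400, "s2": 100}, "b": {"s1": 200, "s2": 50}}
        f = spikein_scale(full, STANDARDS, reference="a")
        assert f["b"] == pytest.approx(2.0)

    def test_all_standards_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no internal standard"):
            spikein_scale({"a": {"s1": 0, "s2": 0}}, STANDARDS)


def _table(sample, counts, rpm=None, factor=1.0):
    rpm = rpm if rpm is not None else {k: 10.0 for k in counts}
    df = pd.DataFrame({
        "cls": {k: "non_palindromic" for k in counts},
        "frac_count": counts,
        "rpm": rpm,
        "norm_abundance": {k: v * factor for k, v in counts.items()},
    })
    df.index.name = "locus"
    from yeastrnai.smallrna import AbundanceTable
    return AbundanceTable(sample, df, 1_000_000, factor)


class TestFoldChanges:
    def test_equal_abundance_gives_zero_log2_fc(self):
        wt = _table("wt", {"l1": 100.0})
        mut = _table("mut", {"l1": 100.0})
        fc = fold_change_table(wt, mut)
        assert fc.table.loc["l1", "log2_fc"] == pytest.approx(0.0)

    def test_low_wt_rpm_locus_excluded(self):
        wt = _table("wt", {"l1": 100.0, "l2": 100.0}, rpm={"l1": 10.0, "l2": 0.5})
        mut = _table("mut", {"l1": 100.0, "l2": 400.0})
        fc = fold_change_table(wt, mut, min_wt_rpm=1.0)
        assert list(fc.table.index) == ["l1"]

    def test_mismatched_locus_sets_rejected(self):
        with pytest.raises(ValueError, match="locus sets"):
            fold_change_table(_table("wt", {"l1": 1.0}), _table("mut", {"l2": 1.0}))

    def test_scale_factors_enter_fold_change(self):
        wt = _table("wt", {"l1": 100.0}, factor=1.0)
        mut = _table("mut", {"l1": 100.0}, factor=2.0)
        fc = fold_change_table(wt, mut)
        assert fc.table.loc["l1", "log2_fc"] == pytest.approx(1.0)


class TestPartition:
    def test_single_palindrome_read(self):
        rec = _rec("A" * 22, 4, [("chr1", 150, 172, "+")])
        assert partition_by_class([rec], LOCI)["palindromic"] == 1.0

    def test_palindromic_plus_yprime_is_both(self):
        rec = _rec("A" * 22, 1, [("chr1", 150, 172, "+"), ("chr2", 150, 172, "+")])
        assert partition_by_class([rec], LOCI)["both"] == 1.0

    def test_fractions_sum_to_one_and_order_invariant(self, mappings, genome):
        alns = mappings["WT"].alignments
        p1 = partition_by_class(alns, genome.loci)
        p2 = partition_by_class(list(reversed(alns)), genome.loci)
        assert sum(p1.values()) == pytest.approx(1.0, abs=1e-12)
        assert p1 == p2


class TestComposition:
    def test_all_u_start_23mers(self):
        recs = [_rec("T" + "A" * 22, 5, [("chr1", 0, 23, "+")])]
        comp = composition_stats(recs)
        assert comp.first_nt.loc[23, "T"] == 1.0

    def test_exclusive_rrna_mappers_excluded(self):
        rrna = [Locus("chr1", 0, 1000, "rdn", "rrna")]
        inside = _rec("A" * 23, 5, [("chr1", 100, 123, "+")])
        outside = _rec("C" * 23, 2, [("chr1", 2000, 2023, "+")])
        comp = composition_stats([inside, outside], exclusion=rrna)
        assert comp.length_counts[23] == 2

    def test_planted_guide_u5_probability_recovered(self, study, effects):
        _, truth = study
        guides = truth.species[truth.species["role"] == "guide"]
        measured = (guides.loc[guides["sequence"].str.startswith("T"), "count_WT"].sum()
                    / guides["count_WT"].sum())
        expected = (guides.loc[guides["sequence"].str.startswith("T"), "expected_WT"].sum()
                    / guides["expected_WT"].sum())
        # read sampling at this depth perturbs the planted fraction by far
        # less than two percentage points
        assert measured == pytest.approx(expected, abs=0.02)
        assert expected > 0.5   # the planted 5'-U bias dominates
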