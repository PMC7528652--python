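"""Synthetic-study generator: construction invariants, determinism, truth."""

import numpy as np
import pytest

import yeastrnai as y
from yeastrnai.geometry import revcomp
from yeastrnai.simulate import CapacityError, simulate_timecourse
from yeastrnai.kinetics import burst_model


class TestMakeGenome:
    def test_zero_loci_gives_empty_annotation(self):
        spec = y.GenomeSpec(n_palindromic_loci=0, n_nonpalindromic_loci=0,
                            n_yprime_loci=0, n_slice_genes=0, seed=1)
        g = y.make_genome(spec)
        assert g.loci == [] and len(g.duplexes) == 0

    def test_palindromic_locus_arms_are_inverted_repeats(self, genome):
        A, loop = genome.spec.arm_length, genome.spec.loop_length
        for loc in genome.loci:
            if loc.cls != "palindromic":
                continue
            seq = genome.chromosomes[loc.chrom][loc.start:loc.end]
            assert revcomp(seq[:A]) == seq[A + loop:]

    def test_fixed_seed_reproduces_outputs_byte_identically(self, tmp_path):
        from yeastrnai import io as yio

        for sub in ("a", "b"):
            g = y.make_genome(y.GenomeSpec(seed=3))
            d = tmp_path / sub
            d.mkdir()
            yio.write_fasta(g.chromosomes, d / "genome.fa")
            yio.write_bed(g.loci, d / "loci.bed")
        assert (tmp_path / "a/genome.fa").read_bytes() == (tmp_path / "b/genome.fa").read_bytes()
        assert (tmp_path / "a/loci.bed").read_bytes() == (tmp_path / "b/loci.bed").read_bytes()

    def test_overfull_genome_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            y.make_genome(y.GenomeSpec(chrom_length=900, n_chromosomes=1,
                                       n_nonpalindromic_loci=10, seed=1))

    def test_planted_duplexes_have_valid_geometry(self, genome):
        from yeastrnai.geometry import is_sirna_duplex

        for row in genome.duplexes.itertuples():
            assert is_sirna_duplex(row.guide, row.passenger)


class TestSimulateLibraries:
    def test_seed_is_mandatory(self, genome, effects, spikeins):
        with pytest.raises(ValueError, match="seed"):
            y.simulate_libraries(genome, effects, spikeins, 1000, seed=None)

    def test_unknown_condition_rejected(self, genome, effects, spikeins):
        with pytest.raises(ValueError, match="condition"):
            y.simulate_libraries(genome, effects, spikeins, 1000, seed=1,
                                 conditions=["WT", "dcp2_del"])

    def test_depth_conservation(self, study):
        libs, truth = study
        for cond, lib in libs.items():
            assert lib.total_reads == lib.depth
            assert truth.species[f"count_{cond}"].sum() == lib.depth

    def test_every_genome_read_aligns_exactly(self, study, genome_index):
        _, truth = study
        genomic = truth.species[~truth.species["role"].isin(["spikein"])]
        rng = np.random.default_rng(0)
        sample = genomic.sample(200, random_state=int(rng.integers(2**31)))
        for seq in sample["sequence"]:
            assert genome_index.find(seq), f"unmappable simulated read {seq}"

    def test_palindromic_duplex_strands_map_to_opposite_arms(self, genome, genome_index):
        A, loop = genome.spec.arm_length, genome.spec.loop_length
        pal = {l.name: l for l in genome.loci if l.cls == "palindromic"}
        rows = genome.duplexes[genome.duplexes["cls"] == "palindromic"]
        for row in rows.itertuples():
            loc = pal[row.locus]
            arm1 = (loc.start, loc.start + A)
            arm2 = (loc.start + A + loop, loc.end)
            g_hits = [h for h in genome_index.find(row.guide)
                      if h.chrom == loc.chrom and h.strand == "+"]
            p_hits = [h for h in genome_index.find(row.passenger)
                      if h.chrom == loc.chrom and h.strand == "+"]
            assert any(arm1[0] <= h.start and h.end <= arm1[1] for h in g_hits)
            # passenger sits on the 3' arm (its 3' overhang may extend 2 nt past it)
            assert any(arm2[0] <= h.start and h.end <= arm2[1] + 2 for h in p_hits)

    def test_slicing_impaired_strain_has_no_fragment_reads(self, study):
        _, truth = study
        frags = truth.species[truth.species["role"].isin(
            ["passenger_5p_frag", "passenger_3p_frag"])]
        assert len(frags) > 0
        assert (frags["count_ago1_mut"] == 0).all()
        assert frags["count_xrn1_del"].sum() > 0

    def test_no_retention_no_fragments_yields_guides_and_spikeins_only(
            self, genome, effects, spikeins):
        import dataclasses

        bare = dataclasses.replace(
            effects,
            passenger_retention={c: 0.0 for c in effects.conditions},
            frag5_rate={c: 0.0 for c in effects.conditions},
            frag3_rate={c: 0.0 for c in effects.conditions},
        )
        libs, truth = y.simulate_libraries(
            genome, bare, spikeins, 20_000, seed=5, background_fraction=0.0)
        emitted = truth.species[truth.species["count_WT"] > 0]
        assert set(emitted["role"]) <= {"guide", "spikein"}

    def test_same_seed_gives_identical_libraries(self, genome, effects, spikeins):
        a, _ = y.simulate_libraries(genome, effects, spikeins, 30_000, seed=9)
        b, _ = y.simulate_libraries(genome, effects, spikeins, 30_000, seed=9)
        assert {c: lib.species for c, lib in a.items()} == \
               {c: lib.species for c, lib in b.items()}


class TestPlantedEffects:
    def test_rates_validated(self, genome):
        with pytest.raises(ValueError, match="rates"):
            y.PlantedEffects.default(
                genome, seed=1, passenger_retention={"WT": 1.5, "xrn1_del": 0.3,
                                                     "ago1_mut": 0.7})

    def test_class_median_folds_match_configuration(self, genome):
        eff = y.PlantedEffects.default(genome, seed=4)
        fold = eff.sirna_abundance["xrn1_del"] / eff.sirna_abundance["WT"]
        cls = {l.name: l.cls for l in genome.loci}
        pal = fold[[n for n in fold.index if cls[n] == "palindromic"]]
        nonpal = fold[[n for n in fold.index if cls[n] == "non_palindromic"]]
        # medians scatter log-normally about the configured class medians
        assert 0.15 < pal.median() < 0.5
        assert 2.5 < nonpal.median() < 6.5


class TestSimulateTimecourse:
    def test_zero_noise_equals_closed_form(self):
        t = np.linspace(0, 60, 13)
        tc = simulate_timecourse(10.0, 0.5, 0.05, t, 0.0, seed=1)
        np.testing.assert_allclose(tc.F, burst_model(t, 10.0, 0.5, 0.05))

    def test_time_zero_gives_zero_product(self):
        tc = simulate_timecourse(10.0, 2.0, 0.3, [0.0], 0.0, seed=1)
        assert tc.F[0] == 0.0

    def test_fixed_seed_reproduces_series(self):
        t = np.linspace(0, 30, 8)
        a = simulate_timecourse(10.0, 0.5, 0.05, t, 0.05, seed=2)
        b = simulate_timecourse(10.0, 0.5, 0.05, t, 0.05, seed=2)
        np.testing.assert_array_equal(a.F, b.F)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_timecourse(10.0, 0.5, 0.05, [0, 1], -0.1, seed=1)
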