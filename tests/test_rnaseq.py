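"""Precursor quantification: TPM, spike normalization, fold changes,
rank correlation and slice-site coverage asymmetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import yeastrnai as y
from yeastrnai.io import Locus
from yeastrnai.mapping import AlignmentRecord, GenomeIndex, Hit
from yeastrnai.rnaseq import (
    asymmetry_contrast, correlate_sirna_precursor, coverage_vector,
    precursor_fold_changes, quantify_loci, slice_site_asymmetry,
)
from yeastrnai.stats import spearman


@pytest.fixture(scope="module")
def rnaseq_study(genome, effects):
    mrna = y.make_mrna_spikeins(seed=21)
    libs, truth = y.simulate_rnaseq(genome, effects, mrna, 100_000, seed=22)
    return libs, truth, mrna


class TestQuantifyLoci:
    def test_tpm_sums_to_one_million(self, rnaseq_study, genome, genome_index):
        libs, _, mrna = rnaseq_study
        ab = quantify_loci(libs["WT"].species, genome_index, genome.loci, mrna)
        assert ab.table["tpm"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_equal_counts_equal_lengths_equal_tpm(self):
        rng = np.random.default_rng(9)
        chrom = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        loci = [Locus("c", 50, 150, "l1", "non_palindromic"),
                Locus("c", 200, 300, "l2", "non_palindromic")]
        idx = GenomeIndex({"c": chrom})
        species = {chrom[60:110]: 5, chrom[210:260]: 5}
        ab = quantify_loci(species, idx, loci)
        assert ab.table.loc["l1", "tpm"] == pytest.approx(ab.table.loc["l2", "tpm"])

    def test_doubling_length_halves_tpm(self):
        rng = np.random.default_rng(3)
        chrom = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        loci = [Locus("c", 50, 150, "short", "non_palindromic"),
                Locus("c", 300, 500, "long", "non_palindromic")]
        idx = GenomeIndex({"c": chrom})
        species = {chrom[60:110]: 10, chrom[320:370]: 10}
        ab = quantify_loci(species, idx, loci)
        assert ab.table.loc["long", "tpm"] == pytest.approx(
            ab.table.loc["short", "tpm"] / 2)

    def test_zero_mapped_reads_is_error(self, genome, genome_index):
        with pytest.raises(ValueError, match="no RNA-seq reads mapped"):
            quantify_loci({"N" * 50: 5}, genome_index, genome.loci)

    def test_mrna_spike_fragments_routed_to_spike_tally(
            self, rnaseq_study, genome, genome_index):
        libs, _, mrna = rnaseq_study
        ab = quantify_loci(libs["WT"].species, genome_index, genome.loci, mrna)
        assert all(v > 0 for v in ab.spike_counts.values())

    def test_planted_precursor_folds_recovered(self, rnaseq_study, genome, genome_index):
        libs, _, mrna = rnaseq_study
        ab = {c: quantify_loci(l.species, genome_index, genome.loci, mrna, c)
              for c, l in libs.items()}
        ab = y.normalize_samples(ab, mrna, "WT")
        fc = precursor_fold_changes(ab["WT"], ab["xrn1_del"])
        eff = y.PlantedEffects.default(genome, seed=12)  # same seed as fixture
        planted = eff.precursor_abundance["xrn1_del"] / eff.precursor_abundance["WT"]
        cls = pd.Series({l.name: l.cls for l in genome.loci})
        for stratum in ("palindromic", "non_palindromic"):
            want = planted[cls == stratum].median()
            got = fc.class_medians[stratum]
            assert got == pytest.approx(want, rel=0.15)


class TestFoldChangeFilter:
    def test_low_tpm_locus_excluded_and_equal_abundance_zero(
            self, rnaseq_study, genome, genome_index):
        libs, _, mrna = rnaseq_study
        ab = quantify_loci(libs["WT"].species, genome_index, genome.loci, mrna)
        fc = precursor_fold_changes(ab, ab, min_wt_tpm=1.0)
        assert (fc.table["wt_tpm"] >= 1.0).all()
        assert np.allclose(fc.table["log2_fc"], 0.0)


class TestSpearman:
    def test_monotone_pairs_give_unit_correlation(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman(x, [30, 16, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        x, yv = rng.normal(size=20), rng.normal(size=20)
        rho, _ = spearman(x, yv)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(yv))[0, 1]
        assert rho == pytest.approx(oracle)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=20, unique=True))
    def test_invariant_under_strictly_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        ys = rng.permutation(len(xs)).astype(float)
        rho1, _ = spearman([float(x) for x in xs], ys)
        rho2, _ = spearman(np.exp(np.asarray(xs, dtype=float) / 50.0), ys)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestCorrelateStrata:
    def _fc(self, loci_cls, values):
        df = pd.DataFrame({"cls": loci_cls, "log2_fc": values})
        df.index = [f"l{i}" for i in range(len(values))]
        return df

    def test_perfectly_coupled_stratum(self):
        cls = ["non_palindromic"] * 6
        s = self._fc(cls, [0.1, 0.5, 1.0, 1.5, 2.0, 2.5])
        p = self._fc(cls, [0.2, 0.6, 1.1, 1.8, 2.2, 3.0])
        res = correlate_sirna_precursor(s, p, strata=("non_palindromic",))
        assert res[0].rho == pytest.approx(1.0)
        assert res[0].n_both_positive == 6

    def test_small_stratum_flagged_undefined(self):
        s = self._fc(["palindromic"] * 2, [0.1, 0.2])
        p = self._fc(["palindromic"] * 2, [0.3, 0.1])
        res = correlate_sirna_precursor(s, p, strata=("palindromic",))
        assert not res[0].defined


class TestSliceAsymmetry:
    def test_uniform_coverage_gives_unit_ratio(self):
        asym = slice_site_asymmetry(np.full(500, 7.0), 250, flank=100)
        assert asym.ratio == pytest.approx(1.0)

    def test_doubled_downstream_gives_ratio_two(self):
        cov = np.concatenate([np.full(250, 5.0), np.full(250, 10.0)])
        asym = slice_site_asymmetry(cov, 249, flank=100)
        assert asym.ratio == pytest.approx(2.0)

    def test_ratio_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(4)
        cov = rng.uniform(1, 5, 400)
        a = slice_site_asymmetry(cov, 200, flank=80).ratio
        b = slice_site_asymmetry(cov * 13.7, 200, flank=80).ratio
        assert a == pytest.approx(b)

    def test_zero_upstream_flagged(self):
        cov = np.concatenate([np.zeros(200), np.ones(200)])
        asym = slice_site_asymmetry(cov, 199, flank=100)
        assert not asym.defined and np.isnan(asym.ratio)

    def test_site_without_flank_is_error(self):
        with pytest.raises(ValueError, match="flank"):
            slice_site_asymmetry(np.ones(300), 10, flank=100)

    def test_planted_downstream_accumulation_gives_contrast_above_one(
            self, rnaseq_study, genome, genome_index):
        libs, truth, _ = rnaseq_study
        gene = genome.slice_genes[0]
        ratios = {}
        for cond in ("WT", "xrn1_del"):
            mapping = y.map_reads(libs[cond].species, genome_index)
            cov = coverage_vector(mapping.alignments, gene.chrom, gene.start, gene.end)
            ratios[cond] = slice_site_asymmetry(cov, gene.site - gene.start, 100)
        assert asymmetry_contrast(ratios["xrn1_del"], ratios["WT"]) > 1.5
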