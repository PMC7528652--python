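# yeastrnai

Quantitative analysis of the budding-yeast RNAi pathway from sequencing and
in vitro kinetics, built around the role of the 5′→3′ exoribonuclease Xrn1
in siRNA biogenesis and turnover.

In RNAi-competent budding yeasts such as *Naumovozyma castellii*, Dicer
processes two kinds of double-stranded precursor into 22–23-nt siRNA
duplexes with 2-nt 3′ overhangs: hairpin transcripts of genomic inverted
repeats (**palindromic loci**) and bimolecular duplexes from convergent
overlapping transcription (**non-palindromic loci**, including prolific
subtelomeric Y′ repeats). Argonaute loads a duplex, slices the passenger
strand — leaving diagnostic 10/11-nt 5′ and 12-nt 3′ cleavage fragments —
and the retained guide directs multiple-turnover target slicing. This
package implements the computational side of such a study end-to-end:

- **small-RNA quantification** (`yeastrnai.smallrna`) — 9–26-nt length
  window, exact mapping, fractional counting of multi-mapping reads over
  siRNA clusters, RPM, spike-in normalization by geometric-mean recovery of
  internal standards, log₂ fold changes with per-class medians, partition of
  reads by locus class, and length / 5′-nucleotide / third-to-last-nucleotide
  composition;
- **duplex calling** (`yeastrnai.duplex_calls`) — perfect guide–passenger
  duplexes from observed species, WT-count orientation, a slicing-impaired
  Argonaute-mutant support filter, end-anchored cleavage-fragment counting,
  and paired log₂ passenger:guide ratio shifts tested with an exact
  two-tailed Wilcoxon signed-rank test;
- **RNA-seq quantification** (`yeastrnai.rnaseq`) — precursor-transcript
  TPM with mRNA spike-ins, fold changes, Spearman correlation of siRNA vs
  precursor changes per class, and coverage asymmetry around slice sites;
- **burst kinetics** (`yeastrnai.kinetics`) — the burst-and-steady-state
  model for multiple-turnover slicing,

  F(t) = E·a²/(a+b)²·(1 − e^−(a+b)t) + E·ab/(a+b)·t,

  for the scheme E + S →(a) E·P →(b) E + P, fitted by bounded multi-start
  least squares (`BurstModel(...).fit()` → results with estimates, standard
  errors and `summary()`), plus the fraction-product and filter-binding
  fraction-bound signal ratios;
- **a synthetic-study generator** (`yeastrnai.simulate`) — genomes with
  planted palindromic / non-palindromic / Y′-like loci, phased duplex
  registries, condition-specific libraries (WT, Δxrn1, slicing-impaired
  ago1) with planted fold changes, passenger retention, cleavage fragments,
  spike-ins and ground-truth tables, so every stage is testable without
  external data.

## Worked example

```python
import numpy as np
import yeastrnai as y

# synthetic study: genome with planted loci, three conditions, spike-ins
genome  = y.make_genome(y.GenomeSpec(seed=1))
effects = y.PlantedEffects.default(genome, seed=2)
spikes  = list(y.DEFAULT_SMALLRNA_SPIKEINS)
libs, truth = y.simulate_libraries(genome, effects, spikes, 200_000, seed=3)

# quantify and normalize to the internal standards
index = y.GenomeIndex(genome.chromosomes)
maps = {c: y.quantify_sample(c, lib.species, index, genome.loci, spikes)[0]
        for c, lib in libs.items()}
factors = y.spikein_scale({c: m.spike_counts for c, m in maps.items()},
                          spikes, reference="WT")
tables = {c: y.abundance_table(c, maps[c], genome.loci, factors[c])
          for c in maps}
fc = y.fold_change_table(tables["WT"], tables["xrn1_del"])
print(fc.class_medians.round(2).to_dict())

# burst kinetics at 10 nM enzyme
tc  = y.simulate_timecourse(10.0, 0.5, 0.05, np.linspace(0, 60, 12), 0.02, seed=2)
print(y.fit_burst(tc).summary())
```

prints

```
{'non_palindromic': 3.35, 'palindromic': 0.23, 'y_prime': 4.46}
Burst-and-steady-state fit
==========================
observations: 12    E (fixed): 10 nM
residual sum of squares: 0.00493998

param     estimate     std err
k1         0.49801     0.00314
k2        0.050052    6.85e-05
```

The class medians are the spike-in-normalized median fold changes
(Δxrn1/WT) of 22–23-nt siRNAs per locus class: palindromic loci drop
several-fold while non-palindromic and Y′-like loci rise, the planted
signature of losing Xrn1. The kinetics fit recovers the burst rate k1
(per min, the fast first turnover) and steady-state rate k2 (per min,
limited by product release) from a noisy simulated time course.

A command-line interface mirrors the library:

```bash
yeastrnai simulate --seed 1 --out demo/
yeastrnai smallrna-quant --reads WT=demo/WT.smallrna.tsv \
    --reads xrn1_del=demo/xrn1_del.smallrna.tsv \
    --genome demo/genome.fa --loci demo/loci.bed \
    --spikeins demo/spikeins.tsv --reference WT --out demo/quant
yeastrnai run-all --seed 1 --out demo/full
```

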