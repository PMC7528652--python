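# Methods

## Duplex geometry

An siRNA duplex is two strands of equal length L ∈ {22, 23} that are
Watson–Crick paired, antiparallel, over their first L−2 nucleotides, leaving
a 2-nt 3′ overhang on each strand — the RNase III signature. The predicate
`is_sirna_duplex(a, b)` tests exactly `a[:L−2] == revcomp(b[:L−2])`; G:U
wobble is not accepted (the stricter, reproducible choice), and a blunt pair
(a strand with its exact reverse complement) fails the register for any
non-degenerate sequence. Sequences are held internally in DNA alphabet; RNA
input is normalized on ingestion.

`dice_duplexes` phases a perfectly paired precursor region into successive
duplexes end-to-end from the sense strand's 5′ end. Its input is the two
strands *in the register fixed by the first cleavage*: the antisense strand
is supplied offset by 2 nt (`duplex_region_pair` builds it as the reverse
complement of `[start−2, end−2)` on the top strand). With that convention
every product of a region of length N carries full overhangs and the region
yields exactly ⌊N/L⌋ duplexes — e.g. a 66-nt region gives 3 phased 22-mers.
Where Dicer actually sets its phasing register on a hairpin is not modeled;
the register is a configuration choice of the generator, not a measurement.

## Synthetic genome and planted effects

`make_genome` places three locus classes on random chromosomes
(default 2 × 60 kb), non-overlapping, with ≥20-nt gaps and 100-nt margins;
overflow raises a capacity error.

- **Palindromic loci** (default 12): exact inverted repeats of
  `arm_length = 66` nt around an 8-nt loop (the loop length is arbitrary —
  only arm pairing matters). Guides come from the 5′ arm, passengers from
  the 3′ arm, so each duplex's strands map to opposite arms and every
  22/23-mer from the stem occurs at two genomic sites (the inverted copy on
  the other strand), exercising fractional counting.
- **Non-palindromic loci** (default 20, 220 nt): convergent-transcription
  regions whose two genomic strands provide the bimolecular duplex.
- **Y′-like loci** (default 2): all copies share one consensus sequence, so
  their reads multi-map across copies — the repeat-family case.

Each planted duplex gets a log-normal relative expression weight (σ = 0.5)
fixed across conditions. Guide 5′ nucleotides are U with probability 0.8
(else uniform over A/C/G), mirroring the observed 5′-U bias of guide
strands; by complementarity this automatically enriches A at the
third-to-last position of passengers.

`PlantedEffects.default` encodes the study conditions for WT, the Xrn1
knockout (`xrn1_del`) and the slicing-impaired Argonaute mutant
(`ago1_mut`):

| quantity | WT | xrn1_del | ago1_mut |
|---|---|---|---|
| siRNA class-median fold vs WT (pal / non-pal / Y′) | 1 | 1/3.5 / 4.1 / 5.0 | 1 |
| precursor class-median fold vs WT | 1 | 2.2 / 3.8 / 14 | 1 |
| passenger retention (fraction of guide) | 0.15 | 0.345 (×2.3) | 0.7 |
| 5′/3′ fragment rate (fraction of guide) | 0.06 | 0.078 (×1.3) | 0 |

Per-locus folds scatter log-normally (σ = 0.35) about the class median.
WT mean abundances (17 / 1 / 2 per class, log-normal σ = 0.4) put ~74% of
WT siRNA reads on palindromic loci, the prolific class. For non-palindromic
loci the siRNA log-fold is coupled to the precursor log-fold through a
regression coefficient β = 0.6 with residual σ = 0.5, giving a moderate
positive rank correlation (≈0.4 in expectation); palindromic folds are
drawn independently because their siRNA and precursor changes point in
opposite directions. `couple_nonpalindromic=False` switches the coupling
off to test the null behavior.

## Library simulation

Small-RNA reads are drawn multinomially at the requested depth over: guide
strands, full-length passengers (at the condition's retention), 10/11-nt 5′
and 12-nt 3′ passenger fragments (the 5′ fragment is 10 nt for a 22-nt
duplex and 11 nt for a 23-nt duplex), spike-in standards, and ~10% background
reads from random non-locus genomic windows (15–26 nt) that exercise the RPM
denominator. Sequencing errors are off by default (the mapper is exact);
an optional substitution rate moves a binomial share of each species to
single-substitution variants. FASTQ output uses constant 'I' qualities. A
missing seed is refused.

Four small-RNA standards (the published spike-in oligos, 0.5 units each) and
two synthetic 600-nt mRNA standards (stand-ins for the bacterial CAT and
firefly luciferase spike transcripts; labelled synthetic) are added at
weights `input_amount × capture_efficiency × scale`, where the per-library
capture efficiency is log-normal (σ = 0.2 by default) and the scale puts
spikes at ~2% of the reference library. **The capture efficiency is a
planted, unremovable distortion**: standards recovered more efficiently in
one library deflate its normalized abundances, and no spike-based
normalization can separate that from a true global change. Ground-truth
comparisons therefore use `TruthTable.expected_measured_fold`, which carries
the eff(ref)/eff(cond) factor; the truth table records each library's
efficiency.

RNA-seq reads (50 nt) are sampled uniformly along each locus's sense
transcript at the condition's precursor abundance, along the mRNA standards,
and along slice-target genes whose windows downstream of the slice site are
boosted 3× in `xrn1_del` (the 3′ slicing product escapes 5′→3′ decay),
planting the downstream coverage accumulation.

## Quantification choices

- Exact-match mapping, 0 mismatches, both strands, every occurrence
  reported; the index is a per-length hash of genome k-mers. Spike-ins are
  matched against the manifest before genome search and never enter genomic
  counts. This is appropriate for error-free synthetic reads; the package
  does not attempt error-tolerant alignment.
- Fractional counting: a species with n genomic hits, k of them in a locus,
  contributes count·k/n (flag to divide by in-locus hits only). A hit
  belongs to a locus when ≥50% of its bases fall inside. Mass is conserved
  to 1e−9.
- RPM denominator: all genome-mapped 9–26-nt reads excluding spike-ins.
- Spike-in factors: geometric mean over recovered standards of
  input/recovered, rescaled so the reference sample (WT) is 1. A sample
  recovering no standard is a hard error.
- Fold-change pseudocount: **half a read added to fractional counts before
  scaling**, not to normalized units — a count-scale pseudocount is
  invariant to the arbitrary normalization scale, whereas 0.5 normalized
  units would distort small values by an amount depending on the spike
  amounts. Class medians are computed on the log₂ scale and reported as
  linear folds.
- TPM uses locus length in kb and sums to 10⁶ over loci; counting is
  strand-aware (directional library) with antisense fragments tallied
  separately and excluded by default.
- Duplex candidates are discovered from sequence complementarity of all
  observed 22/23-nt species (hairpin and bimolecular loci treated
  identically); genomic anchoring is optional and attached afterwards.
  Orientation requires a strict WT-count majority; ties are excluded.
  Support requires a strictly increased passenger:guide ratio in the
  slicing-impaired strain. Ratios use the same half-read pseudocount.
- The Wilcoxon signed-rank test drops zero differences, uses average ranks,
  and computes the exact two-tailed p by convolution over the observed rank
  multiset for n ≤ 25 (ties handled by doubling ranks to integers); above
  that, the normal approximation with continuity correction 0.5 and the
  standard tie correction. Implemented in-package and cross-checked against
  exhaustive enumeration and scipy in the tests.
- Slice-site asymmetry compares mean coverage in `(site, site+flank]` to
  `(site−flank, site]` (flank default 100 nt); zero upstream coverage flags
  the ratio undefined rather than raising.

## Burst kinetics

`burst_model(t, E, a, b)` evaluates the closed form exactly, with the
a = b = 0 limit handled explicitly (F ≡ 0). Fitting is unweighted bounded
least squares (non-negativity on both rates) from a start grid
a ∈ {0.01, 0.1, 1, 10} × b ∈ {0.001, 0.01, 0.1} per minute, keeping the
lowest residual; standard errors come from the Jacobian covariance at the
optimum. E is fixed (10 nM in the canonical assay) with `float_E=True` to
estimate it. F and E must share units — F is in the same units as E times
the fraction cleaved. On noiseless model output the fit is an exact fixed
point; with 2% Gaussian noise on a 12-point, 60-min course the rates are
recovered with a median relative error well under 10%.

`fraction_product` is product/(product+substrate[+intermediate]);
`fraction_bound` is nitrocellulose/(nitrocellulose+nylon). Both are
scale-invariant and return NaN (flagged) on an all-zero denominator.

## Problem sizes and what the tests show

The default test suite runs at 2×10⁵ reads per library; the acceptance
checks use 10⁶ small-RNA reads, 3×10⁵ RNA-seq reads, and a 60-locus
non-palindromic complement where rank-correlation resolving power matters
(the per-class medians are insensitive to locus count; the correlation is
not). The generator emulates read-species composition, multi-mapping
structure, spike-in recovery and condition contrasts; it does **not** model
ligation bias, sequencing errors (by default), rRNA/tRNA contamination,
transcript-end heterogeneity, or Dicer's true phasing register. Passing
tests therefore demonstrate the correctness of the quantification and
inference machinery under the planted model, not the biological fidelity of
any particular parameter value. Y′-like repeat copies share sequences, so
per-copy abundances are unidentifiable by design; recovery there is
assessed on the pooled family.
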