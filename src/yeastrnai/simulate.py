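"""Synthetic study generator.

Emulates the small-RNA and RNA-seq libraries of a budding-yeast RNAi study
in which Dicer processes two kinds of double-stranded precursor:

* **palindromic loci** -- genomic inverted repeats whose transcript folds
  into a hairpin (stem-loop), diced into phased 22-23-nt duplexes;
* **non-palindromic loci** (including a subtelomeric Y'-like repeat family)
  -- convergent overlapping transcription yields bimolecular duplexes.

Three conditions are modeled: wild type (``WT``), an Xrn1 exonuclease
knockout (``xrn1_del``) and a slicing-impaired Argonaute point mutant
(``ago1_mut``).  The generator plants class-specific abundance fold changes,
condition-dependent passenger-strand retention, passenger cleavage-fragment
emission (off in the slicing-impaired mutant), spike-in standards at known
input amounts, and a slice-target gene with downstream coverage
accumulation -- and writes a ground-truth table for every planted quantity.

All randomness flows through a single :class:`numpy.random.Generator` seeded
explicitly; a missing seed is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import is_sirna_duplex, revcomp
from .io import Locus, SpikeInStandard
from .kinetics import burst_model

CONDITIONS = ("WT", "xrn1_del", "ago1_mut")
_BASES = np.array(list("ACGT"))

# Small-RNA internal standards added at known amounts before library prep
# (four oligos at 0.5 nM each, mirroring the assayed protocol).
DEFAULT_SMALLRNA_SPIKEINS = (
    SpikeInStandard("xtr_miR_427", "GAAAGUGCUUUCUGUUUUGGGCG", 0.5, "small_rna"),
    SpikeInStandard("dme_miR_14", "GGGAGCGAGACGGGGACTCACT", 0.5, "small_rna"),
    SpikeInStandard("synthetic_siRNA_1_guide", "UAGUGCAGGUAGGUAUUUUUGUU", 0.5, "small_rna"),
    SpikeInStandard("synthetic_siRNA_1_passenger", "CAAAAAUACCUACCUGCACUAUA", 0.5, "small_rna"),
)


class CapacityError(ValueError):
    """Genome too small to place the requested loci without overlap."""


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("an explicit seed is required (reproducibility contract)")
    return int(seed)


@dataclass
class GenomeSpec:
    """Layout of the synthetic genome.

    ``arm_length`` is the hairpin stem length of palindromic loci (>= 22 so
    at least one duplex fits per arm); ``nonpalindromic_length`` is the
    convergently transcribed overlap of the other locus classes.
    """

    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_palindromic_loci: int = 12
    n_nonpalindromic_loci: int = 20
    n_yprime_loci: int = 2
    arm_length: int = 66
    loop_length: int = 8
    nonpalindromic_length: int = 220
    n_slice_genes: int = 3
    slice_gene_length: int = 1_200
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_chromosomes, self.n_palindromic_loci,
            self.n_nonpalindromic_loci, self.n_yprime_loci, self.n_slice_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.arm_length < 22:
            raise ValueError("arm_length must be >= 22")


@dataclass
class SliceGene:
    """An RNAi-targeted gene with a known slice site (genome coordinate)."""

    name: str
    chrom: str
    start: int
    end: int
    site: int


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    loci: list[Locus]
    duplexes: pd.DataFrame   # duplex_id, locus, cls, length, guide, passenger, weight
    slice_genes: list[SliceGene]
    spec: GenomeSpec
    guide_u5_prob: float


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, n)])


def _bias_first_nt(rng: np.random.Generator, seq: list[str], pos: int, u5_prob: float) -> None:
    # Guide 5' nucleotide: U with probability u5_prob, else uniform over A/C/G.
    seq[pos] = "T" if rng.random() < u5_prob else str(rng.choice(list("ACG")))


def make_genome(spec: GenomeSpec, guide_u5_prob: float = 0.8) -> SyntheticGenome:
    """Build a random genome with planted siRNA loci and slice-target genes.

    Palindromic loci are exact inverted repeats of ``arm_length`` separated
    by a short loop; the hairpin's phased duplexes place the guide on the 5'
    arm and the passenger on the 3' arm (so both strands map to opposite
    arms of the palindrome).  Non-palindromic and Y'-like loci carry phased
    bimolecular duplexes from the two genomic strands; all Y' copies share
    one consensus sequence, exercising fractional multi-mapper counting.
    Each duplex's relative expression weight (log-normal) is fixed here and
    shared by every condition.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    margin, min_gap, max_gap = 100, 20, 80

    chroms = {f"chr{i + 1}": _random_seq(rng, spec.chrom_length)
              for i in range(spec.n_chromosomes)}
    chrom_names = list(chroms)
    cursors = {c: margin for c in chrom_names}

    plan = (
        [("palindromic", 2 * spec.arm_length + spec.loop_length)] * spec.n_palindromic_loci
        + [("non_palindromic", spec.nonpalindromic_length)] * spec.n_nonpalindromic_loci
        + [("y_prime", spec.nonpalindromic_length)] * spec.n_yprime_loci
        + [("slice_gene", spec.slice_gene_length)] * spec.n_slice_genes
    )
    if not chrom_names and plan:
        raise CapacityError("no chromosomes to place loci on")

    loci: list[Locus] = []
    slice_genes: list[SliceGene] = []
    duplex_rows: list[dict] = []
    counters = {"palindromic": 0, "non_palindromic": 0, "y_prime": 0, "slice_gene": 0}
    yprime_consensus: list[str] | None = None
    yprime_L: int | None = None

    for i, (cls, footprint) in enumerate(plan):
        chrom = chrom_names[i % len(chrom_names)]
        start = cursors[chrom] + int(rng.integers(min_gap, max_gap + 1))
        end = start + footprint
        if end > spec.chrom_length - margin:
            placed = False
            for alt in chrom_names:
                start = cursors[alt] + int(rng.integers(min_gap, max_gap + 1))
                end = start + footprint
                if end <= spec.chrom_length - margin:
                    chrom, placed = alt, True
                    break
            if not placed:
                raise CapacityError(
                    f"cannot place locus {i} ({cls}, {footprint} nt): genome too small"
                )
        cursors[chrom] = end
        counters[cls] += 1
        name = f"{cls}_{counters[cls]}"

        if cls == "slice_gene":
            slice_genes.append(SliceGene(name, chrom, start, end, start + footprint // 2))
            continue

        L = int(rng.choice([22, 23]))
        if cls == "palindromic":
            arm = _random_seq(rng, spec.arm_length)
            n_dup = spec.arm_length // L
            for k in range(n_dup):
                _bias_first_nt(rng, arm, k * L, guide_u5_prob)
            loop = _random_seq(rng, spec.loop_length)
            seq = arm + loop + list(revcomp("".join(arm)))
            chroms[chrom][start:end] = seq
            A, LP = spec.arm_length, spec.loop_length
            for k in range(n_dup):
                g0 = start + k * L
                guide = "".join(chroms[chrom][g0:g0 + L])
                a = A - L - k * L + 2   # offset within the 3' arm (k=0 borrows 2 nt of flank)
                p0 = start + A + LP + a
                passenger = "".join(chroms[chrom][p0:p0 + L])
                duplex_rows.append(dict(
                    duplex_id=f"{name}_d{k}", locus=name, cls=cls, length=L,
                    guide=guide, passenger=passenger,
                    chrom=chrom, guide_start=g0, guide_strand="+",
                    weight=float(rng.lognormal(0.0, 0.5)),
                ))
        else:
            if cls == "y_prime" and yprime_consensus is not None:
                seq, L = list(yprime_consensus), yprime_L
            else:
                seq = _random_seq(rng, footprint)
                n_dup = (footprint - 2) // L
                for k in range(n_dup):
                    _bias_first_nt(rng, seq, 2 + k * L, guide_u5_prob)
                if cls == "y_prime":
                    yprime_consensus, yprime_L = list(seq), L
            chroms[chrom][start:end] = seq
            n_dup = (footprint - 2) // L
            for k in range(n_dup):
                g0 = start + 2 + k * L
                guide = "".join(chroms[chrom][g0:g0 + L])
                passenger = revcomp("".join(chroms[chrom][g0 - 2:g0 - 2 + L]))
                duplex_rows.append(dict(
                    duplex_id=f"{name}_d{k}", locus=name, cls=cls, length=L,
                    guide=guide, passenger=passenger,
                    chrom=chrom, guide_start=g0, guide_strand="+",
                    weight=float(rng.lognormal(0.0, 0.5)),
                ))
        loci.append(Locus(chrom, start, end, name, cls, "+"))

    duplexes = pd.DataFrame(duplex_rows, columns=[
        "duplex_id", "locus", "cls", "length", "guide", "passenger",
        "chrom", "guide_start", "guide_strand", "weight",
    ])
    if len(duplexes):
        bad = [
            row.duplex_id for row in duplexes.itertuples()
            if not is_sirna_duplex(row.guide, row.passenger)
        ]
        assert not bad, f"internal error: invalid planted duplex geometry {bad}"
    return SyntheticGenome(
        {c: "".join(s) for c, s in chroms.items()},
        loci, duplexes, slice_genes, spec, guide_u5_prob,
    )


# ---------------------------------------------------------------------------
# Planted effects

@dataclass
class PlantedEffects:
    """Ground-truth per-locus expression and per-condition strand rates.

    ``sirna_abundance`` and ``precursor_abundance`` are locus x condition
    tables in arbitrary per-cell units.  ``passenger_retention`` is the
    steady-state full-length passenger level as a fraction of the guide;
    ``frag5_rate``/``frag3_rate`` are 5'/3' passenger cleavage-fragment
    levels as fractions of the guide.  ``guide_u5_prob`` is the probability
    a guide begins with U.
    """

    sirna_abundance: pd.DataFrame
    precursor_abundance: pd.DataFrame
    passenger_retention: dict[str, float]
    frag5_rate: dict[str, float]
    frag3_rate: dict[str, float]
    guide_u5_prob: float = 0.8

    def __post_init__(self) -> None:
        for tbl in (self.sirna_abundance, self.precursor_abundance):
            if (tbl.to_numpy() < 0).any():
                raise ValueError("abundances must be non-negative")
        for rates in (self.passenger_retention, self.frag5_rate, self.frag3_rate):
            if any(not 0 <= v <= 1 for v in rates.values()):
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.guide_u5_prob <= 1:
            raise ValueError("guide_u5_prob must lie in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return list(self.sirna_abundance.columns)

    @classmethod
    def default(
        cls,
        genome: SyntheticGenome,
        seed: int,
        *,
        sirna_fold: Mapping[str, float] | None = None,
        precursor_fold: Mapping[str, float] | None = None,
        wt_sirna_mean: Mapping[str, float] | None = None,
        wt_precursor_mean: Mapping[str, float] | None = None,
        locus_sigma: float = 0.4,
        fold_sigma: float = 0.35,
        coupling_beta: float = 0.6,
        coupling_sigma: float = 0.5,
        couple_nonpalindromic: bool = True,
        passenger_retention: Mapping[str, float] | None = None,
        frag5_rate: Mapping[str, float] | None = None,
        frag3_rate: Mapping[str, float] | None = None,
        guide_u5_prob: float = 0.8,
    ) -> "PlantedEffects":
        """Study-condition defaults.

        The Xrn1-knockout class-median fold changes follow the study's
        sequencing results: small RNAs from palindromic loci drop 3.5-fold
        while non-palindromic loci rise 4.1-fold (Y'-like, 5-fold);
        precursor transcripts rise 2.2-fold (palindromic), 3.8-fold
        (non-palindromic) and 14-fold (Y'-like).  Per-locus folds scatter
        log-normally about the class median.  For non-palindromic loci the
        siRNA fold is coupled to the precursor fold through a regression
        coefficient ``coupling_beta`` with residual ``coupling_sigma``,
        producing a positive rank correlation; palindromic folds are
        independent (their siRNA and precursor changes point in opposite
        directions, so no coupling is planted).

        WT mean abundances put ~74% of WT siRNA reads on palindromic loci,
        the prolific class.  Passenger retention rises 2.3-fold and fragment
        levels 1.3-fold in the knockout; the slicing-impaired Argonaute
        mutant emits no fragments and retains passengers at a high level.
        """
        rng = np.random.default_rng(_require_seed(seed))
        sirna_fold = dict(sirna_fold or {
            "palindromic": 1 / 3.5, "non_palindromic": 4.1, "y_prime": 5.0})
        precursor_fold = dict(precursor_fold or {
            "palindromic": 2.2, "non_palindromic": 3.8, "y_prime": 14.0})
        wt_sirna_mean = dict(wt_sirna_mean or {
            "palindromic": 17.0, "non_palindromic": 1.0, "y_prime": 2.0})
        wt_precursor_mean = dict(wt_precursor_mean or {
            "palindromic": 2.0, "non_palindromic": 2.0, "y_prime": 5.0})

        rows_s, rows_p = {}, {}
        for loc in genome.loci:
            wt_s = wt_sirna_mean[loc.cls] * rng.lognormal(0.0, locus_sigma)
            wt_p = wt_precursor_mean[loc.cls] * rng.lognormal(0.0, locus_sigma)
            log_fp = np.log(precursor_fold[loc.cls]) + rng.normal(0.0, fold_sigma)
            if couple_nonpalindromic and loc.cls != "palindromic":
                log_fs = (
                    np.log(sirna_fold[loc.cls])
                    + coupling_beta * (log_fp - np.log(precursor_fold[loc.cls]))
                    + rng.normal(0.0, coupling_sigma)
                )
            else:
                log_fs = np.log(sirna_fold[loc.cls]) + rng.normal(0.0, fold_sigma)
            rows_s[loc.name] = dict(
                WT=wt_s, xrn1_del=wt_s * float(np.exp(log_fs)), ago1_mut=wt_s)
            rows_p[loc.name] = dict(
                WT=wt_p, xrn1_del=wt_p * float(np.exp(log_fp)), ago1_mut=wt_p)

        index = [loc.name for loc in genome.loci]
        return cls(
            sirna_abundance=pd.DataFrame.from_dict(rows_s, orient="index").reindex(index)
            if index else pd.DataFrame(columns=list(CONDITIONS)),
            precursor_abundance=pd.DataFrame.from_dict(rows_p, orient="index").reindex(index)
            if index else pd.DataFrame(columns=list(CONDITIONS)),
            passenger_retention=dict(passenger_retention or {
                "WT": 0.15, "xrn1_del": 0.15 * 2.3, "ago1_mut": 0.7}),
            frag5_rate=dict(frag5_rate or {
                "WT": 0.06, "xrn1_del": 0.06 * 1.3, "ago1_mut": 0.0}),
            frag3_rate=dict(frag3_rate or {
                "WT": 0.06, "xrn1_del": 0.06 * 1.3, "ago1_mut": 0.0}),
            guide_u5_prob=guide_u5_prob,
        )


# ---------------------------------------------------------------------------
# Library simulation

@dataclass
class Library:
    """A collapsed sequencing library: unique species -> read multiplicity."""

    condition: str
    depth: int
    species: dict[str, int]
    capture_efficiency: float = 1.0

    @property
    def total_reads(self) -> int:
        return sum(self.species.values())


@dataclass
class TruthTable:
    """Ground truth for one simulated small-RNA study.

    ``species`` maps every emitted species to its provenance (role, duplex,
    loci) with per-condition expected weights and realized counts;
    ``sirna_output`` is the true per-locus 22-23-nt output (guide plus
    retained passenger) per condition; ``libraries`` records depth, spike-in
    scale and capture efficiency per library.
    """

    species: pd.DataFrame
    sirna_output: pd.DataFrame
    libraries: pd.DataFrame
    duplexes: pd.DataFrame

    def expected_measured_fold(self, cond: str, ref: str = "WT") -> pd.Series:
        """Per-locus fold change a spike-in-normalized pipeline should report.

        The planted output fold times the capture-efficiency distortion
        eff(ref)/eff(cond): standards recovered more efficiently in one
        library deflate its normalized abundances, and no normalization can
        separate that from a global abundance change, so the ground-truth
        expectation carries it.
        """
        eff = dict(zip(self.libraries["condition"], self.libraries["capture_efficiency"]))
        return (self.sirna_output[cond] / self.sirna_output[ref]) * (eff[ref] / eff[cond])


def frag5_length(duplex_length: int) -> int:
    """5'-cleavage-fragment length: 10 nt for 22-nt duplexes, 11 for 23."""
    return 10 if duplex_length == 22 else 11


def _overlaps_any(intervals: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def simulate_libraries(
    genome: SyntheticGenome,
    effects: PlantedEffects,
    spikeins: Sequence[SpikeInStandard],
    depth: int | Mapping[str, int],
    seed: int,
    *,
    conditions: Sequence[str] | None = None,
    background_fraction: float = 0.1,
    n_background_species: int = 300,
    background_length_range: tuple[int, int] = (15, 26),
    capture_sigma: float = 0.2,
    spike_scale: float | None = None,
    substitution_rate: float = 0.0,
) -> tuple[dict[str, Library], TruthTable]:
    """Draw per-condition small-RNA libraries and the matching truth table.

    Reads are drawn multinomially over guide strands, full-length passenger
    strands (at condition-dependent retention), 10/11-nt 5' and 12-nt 3'
    passenger cleavage fragments, spike-in standards (per-library capture
    efficiency, log-normal) and a background of non-locus genomic windows.
    The slicing-impaired condition emits no fragments by its planted rates.
    """
    rng = np.random.default_rng(_require_seed(seed))
    conditions = list(conditions or effects.conditions)
    unknown = set(conditions) - set(effects.conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    depths = (dict(depth) if isinstance(depth, Mapping)
              else {c: int(depth) for c in conditions})
    unknown = set(depths) - set(effects.conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s) in depth: {sorted(unknown)}")
    for c, d in depths.items():
        if d <= 0:
            raise ValueError(f"depth for {c} must be positive")

    ret, f5, f3 = effects.passenger_retention, effects.frag5_rate, effects.frag3_rate

    # --- species registry: sequence -> record with per-condition weights
    registry: dict[str, dict] = {}

    def add(seq: str, role: str, duplex_id: str, locus: str, cls: str,
            weights: dict[str, float]) -> None:
        rec = registry.get(seq)
        if rec is None:
            rec = registry[seq] = dict(
                sequence=seq, role=role, duplex_id=duplex_id,
                locus_ids={locus} if locus else set(), cls=cls,
                length=len(seq),
                **{f"expected_{c}": 0.0 for c in conditions},
            )
        else:
            if locus:
                rec["locus_ids"].add(locus)
            if rec["role"] != role:
                rec["role"] = "multi"
        for c, w in weights.items():
            rec[f"expected_{c}"] += w

    for row in genome.duplexes.itertuples():
        base = {c: float(effects.sirna_abundance.at[row.locus, c]) * row.weight
                for c in conditions}
        add(row.guide, "guide", row.duplex_id, row.locus, row.cls, base)
        add(row.passenger, "passenger", row.duplex_id, row.locus, row.cls,
            {c: base[c] * ret[c] for c in conditions})
        k5 = frag5_length(row.length)
        add(row.passenger[:k5], "passenger_5p_frag", row.duplex_id, row.locus, row.cls,
            {c: base[c] * f5[c] for c in conditions})
        add(row.passenger[-12:], "passenger_3p_frag", row.duplex_id, row.locus, row.cls,
            {c: base[c] * f3[c] for c in conditions})

    locus_weight = {c: sum(r[f"expected_{c}"] for r in registry.values())
                    for c in conditions}

    # background: random non-locus genomic windows, weights fixed across
    # conditions up to a per-condition rescale keeping the planted fraction
    locus_iv: dict[str, list[tuple[int, int]]] = {}
    for loc in genome.loci:
        locus_iv.setdefault(loc.chrom, []).append((loc.start, loc.end))
    bg: list[tuple[str, float]] = []
    chrom_names = list(genome.chromosomes)
    lo, hi = background_length_range
    attempts = 0
    while len(bg) < n_background_species and attempts < 50 * n_background_species and chrom_names:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        L = int(rng.integers(lo, hi + 1))
        limit = len(genome.chromosomes[chrom]) - L
        if limit <= 0:
            continue
        s = int(rng.integers(0, limit))
        if _overlaps_any(locus_iv.get(chrom, ()), s, s + L):
            continue
        bg.append((genome.chromosomes[chrom][s:s + L], float(rng.lognormal(0.0, 1.0))))
    bg_norm = sum(w for _, w in bg)
    if bg and background_fraction > 0:
        for c in conditions:
            scale = (background_fraction / (1 - background_fraction)
                     * locus_weight[c] / bg_norm)
            for seq, w in bg:
                add(seq, "background", "", "", "", {c: w * scale})

    # spike-ins: per-library capture efficiency, log-normal
    eff = {c: float(rng.lognormal(0.0, capture_sigma)) for c in conditions}
    total_amt = sum(s.input_amount for s in spikeins)
    if spike_scale is None:
        ref_w = locus_weight[conditions[0]] / (1 - background_fraction or 1.0)
        spike_scale = 0.02 * ref_w / (0.98 * total_amt) if total_amt else 0.0
    for s in spikeins:
        add(s.sequence, "spikein", "", "", "",
            {c: s.input_amount * eff[c] * spike_scale for c in conditions})

    records = list(registry.values())
    seqs = [r["sequence"] for r in records]
    libraries: dict[str, Library] = {}
    for c in conditions:
        w = np.array([r[f"expected_{c}"] for r in records], dtype=float)
        counts = rng.multinomial(depths[c], w / w.sum())
        if substitution_rate > 0:
            counts = _apply_substitutions(rng, seqs, counts, substitution_rate, records, c)
        species = {}
        for r, n in zip(records, counts):
            r[f"count_{c}"] = int(n)
            if n:
                species[r["sequence"]] = int(n)
        libraries[c] = Library(c, depths[c], species, eff[c])

    species_df = pd.DataFrame([
        {**r, "locus_ids": ",".join(sorted(r["locus_ids"]))} for r in records
    ])
    sirna_output = pd.DataFrame({
        c: {
            loc.name: float(sum(
                effects.sirna_abundance.at[loc.name, c] * row.weight * (1 + ret[c])
                for row in genome.duplexes.itertuples() if row.locus == loc.name
            ))
            for loc in genome.loci
        }
        for c in conditions
    })
    lib_df = pd.DataFrame([
        dict(condition=c, depth=depths[c], capture_efficiency=eff[c],
             spike_scale=spike_scale)
        for c in conditions
    ])
    return libraries, TruthTable(species_df, sirna_output, lib_df, genome.duplexes)


def _apply_substitutions(rng, seqs, counts, rate, records, cond):
    """Move a binomial share of each species' reads to single-substitution
    variants (one random position, random alternative base)."""
    counts = counts.copy()
    extra: dict[str, int] = {}
    for i, seq in enumerate(seqs):
        if counts[i] == 0:
            continue
        p_hit = 1.0 - (1.0 - rate) ** len(seq)
        n_mut = rng.binomial(counts[i], p_hit)
        counts[i] -= n_mut
        for _ in range(int(n_mut)):
            pos = int(rng.integers(len(seq)))
            alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            mutant = seq[:pos] + alt + seq[pos + 1:]
            extra[mutant] = extra.get(mutant, 0) + 1
    for seq, n in extra.items():
        records.append({
            "sequence": seq, "role": "error", "duplex_id": "", "locus_ids": set(),
            "cls": "", "length": len(seq),
            **{f"expected_{c}": 0.0 for c in [cond]}, f"count_{cond}": n,
        })
        seqs.append(seq)
        counts = np.append(counts, n)
    return counts


# ---------------------------------------------------------------------------
# RNA-seq simulation

@dataclass
class RnaseqTruth:
    locus_counts: pd.DataFrame        # locus x condition realized fragment counts
    libraries: pd.DataFrame
    slice_genes: pd.DataFrame


def simulate_rnaseq(
    genome: SyntheticGenome,
    effects: PlantedEffects,
    mrna_spikeins: Sequence[SpikeInStandard],
    depth: int | Mapping[str, int],
    seed: int,
    *,
    conditions: Sequence[str] | None = None,
    read_length: int = 50,
    capture_sigma: float = 0.0,
    spike_scale: float | None = None,
    slice_gene_expression: float = 3.0,
    slice_downstream_boost: Mapping[str, float] | None = None,
) -> tuple[dict[str, Library], RnaseqTruth]:
    """Draw per-condition RNA-seq libraries over precursor transcripts.

    Reads are sampled uniformly along each locus's sense transcript with
    per-condition precursor abundance, along mRNA spike-in standards at
    known input amounts, and along slice-target genes whose region
    downstream of the slice site is boosted in the Xrn1 knockout (the 3'
    slicing product escapes 5'->3' decay there).
    """
    rng = np.random.default_rng(_require_seed(seed))
    conditions = list(conditions or effects.conditions)
    unknown = set(conditions) - set(effects.conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    depths = (dict(depth) if isinstance(depth, Mapping)
              else {c: int(depth) for c in conditions})
    boost = dict(slice_downstream_boost or {"WT": 1.0, "xrn1_del": 3.0, "ago1_mut": 1.0})

    # categories: (sequence, source, per-condition weight)
    cat_seqs: list[str] = []
    cat_src: list[str] = []
    cat_w: dict[str, list[float]] = {c: [] for c in conditions}

    def add_windows(seq: str, source: str, weights: dict[str, float],
                    window_weights: np.ndarray | None = None) -> None:
        n_win = len(seq) - read_length + 1
        if n_win <= 0:
            return
        ww = np.ones(n_win) if window_weights is None else window_weights
        ww = ww / ww.sum()
        for i in range(n_win):
            cat_seqs.append(seq[i:i + read_length])
            cat_src.append(source)
            for c in conditions:
                cat_w[c].append(weights[c] * ww[i])

    for loc in genome.loci:
        seq = genome.chromosomes[loc.chrom][loc.start:loc.end]
        add_windows(seq, f"locus::{loc.name}",
                    {c: float(effects.precursor_abundance.at[loc.name, c])
                     for c in conditions})

    # slice-target genes need per-condition window weighting (downstream boost)
    cat_seqs_genes: list[str] = []
    cat_src_genes: list[str] = []
    cat_w_genes: dict[str, list[float]] = {c: [] for c in conditions}
    for gene in genome.slice_genes:
        seq = genome.chromosomes[gene.chrom][gene.start:gene.end]
        n_win = len(seq) - read_length + 1
        if n_win <= 0:
            continue
        site_off = max(0, min(n_win, gene.site - gene.start))
        for i in range(n_win):
            cat_seqs_genes.append(seq[i:i + read_length])
            cat_src_genes.append(f"gene::{gene.name}")
            for c in conditions:
                w = slice_gene_expression / n_win
                if i >= site_off:
                    w *= boost.get(c, 1.0)
                cat_w_genes[c].append(w)

    eff = {c: float(rng.lognormal(0.0, capture_sigma)) for c in conditions}
    total_amt = sum(s.input_amount for s in mrna_spikeins)
    cell_w = {c: sum(cat_w[c]) + sum(cat_w_genes[c]) for c in conditions}
    if spike_scale is None:
        spike_scale = (0.02 * cell_w[conditions[0]] / (0.98 * total_amt)
                       if total_amt else 0.0)
    for s in mrna_spikeins:
        n_win = len(s.sequence) - read_length + 1
        if n_win <= 0:
            continue
        for i in range(n_win):
            cat_seqs.append(s.sequence[i:i + read_length])
            cat_src.append(f"spike::{s.name}")
            for c in conditions:
                cat_w[c].append(s.input_amount * eff[c] * spike_scale / n_win)

    all_seqs = cat_seqs + cat_seqs_genes
    all_src = cat_src + cat_src_genes
    libraries: dict[str, Library] = {}
    locus_counts = {c: {loc.name: 0 for loc in genome.loci} for c in conditions}
    for c in conditions:
        w = np.array(cat_w[c] + cat_w_genes[c], dtype=float)
        counts = rng.multinomial(depths[c], w / w.sum())
        species: dict[str, int] = {}
        for seq, src, n in zip(all_seqs, all_src, counts):
            if not n:
                continue
            species[seq] = species.get(seq, 0) + int(n)
            if src.startswith("locus::"):
                locus_counts[c][src[7:]] += int(n)
        libraries[c] = Library(c, depths[c], species, eff[c])

    truth = RnaseqTruth(
        locus_counts=pd.DataFrame(locus_counts),
        libraries=pd.DataFrame([
            dict(condition=c, depth=depths[c], capture_efficiency=eff[c],
                 spike_scale=spike_scale) for c in conditions
        ]),
        slice_genes=pd.DataFrame([
            dict(name=g.name, chrom=g.chrom, start=g.start, end=g.end, site=g.site,
                 **{f"boost_{c}": boost.get(c, 1.0) for c in conditions})
            for g in genome.slice_genes
        ]),
    )
    return libraries, truth


def make_mrna_spikeins(seed: int, length: int = 600, amount: float = 0.5
                       ) -> list[SpikeInStandard]:
    """Two synthetic mRNA standards (stand-ins for the bacterial CAT and
    firefly luciferase transcripts used as RNA-seq internal standards)."""
    rng = np.random.default_rng(_require_seed(seed))
    return [
        SpikeInStandard(name, "".join(_random_seq(rng, length)), amount, "mrna")
        for name in ("mrna_spike_cat", "mrna_spike_fluc")
    ]


# ---------------------------------------------------------------------------
# Kinetic time-course simulation

@dataclass
class KineticTimeCourse:
    """A slicing time course: fraction product F(t) at enzyme concentration E."""

    times: np.ndarray    # minutes, sorted, >= 0
    F: np.ndarray        # product signal (same units as E times fraction)
    E: float             # enzyme concentration, nM
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.size != self.F.size:
            raise ValueError("times and F must have equal length")
        if (np.diff(self.times) < 0).any() or (self.times < 0).any():
            raise ValueError("times must be sorted and non-negative")


def simulate_timecourse(
    E: float, a: float, b: float, times, noise_sd: float, seed: int,
    label: str = "simulated",
) -> KineticTimeCourse:
    """Burst-model time course with additive Gaussian noise, truncated at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(_require_seed(seed))
    t = np.asarray(times, dtype=float)
    F = burst_model(t, E, a, b)
    if noise_sd > 0:
        F = np.maximum(0.0, F + rng.normal(0.0, noise_sd, size=t.shape))
    return KineticTimeCourse(t, F, E, label)
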