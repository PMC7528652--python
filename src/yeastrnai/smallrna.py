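"""Small-RNA quantification over siRNA clusters.

Implements the library-to-abundance path: length-window filtering of
collapsed reads (9-26 nt), exact mapping, fractional counting of
multi-mapping reads over annotated clusters, spike-in normalization by the
geometric-mean recovery of internal standards, fold changes between
conditions with per-class medians, partition of reads by locus class, and
length / first-nucleotide / third-to-last-nucleotide composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Locus, SpikeInStandard
from .mapping import AlignmentRecord, GenomeIndex, MappingResult, map_reads
from .geometry import normalize_seq

SIRNA_LENGTHS = (22, 23)


def filter_by_length(
    reads: Mapping[str, int] | Iterable[str],
    min_len: int = 9,
    max_len: int = 26,
) -> dict[str, int]:
    """Collapse reads to species and keep lengths within [min_len, max_len]."""
    if not isinstance(reads, Mapping):
        collapsed: dict[str, int] = {}
        for seq in reads:
            seq = normalize_seq(seq)
            collapsed[seq] = collapsed.get(seq, 0) + 1
        reads = collapsed
    out: dict[str, int] = {}
    for seq, count in reads.items():
        seq = normalize_seq(seq)
        if min_len <= len(seq) <= max_len:
            out[seq] = out.get(seq, 0) + int(count)
    return out


def _locus_lookup(loci: Sequence[Locus]):
    """Per-chromosome sorted locus arrays for overlap queries."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Locus]]] = {}
    for chrom in {l.chrom for l in loci}:
        sub = sorted((l for l in loci if l.chrom == chrom), key=lambda l: l.start)
        starts = np.array([l.start for l in sub])
        ends = np.array([l.end for l in sub])
        by_chrom[chrom] = (starts, ends, sub)
    return by_chrom


def assign_hit(lookup, chrom: str, start: int, end: int) -> Locus | None:
    """Locus owning a hit: >= 50% of the read's bases must fall inside."""
    entry = lookup.get(chrom)
    if entry is None:
        return None
    starts, ends, sub = entry
    i = int(np.searchsorted(starts, end)) - 1
    # a short hit can overlap at most the locus at i and its predecessor
    for j in (i, i - 1):
        if 0 <= j < len(sub):
            ov = min(end, ends[j]) - max(start, starts[j])
            if 2 * ov >= end - start:
                return sub[j]
    return None


@dataclass
class FractionalCounts:
    """Per-locus fractional counts plus the unassigned remainder."""

    counts: dict[str, float]
    unassigned: float
    total: float                # total reads considered (within length window)


def fractional_count(
    alignments: Sequence[AlignmentRecord],
    loci: Sequence[Locus],
    lengths: Sequence[int] = SIRNA_LENGTHS,
    denominator: str = "total_hits",
) -> FractionalCounts:
    """Fractionally count multi-mapping reads over non-overlapping loci.

    A species with n total genomic hits, k of which fall in a locus,
    contributes ``count * k / n`` to that locus.  ``denominator`` selects
    whether n is the species' total genomic hit count (default) or only its
    hits within loci (``"locus_hits"``).  Mass is conserved: locus counts
    plus the unassigned remainder equal the total read count (exactly, under
    the default denominator).
    """
    if denominator not in ("total_hits", "locus_hits"):
        raise ValueError("denominator must be 'total_hits' or 'locus_hits'")
    lookup = _locus_lookup(loci)
    lengths = set(lengths)
    counts: dict[str, float] = {l.name: 0.0 for l in loci}
    unassigned = 0.0
    total = 0.0
    for rec in alignments:
        if rec.length not in lengths:
            continue
        total += rec.count
        owners = [assign_hit(lookup, h.chrom, h.start, h.end) for h in rec.hits]
        in_locus = [o for o in owners if o is not None]
        n = rec.n_sites if denominator == "total_hits" else len(in_locus)
        if not in_locus or n == 0:
            unassigned += rec.count
            continue
        for o in in_locus:
            counts[o.name] += rec.count / n
        if denominator == "total_hits":
            unassigned += rec.count * (rec.n_sites - len(in_locus)) / n
    return FractionalCounts(counts, unassigned, total)


def spikein_scale(
    spike_tallies: Mapping[str, Mapping[str, int]],
    manifest: Sequence[SpikeInStandard],
    reference: str | None = None,
) -> dict[str, float]:
    """Per-sample normalization factors from internal-standard recovery.

    For each sample the raw factor is the geometric mean over recovered
    standards of (input amount / recovered read count); factors are then
    rescaled so the reference sample (first key by default) has factor 1.
    Normalized abundance = fractional count x factor.  A sample recovering
    no standard at all is a hard error -- normalization is impossible.
    """
    samples = list(spike_tallies)
    if reference is None:
        reference = samples[0]
    raw: dict[str, float] = {}
    for sample in samples:
        tally = spike_tallies[sample]
        logs = [
            math.log(s.input_amount / tally[s.name])
            for s in manifest
            if tally.get(s.name, 0) > 0
        ]
        if not logs:
            raise ValueError(
                f"sample {sample!r}: no internal standard recovered; "
                "spike-in normalization impossible"
            )
        raw[sample] = math.exp(sum(logs) / len(logs))
    ref = raw[reference]
    return {s: f / ref for s, f in raw.items()}


@dataclass
class AbundanceTable:
    """Per-locus abundances for one sample.

    ``table`` columns: locus, cls, frac_count, rpm, norm_abundance.
    ``rpm`` uses all genome-mapped 9-26-nt reads (spike-ins excluded) as the
    per-million denominator; ``norm_abundance`` is the fractional count
    scaled by the sample's spike-in factor.
    """

    sample: str
    table: pd.DataFrame
    total_mapped: int
    scale_factor: float


def abundance_table(
    sample: str,
    mapping: MappingResult,
    loci: Sequence[Locus],
    scale_factor: float = 1.0,
    lengths: Sequence[int] = SIRNA_LENGTHS,
    denominator: str = "total_hits",
) -> AbundanceTable:
    fc = fractional_count(mapping.alignments, loci, lengths, denominator)
    total = mapping.total_mapped_reads
    per_million = total / 1e6 if total else float("nan")
    rows = [
        dict(
            locus=l.name, cls=l.cls,
            frac_count=fc.counts[l.name],
            rpm=fc.counts[l.name] / per_million if total else float("nan"),
            norm_abundance=fc.counts[l.name] * scale_factor,
        )
        for l in loci
    ]
    df = pd.DataFrame(rows, columns=["locus", "cls", "frac_count", "rpm",
                                     "norm_abundance"]).set_index("locus")
    return AbundanceTable(sample, df, total, scale_factor)


@dataclass
class FoldChanges:
    """Per-locus log2 fold changes (mutant/WT) with per-class medians."""

    table: pd.DataFrame          # cls, wt_rpm, log2_fc (loci passing filter)
    class_medians: pd.Series     # linear fold per class (median on log2 scale)


def fold_change_table(
    table_wt: AbundanceTable,
    table_mut: AbundanceTable,
    min_wt_rpm: float = 1.0,
    pseudocount: float = 0.5,
    value: str = "norm_abundance",
) -> FoldChanges:
    """Fold changes of spike-in-normalized abundance for loci with WT RPM
    >= ``min_wt_rpm``.

    The pseudocount is half a read added to each fractional count before
    scaling (scale-free, unlike a pseudocount on normalized units), so loci
    observed at zero in one sample keep a finite log fold change.
    """
    wt, mut = table_wt.table, table_mut.table
    if not wt.index.equals(mut.index):
        raise ValueError("fold change requires identical locus sets")
    keep = wt["rpm"] >= min_wt_rpm
    num = (mut.loc[keep, "frac_count"] + pseudocount) * table_mut.scale_factor
    den = (wt.loc[keep, "frac_count"] + pseudocount) * table_wt.scale_factor
    log2_fc = np.log2(num / den)
    out = pd.DataFrame({
        "cls": wt.loc[keep, "cls"],
        "wt_rpm": wt.loc[keep, "rpm"],
        "wt_value": wt.loc[keep, value],
        "log2_fc": log2_fc,
    })
    medians = 2.0 ** out.groupby("cls")["log2_fc"].median()
    return FoldChanges(out, medians.rename("median_fold"))


def partition_by_class(
    alignments: Sequence[AlignmentRecord],
    loci: Sequence[Locus],
    lengths: Sequence[int] = SIRNA_LENGTHS,
) -> dict[str, float]:
    """Fraction of locus-mapped reads from palindromic / non-palindromic /
    both locus types.

    A species counts as palindromic when every locus it hits is palindromic,
    non-palindromic when every hit locus is non-palindromic (the Y'-like
    class included), and both otherwise.  Fractions sum to 1 over
    locus-mapped reads of the requested lengths.
    """
    lookup = _locus_lookup(loci)
    lengths = set(lengths)
    tallies = {"palindromic": 0.0, "non_palindromic": 0.0, "both": 0.0}
    total = 0.0
    for rec in alignments:
        if rec.length not in lengths:
            continue
        classes = {
            "palindromic" if o.cls == "palindromic" else "non_palindromic"
            for h in rec.hits
            if (o := assign_hit(lookup, h.chrom, h.start, h.end)) is not None
        }
        if not classes:
            continue
        label = classes.pop() if len(classes) == 1 else "both"
        tallies[label] += rec.count
        total += rec.count
    if total:
        tallies = {k: v / total for k, v in tallies.items()}
    return tallies


@dataclass
class CompositionStats:
    length_counts: pd.Series            # reads per length
    first_nt: pd.DataFrame              # length x base fractions
    third_to_last_23: pd.Series         # base fractions at position L-2 of 23-mers


def composition_stats(
    alignments: Sequence[AlignmentRecord],
    exclusion: Sequence[Locus] = (),
) -> CompositionStats:
    """Length histogram and positional base composition of mapped reads.

    Species mapping *exclusively* within exclusion annotations (e.g.
    rRNA/tRNA intervals) are dropped.  First-nucleotide composition is per
    read length; the third-to-last position (1-based position L-2) is
    reported for 23-nt reads, where an enrichment of A mirrors passenger
    strands pairing guides that begin with U.
    """
    lookup = _locus_lookup(exclusion) if exclusion else None
    len_counts: dict[int, int] = {}
    first: dict[tuple[int, str], int] = {}
    third_last: dict[str, int] = {}
    for rec in alignments:
        if lookup is not None and rec.hits:
            if all(
                assign_hit(lookup, h.chrom, h.start, h.end) is not None
                for h in rec.hits
            ):
                continue
        L = rec.length
        len_counts[L] = len_counts.get(L, 0) + rec.count
        first[(L, rec.sequence[0])] = first.get((L, rec.sequence[0]), 0) + rec.count
        if L == 23:
            base = rec.sequence[L - 3]
            third_last[base] = third_last.get(base, 0) + rec.count

    lengths = sorted(len_counts)
    first_df = pd.DataFrame(
        0.0, index=lengths, columns=list("ACGT"))
    for (L, base), n in first.items():
        first_df.at[L, base] = n
    first_df = first_df.div(first_df.sum(axis=1), axis=0).fillna(0.0)
    t23 = pd.Series({b: third_last.get(b, 0) for b in "ACGT"}, dtype=float)
    if t23.sum():
        t23 = t23 / t23.sum()
    return CompositionStats(
        pd.Series(len_counts).sort_index(), first_df, t23)


def quantify_sample(
    sample: str,
    species: Mapping[str, int],
    index: GenomeIndex,
    loci: Sequence[Locus],
    spikeins: Sequence[SpikeInStandard] = (),
    min_len: int = 9,
    max_len: int = 26,
    lengths: Sequence[int] = SIRNA_LENGTHS,
) -> tuple[MappingResult, AbundanceTable]:
    """Filter, map and count one library (scale factor applied separately)."""
    filtered = filter_by_length(species, min_len, max_len)
    mapping = map_reads(filtered, index, spikeins)
    return mapping, abundance_table(sample, mapping, loci, 1.0, lengths)
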