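"""Precursor-transcript quantification from RNA-seq.

Longer reads are mapped with the same exact-match mapper, counted per locus
strand-awareness (the library is directional: antisense placements are
tallied separately and excluded from TPM by default), normalized to TPM and
to the recovery of mRNA spike-in standards, and compared between conditions.
A coverage-asymmetry statistic around known slice sites quantifies the
accumulation of 3' slicing products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Locus, SpikeInStandard
from .mapping import AlignmentRecord, GenomeIndex, map_reads
from .smallrna import _locus_lookup, assign_hit, spikein_scale
from .stats import spearman


@dataclass
class TranscriptAbundances:
    """Per-locus RNA-seq abundances for one sample.

    ``table`` columns: cls, count (sense fragments), antisense_count, tpm,
    norm_abundance.  TPM sums to 1e6 over loci (spike-ins excluded).
    """

    sample: str
    table: pd.DataFrame
    total_mapped: int
    spike_counts: dict[str, int]
    scale_factor: float = 1.0

    def with_scale(self, factor: float) -> "TranscriptAbundances":
        tbl = self.table.copy()
        tbl["norm_abundance"] = tbl["count"] * factor
        return TranscriptAbundances(
            self.sample, tbl, self.total_mapped, self.spike_counts, factor)


def spike_index(spikeins: Sequence[SpikeInStandard]) -> GenomeIndex:
    """Index of spike-in reference sequences as pseudo-chromosomes."""
    return GenomeIndex({f"spike::{s.name}": s.sequence for s in spikeins})


def quantify_loci(
    species: Mapping[str, int],
    index: GenomeIndex,
    loci: Sequence[Locus],
    mrna_spikeins: Sequence[SpikeInStandard] = (),
    sample: str = "sample",
    count_antisense: bool = False,
) -> TranscriptAbundances:
    """Fragment counts, TPM and spike recovery for one RNA-seq library.

    Reads are first matched against the spike-in references (any exact
    placement on a standard routes the species to that standard's tally),
    then against the genome.  A read on the opposite strand of its locus is
    an antisense fragment, excluded from TPM unless ``count_antisense``.
    Multi-mapping reads are fractionally assigned as in the small-RNA arm.
    Zero mapped reads is an error.
    """
    spk_idx = spike_index(mrna_spikeins) if mrna_spikeins else None
    spike_counts = {s.name: 0 for s in mrna_spikeins}
    genomic: dict[str, int] = {}
    for seq, count in species.items():
        if spk_idx is not None:
            hits = spk_idx.find(seq)
            if hits:
                spike_counts[hits[0].chrom[len("spike::"):]] += count
                continue
        genomic[seq] = count
    mapping = map_reads(genomic, index)
    if mapping.total_mapped_reads == 0:
        raise ValueError(f"sample {sample!r}: no RNA-seq reads mapped")

    lookup = _locus_lookup(loci)
    sense = {l.name: 0.0 for l in loci}
    anti = {l.name: 0.0 for l in loci}
    for rec in mapping.alignments:
        owners = [
            (o, h.strand)
            for h in rec.hits
            if (o := assign_hit(lookup, h.chrom, h.start, h.end)) is not None
        ]
        if not owners:
            continue
        share = rec.count / rec.n_sites
        for o, strand in owners:
            (sense if strand == o.strand else anti)[o.name] += share

    lengths_kb = {l.name: l.length / 1e3 for l in loci}
    counted = {
        name: sense[name] + (anti[name] if count_antisense else 0.0)
        for name in sense
    }
    rate = {name: counted[name] / lengths_kb[name] for name in counted}
    rate_sum = sum(rate.values())
    rows = [
        dict(
            locus=l.name, cls=l.cls, count=counted[l.name],
            antisense_count=anti[l.name],
            tpm=rate[l.name] / rate_sum * 1e6 if rate_sum else 0.0,
            norm_abundance=counted[l.name],
        )
        for l in loci
    ]
    tbl = pd.DataFrame(rows, columns=[
        "locus", "cls", "count", "antisense_count", "tpm", "norm_abundance",
    ]).set_index("locus")
    return TranscriptAbundances(sample, tbl, mapping.total_mapped_reads, spike_counts)


def normalize_samples(
    abundances: Mapping[str, TranscriptAbundances],
    manifest: Sequence[SpikeInStandard],
    reference: str | None = None,
) -> dict[str, TranscriptAbundances]:
    """Apply geometric-mean spike-in factors across samples (reference = 1)."""
    factors = spikein_scale(
        {s: a.spike_counts for s, a in abundances.items()}, manifest, reference)
    return {s: a.with_scale(factors[s]) for s, a in abundances.items()}


@dataclass
class FoldChanges:
    table: pd.DataFrame
    class_medians: pd.Series


def precursor_fold_changes(
    wt: TranscriptAbundances,
    mut: TranscriptAbundances,
    min_wt_tpm: float = 1.0,
    pseudocount: float = 0.5,
) -> FoldChanges:
    """log2 fold changes of normalized precursor abundance for loci
    expressed at >= ``min_wt_tpm`` TPM in WT, with per-class medians
    (reported as linear folds)."""
    if not wt.table.index.equals(mut.table.index):
        raise ValueError("fold change requires identical locus sets")
    keep = wt.table["tpm"] >= min_wt_tpm
    num = (mut.table.loc[keep, "count"] + pseudocount) * mut.scale_factor
    den = (wt.table.loc[keep, "count"] + pseudocount) * wt.scale_factor
    out = pd.DataFrame({
        "cls": wt.table.loc[keep, "cls"],
        "wt_tpm": wt.table.loc[keep, "tpm"],
        "log2_fc": np.log2(num / den),
    })
    medians = 2.0 ** out.groupby("cls")["log2_fc"].median()
    return FoldChanges(out, medians.rename("median_fold"))


@dataclass
class CorrelationResult:
    stratum: str
    n: int
    rho: float
    p_value: float
    n_both_positive: int
    defined: bool = True


def correlate_sirna_precursor(
    sirna_fc: pd.DataFrame,
    precursor_fc: pd.DataFrame,
    strata: Sequence[str] = ("palindromic", "non_palindromic"),
    yprime_with: str = "non_palindromic",
) -> list[CorrelationResult]:
    """Spearman correlation of siRNA vs precursor log2 fold changes.

    Joins the two fold-change tables on locus (each already filtered to >= 1
    RPM and >= 1 TPM in WT respectively, so the join is the intersection),
    computes Spearman with average ranks per class stratum, and counts loci
    where both changes are positive.  Strata with fewer than 3 loci are
    flagged undefined.
    """
    joined = sirna_fc[["cls", "log2_fc"]].join(
        precursor_fc[["log2_fc"]], how="inner", lsuffix="_sirna", rsuffix="_prec")
    cls = joined["cls"].where(joined["cls"] != "y_prime", yprime_with)
    out = []
    for stratum in strata:
        sub = joined[cls == stratum]
        n = len(sub)
        both_pos = int(((sub["log2_fc_sirna"] > 0) & (sub["log2_fc_prec"] > 0)).sum())
        if n < 3:
            out.append(CorrelationResult(stratum, n, float("nan"), float("nan"),
                                         both_pos, defined=False))
            continue
        rho, p = spearman(sub["log2_fc_prec"], sub["log2_fc_sirna"])
        out.append(CorrelationResult(stratum, n, rho, p, both_pos))
    return out


# ---------------------------------------------------------------------------
# Coverage asymmetry around slice sites

def coverage_vector(
    alignments: Sequence[AlignmentRecord],
    chrom: str,
    start: int,
    end: int,
) -> np.ndarray:
    """Per-base read coverage over [start, end) from exact alignments
    (multi-mapping reads contribute fractionally)."""
    cov = np.zeros(end - start, dtype=float)
    for rec in alignments:
        share = rec.count / rec.n_sites
        for h in rec.hits:
            if h.chrom != chrom or h.end <= start or h.start >= end:
                continue
            cov[max(0, h.start - start):min(end - start, h.end - start)] += share
    return cov


@dataclass
class SliceAsymmetry:
    gene: str
    site: int
    ratio: float          # mean coverage downstream / mean upstream
    flank: int
    defined: bool = True


def slice_site_asymmetry(
    coverage: np.ndarray,
    site: int,
    flank: int = 100,
    gene: str = "",
) -> SliceAsymmetry:
    """Downstream/upstream mean-coverage ratio around a slice site.

    ``site`` indexes into ``coverage``; the ratio compares the mean of
    ``(site, site + flank]`` to the mean of ``(site - flank, site]``.  Zero
    upstream coverage leaves the ratio undefined (NaN, flagged).  The ratio
    is invariant to uniform coverage scaling.
    """
    cov = np.asarray(coverage, dtype=float)
    if not flank > 0:
        raise ValueError("flank must be positive")
    if site - flank < 0 or site + flank > cov.size - 1:
        raise ValueError("site must have >= flank bases on each side")
    up = cov[site - flank + 1:site + 1].mean()
    down = cov[site + 1:site + flank + 1].mean()
    if up == 0:
        return SliceAsymmetry(gene, site, float("nan"), flank, defined=False)
    return SliceAsymmetry(gene, site, down / up, flank)


def asymmetry_contrast(mut: SliceAsymmetry, wt: SliceAsymmetry) -> float:
    """Strain contrast of the asymmetry ratio (mutant / WT)."""
    return mut.ratio / wt.ratio
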