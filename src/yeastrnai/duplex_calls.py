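"""Guide-passenger duplex calling from observed small-RNA species.

The procedure mirrors how experimentally supported siRNA duplexes are
identified from sequencing alone:

1. every unordered pair of observed 22- or 23-nt species that forms a
   perfect Watson-Crick duplex with 2-nt 3' overhangs is a candidate;
2. the strand with strictly more reads in the WT library is the guide
   (ties and zero-zero pairs are excluded);
3. duplexes whose passenger-to-guide ratio rises in the slicing-impaired
   Argonaute mutant are carried forward as supported -- a passenger that
   persists when slicing is dead behaves like a real passenger strand;
4. passenger cleavage fragments are counted by exact end-anchored matching:
   12-nt species equal to the passenger's 3' end, and 10-nt (22-nt duplex)
   or 11-nt (23-nt duplex) species equal to its 5' end.

Ratios use a half-read pseudocount throughout.  Pairing is discovered from
sequence complementarity of the observed species, not genomic adjacency, so
hairpin-derived and bimolecular duplexes are treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import OVERHANG, is_sirna_duplex, normalize_seq, revcomp
from .simulate import frag5_length
from .stats import PairedTestResult, wilcoxon_signed_rank

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DuplexCall:
    """An oriented guide-passenger duplex with per-strain counts."""

    guide: str
    passenger: str
    duplex_length: int
    guide_counts: dict[str, int] = field(default_factory=dict)
    passenger_counts: dict[str, int] = field(default_factory=dict)
    frag5_counts: dict[str, int] = field(default_factory=dict)
    frag3_counts: dict[str, int] = field(default_factory=dict)

    def ratio(self, strain: str, which: str = "full",
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
        """(passenger-species + psi) / (guide + psi) for one strain."""
        if which == "full":
            num = self.passenger_counts.get(strain, 0)
        elif which == "cleaved":
            num = (self.frag5_counts.get(strain, 0)
                   + self.frag3_counts.get(strain, 0))
        else:
            raise ValueError("which must be 'full' or 'cleaved'")
        return (num + pseudocount) / (self.guide_counts.get(strain, 0) + pseudocount)


def _species_of_length(species: Mapping[str, int], lengths=(22, 23)) -> dict[str, int]:
    return {normalize_seq(s): c for s, c in species.items() if len(s) in lengths}


def find_perfect_duplexes(
    species_by_strain: Mapping[str, Mapping[str, int]],
) -> list[tuple[str, str]]:
    """All unordered pairs of observed 22/23-nt species forming a perfect
    duplex with 2-nt 3' overhangs.

    Pairing is Watson-Crick only and length-matched (a 22-nt species never
    pairs a 23-nt one); a species cannot pair with itself, so a perfectly
    self-complementary sequence yields no call.  The pair is returned in
    lexicographic order, making the result independent of input order.
    """
    universe: set[str] = set()
    for species in species_by_strain.values():
        universe |= set(_species_of_length(species))
    by_core: dict[str, list[str]] = {}
    for seq in universe:
        by_core.setdefault(seq[:len(seq) - OVERHANG], []).append(seq)
    pairs: set[tuple[str, str]] = set()
    for seq in universe:
        want = revcomp(seq[:len(seq) - OVERHANG])
        for partner in by_core.get(want, ()):
            if partner == seq or len(partner) != len(seq):
                continue
            if is_sirna_duplex(seq, partner):
                pairs.add(tuple(sorted((seq, partner))))
    return sorted(pairs)


def assign_guide_passenger(
    pair: tuple[str, str],
    wt_counts: Mapping[str, int],
) -> tuple[str, str] | None:
    """Orient a duplex: the strand with strictly more WT reads is the guide.

    Returns (guide, passenger), or None when the WT counts tie (including
    the zero-zero case) -- orientation would be arbitrary.
    """
    a, b = pair
    ca, cb = wt_counts.get(a, 0), wt_counts.get(b, 0)
    if ca == cb:
        return None
    return (a, b) if ca > cb else (b, a)


def count_cleavage_fragments(
    call: DuplexCall,
    species_by_strain: Mapping[str, Mapping[str, int]],
) -> None:
    """Fill the call's fragment tallies from 9-26-nt species, in place.

    Only exact end-anchored matches count: the 5' fragment is the
    passenger's first 10 nt (22-nt duplex) or 11 nt (23-nt duplex); the 3'
    fragment is its last 12 nt.  Internal-window matches never count.
    """
    k5 = frag5_length(call.duplex_length)
    f5 = call.passenger[:k5]
    f3 = call.passenger[-12:]
    for strain, species in species_by_strain.items():
        call.frag5_counts[strain] = species.get(f5, 0)
        call.frag3_counts[strain] = species.get(f3, 0)


def call_duplexes(
    species_by_strain: Mapping[str, Mapping[str, int]],
    wt: str = "WT",
    ago1: str = "ago1_mut",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_support: bool = True,
) -> list[DuplexCall]:
    """Full calling pipeline: pair, orient, count fragments, filter.

    ``species_by_strain`` maps strain label -> collapsed species counts
    (9-26-nt; only 22/23-nt species seed duplexes, but fragment matching
    uses the full window).  With ``require_support`` the slicing-impaired
    strain must show a strictly increased full-length passenger:guide ratio
    relative to WT.
    """
    strains = list(species_by_strain)
    if wt not in species_by_strain:
        raise ValueError(f"WT strain {wt!r} missing from input")
    calls: list[DuplexCall] = []
    sirna = {s: _species_of_length(species_by_strain[s]) for s in strains}
    for pair in find_perfect_duplexes(species_by_strain):
        oriented = assign_guide_passenger(pair, sirna[wt])
        if oriented is None:
            continue
        guide, passenger = oriented
        call = DuplexCall(
            guide, passenger, len(guide),
            guide_counts={s: sirna[s].get(guide, 0) for s in strains},
            passenger_counts={s: sirna[s].get(passenger, 0) for s in strains},
        )
        count_cleavage_fragments(call, species_by_strain)
        calls.append(call)
    if require_support:
        if ago1 not in species_by_strain:
            raise ValueError(f"slicing-impaired strain {ago1!r} missing from input")
        calls = filter_supported(calls, wt, ago1, pseudocount)
    return calls


def filter_supported(
    calls: Sequence[DuplexCall],
    wt: str = "WT",
    ago1: str = "ago1_mut",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DuplexCall]:
    """Keep duplexes whose passenger:guide ratio strictly increases in the
    slicing-impaired strain relative to WT."""
    return [
        c for c in calls
        if c.ratio(ago1, "full", pseudocount) > c.ratio(wt, "full", pseudocount)
    ]


@dataclass
class RatioAnalysis:
    """Per-duplex log2 ratio shifts for one strain contrast, with the
    paired signed-rank test."""

    which: str                    # 'full' or 'cleaved'
    contrast: tuple[str, str]     # (strain, reference), e.g. (xrn1_del, WT)
    table: pd.DataFrame           # guide, passenger, log2_ratio_a/b, diff
    test: PairedTestResult


def passenger_ratio_analysis(
    calls: Sequence[DuplexCall],
    contrast: tuple[str, str],
    which: str = "full",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_pairs: int = 6,
) -> RatioAnalysis:
    """log2 passenger:guide ratio shifts between two strains.

    For each duplex the difference log2 r(strain) - log2 r(reference) enters
    a two-tailed Wilcoxon signed-rank test; the median shift is reported as
    a linear fold.  Fewer than ``min_pairs`` usable pairs is an error (the
    test would be meaningless).
    """
    strain, ref = contrast
    rows = []
    for c in calls:
        ra = c.ratio(strain, which, pseudocount)
        rb = c.ratio(ref, which, pseudocount)
        rows.append(dict(
            guide=c.guide, passenger=c.passenger,
            log2_ratio_strain=np.log2(ra), log2_ratio_ref=np.log2(rb),
            diff=np.log2(ra / rb),
        ))
    df = pd.DataFrame(rows, columns=[
        "guide", "passenger", "log2_ratio_strain", "log2_ratio_ref", "diff"])
    if len(df) < min_pairs:
        raise ValueError(
            f"only {len(df)} usable duplex pairs; need >= {min_pairs}")
    test = wilcoxon_signed_rank(df["diff"].to_numpy())
    return RatioAnalysis(which, contrast, df, test)


def calls_to_frame(calls: Sequence[DuplexCall], strains: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = dict(guide=c.guide, passenger=c.passenger, length=c.duplex_length)
        for s in strains:
            row[f"guide_{s}"] = c.guide_counts.get(s, 0)
            row[f"passenger_{s}"] = c.passenger_counts.get(s, 0)
            row[f"frag5_{s}"] = c.frag5_counts.get(s, 0)
            row[f"frag3_{s}"] = c.frag3_counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
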