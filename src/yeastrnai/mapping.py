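"""Exact-match read mapping against a small genome.

Synthetic reads carry no sequencing errors, so mapping is exact substring
search on both strands, with every occurrence reported (no best-hit
heuristics).  The index is a per-length hash of genome k-mers, which for the
compact genomes this package targets is both simple and fast.

Spike-in standards are matched against their manifest *before* the genome
search and routed to a separate tally so they never enter genomic counts.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .geometry import normalize_seq, revcomp
from .io import SpikeInStandard

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class AlignmentRecord:
    """All exact placements of one read species."""

    sequence: str
    count: int
    hits: tuple[Hit, ...]

    @property
    def n_sites(self) -> int:
        return len(self.hits)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MappingResult:
    alignments: list[AlignmentRecord]
    spike_counts: dict[str, int]
    unmapped: dict[str, int]
    n_skipped: int = 0

    @property
    def total_mapped_reads(self) -> int:
        return sum(a.count for a in self.alignments)


class GenomeIndex:
    """Hash index of genome k-mers, built lazily per query length."""

    def __init__(self, genome: Mapping[str, str]):
        self.genome = {c: normalize_seq(s) for c, s in genome.items()}
        self._by_length: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._by_length.get(k)
        if idx is None:
            idx = collections.defaultdict(list)
            for chrom, seq in self.genome.items():
                for i in range(len(seq) - k + 1):
                    idx[seq[i:i + k]].append((chrom, i))
            self._by_length[k] = idx = dict(idx)
        return idx

    def find(self, seq: str) -> tuple[Hit, ...]:
        """Every exact occurrence of ``seq`` on either strand."""
        k = len(seq)
        idx = self._index_for(k)
        hits = [Hit(c, p, p + k, "+") for c, p in idx.get(seq, ())]
        rc = revcomp(seq)
        hits += [Hit(c, p, p + k, "-") for c, p in idx.get(rc, ())]
        return tuple(sorted(hits, key=lambda h: (h.chrom, h.start, h.strand)))


def map_reads(
    species: Mapping[str, int],
    index: GenomeIndex,
    spikeins: Sequence[SpikeInStandard] = (),
) -> MappingResult:
    """Place collapsed read species on the genome.

    Species whose sequence equals a spike-in standard are tallied under the
    standard's name and excluded from genomic mapping.  Species containing
    non-ACGT characters are skipped (counted in ``n_skipped``); species with
    zero genomic occurrences are reported in ``unmapped``.
    """
    spike_by_seq = {s.sequence: s.name for s in spikeins}
    spike_counts = {s.name: 0 for s in spikeins}
    alignments: list[AlignmentRecord] = []
    unmapped: dict[str, int] = {}
    n_skipped = 0
    for seq, count in species.items():
        seq = normalize_seq(seq)
        name = spike_by_seq.get(seq)
        if name is not None:
            spike_counts[name] += count
            continue
        if not set(seq) <= _VALID:
            n_skipped += count
            continue
        hits = index.find(seq)
        if hits:
            alignments.append(AlignmentRecord(seq, count, hits))
        else:
            unmapped[seq] = count
    return MappingResult(alignments, spike_counts, unmapped, n_skipped)
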