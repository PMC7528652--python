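"""siRNA duplex geometry.

Dicer products are short RNA duplexes whose two strands are paired over all
but their final two 3' nucleotides, leaving a 2-nt 3' overhang on each
strand -- the signature of RNase III cleavage.  This module holds the
sequence-level predicates and the phased "dicing" of a long perfectly paired
precursor region into successive duplexes.

Sequences are handled in DNA alphabet internally (A/C/G/T); RNA input with U
is accepted and normalized.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DUPLEX_LENGTHS = (22, 23)
OVERHANG = 2


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_sirna_duplex(strand_a: str, strand_b: str) -> bool:
    """True when the two strands form a perfect siRNA duplex.

    The criterion is full Watson-Crick complementarity over the first
    ``L - 2`` nucleotides of each strand (antiparallel register), which
    leaves the last two nucleotides of each strand as 3' overhangs.  Blunt
    pairings (a strand with its exact reverse complement) fail this register
    for any non-degenerate sequence, as do mixed-length pairs.

    G:U wobble is not accepted: Watson-Crick pairing only.
    """
    a = normalize_seq(strand_a)
    b = normalize_seq(strand_b)
    if len(a) != len(b) or len(a) <= OVERHANG:
        return False
    core = len(a) - OVERHANG
    return a[:core] == revcomp(b[:core])


@dataclass(frozen=True)
class Duplex:
    """An oriented pair of strands with valid siRNA geometry.

    ``sense_offset`` is the offset of the sense strand within the diced
    region (when produced by :func:`dice_duplexes`), else 0.
    """

    sense: str
    antisense: str
    sense_offset: int = 0

    def __post_init__(self) -> None:
        if not is_sirna_duplex(self.sense, self.antisense):
            raise ValueError(
                "strands do not form a perfect duplex with 2-nt 3' overhangs"
            )

    @property
    def length(self) -> int:
        return len(self.sense)


def duplex_region_pair(genome_seq: str, start: int, end: int) -> tuple[str, str]:
    """Return the (sense, antisense) strand pair of a paired genomic region.

    The antisense strand is returned in the 2-nt-offset register set by the
    first cleavage: it is the reverse complement of ``[start - 2, end - 2)``
    on the top strand, so every phased duplex produced by
    :func:`dice_duplexes` carries full 3' overhangs.  Requires ``start >= 2``.
    """
    if start < OVERHANG:
        raise ValueError("need 2 nt of upstream context for the overhang register")
    sense = normalize_seq(genome_seq[start:end])
    antisense = revcomp(normalize_seq(genome_seq[start - OVERHANG:end - OVERHANG]))
    return sense, antisense


def dice_duplexes(
    region: tuple[str, str], duplex_length: int
) -> list[Duplex]:
    """Phase a perfectly paired precursor region into successive duplexes.

    ``region`` is the (sense, antisense) strand pair, both 5'->3', with the
    antisense strand in the overhang register (see
    :func:`duplex_region_pair`).  Products are emitted end-to-end from the
    sense strand's 5' end; a region shorter than one duplex yields an empty
    list.  Candidates that fail the duplex geometry (e.g. when the caller
    supplies a blunt, unshifted strand pair) are dropped.
    """
    if duplex_length not in DUPLEX_LENGTHS:
        raise ValueError(f"duplex_length must be one of {DUPLEX_LENGTHS}")
    sense, antisense = (normalize_seq(s) for s in region)
    if len(sense) != len(antisense):
        raise ValueError("strand pair must have equal lengths")
    n = len(sense)
    out: list[Duplex] = []
    for k in range(n // duplex_length):
        lo = k * duplex_length
        hi = lo + duplex_length
        guide = sense[lo:hi]
        passenger = antisense[n - hi:n - lo]
        if is_sirna_duplex(guide, passenger):
            out.append(Duplex(guide, passenger, sense_offset=lo))
    return out


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i:i + k]
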