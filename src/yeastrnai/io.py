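"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing goes through Biopython; BED, spike-in manifests and
abundance tables are TSV via pandas.  Small-RNA libraries are collapsed on
ingestion to unique read species with multiplicities, which is the in-memory
currency of the whole package.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .geometry import normalize_seq


@dataclass(frozen=True)
class Locus:
    """A genomic interval with an siRNA-class label.

    ``cls`` is one of ``palindromic``, ``non_palindromic``, ``y_prime``.
    Coordinates are 0-based half-open; ``name`` is a unique locus id.
    """

    chrom: str
    start: int
    end: int
    name: str
    cls: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpikeInStandard:
    """An exogenous standard of known input amount.

    ``kind`` is ``small_rna`` or ``mrna``; ``input_amount`` is in arbitrary
    units (the same units across standards of one kind -- only ratios between
    samples matter for normalization).
    """

    name: str
    sequence: str
    input_amount: float
    kind: str = "small_rna"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("spike-in sequence must be non-empty")
        if self.input_amount <= 0:
            raise ValueError("spike-in input amount must be positive")
        if self.kind == "small_rna" and not 9 <= len(self.sequence) <= 26:
            raise ValueError("small-RNA spike-in length must be within 9-26 nt")
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def collapse_reads(seqs: Iterable[str]) -> dict[str, int]:
    """Collapse raw read sequences to species -> multiplicity."""
    counter: collections.Counter[str] = collections.Counter(
        normalize_seq(s) for s in seqs
    )
    return dict(counter)


def read_fastq_species(path: str | Path) -> dict[str, int]:
    return collapse_reads(str(rec.seq) for rec in SeqIO.parse(str(path), "fastq"))


def write_fastq(species: Mapping[str, int], path: str | Path, prefix: str = "read") -> None:
    """Expand collapsed species to a FASTQ file with constant 'I' qualities."""
    i = 0
    with open(path, "w") as fh:
        for seq in sorted(species):
            for _ in range(species[seq]):
                fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1


def read_species_tsv(path: str | Path) -> dict[str, int]:
    """Read a collapsed species table (columns: sequence, count)."""
    df = pd.read_csv(path, sep="\t")
    return {normalize_seq(s): int(c) for s, c in zip(df["sequence"], df["count"])}


def write_species_tsv(species: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(species.items()), columns=["sequence", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[Locus]:
    """Read a 6-column BED whose name field is ``<id>|<class>``."""
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split()[:6]
            locus_id, _, cls = name.partition("|")
            loci.append(Locus(chrom, int(start), int(end), locus_id, cls or "non_palindromic", strand))
    return loci


def write_bed(loci: Iterable[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.name}|{loc.cls}\t0\t{loc.strand}\n"
            )


def read_spikein_manifest(path: str | Path) -> list[SpikeInStandard]:
    """Read a spike-in manifest TSV (name, sequence, input_amount[, kind])."""
    df = pd.read_csv(path, sep="\t")
    kind = df["kind"] if "kind" in df.columns else ["small_rna"] * len(df)
    return [
        SpikeInStandard(str(n), str(s), float(a), str(k))
        for n, s, a, k in zip(df["name"], df["sequence"], df["input_amount"], kind)
    ]


def write_spikein_manifest(standards: Iterable[SpikeInStandard], path: str | Path) -> None:
    pd.DataFrame(
        [(s.name, s.sequence, s.input_amount, s.kind) for s in standards],
        columns=["name", "sequence", "input_amount", "kind"],
    ).to_csv(path, sep="\t", index=False)
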