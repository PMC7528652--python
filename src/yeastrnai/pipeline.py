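"""End-to-end orchestration: simulate -> quantify -> call -> report.

A single YAML-style config (with CLI overrides) drives every stage; all
randomness funnels through the one seed recorded in the run report.  Each
stage writes its outputs under the run directory and the report carries
parameters and checksums, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as yio
from .duplex_calls import call_duplexes, calls_to_frame, passenger_ratio_analysis
from .mapping import GenomeIndex
from .rnaseq import (
    asymmetry_contrast, coverage_vector, correlate_sirna_precursor,
    normalize_samples, precursor_fold_changes, quantify_loci,
    slice_site_asymmetry, spike_index,
)
from .simulate import (
    DEFAULT_SMALLRNA_SPIKEINS, GenomeSpec, PlantedEffects, make_genome,
    make_mrna_spikeins, simulate_libraries, simulate_rnaseq,
)
from .smallrna import (
    abundance_table, composition_stats, fold_change_table, partition_by_class,
    quantify_sample, spikein_scale,
)
from .mapping import map_reads
from .smallrna import filter_by_length

log = logging.getLogger("yeastrnai")

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "simulate": {
        "depth_smallrna": 100_000,
        "depth_rnaseq": 50_000,
        "background_fraction": 0.1,
        "capture_sigma": 0.2,
        "guide_u5_prob": 0.8,
    },
    "smallrna": {
        "min_len": 9, "max_len": 26, "sirna_lengths": [22, 23],
        "min_wt_rpm": 1.0, "pseudocount": 0.5,
    },
    "duplex": {"pseudocount": 0.5, "min_pairs": 6},
    "rnaseq": {"min_wt_tpm": 1.0, "flank": 100},
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``genome_spec`` holds overrides for :class:`GenomeSpec`; ``params`` is a
    per-stage parameter block merged over :data:`DEFAULT_PARAMS`.
    """

    seed: int
    outdir: Path
    genome_spec: dict[str, Any] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        self.outdir = Path(self.outdir)
        merged = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
        for stage, block in (self.params or {}).items():
            if stage not in merged:
                raise ValueError(f"unknown parameter block {stage!r}")
            merged[stage].update(block)
        self.params = merged
        GenomeSpec(**{**self.genome_spec, "seed": 0})  # validate field names early
        # every referenced input path must exist before any stage runs
        for name, path in (self.inputs or {}).items():
            if not Path(path).exists():
                raise ValueError(f"input path for {name!r} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        missing = {"seed", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"config missing required key(s): {sorted(missing)}")
        return cls(
            seed=int(raw["seed"]), outdir=raw["outdir"],
            genome_spec=raw.get("genome_spec", {}) or {},
            params=raw.get("params", {}) or {},
            inputs=raw.get("inputs", {}) or {},
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": str(self.outdir),
            "genome_spec": self.genome_spec, "params": self.params,
            "inputs": self.inputs,
        }


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulation, small-RNA quantification, duplex calling and RNA-seq
    analysis; write all stage outputs plus a machine-readable report.

    A stage failure aborts the run with the failing stage named and leaves a
    ``FAILED_<stage>`` marker next to any partial outputs.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed, "config": config.to_dict(), "stages": {},
    }
    stage = "simulate"
    try:
        sim = report["stages"]["simulate"] = {}
        p = config.params["simulate"]
        genome = make_genome(
            GenomeSpec(**{**config.genome_spec, "seed": config.seed}),
            guide_u5_prob=p["guide_u5_prob"],
        )
        effects = PlantedEffects.default(genome, seed=config.seed + 1,
                                         guide_u5_prob=p["guide_u5_prob"])
        spikes = list(DEFAULT_SMALLRNA_SPIKEINS)
        mrna_spikes = make_mrna_spikeins(seed=config.seed + 2)
        libs, truth = simulate_libraries(
            genome, effects, spikes, p["depth_smallrna"], seed=config.seed + 3,
            background_fraction=p["background_fraction"],
            capture_sigma=p["capture_sigma"],
        )
        rlibs, rtruth = simulate_rnaseq(
            genome, effects, mrna_spikes, p["depth_rnaseq"], seed=config.seed + 4)

        yio.write_fasta(genome.chromosomes, out / "genome.fa")
        yio.write_bed(genome.loci, out / "loci.bed")
        yio.write_spikein_manifest(spikes + mrna_spikes, out / "spikeins.tsv")
        for cond, lib in libs.items():
            yio.write_species_tsv(lib.species, out / f"{cond}.smallrna.tsv")
        for cond, lib in rlibs.items():
            yio.write_species_tsv(lib.species, out / f"{cond}.rnaseq.tsv")
        truth.species.to_csv(out / "truth_species.tsv", sep="\t", index=False)
        truth.sirna_output.to_csv(out / "truth_sirna_output.tsv", sep="\t")
        rtruth.locus_counts.to_csv(out / "truth_rnaseq_counts.tsv", sep="\t")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        sim["n_loci"] = len(genome.loci)
        sim["n_duplexes"] = int(len(genome.duplexes))
        sim["conditions"] = list(libs)

        stage = "smallrna_quant"
        sq = report["stages"][stage] = {}
        ps = config.params["smallrna"]
        index = GenomeIndex(genome.chromosomes)
        mappings, tables = {}, {}
        for cond, lib in libs.items():
            mapping, _ = quantify_sample(
                cond, lib.species, index, genome.loci, spikes,
                ps["min_len"], ps["max_len"], tuple(ps["sirna_lengths"]))
            mappings[cond] = mapping
        factors = spikein_scale(
            {c: m.spike_counts for c, m in mappings.items()}, spikes, "WT")
        for cond, mapping in mappings.items():
            tables[cond] = abundance_table(
                cond, mapping, genome.loci, factors[cond],
                tuple(ps["sirna_lengths"]))
            tables[cond].table.to_csv(out / f"{cond}.abundance.tsv", sep="\t")
        fc = fold_change_table(tables["WT"], tables["xrn1_del"],
                               ps["min_wt_rpm"], ps["pseudocount"])
        fc.table.to_csv(out / "sirna_foldchange.tsv", sep="\t")
        sq["scale_factors"] = factors
        sq["class_median_fold"] = fc.class_medians.to_dict()
        sq["partition_WT"] = partition_by_class(
            mappings["WT"].alignments, genome.loci, tuple(ps["sirna_lengths"]))
        sq["partition_xrn1_del"] = partition_by_class(
            mappings["xrn1_del"].alignments, genome.loci, tuple(ps["sirna_lengths"]))
        comp = composition_stats(mappings["WT"].alignments)
        comp.first_nt.to_csv(out / "WT.first_nt.tsv", sep="\t")
        comp.length_counts.to_csv(out / "WT.length_hist.tsv", sep="\t")

        stage = "duplex_call"
        dq = report["stages"][stage] = {}
        pd_ = config.params["duplex"]
        strains = {c: filter_by_length(l.species) for c, l in libs.items()}
        calls = call_duplexes(strains, pseudocount=pd_["pseudocount"])
        calls_to_frame(calls, list(strains)).to_csv(
            out / "duplex_calls.tsv", sep="\t", index=False)
        dq["n_supported"] = len(calls)
        if len(calls) >= pd_["min_pairs"]:
            for which in ("full", "cleaved"):
                ra = passenger_ratio_analysis(
                    calls, ("xrn1_del", "WT"), which, pd_["pseudocount"],
                    pd_["min_pairs"])
                dq[f"{which}_median_shift"] = ra.test.median_shift
                dq[f"{which}_p_value"] = ra.test.p_value

        stage = "rnaseq_quant"
        rq = report["stages"][stage] = {}
        pr = config.params["rnaseq"]
        abund = {
            cond: quantify_loci(lib.species, index, genome.loci, mrna_spikes, cond)
            for cond, lib in rlibs.items()
        }
        abund = normalize_samples(abund, mrna_spikes, "WT")
        for cond, a in abund.items():
            a.table.to_csv(out / f"{cond}.rnaseq_abundance.tsv", sep="\t")
        pfc = precursor_fold_changes(abund["WT"], abund["xrn1_del"],
                                     pr["min_wt_tpm"])
        pfc.table.to_csv(out / "precursor_foldchange.tsv", sep="\t")
        rq["class_median_fold"] = pfc.class_medians.to_dict()
        corr = correlate_sirna_precursor(fc.table, pfc.table)
        rq["correlations"] = [
            dict(stratum=c.stratum, n=c.n, rho=c.rho, p=c.p_value,
                 n_both_positive=c.n_both_positive, defined=c.defined)
            for c in corr
        ]

        stage = "slice_asym"
        sa = report["stages"][stage] = []
        rmaps = {
            cond: map_reads(lib.species, index) for cond, lib in rlibs.items()
        }
        for gene in genome.slice_genes:
            ratios = {}
            for cond in ("WT", "xrn1_del"):
                cov = coverage_vector(
                    rmaps[cond].alignments, gene.chrom, gene.start, gene.end)
                ratios[cond] = slice_site_asymmetry(
                    cov, gene.site - gene.start, pr["flank"], gene.name)
            sa.append(dict(
                gene=gene.name,
                ratio_WT=ratios["WT"].ratio,
                ratio_xrn1_del=ratios["xrn1_del"].ratio,
                contrast=asymmetry_contrast(ratios["xrn1_del"], ratios["WT"]),
            ))
    except Exception:
        (out / f"FAILED_{stage}").touch()
        log.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None

    report["checksums"] = {
        p.name: _md5(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    report["checksums"]["genome.fa"] = _md5(out / "genome.fa")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
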