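"""Run orchestration: the two-step comparison workflow over a file bundle.

`run_full_analysis` ties the stages together the way the study design does:
step 1 runs the three pairwise comparisons, each restricted to the
intersection of the two capture designs; step 2 runs the three-way
confirmation inside the region shared by all platforms.  Coverage summaries,
per-gene low-coverage reports, allele-balance/depth analyses, genotype
discordance and exclusive-call annotation are emitted alongside, all as
deterministically sorted TSV/JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .abdp import ABDepthAnalysis
from .callsets import Callset, read_vcf, write_tsv
from .concord import (
    PairwiseConcordance,
    QualityCriteria,
    ThreeWayConcordance,
    annotate_fe,
    genotype_discordance,
)
from .coverage import (
    CoverageThresholds,
    flagged_genes,
    gc_windows,
    per_gene_low_fraction,
    read_depth_tsv,
    summarize,
    write_gene_report,
    write_histogram,
)
from .regions import RegionSet, intersect, read_bed, read_gene_bed

logger = logging.getLogger(__name__)


@dataclass
class SampleFiles:
    vcf: str
    depth_tsv: Optional[str] = None


@dataclass
class MethodFiles:
    capture_bed: str
    samples: dict[str, SampleFiles]


@dataclass
class RunConfig:
    """File layout and parameters for one analysis run."""

    methods: dict[str, MethodFiles]
    output_dir: str
    gene_bed: Optional[str] = None
    repeat_bed: Optional[str] = None
    reference_fasta: Optional[str] = None
    criteria: QualityCriteria = field(default_factory=QualityCriteria)
    coverage_cutoffs: CoverageThresholds = field(default_factory=CoverageThresholds)
    gc_threshold: float = 0.60
    gc_window: int = 100

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        methods = {
            m: MethodFiles(
                capture_bed=spec["capture_bed"],
                samples={
                    s: SampleFiles(**files) for s, files in spec["samples"].items()
                },
            )
            for m, spec in raw["methods"].items()
        }
        criteria = QualityCriteria(**raw["criteria"]) if "criteria" in raw else QualityCriteria()
        cutoffs = (
            CoverageThresholds(raw["coverage_cutoffs"])
            if "coverage_cutoffs" in raw
            else CoverageThresholds()
        )
        return cls(
            methods=methods,
            output_dir=raw["output_dir"],
            gene_bed=raw.get("gene_bed"),
            repeat_bed=raw.get("repeat_bed"),
            reference_fasta=raw.get("reference_fasta"),
            criteria=criteria,
            coverage_cutoffs=cutoffs,
            gc_threshold=raw.get("gc_threshold", 0.60),
            gc_window=raw.get("gc_window", 100),
        )


def _load_callsets(config: RunConfig) -> tuple[dict[str, RegionSet], dict[str, list[Callset]]]:
    captures = {m: read_bed(mf.capture_bed, label=m) for m, mf in config.methods.items()}
    callsets: dict[str, list[Callset]] = {}
    rosters = [sorted(mf.samples) for mf in config.methods.values()]
    common = set(rosters[0])
    for r in rosters[1:]:
        common &= set(r)
    skipped = set().union(*(set(r) for r in rosters)) - common
    for s in sorted(skipped):
        logger.warning("sample %s lacks data for some platform; skipped", s)
    if not common:
        raise ValueError("no sample has data for every platform")
    for m, mf in config.methods.items():
        callsets[m] = [
            read_vcf(mf.samples[s].vcf, capture=captures[m], method=m, sample=None)
            for s in sorted(common)
        ]
        # trust the configured sample id over the VCF column name
        for cs, s in zip(callsets[m], sorted(common)):
            cs.sample = s
    return captures, callsets


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full two-step workflow and write the report bundle."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    captures, callsets = _load_callsets(config)
    methods = list(config.methods)
    if len(methods) != 3:
        raise ValueError("the full analysis requires exactly three platforms")

    reference = None
    gc_rich = None
    if config.reference_fasta:
        from pyfaidx import Fasta

        reference = Fasta(config.reference_fasta, as_raw=True, sequence_always_upper=True)
        gc_rich = gc_windows(reference, window=config.gc_window, threshold=config.gc_threshold)
    repeats = read_bed(config.repeat_bed, label="repeats") if config.repeat_bed else None
    genes = read_gene_bed(config.gene_bed) if config.gene_bed else None

    manifest: dict = {
        "version": __version__,
        "methods": methods,
        "samples": sorted({cs.sample for lst in callsets.values() for cs in lst}),
        "criteria": {
            "min_depth": config.criteria.min_depth,
            "ab_low": config.criteria.ab_low,
            "ab_high": config.criteria.ab_high,
        },
        "region_bases": {},
    }

    # --- step 1: pairwise comparisons on pairwise-intersected captures
    pair_tables = []
    fe_calls_all = []
    hqfe_keys = set()
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    for mx, my in pairs:
        region = intersect(captures[mx], captures[my], label=f"{mx}&{my}")
        manifest["region_bases"][f"{mx}&{my}"] = region.total_bases
        res = PairwiseConcordance(
            callsets[mx], callsets[my], region=region, criteria=config.criteria
        ).fit()
        tab = res.median_table()
        tab.insert(0, "comparison", f"{mx} vs {my}")
        pair_tables.append(tab)
        res.tallies.to_csv(outdir / f"pairwise_{mx}_{my}_per_sample.tsv", sep="\t", index=False)
        fe_calls_all.extend(res.fe_calls())
        hqfe_keys |= {(c.method, c.sample, c.key) for c in res.hqfe_calls()}
    table1 = pd.concat(pair_tables, ignore_index=True)
    table1.to_csv(outdir / "pairwise_medians.tsv", sep="\t", index=False)

    # --- step 2: three-way confirmation in the triple-shared region
    triple = intersect(
        intersect(captures[methods[0]], captures[methods[1]]), captures[methods[2]],
        label="triple",
    )
    manifest["region_bases"]["triple"] = triple.total_bases
    three = ThreeWayConcordance(callsets, region=triple, criteria=config.criteria).fit()
    three.table().to_csv(outdir / "threeway_report.tsv", sep="\t")
    with open(outdir / "threeway_summary.txt", "w") as fh:
        fh.write(three.summary() + "\n")

    # --- discordant genotypes (within the triple region)
    disc_frames = []
    for sample in manifest["samples"]:
        trio = {
            m: next(cs for cs in callsets[m] if cs.sample == sample) for m in methods
        }
        d = genotype_discordance(trio, region=triple)
        if len(d):
            d.insert(0, "sample", sample)
            disc_frames.append(d)
    disc = (
        pd.concat(disc_frames, ignore_index=True)
        if disc_frames
        else pd.DataFrame(columns=["sample", "chrom", "pos", "ref", "alt", *methods])
    )
    disc.to_csv(outdir / "discordant_genotypes.tsv", sep="\t", index=False)

    # --- FE annotation (repeat / GC-rich context)
    ann = annotate_fe(fe_calls_all, repeats=repeats, gc_rich=gc_rich)
    ann["hqfe"] = [
        (r.method, r.sample, _key_from_row(r)) in hqfe_keys for r in ann.itertuples()
    ]
    ann = ann.sort_values(["method", "sample", "chrom", "pos"]).reset_index(drop=True)
    ann.to_csv(outdir / "fe_annotation.tsv", sep="\t", index=False)
    write_tsv(fe_calls_all, outdir / "fe_calls.tsv")

    # --- coverage and AB/DP per platform
    abdp_results = {}
    for m in methods:
        pooled = [c for cs in callsets[m] for c in cs.restrict(triple)]
        res = ABDepthAnalysis(pooled).fit()
        abdp_results[m] = res.to_json_dict()
        depth_files = [
            (s, config.methods[m].samples[s].depth_tsv)
            for s in manifest["samples"]
            if config.methods[m].samples[s].depth_tsv
        ]
        if depth_files:
            cutoff = config.coverage_cutoffs[m]
            summaries = []
            for s, path in depth_files:
                track = read_depth_tsv(path, m, s, captures[m])
                summ = summarize(track, cutoff)
                summaries.append((s, summ.mean, summ.median, summ.low_fraction))
                if genes:
                    rows = per_gene_low_fraction(track, genes, cutoff)
                    write_gene_report(rows, outdir / f"gene_coverage_{m}_{s}.tsv")
                write_histogram(summ, outdir / f"coverage_hist_{m}_{s}.tsv")
            pd.DataFrame(
                summaries, columns=["sample", "mean", "median", "low_fraction"]
            ).to_csv(outdir / f"coverage_summary_{m}.tsv", sep="\t", index=False)
    with open(outdir / "abdp.json", "w") as fh:
        json.dump(abdp_results, fh, indent=1, sort_keys=True)

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("full analysis written to %s in %.1fs", outdir, manifest["elapsed_s"])
    return {
        "table1": table1,
        "threeway": three,
        "discordance": disc,
        "annotation": ann,
        "manifest": manifest,
    }


def _key_from_row(row):
    from .callsets import VariantKey

    return VariantKey(row.chrom, row.pos, row.ref, row.alt)
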