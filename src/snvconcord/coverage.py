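"""Per-base depth summaries, per-gene low-coverage reporting, and GC content.

Depth is consumed pre-tabulated (3-column TSV: chrom, 1-based position,
depth), as written by standard depth utilities; positions absent from the
table but inside the region of interest count as depth 0.  "Low-covered" is
strict: a base is low-covered when its depth is strictly below the
platform's cutoff (10x for PCR-free whole-genome, 40x for capture assays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GeneModel, RegionSet, intersect

DEFAULT_CUTOFFS = {"WGS": 10, "WES": 40, "HES": 40}


@dataclass
class CoverageThresholds:
    """Per-platform low-coverage cutoffs (reads)."""

    cutoffs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self) -> None:
        for m, c in self.cutoffs.items():
            if c <= 0:
                raise ValueError(f"cutoff for {m} must be positive")

    def __getitem__(self, method: str) -> int:
        return self.cutoffs[method]


class DepthTrack:
    """Per-base read depth over a region set, in region order."""

    def __init__(self, method: str, sample: str, regions: RegionSet, depths):
        depths = np.asarray(depths)
        if depths.size != regions.total_bases:
            raise ValueError(
                f"{depths.size} depth values for {regions.total_bases} region bases"
            )
        if depths.size and depths.min() < 0:
            raise ValueError("negative depth")
        self.method = method
        self.sample = sample
        self.regions = regions
        self.depths = depths.astype(np.int64)

    def __len__(self) -> int:
        return len(self.depths)

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a 1-based position (0 outside the track's regions)."""
        off = pos - 1
        cursor = 0
        for iv in self.regions:
            if iv.chrom == chrom and iv.start <= off < iv.end:
                return int(self.depths[cursor + off - iv.start])
            cursor += len(iv)
        return 0

    def subset(self, region: RegionSet) -> np.ndarray:
        """Depths over ``region`` bases; bases outside the track are depth 0."""
        pos_to_depth = {}
        cursor = 0
        for iv in self.regions:
            for i, off in enumerate(range(iv.start, iv.end)):
                pos_to_depth[(iv.chrom, off)] = self.depths[cursor + i]
            cursor += len(iv)
        return np.array(
            [pos_to_depth.get(p, 0) for p in region.iter_positions()], dtype=np.int64
        )


@dataclass
class CoverageSummary:
    mean: float
    median: float
    low_fraction: float
    n_bases: int
    cutoff: int
    histogram: pd.Series  # depth -> base count, bin width 1


def summarize(track: DepthTrack, cutoff: int) -> CoverageSummary:
    """Mean/median depth, strict low-coverage fraction, and a width-1 histogram."""
    if len(track) == 0:
        raise ValueError("empty depth track")
    d = track.depths
    values, counts = np.unique(d, return_counts=True)
    hist = pd.Series(counts, index=values, name="bases")
    hist.index.name = "depth"
    return CoverageSummary(
        mean=float(d.mean()),
        median=float(np.median(d)),
        low_fraction=float((d < cutoff).mean()),
        n_bases=int(d.size),
        cutoff=int(cutoff),
        histogram=hist,
    )


@dataclass
class GeneCoverageRow:
    gene: str
    acmg_flag: bool
    low_fraction: float
    mean_depth: float
    n_bases: int


def per_gene_low_fraction(
    track: DepthTrack, genes: Sequence[GeneModel], cutoff: int
) -> list[GeneCoverageRow]:
    """One low-coverage row per gene; overlapping genes count independently.

    Gene bases outside the track's regions are treated as uncovered (depth 0).
    """
    rows = []
    for gene in genes:
        if gene.intervals.total_bases == 0:
            raise ValueError(f"gene {gene.symbol} spans zero bases")
        d = track.subset(gene.intervals)
        rows.append(
            GeneCoverageRow(
                gene=gene.symbol,
                acmg_flag=gene.acmg_flag,
                low_fraction=float((d < cutoff).mean()),
                mean_depth=float(d.mean()),
                n_bases=int(d.size),
            )
        )
    return rows


def gene_report_frame(rows: Iterable[GeneCoverageRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.gene, r.acmg_flag, r.low_fraction, r.mean_depth, r.n_bases) for r in rows],
        columns=["gene", "acmg_flag", "low_fraction", "mean_depth", "n_bases"],
    )
    return df.sort_values(["low_fraction", "gene"], ascending=[False, True]).reset_index(drop=True)


def flagged_genes(
    rows: Iterable[GeneCoverageRow], threshold: float = 0.10, acmg_threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Genes exceeding the low-coverage threshold; ACMG genes use a stricter one."""
    over = sorted(r.gene for r in rows if r.low_fraction > threshold)
    acmg_over = sorted(r.gene for r in rows if r.acmg_flag and r.low_fraction > acmg_threshold)
    return over, acmg_over


# ---------------------------------------------------------------------------
# GC content


def gc_content(regions: RegionSet, reference: Mapping[str, str]) -> float:
    """(G+C) / (A+C+G+T) over region bases; ambiguous bases excluded.

    ``reference`` maps chromosome name to sequence (a pyfaidx.Fasta works).
    """
    gc = acgt = 0
    for iv in regions:
        if iv.chrom not in reference:
            raise KeyError(f"chromosome {iv.chrom!r} absent from reference")
        seq = str(reference[iv.chrom][iv.start : iv.end]).upper()
        if len(seq) < len(iv):
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} extends past reference end"
            )
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases in regions")
    return gc / acgt


def gc_windows(
    reference: Mapping[str, str],
    window: int = 100,
    threshold: float = 0.60,
    chroms: Iterable[str] | None = None,
) -> RegionSet:
    """Merged fixed-width windows whose GC fraction exceeds ``threshold``.

    The last, possibly short, window of each chromosome is included if its
    GC fraction qualifies.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    from .regions import GenomicInterval, normalize

    hits = []
    names = list(chroms) if chroms is not None else list(_reference_keys(reference))
    for chrom in names:
        seq = str(reference[chrom][:]).upper()
        for start in range(0, len(seq), window):
            chunk = seq[start : start + window]
            acgt = sum(chunk.count(b) for b in "ACGT")
            if acgt == 0:
                continue
            gc = (chunk.count("G") + chunk.count("C")) / acgt
            if gc > threshold:
                hits.append(GenomicInterval(chrom, start, start + len(chunk)))
    return normalize(hits, label=f"GC>{threshold:g}")


def _reference_keys(reference: Mapping[str, str]) -> Iterable[str]:
    keys = getattr(reference, "keys", None)
    if callable(keys):
        return keys()
    raise TypeError("reference must expose .keys()")


# ---------------------------------------------------------------------------
# Depth TSV I/O


def read_depth_tsv(
    path: str | Path, method: str, sample: str, regions: RegionSet
) -> DepthTrack:
    """Read a (chrom, 1-based pos, depth) TSV into a track over ``regions``.

    Positions inside ``regions`` that are missing from the file get depth 0;
    positions outside ``regions`` are ignored.
    """
    table: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            table[(parts[0], int(parts[1]) - 1)] = int(parts[2])
    depths = [table.get(p, 0) for p in regions.iter_positions()]
    return DepthTrack(method, sample, regions, depths)


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        cursor = 0
        for iv in track.regions:
            for i, off in enumerate(range(iv.start, iv.end)):
                fh.write(f"{iv.chrom}\t{off + 1}\t{track.depths[cursor + i]}\n")
            cursor += len(iv)


def write_gene_report(rows: Iterable[GeneCoverageRow], path: str | Path) -> None:
    gene_report_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_histogram(summary: CoverageSummary, path: str | Path) -> None:
    summary.histogram.to_csv(path, sep="\t", header=True)
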