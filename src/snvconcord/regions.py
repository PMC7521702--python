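"""Genomic interval arithmetic and flat gene models.

Every comparison in the package is restricted to a region set: the capture
design of a probe-based assay (WES, HES), the pairwise intersection of two
designs, or the triple intersection shared by all platforms.  Intervals are
held 0-based half-open internally (the BED convention); VCF positions are
converted at the boundary.

Overlapping *and abutting* intervals are merged during normalisation, so a
``RegionSet`` is a canonical representation of a set of bases and
``total_bases`` is well defined.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """A normalised (sorted, merged, non-abutting) collection of intervals.

    Construct through :func:`normalize` or :meth:`RegionSet.from_intervals`
    unless the input is already canonical.
    """

    __slots__ = ("intervals", "label", "_index")

    def __init__(self, intervals: Sequence[GenomicInterval], label: str = ""):
        self.intervals: tuple[GenomicInterval, ...] = tuple(intervals)
        self.label = label
        # per-chromosome sorted start/end arrays for O(log n) membership
        index: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = index.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        self._index = index

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], label: str = ""
    ) -> "RegionSet":
        return normalize(intervals, label=label)

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self._index)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<RegionSet{lab}: {len(self.intervals)} intervals, {self.total_bases} bases>"

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (the VCF convention)."""
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        offset = pos - 1
        i = bisect.bisect_right(starts, offset) - 1
        return i >= 0 and offset < ends[i]

    def iter_positions(self) -> Iterator[tuple[str, int]]:
        """Yield every (chrom, 0-based offset) base in region order."""
        for iv in self.intervals:
            for off in range(iv.start, iv.end):
                yield iv.chrom, off


def normalize(intervals: Iterable[GenomicInterval], label: str = "") -> RegionSet:
    """Sort intervals and merge overlapping or abutting ones.

    Total base count is preserved for disjoint input; abutting intervals
    ([10,20), [20,30)) collapse to one.
    """
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return RegionSet(merged, label=label)


def _check_chrom_overlap(a: RegionSet, b: RegionSet) -> None:
    if a.intervals and b.intervals and not (a.chroms & b.chroms):
        warnings.warn(
            f"region sets {a.label or 'a'!r} and {b.label or 'b'!r} share no "
            "chromosome names; check naming conventions ('chr1' vs '1')",
            stacklevel=3,
        )


def intersect(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Bases present in both region sets."""
    _check_chrom_overlap(a, b)
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        j = 0
        others = by_chrom_b.get(iv.chrom, [])
        # two-pointer sweep within the chromosome
        lo = bisect.bisect_left([o.end for o in others], iv.start + 1)
        for o in others[lo:]:
            if o.start >= iv.end:
                break
            s, e = max(iv.start, o.start), min(iv.end, o.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return RegionSet(out, label=label)


def subtract(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Bases in ``a`` and not in ``b``."""
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        cursor = iv.start
        for o in by_chrom_b.get(iv.chrom, []):
            if o.end <= cursor or o.start >= iv.end:
                continue
            if o.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, o.start))
            cursor = max(cursor, o.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return RegionSet(out, label=label)


def contains(r: RegionSet, chrom: str, pos: int) -> bool:
    """Whether the 1-based position lies inside the region set."""
    return r.contains(chrom, pos)


@dataclass
class GeneModel:
    """A flat gene model: exons (plus flank) as a region set.

    ``acmg_flag`` marks genes on the ACMG SF v.2.0 secondary-findings list,
    which per-gene coverage reports highlight.
    """

    symbol: str
    intervals: RegionSet
    acmg_flag: bool = False

    def __post_init__(self) -> None:
        if not self.intervals.intervals:
            raise ValueError(f"gene {self.symbol!r} has no intervals")


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read a 3+ column BED file into a normalised RegionSet."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return normalize(ivs, label=label or str(path))


def write_bed(r: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in r:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_bed(path: str | Path, acmg_genes: set[str] | None = None) -> list[GeneModel]:
    """Read gene models from BED with the name column holding the symbol.

    Column 4 is the gene symbol; an optional column 5 value of ``ACMG``/``1``
    sets the flag explicitly, otherwise membership in ``acmg_genes``
    (default: the bundled ACMG SF v.2.0 study-gene list) is used.
    """
    if acmg_genes is None:
        acmg_genes = acmg_sf_genes()
    raw: dict[str, list[GenomicInterval]] = {}
    explicit: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs a name column")
            symbol = parts[3]
            raw.setdefault(symbol, []).append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            )
            if len(parts) >= 5 and parts[4] != ".":
                explicit[symbol] = parts[4] in ("ACMG", "1", "true", "True")
    genes = []
    for symbol, ivs in raw.items():
        flag = explicit.get(symbol, symbol in acmg_genes)
        genes.append(GeneModel(symbol, normalize(ivs, label=symbol), acmg_flag=flag))
    genes.sort(key=lambda g: g.symbol)
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            flag = "ACMG" if gene.acmg_flag else "."
            for iv in gene.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene.symbol}\t{flag}\n")


def acmg_sf_genes() -> set[str]:
    """The 20 ACMG SF v.2.0-listed genes among the 100 cardiac study genes."""
    text = resources.files("snvconcord").joinpath("data/acmg_sf_genes.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}
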