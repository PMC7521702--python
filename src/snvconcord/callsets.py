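"""Per-platform SNV call sets with the genotype/depth annotations the filters need.

A call set is one platform x one sample: the biallelic single-nucleotide
substitutions from that platform's VCF, keyed by (chrom, pos, ref, alt).
Genotype is *not* part of the key — two platforms calling the same locus with
different zygosity still share the locus, and the disagreement is reported by
the genotype-discordance analysis, not as an exclusive call.

Multi-allelic records are decomposed into biallelic records on ingest; indels,
MNVs and symbolic alleles are dropped (counted in ``Callset.dropped``).  No
FILTER screening is applied by default: exclusivity is defined on raw presence,
and quality enters only at the high-quality (HQFE) tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from cyvcf2 import VCF

from .regions import RegionSet

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

HET = "het"
HOM_ALT = "hom_alt"


@dataclass(frozen=True, order=True)
class VariantKey:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class VariantCall:
    key: VariantKey
    genotype: str  # HET or HOM_ALT
    depth: Optional[int]  # total site depth (DP); None = unknown
    ref_reads: Optional[int]
    alt_reads: Optional[int]
    method: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in (HET, HOM_ALT):
            raise ValueError(f"genotype must be het/hom_alt, got {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        if (
            self.depth is not None
            and self.ref_reads is not None
            and self.alt_reads is not None
            and self.ref_reads + self.alt_reads > self.depth
        ):
            raise ValueError("allele reads exceed total depth")

    @property
    def has_quality_fields(self) -> bool:
        return self.depth is not None and self.ref_reads is not None and self.alt_reads is not None


def allele_balance(call: VariantCall) -> Optional[float]:
    """Minor-allele fraction min(ref, alt) / (ref + alt), in [0, 0.5].

    Returns None when allele counts are unknown or sum to zero.
    """
    if call.ref_reads is None or call.alt_reads is None:
        return None
    total = call.ref_reads + call.alt_reads
    if total == 0:
        return None
    return min(call.ref_reads, call.alt_reads) / total


class Callset:
    """SNV calls for one (method, sample), at most one call per variant key."""

    def __init__(
        self,
        method: str,
        sample: str,
        calls: Iterable[VariantCall] = (),
        capture: RegionSet | None = None,
        dropped: dict[str, int] | None = None,
    ):
        self.method = method
        self.sample = sample
        self.capture = capture
        self.dropped = dict(dropped or {})
        self._calls: dict[VariantKey, VariantCall] = {}
        for c in calls:
            if c.key in self._calls:
                raise ValueError(f"duplicate call at {c.key}")
            self._calls[c.key] = c

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._calls.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._calls

    def __getitem__(self, key: VariantKey) -> VariantCall:
        return self._calls[key]

    def get(self, key: VariantKey) -> Optional[VariantCall]:
        return self._calls.get(key)

    @property
    def keys(self) -> set[VariantKey]:
        return set(self._calls)

    def sorted_calls(self) -> list[VariantCall]:
        return [self._calls[k] for k in sorted(self._calls)]

    def restrict(self, region: RegionSet) -> "Callset":
        """Keep only calls whose position lies in ``region``."""
        kept = [c for c in self if region.contains(c.key.chrom, c.key.pos)]
        return Callset(self.method, self.sample, kept, capture=self.capture,
                       dropped=self.dropped)


def restrict(cs: Callset, region: RegionSet) -> Callset:
    return cs.restrict(region)


# ---------------------------------------------------------------------------
# VCF ingest


def _map_genotype(alleles: list[int], alt_index: int) -> Optional[str]:
    # alleles: the two GT allele indices; alt_index: this alt's index (1-based)
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 2:
        return HOM_ALT
    if n_alt == 1:
        return HET
    return None


def read_vcf(
    path: str | Path,
    capture: RegionSet | None = None,
    method: str = "",
    sample: str | None = None,
    pass_only: bool = False,
) -> Callset:
    """Read one sample's SNV calls from a VCF.

    Multi-allelic records are decomposed per alternate allele; only
    single-nucleotide substitutions with a non-reference genotype survive.
    Records lacking DP/AD are retained with quality fields unknown (they can
    be exclusive calls but never high-quality ones).  ``pass_only`` optionally
    drops records with a non-PASS FILTER.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (genotypes required)")
    if sample is None:
        sample = samples[0]
    try:
        si = samples.index(sample)
    except ValueError:
        raise ValueError(f"{path}: sample {sample!r} not in VCF ({samples})") from None

    calls: list[VariantCall] = []
    dropped = {"non_snv": 0, "hom_ref_or_nocall": 0, "filtered": 0,
               "outside_capture": 0, "missing_quality_fields": 0}
    for rec in vcf:
        if pass_only and rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            dropped["filtered"] += 1
            continue
        gt = rec.genotypes[si]
        alleles = [a for a in gt[:-1] if isinstance(a, int)]
        if len(alleles) != 2 or any(a < 0 for a in alleles):
            dropped["hom_ref_or_nocall"] += 1
            continue
        try:
            dp_arr = rec.format("DP")
        except KeyError:
            dp_arr = None
        try:
            ad_arr = rec.format("AD")
        except KeyError:
            ad_arr = None
        depth = None
        if dp_arr is not None:
            v = int(dp_arr[si][0])
            depth = v if v >= 0 else None
        for ai, alt in enumerate(rec.ALT, start=1):
            if len(rec.REF) != 1 or len(alt) != 1 or rec.REF not in _BASES or alt not in _BASES:
                dropped["non_snv"] += 1
                continue
            genotype = _map_genotype(alleles, ai)
            if genotype is None:
                dropped["hom_ref_or_nocall"] += 1
                continue
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt)
            if capture is not None and not capture.contains(key.chrom, key.pos):
                dropped["outside_capture"] += 1
                continue
            ref_reads = alt_reads = None
            if ad_arr is not None and ad_arr.shape[1] > ai:
                r, a = int(ad_arr[si][0]), int(ad_arr[si][ai])
                if r >= 0 and a >= 0:
                    ref_reads, alt_reads = r, a
            d = depth
            if d is not None and ref_reads is not None and ref_reads + alt_reads > d:
                # inconsistent DP (common after decomposition); trust AD sum
                d = ref_reads + alt_reads
            if d is None or ref_reads is None:
                dropped["missing_quality_fields"] += 1
            calls.append(
                VariantCall(key, genotype, d, ref_reads, alt_reads,
                            method=method, sample=sample)
            )
    dropped = {k: v for k, v in dropped.items() if v}
    if dropped:
        logger.info("read_vcf(%s): dropped %s", path, dropped)
    return Callset(method, sample, calls, capture=capture, dropped=dropped)


# ---------------------------------------------------------------------------
# VCF / TSV output

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=snvconcord
##INFO=<ID=CATEGORY,Number=1,Type=String,Description="Concordance category (FE/HQFE/shared)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    sample: str,
    contigs: dict[str, int] | None = None,
    categories: dict[VariantKey, str] | None = None,
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 (GT:DP:AD)."""
    calls = sorted(calls, key=lambda c: c.key)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for c in calls:
            gt = "0/1" if c.genotype == HET else "1/1"
            dp = str(c.depth) if c.depth is not None else "."
            ad = (
                f"{c.ref_reads},{c.alt_reads}"
                if c.ref_reads is not None and c.alt_reads is not None
                else ".,."
            )
            info = "."
            if categories and c.key in categories:
                info = f"CATEGORY={categories[c.key]}"
            fh.write(
                f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t.\t.\t"
                f"{info}\tGT:DP:AD\t{gt}:{dp}:{ad}\n"
            )


def write_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tmethod\tsample\tgenotype\tdepth\tref_reads\talt_reads\tallele_balance\n")
        for c in sorted(calls, key=lambda c: (c.method, c.sample, c.key)):
            ab = allele_balance(c)
            fh.write(
                "\t".join(
                    [
                        c.key.chrom, str(c.key.pos), c.key.ref, c.key.alt,
                        c.method, c.sample, c.genotype,
                        "." if c.depth is None else str(c.depth),
                        "." if c.ref_reads is None else str(c.ref_reads),
                        "." if c.alt_reads is None else str(c.alt_reads),
                        "." if ab is None else f"{ab:.4f}",
                    ]
                )
                + "\n"
            )
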