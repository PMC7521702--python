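"""Three-platform sequencing simulator: truth sets, depth tracks, callsets.

The generator emulates the phenomenology the comparison framework assumes,
per platform:

* a per-base depth law — symmetric (normal) for PCR-free whole-genome
  sequencing, right-skewed (lognormal) for the capture assays;
* GC-dependent capture dropout — windows above a GC threshold lose depth
  with some probability, by a multiplicative attenuation;
* detection noise — a baseline false-negative rate, a hard depth floor below
  which a true variant is never called, and Poisson-placed false positives
  (enriched inside repeat regions);
* allele-level noise — capture/PCR allele bias at heterozygous sites,
  a small per-read minor-allele error rate at homozygous sites, and a
  caller-style zygosity label driven by the observed minor-allele fraction.

No reads are simulated; the output is exactly what the analysis consumes:
a callset (VCF-shaped) and a per-base depth track per platform and sample.
All randomness flows through substreams keyed by (master seed, platform,
sample), so adding a sample never perturbs another sample's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import substream
from .callsets import HET, HOM_ALT, Callset, VariantCall, VariantKey
from .coverage import DepthTrack
from .regions import GeneModel, GenomicInterval, RegionSet, intersect, normalize, subtract

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Platform profiles


@dataclass(frozen=True)
class NormalDepth:
    """Symmetric per-base depth: N(mean, sd), truncated at 0 and rounded."""

    mean_depth: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean_depth, self.sd, size=n)

    @property
    def mean(self) -> float:
        return self.mean_depth

    @property
    def median(self) -> float:
        return self.mean_depth


@dataclass(frozen=True)
class LognormalDepth:
    """Right-skewed per-base depth: exp(N(log_median, sigma))."""

    log_median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.log_median, self.sigma, size=n)

    @property
    def mean(self) -> float:
        return math.exp(self.log_median + self.sigma**2 / 2)

    @property
    def median(self) -> float:
        return math.exp(self.log_median)


@dataclass(frozen=True)
class GCDropout:
    """Capture dropout in high-GC windows.

    Each window with GC above ``threshold`` independently drops out with
    probability ``dropout_prob``; its bases keep ``attenuation`` of their
    drawn depth.
    """

    threshold: float = 0.60
    dropout_prob: float = 0.0
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_prob <= 1):
            raise ValueError("dropout_prob must be a probability")
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")


@dataclass(frozen=True)
class PlatformProfile:
    """Everything the simulator needs to emulate one sequencing platform."""

    name: str
    depth_law: NormalDepth | LognormalDepth
    gc_dropout: GCDropout = GCDropout()
    fn_base_rate: float = 0.0  # P(true variant uncalled) at adequate depth
    depth_fn_cutoff: int = 1  # below this depth a true variant is never called
    fp_rate: float = 0.0  # expected false calls per megabase of capture
    repeat_fp_multiplier: float = 1.0
    allele_bias: float = 1.0  # relative capture efficiency of the alt allele
    minor_read_rate: float = 0.0  # per-read minor-allele error rate at hom sites
    het_call_cutoff: float = 0.15  # minor fraction >= cutoff labels a call het

    def __post_init__(self) -> None:
        for p in (self.fn_base_rate, self.minor_read_rate, self.het_call_cutoff):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.allele_bias <= 0:
            raise ValueError("allele_bias must be positive")

    @property
    def het_alt_prob(self) -> float:
        """P(a read carries the alt allele) at a het site under the bias."""
        return self.allele_bias / (1.0 + self.allele_bias)


def default_profiles() -> dict[str, PlatformProfile]:
    """The three study-condition platform profiles.

    Depth laws are moment-matched to the platforms' printed coverage
    statistics (WGS mean = median 37; WES mean 332 / median 265; HES mean
    482 / median 431).  Minor-read rates are set so the expected fraction of
    homozygous calls with >= 1 minor read at the platform's mean depth
    matches the printed 2.7% / 10.5% / 21.2%:  epsilon = -ln(1 - f) / mean.
    False-negative and false-positive rates reflect the platforms' relative
    ordering of missed and unconfirmed exclusive calls.
    """
    return {
        "WGS": PlatformProfile(
            name="WGS",
            depth_law=NormalDepth(37.0, 10.0),
            gc_dropout=GCDropout(0.60, 0.0, 1.0),  # PCR-free: no capture dropout
            fn_base_rate=0.001,
            depth_fn_cutoff=4,
            fp_rate=9.0,
            repeat_fp_multiplier=2.0,
            allele_bias=1.0,
            minor_read_rate=7.4e-4,
            het_call_cutoff=0.15,
        ),
        "WES": PlatformProfile(
            name="WES",
            depth_law=LognormalDepth(math.log(265.0), 0.672),
            gc_dropout=GCDropout(0.60, 0.5, 0.10),
            fn_base_rate=0.002,
            depth_fn_cutoff=8,
            fp_rate=0.5,
            repeat_fp_multiplier=1.0,
            allele_bias=0.95,
            minor_read_rate=3.3e-4,
            het_call_cutoff=0.15,
        ),
        "HES": PlatformProfile(
            name="HES",
            depth_law=LognormalDepth(math.log(431.0), 0.473),
            gc_dropout=GCDropout(0.60, 0.7, 0.08),
            fn_base_rate=0.009,
            depth_fn_cutoff=8,
            fp_rate=7.0,
            repeat_fp_multiplier=5.0,
            allele_bias=0.85,
            minor_read_rate=4.9e-4,
            het_call_cutoff=0.15,
        ),
    }


def noiseless_profiles(depth: float = 150.0) -> dict[str, PlatformProfile]:
    """Error-free profiles for limit-case tests: deep, unbiased, no dropout."""
    out = {}
    for name in ("WGS", "WES", "HES"):
        out[name] = PlatformProfile(
            name=name,
            depth_law=NormalDepth(depth, depth / 10.0),
            gc_dropout=GCDropout(0.60, 0.0, 1.0),
            fn_base_rate=0.0,
            depth_fn_cutoff=1,
            fp_rate=0.0,
            repeat_fp_multiplier=1.0,
            allele_bias=1.0,
            minor_read_rate=0.0,
            het_call_cutoff=0.15,
        )
    return out


# ---------------------------------------------------------------------------
# Reference + gene models


@dataclass
class ReferenceBundle:
    """A synthetic reference with gene models, repeats, and capture designs."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: RegionSet
    captures: dict[str, RegionSet]
    gc_targets: dict[str, float]  # per-gene exon GC targets actually used
    flank: int

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def keys(self):
        return self.sequences.keys()

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


def _draw_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    # exact GC composition so planted GC targets are hit by construction
    n_gc = int(round(gc * n))
    strong = rng.choice(np.array(list("GC")), size=n_gc)
    weak = rng.choice(np.array(list("AT")), size=n - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def make_reference(
    n_genes: int = 20,
    exons_per_gene: int = 8,
    exon_size: int = 150,
    intron_size: int = 200,
    intergenic: int = 500,
    flank: int = 25,
    base_gc: float = 0.41,
    high_gc_genes: Sequence[float] = (0.73, 0.64, 0.69, 0.56),
    wes_omit_exon_fraction: float = 0.10,
    repeat_fraction: float = 0.05,
    n_chroms: int = 2,
    seed: int = 0,
) -> ReferenceBundle:
    """Build a synthetic reference with genes, repeats, and capture designs.

    Genes are laid out exon/intron alternating, separated by intergenic gaps,
    spread over ``n_chroms`` chromosomes.  The first ``len(high_gc_genes)``
    genes get exons drawn at the given elevated GC targets, mimicking the
    handful of GC-rich genes that capture assays cover poorly.  Capture
    designs: the targeted panel (HES) covers every exon plus ``flank`` bases
    of adjacent intron; the exome (WES) covers exons only and omits a random
    fraction of them; whole-genome (WGS) covers everything.
    """
    if min(n_genes, exons_per_gene, exon_size, intron_size, intergenic) <= 0:
        raise ValueError("all sizes must be positive")
    if flank < 0 or flank > intron_size // 2:
        raise ValueError("flank must fit inside the introns")
    rng = substream(seed, "reference")
    gc_targets: dict[str, float] = {}
    genes: list[GeneModel] = []
    hes_ivs: list[GenomicInterval] = []
    wes_ivs: list[GenomicInterval] = []
    repeat_ivs: list[GenomicInterval] = []
    sequences: dict[str, str] = {}

    per_chrom = math.ceil(n_genes / n_chroms)
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0
        while gi < n_genes and gi < (ci + 1) * per_chrom:
            symbol = f"GENE{gi + 1:03d}"
            gc = high_gc_genes[gi] if gi < len(high_gc_genes) else base_gc
            gc_targets[symbol] = gc
            parts.append(_draw_seq(rng, intergenic, base_gc))
            cursor += intergenic
            exon_ivs = []
            for ei in range(exons_per_gene):
                if ei > 0:
                    parts.append(_draw_seq(rng, intron_size, base_gc))
                    cursor += intron_size
                parts.append(_draw_seq(rng, exon_size, gc))
                exon_ivs.append(GenomicInterval(chrom, cursor, cursor + exon_size))
                cursor += exon_size
            model_ivs = [
                GenomicInterval(chrom, iv.start - flank, iv.end + flank) for iv in exon_ivs
            ]
            genes.append(GeneModel(symbol, normalize(model_ivs, label=symbol)))
            hes_ivs.extend(model_ivs)
            for iv in exon_ivs:
                if rng.random() >= wes_omit_exon_fraction:
                    wes_ivs.append(iv)
            gi += 1
        parts.append(_draw_seq(rng, intergenic, base_gc))
        cursor += intergenic
        sequences[chrom] = "".join(parts)
        # repeats: random blocks over the chromosome
        n_rep = max(1, int(repeat_fraction * cursor / 200))
        for _ in range(n_rep):
            start = int(rng.integers(0, max(1, cursor - 200)))
            repeat_ivs.append(GenomicInterval(chrom, start, min(cursor, start + 200)))

    wgs = normalize(
        [GenomicInterval(c, 0, len(s)) for c, s in sequences.items()], label="WGS"
    )
    captures = {
        "WGS": wgs,
        "WES": normalize(wes_ivs, label="WES"),
        "HES": normalize(hes_ivs, label="HES"),
    }
    return ReferenceBundle(
        sequences=sequences,
        genes=genes,
        repeats=normalize(repeat_ivs, label="repeats"),
        captures=captures,
        gc_targets=gc_targets,
        flank=flank,
    )


# ---------------------------------------------------------------------------
# Truth sets


@dataclass
class TruthSet:
    """Planted variant loci with per-sample diploid genotypes.

    ``genotypes`` maps (sample, key) -> 'het' | 'hom_alt'; absent pairs are
    homozygous reference.
    """

    samples: list[str]
    loci: list[VariantKey]
    genotypes: dict[tuple[str, VariantKey], str]
    captures: dict[str, RegionSet]
    reference: Optional[ReferenceBundle] = None
    repeats: Optional[RegionSet] = None

    def sample_keys(self, sample: str) -> list[VariantKey]:
        return [k for k in self.loci if (sample, k) in self.genotypes]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.loci):
            for s in self.samples:
                gt = self.genotypes.get((s, k))
                if gt:
                    rows.append((s, k.chrom, k.pos, k.ref, k.alt, gt))
        return pd.DataFrame(
            rows, columns=["sample", "chrom", "pos", "ref", "alt", "genotype"]
        )


def _sample_positions(rng: np.random.Generator, region: RegionSet, n: int) -> list[tuple[str, int]]:
    """Draw n distinct uniform bases (chrom, 0-based offset) from a region set."""
    lengths = np.array([len(iv) for iv in region.intervals], dtype=np.int64)
    if lengths.sum() == 0:
        return []
    n = min(n, int(lengths.sum()))
    cum = np.cumsum(lengths)
    chosen: set[tuple[str, int]] = set()
    while len(chosen) < n:
        draws = rng.integers(0, cum[-1], size=n - len(chosen))
        for g in draws:
            i = int(np.searchsorted(cum, g, side="right"))
            iv = region.intervals[i]
            off = int(g - (cum[i] - lengths[i]))
            chosen.add((iv.chrom, iv.start + off))
    return sorted(chosen)


def simulate_truth(
    reference: ReferenceBundle | RegionSet,
    n_samples: int = 10,
    snv_density: float = 1.0e-3,
    het_fraction: float = 0.6,
    carrier_prob: float = 0.8,
    seed: int = 0,
) -> TruthSet:
    """Plant SNV loci uniformly over the captured union and draw genotypes.

    The locus count is Poisson(density x union bases).  Each sample carries
    each locus with probability ``carrier_prob``; a carried locus is
    heterozygous with probability ``het_fraction``, else homozygous-alt.
    ``reference`` may be a plain RegionSet when no sequence context is
    needed (reference alleles are then drawn at random).
    """
    if snv_density <= 0:
        raise ValueError("snv_density must be positive")
    rng = substream(seed, "truth")
    if isinstance(reference, RegionSet):
        union = reference
        captures = {"WGS": reference, "WES": reference, "HES": reference}
        ref_bundle = None
        repeats = None
    else:
        ref_bundle = reference
        captures = reference.captures
        union = captures["WGS"]  # covers everything by construction
        repeats = reference.repeats
    n_loci = int(rng.poisson(snv_density * union.total_bases))
    positions = _sample_positions(rng, union, n_loci)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    loci: list[VariantKey] = []
    genotypes: dict[tuple[str, VariantKey], str] = {}
    for chrom, off in positions:
        if ref_bundle is not None:
            ref = ref_bundle.sequences[chrom][off]
        else:
            ref = str(rng.choice(_BASES))
        alts = [b for b in "ACGT" if b != ref]
        alt = str(rng.choice(alts))
        key = VariantKey(chrom, off + 1, ref, alt)
        loci.append(key)
        for s in samples:
            if rng.random() < carrier_prob:
                genotypes[(s, key)] = HET if rng.random() < het_fraction else HOM_ALT
    return TruthSet(
        samples=samples,
        loci=loci,
        genotypes=genotypes,
        captures=captures,
        reference=ref_bundle,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# Platform simulation


@dataclass
class SimulationRecord:
    """What the simulator actually did — the per-run planted truth."""

    fn_dropped: list[VariantKey] = field(default_factory=list)
    false_positives: list[VariantKey] = field(default_factory=list)
    genotype_errors: list[VariantKey] = field(default_factory=list)  # truth != label


def _window_gc(seq: str, window: int = 100) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    n_win = math.ceil(len(seq) / window)
    out = np.empty(n_win)
    for w in range(n_win):
        chunk = is_gc[w * window : (w + 1) * window]
        out[w] = chunk.mean() if chunk.size else 0.0
    return out


def simulate_depth(
    profile: PlatformProfile,
    regions: RegionSet,
    reference: ReferenceBundle | None = None,
    rng: np.random.Generator | None = None,
    sample: str = "",
    gc_window: int = 100,
) -> DepthTrack:
    """Draw a per-base depth track over ``regions`` under the profile.

    GC dropout applies only when a reference is supplied: each high-GC
    window independently attenuates for this (platform, sample) run.
    """
    rng = rng if rng is not None else np.random.default_rng()
    drop = profile.gc_dropout
    window_state: dict[str, np.ndarray] = {}
    if reference is not None and drop.dropout_prob > 0:
        for chrom, seq in reference.sequences.items():
            gc = _window_gc(seq, gc_window)
            dropped = (gc > drop.threshold) & (rng.random(gc.size) < drop.dropout_prob)
            window_state[chrom] = dropped
    chunks = []
    for iv in regions:
        d = profile.depth_law.sample(rng, len(iv))
        dropped = window_state.get(iv.chrom)
        if dropped is not None:
            widx = np.arange(iv.start, iv.end) // gc_window
            widx = np.clip(widx, 0, dropped.size - 1)
            d = np.where(dropped[widx], d * drop.attenuation, d)
        chunks.append(np.maximum(np.rint(d), 0).astype(np.int64))
    depths = np.concatenate(chunks) if chunks else np.array([], dtype=np.int64)
    return DepthTrack(profile.name, sample, regions, depths)


def _depth_lookup(track: DepthTrack) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chrom (starts, ends, cumulative offsets) for O(log n) site depth."""
    by_chrom: dict[str, tuple[list, list, list]] = {}
    cursor = 0
    for iv in track.regions:
        s, e, o = by_chrom.setdefault(iv.chrom, ([], [], []))
        s.append(iv.start)
        e.append(iv.end)
        o.append(cursor)
        cursor += len(iv)
    return {
        c: (np.array(s), np.array(e), np.array(o)) for c, (s, e, o) in by_chrom.items()
    }


def _site_depth(lookup, track: DepthTrack, chrom: str, pos: int) -> int:
    entry = lookup.get(chrom)
    if entry is None:
        return 0
    starts, ends, offs = entry
    i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
    if i < 0 or pos - 1 >= ends[i]:
        return 0
    return int(track.depths[offs[i] + (pos - 1) - starts[i]])


def simulate_platform(
    truth: TruthSet,
    profile: PlatformProfile,
    sample: str,
    seed: int = 0,
) -> tuple[Callset, DepthTrack, SimulationRecord]:
    """Simulate one platform x sample: depth track plus called variants.

    At each true variant site inside the platform's capture, alt-supporting
    reads are Binomial(depth, p) with p = bias/(1+bias) for hets and
    p = 1 - epsilon for hom-alts.  The site goes uncalled when depth falls
    below the hard floor, no alt read is seen, the baseline false-negative
    coin fires, or the observed alt fraction stays below the het-call cutoff
    with the reference allele in the majority.  The zygosity label is het
    when the minor-allele fraction reaches the cutoff, hom-alt otherwise.
    False positives arrive as a Poisson stream over capture megabases,
    multiplied inside repeats.
    """
    rng = substream(seed, "platform", profile.name, sample)
    capture = truth.captures[profile.name]
    track = simulate_depth(profile, capture, truth.reference, rng, sample=sample)
    lookup = _depth_lookup(track)
    record = SimulationRecord()
    calls: dict[VariantKey, VariantCall] = {}

    for key in truth.loci:
        gt = truth.genotypes.get((sample, key))
        if gt is None or not capture.contains(key.chrom, key.pos):
            continue
        depth = _site_depth(lookup, track, key.chrom, key.pos)
        if depth < profile.depth_fn_cutoff:
            record.fn_dropped.append(key)
            continue
        if rng.random() < profile.fn_base_rate:
            record.fn_dropped.append(key)
            continue
        p_alt = profile.het_alt_prob if gt == HET else 1.0 - profile.minor_read_rate
        alt_reads = int(rng.binomial(depth, p_alt))
        ref_reads = depth - alt_reads
        if alt_reads == 0:
            record.fn_dropped.append(key)
            continue
        minor_frac = min(ref_reads, alt_reads) / depth
        if minor_frac >= profile.het_call_cutoff:
            label = HET
        elif alt_reads > ref_reads:
            label = HOM_ALT
        else:
            # too few alt reads to call a variant at all
            record.fn_dropped.append(key)
            continue
        if label != gt:
            record.genotype_errors.append(key)
        calls[key] = VariantCall(
            key, label, depth, ref_reads, alt_reads, method=profile.name, sample=sample
        )

    _place_false_positives(rng, profile, truth, capture, track, lookup, calls, record, sample)

    callset = Callset(
        profile.name, sample, calls.values(), capture=capture
    )
    return callset, track, record


def _place_false_positives(rng, profile, truth, capture, track, lookup, calls, record, sample):
    if profile.fp_rate <= 0:
        return
    repeats = truth.repeats if truth.repeats is not None else RegionSet([])
    in_rep = intersect(capture, repeats)
    plain = subtract(capture, repeats)
    occupied = {(k.chrom, k.pos) for k in truth.loci} | {
        (k.chrom, k.pos) for k in calls
    }
    for region, rate in (
        (plain, profile.fp_rate),
        (in_rep, profile.fp_rate * profile.repeat_fp_multiplier),
    ):
        mb = region.total_bases / 1e6
        n = int(rng.poisson(rate * mb))
        if n == 0:
            continue
        for chrom, off in _sample_positions(rng, region, n):
            pos = off + 1
            if (chrom, pos) in occupied:
                continue
            occupied.add((chrom, pos))
            if truth.reference is not None:
                ref = truth.reference.base_at(chrom, pos)
                if ref not in "ACGT":
                    continue
            else:
                ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            key = VariantKey(chrom, pos, ref, alt)
            depth = _site_depth(lookup, track, chrom, pos)
            if depth < profile.depth_fn_cutoff:
                continue
            alt_reads = int(rng.binomial(depth, 0.5))
            ref_reads = depth - alt_reads
            if alt_reads == 0:
                continue
            minor_frac = min(ref_reads, alt_reads) / depth
            label = HET if minor_frac >= profile.het_call_cutoff else (
                HOM_ALT if alt_reads > ref_reads else HET
            )
            calls[key] = VariantCall(
                key, label, depth, ref_reads, alt_reads,
                method=profile.name, sample=sample,
            )
            record.false_positives.append(key)


# ---------------------------------------------------------------------------
# Cohort fixture


@dataclass
class CohortBundle:
    """A complete three-platform, multi-sample synthetic study."""

    reference: ReferenceBundle
    truth: TruthSet
    profiles: dict[str, PlatformProfile]
    callsets: dict[str, list[Callset]]  # platform -> per-sample callsets
    tracks: dict[tuple[str, str], DepthTrack]  # (platform, sample) -> track
    records: dict[tuple[str, str], SimulationRecord]
    seed: int

    def record_frame(self) -> pd.DataFrame:
        """Every planted detection event: FN drops, FPs, genotype errors."""
        rows = []
        for (platform, sample), rec in sorted(self.records.items()):
            for kind, keys in (
                ("fn_dropped", rec.fn_dropped),
                ("false_positive", rec.false_positives),
                ("genotype_error", rec.genotype_errors),
            ):
                for k in keys:
                    rows.append((platform, sample, kind, k.chrom, k.pos, k.ref, k.alt))
        return pd.DataFrame(
            rows, columns=["platform", "sample", "event", "chrom", "pos", "ref", "alt"]
        )


def make_cohort_fixture(
    seed: int = 0,
    n_samples: int = 10,
    n_genes: int = 20,
    snv_density: float = 1.0e-3,
    noiseless: bool = False,
    profiles: Mapping[str, PlatformProfile] | None = None,
    reference: ReferenceBundle | None = None,
) -> CohortBundle:
    """Generate the standard end-to-end test cohort (deterministic per seed)."""
    if reference is None:
        reference = make_reference(n_genes=n_genes, seed=seed)
    if profiles is None:
        profiles = noiseless_profiles() if noiseless else default_profiles()
    truth = simulate_truth(reference, n_samples=n_samples, snv_density=snv_density, seed=seed)
    callsets: dict[str, list[Callset]] = {m: [] for m in profiles}
    tracks: dict[tuple[str, str], DepthTrack] = {}
    records: dict[tuple[str, str], SimulationRecord] = {}
    for m, profile in profiles.items():
        for sample in truth.samples:
            cs, track, rec = simulate_platform(truth, profile, sample, seed=seed)
            callsets[m].append(cs)
            tracks[(m, sample)] = track
            records[(m, sample)] = rec
    return CohortBundle(
        reference=reference,
        truth=truth,
        profiles=dict(profiles),
        callsets=callsets,
        tracks=tracks,
        records=records,
        seed=seed,
    )


def plant_genotype_flips(cs: Callset, keys: Iterable[VariantKey]) -> Callset:
    """Return a copy of the callset with zygosity flipped at the given keys."""
    flipped = []
    keys = set(keys)
    for c in cs:
        if c.key in keys:
            c = replace(c, genotype=HOM_ALT if c.genotype == HET else HET)
        flipped.append(c)
    return Callset(cs.method, cs.sample, flipped, capture=cs.capture, dropped=cs.dropped)


def write_fasta(reference: ReferenceBundle, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
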