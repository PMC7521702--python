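"""Pairwise and three-way SNV concordance: exclusivity, confirmation, sensitivity.

The comparison design has two steps.  Step 1 compares each pair of platforms
inside the intersection of their capture regions: an SNV called by exactly one
platform of the pair is *fully exclusive* (FE) — no quality filter is applied
to earn that label.  FE calls that additionally meet the platform's minimum
depth and, for heterozygotes, a balanced allele-balance window (0.2-0.5) are
*high-quality FE* (HQFE).  Step 2 moves to the region shared by all three
platforms: an FE call of platform X (vs. Y) that the third platform Z also
called is *confirmed*, and simultaneously a *missed variant* (MV) — a false
negative — of Y.  Sensitivity per platform is then

    100 x (confirmed_by_all + FE confirmed) / (confirmed_by_all + FE confirmed + MV)

and the HQFE tier repeats the bookkeeping with the quality-filtered exclusives.

Confirmation is presence-based: a genotype mismatch at a shared locus does not
block confirmation; it is surfaced separately by `genotype_discordance`.

The module exposes the individual operations as functions and wraps the two
analyses in model classes (`PairwiseConcordance`, `ThreeWayConcordance`) whose
``fit()`` returns Results objects with count tables, sensitivities, Wilson
confidence intervals and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._util import median_even_mean, round_half_up
from .callsets import HET, Callset, VariantCall, VariantKey, allele_balance
from .regions import RegionSet, intersect

DEFAULT_MIN_DEPTH = {"WGS": 10, "WES": 40, "HES": 40}


@dataclass
class QualityCriteria:
    """HQFE filter: per-platform minimum depth and het allele-balance window.

    Depth is inclusive (depth >= cutoff passes).  The allele-balance window
    [ab_low, ab_high] applies to heterozygous calls only; homozygous-alt
    exclusives pass on depth alone.  Calls with unknown depth or allele
    counts never pass.
    """

    min_depth: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MIN_DEPTH))
    ab_low: float = 0.2
    ab_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.ab_low < self.ab_high <= 0.5):
            raise ValueError("require 0 <= ab_low < ab_high <= 0.5")
        for m, d in self.min_depth.items():
            if d <= 0:
                raise ValueError(f"min_depth for {m} must be positive")

    def depth_for(self, method: str) -> int:
        return self.min_depth[method]

    def passes(self, call: VariantCall) -> bool:
        if not call.has_quality_fields:
            return False
        if call.depth < self.depth_for(call.method):
            return False
        if call.genotype == HET:
            ab = allele_balance(call)
            if ab is None or not (self.ab_low <= ab <= self.ab_high):
                return False
        return True


def hqfe_filter(fe_calls: Iterable[VariantCall], criteria: QualityCriteria) -> list[VariantCall]:
    """The subset of exclusive calls passing the high-quality criteria."""
    return [c for c in fe_calls if criteria.passes(c)]


# ---------------------------------------------------------------------------
# Step 1: pairwise comparison


@dataclass
class PairwiseComparison:
    """Shared and exclusive calls for one (method_x, method_y, sample)."""

    method_x: str
    method_y: str
    sample: str
    region: RegionSet
    shared: set[VariantKey]
    fe_x: list[VariantCall]
    fe_y: list[VariantCall]
    hqfe_x: list[VariantCall]
    hqfe_y: list[VariantCall]
    n_x: int  # total calls of x in region
    n_y: int

    def tallies(self) -> pd.DataFrame:
        rows = [
            (self.sample, self.method_x, self.n_x, len(self.fe_x), len(self.hqfe_x)),
            (self.sample, self.method_y, self.n_y, len(self.fe_y), len(self.hqfe_y)),
        ]
        return pd.DataFrame(rows, columns=["sample", "method", "snvs", "fe", "hqfe"])


def pairwise_compare(
    x: Callset,
    y: Callset,
    region: RegionSet,
    criteria: QualityCriteria | None = None,
) -> PairwiseComparison:
    """Classify each platform's calls in ``region`` as shared or exclusive."""
    if x.sample != y.sample:
        raise ValueError(f"sample mismatch: {x.sample!r} vs {y.sample!r}")
    criteria = criteria or QualityCriteria()
    rx, ry = x.restrict(region), y.restrict(region)
    shared = rx.keys & ry.keys
    fe_x = [rx[k] for k in sorted(rx.keys - shared)]
    fe_y = [ry[k] for k in sorted(ry.keys - shared)]
    return PairwiseComparison(
        method_x=x.method,
        method_y=y.method,
        sample=x.sample,
        region=region,
        shared=shared,
        fe_x=fe_x,
        fe_y=fe_y,
        hqfe_x=hqfe_filter(fe_x, criteria),
        hqfe_y=hqfe_filter(fe_y, criteria),
        n_x=len(rx),
        n_y=len(ry),
    )


# ---------------------------------------------------------------------------
# Step 2: three-way confirmation


_COUNT_COLS = [
    "total_detected",
    "confirmed_by_all",
    "fe",
    "fe_confirmed",
    "fe_not_confirmed",
    "missed",
    "hqfe",
    "hqfe_confirmed",
    "hqfe_not_confirmed",
    "hqfe_missed",
]


def sensitivity(confirmed_by_all: int, confirmed_exclusive: int, missed: int) -> float:
    """True positive rate in percent, rounded to one decimal (half away from zero)."""
    num = confirmed_by_all + confirmed_exclusive
    den = num + missed
    if den == 0:
        raise ValueError("sensitivity undefined: no true positives")
    return round_half_up(100.0 * num / den, 1)


def three_way_counts(
    callsets: Mapping[str, Callset],
    region: RegionSet,
    criteria: QualityCriteria | None = None,
) -> pd.DataFrame:
    """Per-platform FE/HQFE confirmation counts for one sample, per key.

    Each key inside ``region`` falls in one of seven presence patterns over
    the three platforms:

    * present in all three       -> confirmed_by_all for every platform;
    * present in exactly two     -> FE of each caller (vs. the absent one),
      confirmed by the other caller; an MV of the absent platform;
    * present in exactly one     -> FE of the caller, not confirmed.

    The HQFE tier re-runs the bookkeeping with quality-filtered exclusives;
    a two-caller key is an HQFE-tier MV of the absent platform when either
    caller's exclusive call passes the quality criteria.
    """
    criteria = criteria or QualityCriteria()
    methods = list(callsets)
    if len(methods) != 3:
        raise ValueError("three-way comparison needs exactly three callsets")
    samples = {cs.sample for cs in callsets.values()}
    if len(samples) != 1:
        raise ValueError(f"callsets from different samples: {sorted(samples)}")
    for m, cs in callsets.items():
        if cs.capture is not None and intersect(region, cs.capture).total_bases != region.total_bases:
            raise ValueError(f"comparison region not contained in {m} capture")
    restricted = {m: cs.restrict(region) for m, cs in callsets.items()}
    tally = {m: dict.fromkeys(_COUNT_COLS, 0) for m in methods}
    all_keys = set().union(*(cs.keys for cs in restricted.values()))
    for key in all_keys:
        present = [m for m in methods if key in restricted[m]]
        if len(present) == 3:
            for m in methods:
                tally[m]["total_detected"] += 1
                tally[m]["confirmed_by_all"] += 1
        elif len(present) == 2:
            absent = next(m for m in methods if m not in present)
            hq = {m: criteria.passes(restricted[m][key]) for m in present}
            for m in present:
                t = tally[m]
                t["total_detected"] += 1
                t["fe"] += 1
                t["fe_confirmed"] += 1
                if hq[m]:
                    t["hqfe"] += 1
                    t["hqfe_confirmed"] += 1
            tally[absent]["missed"] += 1
            if any(hq.values()):
                tally[absent]["hqfe_missed"] += 1
        else:
            t = tally[present[0]]
            t["total_detected"] += 1
            t["fe"] += 1
            t["fe_not_confirmed"] += 1
            if criteria.passes(restricted[present[0]][key]):
                t["hqfe"] += 1
                t["hqfe_not_confirmed"] += 1
    counts = pd.DataFrame.from_dict(tally, orient="index")[_COUNT_COLS].astype(int)
    counts.index.name = "method"
    return counts.reindex(methods)


# ---------------------------------------------------------------------------
# Genotype discordance and FE annotation


def genotype_discordance(
    callsets: Mapping[str, Callset], region: RegionSet | None = None
) -> pd.DataFrame:
    """Loci called by >= 2 platforms whose genotype labels disagree.

    Returns a frame with one row per discordant key and one genotype column
    per platform ('.' where the platform did not call the locus).
    """
    methods = list(callsets)
    restricted = {
        m: (cs.restrict(region) if region is not None else cs) for m, cs in callsets.items()
    }
    rows = []
    all_keys = set().union(*(cs.keys for cs in restricted.values()))
    for key in sorted(all_keys):
        gts = {m: restricted[m][key].genotype for m in methods if key in restricted[m]}
        if len(gts) >= 2 and len(set(gts.values())) > 1:
            rows.append(
                [key.chrom, key.pos, key.ref, key.alt]
                + [gts.get(m, ".") for m in methods]
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *methods])


def annotate_fe(
    fe_calls: Iterable[VariantCall],
    repeats: RegionSet | None = None,
    gc_rich: RegionSet | None = None,
) -> pd.DataFrame:
    """Tag exclusive calls with repeat / GC-rich context; one row per call."""
    rows = []
    for c in sorted(fe_calls, key=lambda c: (c.method, c.sample, c.key)):
        in_repeat = repeats.contains(c.key.chrom, c.key.pos) if repeats is not None else False
        in_gc = gc_rich.contains(c.key.chrom, c.key.pos) if gc_rich is not None else False
        ab = allele_balance(c)
        rows.append(
            (
                c.key.chrom, c.key.pos, c.key.ref, c.key.alt, c.method, c.sample,
                c.genotype, c.depth, None if ab is None else round(ab, 4),
                in_repeat, in_gc,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "method", "sample", "genotype",
            "depth", "allele_balance", "in_repeat", "in_gc_rich",
        ],
    )


def median_summary(tallies: pd.DataFrame) -> pd.DataFrame:
    """Cohort medians of per-sample SNV/FE/HQFE tallies, with percentages.

    ``tallies`` has one row per (sample, method) with columns
    sample/method/snvs/fe/hqfe.  Medians use the mean-of-central-pair
    convention for even cohorts; FE%% and HQFE%% are each exclusive-call
    median over SNV median, rounded to one decimal half-away-from-zero.
    """
    rows = []
    for method, grp in tallies.groupby("method", sort=False):
        med_snv = median_even_mean(grp["snvs"])
        med_fe = median_even_mean(grp["fe"])
        med_hqfe = median_even_mean(grp["hqfe"])
        rows.append(
            (
                method, med_snv, med_fe,
                round_half_up(100 * med_fe / med_snv, 1) if med_snv else float("nan"),
                med_hqfe,
                round_half_up(100 * med_hqfe / med_snv, 1) if med_snv else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["method", "median_snvs", "median_fe", "fe_pct", "median_hqfe", "hqfe_pct"]
    )


# ---------------------------------------------------------------------------
# Model / Results


class PairwiseConcordance:
    """Step-1 model: one platform pair over a sample cohort.

    Parameters
    ----------
    callsets_x, callsets_y
        One callset per sample for each platform (same sample order is not
        required; samples are matched by id).
    region
        Comparison region; defaults to the intersection of the two capture
        sets attached to the callsets.
    criteria
        HQFE quality criteria; defaults to the standard thresholds
        (WGS 10x, WES/HES 40x, AB window 0.2-0.5).
    """

    def __init__(
        self,
        callsets_x: Sequence[Callset] | Callset,
        callsets_y: Sequence[Callset] | Callset,
        region: RegionSet | None = None,
        criteria: QualityCriteria | None = None,
    ):
        xs = [callsets_x] if isinstance(callsets_x, Callset) else list(callsets_x)
        ys = [callsets_y] if isinstance(callsets_y, Callset) else list(callsets_y)
        by_sample_y = {cs.sample: cs for cs in ys}
        self.pairs = []
        for cx in xs:
            if cx.sample not in by_sample_y:
                raise ValueError(f"no {ys[0].method} callset for sample {cx.sample!r}")
            self.pairs.append((cx, by_sample_y[cx.sample]))
        if region is None:
            cap_x, cap_y = xs[0].capture, ys[0].capture
            if cap_x is None or cap_y is None:
                raise ValueError("region not given and callsets carry no capture sets")
            region = intersect(cap_x, cap_y, label=f"{xs[0].method}&{ys[0].method}")
        self.region = region
        self.criteria = criteria or QualityCriteria()
        self.method_x = xs[0].method
        self.method_y = ys[0].method

    def fit(self) -> "PairwiseConcordanceResults":
        comparisons = [
            pairwise_compare(cx, cy, self.region, self.criteria) for cx, cy in self.pairs
        ]
        return PairwiseConcordanceResults(self, comparisons)


class PairwiseConcordanceResults:
    """Per-sample tallies and cohort medians for one platform pair."""

    def __init__(self, model: PairwiseConcordance, comparisons: list[PairwiseComparison]):
        self.model = model
        self.comparisons = comparisons
        self.tallies = pd.concat([c.tallies() for c in comparisons], ignore_index=True)

    @property
    def region_bases(self) -> int:
        return self.model.region.total_bases

    def median_table(self) -> pd.DataFrame:
        return median_summary(self.tallies)

    def fe_calls(self, method: str | None = None) -> list[VariantCall]:
        out = []
        for c in self.comparisons:
            out.extend(c.fe_x if method in (None, c.method_x) else [])
            out.extend(c.fe_y if method in (None, c.method_y) else [])
        return out

    def hqfe_calls(self, method: str | None = None) -> list[VariantCall]:
        out = []
        for c in self.comparisons:
            out.extend(c.hqfe_x if method in (None, c.method_x) else [])
            out.extend(c.hqfe_y if method in (None, c.method_y) else [])
        return out

    def summary(self) -> str:
        lines = [
            f"Pairwise concordance: {self.model.method_x} vs {self.model.method_y}",
            f"Comparison region: {self.region_bases:,} bases"
            f" ({len(self.model.region)} intervals)",
            f"Samples: {len(self.comparisons)}",
            "",
            self.median_table().to_string(index=False),
        ]
        return "\n".join(lines)


class ThreeWayConcordance:
    """Step-2 model: FE/HQFE confirmation and sensitivity over three platforms.

    Parameters
    ----------
    callsets
        Mapping of platform label -> callset or list of per-sample callsets.
    region
        Triple-shared region; defaults to the intersection of the three
        capture sets attached to the callsets.
    criteria
        HQFE quality criteria.
    """

    def __init__(
        self,
        callsets: Mapping[str, Sequence[Callset] | Callset],
        region: RegionSet | None = None,
        criteria: QualityCriteria | None = None,
    ):
        self.callsets: dict[str, list[Callset]] = {
            m: ([cs] if isinstance(cs, Callset) else list(cs)) for m, cs in callsets.items()
        }
        if len(self.callsets) != 3:
            raise ValueError("three-way comparison needs exactly three platforms")
        self.methods = list(self.callsets)
        samples = None
        for m, lst in self.callsets.items():
            s = sorted(cs.sample for cs in lst)
            if samples is None:
                samples = s
            elif s != samples:
                raise ValueError(f"platform {m} has a different sample roster")
        self.samples = samples or []
        if region is None:
            caps = [lst[0].capture for lst in self.callsets.values()]
            if any(c is None for c in caps):
                raise ValueError("region not given and callsets carry no capture sets")
            region = intersect(intersect(caps[0], caps[1]), caps[2], label="triple")
        self.region = region
        self.criteria = criteria or QualityCriteria()

    def fit(self) -> "ThreeWayResults":
        per_sample = {}
        for sample in self.samples:
            trio = {
                m: next(cs for cs in lst if cs.sample == sample)
                for m, lst in self.callsets.items()
            }
            per_sample[sample] = three_way_counts(trio, self.region, self.criteria)
        pooled = sum(per_sample.values())
        pooled = pooled.reindex(self.methods)
        return ThreeWayResults(pooled, per_sample=per_sample, model=self)


class ThreeWayResults:
    """Pooled confirmation counts and per-platform sensitivities.

    May also be built directly from a counts table (e.g. published counts)
    via :meth:`from_counts`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        per_sample: dict[str, pd.DataFrame] | None = None,
        model: ThreeWayConcordance | None = None,
    ):
        missing = [c for c in _COUNT_COLS if c not in counts.columns]
        if missing:
            raise ValueError(f"counts table lacks columns {missing}")
        self.counts = counts
        self.per_sample = per_sample or {}
        self.model = model
        self._check_identities()

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    ) -> "ThreeWayResults":
        """Build results from a {method: {column: count}} mapping.

        Missing HQFE-tier columns default to the FE-tier values being absent
        (zero); the identity total = confirmed_by_all + fe is filled in when
        total_detected is omitted.
        """
        df = pd.DataFrame(counts).T if not isinstance(counts, pd.DataFrame) else counts.copy()
        for col in _COUNT_COLS:
            if col not in df.columns:
                df[col] = 0
        if (df["total_detected"] == 0).all():
            df["total_detected"] = df["confirmed_by_all"] + df["fe"]
        df.index.name = "method"
        return cls(df[_COUNT_COLS].astype(int))

    def _check_identities(self) -> None:
        c = self.counts
        bad = c.index[c["total_detected"] != c["confirmed_by_all"] + c["fe"]]
        if len(bad):
            raise ValueError(f"count identity violated for {list(bad)}: total != confirmed + FE")
        bad = c.index[c["fe"] != c["fe_confirmed"] + c["fe_not_confirmed"]]
        if len(bad):
            raise ValueError(f"FE partition violated for {list(bad)}")

    @property
    def methods(self) -> list[str]:
        return list(self.counts.index)

    def sensitivity(self, method: str, tier: str = "fe") -> float:
        """Percent sensitivity for one platform, FE or HQFE tier."""
        row = self.counts.loc[method]
        if tier == "fe":
            return sensitivity(row["confirmed_by_all"], row["fe_confirmed"], row["missed"])
        if tier == "hqfe":
            return sensitivity(row["confirmed_by_all"], row["hqfe_confirmed"], row["hqfe_missed"])
        raise ValueError("tier must be 'fe' or 'hqfe'")

    def sensitivities(self, tier: str = "fe") -> dict[str, float]:
        return {m: self.sensitivity(m, tier) for m in self.methods}

    def conf_int(self, method: str, tier: str = "fe", alpha: float = 0.05) -> tuple[float, float]:
        """Wilson score interval for the sensitivity, in percent."""
        row = self.counts.loc[method]
        conf = row["fe_confirmed"] if tier == "fe" else row["hqfe_confirmed"]
        miss = row["missed"] if tier == "fe" else row["hqfe_missed"]
        num = int(row["confirmed_by_all"] + conf)
        den = int(num + miss)
        lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
        return 100 * lo, 100 * hi

    def table(self) -> pd.DataFrame:
        """The full report: counts plus sensitivities per tier."""
        out = self.counts.copy()
        out["sensitivity_fe_pct"] = [self.sensitivity(m, "fe") for m in self.methods]
        out["sensitivity_hqfe_pct"] = [self.sensitivity(m, "hqfe") for m in self.methods]
        return out

    def summary(self) -> str:
        lines = ["Three-way SNV detection performance"]
        if self.model is not None:
            lines.append(
                f"Triple-shared region: {self.model.region.total_bases:,} bases; "
                f"samples: {len(self.model.samples)}"
            )
        t = self.table().T
        lines += ["", t.to_string()]
        for tier in ("fe", "hqfe"):
            cis = {
                m: "%.1f-%.1f" % self.conf_int(m, tier) for m in self.methods
            }
            lines.append(f"{tier.upper()} sensitivity 95% CI (Wilson): {cis}")
        return "\n".join(lines)
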