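"""Allele-balance / read-depth stratification and trend tests.

Two phenomena tie allele balance (AB = minor reads / total allele reads) to
depth.  First, heterozygous sites drift away from the ideal AB of 0.5 when
depth is low, simply because a thin binomial sample is noisy — so AB and
depth are positively associated among het calls.  Second, homozygous-alt
sites acquire spurious minor-allele reads at a small per-read rate, and the
chance of seeing at least one grows with depth — so hom calls *with* a minor
read run deeper than those without.

The het analysis bins AB at width 0.1 (final bin closed at 0.5) and tests the
depth-AB association with a one-sided Spearman rank correlation; the hom
analysis splits on minor-allele presence and compares depths with a one-sided
Mann-Whitney U test.  Both are distribution-free, matching the quartile-level
summaries the stratification reports.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .callsets import HET, HOM_ALT, Callset, VariantCall, allele_balance

HET_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
HET_BIN_LABELS = ("[0,0.1)", "[0.1,0.2)", "[0.2,0.3)", "[0.3,0.4)", "[0.4,0.5]")


def het_bin(ab: float) -> str:
    """AB category for a heterozygous call; the last bin is closed at 0.5."""
    if not (0 <= ab <= 0.5):
        raise ValueError(f"allele balance {ab} outside [0, 0.5]")
    # bisect on the exact edges avoids float-division misassignment at 0.3
    i = min(bisect.bisect_right(HET_BIN_EDGES, ab) - 1, 4)
    return HET_BIN_LABELS[i]


@dataclass
class ABStratification:
    """Per-bin SNV fractions and depth summaries, split by genotype class."""

    het_table: pd.DataFrame  # bin, n, percent, depth quartiles
    hom_table: pd.DataFrame  # minor-allele presence, n, percent, depth quartiles
    n_het: int
    n_hom: int

    @property
    def empty(self) -> bool:
        return self.n_het == 0 and self.n_hom == 0

    @property
    def hom_minor_fraction(self) -> float:
        """Fraction of homozygous-alt calls carrying >= 1 minor-allele read."""
        if self.n_hom == 0:
            raise ValueError("no homozygous calls")
        row = self.hom_table.set_index("group")
        n_with = row.loc["minor_reads", "n"] if "minor_reads" in row.index else 0
        return n_with / self.n_hom

    @property
    def balanced_het_fraction(self) -> float:
        """Fraction of het calls in the balanced top bin [0.4, 0.5]."""
        if self.n_het == 0:
            raise ValueError("no heterozygous calls")
        t = self.het_table.set_index("bin")
        return (t.loc["[0.4,0.5]", "n"] / self.n_het) if "[0.4,0.5]" in t.index else 0.0


def _depth_quartiles(depths: np.ndarray) -> tuple[float, float, float]:
    if depths.size == 0:
        return (float("nan"),) * 3
    q1, q2, q3 = np.percentile(depths, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def _eligible(cs: Iterable[VariantCall]) -> list[tuple[VariantCall, float, int]]:
    out = []
    for c in cs:
        ab = allele_balance(c)
        if ab is None or c.depth is None:
            continue
        out.append((c, ab, c.depth))
    return out


def stratify(cs: Callset | Iterable[VariantCall]) -> ABStratification:
    """Bin calls by AB category (het) or minor-allele presence (hom).

    Calls with unknown AB or depth are excluded.  An empty stratification is
    returned (flagged via ``.empty``) when no call is eligible.
    """
    triples = _eligible(cs)
    het = [(ab, d) for c, ab, d in triples if c.genotype == HET]
    hom = [(c, ab, d) for c, ab, d in triples if c.genotype == HOM_ALT]

    het_rows = []
    if het:
        by_bin: dict[str, list[int]] = {lab: [] for lab in HET_BIN_LABELS}
        for ab, d in het:
            by_bin[het_bin(ab)].append(d)
        for lab in HET_BIN_LABELS:
            depths = np.array(by_bin[lab])
            q1, q2, q3 = _depth_quartiles(depths)
            het_rows.append((lab, depths.size, 100.0 * depths.size / len(het), q1, q2, q3))
    het_table = pd.DataFrame(
        het_rows, columns=["bin", "n", "percent", "dp_q1", "dp_median", "dp_q3"]
    )

    hom_rows = []
    if hom:
        groups = {"no_minor_reads": [], "minor_reads": []}
        for c, ab, d in hom:
            minor = min(c.ref_reads, c.alt_reads)
            groups["minor_reads" if minor > 0 else "no_minor_reads"].append(d)
        for lab in ("no_minor_reads", "minor_reads"):
            depths = np.array(groups[lab])
            q1, q2, q3 = _depth_quartiles(depths)
            hom_rows.append((lab, depths.size, 100.0 * depths.size / len(hom), q1, q2, q3))
    hom_table = pd.DataFrame(
        hom_rows, columns=["group", "n", "percent", "dp_q1", "dp_median", "dp_q3"]
    )
    return ABStratification(het_table, hom_table, n_het=len(het), n_hom=len(hom))


@dataclass
class TrendTestResult:
    statistic: float
    p_value: float
    n: int
    significant: bool  # p < 0.05, one-sided in the stated direction
    direction: str


def ab_dp_trend(calls: Callset | Iterable[VariantCall], min_n: int = 10) -> TrendTestResult:
    """One-sided Spearman test for depth increasing with het allele balance."""
    pts = [(ab, d) for c, ab, d in _eligible(calls) if c.genotype == HET]
    if len(pts) < min_n:
        raise ValueError(f"need >= {min_n} het calls with AB and depth, got {len(pts)}")
    ab, dp = zip(*pts)
    res = stats.spearmanr(ab, dp, alternative="greater")
    return TrendTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(pts),
        significant=bool(res.pvalue < 0.05),
        direction="DP increases with AB",
    )


@dataclass
class HomMinorTestResult:
    fraction_with_minor: float
    statistic: Optional[float]
    p_value: Optional[float]
    n_with: int
    n_without: int
    significant: Optional[bool]
    note: str = ""


def hom_minor_test(calls: Callset | Iterable[VariantCall], min_n: int = 10) -> HomMinorTestResult:
    """Minor-read fraction among hom-alt calls, plus a one-sided depth test.

    Tests whether hom calls *with* minor-allele reads run deeper than those
    without (Mann-Whitney U, one-sided).  With one group empty the fraction
    is still reported and the test is skipped.
    """
    hom = [(c, ab, d) for c, ab, d in _eligible(calls) if c.genotype == HOM_ALT]
    if len(hom) < min_n:
        raise ValueError(f"need >= {min_n} hom calls with AD and depth, got {len(hom)}")
    with_minor = [d for c, ab, d in hom if min(c.ref_reads, c.alt_reads) > 0]
    without = [d for c, ab, d in hom if min(c.ref_reads, c.alt_reads) == 0]
    frac = len(with_minor) / len(hom)
    if not with_minor or not without:
        return HomMinorTestResult(
            fraction_with_minor=frac,
            statistic=None, p_value=None,
            n_with=len(with_minor), n_without=len(without),
            significant=None,
            note="one group empty; depth test skipped",
        )
    res = stats.mannwhitneyu(with_minor, without, alternative="greater")
    return HomMinorTestResult(
        fraction_with_minor=frac,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_with=len(with_minor),
        n_without=len(without),
        significant=bool(res.pvalue < 0.05),
    )


class ABDepthAnalysis:
    """Model wrapper: stratification plus both tests for one callset."""

    def __init__(self, callset: Callset | Iterable[VariantCall], min_n: int = 10):
        self.calls = list(callset)
        self.min_n = min_n

    def fit(self) -> "ABDepthResults":
        strat = stratify(self.calls)
        trend = ab_dp_trend(self.calls, self.min_n) if strat.n_het >= self.min_n else None
        hom = hom_minor_test(self.calls, self.min_n) if strat.n_hom >= self.min_n else None
        return ABDepthResults(strat, trend, hom)


@dataclass
class ABDepthResults:
    stratification: ABStratification
    trend: Optional[TrendTestResult]
    hom_minor: Optional[HomMinorTestResult]

    def summary(self) -> str:
        s = self.stratification
        lines = ["Allele balance / read depth analysis", ""]
        if s.n_het:
            lines += [f"Heterozygous calls (n={s.n_het}):", s.het_table.to_string(index=False), ""]
        if s.n_hom:
            lines += [f"Homozygous-alt calls (n={s.n_hom}):", s.hom_table.to_string(index=False), ""]
        if self.trend:
            t = self.trend
            lines.append(
                f"DP-AB trend (Spearman, one-sided): rho={t.statistic:.3f}, "
                f"p={t.p_value:.3g}, n={t.n}, significant={t.significant}"
            )
        if self.hom_minor:
            h = self.hom_minor
            lines.append(
                f"Hom minor-read fraction: {100 * h.fraction_with_minor:.1f}% "
                f"({h.n_with}/{h.n_with + h.n_without})"
            )
            if h.p_value is not None:
                lines.append(
                    f"Depth, with- vs without-minor (Mann-Whitney, one-sided): "
                    f"U={h.statistic:.0f}, p={h.p_value:.3g}, significant={h.significant}"
                )
            elif h.note:
                lines.append(h.note)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        out: dict = {
            "n_het": self.stratification.n_het,
            "n_hom": self.stratification.n_hom,
            "het_bins": self.stratification.het_table.to_dict("records"),
            "hom_groups": self.stratification.hom_table.to_dict("records"),
        }
        if self.trend:
            out["ab_dp_trend"] = {
                "statistic": self.trend.statistic,
                "p_value": self.trend.p_value,
                "n": self.trend.n,
                "significant": self.trend.significant,
            }
        if self.hom_minor:
            out["hom_minor"] = {
                "fraction_with_minor": self.hom_minor.fraction_with_minor,
                "statistic": self.hom_minor.statistic,
                "p_value": self.hom_minor.p_value,
                "significant": self.hom_minor.significant,
            }
        return out
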