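"""FE/HQFE classification, three-way confirmation, and sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snvconcord.callsets import HET, HOM_ALT, Callset, VariantCall, VariantKey
from snvconcord.concord import (
    PairwiseConcordance,
    QualityCriteria,
    ThreeWayConcordance,
    ThreeWayResults,
    annotate_fe,
    genotype_discordance,
    hqfe_filter,
    median_summary,
    pairwise_compare,
    sensitivity,
    three_way_counts,
)
from snvconcord.regions import GenomicInterval, normalize

from conftest import make_call

REGION = normalize([GenomicInterval("chr1", 0, 10_000)], label="cap")


def callset_from_keys(keys, method="WGS", sample="S01", **call_kw):
    calls = [
        make_call(pos=k.pos, ref=k.ref, alt=k.alt, method=method, sample=sample, **call_kw)
        for k in keys
    ]
    return Callset(method, sample, calls, capture=REGION)


def keys(*positions):
    return [VariantKey("chr1", p, "A", "G") for p in positions]


class TestPairwise:
    def test_shared_and_exclusive_split(self):
        x = callset_from_keys(keys(1, 2, 3), method="WGS")
        y = callset_from_keys(keys(2, 3, 4), method="WES")
        cmp = pairwise_compare(x, y, REGION)
        assert cmp.shared == set(keys(2, 3))
        assert [c.key for c in cmp.fe_x] == keys(1)
        assert [c.key for c in cmp.fe_y] == keys(4)
        # partition identity: shared + FE = total per method
        assert len(cmp.shared) + len(cmp.fe_x) == cmp.n_x
        assert len(cmp.shared) + len(cmp.fe_y) == cmp.n_y

    def test_identical_callsets_have_no_exclusives(self):
        x = callset_from_keys(keys(1, 2, 3), method="WGS")
        y = callset_from_keys(keys(1, 2, 3), method="WES")
        cmp = pairwise_compare(x, y, REGION)
        assert not cmp.fe_x and not cmp.fe_y

    def test_sample_mismatch_rejected(self):
        x = callset_from_keys(keys(1), sample="S01")
        y = callset_from_keys(keys(1), sample="S02", method="WES")
        with pytest.raises(ValueError, match="sample mismatch"):
            pairwise_compare(x, y, REGION)

    def test_genotype_difference_is_still_shared(self):
        x = callset_from_keys(keys(5), method="WGS", genotype=HET)
        y = callset_from_keys(keys(5), method="WES", genotype=HOM_ALT,
                              ref_reads=0, alt_reads=50)
        cmp = pairwise_compare(x, y, REGION)
        assert cmp.shared == set(keys(5)) and not cmp.fe_x


class TestHqfeFilter:
    def test_wgs_het_passes_on_depth_and_balance(self):
        call = make_call(method="WGS", depth=12, ref_reads=7, alt_reads=5)
        assert hqfe_filter([call], QualityCriteria()) == [call]

    def test_wes_fails_below_depth_regardless_of_balance(self):
        call = make_call(method="WES", depth=39, ref_reads=20, alt_reads=19)
        assert hqfe_filter([call], QualityCriteria()) == []

    def test_het_fails_outside_balance_window(self):
        call = make_call(method="HES", depth=200, ref_reads=170, alt_reads=30)
        assert hqfe_filter([call], QualityCriteria()) == []

    def test_hom_alt_passes_on_depth_alone(self):
        call = make_call(method="WGS", genotype=HOM_ALT, depth=30, ref_reads=0, alt_reads=30)
        assert hqfe_filter([call], QualityCriteria()) == [call]

    def test_unknown_quality_fields_fail(self):
        call = VariantCall(VariantKey("chr1", 9, "A", "G"), HET, None, None, None, method="WGS")
        assert hqfe_filter([call], QualityCriteria()) == []

    def test_bounds_are_inclusive(self):
        lo = make_call(method="WGS", depth=10, ref_reads=2, alt_reads=8)  # AB = 0.2
        hi = make_call(method="WGS", depth=10, ref_reads=5, alt_reads=5)  # AB = 0.5
        assert hqfe_filter([lo, hi], QualityCriteria()) == [lo, hi]

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            QualityCriteria(ab_low=0.5, ab_high=0.5)
        with pytest.raises(ValueError):
            QualityCriteria(min_depth={"WGS": 0})


def oracle_counts(presence, methods, hq):
    """Per-key truth-table oracle over the seven non-empty presence patterns."""
    cols = [
        "total_detected", "confirmed_by_all", "fe", "fe_confirmed",
        "fe_not_confirmed", "missed", "hqfe", "hqfe_confirmed",
        "hqfe_not_confirmed", "hqfe_missed",
    ]
    out = {m: dict.fromkeys(cols, 0) for m in methods}
    for key, present in presence.items():
        if len(present) == 3:
            for m in methods:
                out[m]["total_detected"] += 1
                out[m]["confirmed_by_all"] += 1
        elif len(present) == 2:
            (absent,) = set(methods) - set(present)
            for m in present:
                out[m]["total_detected"] += 1
                out[m]["fe"] += 1
                out[m]["fe_confirmed"] += 1
                if hq[(m, key)]:
                    out[m]["hqfe"] += 1
                    out[m]["hqfe_confirmed"] += 1
            out[absent]["missed"] += 1
            if any(hq[(m, key)] for m in present):
                out[absent]["hqfe_missed"] += 1
        else:
            (m,) = present
            out[m]["total_detected"] += 1
            out[m]["fe"] += 1
            out[m]["fe_not_confirmed"] += 1
            if hq[(m, key)]:
                out[m]["hqfe"] += 1
                out[m]["hqfe_not_confirmed"] += 1
    return pd.DataFrame.from_dict(out, orient="index")[cols]


class TestThreeWay:
    def test_all_presence_patterns_match_oracle(self):
        """Random presence/quality over many keys equals the per-key oracle."""
        rng = np.random.default_rng(17)
        methods = ["WGS", "WES", "HES"]
        patterns = [p for r in (1, 2, 3) for p in itertools.combinations(methods, r)]
        for _ in range(10):
            presence, hq, calls = {}, {}, {m: [] for m in methods}
            for i, pos in enumerate(range(1, 41)):
                key = VariantKey("chr1", pos, "A", "G")
                present = patterns[rng.integers(0, len(patterns))]
                presence[key] = present
                for m in present:
                    good = bool(rng.random() < 0.5)
                    hq[(m, key)] = good
                    depth = 100 if good else 5
                    calls[m].append(
                        make_call(pos=pos, method=m, depth=depth,
                                  ref_reads=depth // 2, alt_reads=depth - depth // 2)
                    )
            callsets = {m: Callset(m, "S01", calls[m], capture=REGION) for m in methods}
            got = three_way_counts(callsets, REGION)
            expect = oracle_counts(presence, methods, hq)
            pd.testing.assert_frame_equal(got, expect.loc[got.index], check_names=False)

    def test_count_identities_always_hold(self):
        rng = np.random.default_rng(23)
        methods = ["WGS", "WES", "HES"]
        for _ in range(5):
            callsets = {}
            for m in methods:
                ps = rng.choice(np.arange(1, 60), size=rng.integers(5, 30), replace=False)
                callsets[m] = callset_from_keys(keys(*map(int, ps)), method=m)
            c = three_way_counts(callsets, REGION)
            assert (c["total_detected"] == c["confirmed_by_all"] + c["fe"]).all()
            assert (c["fe"] == c["fe_confirmed"] + c["fe_not_confirmed"]).all()
            assert (c["hqfe"] == c["hqfe_confirmed"] + c["hqfe_not_confirmed"]).all()

    def test_label_permutation_equivariance(self):
        methods = ["WGS", "WES", "HES"]
        base = {
            "WGS": keys(1, 2, 3, 4),
            "WES": keys(2, 3, 5),
            "HES": keys(3, 4, 5, 6),
        }
        callsets = {m: callset_from_keys(base[m], method=m) for m in methods}
        c1 = three_way_counts(callsets, REGION)
        relabel = {"WGS": "HES", "WES": "WGS", "HES": "WES"}
        swapped = {
            relabel[m]: callset_from_keys(base[m], method=relabel[m]) for m in methods
        }
        c2 = three_way_counts(swapped, REGION)
        for m in methods:
            assert c1.loc[m].tolist() == c2.loc[relabel[m]].tolist()

    def test_identical_callsets_are_perfectly_sensitive(self):
        callsets = {m: callset_from_keys(keys(1, 2, 3), method=m) for m in ("WGS", "WES", "HES")}
        res = ThreeWayResults(three_way_counts(callsets, REGION))
        assert (res.counts["fe"] == 0).all() and (res.counts["missed"] == 0).all()
        assert set(res.sensitivities().values()) == {100.0}

    def test_region_outside_capture_rejected(self):
        small = normalize([GenomicInterval("chr1", 0, 10)])
        cs = {m: Callset(m, "S01", [], capture=small) for m in ("WGS", "WES", "HES")}
        with pytest.raises(ValueError, match="not contained"):
            three_way_counts(cs, REGION)

    def test_model_pools_over_samples(self):
        methods = ["WGS", "WES", "HES"]
        callsets = {
            m: [
                callset_from_keys(keys(1, 2), method=m, sample="S01"),
                callset_from_keys(keys(3), method=m, sample="S02"),
            ]
            for m in methods
        }
        res = ThreeWayConcordance(callsets, region=REGION).fit()
        assert (res.counts["confirmed_by_all"] == 3).all()
        assert len(res.per_sample) == 2


class TestSensitivity:
    def test_published_style_counts(self):
        assert sensitivity(2252, 24, 2) == 99.9
        assert sensitivity(2252, 22, 4) == 99.8
        assert sensitivity(2252, 6, 20) == 99.1

    def test_zero_missed_is_perfect(self):
        assert sensitivity(10, 0, 0) == 100.0

    def test_undefined_without_true_positives(self):
        with pytest.raises(ValueError):
            sensitivity(0, 0, 0)

    def test_wilson_interval_brackets_estimate(self):
        counts = {
            m: dict(confirmed_by_all=2252, fe=30, fe_confirmed=20, fe_not_confirmed=10, missed=5)
            for m in ("WGS", "WES", "HES")
        }
        res = ThreeWayResults.from_counts(counts)
        lo, hi = res.conf_int("WGS")
        assert lo < res.sensitivity("WGS") < hi


class TestMedianSummary:
    def test_even_cohort_median_and_percent(self):
        tallies = pd.DataFrame(
            {
                "sample": ["S01", "S02", "S03", "S04"],
                "method": ["WGS"] * 4,
                "snvs": [400, 404, 398, 410],
                "fe": [5, 7, 6, 6],
                "hqfe": [3, 3, 2, 4],
            }
        )
        row = median_summary(tallies).iloc[0]
        assert row["median_snvs"] == 402.0  # mean of central pair
        assert row["median_fe"] == 6.0
        assert row["fe_pct"] == 1.5


class TestDiscordance:
    def test_mixed_genotypes_reported(self):
        cs = {
            "WGS": callset_from_keys(keys(7), method="WGS", genotype=HET),
            "WES": callset_from_keys(keys(7), method="WES", genotype=HET),
            "HES": Callset(
                "HES", "S01",
                [make_call(pos=7, method="HES", genotype=HOM_ALT, ref_reads=0, alt_reads=50)],
                capture=REGION,
            ),
        }
        d = genotype_discordance(cs, REGION)
        assert len(d) == 1
        assert d.iloc[0][["WGS", "WES", "HES"]].tolist() == [HET, HET, HOM_ALT]

    def test_concordant_or_single_caller_not_reported(self):
        cs = {
            "WGS": callset_from_keys(keys(1, 2), method="WGS"),
            "WES": callset_from_keys(keys(1), method="WES"),
            "HES": callset_from_keys(keys(3), method="HES"),
        }
        assert len(genotype_discordance(cs, REGION)) == 0

    def test_random_assignments_match_brute_force(self):
        rng = np.random.default_rng(29)
        methods = ["WGS", "WES", "HES"]
        gts = {}
        calls = {m: [] for m in methods}
        for pos in range(1, 101):
            present = [m for m in methods if rng.random() < 0.7]
            for m in present:
                gt = HET if rng.random() < 0.8 else HOM_ALT
                gts[(m, pos)] = gt
                rr = 25 if gt == HET else 0
                calls[m].append(make_call(pos=pos, method=m, genotype=gt,
                                          ref_reads=rr, alt_reads=50 - rr))
        cs = {m: Callset(m, "S01", calls[m], capture=REGION) for m in methods}
        d = genotype_discordance(cs, REGION)
        expect = set()
        for pos in range(1, 101):
            labels = [gts[(m, pos)] for m in methods if (m, pos) in gts]
            if len(labels) >= 2 and len(set(labels)) > 1:
                expect.add(pos)
        assert set(d["pos"]) == expect


class TestAnnotate:
    def test_repeat_and_gc_tags(self):
        repeats = normalize([GenomicInterval("chr1", 0, 50)])
        gc = normalize([GenomicInterval("chr1", 90, 200)])
        calls = [make_call(pos=10), make_call(pos=100), make_call(pos=60)]
        ann = annotate_fe(calls, repeats=repeats, gc_rich=gc).set_index("pos")
        assert ann.loc[10, "in_repeat"] and not ann.loc[10, "in_gc_rich"]
        assert ann.loc[100, "in_gc_rich"] and not ann.loc[100, "in_repeat"]
        assert not ann.loc[60, "in_repeat"] and not ann.loc[60, "in_gc_rich"]

    def test_missing_annotation_sets_tag_false(self):
        ann = annotate_fe([make_call(pos=5)])
        assert not ann["in_repeat"].any() and not ann["in_gc_rich"].any()

    def test_fractions_equal_direct_counting(self):
        rng = np.random.default_rng(33)
        repeats = normalize([GenomicInterval("chr1", 100, 300)])
        positions = rng.choice(np.arange(1, 500), 60, replace=False)
        calls = [make_call(pos=int(p)) for p in positions]
        ann = annotate_fe(calls, repeats=repeats)
        expect = np.mean([(101 <= p <= 300) for p in positions])
        assert ann["in_repeat"].mean() == pytest.approx(expect)
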