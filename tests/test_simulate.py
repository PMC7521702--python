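"""Generator calibration, determinism, and planted-truth recovery."""

import numpy as np
import pytest

from snvconcord.callsets import HET, HOM_ALT, VariantKey
from snvconcord.concord import ThreeWayConcordance, genotype_discordance
from snvconcord.coverage import gc_content, summarize
from snvconcord.regions import GenomicInterval, intersect, normalize, subtract
from snvconcord.simulate import (
    LognormalDepth,
    NormalDepth,
    PlatformProfile,
    TruthSet,
    default_profiles,
    make_cohort_fixture,
    make_reference,
    noiseless_profiles,
    plant_genotype_flips,
    simulate_depth,
    simulate_platform,
    simulate_truth,
)
from snvconcord._util import substream


def triple_region(reference):
    caps = reference.captures
    return intersect(intersect(caps["WGS"], caps["WES"]), caps["HES"])


class TestReference:
    def test_deterministic_per_seed(self):
        a = make_reference(n_genes=6, seed=5)
        b = make_reference(n_genes=6, seed=5)
        assert a.sequences == b.sequences
        assert a.captures["WES"] == b.captures["WES"]
        assert make_reference(n_genes=6, seed=6).sequences != a.sequences

    def test_capture_containment(self):
        ref = make_reference(n_genes=8, seed=2)
        wgs, wes, hes = (ref.captures[m] for m in ("WGS", "WES", "HES"))
        assert subtract(wes, wgs).total_bases == 0  # WES within WGS
        assert subtract(hes, wgs).total_bases == 0
        tri = triple_region(ref)
        for cap in (wgs, wes, hes):
            assert subtract(tri, cap).total_bases == 0

    def test_high_gc_gene_hits_target(self):
        ref = make_reference(n_genes=8, seed=3)
        for gene in ref.genes[:4]:
            target = ref.gc_targets[gene.symbol]
            exons = normalize(
                [GenomicInterval(iv.chrom, iv.start + ref.flank, iv.end - ref.flank)
                 for iv in gene.intervals]
            )
            assert gc_content(exons, ref) == pytest.approx(target, abs=0.02)

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_reference(n_genes=0)
        with pytest.raises(ValueError):
            make_reference(flank=500, intron_size=100)


class TestTruth:
    def test_locus_count_near_poisson_expectation(self):
        region = normalize([GenomicInterval("chr1", 0, 600_000)])
        truth = simulate_truth(region, n_samples=2, snv_density=1e-3, seed=8)
        assert abs(len(truth.loci) - 600) < 4 * np.sqrt(600)

    def test_het_fraction_one_gives_no_homs(self):
        region = normalize([GenomicInterval("chr1", 0, 50_000)])
        truth = simulate_truth(region, n_samples=3, het_fraction=1.0, seed=9)
        assert all(gt == HET for gt in truth.genotypes.values())

    def test_reproducible_and_loci_on_reference(self):
        ref = make_reference(n_genes=5, seed=4)
        t1 = simulate_truth(ref, n_samples=2, seed=4)
        t2 = simulate_truth(ref, n_samples=2, seed=4)
        assert t1.loci == t2.loci and t1.genotypes == t2.genotypes
        for k in t1.loci:
            assert ref.base_at(k.chrom, k.pos) == k.ref


class TestDepth:
    def test_wgs_depth_moments(self):
        region = normalize([GenomicInterval("chr1", 0, 200_000)])
        track = simulate_depth(default_profiles()["WGS"], region, rng=substream(1, "t"))
        s = summarize(track, 10)
        assert s.mean == pytest.approx(37, abs=0.2)
        assert s.median == 37

    def test_capture_platforms_right_skewed(self):
        region = normalize([GenomicInterval("chr1", 0, 100_000)])
        for name in ("WES", "HES"):
            prof = default_profiles()[name]
            track = simulate_depth(prof, region, rng=substream(2, name))
            s = summarize(track, 40)
            assert s.mean > s.median  # right skew
            assert s.mean == pytest.approx(prof.depth_law.mean, rel=0.05)

    def test_gc_dropout_reduces_depth_in_gc_rich_exons(self):
        ref = make_reference(n_genes=8, seed=6)
        prof = default_profiles()["HES"]
        rng = substream(3, "gc")
        track = simulate_depth(prof, ref.captures["HES"], reference=ref, rng=rng)
        gc_gene = ref.genes[0].intervals  # GC target 0.73
        normal_gene = ref.genes[-1].intervals
        assert track.subset(gc_gene).mean() < 0.8 * track.subset(normal_gene).mean()


class TestPlatform:
    def test_noiseless_limit_reproduces_truth_exactly(self):
        ref = make_reference(n_genes=6, seed=7)
        truth = simulate_truth(ref, n_samples=2, seed=7)
        prof = noiseless_profiles()["WGS"]
        cs, track, rec = simulate_platform(truth, prof, "S01", seed=7)
        expect = {k: truth.genotypes[("S01", k)] for k in truth.sample_keys("S01")}
        assert cs.keys == set(expect)
        assert all(cs[k].genotype == expect[k] for k in expect)
        assert not rec.fn_dropped and not rec.false_positives and not rec.genotype_errors

    def test_fixed_seed_is_bit_identical(self):
        ref = make_reference(n_genes=5, seed=1)
        truth = simulate_truth(ref, n_samples=2, seed=1)
        prof = default_profiles()["HES"]
        a = simulate_platform(truth, prof, "S01", seed=5)
        b = simulate_platform(truth, prof, "S01", seed=5)
        assert a[0].keys == b[0].keys
        assert np.array_equal(a[1].depths, b[1].depths)

    def test_hom_minor_fraction_matches_closed_form(self):
        n = 30_000
        region = normalize([GenomicInterval("chr1", 0, n)])
        loci = [VariantKey("chr1", p + 1, "A", "G") for p in range(n)]
        truth = TruthSet(["S01"], loci, {("S01", k): HOM_ALT for k in loci},
                         captures={"WGS": region})
        prof = default_profiles()["WGS"]
        cs, track, _ = simulate_platform(truth, prof, "S01", seed=2)
        eps = prof.minor_read_rate
        # expectation of 1-(1-eps)^D over the realized depth law
        depths = track.depths[track.depths >= prof.depth_fn_cutoff]
        expect = float(np.mean(1 - (1 - eps) ** depths))
        homs = [c for c in cs if c.genotype == HOM_ALT]
        observed = np.mean([min(c.ref_reads, c.alt_reads) > 0 for c in homs])
        se = np.sqrt(expect * (1 - expect) / len(homs))
        assert abs(observed - expect) < 4 * se

    def test_allele_bias_shifts_het_balance(self):
        n = 5_000
        region = normalize([GenomicInterval("chr1", 0, n)])
        loci = [VariantKey("chr1", p + 1, "A", "G") for p in range(n)]
        truth = TruthSet(["S01"], loci, {("S01", k): HET for k in loci},
                         captures={"X": region})
        prof = PlatformProfile("X", NormalDepth(100, 5), allele_bias=0.5,
                               het_call_cutoff=0.05)
        cs, _, _ = simulate_platform(truth, prof, "S01", seed=3)
        alt_frac = np.mean([c.alt_reads / c.depth for c in cs])
        assert alt_frac == pytest.approx(1 / 3, abs=0.01)

    def test_injected_fn_rate_is_recovered(self):
        n = 20_000
        region = normalize([GenomicInterval("chr1", 0, n)])
        loci = [VariantKey("chr1", p + 1, "A", "G") for p in range(n)]
        truth = TruthSet(["S01"], loci, {("S01", k): HET for k in loci},
                         captures={"X": region})
        q = 0.05
        prof = PlatformProfile("X", NormalDepth(100, 5), fn_base_rate=q)
        cs, _, rec = simulate_platform(truth, prof, "S01", seed=4)
        observed = len(rec.fn_dropped) / n
        assert abs(observed - q) < 3 * np.sqrt(q * (1 - q) / n)


class TestCohort:
    def test_cohort_deterministic(self, small_cohort):
        again = make_cohort_fixture(seed=11, n_samples=4, n_genes=10)
        for m, lst in small_cohort.callsets.items():
            for cs1, cs2 in zip(lst, again.callsets[m]):
                assert cs1.keys == cs2.keys

    def test_noiseless_cohort_end_to_end(self, noiseless_cohort):
        b = noiseless_cohort
        res = ThreeWayConcordance(b.callsets, region=triple_region(b.reference)).fit()
        assert (res.counts["fe"] == 0).all()
        assert (res.counts["missed"] == 0).all()
        assert set(res.sensitivities().values()) == {100.0}
        assert len(b.record_frame()) == 0

    def test_planted_genotype_flips_recovered(self, noiseless_cohort):
        b = noiseless_cohort
        region = triple_region(b.reference)
        trio = {m: b.callsets[m][0] for m in b.callsets}
        keys_in_region = sorted(
            k for k in trio["HES"].keys if region.contains(k.chrom, k.pos)
        )[:5]
        trio["HES"] = plant_genotype_flips(trio["HES"], keys_in_region)
        d = genotype_discordance(trio, region)
        found = {VariantKey(r.chrom, r.pos, r.ref, r.alt) for r in d.itertuples()}
        assert found == set(keys_in_region)
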