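import numpy as np
import pytest

from snvconcord.callsets import HET, HOM_ALT, Callset, VariantCall, VariantKey
from snvconcord.regions import GenomicInterval, RegionSet, normalize
from snvconcord.simulate import make_cohort_fixture


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    genotype=HET,
    depth=50,
    ref_reads=25,
    alt_reads=25,
    method="WGS",
    sample="S01",
):
    return VariantCall(
        VariantKey(chrom, pos, ref, alt), genotype, depth, ref_reads, alt_reads,
        method=method, sample=sample,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy three-platform cohort, deterministic."""
    return make_cohort_fixture(seed=11, n_samples=4, n_genes=10)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return make_cohort_fixture(seed=13, n_samples=3, n_genes=8, noiseless=True)


def random_region_set(rng, max_intervals=8, coord_range=60, label=""):
    n = rng.integers(0, max_intervals + 1)
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, coord_range - 1))
        end = int(rng.integers(start + 1, coord_range + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return normalize(ivs, label=label)


def base_set(r: RegionSet) -> set:
    """Brute-force enumeration of every base in a region set."""
    return set(r.iter_positions())
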