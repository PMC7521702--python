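# Methods

## The comparison model

The package treats multi-platform SNV concordance as a set problem over
variant *keys* `(chrom, pos, ref, alt)`.  Genotype is deliberately excluded
from the key: two platforms calling the same locus with different zygosity
share the locus, and the disagreement is surfaced by the separate
genotype-discordance report.  Folding genotype into presence matching would
misclassify such loci as exclusive calls.

All region logic uses 0-based half-open intervals internally (the BED
convention); VCF positions are converted at the boundary.  Region sets are
canonical — sorted, with overlapping *and abutting* intervals merged — so a
region set is exactly a set of bases and `total_bases` is well defined.
Chromosome names are matched as exact strings; a warning is raised when two
inputs share no chromosome names, which almost always indicates a
`chr1`-versus-`1` naming mismatch rather than genuine disjointness.

### Pairwise tier (FE / HQFE)

For a platform pair, callsets are restricted to the intersection of the two
capture designs.  Keys in both callsets are *shared*; keys in exactly one
are *fully exclusive* (FE) for that platform.  No quality screening is
applied at the FE tier (including no FILTER-column screening on ingest — a
`pass_only` flag exists but is off by default): exclusivity is a statement
about raw caller output.  The *high-quality* tier (HQFE) then applies, per
exclusive call:

* depth ≥ the calling platform's minimum (defaults: 10 for WGS, 40 for
  WES/HES), inclusive;
* for heterozygous calls only, allele balance within [0.2, 0.5], both ends
  inclusive.  Homozygous-alt exclusives pass on depth alone, since the
  balance criterion is defined for heterozygotes; no homozygous analogue is
  imposed.
* calls lacking DP or AD can be FE but never HQFE.

Cohort reporting takes per-sample medians (even cohorts: mean of the central
pair) of SNV/FE/HQFE counts, with FE% and HQFE% computed from those medians
and rounded to one decimal, half away from zero.  All printed percentages in
the package use that rounding rule.

### Three-way tier (confirmation, MV, sensitivity)

Inside the triple-shared region every key falls in one of seven presence
patterns.  The bookkeeping per key is:

| pattern            | effect |
|--------------------|--------|
| all three          | `confirmed_by_all` for every platform |
| exactly two (X, Z) | FE of X and of Z, each *confirmed* by the other; a *missed variant* of the absent platform Y |
| exactly one (X)    | FE of X, *not confirmed* |

Sensitivity per platform is
`100·(confirmed_by_all + fe_confirmed) / (confirmed_by_all + fe_confirmed + missed)`.
The HQFE tier repeats the bookkeeping using quality-filtered exclusives; a
two-caller key counts as an HQFE-tier MV of the absent platform when either
caller's call passes the quality criteria.  Confirmation is presence-based
throughout: a genotype mismatch does not block confirmation.

Counts are pooled over samples for the headline table (each sample×key event
counts once), with the per-sample breakdown retained on the Results object.
`ThreeWayResults` also reports Wilson score intervals for each sensitivity.

One arithmetic corner is worth noting: with HQFE counts of
2252 + 4 confirmed against 19 missed, the formula gives 99.17 → 99.2 at one
decimal.  A published table with those inputs may print 99.1; the package
follows the formula.

## Coverage and GC diagnostics

Depth is consumed pre-tabulated (chrom, 1-based pos, depth TSV); positions
missing from the table inside the region of interest count as depth 0.
"Low-covered" is strict (`depth < cutoff`).  Medians of even-length vectors
are the mean of the central order statistics.  Per-gene reports treat
overlapping genes independently (a base may count toward several genes) and
flag genes above 10% low-covered bases, with a stricter 5% threshold applied
to genes on the bundled ACMG SF v2.0 list (the 20 cardiac study genes).

GC content is (G+C)/(A+C+G+T) with ambiguous bases excluded from the
denominator.  GC-rich regions are fixed-width windows (default 100 bp) whose
GC fraction exceeds a threshold (default 0.60), merged; the trailing short
window of a chromosome participates if it qualifies.

## Allele balance and depth

Heterozygous calls are binned on AB at width 0.1 with the final bin closed
([0, 0.1), …, [0.4, 0.5]); bin assignment bisects the exact edges to avoid
float-division misclassification at 0.3.  "Balanced" means the top bin.
Homozygous-alt calls split on minor-allele presence (any minor read vs
none).

The depth–AB association among heterozygotes is tested with a one-sided
Spearman rank correlation (alternative: depth increases with AB), and the
depth difference between homozygous calls with and without minor reads with
a one-sided Mann–Whitney U test.  The underlying studies do not name their
tests, so nonparametric choices were made to match the quartile-level
presentation; mid-ranks handle ties.  Both tests require n ≥ 10 and are
validated for type-I error ≈ 5% at α = 0.05 under null simulation (1,000
replicates) in the test suite.

## The simulator

The generator emulates platform phenomenology at the level the analysis
consumes (depth tracks and callsets; no reads):

* **Depth laws.**  WGS: normal(μ = 37, σ = 10), matching the symmetric
  mean-=-median-37 profile of PCR-free data; σ = 10 puts the <10× fraction
  near 0.3%.  WES: lognormal(log-median = ln 265, σ = 0.672) so the mean is
  ≈ 332; HES: lognormal(log-median = ln 431, σ = 0.473) so the mean is
  ≈ 482.  The sources report only mean/median, so the σ values are
  moment-matching calibration choices.  Draws are truncated at 0 and
  rounded.
* **GC dropout.**  Windows (100 bp) with GC > 0.60 independently lose depth
  with probability 0.5 (WES) or 0.7 (HES), attenuated to 10% / 8% of the
  drawn value; WGS has no dropout.  These defaults push the capture
  platforms toward low-coverage fractions of a few percent, the regime
  capture assays show on GC-rich genes.
* **Detection noise.**  Baseline false-negative rates 0.001 / 0.002 / 0.009
  (WGS / WES / HES), reflecting the platforms' relative ordering of missed
  variants; a hard depth floor (4 / 8 / 8 reads) below which a true variant
  is never called; Poisson false positives at 9 / 0.5 / 7 per captured
  megabase, multiplied ×2 / ×1 / ×5 inside repeat regions.
* **Allele-level noise.**  At het sites alt reads are Binomial(depth, b/(1+b))
  with allele bias b (1.0 / 0.95 / 0.85) — capture probes and PCR can favour
  one allele.  At hom-alt sites each read is a minor-allele error with rate
  ε, set in closed form from the targeted hom-minor fractions f at the
  platform's mean depth D̄: ε = −ln(1−f)/D̄, giving 7.4×10⁻⁴ (f = 2.7%,
  WGS), 3.3×10⁻⁴ (10.5%, WES), 4.9×10⁻⁴ (21.2%, HES).  The simulated caller
  labels a site het when the minor fraction reaches γ = 0.15, hom-alt when
  alt reads dominate, and makes no call when alt evidence is absent.
* **Truth sets.**  Loci are placed uniformly over the captured union with a
  Poisson count (default density 10⁻³/base ≈ one SNV per kb, the density
  observed in the study regions).  Each sample carries each locus with
  probability 0.8; carried loci are het with probability 0.6.  The carrier
  probability is a realism choice (cohort members share most but not all
  variants) not dictated by any source.
* **Reference.**  Synthetic genes (default 20, 8 exons × 150 bp, 200-bp
  introns, 25-bp capture flank) across two chromosomes; the first four
  genes get exon GC planted at 0.73/0.64/0.69/0.56 — sequences are drawn
  with *exact* GC composition so planted targets are hit by construction.
  Capture designs: HES covers all exons ± flank, WES covers exons only and
  omits 10% of them at random, WGS covers everything; repeats are random
  200-bp blocks (~5% of the genome).
* **Randomness.**  One master seed; every (platform, sample) pair draws
  from its own `SeedSequence` substream, so adding a sample or platform
  never perturbs existing draws, and fixed seeds give bit-identical output.

### What the simulator does and does not show

Passing tests on synthetic cohorts demonstrate that the bookkeeping —
restriction, FE/HQFE classification, confirmation, sensitivity, discordance
— is correct, and that injected parameters (false-negative rates, genotype
flips, GC targets, depth moments, hom-minor fractions) are recovered.  They
do not certify behaviour on real caller output: real pipelines produce
correlated errors near indels and in homopolymers, caller-specific FILTER
semantics and VCF dialects, mapping artefacts in segmental duplications,
and depth autocorrelation along the genome, none of which are modelled.
Indels, MNVs and structural variants are out of scope throughout (dropped
on ingest with a logged count).

## Problem sizes and numerical conventions

The acceptance script measures mean depth on a 10⁶-base track (Monte-Carlo
SE of the mean ≈ 0.01 reads) and the hom-minor percentage on 10⁵ sites
(SE ≈ 0.05 pp); the in-suite recovery test injects a 0.9% false-negative
rate over ≈1.2×10⁴ loci and checks the recovered sensitivity within three
binomial standard errors.  Percentages print to one decimal, half away from
zero; counts are plain integers; all output tables sort deterministically
(method order, then chrom/pos), so re-running a report on identical inputs
is byte-identical.

Degenerate inputs: empty region sets are legal everywhere (an empty
intersection is an answer, not an error); empty depth tracks, genes with
zero bases, malformed intervals (start ≥ end), sample mismatches between
compared callsets, and comparison regions not contained in a capture are
rejected with explicit errors; trend tests refuse n < 10 rather than return
unstable p-values.

## Known limitations

* Confirmation requires only presence, not genotype agreement — a locus
  confirmed by a platform that disagrees on zygosity still counts; the
  discordance report is the place to catch those.
* Sensitivity here is relative to the three-platform consensus, not to an
  external gold standard: a variant missed by all platforms is invisible.
* Per-gene coverage treats gene models as flat interval sets; no
  transcript-aware (GFF/GTF) logic.
* The depth simulator draws bases independently; real coverage is
  autocorrelated, so simulated low-coverage *runs* are shorter than real
  ones.
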