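# Methods

This note documents the models, estimators and numerical conventions behind
`hybridkit`, the defaults and why they were chosen, and what the synthetic
data used in the test suite does and does not establish about real data.

## Genotype representation and site filters

Genotypes are biallelic SNP alt-allele dosages (0/1/2, −1 missing) in a
samples × sites int8 matrix with a pandas site table (scaffold, 1-based
position, ref, alt). Multiallelic records and indels are dropped at
ingestion; caller-level quality filters are assumed already applied
upstream, since this package implements the population-genetic analysis,
not variant calling.

Two cohort-level site filters are provided, both strict inequalities:
summed site depth > `max_total_depth` (default 450; a collapsed-repeat
guard whose right value scales with cohort size and coverage and must be
adjusted per data set — the bundled demo uses 1500 for its 21 samples at
~30×) and missing-genotype fraction > `max_missing_fraction` (default
0.20). Depth uses INFO/DP when present, else summed AD; sites with neither
are not depth-filtered. Filtering is idempotent and order-preserving.

The reference-bias check summarizes, per sample, the distribution of
ref/(ref+alt) read counts at heterozygous genotypes; medians near 0.5 are
the unbiased expectation. Samples with no usable heterozygous genotype are
flagged not-assessable rather than erroring.

## Diagnostic fixed sites and ancestry painting

A site is *fixed* between two parental panels when, among non-missing
genotypes, every panel-0 individual is homozygous for one allele and every
panel-1 individual homozygous for the other. The default demands zero
missingness inside the panels (the strict reading of "all individuals");
`allow_missing_fraction` relaxes this per panel for sparse real data.

The hybrid index counts allele copies, not sites: HI = (copies of the
species-1 allele) / (2 × analyzed sites). The allele-copy definition makes
the pedigree expectations exact (F1 → 0.5, BC1 → 0.75/0.25) and gives the
exact complement identity HI + HI(flipped orientation) = 1. A fixed site is
analyzed for an individual when its own genotype is present and the site is
genotyped in ≥ 80% of the painted cohort (`min_completeness`); the
completeness denominator is all painted samples, parentals included, a
choice that had to be made because either reading is defensible — it is
configurable via `painted_samples`.

Classification applies, in order: an F1 window (|HI − 0.5| ≤ 0.05 and
het ≥ 0.9 — deliberately conservative, since the underlying expectations
are ≈0.5/≈1.0 rather than published thresholds); a parental band
(HI ≤ 0.02 or ≥ 0.98 with het ≤ 0.02) so nonadmixed controls get a label;
inclusive backcross bounds HI ≤ 0.25 / ≥ 0.75; the strict later-generation
rule 0.25 < HI < 0.75 with het < 0.5; else *unclear* (intermediate HI with
high heterozygosity, e.g. an individual one parent of which was itself a
recent hybrid). Boundary semantics (≤/≥ for backcross, strict < for
later-generation) follow the published inequalities exactly; the 14
reference (HI, het) → interpretation pairs are reproduced verbatim by the
test suite. Note that a true BC1 sits *on* the 0.25/0.75 boundary, so with
finite sites roughly half of real BC1s land just inside the unclear/later
region — a property of the rule, not a bug.

Profiles from fewer than `min_sites` (100) analyzed sites are flagged
unreliable and left unclassified instead of raising.

## Window statistics

Estimators use per-site sample-frequency terms (n = non-missing allele
copies in the panel at the site; a site is skipped for a statistic when a
participating panel has fewer than 2 copies):

- π site term: 2·p̂(1−p̂)·n/(n−1) — the unbiased mean pairwise difference.
- d_xy site term: p̂_A(1−p̂_B) + p̂_B(1−p̂_A).
- F_ST: Hudson/Bhatia *ratio of averages* — the window's summed numerator
  (p̂_A−p̂_B)² − p̂_A(1−p̂_A)/(n_A−1) − p̂_B(1−p̂_B)/(n_B−1) over its summed
  d_xy terms. Ratio-of-averages is stable under window aggregation where
  average-of-ratios is not; the estimator name is recorded in output
  headers. Negative window values are retained so genome-wide means stay
  unbiased.

π and d_xy are rates per genotyped site, so the denominator must count
variant *and* invariant genotyped positions: callability comes from an
all-sites VCF, a per-scaffold position mask, or precomputed per-window
counts. With `callability=None` every window position is assumed genotyped,
which is only appropriate for fully called simulations. Windows slide from
position 1 per scaffold (defaults 100 kb / 10 kb step); trailing short
windows are emitted but flagged `truncated`; windows under
`min_genotyped` (default 20,000) are marked invalid and excluded from
outlier calling.

Outliers are windows with F_ST at or above the empirical 95th percentile of
valid windows (ties can push the fraction above 5%). Overlap between
outlier sets is tested by drawing the observed set sizes without
replacement from the universe of windows (or genes) 1,000 times; the
summary reports the permutation mean, min/max, the ≥-observed tail
fraction, and the hypergeometric closed form n₁·n₂/N. Three-way
intersections use joint draws; pairwise comparisons of the three pairs are
also emitted. The permutation mean and the closed form agree to within
Monte-Carlo error by construction — any published expectation that
disagrees with n₁·n₂/N for the stated sizes implies a differently filtered
universe rather than a different null.

## f3 with block jackknife

Per analyzed site, t = (ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_C−1); f3 is the mean of t.
The correction is applied to the target C only: ĉ appears in both factors,
so Var(ĉ) biases the product upward, while â and b̂ each appear once and
their noise cancels in expectation. The normalized f3* variant is not
implemented. Sites are dropped when any panel is entirely missing;
sites monomorphic for the same allele in all three panels are excluded by
default (they carry no signal); no frequency filter is applied otherwise.

Standard errors use the weighted delete-one block jackknife (Busing
pseudovalues, blocks weighted by site counts), Z = f3/SE, and the verdict
is *admixed* iff Z < −3 (strict). The default block scheme is one block per
scaffold when ≥ 20 scaffolds are present, else contiguous 500-SNP chunks;
`n_blocks` forces a fixed count. Degenerate zero-variance input reports
SE = 0 with a signed-infinite Z and a warning instead of dividing by zero.

## Ancestry tracts

A tract is a maximal run of identical non-missing ancestry state within one
scaffold; runs end at a state switch or a scaffold end. Missing sites
bridge runs by default (the tract rule mentions only switches and scaffold
ends); `bridge_missing=False` makes them break runs. Tract length is
reported both in SNPs and in bp (last − first position + 1, so a
single-SNP tract is 1 bp); bp lengths feed the histograms. Transitions per
individual are tracts minus scaffolds-with-data, i.e. only within-scaffold
switches count. Unphased (diploid, 3-state) and phased (haplotype, 2-state)
sequences are kept in separate containers and never mixed; transition
counts on unphased data are over the 3-state sequence and labelled as such.

## Simulator

The divergence model is Balding–Nichols: per species, each site's frequency
is Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p drawn
uniform on [0.05, 0.95], giving Var = F·p(1−p) so F is directly the
expected FST scale. Diagnostic sites are frequency-(0,1) between the focal
pair with random orientation, making F1 expectations exact. Parental
genotypes are Binomial(2, p); hybrid genotypes are drawn haplotype-wise
from the frequency of each segment's ancestry species.

Recombination is a Poisson crossover process (count ~ length × Morgans/bp,
positions uniform, no interference — nothing in the analyses is sensitive
to interference). Pedigrees: F1 = one pure haplotype per species; BCn =
n successive backcrosses of the running hybrid to a pure recurrent parent;
later-generation(g) = a closed swarm of four F1s mated randomly for g−1
further generations, so g counts sexual generations since the parental
cross and every mating involves admixed parents. Truth records carry the
exact bp ancestry proportion and within-haplotype breakpoint counts.

Defaults: 10 scaffolds × 1 Mb and 1 cM/Mb (a typical metazoan density).
Because the simulated genome is a ~10-Mb miniature, test and demo
configurations scale the crossover density up (1–2 × 10⁻⁶ M/bp, about one
crossover per scaffold per meiosis) so that tract-length contrasts between
pedigree depths are visible at this genome size; the genome-wide
recombination rate of any real study system is a free parameter, not a
claim. Read depths are Poisson(30) totals with Binomial(depth, 0.5)
reference reads at heterozygotes.

Simulated data reproduce the *structural* expectations (pedigree means,
estimator identities, null distributions) but are idealized: sites are
independent given the frequencies (no coalescent linkage within panels),
there is no sequencing error, no allele-specific mapping bias, no selection
and no gene flow after the configured pedigree. Passing tests therefore
validate the estimators and decision rules, not the adequacy of any
particular threshold for a given real cohort.

## Reproducibility and problem sizes

All randomness flows from numpy `Generator` objects; every public function
takes a seed or generator, the pipeline fans one global seed out to
per-stage children, and equal config + seed gives byte-identical output
bundles (TSVs carry version/seed/estimator headers). The benchmark script
spawns independent child seeds per quantity via `SeedSequence`. Problem
sizes were chosen as the smallest at which each check is statistically
decisive: 1,000–1,500 diagnostic sites and 100 pedigree replicates for
painting recovery; 10 × 10,000 genotypes for allele balance; 50,000 SNPs,
20 diploids per panel and 100 jackknife blocks for f3; ≤ 500-site instances
for brute-force oracle comparisons.
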