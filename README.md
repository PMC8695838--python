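# hybridkit

Hybridization and introgression analysis for panels of diverged, closely
related species — the situation found in species complexes such as the
*Daphnia longispina* group, where parental species, F1s, backcrosses and
later-generation hybrids co-occur in the same lakes and even in the same
sediment egg banks. Given a multi-sample SNP VCF and a sample→species
assignment, `hybridkit` answers: *which individuals are hybrids, of what
kind, between which species, and how old is the admixture?*

## What it computes

**Ancestry painting.** Diagnostic *fixed sites* are sites where one allele is
fixed in every individual of parental species 0 and a different allele fixed
in species 1. Over those sites each individual gets a **hybrid index**
(fraction of allele copies from the species mapped to scale value 1) and a
**fixed-site heterozygosity**. Expectations: F1 → (0.5, ≈1.0); first
backcross → hybrid index ≈0.25 or ≈0.75 with heterozygosity ≈0.5;
later-generation hybrids → intermediate hybrid index with reduced
heterozygosity. The classifier applies the inclusive backcross bounds
(HI ≤ 0.25 / ≥ 0.75) and the strict later-generation rule
(0.25 < HI < 0.75 and het < 0.5), with a conservative F1 window and a
parental band for nonadmixed controls.

**Window statistics.** Per-population nucleotide diversity π, pairwise
divergence d_xy and Hudson/Bhatia ratio-of-averages F_ST in sliding windows
(default 100 kb, 10-kb step, ≥20 kb genotyped sites), with per-site unbiased
frequency terms:

    pi   site term:  2·p̂(1−p̂)·n/(n−1)
    dxy  site term:  p̂_A(1−p̂_B) + p̂_B(1−p̂_A)
    FST  window:     Σ[(p̂_A−p̂_B)² − p̂_A(1−p̂_A)/(n_A−1) − p̂_B(1−p̂_B)/(n_B−1)] / Σ dxy terms

π and d_xy are normalized by the genotyped (variant + invariant) site count,
so an all-sites callability source is required for absolute rates. Outlier
windows (F_ST ≥ 95th percentile) are intersected across species pairs and
compared against a without-replacement permutation null (with the
hypergeometric closed form n₁·n₂/N reported alongside).

**f3 admixture tests.** f3(C; A, B) = mean over sites of
(ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_C−1), with a weighted delete-one block jackknife
for the standard error; Z < −3 declares target C admixed between relatives
of A and B.

**Ancestry tracts.** Per-SNP ancestry states — from the diagnostic painting,
from the bundled simulator's truth, or from an external local-ancestry
tool's phased matrix — are cut into maximal constant-ancestry runs that end
at a state switch or a scaffold end, then summarized as ancestry proportion,
ancestry heterozygosity, transition counts and tract-length distributions
(shorter tracts ⇒ more generations of recombination since admixture).

**Simulator.** All of the above is testable without any external data: a
Balding–Nichols divergence model (per-species Beta frequencies around a
shared ancestral frequency, divergence parameter F) plus an explicit
hybrid-pedigree engine (Poisson crossovers, F1/BCn/later-generation
pedigrees) generates VCFs with per-individual ancestry truth.

## Worked example

`examples/02_ancestry_painting.py` simulates 5+5 parental diploids of two
species (F = 0.3, half the 3,000 sites diagnostic) plus three hybrids of
known pedigree, then discovers fixed sites and paints everyone:

```
fixed diagnostic sites between the panels: 1507
   sample  hybrid_index  heterozygosity  n_sites  interpretation
   ...
   hyb_F1      0.500000        1.000000     1507         F1_like
hyb_BC1_B      0.802588        0.394824     1507     backcross_1
  hyb_LG5      0.490046        0.197080     1507  later_generation
```

The F1 sits exactly at hybrid index 0.5 with every fixed site heterozygous;
the backcross toward species B lands near 0.75 on the B side of the scale;
the fifth-generation hybrid keeps an intermediate hybrid index but has lost
half its ancestry heterozygosity to recombination and is classified
later-generation. `examples/04_f3_admixture_test.py` prints the
corresponding admixture signal:

```
f3(C; A, B) = -0.01774  SE=0.00014  Z=-124.3  sites=48585  -> admixed
f3(D; A, B) = +0.00294  SE=0.00013  Z=+22.0   sites=48508  -> not_supported
```

The other examples cover simulation output, window scans with outlier
permutation, ancestry tracts, and the one-call pipeline demo
(`hybridkit demo --seed 0` on the shell does the same).

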