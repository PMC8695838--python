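"""Diagnostic fixed sites, hybrid index/heterozygosity, hybrid classification.

Builds a small two-species cohort, discovers sites fixed for different
alleles between the parental panels, and paints each individual.
"""

import numpy as np

from hybridkit import sim
from hybridkit.painting import (
    ClassifierThresholds, find_fixed_sites, hybrid_profile, profile_table)
from hybridkit.vcfio import GenotypeMatrix

layout = sim.default_layout(n_scaffolds=10, scaffold_bp=500_000)
freqs = sim.build_species_frequencies(layout, 3_000, fst=0.3,
                                      prop_diagnostic=0.5, seed=3)
pedigrees = [
    ("hyb_F1", sim.PedigreeSpec(kind="F1")),
    ("hyb_BC1_B", sim.PedigreeSpec(kind="BC1", backcross_to="B")),
    ("hyb_LG5", sim.PedigreeSpec(kind="later_generation", g=5)),
]
ds = sim.simulate_dataset(layout, freqs, {"A": 5, "B": 5}, pedigrees, seed=3)
gm = GenotypeMatrix(samples=ds.samples, sites=freqs.sites.assign(ref="A", alt="T"),
                    dosage=ds.dosage)

fixed = find_fixed_sites(gm, ds.panels["A"], ds.panels["B"],
                         species0="A", species1="B")
print(f"fixed diagnostic sites between the panels: {len(fixed)}")

thresholds = ClassifierThresholds()  # backcross bound 0.25, later-gen het < 0.5
profiles = [hybrid_profile(gm, fixed, s, thresholds) for s in ds.samples]
print(profile_table(profiles, fixed).to_string(index=False))
# hybrid_index is the fraction of allele copies from species B (scale 0=A,
# 1=B): an F1 sits at 0.5 with heterozygosity ~1.0; the backcross toward B
# near 0.75; the later-generation hybrid is intermediate with reduced
# heterozygosity, which is what separates it from an F1.
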