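"""Ancestry tracts: recombination chops ancestry into shorter blocks each
generation, so tract length dates the hybridization depth.

Compares a BC1 against later-generation hybrids (g = 4 and g = 8).
"""

import numpy as np

from hybridkit import sim
from hybridkit.tracts import extract_tracts, states_from_truth, summarize_ancestry

layout = sim.default_layout(n_scaffolds=10, scaffold_bp=500_000, morgans_per_bp=2e-6)
freqs = sim.build_species_frequencies(layout, 5_000, fst=0.3,
                                      prop_diagnostic=1.0, seed=5)
pedigrees = [
    ("BC1", sim.PedigreeSpec(kind="BC1", backcross_to="A")),
    ("LG4", sim.PedigreeSpec(kind="later_generation", g=4)),
    ("LG8", sim.PedigreeSpec(kind="later_generation", g=8)),
]
ds = sim.simulate_dataset(layout, freqs, {}, pedigrees, seed=5)

states = states_from_truth(ds)          # phased per-haplotype ancestry
tracts = extract_tracts(states)         # runs end at switches or scaffold ends
summary = summarize_ancestry(tracts, states)
cols = ["id", "prop_A", "n_transitions", "n_tracts", "mean_tract_bp", "max_tract_bp"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# prop_A is the per-haplotype fraction of SNPs with species-A ancestry;
# n_transitions counts within-scaffold ancestry switches. More sexual
# generations -> more switches and shorter mean tracts, which is the signal
# used to argue that short-tract hybrids descend from older admixture.
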