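"""Simulate a hybrid cohort with known pedigree truth and write it to disk.

Two diverged species (Balding-Nichols F = 0.25, 10% diagnostic sites) with
parental panels plus an F1, a backcross and a later-generation hybrid.
"""

from hybridkit import sim

layout = sim.default_layout(n_scaffolds=10, scaffold_bp=500_000, morgans_per_bp=2e-6)
freqs = sim.build_species_frequencies(layout, n_sites=5_000, fst=0.25,
                                      prop_diagnostic=0.10, seed=1)
pedigrees = [
    ("hyb_F1", sim.PedigreeSpec(kind="F1")),
    ("hyb_BC1", sim.PedigreeSpec(kind="BC1", backcross_to="B")),
    ("hyb_LG5", sim.PedigreeSpec(kind="later_generation", g=5)),
]
ds = sim.simulate_dataset(layout, freqs, {"A": 5, "B": 5}, pedigrees,
                          seed=1, missing_rate=0.02, with_depth=True)
paths = sim.emit_dataset(ds, "scratch_example_cohort", seed=1)

print(f"samples: {ds.samples}")
for t in ds.truth:
    print(f"{t.sample:10s} {t.pedigree:17s} true A-ancestry={t.prop_a:.3f} "
          f"haplotype breakpoints={t.breakpoints}")
print(f"files written: {sorted(paths.values())}")
# true A-ancestry is the bp fraction of the genome inherited from species A:
# exactly 0.5 for an F1, around 0.25 for a backcross toward B; breakpoints
# count within-haplotype ancestry switches created by recombination.
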