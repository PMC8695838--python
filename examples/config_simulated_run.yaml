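# Full pipeline run on a simulated three-species cohort.
# Usage: hybridkit run examples/config_simulated_run.yaml
outdir: scratch_config_run
seed: 7
stages: [paint, windows, f3, tracts]
max_depth: 1500        # summed-depth cap; scale to cohort size x coverage
max_missing: 0.20
percentile: 95
permutation_reps: 1000
z_threshold: -3.0
painting_pair: [A, B]
f3_targets: [admixed, C]
window:
  window_bp: 100000
  step_bp: 10000
  min_genotyped: 50    # simulated SNP-only callability; see docs/methods.md
simulate:
  n_scaffolds: 20
  scaffold_bp: 500000
  morgans_per_bp: 2.0e-6
  n_sites: 20000
  fst: 0.25
  prop_diagnostic: 0.10
  species: [A, B, C]
  focal_pair: [A, B]
  panel_sizes: {A: 6, B: 6, C: 4}
  missing_rate: 0.02
  with_depth: true
  pedigrees:
    - {sample: hyb_F1, kind: F1}
    - {sample: hyb_BC1_A, kind: BC1, backcross_to: A}
    - {sample: hyb_BC1_B, kind: BC1, backcross_to: B}
    - {sample: hyb_LG4, kind: later_generation, g: 4}
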