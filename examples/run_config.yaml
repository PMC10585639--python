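# Annotated pipeline configuration for `octnorms run --config run_config.yaml`.
# Any field omitted falls back to the library default.

outdir: octnorms-run        # all stage outputs and manifest.json land here
seed: 1                     # global seed; per-stage seeds derive from it

# Stages run in this order; later stages may depend on earlier ones
# ('sensitivity' and 'power' need 'fit'; 'fit' needs 'simulate' or a
# cohort_path pointing at an existing per-eye CSV).
stages: [simulate, fit, sensitivity, meta, power]
# cohort_path: my_cohort.csv   # analyse real data instead of simulating

# Measurement-error Monte Carlo (applied to each response below).
sensitivity:
  n_sims_per_level: 200     # simulations per error magnitude
  alpha: 0.05               # significance level for P_sim
  target_group: Ghanaian    # Ghanaian | European | all
  error_law: uniform        # uniform | normal | one_sided
sensitivity_responses: [c0, choroid]

# Parametric-bootstrap post-hoc power for the ethnicity coefficient.
posthoc_responses: [c0, choroid]
posthoc_n_sims: 200
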