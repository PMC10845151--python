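# Default study configuration for `deltabh run --config examples/config.yaml`.
# Every threshold the pipeline uses is explicit here; nothing is hidden.

n_reactions: 500          # synthetic reactions to generate
seed: 0                   # one seed fixes data, splits and tree/GP metrics
noise_sd: 2.0             # kcal/mol irreducible noise in the true correction

# fraction of records planted with each curation failure (sum <= 1)
failure_fractions:
  ts_opt_failed: 0.10
  connectivity_mismatch: 0.15
  conformation_mismatch: 0.05

model_kinds: [xgb, gp]    # any of xgb, gp, multitask_nn
correlation_threshold: 0.9    # |Pearson r| above which a column is pruned
split_fractions: [0.85, 0.05, 0.10]   # train / validation / test
reduced_set_size: 49      # size of the importance-ranked reduced feature set
hpo_budget: 6             # sampled configurations in the seeded random search
gp_max_train: 1000        # GP training subsample cap (cubic cost in n)

temperatures: [300.0, 500.0, 1000.0]  # K, for activation Gibbs energies
freq_scale_low: 1.0       # harmonic frequency scaling, low level
freq_scale_ref: 0.9914    # harmonic frequency scaling, reference level

out_dir: runs
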